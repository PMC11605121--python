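"""Stick-diagram rendering of walker trajectories.

A stick diagram draws the segment line-work of the walker at regular
time intervals along the distance axis — the standard way of showing
how a simulated gait unfolds, including slips (poses bunch up and slide)
and trips (poses pitch forward).  Only trajectories that carry the full
segment-state block (simulator output) can be rendered.
"""

from __future__ import annotations

import numpy as np

from .anthropometry import AnthropometricSet, build_anthropometry
from .dynamics import joint_attachments, contact_attachments
from .trajectory import Trajectory

__all__ = ["render_stick_diagram", "pose_segments"]


def _rot(c, s, r):
    return np.array([c * r[0] - s * r[1], s * r[0] + c * r[1]])


def pose_segments(traj: Trajectory, idx: int,
                  anthro: AnthropometricSet | None = None):
    """Line segments [(x0,y0),(x1,y1)] of the walker at sample ``idx``."""
    anthro = anthro or build_anthropometry()
    if "q0" not in traj.data.columns:
        raise ValueError("trajectory has no segment-state block (q columns)")
    q = np.array([traj.col(f"q{k}")[idx] for k in range(24)])
    x, y, th = q[:8], q[8:16], q[16:24]
    c, s = np.cos(th), np.sin(th)
    jt = joint_attachments(anthro)
    pts = {}
    for j, (p, d, rp, rd) in enumerate(jt):
        pos = np.array([x[p], y[p]]) + _rot(c[p], s[p], rp)
        pts[j] = pos
    # head top: HAT CoM + remaining length along the HAT axis
    head = np.array([x[0], y[0]]) + _rot(c[0], s[0],
                                         (0.0, anthro.length[0] - anthro.com_offset[0]))
    ca = contact_attachments(anthro)
    heel_r = np.array([x[6], y[6]]) + _rot(c[6], s[6], ca[0][1])
    toe_r = np.array([x[6], y[6]]) + _rot(c[6], s[6], ca[1][1])
    heel_l = np.array([x[7], y[7]]) + _rot(c[7], s[7], ca[2][1])
    toe_l = np.array([x[7], y[7]]) + _rot(c[7], s[7], ca[3][1])
    trunk_j, hip_r, hip_l, knee_r, knee_l, ankle_r, ankle_l = (pts[i] for i in range(7))
    return [
        (trunk_j, head),
        (hip_r, trunk_j),
        (hip_r, knee_r), (knee_r, ankle_r), (heel_r, toe_r), (ankle_r, heel_r),
        (hip_l, knee_l), (knee_l, ankle_l), (heel_l, toe_l), (ankle_l, heel_l),
    ]


def render_stick_diagram(traj: Trajectory, interval: float = 0.5,
                         path=None, ax=None,
                         anthro: AnthropometricSet | None = None):
    """Draw walker poses every ``interval`` seconds over the distance axis.

    The number of rendered poses is ``floor(duration / interval) + 1``;
    a trial that ends in a fall is rendered through its final frame.
    Returns the matplotlib Axes.
    """
    import matplotlib
    if path is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if interval <= 0:
        raise ValueError("interval must be positive")
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    t = traj.t
    n_pose = int(np.floor((t[-1] - t[0]) / interval)) + 1
    if ax is None:
        _, ax = plt.subplots(figsize=(12, 3))
    for k in range(n_pose):
        idx = int(np.searchsorted(t, t[0] + k * interval))
        idx = min(idx, len(t) - 1)
        for (p0, p1) in pose_segments(traj, idx, anthro):
            ax.plot([p0[0], p1[0]], [p0[1], p1[1]], color="k", lw=1.0)
    ax.axhline(0.0, color="0.6", lw=0.8)
    ax.set_xlabel("x (m)")
    ax.set_ylabel("y (m)")
    ax.set_aspect("equal")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
    return ax
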