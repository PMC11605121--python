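"""Planar constrained rigid-body dynamics of the 8-segment walker.

Each segment carries three redundant coordinates (CoM position x, y and
inertial angle theta, counterclockwise from the standing pose), giving a
24-dimensional configuration.  The seven pin joints contribute 14
holonomic constraints ``C(q) = 0`` (coincidence of the two segments'
attachment points).  Accelerations and joint constraint forces are
obtained together from the saddle-point (KKT) system

    [ M   -J^T ] [qdd]   [ Q ]
    [ J    0   ] [lam] = [ rhs ]

where ``M`` is the diagonal mass/inertia matrix, ``J = dC/dq`` and ``Q``
collects gravity, joint torques and ground reaction forces.  Baumgarte
stabilization (``Cdd + 2a Cd + a^2 C = 0``, critically damped) keeps the
joint-coincidence drift bounded over long runs.  ``lam`` is the joint
force applied to the proximal segment; the distal segment receives the
opposite force by construction.

Sign conventions: x forward along travel, y up, angles counterclockwise;
for segments hanging downward (thighs, shanks) a positive angle tilts the
distal end forward.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .anthropometry import AnthropometricSet, SEGMENT_NAMES, JOINT_NAMES
from .cpg import JOINT_SEGMENTS

__all__ = [
    "BodyState",
    "ConstraintSolution",
    "NumericalError",
    "compute_accelerations",
    "whole_body_com",
    "assemble_state",
    "joint_attachments",
    "contact_attachments",
    "joint_residuals",
    "BAUMGARTE_ALPHA",
]

G = 9.81
N_SEG = 8
N_JOINT = 7
BAUMGARTE_ALPHA = 400.0  # 1/s; critically damped constraint stabilization


class NumericalError(RuntimeError):
    """Raised when the constraint system is singular or the state diverges."""

    def __init__(self, msg: str, cond: float | None = None, time: float | None = None):
        super().__init__(msg)
        self.cond = cond
        self.time = time


@dataclass
class BodyState:
    """Redundant-coordinate mechanical state of the walker."""

    time: float
    x: np.ndarray
    y: np.ndarray
    theta: np.ndarray
    xd: np.ndarray
    yd: np.ndarray
    thetad: np.ndarray

    def copy(self) -> "BodyState":
        return BodyState(self.time, self.x.copy(), self.y.copy(), self.theta.copy(),
                         self.xd.copy(), self.yd.copy(), self.thetad.copy())

    @property
    def q(self) -> np.ndarray:
        return np.concatenate([self.x, self.y, self.theta])

    @property
    def qd(self) -> np.ndarray:
        return np.concatenate([self.xd, self.yd, self.thetad])

    @classmethod
    def from_q(cls, time: float, q: np.ndarray, qd: np.ndarray) -> "BodyState":
        return cls(time, q[:8].copy(), q[8:16].copy(), q[16:24].copy(),
                   qd[:8].copy(), qd[8:16].copy(), qd[16:24].copy())

    def is_finite(self) -> bool:
        return bool(np.isfinite(self.q).all() and np.isfinite(self.qd).all())


@dataclass
class ConstraintSolution:
    """Accelerations plus joint constraint forces from one KKT solve."""

    xdd: np.ndarray      # (8,)
    ydd: np.ndarray      # (8,)
    thetadd: np.ndarray  # (8,)
    fx: np.ndarray       # (7,) horizontal joint force on the proximal segment
    fy: np.ndarray       # (7,) vertical joint force on the proximal segment


def _rot(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


def joint_attachments(anthro: AnthropometricSet):
    """Per-joint (prox segment, dist segment, r_prox, r_dist).

    ``r`` vectors are attachment-point offsets from the segment CoM in
    the body frame (standing pose).
    """
    L = anthro.length
    c = anthro.com_offset
    lf, h = anthro.foot_length, anthro.ankle_height
    # foot CoM sits midway between heel and toe horizontally, half the
    # ankle height below the ankle joint
    ankle_from_com = np.array([-0.25 * lf, 0.5 * h])
    table = []
    r_by_joint = {
        "trunk": ((0.0, L[1] - c[1]), (0.0, -c[0])),
        "hip_r": ((0.0, -c[1]), (0.0, c[2])),
        "hip_l": ((0.0, -c[1]), (0.0, c[3])),
        "knee_r": ((0.0, -(L[2] - c[2])), (0.0, c[4])),
        "knee_l": ((0.0, -(L[3] - c[3])), (0.0, c[5])),
        "ankle_r": ((0.0, -(L[4] - c[4])), tuple(ankle_from_com)),
        "ankle_l": ((0.0, -(L[5] - c[5])), tuple(ankle_from_com)),
    }
    for j, name in enumerate(JOINT_NAMES):
        p, d = JOINT_SEGMENTS[j]
        rp, rd = r_by_joint[name]
        table.append((p, d, np.array(rp), np.array(rd)))
    return table


def contact_attachments(anthro: AnthropometricSet):
    """(segment, offset-from-CoM) for the 4 contact points
    (heel_r, toe_r, heel_l, toe_l)."""
    lf, h = anthro.foot_length, anthro.ankle_height
    heel = np.array([-0.5 * lf, -0.5 * h])
    toe = np.array([0.5 * lf, -0.5 * h])
    return [(6, heel), (6, toe), (7, heel), (7, toe)]


def _attachment_world(state: BodyState, seg: int, r: np.ndarray):
    """World position and velocity of a body-fixed point."""
    R = _rot(state.theta[seg])
    d = R @ r
    pos = np.array([state.x[seg], state.y[seg]]) + d
    # velocity: v_com + thetad * perp(d)
    w = state.thetad[seg]
    vel = np.array([state.xd[seg] - w * d[1], state.yd[seg] + w * d[0]])
    return pos, vel, d


def contact_point_states(state: BodyState, anthro: AnthropometricSet):
    """Positions (4,2) and velocities (4,2) of the contact points."""
    pos = np.empty((4, 2))
    vel = np.empty((4, 2))
    for n, (seg, r) in enumerate(contact_attachments(anthro)):
        p, v, _ = _attachment_world(state, seg, r)
        pos[n] = p
        vel[n] = v
    return pos, vel


def joint_residuals(state: BodyState, anthro: AnthropometricSet) -> np.ndarray:
    """Distance between the two segments' attachment points at each joint."""
    res = np.empty(N_JOINT)
    for j, (p, d, rp, rd) in enumerate(joint_attachments(anthro)):
        pp, _, _ = _attachment_world(state, p, rp)
        pd, _, _ = _attachment_world(state, d, rd)
        res[j] = np.hypot(*(pp - pd))
    return res


def compute_accelerations(
    state: BodyState,
    active_torque: np.ndarray,
    passive_torque: np.ndarray,
    ground_forces: np.ndarray,
    anthro: AnthropometricSet,
    baumgarte_alpha: float = BAUMGARTE_ALPHA,
) -> ConstraintSolution:
    """Solve the constrained equations of motion at one instant.

    ``active_torque`` and ``passive_torque`` are (7,) joint torques
    (positive counterclockwise on the distal segment), ``ground_forces``
    is (4, 2) — one (Fx, Fy) row per contact point in the order right
    heel, right toe, left heel, left toe.

    Raises :class:`NumericalError` if the KKT system is singular or
    ill-conditioned.
    """
    m = anthro.mass
    inertia = anthro.inertia
    M = np.concatenate([m, m, inertia])

    # applied generalized forces
    Q = np.zeros(24)
    Q[8:16] = -m * G
    torque = active_torque + passive_torque
    for j, (p, d, _, _) in enumerate(joint_attachments(anthro)):
        Q[16 + d] += torque[j]
        Q[16 + p] -= torque[j]
    for n, (seg, r) in enumerate(contact_attachments(anthro)):
        fxn, fyn = ground_forces[n]
        dvec = _rot(state.theta[seg]) @ r
        Q[seg] += fxn
        Q[8 + seg] += fyn
        Q[16 + seg] += dvec[0] * fyn - dvec[1] * fxn

    # constraint Jacobian, violation, and velocity terms
    J = np.zeros((2 * N_JOINT, 24))
    C = np.zeros(2 * N_JOINT)
    Cd = np.zeros(2 * N_JOINT)
    gamma = np.zeros(2 * N_JOINT)
    for j, (p, d, rp, rd) in enumerate(joint_attachments(anthro)):
        pp, vp, dp = _attachment_world(state, p, rp)
        pd_, vd, dd = _attachment_world(state, d, rd)
        row = 2 * j
        C[row:row + 2] = pp - pd_
        Cd[row:row + 2] = vp - vd
        J[row, p] = 1.0
        J[row, d] = -1.0
        J[row + 1, 8 + p] = 1.0
        J[row + 1, 8 + d] = -1.0
        # d/dtheta of R(theta) r = perp(R r)
        J[row, 16 + p] = -dp[1]
        J[row + 1, 16 + p] = dp[0]
        J[row, 16 + d] = dd[1]
        J[row + 1, 16 + d] = -dd[0]
        # Jdot qd = -R thp^2 rp + R thd^2 rd (second derivative of the rotations)
        wp, wd = state.thetad[p], state.thetad[d]
        gamma[row:row + 2] = -dp * wp ** 2 + dd * wd ** 2

    a = baumgarte_alpha
    rhs_c = -gamma - 2.0 * a * Cd - a * a * C

    K = np.zeros((24 + 2 * N_JOINT, 24 + 2 * N_JOINT))
    K[:24, :24] = np.diag(M)
    K[:24, 24:] = -J.T
    K[24:, :24] = J
    b = np.concatenate([Q, rhs_c])
    try:
        sol = np.linalg.solve(K, b)
    except np.linalg.LinAlgError as exc:
        raise NumericalError("singular constraint system", time=state.time) from exc
    if not np.isfinite(sol).all():
        raise NumericalError("non-finite KKT solution", time=state.time)
    resid = K @ sol - b
    if np.linalg.norm(resid) > 1e-6 * max(1.0, np.linalg.norm(b)):
        cond = float(np.linalg.cond(K))
        raise NumericalError(
            f"ill-conditioned constraint system (cond={cond:.3e})",
            cond=cond, time=state.time,
        )
    qdd = sol[:24]
    lam = sol[24:]
    return ConstraintSolution(
        xdd=qdd[:8], ydd=qdd[8:16], thetadd=qdd[16:24],
        fx=lam[0::2], fy=lam[1::2],
    )


def whole_body_com(state: BodyState, anthro: AnthropometricSet):
    """Mass-weighted whole-body CoM position and velocity (each (2,))."""
    m = anthro.mass
    mt = m.sum()
    pos = np.array([np.dot(m, state.x), np.dot(m, state.y)]) / mt
    vel = np.array([np.dot(m, state.xd), np.dot(m, state.yd)]) / mt
    return pos, vel


def assemble_state(
    anthro: AnthropometricSet,
    pelvis_pos: tuple[float, float],
    theta: np.ndarray,
    velocity: tuple[float, float] = (0.0, 0.0),
    time: float = 0.0,
) -> BodyState:
    """Build a joint-consistent state from segment angles.

    The pelvis CoM is placed at ``pelvis_pos``; every other segment CoM
    follows from the kinematic chain, so the joint-coincidence residual
    is zero by construction.  All segments share the same translational
    ``velocity``; angular rates start at zero.
    """
    theta = np.asarray(theta, dtype=float)
    x = np.zeros(N_SEG)
    y = np.zeros(N_SEG)
    x[1], y[1] = pelvis_pos
    for j, (p, d, rp, rd) in enumerate(joint_attachments(anthro)):
        # joint world position from the proximal side, then place distal CoM
        pj = np.array([x[p], y[p]]) + _rot(theta[p]) @ rp
        cd = pj - _rot(theta[d]) @ rd
        x[d], y[d] = cd
    vx, vy = velocity
    return BodyState(
        time=time, x=x, y=y, theta=theta.copy(),
        xd=np.full(N_SEG, vx), yd=np.full(N_SEG, vy),
        thetad=np.zeros(N_SEG),
    )
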