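"""Foot-ground interaction: spring-damper reaction forces and Coulomb cap.

The walker touches the ground at four points (left/right heel and toe).
Each point in contact is tethered to an *anchor* — the horizontal position
where the current contact episode began — by a horizontal spring-damper,
and pushed out of the ground by a vertical spring with a one-sided damper
that only resists downward motion (so the ground never pulls the foot
down).  Both forces are scaled by a smooth indicator that ramps from 0 to
1 over the first centimetre of penetration, which keeps the vector field
continuous at touchdown.

Static friction enters as a cap: once a static coefficient of friction
``mu_s`` is set for the ground under a point, the shear force is clamped
to ``mu_s`` times the normal force, preserving its sign.  Sliding is then
emergent — the anchor is *not* dragged along during a slide, so a capped
contact simply stops resisting further horizontal displacement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "GroundModel",
    "ContactState",
    "CONTACT_POINT_NAMES",
    "smooth_indicator",
    "ground_reaction",
    "friction_cap",
    "update_anchors",
]

#: Contact point order used everywhere: right heel, right toe, left heel, left toe.
CONTACT_POINT_NAMES = ("heel_r", "toe_r", "heel_l", "toe_l")

#: Ramp width of the contact indicator (m of penetration until full force).
INDICATOR_RAMP = 0.01


@dataclass
class GroundModel:
    """Ground compliance, profile and friction schedule.

    The default stiffness/damping constants are the calibrated values for
    a firm level floor: k_gx = 27 kN/m, k_gy = 18 kN/m, b_gx = 2250 N s/m,
    b_gy = 1000 N s/m.  ``friction_segments`` is a piecewise-constant
    schedule ``(x_start, x_end, mu_s | None)``; ``None`` means the cap is
    not applied there (unlimited traction).
    """

    k_gx: float = 27_000.0
    k_gy: float = 18_000.0
    b_gx: float = 2_250.0
    b_gy: float = 1_000.0
    profile: Callable[[float], float] | None = None  # y_g(x); None = flat 0
    friction_segments: Sequence[tuple[float, float, float | None]] = field(
        default_factory=list
    )

    def __post_init__(self) -> None:
        for c in (self.k_gx, self.k_gy, self.b_gx, self.b_gy):
            if c <= 0:
                raise ValueError("ground stiffness/damping must be strictly positive")
        for x0, x1, mu in self.friction_segments:
            if mu is not None and not (0.05 <= mu <= 2.0):
                raise ValueError(f"mu_s={mu} outside the supported range [0.05, 2.0]")

    def y_g(self, x: float) -> float:
        return 0.0 if self.profile is None else float(self.profile(x))

    def mu_at(self, x: float) -> float | None:
        """Static friction coefficient under horizontal position ``x`` (None = unset)."""
        for x0, x1, mu in self.friction_segments:
            if x0 <= x < x1:
                return mu
        return None


@dataclass
class ContactState:
    """Per-point anchors, contact flags and most recent forces (order of
    :data:`CONTACT_POINT_NAMES`)."""

    anchor_x: np.ndarray = field(default_factory=lambda: np.zeros(4))
    in_contact: np.ndarray = field(default_factory=lambda: np.zeros(4, dtype=bool))
    force_x: np.ndarray = field(default_factory=lambda: np.zeros(4))
    force_y: np.ndarray = field(default_factory=lambda: np.zeros(4))

    def copy(self) -> "ContactState":
        return ContactState(
            self.anchor_x.copy(), self.in_contact.copy(),
            self.force_x.copy(), self.force_y.copy(),
        )


def smooth_indicator(x: float) -> float:
    """Contact ramp: 0 for x < 0, 100*x for 0 <= x <= 0.01, 1 beyond."""
    if x < 0.0:
        return 0.0
    if x <= INDICATOR_RAMP:
        return 100.0 * x
    return 1.0


def ground_reaction(
    x_f: float,
    y_f: float,
    vx_f: float,
    vy_f: float,
    anchor_x: float,
    ground: GroundModel,
) -> tuple[float, float]:
    """Spring-damper ground reaction at one contact point.

    Horizontal: spring to the episode anchor plus viscous damping.
    Vertical: penetration spring plus a damper acting only against
    downward motion (``max(0, -vy)``).  Both are multiplied by the
    indicator of penetration depth, so a point above the ground
    produces exactly (0, 0).
    """
    yg = ground.y_g(anchor_x)
    ind = smooth_indicator(yg - y_f)
    if ind == 0.0:
        return 0.0, 0.0
    f_gx = (-ground.k_gx * (x_f - anchor_x) - ground.b_gx * vx_f) * ind
    f_gy = (-ground.k_gy * (y_f - yg) + ground.b_gy * max(0.0, -vy_f)) * ind
    return f_gx, f_gy


def friction_cap(f_gx: float, f_gy: float, mu_s: float | None) -> float:
    """Clamp shear to the friction cone ``|F_gx| <= mu_s * F_gy``.

    ``mu_s=None`` (friction not set) leaves the shear untouched.  The sign
    of the shear force is preserved, so forward and backward sliding are
    capped symmetrically.
    """
    if mu_s is None:
        return f_gx
    if f_gy < 0:
        raise ValueError("normal force must be non-negative")
    limit = mu_s * f_gy
    if abs(f_gx) <= limit:
        return f_gx
    return np.sign(f_gx) * limit


def update_anchors(
    contacts: ContactState,
    point_x: np.ndarray,
    point_y: np.ndarray,
    ground: GroundModel,
) -> ContactState:
    """Advance the discrete contact state after an integration step.

    On a touchdown (point passes from at/above ground to below), the
    anchor is reset to the touchdown horizontal position; while contact
    persists the anchor is frozen; on lift-off the flag clears.  Returns a
    new :class:`ContactState`, leaving the input untouched.
    """
    out = contacts.copy()
    for n in range(4):
        below = point_y[n] < ground.y_g(point_x[n])
        if below and not out.in_contact[n]:
            out.in_contact[n] = True
            out.anchor_x[n] = point_x[n]
        elif not below:
            out.in_contact[n] = False
    return out
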