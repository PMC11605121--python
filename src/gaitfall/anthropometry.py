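"""Segment anthropometry for the planar 8-segment walker.

The walker is built from eight rigid segments — head–arms–trunk (HAT),
pelvis, and left/right thighs, shanks and feet — connected by seven pin
joints (trunk, hips, knees, ankles).  Only the totals (body mass, standing
height) are free inputs; the partition into segment masses, lengths,
centre-of-mass offsets and moments of inertia follows a fixed proportional
convention adapted from standard gait-analysis segment-parameter tables
(Winter-style fractions, with the trunk split into a pelvis segment and a
HAT segment).  All quantities scale linearly in total mass and height
(inertias as mass x length^2), so a (35 kg, 0.9 m) model is geometrically
half the (70 kg, 1.8 m) default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["AnthropometricSet", "build_anthropometry", "SEGMENT_NAMES", "JOINT_NAMES"]

#: Segment order used everywhere in the package.
SEGMENT_NAMES = ("HAT", "pelvis", "thigh_r", "thigh_l", "shank_r", "shank_l", "foot_r", "foot_l")

#: Joint order: trunk joint, hips, knees, ankles.
JOINT_NAMES = ("trunk", "hip_r", "hip_l", "knee_r", "knee_l", "ankle_r", "ankle_l")

# Mass fractions of total body mass.  HAT lumps head, arms and the thorax;
# the pelvis segment carries the remaining trunk mass.  Sums to 1 exactly.
_MASS_FRACTIONS = {
    "HAT": 0.536,
    "pelvis": 0.142,
    "thigh": 0.100,
    "shank": 0.0465,
    "foot": 0.0145,
}

# Length fractions of standing height.  The stack
#   ankle height + shank + thigh + pelvis + HAT
# equals the standing height exactly (the HAT length runs from the
# trunk joint to the top of the head).
_ANKLE_HEIGHT_FRAC = 0.039
_SHANK_FRAC = 0.246
_THIGH_FRAC = 0.245
_PELVIS_FRAC = 0.050
_HAT_FRAC = 1.0 - (_ANKLE_HEIGHT_FRAC + _SHANK_FRAC + _THIGH_FRAC + _PELVIS_FRAC)

_FOOT_LENGTH_FRAC = 0.152  # heel-to-toe
# Horizontal offsets of heel and toe from the ankle joint, as fractions of
# foot length; the ankle sits a quarter of the way back from mid-foot.
_HEEL_BACK_FRAC = 0.25
_TOE_FWD_FRAC = 0.75

# CoM position from the proximal end, as a fraction of segment length,
# and radius of gyration about the CoM as a fraction of segment length.
_COM_FRAC = {"HAT": 0.45, "pelvis": 0.50, "thigh": 0.433, "shank": 0.433, "foot": 0.50}
_RGYR_FRAC = {"HAT": 0.35, "pelvis": 0.35, "thigh": 0.323, "shank": 0.302, "foot": 0.475}


@dataclass(frozen=True)
class AnthropometricSet:
    """Frozen per-segment mass/geometry table for one walker.

    Arrays are ordered as :data:`SEGMENT_NAMES`.  ``com_offset`` is the
    distance from the segment's proximal end to its centre of mass; for the
    feet the "proximal end" is the ankle joint and the offset is stored as
    a 2-vector in the foot body frame instead (see ``foot_*`` fields).
    """

    total_mass: float
    total_height: float
    mass: np.ndarray            # (8,) kg
    length: np.ndarray          # (8,) m, along the segment's long axis
    com_offset: np.ndarray      # (8,) m from proximal end (feet: see below)
    inertia: np.ndarray         # (8,) kg m^2 about the segment CoM
    foot_length: float          # m, heel-to-toe
    ankle_height: float         # m, ankle joint above the sole
    heel_offset: np.ndarray = field(default=None)  # (2,) m from ankle, foot frame
    toe_offset: np.ndarray = field(default=None)   # (2,) m from ankle, foot frame

    def index(self, name: str) -> int:
        return SEGMENT_NAMES.index(name)


def build_anthropometry(total_mass: float = 70.0, total_height: float = 1.8) -> AnthropometricSet:
    """Build the full segment-parameter set for a walker.

    Parameters
    ----------
    total_mass
        Whole-body mass in kg (default 70 kg).
    total_height
        Standing height in m (default 1.8 m).

    Raises
    ------
    ValueError
        If either total is not strictly positive.
    """
    if not (total_mass > 0 and total_height > 0):
        raise ValueError(
            f"total_mass and total_height must be positive, got ({total_mass}, {total_height})"
        )

    frac = _MASS_FRACTIONS
    mass = np.array(
        [frac["HAT"], frac["pelvis"], frac["thigh"], frac["thigh"],
         frac["shank"], frac["shank"], frac["foot"], frac["foot"]]
    ) * total_mass
    # absorb rounding so the masses sum to the total exactly
    mass[0] += total_mass - mass.sum()

    H = total_height
    foot_length = _FOOT_LENGTH_FRAC * H
    ankle_height = _ANKLE_HEIGHT_FRAC * H
    length = np.array(
        [_HAT_FRAC, _PELVIS_FRAC, _THIGH_FRAC, _THIGH_FRAC,
         _SHANK_FRAC, _SHANK_FRAC, 0.0, 0.0]
    ) * H
    length[6] = length[7] = foot_length

    kinds = ["HAT", "pelvis", "thigh", "thigh", "shank", "shank", "foot", "foot"]
    com_offset = np.array([_COM_FRAC[k] for k in kinds]) * length
    inertia = mass * (np.array([_RGYR_FRAC[k] for k in kinds]) * length) ** 2

    heel_offset = np.array([-_HEEL_BACK_FRAC * foot_length, -ankle_height])
    toe_offset = np.array([_TOE_FWD_FRAC * foot_length, -ankle_height])

    return AnthropometricSet(
        total_mass=total_mass,
        total_height=total_height,
        mass=mass,
        length=length,
        com_offset=com_offset,
        inertia=inertia,
        foot_length=foot_length,
        ankle_height=ankle_height,
        heel_offset=heel_offset,
        toe_offset=toe_offset,
    )
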