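"""Synthetic kinematic gait fixtures with exactly known ground truth.

These generators emulate the statistical structure of sagittal-plane
gait — periodic strides with prescribed stride length, speed, duty
factor, toe/heel clearances and per-stride multiplicative noise — using
piecewise sinusoids for the swing-foot paths and square-wave vertical
ground forces.  They are *kinematic only*: no dynamics is consistent
with them by construction, but every per-stride quantity is recorded in
a ground-truth table, which makes them the independent test bed for the
metrics and fall-classification layers.

Foot-path construction per swing (phase s in [0, 1], mid-swing window
is the middle tercile):

* toe height: rises to an apex, dips to exactly the programmed minimum
  clearance at s = 1/2 (the analytic minimum over the mid-swing window),
  and returns to 0;
* heel height: a single sinusoidal arc peaking at exactly the
  programmed maximum clearance at s = 1/2.

Scripted falls overwrite the tail of a clean walk so the classifier's
three outcomes can each be produced on demand with a known label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trajectory import Trajectory

__all__ = ["FixtureSpec", "make_kinematic_walker", "make_fall_fixture"]

BODY_WEIGHT_N = 70.0 * 9.81
HIP_HEIGHT = 0.92
FOOT_LEN = 0.15
SAMPLE_HZ = 500.0


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic walking trajectory."""

    stride_length: float = 1.4       # m
    walking_speed: float = 1.25      # m/s
    min_toe_clearance: float = 0.02  # m
    max_heel_clearance: float = 0.30 # m
    duty_factor: float = 0.62        # stance fraction of the gait cycle
    n_strides: int = 14
    noise_sd: float = 0.0            # per-stride multiplicative SD (fraction)
    seed: int = 0
    fall: str | None = None          # None | "slip" | "trip"
    fall_step: int = 6               # stride index at which the scripted fall begins

    def __post_init__(self):
        if not (0.5 < self.duty_factor < 0.8):
            raise ValueError("duty factor must lie in (0.5, 0.8)")
        if min(self.stride_length, self.walking_speed,
               self.min_toe_clearance, self.max_heel_clearance) <= 0:
            raise ValueError("lengths and speed must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be non-negative")
        if self.fall not in (None, "slip", "trip"):
            raise ValueError("fall must be None, 'slip' or 'trip'")


def _toe_height(s: np.ndarray, c_min: float, apex: float) -> np.ndarray:
    """Piecewise toe-height profile with analytic mid-swing minimum c_min."""
    h = np.zeros_like(s)
    a = s < 1.0 / 3.0
    b = (s >= 1.0 / 3.0) & (s <= 2.0 / 3.0)
    c = s > 2.0 / 3.0
    h[a] = apex * np.sin(1.5 * np.pi * s[a])
    # cosine valley from the apex down to exactly c_min at s = 1/2
    h[b] = apex - (apex - c_min) * np.cos(np.pi * (3.0 * s[b] - 1.5)) ** 2
    h[c] = apex * np.sin(1.5 * np.pi * (1.0 - s[c]))
    return h


def _swing_ramp(s: np.ndarray) -> np.ndarray:
    """Smooth 0->1 horizontal progression over the swing (zero end rates)."""
    return 0.5 * (1.0 - np.cos(np.pi * s))


def make_kinematic_walker(spec: FixtureSpec):
    """Build a synthetic trajectory plus its ground-truth table.

    Returns ``(Trajectory, DataFrame)`` where the table holds the
    realized (noise-included) per-stride stride length, speed and
    clearances for both feet.
    """
    rng = np.random.default_rng(spec.seed)
    T = spec.stride_length / spec.walking_speed     # stride (cycle) time
    swing_frac = 1.0 - spec.duty_factor
    n_cycles = spec.n_strides + 1                   # pad one cycle for alignment

    # realized per-stride parameters (shared by both feet within a cycle)
    def draw(nominal, n):
        if spec.noise_sd == 0:
            return np.full(n, nominal)
        return nominal * (1.0 + spec.noise_sd * rng.standard_normal(n))

    sl = draw(spec.stride_length, n_cycles)
    mtc = np.maximum(1e-4, draw(spec.min_toe_clearance, n_cycles))
    mhc = np.maximum(1e-3, draw(spec.max_heel_clearance, n_cycles))

    t_total = n_cycles * T
    t = np.arange(0.0, t_total, 1.0 / SAMPLE_HZ)
    n = len(t)

    def foot_tracks(phase_offset, start_x):
        toe_x = np.empty(n); toe_y = np.zeros(n)
        heel_y = np.zeros(n)
        stance_fgy = np.zeros(n)
        cur = start_x
        cyc = np.floor(t / T + phase_offset).astype(int)
        ph = (t / T + phase_offset) % 1.0
        # stance occupies [0, duty), swing [duty, 1)
        for k in range(n):
            c = cyc[k]
            if ph[k] < spec.duty_factor:
                x = start_x + sl[:c].sum() if c > 0 else start_x
                toe_x[k] = x
                toe_y[k] = 0.0
                heel_y[k] = 0.0
                stance_fgy[k] = BODY_WEIGHT_N / 2.0
            else:
                s = (ph[k] - spec.duty_factor) / swing_frac
                x0 = start_x + (sl[:c].sum() if c > 0 else 0.0)
                stride_k = sl[c] if c < n_cycles else sl[-1]
                apex = max(3.0 * mtc[min(c, n_cycles - 1)], 0.08)
                toe_x[k] = x0 + stride_k * _swing_ramp(np.array([s]))[0]
                toe_y[k] = _toe_height(np.array([s]), mtc[min(c, n_cycles - 1)], apex)[0]
                heel_y[k] = mhc[min(c, n_cycles - 1)] * np.sin(np.pi * s) ** 2
        return toe_x, toe_y, heel_y, stance_fgy

    toe_r_x, toe_r_y, heel_r_y, fgy_r = foot_tracks(0.0, 0.0)
    toe_l_x, toe_l_y, heel_l_y, fgy_l = foot_tracks(0.5, -spec.stride_length / 2.0)

    heel_r_x = toe_r_x - FOOT_LEN
    heel_l_x = toe_l_x - FOOT_LEN

    # piecewise speed so each cycle's realized stride length is covered in T
    cyc = np.floor(t / T).astype(int)
    ph = (t / T) % 1.0
    base = np.concatenate([[0.0], np.cumsum(sl)])
    com_x = base[np.minimum(cyc, n_cycles - 1)] + sl[np.minimum(cyc, n_cycles - 1)] * ph
    com_x -= spec.stride_length / 2.0
    com_vx = np.gradient(com_x, t)
    com_y = np.full(n, HIP_HEIGHT + 0.1)
    com_vy = np.zeros(n)
    hip_y = np.full(n, HIP_HEIGHT)
    hip_x = com_x.copy()

    foot_r_vx = np.gradient(toe_r_x, t)
    foot_l_vx = np.gradient(toe_l_x, t)

    fgx_r = 0.15 * fgy_r * np.sin(2.0 * np.pi * t / T)
    fgx_l = 0.15 * fgy_l * np.sin(2.0 * np.pi * t / T + np.pi)

    truth = pd.DataFrame(dict(
        stride=np.arange(n_cycles),
        stride_length=sl,
        walking_speed=sl / T,
        min_toe_clearance=mtc,
        max_heel_clearance=mhc,
    ))

    label = "no_fall"
    if spec.fall is not None:
        t_fall = (spec.fall_step + 0.25) * T   # mid-stance of the scripted stride
        k_fall = int(np.searchsorted(t, t_fall))
        k_fall = min(k_fall, n - 2)
        tt = t[k_fall:] - t[k_fall]
        # hip/CoM drop below the 0.70 m fall threshold over ~0.4 s
        drop = np.minimum(1.0, tt / 0.4)
        hip_y[k_fall:] = HIP_HEIGHT - drop * (HIP_HEIGHT - 0.45)
        com_y[k_fall:] = HIP_HEIGHT + 0.1 - drop * (HIP_HEIGHT - 0.45)
        if spec.fall == "slip":
            label = "slip_fall"
            # stance foot (right) slides forward fast before the fall
            pre = (t >= t_fall - 0.15) & (t < t_fall + 0.3)
            slide_v = 0.8
            sel = np.where(pre)[0]
            dtv = np.diff(t[sel], prepend=t[sel[0]])
            toe_r_x[sel] = toe_r_x[sel[0]] + np.cumsum(slide_v * dtv)
            heel_r_x[sel] = toe_r_x[sel] - FOOT_LEN
            foot_r_vx[sel] = slide_v
            fgy_r[sel] = BODY_WEIGHT_N / 2.0       # still loaded while sliding
            # backward imbalance: CoM velocity reverses
            com_vx[k_fall:] = -0.8
            com_x[k_fall:] = com_x[k_fall] - 0.8 * tt
        else:
            label = "trip_fall"
            # stance foot pinned (speed ~0), body pitches forward past the toe
            sel = t >= t_fall - 0.15
            foot_r_vx[sel & (fgy_r > 0)] = 0.0
            com_vx[k_fall:] = 1.8
            com_x[k_fall:] = com_x[k_fall] + 1.8 * tt
        # freeze contacts after the body is down
        down = hip_y < 0.45
        for arr in (fgy_r, fgy_l, fgx_r, fgx_l):
            arr[down] = 0.0

    data = pd.DataFrame(dict(
        t=t,
        com_x=com_x, com_y=com_y, com_vx=com_vx, com_vy=com_vy,
        hip_x=hip_x, hip_y=hip_y,
        toe_r_x=toe_r_x, toe_r_y=toe_r_y,
        heel_r_x=heel_r_x, heel_r_y=heel_r_y,
        toe_l_x=toe_l_x, toe_l_y=toe_l_y,
        heel_l_x=heel_l_x, heel_l_y=heel_l_y,
        ankle_r_x=toe_r_x - 0.75 * FOOT_LEN, ankle_r_y=toe_r_y + 0.07,
        ankle_l_x=toe_l_x - 0.75 * FOOT_LEN, ankle_l_y=toe_l_y + 0.07,
        foot_r_vx=foot_r_vx, foot_l_vx=foot_l_vx,
        fgx_heel_r=fgx_r / 2, fgy_heel_r=fgy_r / 2,
        fgx_toe_r=fgx_r / 2, fgy_toe_r=fgy_r / 2,
        fgx_heel_l=fgx_l / 2, fgy_heel_l=fgy_l / 2,
        fgx_toe_l=fgx_l / 2, fgy_toe_l=fgy_l / 2,
    ))
    meta = {"source": "synthetic-fixture", "label": label,
            "seed": str(spec.seed)}
    return Trajectory(data, meta), truth


def make_fall_fixture(kind: str, seed: int = 0,
                      spec: FixtureSpec | None = None):
    """Scripted trajectory with a known outcome label.

    ``kind`` is one of ``no_fall``, ``slip_fall``, ``trip_fall``.
    Returns ``(Trajectory, expected_label)``.  The scripted fall is
    placed so it occurs inside the 5-15 m assessment window.
    """
    kinds = {"no_fall": None, "slip_fall": "slip", "trip_fall": "trip"}
    if kind not in kinds:
        raise ValueError(f"unknown fixture kind {kind!r}")
    base = spec or FixtureSpec()
    fall_step = max(5, int(np.ceil(6.0 / base.stride_length)))
    fx = FixtureSpec(
        stride_length=base.stride_length, walking_speed=base.walking_speed,
        min_toe_clearance=base.min_toe_clearance,
        max_heel_clearance=base.max_heel_clearance,
        duty_factor=base.duty_factor,
        n_strides=max(base.n_strides, fall_step + 4),
        noise_sd=base.noise_sd, seed=seed,
        fall=kinds[kind], fall_step=fall_step,
    )
    traj, _ = make_kinematic_walker(fx)
    return traj, kind
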