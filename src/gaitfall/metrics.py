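"""Gait metrics: events, stride parameters, clearances, MOS, traction.

All computations run on a :class:`~gaitfall.trajectory.Trajectory` — the
analysis layer never needs the dynamics engine, so synthetic fixtures
and simulated trials are treated identically.

Definitions follow standard gait-analysis practice for a planar walker:

* gait events from vertical-GRF threshold crossings (1 N, 10 ms debounce);
* stride length = horizontal right-toe displacement between consecutive
  right-foot touchdowns; walking speed = stride length / stride time;
  cadence = 1 / stride time;
* minimum foot clearance = minimum toe height during the mid-swing
  window (middle tercile of the swing phase); maximum foot clearance =
  maximum heel height in the same window;
* margin of stability (MOS) from the extrapolated centre of mass
  XCoM = X + V / sqrt(g / l) against the anterior (toe) and posterior
  (heel) borders of the base of support, arranged so that positive
  means stable;
* traction coefficient = |F_gx| / F_gy per contact point, its per-stance
  maximum being the required coefficient of friction (RCOF).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trajectory import Trajectory

__all__ = [
    "GaitEvents", "StepMetrics", "GaitSummary", "MosSeries",
    "InsufficientDataError",
    "detect_gait_events", "stride_metrics", "clearance_metrics",
    "summarize_gait", "compute_mos", "traction_series",
]

GRF_THRESHOLD_N = 1.0     # contact if vertical GRF exceeds this
DEBOUNCE_S = 0.010        # minimum dwell for a contact transition

# phase codes
DOUBLE_SUPPORT = 0
SINGLE_R = 1
SINGLE_L = 2
FLIGHT = 3


class InsufficientDataError(ValueError):
    """The trajectory does not contain enough gait to compute a metric."""


@dataclass
class GaitEvents:
    """Touchdown/liftoff times per foot plus a per-sample phase label."""

    touchdown_r: np.ndarray   # times (s)
    liftoff_r: np.ndarray
    touchdown_l: np.ndarray
    liftoff_l: np.ndarray
    stance_r: np.ndarray      # bool per sample (debounced)
    stance_l: np.ndarray
    phase: np.ndarray         # int per sample


@dataclass
class StepMetrics:
    """Per-stride scalar metrics (stride = right touchdown to next)."""

    index: int
    t_start: float
    stride_length: float
    stride_time: float
    walking_speed: float
    cadence: float
    min_toe_clearance: float | None = None
    max_heel_clearance: float | None = None
    min_anterior_mos: float | None = None
    min_posterior_mos: float | None = None
    max_traction: float | None = None


@dataclass
class GaitSummary:
    """Mean and CV (%) over ``n`` consecutive strides, plus SL_FC."""

    n: int
    mean: dict
    cv: dict
    sl_fc: float


@dataclass
class MosSeries:
    """Per-sample margins of stability and their per-step minima."""

    t: np.ndarray
    xcom: np.ndarray
    anterior_border: np.ndarray
    posterior_border: np.ndarray
    anterior_mos: np.ndarray
    posterior_mos: np.ndarray
    l_eff: np.ndarray                 # effective pendulum length used per sample
    g: float
    step_minima: pd.DataFrame = field(default=None)  # step, t, min_ant, min_post


def _debounce(flag: np.ndarray, t: np.ndarray, min_dwell: float) -> np.ndarray:
    """Remove state dwells shorter than ``min_dwell`` (keeps prior state)."""
    out = flag.copy()
    n = len(out)
    i = 0
    while i < n:
        j = i
        while j < n and out[j] == out[i]:
            j += 1
        if j < n and (t[j - 1] - t[i]) < min_dwell and i > 0:
            out[i:j] = out[i - 1]
        i = j if j > i else i + 1
    return out


def detect_gait_events(traj: Trajectory,
                       threshold: float = GRF_THRESHOLD_N,
                       debounce: float = DEBOUNCE_S) -> GaitEvents:
    """Touchdowns/liftoffs from vertical-GRF threshold crossings."""
    t = traj.t
    if len(t) < 3:
        raise InsufficientDataError("trajectory too short for event detection")
    stance = {}
    for side in ("r", "l"):
        raw = traj.grf_y(side) > threshold
        stance[side] = _debounce(raw, t, debounce)
    sr, sl = stance["r"], stance["l"]

    def transitions(s):
        td = t[1:][~s[:-1] & s[1:]]
        lo = t[1:][s[:-1] & ~s[1:]]
        return td, lo

    td_r, lo_r = transitions(sr)
    td_l, lo_l = transitions(sl)
    if len(td_r) + len(td_l) + len(lo_r) + len(lo_l) == 0 and not (sr.any() or sl.any()):
        raise InsufficientDataError("no ground contact found in trajectory")
    phase = np.full(len(t), FLIGHT, dtype=np.int64)
    phase[sr & sl] = DOUBLE_SUPPORT
    phase[sr & ~sl] = SINGLE_R
    phase[~sr & sl] = SINGLE_L
    return GaitEvents(td_r, lo_r, td_l, lo_l, sr, sl, phase)


def stride_metrics(traj: Trajectory, events: GaitEvents) -> list[StepMetrics]:
    """Per-stride length/time/speed/cadence from right-toe touchdowns."""
    td = events.touchdown_r
    if len(td) < 2:
        raise InsufficientDataError(
            f"need >= 2 right-foot touchdowns, found {len(td)}")
    t = traj.t
    toe_x = traj.col("toe_r_x")
    out = []
    for i in range(len(td) - 1):
        i0 = int(np.searchsorted(t, td[i]))
        i1 = int(np.searchsorted(t, td[i + 1]))
        dx = toe_x[i1] - toe_x[i0]
        dt_ = td[i + 1] - td[i]
        if dx <= 0:
            raise InsufficientDataError(
                f"non-forward stride displacement ({dx:.3f} m) at stride {i}; "
                "trajectory is not a forward walk")
        out.append(StepMetrics(
            index=i, t_start=float(td[i]),
            stride_length=float(dx), stride_time=float(dt_),
            walking_speed=float(dx / dt_), cadence=float(1.0 / dt_),
        ))
    return out


def _swing_windows(t: np.ndarray, stance: np.ndarray):
    """(start, end) times of complete swing phases of one foot."""
    lo = np.where(stance[:-1] & ~stance[1:])[0] + 1
    td = np.where(~stance[:-1] & stance[1:])[0] + 1
    wins = []
    for i0 in lo:
        nxt = td[td > i0]
        if len(nxt):
            wins.append((i0, int(nxt[0])))
    return wins


def clearance_metrics(traj: Trajectory, events: GaitEvents,
                      side: str = "r") -> pd.DataFrame:
    """Min toe / max heel clearance per swing (mid-swing window).

    The mid-swing window is the middle tercile of each swing phase by
    time.  Heights are measured above flat ground (y = 0).
    """
    t = traj.t
    stance = events.stance_r if side == "r" else events.stance_l
    wins = _swing_windows(t, stance)
    if not wins:
        raise InsufficientDataError(f"no complete swing phase for foot {side!r}")
    toe_y = traj.col(f"toe_{side}_y")
    heel_y = traj.col(f"heel_{side}_y")
    rows = []
    for k, (i0, i1) in enumerate(wins):
        t0, t1 = t[i0], t[i1]
        m0, m1 = t0 + (t1 - t0) / 3.0, t0 + 2.0 * (t1 - t0) / 3.0
        sel = (t >= m0) & (t <= m1)
        if not sel.any():
            continue
        rows.append(dict(
            swing=k, t_start=float(t0), t_end=float(t1),
            min_toe_clearance=float(toe_y[sel].min()),
            max_heel_clearance=float(heel_y[sel].max()),
        ))
    if not rows:
        raise InsufficientDataError("swing phases too short to resolve mid-swing")
    return pd.DataFrame(rows)


_SUMMARY_VARS = ("stride_length", "walking_speed",
                 "max_heel_clearance", "min_toe_clearance")


def summarize_gait(strides: list[StepMetrics], clearances: pd.DataFrame,
                   n: int = 10, start: int = 0) -> GaitSummary:
    """Mean and CV over ``n`` consecutive strides.

    CV = 100 * SD / mean with the sample (n-1) standard deviation.
    SL_FC = mean stride length / mean minimum (toe) foot clearance.
    Strides and swings are aligned by order after ``start``.
    """
    if len(strides) < start + n:
        raise InsufficientDataError(
            f"need {start + n} strides, have {len(strides)}")
    if len(clearances) < start + n:
        raise InsufficientDataError(
            f"need {start + n} swings, have {len(clearances)}")
    sl = np.array([s.stride_length for s in strides[start:start + n]])
    sp = np.array([s.walking_speed for s in strides[start:start + n]])
    mtc = clearances["min_toe_clearance"].to_numpy()[start:start + n]
    mhc = clearances["max_heel_clearance"].to_numpy()[start:start + n]
    mean = {}
    cv = {}
    for name, arr in zip(_SUMMARY_VARS, (sl, sp, mhc, mtc)):
        mean[name] = float(arr.mean())
        cv[name] = float(100.0 * arr.std(ddof=1) / arr.mean())
    return GaitSummary(n=n, mean=mean, cv=cv,
                       sl_fc=float(mean["stride_length"] / mean["min_toe_clearance"]))


def effective_pendulum_length(traj: Trajectory, events: GaitEvents) -> np.ndarray:
    """Per-sample effective pendulum length: distance from the stance
    ankle to the whole-body CoM, evaluated at mid-stance of each step and
    held constant over that step."""
    t = traj.t
    com_x, com_y = traj.col("com_x"), traj.col("com_y")
    l = np.empty(len(t))
    # default: instantaneous CoM height (used before the first resolved step)
    current = float(np.median(com_y[:max(1, len(com_y) // 10)]))
    stances = []
    for side, st in (("r", events.stance_r), ("l", events.stance_l)):
        td = np.where(~st[:-1] & st[1:])[0] + 1
        lo = np.where(st[:-1] & ~st[1:])[0] + 1
        for i0 in td:
            nxt = lo[lo > i0]
            i1 = int(nxt[0]) if len(nxt) else len(t) - 1
            stances.append((i0, i1, side))
    stances.sort()
    l[:] = current
    for i0, i1, side in stances:
        mid = (i0 + i1) // 2
        ax = traj.col(f"ankle_{side}_x")[mid]
        ay = traj.col(f"ankle_{side}_y")[mid]
        current = float(np.hypot(com_x[mid] - ax, com_y[mid] - ay))
        l[i0:] = current
    return l


def compute_mos(traj: Trajectory, events: GaitEvents,
                l: float | np.ndarray | None = None,
                g: float = 9.81) -> MosSeries:
    """Anterior/posterior margins of stability (positive = stable).

    XCoM = X + V / sqrt(g / l).  The anterior border is the toe of the
    leading foot in double support and the toe of the stance foot in
    single support; the posterior border is the heel of the trailing
    (resp. stance) foot.  During flight the borders are carried over
    from the last supported sample.  ``l`` may be a scalar, a per-sample
    array, or None to recompute it per step from the stance ankle-to-CoM
    distance at mid-stance.
    """
    t = traj.t
    if l is None:
        l_eff = effective_pendulum_length(traj, events)
    else:
        l_eff = np.broadcast_to(np.asarray(l, dtype=float), t.shape).copy()
    if np.any(l_eff <= 0):
        raise ValueError("effective pendulum length must be positive")
    xcom = traj.col("com_x") + traj.col("com_vx") / np.sqrt(g / l_eff)

    toe_r, toe_l = traj.col("toe_r_x"), traj.col("toe_l_x")
    heel_r, heel_l = traj.col("heel_r_x"), traj.col("heel_l_x")
    sr, sl_ = events.stance_r, events.stance_l
    n = len(t)
    ant = np.empty(n)
    post = np.empty(n)
    for i in range(n):
        if sr[i] and sl_[i]:
            ant[i] = max(toe_r[i], toe_l[i])
            post[i] = min(heel_r[i], heel_l[i])
        elif sr[i]:
            ant[i], post[i] = toe_r[i], heel_r[i]
        elif sl_[i]:
            ant[i], post[i] = toe_l[i], heel_l[i]
        else:
            ant[i] = ant[i - 1] if i else np.nan
            post[i] = post[i - 1] if i else np.nan
    if np.isnan(ant[0]):
        # leading flight samples: borrow the first supported borders
        first = np.argmax(~np.isnan(ant)) if (~np.isnan(ant)).any() else None
        if first is None:
            raise InsufficientDataError("no supported samples for BOS borders")
        ant[:first] = ant[first]
        post[:first] = post[first]

    ant_mos = ant - xcom
    post_mos = xcom - post

    # per-step minima: step boundaries at every touchdown (either foot)
    tds = np.sort(np.concatenate([events.touchdown_r, events.touchdown_l]))
    rows = []
    for k in range(len(tds)):
        t0 = tds[k]
        t1 = tds[k + 1] if k + 1 < len(tds) else t[-1]
        sel = (t >= t0) & (t < t1)
        if not sel.any():
            continue
        rows.append(dict(step=k, t_start=float(t0),
                         min_anterior_mos=float(ant_mos[sel].min()),
                         min_posterior_mos=float(post_mos[sel].min())))
    return MosSeries(
        t=t, xcom=xcom, anterior_border=ant, posterior_border=post,
        anterior_mos=ant_mos, posterior_mos=post_mos,
        l_eff=l_eff, g=g,
        step_minima=pd.DataFrame(rows),
    )


def traction_series(traj: Trajectory, events: GaitEvents,
                    min_normal: float = 1.0) -> pd.DataFrame:
    """Per-stance maxima of |F_gx|/F_gy per foot.

    Samples with F_gy <= ``min_normal`` N are excluded (the ratio is
    undefined at contact onset).  The returned table has one row per
    stance phase: foot, start/end time, and the maximum traction ratio
    over both of that foot's contact points.
    """
    t = traj.t
    rows = []
    for side, st in (("r", events.stance_r), ("l", events.stance_l)):
        td = np.where(~st[:-1] & st[1:])[0] + 1
        lo = np.where(st[:-1] & ~st[1:])[0] + 1
        if st[0]:
            td = np.concatenate([[0], td])
        for i0 in td:
            nxt = lo[lo > i0]
            i1 = int(nxt[0]) if len(nxt) else len(t)
            best = 0.0
            for pt in ("heel", "toe"):
                fy = traj.col(f"fgy_{pt}_{side}")[i0:i1]
                fx = traj.col(f"fgx_{pt}_{side}")[i0:i1]
                ok = fy > min_normal
                if ok.any():
                    best = max(best, float(np.max(np.abs(fx[ok]) / fy[ok])))
            rows.append(dict(foot=side, t_start=float(t[i0]),
                             t_end=float(t[min(i1, len(t) - 1)]),
                             max_traction=best))
    return pd.DataFrame(rows).sort_values("t_start").reset_index(drop=True)
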