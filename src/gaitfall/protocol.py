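"""Friction-sweep protocol: trials, fall classification, thresholds.

One trial walks a gait model 15 m over ground whose static friction
coefficient is *unset* for the first 5 m (the traction ratio may take
any value) and equals ``mu_s`` beyond; the 5-15 m window is then scored:

* **fall** — hip height drops below 0.70 m inside the window;
* **slip-induced fall** — a fall preceded (within the window) by a
  stance-phase foot moving faster than 0.3 m/s for at least 10 ms;
* **trip-induced fall** — a forward fall without such sliding.

Fall direction is decided at the first instant the hip crosses the
threshold by comparing the extrapolated CoM against the base-of-support
borders (ahead of the anterior border = forward, behind the posterior
border = backward); in the rare in-between case the sign of the CoM
velocity decides.  A backward fall without detected sliding is also
labelled slip-induced — backward imbalance on level ground has no other
mechanism here.

The sweep runs 5 seeded trials per gait model at each of the 25 grid
values ``{0.05..0.50 step 0.05} + {0.60..2.00 step 0.10}`` (125 trials),
and ``mu_s_slip`` is the largest grid value at which at least one
slip-induced fall occurred.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dynamics import NumericalError
from .engine import RunConfig, simulate_trial
from .metrics import (
    InsufficientDataError, compute_mos, detect_gait_events,
    effective_pendulum_length, traction_series,
)
from .models import GaitModelSpec, build_cpg_parameters, build_gait_model
from .trajectory import Trajectory

logger = logging.getLogger(__name__)

__all__ = [
    "TrialResult", "SweepResult", "OUTCOMES",
    "mu_grid", "classify_outcome", "mu_slip_threshold",
    "run_trial", "run_sweep", "trial_seed",
]

OUTCOMES = ("no_fall", "slip_fall", "trip_fall")


@dataclass
class TrialResult:
    """Outcome and annotations of one trial."""

    model: str
    mu_s: float | None
    seed: int
    outcome: str                       # one of OUTCOMES, or "invalid"
    fall_x: float | None = None        # CoM position at the fall (m)
    fall_t: float | None = None        # time of the fall (s)
    slipped: bool = False              # stance-foot sliding detected in window
    max_traction: float | None = None  # max per-stance |Fgx|/Fgy in window
    error: str | None = None
    trajectory: Trajectory | None = None

    def __post_init__(self):
        if self.outcome not in OUTCOMES + ("invalid",):
            raise ValueError(f"bad outcome {self.outcome!r}")
        if self.outcome in ("slip_fall", "trip_fall"):
            assert self.fall_x is not None and self.fall_t is not None


@dataclass
class SweepResult:
    """All trials of one model over the friction grid."""

    model: str
    table: pd.DataFrame    # columns: mu_s, trial, seed, outcome, fall_x, fall_t

    @property
    def mu_s_slip(self) -> float | None:
        return mu_slip_threshold(self)


def mu_grid() -> np.ndarray:
    """The 25-value friction grid: 0.05..0.50 by 0.05, then 0.60..2.0 by 0.1."""
    low = np.round(np.arange(1, 11) * 0.05, 10)
    high = np.round(0.5 + np.arange(1, 16) * 0.1, 10)
    return np.concatenate([low, high])


def _first_true_run(t: np.ndarray, cond: np.ndarray, min_dwell: float) -> int | None:
    """Index of the first sample where ``cond`` has held for >= min_dwell."""
    idx = None
    start = None
    for i, c in enumerate(cond):
        if c and start is None:
            start = i
        elif not c:
            start = None
        if start is not None and t[i] - t[start] >= min_dwell:
            idx = start
            break
    return idx


def classify_outcome(traj: Trajectory, config: RunConfig | None = None):
    """Label a trial trajectory (see module docstring for the rules).

    Returns ``(outcome, annotations)`` where annotations carry the fall
    position/time, whether sliding was detected, and the fall direction.
    Raises :class:`InsufficientDataError` if the trajectory neither
    covers the assessment window nor ends in a fall.
    """
    config = config or RunConfig()
    t = traj.t
    x = traj.col("com_x")
    hip = traj.col("hip_y")
    x0, x1 = config.switch_x, config.total_distance
    in_window = (x >= x0) & (x <= x1)
    if not in_window.any():
        raise InsufficientDataError("trajectory never reaches the assessment window")

    fall_mask = in_window & (hip < config.fall_hip_height)
    fall_idx = int(np.argmax(fall_mask)) if fall_mask.any() else None

    if fall_idx is None:
        if x.max() < x1 - 1e-6:
            raise InsufficientDataError(
                f"no fall, but the walk ends at {x.max():.2f} m < {x1:.2f} m")
        return "no_fall", dict(fall_x=None, fall_t=None, slipped=False, direction=None)

    # sliding of a loaded foot inside the window, before the fall
    upto = fall_idx + 1
    slipped = False
    for side in ("r", "l"):
        loaded = traj.grf_y(side)[:upto] > 1.0
        fast = np.abs(traj.col(f"foot_{side}_vx")[:upto]) > config.slip_speed
        cond = loaded & fast & in_window[:upto]
        if _first_true_run(t[:upto], cond, config.debounce_s) is not None:
            slipped = True
            break

    # fall direction from XCoM vs the BOS borders at the fall instant
    direction = None
    try:
        events = detect_gait_events(traj)
        mos = compute_mos(traj, events)
        if mos.xcom[fall_idx] > mos.anterior_border[fall_idx]:
            direction = "forward"
        elif mos.xcom[fall_idx] < mos.posterior_border[fall_idx]:
            direction = "backward"
        else:
            direction = "forward" if traj.col("com_vx")[fall_idx] > 0 else "backward"
    except InsufficientDataError:
        direction = "forward" if traj.col("com_vx")[fall_idx] > 0 else "backward"

    ann = dict(fall_x=float(x[fall_idx]), fall_t=float(t[fall_idx]),
               slipped=slipped, direction=direction)
    if slipped:
        return "slip_fall", ann
    if direction == "forward":
        return "trip_fall", ann
    return "slip_fall", ann


def mu_slip_threshold(sweep: SweepResult) -> float | None:
    """Largest grid mu_s with at least one slip-induced fall (None if none)."""
    tab = sweep.table
    hit = tab.loc[tab["outcome"] == "slip_fall", "mu_s"]
    return float(hit.max()) if len(hit) else None


def trial_seed(base_seed: int, model: str, mu_index: int, trial: int) -> int:
    """Deterministic per-trial seed, recorded in sweep output."""
    import zlib
    model_key = zlib.crc32(model.encode()) & 0xFFFF
    ss = np.random.SeedSequence(base_seed, spawn_key=(model_key, mu_index, trial))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def run_trial(model: GaitModelSpec | str, mu_s: float | None, seed: int,
              config: RunConfig | None = None,
              keep_trajectory: bool = False) -> TrialResult:
    """Simulate one trial and classify its outcome.

    A diverging integration is retried once at half the step; if it
    still diverges the trial is marked ``invalid`` (never silently
    classified as a fall).
    """
    if isinstance(model, str):
        model = build_gait_model(model)
    if mu_s is not None and not (0.05 <= mu_s <= 2.0):
        raise ValueError(f"mu_s={mu_s} outside the protocol range [0.05, 2.0]")
    config = config or RunConfig()
    config = replace(config, mu_s=mu_s)
    params = build_cpg_parameters(model)

    traj = None
    err = None
    for attempt, cfg in enumerate((config, replace(config, dt=config.dt / 2,
                                                   record_every=config.record_every * 2))):
        try:
            traj, status = simulate_trial(params, cfg, seed=seed,
                                          meta={"model": model.name,
                                                "mu_s": str(mu_s), "seed": str(seed)})
            err = None
            break
        except NumericalError as exc:
            err = str(exc)
            logger.warning("trial (%s, mu=%s, seed=%d) diverged (attempt %d): %s",
                           model.name, mu_s, seed, attempt + 1, exc)
    if traj is None:
        return TrialResult(model.name, mu_s, seed, "invalid", error=err)

    try:
        outcome, ann = classify_outcome(traj, config)
    except InsufficientDataError as exc:
        logger.warning("trial (%s, mu=%s, seed=%d) unclassifiable: %s",
                       model.name, mu_s, seed, exc)
        return TrialResult(model.name, mu_s, seed, "invalid", error=str(exc),
                           trajectory=traj if keep_trajectory else None)

    max_tr = None
    try:
        events = detect_gait_events(traj)
        tr = traction_series(traj, events)
        sel = tr[tr["t_start"] > 0]
        if len(sel):
            max_tr = float(sel["max_traction"].max())
    except InsufficientDataError:
        pass

    return TrialResult(model.name, mu_s, seed, outcome,
                       fall_x=ann["fall_x"], fall_t=ann["fall_t"],
                       slipped=ann["slipped"], max_traction=max_tr,
                       trajectory=traj if keep_trajectory else None)


def run_sweep(model: GaitModelSpec | str, trials_per_mu: int = 5,
              base_seed: int = 0, grid: np.ndarray | None = None,
              config: RunConfig | None = None,
              progress: bool = False) -> SweepResult:
    """Run the full friction sweep for one gait model.

    Per-trial seeds derive deterministically from ``base_seed`` so any
    single trial can be reproduced in isolation.  Divergent trials are
    recorded as ``invalid`` rows without aborting the sweep.
    """
    if isinstance(model, str):
        model = build_gait_model(model)
    grid = mu_grid() if grid is None else np.asarray(grid, dtype=float)
    rows = []
    for mi, mu in enumerate(grid):
        for k in range(trials_per_mu):
            seed = trial_seed(base_seed, model.name, mi, k)
            res = run_trial(model, float(mu), seed, config=config)
            rows.append(dict(mu_s=float(mu), trial=k, seed=seed,
                             outcome=res.outcome,
                             fall_x=res.fall_x, fall_t=res.fall_t,
                             max_traction=res.max_traction))
            if progress:
                print(f"  mu={mu:.2f} trial {k}: {res.outcome}", flush=True)
    return SweepResult(model.name, pd.DataFrame(rows))
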