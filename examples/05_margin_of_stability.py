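"""Margin-of-stability (MOS) analysis of a synthetic walk.

The extrapolated centre of mass XCoM = X + V/sqrt(g/l) is compared
against the base-of-support borders: anterior (leading toe) and
posterior (trailing heel).  Positive margins mean the body's extrapolated
state stays over the feet; a negative anterior margin signals forward
instability (trip direction), a negative posterior margin backward
instability (slip direction).
"""

from gaitfall import (FixtureSpec, make_kinematic_walker, detect_gait_events,
                      compute_mos)

traj, _ = make_kinematic_walker(FixtureSpec(seed=3, noise_sd=0.02))
events = detect_gait_events(traj)
mos = compute_mos(traj, events)   # pendulum length re-estimated per step

mins = mos.step_minima
print(mins.head(8).to_string(index=False,
                             float_format=lambda v: f"{v:7.3f}"))
print(f"\nsamples: {len(mos.t)}; effective pendulum length "
      f"{mos.l_eff.mean():.2f} m (stance ankle to CoM at mid-stance)")
print("the posterior minima stay positive: the walk is backward-stable "
      "(no slip risk); anterior minima are negative in normal gait — "
      "forward progression is a controlled fall resolved by the next "
      "step — and a sharp further drop marks trip-type instability")
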