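"""Run one walking trial of the young-adult model and print what happened.

Builds the young-adult gait parameterization and walks it 15 m with the
static friction coefficient left unset (the baseline protocol used to
characterize each gait model), then prints the trial outcome plus basic
gait numbers.
"""

from gaitfall import (RunConfig, build_cpg_parameters, build_gait_model,
                      simulate_trial, detect_gait_events, stride_metrics)

spec = build_gait_model("young")
params = build_cpg_parameters(spec)
config = RunConfig()          # mu_s=None: friction never set

traj, status = simulate_trial(params, config, seed=1)
print(f"run ended: {status.label} after {status.t_end:.1f} s at x = {status.x_end:.2f} m")

events = detect_gait_events(traj)
strides = stride_metrics(traj, events)
if strides:
    mean_sl = sum(s.stride_length for s in strides) / len(strides)
    mean_v = sum(s.walking_speed for s in strides) / len(strides)
    print(f"{len(strides)} strides; mean stride length {mean_sl:.2f} m, "
          f"mean speed {mean_v:.2f} m/s")
    print("(stride length is the right-toe displacement between successive "
          "right-foot touchdowns; speed = stride length / stride time)")
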