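# gaitfall

Planar neuromusculoskeletal gait simulation and slip/trip fall-risk
analysis.

## What this is for

How slippery — or how grippy — can a floor be before people fall?  Low
friction causes slip-induced falls; there is also clinical evidence that
*excessive* friction can cause trip-induced falls in older adults whose
gait has low foot clearance.  `gaitfall` studies this computationally: a
two-dimensional walking model whose gait *emerges* from the interaction
of a rigid-body skeleton, a network of neural oscillators and the
ground, is walked over floors with a settable static friction
coefficient μs, and every trial is automatically classified as no fall,
slip-induced fall or trip-induced fall.  Because the model parameters
can be aged — lower tonic drive, different oscillator time-constant
ratios, weaker muscle-transfer coefficients — the same pipeline compares
a young adult, an elderly non-faller and an elderly faller under
identical floor conditions.

The intended users are biomechanics and motor-control researchers who
want a reproducible sandbox for friction/fall experiments that would be
unsafe or impractical with human subjects.

## The model in brief

* **Skeleton** — 8 segments (HAT, pelvis, thighs, shanks, feet), 7 pin
  joints, 70 kg / 1.8 m, planar redundant-coordinate dynamics
  `M q̈ = Q + Jᵀλ` with joint constraint forces solved per step
  (Baumgarte-stabilized KKT system), integrated by fixed-step RK4 at
  dt = 2·10⁻⁴ s.
* **Ground** — four contact points (heels, toes) on spring–damper
  ground (k_gx = 27 kN/m, k_gy = 18 kN/m, b_gx = 2250, b_gy = 1000
  N·s/m), with the Coulomb cap |F_gx| ≤ μs·F_gy wherever μs is set.
  Sliding is emergent once the cap saturates.
* **Controller** — 14 Matsuoka neurons (one flexor/extensor oscillator
  per joint): τ u̇ = −u − β f(v) + Σ w f(u) + u0 + S, τ' v̇ = −v + f(u),
  f(u) = max(0, u), with load- and posture-dependent feedback S and 18
  torque transfer channels p_k.
* **Gait models** — `young` (u0 = 7.08, τ/τ' = 0.036, noise 8.5 %),
  `elderly_nonfaller` (5.16, 0.100, 2 %), `elderly_faller` (5.10,
  0.076, 0.1 %, reduced p_k).
* **Analysis** — stride length, walking speed, cadence, min/max foot
  clearance and their CVs over 10 strides; SL_FC (stride length /
  minimum foot clearance); margins of stability from the extrapolated
  CoM (XCoM = X + V/√(g/l)) against the toe/heel base-of-support
  borders; per-stance maxima of the traction ratio |F_gx|/F_gy; and the
  slip/trip fall classifier (fall = hip below 0.70 m in the 5–15 m
  window; slip = loaded foot faster than 0.3 m/s).

See `docs/methods.md` for the full account, including every numerical
and design choice.

## A worked example

`examples/02_gait_metrics_on_fixtures.py` builds a synthetic walker
with known ground truth and runs the metrics pipeline over it:

```
programmed:  stride 1.300 m, speed 1.200 m/s, min clearance 18.0 mm, noise SD 5%
recovered :  stride 1.294 m (CV 5.0%), speed 1.194 m/s, min clearance 18.0 mm
SL_FC (stride length / min foot clearance) = 71.9
```

The recovered means match the programmed gait to a fraction of a
percent and the stride-length CV reproduces the injected 5 % per-stride
noise; SL_FC is the slip-risk indicator used to compare gait models.
`examples/03_fall_classification.py` shows the classifier recovering
scripted slip/trip/no-fall outcomes:

```
scripted no_fall    -> classified no_fall
scripted slip_fall  -> classified slip_fall at x = 6.5 m (backward)
scripted trip_fall  -> classified trip_fall at x = 7.0 m (forward)
```

The other examples run a single simulated trial
(`examples/01_single_trial.py`, which prints
`run ended: finished after 14.7 s at x = 15.20 m` followed by the
stride summary of the emergent gait), a reduced friction sweep, and a
margin-of-stability analysis.  A thin CLI wraps the same library calls:

```
gaitfall simulate --model young --mu 0.3 --seed 1 --out walk.tsv
gaitfall metrics walk.tsv
gaitfall sweep --model elderly_faller --seed 1 --out sweep.tsv
gaitfall plot walk.tsv --out stick.png
```

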