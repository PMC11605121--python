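# Methods

## The model

`gaitfall` simulates planar (sagittal-plane) bipedal walking with a
neuromusculoskeletal model in the Taga tradition: gait is not prescribed
as joint trajectories but emerges from the interaction of three coupled
systems — a rigid-body skeleton, a network of neural oscillators, and
the ground.

### Skeleton

Eight rigid segments — head–arms–trunk (HAT), pelvis, and left/right
thighs, shanks and feet — are connected by seven pin joints (trunk,
hips, knees, ankles; the two hip joints coincide at the bottom of the
pelvis segment).  Total mass is 70 kg and standing height 1.8 m; the
partition into segment masses, lengths, centre-of-mass offsets and
moments of inertia follows Winter-style proportional tables, with the
trunk split into a pelvis segment (14.2 % of body mass, 0.05 H long) and
a HAT segment.  All segment parameters scale linearly with the totals
(inertias as mass × length²).

Dynamics use redundant coordinates — each segment carries (x, y, θ) —
with the 14 joint-coincidence constraints enforced through a
saddle-point (KKT) solve that yields accelerations and joint constraint
forces simultaneously.  Baumgarte stabilization (critically damped,
α = 400 s⁻¹) bounds constraint drift; joint residuals stay below 1 µm
over full trials.  The production integrator is a fused, numba-compiled
classical RK4 loop at dt = 2·10⁻⁴ s (the ~27 kN/m ground springs set
the fastest time scale); a readable numpy reference path implements the
same step and is pinned to the fused loop by test.

### Ground contact

The feet touch the ground at four points (left/right heel and toe).
Each point in contact is tethered to the horizontal position where the
contact episode began (its anchor) by a spring–damper
(k_gx = 27 000 N/m, b_gx = 2250 N·s/m) and supported vertically by a
one-sided spring–damper (k_gy = 18 000 N/m, b_gy = 1000 N·s/m; the
damper only resists downward motion, so the ground never pulls).  Both
forces are scaled by an indicator ramping 0→1 over the first centimetre
of penetration, keeping the vector field continuous at touchdown.

Static friction is a cap: wherever a coefficient μs is set, the shear
force is clamped to ±μs·F_gy.  Before the 5 m switch point μs is unset
and shear is unlimited.  Sliding is emergent — a capped contact simply
stops resisting horizontal motion; the anchor is not dragged along
during a slide.

### Neural rhythm generation

Each joint hosts a two-neuron Matsuoka oscillator (14 neurons total,
flexor/extensor per joint):

    τ  du/dt = −u − β f(v) + Σ_j w_ij f(u_j) + u0 + S_i
    τ' dv/dt = −v + f(u),        f(u) = max(0, u)

with β = 2.5, mutual inhibition −2 within each pair, left–right
inhibition −1 between the hip oscillators and descending excitation
+0.6 from each hip neuron to the ipsilateral knee and ankle neuron of
the same function.  The ratio τ/τ' is a gait-model parameter; the
absolute τ sets the cadence and is calibrated per model (the free-pair
period is proportional to τ at fixed ratio).

White noise enters through the tonic drive: each integration step draws
u0·(1 + (noise%/100)·ε) with a single standard-normal ε shared by all
neurons.

### From neurons to torques

Rectified neuron outputs reach the seven joints through 18 weighted
channels with transfer coefficients p_k (Table-style values fixed per
gait model).  Channels may be load-gated — scaled by the fraction of
body weight on the ipsilateral (or contralateral) foot, saturating at
250 N — which lets the same oscillator drive stance support and swing
shaping with different gains.  The channel map (which neuron, joint,
sign, gate and weight each channel uses) is the package's calibration
and ships in `src/gaitfall/params/cpg_default.yaml`.  The channels whose
p_k values are most strongly reduced in the elderly-faller
parameterization are assigned swing-shaping roles (swing hip flexion,
swing knee flexion, swing dorsiflexion, pre-swing hip pull), which is
what lowers that model's stride and foot clearance.

Passive joint torques are viscoelastic stops: light always-on viscosity
(3 N·m·s/rad) plus a stiff spring–damper (4000 N·m/rad, 150 N·m·s/rad)
beyond the physiological range.  The knee stop at full extension is
what lets the stance leg bear weight economically; the trunk joint stops
are deliberately narrow (±0.10 rad), making the pelvis–HAT assembly
near-rigid — torso attitude is controlled through the hips, as in most
planar walker models.

### Sensory feedback

The feedback S_i implements the classic entrainment and balance
pathways of oscillator-driven walkers, all left/right mirror-symmetric:

* trunk and pelvis verticality error to the trunk and hip neurons
  (forward lean recruits extensors), plus pelvis pitch-rate damping;
* the inter-thigh angle and the load difference between the feet to the
  hip pairs (swing the unloaded, trailing leg forward);
* own-side load to the knee extensor and plantarflexor (stance
  support and push-off against a forward-rolled shank), unloading to
  the knee flexor and dorsiflexor (swing shaping and toe clearance);
* a bidirectional stance ankle strategy (plantarflex against forward
  shank roll, dorsiflex against backward lean);
* a late-swing retraction reflex: once an unloaded thigh passes a
  forward threshold the hip and knee extensors are recruited, capping
  the stride and straightening the leg for landing.  The threshold
  grows with CoM velocity (capture-point-style foot placement), which
  is how the walker regulates its speed.

## Gait models

Three parameterizations differ only in the tonic drive u0, the ratio
τ/τ', the 18 transfer coefficients and the noise level:

| model              | u0   | τ/τ'  | noise (% u0) | p_k     |
|--------------------|------|-------|--------------|---------|
| young              | 7.08 | 0.036 | 8.50         | base    |
| elderly_nonfaller  | 5.16 | 0.100 | 2.00         | base    |
| elderly_faller     | 5.10 | 0.076 | 0.100        | reduced |

## Protocol and classification

A trial starts from a frozen mid-step posture (stance right leg,
trailing left leg with flexed knee, forward CoM speed) and walks toward
15 m.  μs is unset for the first 5 m and applied beyond.  Within the
5–15 m window: a fall is a hip-height (hip-joint centre) drop below
0.70 m; a slip is a loaded foot moving faster than 0.3 m/s for at least
10 ms; a fall is slip-induced if such sliding preceded it and
trip-induced if it is forward without sliding.  Fall direction is
decided at the threshold crossing by comparing the extrapolated CoM
(XCoM = X + V/√(g/l)) against the base-of-support borders, tie-broken
by CoM velocity sign; a backward fall without detected sliding is also
labelled slip-induced, since backward imbalance on level ground has no
other mechanism here.  Trials that diverge numerically are retried once
at dt/2 and otherwise marked invalid — never silently classified.

The sweep runs 5 seeded trials per μs over the grid {0.05…0.50 step
0.05} ∪ {0.60…2.00 step 0.10} (125 trials per model); per-trial seeds
derive deterministically from the base seed, the model name and the
grid/trial indices, so any single trial is reproducible in isolation.

## Metrics

Gait events come from vertical-GRF threshold crossings (1 N, 10 ms
debounce).  Stride length is the right-toe displacement between
consecutive right-foot touchdowns; speed = stride length / stride time;
cadence = 1/stride time.  Minimum (toe) and maximum (heel) foot
clearances are extrema over the mid-swing window, taken as the middle
tercile of each swing by time.  Summaries (mean, CV) use 10 consecutive
strides with the sample (n−1) standard deviation; SL_FC divides mean
stride length by mean *minimum* clearance.  The effective pendulum
length for XCoM is re-estimated each step as the stance-ankle-to-CoM
distance at mid-stance.  Traction ratios |F_gx|/F_gy exclude samples
with F_gy ≤ 1 N (the ratio is undefined at contact onset).

## Synthetic fixtures

The metrics and classification layers are validated against kinematic
fixtures: periodic toe/heel/hip/CoM traces with programmed stride
length, speed, duty factor and clearances, piecewise-sinusoidal swing
paths whose mid-swing extrema are analytic, square-wave vertical forces,
and optional scripted slip/trip falls.  Fixtures share the trajectory
schema with simulator output, so the analysis code cannot tell them
apart.  They are kinematic only — no force is consistent with any mass
— so passing metrics tests on fixtures validates the *analysis*, not
the dynamics; the dynamics layer has its own oracle tests
(minimal-coordinate Lagrangian comparison, energy/momentum
conservation, convergence order).

## Numerical choices and degenerate inputs

* KKT systems are solved per stage; the fast path uses the Schur
  complement of the diagonal mass matrix (14×14 SPD solve).
* Contact anchors, flags and the noisy u0 are held constant within an
  RK4 step and updated between steps; trials are bitwise reproducible
  from their seed.
* A trajectory that neither covers the assessment window nor ends in a
  fall raises an insufficient-data error; time-reversed walks are
  rejected by the stride extractor (negative displacement).
* Classifier labels are exhaustive and exclusive over completed trials.

## Problem sizes

The test suite runs the dynamics only at short horizons (≤ a few
seconds) and reduced grids; the acceptance script runs the low-friction
half of the grid (μs ≤ 0.50, 5 trials per value) for the young and
elderly-faller models, which is where the slip and first-trip
thresholds live.  The full 3-model × 125-trial sweep is a long-running
check reachable through `gaitfall sweep`.

## Known limitations

* Sagittal plane only; no mediolateral balance.
* No compensatory feedback to large disturbances beyond the reflex
  pathways above; responses to slips/trips are purely emergent.
* The walker cannot stand quietly: the tonic drive keeps the oscillator
  network active, so "standing" is marching in place.  Static-load
  checks therefore use time-averaged (impulse-balance) ground forces.
* The gait limit cycle depends on a hand-plus-search calibrated channel
  map and feedback gains; these ship frozen in the parameter file, and
  the calibration quality bounds how closely the published group means
  are reproduced.  The stable limit cycle found by the calibration walks
  with a higher cadence and shorter strides than human gait (the
  acceptance tests report the exact values): group *orderings* of
  stride length, speed and clearance reproduce correctly across the
  three models, and the slip-fall versus no-fall transition with
  friction is reproduced, but the slip threshold sits higher than the
  published one and the faller model's swing clearance never gets low
  enough to scuff, so no trip-induced falls occur.  The per-model
  absolute τ values ended up small (high cadence) because that is where
  the search found stability; the τ/τ' ratios are exactly the published
  ones.
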