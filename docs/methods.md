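# Methods

This note documents the models, parameter choices and numerical details
behind `gaitcue`, and what the synthetic experiments do and do not show.

## Signal model and units

All components share one session clock starting at 0 s. Public units are
seconds, m/s², °/s and degrees. The inertial stream emulates a 200 Hz
foot-mounted 6-axis MEMS sensor with ±16 g and ±2000 °/s ranges; streams
are validated against these ranges and against strict timestamp
monotonicity (median sample interval within 1 % of nominal).

The sensor frame is x-forward (toe), y-left, z-up; orientation is the
body→global rotation R = Rz(ψ)·Ry(−θ) with yaw ψ, toe-up pitch θ and
roll ≈ 0. The accelerometer measures specific force Rᵀ(p̈ + g ẑ) with
g = 9.80665 m/s².

## Synthetic gait generator

Each swing is a smooth, twice-differentiable trajectory:

* forward displacement: minimum-jerk profile s(τ) = L(10τ³ − 15τ⁴ + 6τ⁵),
  τ ∈ [0, 1], so velocity and acceleration vanish at both ends;
* foot pitch: θ(τ) = −A·sin(2πτ)·sin²(πτ) (normalized to peak A), which
  dips negative after toe-off (plantar-flexion) and rises positive before
  heel strike, with zero angle *and* zero rate at both ends — signal
  energy ramps smoothly in and out of the motion phase;
* ground clearance: sin²(πτ) bump (4 cm for a nominal stride);
* pivot turns: per-stride yaw increments with a smoothed ramp
  ψ(τ) ∝ τ − sin(2πτ)/2π (no magnetometer is modeled, so turning truth is
  expressed per-stride, not as absolute heading).

Body rates follow from the Euler rates (ω_x = ψ̇ sin θ, ω_y = −θ̇,
ω_z = ψ̇ cos θ); accelerometer readings are the specific force rotated
into the sensor frame; derivatives are taken numerically on the 200 Hz
grid (second-order central differences), which keeps the generated
signals self-consistent: double integration of the noise-free
gravity-free acceleration over a swing recovers the programmed stride
length to ≈0.1 %.

Defaults (config-exposed): stride 1.2 m, cadence 1 Hz, swing duty 40 %
of the stride interval (0.4 s at nominal cadence — long enough that peak
accelerations stay well inside ±16 g), foot lift 20°. FoG subtypes:

* *shuffling* — stride ≤ 0.25 m with foot lift < 5°;
* *festination* — stride length shrinking geometrically (ratio 0.85) with
  cadence growing 1.1×/stride, capped at 2.5 Hz;
* *trembling* — heel-lift micro-phases (0.3 s, 8° lift) carrying a 5 Hz
  pitch oscillation (4°), separated by quiet gaps at 0.7 s period;
* *akinesia* — no movement at all, hence no motion phases (step-based
  detection is blind to it by construction; the rhythmic open-loop mode
  exists for exactly this case).

Noise: white Gaussian, σ_acc = 0.15 m/s² and σ_gyr = 1.5 °/s per axis
(typical consumer MEMS), plus a constant per-trial gyro bias drawn
U(−0.5, 0.5) °/s. Ground truth records every programmed swing as an
annotated motion phase and covers each non-normal segment with one FoG
episode, standing in for expert video annotation.

Cohorts draw subject-level parameters once per subject (stride
1.0–1.4 m, cadence 0.8–1.2 Hz, lift 15–25°, shuffle stride 0.12–0.25 m)
and trial noise independently; the default trial is a ~60 s mix of
straight walking, shuffling, trembling, festination, a 180° turn and a
short akinetic episode.

**What the generator does not emulate:** soft-tissue and mounting
artifacts, heteroscedastic or colored sensor noise, magnetic disturbance,
gait variability within a segment, double-support dynamics, or any
physiological response to stimulation. Detection and classification
results on this data demonstrate internal consistency of the pipeline —
that the algorithms recover what the kinematic model encodes — not
clinical performance. Real-patient detection rates and classifier metrics
cannot be reproduced from synthetic data, and the near-perfect synthetic
separability of FoG subtypes (by construction: stride length and foot
lift differ strongly) should be read accordingly.

## Orientation estimation

A complementary filter: gyro quaternion integration (axis-angle per
sample) corrected toward the accelerometer inclination in roll and pitch
with gain 0.02 per sample (time constant 0.25 s at 200 Hz); yaw is
gyro-integrated and drifts, so all turning quantities are per-phase
relative angles. The correction is *gated* on quasi-static conditions:
|‖a‖ − g| < 0.5 m/s² **and** ‖ω‖ < 20 °/s. The rate gate matters: a
lateral acceleration perpendicular to gravity barely changes the
accelerometer norm, so a norm-only gate corrupts roll/pitch during pivot
turns. An all-zero accelerometer at startup is a degenerate-inclination
error.

## Phase detection

A causal per-sample state machine (identical code drives the batch and
streaming entry points, so both produce the same phase list):

* **rest** — ‖ω‖ < 10 °/s and gravity-free ‖a_g‖ < 0.6 m/s² sustained
  100 ms; exit hysteresis at 1.5× the entry band so single noise
  outliers do not fragment rest intervals;
* **motion** (sub-phase of unrest) — opens when ‖ω‖ > 50 °/s or the pitch
  excursion from the rest posture exceeds 3° (toe-off proxy); closes
  after both fall below half their thresholds for a 35 ms dwell
  (heel-strike proxy); the phase end is stamped at dwell completion.
  Phases whose active part (quiet onset − start) is shorter than 60 ms
  are discarded.

The 35 ms close dwell (rather than 50 ms) keeps the median end-detection
delay below the median start delay while both stay non-negative — the
start of a swing is intrinsically harder to detect than its end because
the opening threshold is crossed later in the energy ramp than the
closing threshold is re-crossed. With the default profile this yields
median start ≈ 20 ms, end ≈ 10 ms, and slightly negative duration
differences (detected phases shorter than annotated ones).

Thresholds were chosen so that shuffling (small foot lift, high pitch
rate) and trembling micro-lifts are detected while rest noise is
rejected; they are validated by the cohort detection-rate property
rather than tuned per trial. Tie-break: a sample inside an open motion
phase is labeled motion even if the rest condition momentarily holds.

## Feature extraction

Computed strictly from samples up to the phase end (causal). Velocity is
integrated from the last rest sample before the phase (zero-velocity
anchor; searched up to 5 s back — otherwise the vector is flagged
degraded and integration starts at the phase start), then linearly
de-trended so it returns exactly to zero at the phase end — the standard
pedestrian dead-reckoning drift correction. Stride length is the norm of
the horizontal displacement over the phase; "transverse plane" is the
global horizontal plane after gravity alignment and stride velocity is
the horizontal speed. Turning angle is the unwrapped yaw difference over
the phase; the turned flag fires above |22.5°| (half of a 45° pivot
step, so pivot steps are flagged but gait-line wander is not;
configurable). Pitch is toe-up positive. Whether stride length should
span the motion phase only or the full rest-to-rest cycle is ambiguous
in step-based pipelines; the phase-only convention is implemented.

## Classifier

Discrete SAMME with scikit-learn decision trees (depth ≤ 3) as weak
learners, 10 estimators, learning rate 1. The score of a phase is the
weighted fraction of weak-learner votes for the FoG class; the label
threshold defaults to 0.5 (the operating point is configurable; no
tuning is performed). No class reweighting by default; a balance flag
exists. Models serialize to JSON as raw tree arrays plus vote weights
and predict without scikit-learn after loading. AUC is computed from the
continuous vote score by rank statistic. LOSO folds with a single-class
training set are skipped with a warning; folds with a single-class test
set contribute no AUC. Aggregation is mean ± sd over folds plus totals
from the summed confusion matrix.

## Cueing controller

Runs on an integer-millisecond clock (events are shifted by the
configured transport latency, default 7.5 ms, and quantized to 1 ms —
mirroring typical sensor/stimulator synchronization accuracy). Rules:

* a FoG-classified phase end opens an on-demand interval ending
  t_AGSC,on (default 5 s) later, or extends an active one (extension
  never shortens the end);
* while an interval is active (strictly before its end), each motion
  start opens a pulse train unless within t_off (default 0.1 s) of the
  previous train's end;
* at the motion end the train closes at max(start + t_min, end), capped
  at start + t_max; t_min = 0.2 s, t_max = 0.8 s;
* the interval-*opening* phase is classified only at its end, so
  onset-locked cueing of that first phase is causally impossible; it is
  cued retroactively with a t_min train starting at the classification
  instant (disable with `cue_triggering_phase=False`).

t_AGSC,on = 5 s keeps an episode covered across typical inter-stride
intervals (~1 s) without cueing long after gait normalizes; t_off stays
below the shortest plausible inter-phase gap. The controller is verified
to agree *exactly* (train lists and interval unions) with an independent
1 ms rasterized timeline simulator on thousands of randomized sessions.
The rhythmic fallback emits duty·period trains (lengthened to t_min with
a warning if shorter) from start to stop.

## Evaluation

Interval overlap is half-open [start, end): a shared endpoint is not an
overlap (avoids double matching at boundaries). An annotated phase is
correctly detected iff some detected phase overlaps it exclusively
(touching no other annotated phase); among several exclusive matches the
earliest by start time is the match and the rest are neglected; detected
phases touching zero or ≥ 2 annotated phases count once as false
detections. Delays are detected − annotated per matched pair. Coverage
restricts to the union of on-demand intervals and reports the stimulated
shares of motion-phase and non-motion time by exact interval arithmetic
(agrees with a 1 ms rasterization within 0.1 pp). Detected phases
inherit FoG truth from the episode containing their end time (start
inclusive, end exclusive). Printed percentages are rounded half-up to
one decimal; per-subject percentage aggregation is the arithmetic mean.

## Problem sizes

The default experiment sizes — a 20-subject cohort of ~60 s trials for
the detection-rate and LOSO properties, 1000 randomized ~15 s sessions
for controller/oracle equivalence, 200 random instances for matching
oracles — were chosen so the whole suite and the acceptance script each
complete in well under a minute on a laptop-class single core while
leaving the stochastic margins wide (the detection-rate and AUC
properties pass with ≥ 5-point margins across seeds).

## Known limitations

* Single foot only; no bilateral detection or multi-sensor gait analysis.
* Akinesia is undetectable by design (no step, no classification); only
  the programmatically triggered rhythmic mode addresses it.
* Yaw drift is unmodeled beyond gyro bias; absolute heading is never
  used, only per-phase turning.
* The classifier's synthetic performance ceiling says nothing about
  patient data (see the generator caveats above).
* Stimulation is metadata (channel, amplitude, pulse width, frequency
  validated against 1–5, ≤ 100 mA, 30–1000 µs, 1–100 Hz); no waveform
  synthesis or electrode/skin physics.
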