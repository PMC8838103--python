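# Methods

This note documents the models, parameter choices, and numerical
decisions behind `walkdist`, and what the simulator-based tests do and
do not demonstrate about real recordings.

## Sensor model and units

A recording is one foot's uniformly sampled stream of body-frame
triaxial accelerometer (gravity-inclusive specific force) and gyroscope
signals. Canonical units are m/s² and rad/s; readers convert declared
`g` / `deg/s` data on ingest, because gravity subtraction requires
absolute acceleration units. The nominal rate is 128 Hz. Timestamp
jitter above 10% of the nominal period must be repaired with
`resample_uniform` (linear interpolation) before the fixed-step
integrators run. Magnetometer channels are not used: heading is
unobservable and unnecessary — per-stride chord lengths are invariant to
any global yaw, a property the tests exercise directly.

## Orientation filter

A gated complementary filter tracks the body→Earth quaternion (Hamilton
convention, scalar-first, passive; Earth z up, x/y arbitrary per
recording):

* **Propagation** — exponential-map quaternion update using the
  midpoint (trapezoidal) gyro sample over each step. Midpoint sampling
  matters: left-sample propagation leaves an orientation ripple of
  ~1e-2 rad·s⁻¹-scale error that dominates the gravity-residual budget.
* **Correction** — proportional pull (gain `kp`, default 0.5 s⁻¹) of
  the estimated up direction toward the measured accelerometer
  direction, applied only on *quasi-static* samples: accelerometer
  magnitude within [0.9 g, 1.1 g] **and** gyro magnitude below
  0.3 rad/s, with both conditions required over a sliding 0.1 s
  window. The windowed test is essential — smooth swing onsets can
  satisfy both point conditions for a few samples while the foot
  accelerates at >1 m/s², and instantaneous gating lets those samples
  bend the tilt estimate by ~0.05°, an order of magnitude above the
  otherwise achievable error.
* **Initialization** — walking tests begin standing still, so the
  first 0.25 s supplies the initial tilt from the mean accelerometer
  vector; initial yaw is zero.
* **Gyro bias** — re-estimated per recording as the component-wise
  *median* of the gyroscope over detected stationary samples, then the
  filter is re-run once. The median, not the mean: slow-rotation tails
  of pivot turns (yaw rate still under the stationarity threshold) leak
  into the stationary mask, and averaging them in fabricates a yaw-rate
  bias that visibly corkscrews the reconstructed path.

g = 9.80665 m/s² throughout.

## Foot-flat detection

A sample is stationary when gyro magnitude < 0.5 rad/s and
| ‖accel‖ − g | < 0.5 m/s², both over a sliding 0.05 s window
(minimum-filter erosion). Runs become intervals; gaps shorter than
0.05 s are merged and intervals shorter than 0.05 s dropped. The
representative foot-flat time tᵢ is the interval midpoint — the foot is
still throughout, so any in-interval convention yields the same
position; the midpoint is symmetric and stable. Thresholds were fixed
against the simulator only; no external data informed them.

## Trajectory and distance

Trapezoidal double integration of Earth-frame free acceleration, with
the classic linear de-drift between stances: within each inter-stance
segment, velocity is re-referenced to zero at departure and a
linear-in-time ramp ending at the arrival residual is subtracted, so
velocity is exactly zero at both bounding stances; stance velocity is
pinned to zero. Position starts at the origin (only displacements
matter). Samples before the first and after the last stance carry
one-sided unbounded drift and are excluded from distance computations —
which use only positions at foot-flat times, read from the sample
nearest tᵢ (no sub-sample interpolation; the foot is still to first
order during stance).

Per-stride chords, per-foot totals, and the bilateral average are as in
the README. Turns are never excluded: there is no robust criterion for
delimiting them, and the chord geometry already under-counts lateral
wander conservatively. If per-foot totals disagree by more than 10%, a
quality warning is attached but the average is still reported. The
horizontal arc length ∫‖(vx, vy)‖ dt is implemented for comparison
only; it upper-bounds the chord total on every walk (swing-path
curvature) and is the rejected design for exactly that reason.

## Synthetic gait simulator

The simulator emulates the two walking-test protocols: fixed-distance
laps between cones 20 m apart (10 out-and-back laps = 400 m) and
fixed-time back-and-forth walking on a 15 m or 20 m walkway. It is a
*kinematic* model with closed-form derivatives, mapped through an exact
inverse sensor model (gyro = body-frame angular rate of R = Rz(ψ)·Ry(θ);
accel = Rᵀ(a_earth + g e_z) + bias + white noise), so every intermediate
pipeline quantity has an analytic ground truth.

Choices and defaults:

* Swing: minimum-jerk quintic horizontal displacement; vertical lift is
  a sin⁴ bump (apex 0.05 m). sin⁴ rather than a half-sine or sin²: the
  half-sine has nonzero boundary *velocity* (contradicting still
  stance) and sin² has nonzero boundary *acceleration*, which makes
  trapezoidal quadrature against the truth converge only at first
  order; sin⁴ is C² across stance boundaries. Sagittal foot pitch
  sin(2πu)·sin²(πu), amplitude 0.35 rad, zero angle and rate at the
  boundaries.
* Defaults: stride 1.3 m (snapped to divide the walkway evenly, so the
  straight-segment truth distance is exact), cadence 0.9 strides/s per
  foot, stance fraction 0.35 of the cycle — plausible fast-walk values;
  the protocols give no subject-level gait statistics, so these are
  literature-plausible, not protocol-derived. All are config-exposed.
* Both feet land at the same along-walkway stations, laterally offset
  by ±0.1 m (step width 0.2 m) and offset by half a cycle in time; each
  foot is processed independently downstream, so the simplification is
  invisible to the pipeline.
* Turns: `pivot` (default) rotates the heading by 180° during an
  extended stationary dwell (1 s, minimum-jerk yaw profile) — the foot
  does not translate, and the detector correctly splits the dwell
  around the rotation; `arc` takes 4 short strides bulging along a
  semicircle (radius 0.5 m) with the heading rotating through the
  swings. Lateral turn chords are counted in the truth exactly as the
  distance definition counts them.
* 2 s of quiet standing precede the walk (filter initialization) and
  1.5 s follow it. Noise is seeded `numpy` Gaussian white noise plus
  constant per-run biases; identical seeds give bitwise-identical
  recordings. An optional 4th-order 48 Hz low-pass emulates sensor
  bandwidth rolloff; it is off by default.

### What passing simulator tests shows — and does not

The simulator validates the *algorithmic* chain: orientation fidelity,
ZUPT detection, drift cancellation, chord bookkeeping, turn handling.
Its gait is smooth, periodic, and exactly zero-velocity during stance.
Real feet scuff, shuffle, vibrate at heel strike, bend at the forefoot
(violating the rigid-sensor assumption late in stance), and real
sensors saturate, alias, and drift with temperature. Simulated error
rates (≪1% under moderate noise) are therefore a lower bound of the
machinery, not a forecast of clinical accuracy, which published
validations of this class of algorithm place in the 2–4% range.

## Agreement statistics

Differences are `digital − manual` throughout (negative bias =
underestimation); published reports of this analysis are ambiguous
about direction, so the convention is fixed and stated in the output.
Bland–Altman: bias = mean difference, LOA = bias ± 1.96·SD (sample SD,
n−1); 95% CIs via the t distribution with SE(bias) = SD/√n and
SE(LOA) = √3·SD/√n — this convention reproduces the published CI widths
for these cohorts to 0.01 m, which is how it was selected over the
normal-quantile variant. ICC(2,1) (two-way random effects, absolute
agreement, single measure) is computed through `pingouin`
(`ICC(A,1)` in McGraw–Wong naming) with its exact F-based CI; the test
suite checks it against an independent ANOVA-from-sums oracle. ICC
requires ≥ 5 subjects and a non-constant ratings matrix; Bland–Altman
CIs require n ≥ 3 and nonzero variance; degenerate inputs are flagged
rather than silently extrapolated.

## Problem sizes

The test suite and acceptance script use 10-stride walks for
stage-level oracles, 2-length (40 m) walks for turn handling, and the
full 400 m protocol (≈8 minutes of 128 Hz data per foot) over 20 seeds
for the end-to-end error distribution — sizes at which every
stage-level tolerance is already binding while the whole run stays in
the tens of seconds.

## Known limitations

* Linear de-drifting assumes the velocity error grows linearly between
  stances; a Kalman ZUPT filter could replace it behind the same
  contract.
* No gait-event decomposition beyond foot-flat, no stair/run handling,
  no pathological gait phenotypes in the simulator.
* Heading is never observable; only distances, not routes, are
  trustworthy outputs.
* With one unusable foot the result falls back to the other foot with a
  warning; bilateral averaging cannot then suppress per-foot bias.
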