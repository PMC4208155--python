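# Methods

This note documents the models, conventions, parameter choices and known
limitations of `kneegait`.

## Frames and conventions

World frame: z up, x along the horizontal component of the magnetic
field (magnetic north), y completing a right-handed triad.  Quaternions
are scalar-last (x, y, z, w) and map sensor coordinates to world
coordinates.  In the simulator the standing pose is the identity for all
three segments, travel is along +x, and the mediolateral axis is +y.
Hip flexion (knee forward) is a rotation about −y, knee flexion (shank
folding backward relative to the thigh) a rotation about +y, so the knee
flexion axis is +y in both segment frames and flexion is positive when
the knee bends.  Pelvic tilt is positive leaning forward.

## Orientation fusion

The filter integrates the gyroscope exactly (quaternion exponential of
the per-sample body-rate increment; with `gain = 0` it is pure
closed-form integration) and applies normalized gradient-descent
correction steps toward the gravity and magnetic-field reference
directions, in the style of gradient-descent complementary filters.
The magnetometer enters through the reference-field trick (the reference
is rebuilt from the measured field's horizontal/vertical split at every
step), so it chiefly constrains heading and cannot be corrupted by
linear acceleration.

Corrections are *scheduled*, not always-on:

- A static-interval detector, computed from the raw signals only (over a
  0.25 s sliding window: max |ω| < 0.3 rad/s, specific-force standard
  deviation < 0.3 m/s², mean |a| within 10% of g), marks truly quiet
  samples — quiet standing, protocol rests, foot-flat instants.
- During static samples the full accelerometer + magnetometer correction
  runs at `static_gain` (default 10 × `gain` = 0.2 rad/s).
- During movement only the magnetometer correction runs (at `gain`,
  default 0.02 rad/s, and only below 1.5 rad/s angular rate).

Rationale: during gait, accelerometer samples whose magnitude happens to
be near 1 g are still dominated by linear acceleration of the leg
segments; feeding them to the filter produces a systematic differential
tilt drift between the thigh and shank estimates that directly biases
the knee angle by several degrees.  Restricting gravity corrections to
detected static intervals (the standard zero-velocity-update idea)
removes that bias while the rests interspersed through the test protocol
provide frequent re-anchoring.

Gyro bias is estimated as the pooled mean angular rate over all
quasi-static calibration captures (5 s standing + three 3 s supine
holds), refined with zero-rate updates from the static intervals
detected in the session itself, and subtracted before fusion.  Without
this, a realistic 0.003 rad/s fixed bias drifts the orientation by more
than 10° over a 100-m walk.  A residual bias of a few 10⁻⁴ rad/s
remains and is the dominant error source on multi-minute uninterrupted
walks.

Initialization assumes the first 0.5 s quasi-static (TRIAD from mean
accelerometer and magnetometer), which the protocol guarantees because
recording starts from quiet standing.

## Anatomical calibration

The flexion axis is the least-squares principal direction of the
rotation vectors of the pairwise relative thigh–shank rotations across
the three supine holds, computed in the shank frame (`Qᵢ⁻¹Qⱼ`) and the
thigh frame (`QⱼQᵢ⁻¹`), with the sign fixed so flexion increases from
the lowest to the highest nominal pose angle.  Poses whose total
rotation spread is below 20° are rejected as degenerate.  Nominal pose
angles default to 0°/45°/90° (user-configurable; the protocol does not
fix them).  The quasi-static gate is 0.05 rad/s gyro RMS.

The standing capture defines the zero-flexion relative orientation, the
pelvis neutral, and the planes: mediolateral = the flexion axis mapped
to world coordinates and projected to the horizontal; anteroposterior =
mediolateral × up.  Knee flexion at time t is the swing–twist angle of
`Q_stand⁻¹ Q(t)` about the axis — robust to ab/adduction cross-talk,
unlike a full Euler sequence, and exactly what a single-axis report
needs.  Pelvis tilt/obliquity are the pitch/roll of an intrinsic
yaw-pitch-roll decomposition in the anatomical frame, so they survive
the 180° turns of the TUG (heading lands in yaw).

## Event detection

The detection channel is the shank gyroscope projected on the calibrated
flexion axis, low-passed at 6 Hz (zero-phase) and sign-oriented so the
mid-swing forward swing is positive.  Heel strike = the first
negative-going zero crossing after each prominent mid-swing peak
(height ≥ 45% of the global maximum, ≥ 0.45 s apart); toe-off = the last
positive-going crossing before the peak.  The rule holds across walking,
running and stairs because the mid-swing shank rotation dominates at
every speed.  Intervals with fewer than four strides are rejected.

Single-leg support of the instrumented limb is approximated as the
12%–48% stride fraction (contralateral toe-off to contralateral heel
strike): with sensors on the affected leg only, contralateral events
are not observable and this inference is nominal-timing based.  The
stability amplitudes are therefore comparative quantities, not
validated stance-phase measurements.

Stair steps alternate feet, so time per staircase step is half the
interval between successive ipsilateral contacts.  A stairs interval
whose median knee flexion at contact is below 8° shows no stair-like
loading and is flagged low-confidence rather than silently analyzed.

TUG phases: the sit-to-stand transfer is the first sustained (≥ 0.8 s)
excursion of pelvic tilt beyond a 2° band around the seated baseline,
stand-to-sit the last; the turn is the dominant pelvic angular-rate
burst between them; walk phases fill the gaps.  The band-crossing
definition clips ~0.1 s off the true transfer duration for smooth
profiles; the recovery tolerance (±0.15 s) absorbs this.

## Metrics

- Spatiotemporal values are anchored to the surveyed path length:
  speed = path/duration; steps are counted from pelvic-obliquity zero
  crossings (two per stride), reported as duration divided by the mean
  step period (fractional, avoiding ±1 edge quantization); cadence =
  steps/duration × 60; step length = path/steps.  The identity
  step_length = 60·speed/cadence then holds exactly.
- The obliquity-crossing baseline is a rolling mid-range, not the mean:
  an asymmetric (time-warped) oscillation carries genuine DC which
  mean-subtraction would convert into a symmetric-ward bias of the
  step-timing symmetry index min(r, 1/r).
- Power of acceleration/deceleration: peak knee angular-velocity
  magnitude in the sprint sub-windows.  The split is derived from the
  smoothed pelvic angular-rate envelope — a forward-speed proxy — with
  the acceleration window ending at the envelope peak and the stopping
  window starting where the envelope last falls below 60% of it.  The
  published values are unitless; this package reports rad/s and treats
  only structure and direction as comparable.
- Stability amplitudes: per-stride peak of the shank gyro projected on
  the coronal (anteroposterior axis) and sagittal (flexion axis) plane
  normals within single-leg support, low-passed at 12 Hz, aggregated as
  the median over included strides (robust to single missteps);
  spatiotemporal aggregates use means, matching how cohort tables are
  reported.
- Fatigue: ordinary least-squares slope (deg/min) of per-stride
  peak-to-peak pelvic obliquity + tilt versus stride mid-time, on walk
  intervals of at least 60 s.
- First and last `n_exclude = 2` strides of every interval are flagged
  excluded (never dropped) before aggregation; the count is not fixed by
  the protocol description and is configurable.

## Outcome analysis

Delta = post − pre exactly; cohort means use patients with both
timepoints.  KSS bands: <60 poor, 60–69 fair, 70–79 good, ≥80
excellent; OKS bands: ≤19 poor, 20–29 fair, 30–39 good, ≥40 excellent —
the standard published bandings, which reproduce all 24 labels of the
bundled cohort.  Correlations default to Spearman (n = 6, ordinal
scores); no p-values and no multiplicity correction are reported at this
sample size — the correlations are descriptive.  Two known
inconsistencies inside the reference cohort's source material (prose
mean walking-speed delta +0.225 m/s and step-length delta +0.1 m vs the
table-derived 0.218 and 0.067; prose descending-flexion means vs the
table's) are resolved in favour of the tables, which this package
recomputes.

## The simulator — what it emulates and what it does not

The generator drives a pelvis–thigh–shank chain from stride-phase
waveforms: the knee is a sum of two raised-cosine bumps (stance bump,
default 15°, and a swing bump whose peak is exactly the configured
maximum); the shank forward lean is a periodic spline with a foot-flat
plateau in early stance and a forward-swing velocity peak whose zero
crossing lands exactly on integer stride phase (so true heel strikes are
well-defined); the thigh is shank lean + knee flexion.  Pelvic tilt,
obliquity and yaw oscillate at stride/step frequency; an optional
within-stride phase warp makes the two steps of a stride unequal
(step-timing asymmetry); `instability_gain` adds an 8 Hz coronal shank
wobble during single-leg support (3° amplitude per unit gain);
`fatigue_slope` grows the obliquity amplitude linearly in time.  Stairs
use a loaded-contact waveform (configurable flexion at contact and
maximum) plus a climb; the TUG repetition is framed by unannotated
sit-down/stand-up transitions so every activity segment starts and ends
in quiet standing (C¹ continuity across concatenation); the sprint ramps
cadence, holds, and collapses at a heel strike while a rapid stopping
flexion transient (45° over 0.5 s by default) plays out.

Sensors are rigidly mounted with fixed rotation offsets (the
misalignment calibration must recover) and lever arms (thigh and shank
units 20 cm from the joint line).  The gyroscope reports exact
zero-order-hold body rates plus a fixed random-direction bias
(0.003 rad/s) and white noise (0.01 rad/s); the accelerometer reports
sensor-frame gravity plus the linear acceleration of the attachment
point (second differences of the chain positions) plus white noise
(0.1 m/s², typical for the sensor class at 100 Hz); the magnetometer
sees a homogeneous field with a 60° dip and no disturbances.  Default
sampling rate 100 Hz.

Not modelled: soft-tissue artifact, magnetic disturbances, double
support of the contralateral limb (no contralateral sensor exists in
the setup), ground-reaction-driven stance dynamics (the chain hangs
from a constant-velocity pelvis, so stance-leg accelerations are
somewhat larger than in vivo), impacts, and sensor dropouts beyond the
gap policy.  Passing recovery tests therefore demonstrates the
correctness and noise robustness of the algorithm chain under an
idealized rigid-body signal model — not clinical accuracy on real
patients, which requires the validation studies the measurement approach
builds on.

## Problem sizes and numerics

Recovery studies use 20 sessions (60-m walk + one stair flight each way
+ one TUG repetition) with parameters drawn across the cohort's observed
ranges (cadence 100–126 steps/min, speed 0.9–1.7 m/s, stair step time
0.4–0.75 s, sit-to-stand 1.5–2.6 s, max flexion 44–71°), and 100 seeds
for the calibration Monte-Carlo.  Report rounding follows the cohort
tables' printed precision (speeds/lengths/times 2 dp, angles whole
degrees) with ties away from zero.  Event zero crossings are linearly
interpolated between samples.  Gap policy on load: linear interpolation
up to 10 consecutive missing samples and at most 1% missing overall,
otherwise the stream is rejected.
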