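# Methods

This note documents the model, the numerical choices, and what the
synthetic-data generator does and does not emulate.

## Load model

The vertical plantar load is the whole-body Newton balance of a
seven-rigid-link sagittal model,

N(t) = m_b (a_b + g) + Σ_i m_i (a_iR + a_iL + 2g),  g = 9.8 m/s²,

with all accelerations *dynamic* (gravity-free).  Gravity enters only
through the explicit g terms, which is the only reading under which quiet
standing returns exactly body weight; consequently every sensor-frame
acceleration has its static-window mean (the gravity projection plus sensor
bias) subtracted before the vertical transforms.  Loads are reported both
in newtons and in kilogram-force (kgf = N/9.8), the unit used for
thresholds.

Segment masses are anthropometric fractions of body mass, per side: foot
0.011, shank 0.051, thigh 0.110, upper body the remainder (0.656).  The
foot fraction reproduces the reported per-patient foot masses (105 kg →
1.155 → 1.2 kg; 55 kg → 0.605 → 0.6 kg at one decimal); the shank and thigh
values are standard adult values and only affect the weighting of the full
mode.  The table is configurable.

N is whole-body and is deliberately not apportioned between the feet during
double support: the load under one foot cannot exceed the total, so the
estimate never understates the forefoot load.  A `foot_only` mode sets all
non-foot dynamic terms to zero — the configuration available when patients
wear one sensor per shoe.  Its additive constant is immaterial because
accuracy is judged by correlation, which is shift/scale invariant.

## Filtering

All sensor channels (and force references) are low-pass filtered with a
4th-order, zero-lag, critically damped filter at 20 Hz.  Critical damping
(a repeated real pole) is chosen over Butterworth because gait-event
detection keys on zero crossings: ringing or overshoot around sharp
transients would create spurious crossings.

Realization: each pass cascades identical first-order sections
`(1−p)/(1−p z⁻¹)` and the filter is applied forward and backward (two
passes of order 2 → net order 4, zero phase).  The pole is *matched*
(positive real) rather than bilinear-transformed: at cutoffs that are a
large fraction of the sampling rate, the bilinear mapping of the
pass-corrected cutoff (20/0.435 ≈ 46 Hz at 100 Hz sampling) flips the pole
sign and produces ~5% step overshoot per pass, destroying the property the
filter is named for.  With the matched pole the impulse response is
nonnegative, so step responses are monotone with zero overshoot.  The
cutoff correction for the repeated poles and passes is exact: with
q = 2^(−1/order), the per-section pole solves
(1−q)p² − 2(1 − q cos w)p + (1−q) = 0 at the cutoff's digital frequency w,
placing the *net* −3 dB point exactly at the requested cutoff (verified:
|H|² = 0.70711 at 20 Hz, 0.9957 at 2 Hz, DC gain 1 to machine precision).

## Orientation and frames

Sensor frames: x is the medio-lateral pitch axis; y/z span the sagittal
plane.  The foot sensor's z-axis is the sole normal (tilt θ₃ = 0 with the
foot flat), thigh/shank/sacrum sensors have z along the segment's long axis
(θ = π/2 when vertical).  These are the only conventions under which the
two vertical-acceleration transforms reduce correctly in the static limits.
The sacrum is treated as a long segment for the trunk's vertical
acceleration — the model gives no separate trunk transform, and symmetry
with the thigh/shank transform is the natural completion.

Initial tilt comes from the gravity direction averaged over the first 1.0 s
of the recording, which is assumed stationary; tilt is then propagated by
trapezoidal integration of the pitch gyro.  For short (≤60 s) trials no
drift correction is applied.  For long free-living streams the integration
is re-anchored at every stationary interval (pitch-rate magnitude below
0.1 rad/s for at least 0.5 s): the tilt is reset to the accelerometer-derived
value there, bounding gyro drift by the interval between rests.

## Gait events

Heel contact: sign change of the offset-free filtered foot z-acceleration,
accepted only if ≥0.2 s has passed since the most recent *contralateral*
toe off.  Toe off: sign change of the filtered foot pitch angular velocity,
accepted only if ≥0.6 s has passed since the most recent *ipsilateral* heel
contact, keeping at most one TO per HC.

Conventions required to make the sign-change rules deterministic:

* the event timestamp is the later sample of the sign-change pair;
* a run of exact zeros entered from a nonzero sample yields one event at
  its first zero; a run that begins at the edge of the searched range
  yields none (no transition was observed);
* magnitudes at or below 10⁻⁹ of the channel's peak are treated as exact
  zeros, so filter residue in silent stretches cannot masquerade as
  crossings;
* the search starts at the end of the static initialization window (led by
  two samples so a liftoff exactly at the boundary keeps its sign-change
  pair), because offset-free signals hover at zero while the subject
  stands;
* the two feet are processed jointly in time order, and an HC candidate is
  additionally rejected while its foot still awaits a TO.  This alternation
  gate is the online form of the step invariant (between consecutive HCs of
  one foot lies exactly one TO) and is what discards the benign second
  crossing each gait cycle produces early in stance.

Midstance is taken to begin at the *contralateral* TO.  The source
description literally says the ipsilateral TO, but the ipsilateral TO is
the event that *ends* the forefoot window; only the contralateral reading
yields the ~0.6 s midstance-plus-push-off window the validation protocol
describes, so the contralateral reading is implemented.

Steps pair each HC with the following TO of the same foot and are screened
for plausibility: stance ≥ 0.4 s, swing ≥ 0.2 s, stance fraction of the
gait cycle within 60% ± 15%.  The minima and the band are conventional
values; the source calls them empirical without printing them.  A foot's
final step, which has no following HC, uses its preceding cycle as the
cycle-duration proxy.  Unpaired events at the stream edges are dropped and
counted.  Walking bouts split at gaps > 1.5 s between successive HCs
(just above the longest plausible cycle) and must last ≥ 30 s.

## Validation protocol

Per step, the Pearson coefficient is computed between the estimated FL and
the reference force trace over the forefoot window (~60 samples at 100 Hz).
The reference is the single channel among four with the largest peak in the
window (ties → lowest index); samples at the 40 N sensor limit are flagged
as saturated.  Corridor summaries exclude the first and last step and
average 30 steps; stair summaries exclude the last step and average 9.
Steps with zero variance in either trace are excluded with a logged reason.
Category bands on |r|: weak ≤ 0.35 < moderate ≤ 0.65 < strong ≤ 0.9 <
excellent (the published band table skips (0.65, 0.67]; the gap is closed
at 0.65, which changes no published classification).

Trials whose inter-sample intervals deviate from the nominal period by
more than 10% are excluded from validation; free-living recordings are
instead split at each gap and the chunks processed independently.

## Excessive forefoot load

The threshold is mean + 2·SD of the per-step maximum FL of the first 15
steps of a designated corridor trial, rounded to one decimal.  The SD uses
the population (n) denominator: with the printed baseline 1.5 ± 0.84 kgf
this gives round(3.18, 1) = 3.2 kgf, matching the published threshold for
the self-consistent patient.  For the other patient the printed values
7.0 ± 1.8 kgf give 10.6 kgf where 10.0 kgf was published; no mean+2SD
arithmetic produces 10.0 from those numbers, so the implementation keeps
the rule and documents the discrepancy rather than special-casing it.
A step is excessive iff its window maximum strictly exceeds the threshold
(exceedance is counted at step granularity, matching how the published
counts are phrased), and the rate is the rounded number of steps per
excessive event.

## Synthetic gait generator

The generator prescribes the trial and inverts the model, so every other
module can be tested against known ground truth:

* an event schedule for both feet (configurable cycle duration, stance
  fraction, step count) satisfying the 0.2 s/0.6 s detector constraints by
  construction, with gait initiation, terminal landings, and a standing
  lead-in/tail;
* per-foot loads: body weight × a smooth contact-share crossfade × a
  two-hump stance modulation (raised-sine humps at 25%/75% of stance,
  default peaks 1.2/1.1 body weight, midstance valley solved so the net
  vertical impulse over a cycle is zero).  The whole-body load N* is their
  sum; per-step excess is planted by scaling a step's modulation;
* foot z-acceleration: a one-harmonic waveform with exactly two zero
  crossings per cycle — downward at HC, upward early in stance where the
  timing rules discard it; foot pitch rate: three raised-sine lobes around
  each TO whose areas cancel so the tilt is cyclic;
* thigh/shank vertical accelerations are small sinusoids; the trunk's is
  *solved* from the Newton balance so the seven segments reproduce N*(t)
  exactly (closure to 1e-9 relative, by construction);
* vertical accelerations are mapped into sensor frames through the inverse
  transforms given the tilt series, plus the constant gravity projection at
  the initial tilt; sensor noise is additive white Gaussian from one seeded
  generator (bit-reproducible per seed);
* force references share `forefoot_coupling` (default 0.07) of N* across
  four channels with weights (0.4, 0.3, 0.2, 0.1) inside each forefoot
  window, tapered to zero outside, clipped at 40 N saturation;
* a `foot_dominated` variant routes each foot's load deviation from its
  quasi-static share through that foot's acceleration (with a swing lobe
  preserving the detector's crossing structure), so the foot-only mode's
  ability to track the load can be exercised; the default variant instead
  carries load variation in the trunk term, as in level walking;
* `simulate_daily_walk` concatenates bout trials with standing idle gaps;
  `inject_sampling_gaps` plants timestamp defects for the sampling screen.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: gravity is emitted as a constant projection at
the initial tilt (exact only because the pipeline's static-offset removal
assumes the same), soft-tissue artifact, axis misalignment, turning,
stairs and slopes, inter-step variability and asymmetry are absent, and
the force reference is proportional to the total load inside the window,
so noise-free correlations approach 1 by construction.  The simulator
demonstrates the pipeline's correctness and noise robustness, not the
field accuracy of the method, which on real corridor data was reported as
moderate (mean r ≈ 0.6).

## Problem sizes and numerical choices

Tests and the acceptance script use 100 Hz trials of 16-36 steps (~10-25 s)
and synthetic days of three bouts (~2 min total), sizes at which every
check runs in seconds while still exercising 30-step protocol summaries
and the 30 s bout rule.  Sensor-noise levels in the robustness checks are
0.5 m/s² (accelerometer) and 0.05 rad/s (gyro), conservative for modern
MEMS parts.  Rounding for reported kgf values is one decimal (Python
round-half-even, which reproduces all published roundings used).
Integration is trapezoidal throughout.  Reference-channel ties break to
the lowest index.  CSV floats are written at 10 significant digits, enough
for lossless round trips at test tolerances.

## Known limitations

Stair *descent* is out of scope (landing style varies too much between
people for a single zero-crossing rule); shear/horizontal load is not
modeled although it matters for callus formation; double-support load is
not apportioned between feet; correlation-based validation cannot certify
absolute accuracy in kgf, only waveform agreement.
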