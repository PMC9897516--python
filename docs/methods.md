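# Methods

`ppgbp` estimates systolic and diastolic blood pressure (SBP/DBP) from the
morphology of the photoplethysmogram (PPG) and evaluates both absolute
accuracy and the ability to track BP *changes*.  This note describes the
processing model, the synthetic cohort that stands in for clinical data, the
parameters that matter, and the numerical choices made where the design was
open.

## Signal model and preprocessing

A recording is a pair of uniformly sampled waveforms: a finger PPG (arbitrary
units) and an invasive arterial pressure (ABP, mmHg), optionally aligned by
normalized cross-correlation of their band-passed versions (the PPG pulse
lags the arterial pulse by a transit delay).

Preprocessing applies two 3rd-order Butterworth filters — low-pass 15 Hz and
high-pass 0.5 Hz — both forward-backward (`sosfiltfilt`), so the effective
magnitude response is the squared Butterworth response and the phase is
exactly zero.  Zero phase matters because downstream features are timings of
waveform landmarks; a causal filter's group delay would bias them.

The filtered record is cut into 20-s windows with 50% overlap (a T-second
record yields `floor((T-20)/10)+1` windows).  Beats are segmented at pulse
feet: the steepest upstroke is a peak of the first derivative (refractory
distance 0.24 s, adaptive prominence), and the foot is the waveform minimum
in the 0.3 s before it.  Inter-beat intervals outside 0.24–3.0 s
(20–250 bpm) are discarded.

Each beat, resampled to L = 256 samples foot-to-foot, receives a signal
quality index (SQI): the mean of (a) its Pearson correlation with the
recording's median-beat template and (b) the mean correlation with its
adjacent beats, each mapped from [-1, 1] to [0, 1].  One ensemble-average
(EA) pulse per window is the SQI-weighted mean beat; its heart rate is 60
over the median inter-beat interval, and its own SQI is the weighted mean of
beat SQIs.  L = 256 (power of two) preserves all content below the 15 Hz
cut-off at any physiologic heart rate.

The reference BP of a window is the median of per-beat SBP (beat maximum),
DBP (minimum) and MBP (mean) from the ABP.  A window survives gating iff the
EA-pulse SQI >= 0.75 and the per-beat variability (std/mean) of *both* the
SBP and DBP series is <= 0.10; requiring both series is the conservative
reading of "reference variability".  Windows touching non-finite samples are
always rejected.

## Pulse-wave analysis

The EA pulse's first three derivatives — velocity (VPG), acceleration (APG)
and jerk (JPG) plethysmograms — are estimated by Savitzky–Golay local
polynomial fits (window 9, order 4, `deriv=k` directly from the pulse).
Direct SG differentiation is used instead of cascaded finite differences
because cascading amplifies endpoint errors into the early pulse, exactly
where the APG a-wave sits; the SG estimate is exact for polynomials and
symmetric, so extremum timing is unbiased.

Fiducial points follow the standard PPG nomenclature:

* APG a–e waves: the first five alternating local extrema (max, min, max,
  min, max) after the foot;
* VPG w (global maximum = steepest upstroke), y (first local minimum after
  the systolic peak), z (next local maximum);
* JPG p0–p3: the first four alternating extrema;
* systolic peak (global PPG maximum), dicrotic notch (taken at the APG
  e-wave time, falling back to VPG z), diastolic peak (first PPG local
  maximum after the notch, with fallbacks for pulses whose e-wave lands
  after a pronounced early diastolic wave).

A greedy alternation walk (skip extrema of the wrong kind) makes the a–e
labelling robust to small ripples; a relative prominence floor of 1e-6
suppresses numerical noise.  Missing points on degenerate pulses simply stay
absent, and features that need them become missing; windows with missing
values are dropped from the learning tables.

Scalar features are computed on the foot-anchored pulse (waveform minus its
minimum, so amplitudes and areas are nonnegative as on a pressure pulse),
with notch time T_n and pulse duration T:

* MAP, MSBP, MDBP — means over [0, T], [0, T_n], [T_n, T];
* ESP — value at T_n; SPTI, DPTI — trapezoidal areas of the systolic and
  diastolic sub-intervals; SEVR = DPTI/SPTI (SPTI + DPTI equals the total
  area to quadrature accuracy);
* PI (perfusion index) = 100 x (half peak-to-peak amplitude) / DC, where DC
  is the mean of the *unfiltered* window (the high-pass removed it from the
  pulse, so the pipeline carries the raw window mean alongside each EA
  pulse);
* AIx75 — augmentation index 100 x (peak - inflection)/amplitude with the
  inflection at the APG d-wave time (configurable; the reflected-wave onset
  convention differs across instruments), linearly corrected to 75 bpm with
  0.48 %/bpm, the conventional slope;
* HR, plus the (t, a) coordinates of every fiducial point, and optionally
  the subject's age, weight, height and gender (0/1).

All amplitude features are in PPG signal units; the pipeline never converts
the optical signal to pressure, the regression models do that implicitly.

## Calibration pairing and the split

A calibration sample concatenates: the features of an earlier window, its
reference (SBP, DBP, MBP), the features of a later window, and the
demographics; the later window's reference is the target.  Every ordered
pair (i < j) of gated windows within a recording is used, with no upper
limit on the time span, so n valid windows give n(n-1)/2 samples and the
smallest span equals the 10-s stride.  The calibration-free variant uses one
sample per window (features + demographics).  Pairs where either window
failed gating are excluded (both-must-pass).

Subjects are split 80/20 at the subject level, stratified on per-subject
mean SBP: subjects are rank-binned into quartiles and sampled proportionally
within bins (largest-remainder quota so the test set is never empty);
candidate draws derived deterministically from the seed are accepted once
train/test mean SBP differ by less than half the pooled SD.  No subject ever
contributes to both sets; the split constructor asserts this.

## Feature selection, relevance, models

Selection is an L1-penalised (Lasso) regression on standardized features
(constants computed on training data only and frozen).  The penalty grid is
100 log-spaced values from the analytic lambda_max = max|X'y~|/n down to
1e-4 lambda_max, and the minimum-CV-MSE penalty is chosen with 10-fold
cross-validation whose folds never split a subject.  Minimum-MSE (rather
than the 1-SE rule) is used because the task benefits from fairly dense
selected sets.  On tables beyond 20k rows the CV runs on a seeded grouped
subsample and the final model is refit on everything.

Permutation relevance of a trained model on the held-out test set: permute
one feature across all test samples, re-predict, record the relative
increase of the error standard deviation (STDE); 100 repetitions per
feature, reported as mean ± sd and ranked descending (ties broken by
feature name).  The permutation stream for feature j is
`default_rng([seed, j])` with one `permutation(n)` per repetition — the
scheme is part of the API so the computation can be reproduced bit-exactly
by an independent loop.

Three estimators plus a control are trained per target (SBP and DBP get
separate models):

* **Lasso** — the selection machinery itself (grid CV penalty).
* **SVR** — RBF kernel; kernel width, box constraint C and epsilon-band
  tuned by a seeded Bayesian optimization (GP surrogate, expected
  improvement, 30 evaluations) of the subject-stratified 10-fold CV error in
  log-parameter space.
* **GPR** — squared-exponential kernel with one shared length-scale (ARD is
  deliberately off by default to limit overfitting) plus a linear
  (dot-product) component and a white-noise term; all kernel parameters
  including the noise level by marginal-likelihood maximisation with
  L-BFGS.  The linear component matters: the feature–BP relation is
  dominantly linear, and at the small training caps a lone shared-scale RBF
  cannot represent it.
* **Flat model** — the no-dynamics control: in calibration mode it predicts
  the calibration reference; calibration-free, the training-set mean.  Its
  STDE measures the BP variability of the data itself.

Kernel models do not scale to the ~10^5-row pair table on one core, so their
hyperparameter search uses an 800-row seeded subsample and the final fits
are capped at 3000 (SVR) / 1000 (GPR) rows; the Lasso trains on everything.
The caps are configuration options sized to single-core O(n^2)-O(n^3)
kernel-method cost; the acceptance script reports what the models achieve
under them.

## Evaluation

Absolute accuracy: ME (mean of estimate minus reference) and STDE (sample
standard deviation of that error), cohort-wise and per subject, on train and
test.

Trending ability: per test subject, the first gated window is the
calibration anchor and the model estimates every later window, giving an
estimated series next to the reference series.  All window pairs whose
reference change is at least 20% of the earlier value (boundary included;
the earlier window is the only causal baseline) become trend pairs, binned
into rapid (<= 3 min) and slow (> 3 min) spans.  The four-quadrant
concordance rate is the percentage of pairs whose changes agree in sign (a
zero estimated change counts as discordant unless the reference change is
also zero), alongside the Pearson correlation.  The polar view maps each
pair to radius (d_inv + d_est)/2 and angle atan2(d_est, d_inv) - 45 deg, the
deviation from the identity line; pairs with negative mean change are
mirrored through the origin (Critchley-style half-plane reflection) so
like-direction changes compare.  Reported: angular concordance at ±30 deg,
angular bias and SD, and 95% radial limits of agreement (bias ± 1.96 SD).

## The synthetic cohort

No public dataset pairs finger PPG with invasive ABP during anesthesia
induction at the needed quality, so the generator emulates one, and every
end-to-end claim in the test suite is relative to it.

**Trajectories.**  Each subject's SBP follows: baseline plateau, a logistic
induction drop of 20–45% (time constant 10–30 s, i.e. a 1–3 min transition)
starting at 25–45% of the recording, one to three Gaussian
vasopressor-like recovery bumps, and an AR(1) drift with 3 mmHg stationary
sd.  DBP follows with 80% of the relative drop and correlated drift, kept at
least 15 mmHg below SBP.  The per-subject *time-mean* SBP is drawn from
N(124.3, 24.8) clipped to [85, 200] mmHg (DBP: N(63.0, 10.4) on [42, 86]);
the plateau level is then solved so the realized recording mean equals the
draw, and the drop fraction is capped at 66/(mean+33) so per-subject SBP
standard deviations stay inside the 5–33 mmHg band observed in adult
surgical cohorts.  Recordings last 9–19 min at 125 Hz; 40 subjects by
default.

**Beats.**  Each beat is a sum of two Gaussians (systolic wave at 0.16 T,
diastolic/reflected wave near 0.45 T).  The closed-form link from (SBP, DBP,
HR) to shape parameters is deliberately simple and linear around the
120/63 mmHg operating point: higher SBP narrows the systolic wave
(-0.00015 fraction/mmHg), advances the reflected wave (-0.0009 /mmHg) and
grows its amplitude (+0.004 /mmHg, plus +0.003 per mmHg DBP); DBP widens the
diastolic wave (+0.0006 /mmHg); the overall AC amplitude shrinks with SBP
(-0.002 /mmHg), which plants a perfusion-index link.  Gaussians are
analytically differentiable, so every fiducial has a dense-grid closed-form
oracle, and the planted slopes are recoverable by regression — this is what
makes the selection and model tests well-posed.

**Inter-subject variability.**  Each subject adds random offsets to the
shape coefficients (sd: 0.003 systolic width, 0.012 reflected-wave timing,
0.05 reflected-wave amplitude, 0.008 diastolic width, all as fractions of
the beat period or unit amplitude) plus a log-normal PPG gain (sigma 0.15)
and a random DC level.  These offsets are the reason a calibration measure
helps: they shift the morphology–BP map per subject, are common to the
calibration and estimation segments of a pair, and cannot be learned from
demographics.

**Rendering.**  The PPG is DC + gain x beat pulses + 0.08 Hz baseline
wander + white noise (sd 2% of the AC amplitude), with 2% of beats replaced
by noise bursts to exercise SQI gating.  The ABP reuses each beat's shape,
rescaled per beat so its maximum/minimum equal the commanded SBP/DBP exactly
(then 0.05 mmHg measurement noise).  Everything derives from
`default_rng([seed, subject])` streams, so cohorts are bit-reproducible.

**What the generator does not emulate** — and hence what passing tests do
not show about clinical data: true arterial wave reflection physics
(Windkessel dynamics, pressure-dependent pulse-wave velocity),
drug-specific pharmacokinetics, motion and probe-contact artifacts beyond
whole-beat corruption, respiration-synchronous modulation, arrhythmias, and
any nonlinearity or drift of the real PPG-BP relationship.  The planted link
is far cleaner than physiology, so the absolute error levels reported by the
acceptance script characterise the pipeline's mechanics, not clinical
performance.

## Problem sizes and determinism

The default evaluation cohort is 40 subjects (~3,500 gated windows,
~155,000 calibration pairs); with the kernel-model caps above a full run
takes a few minutes on one core.  A single run-level seed fans out to each
stage by hashing the stage name, so stages are independently reproducible
and every artifact records the configuration hash and seed.  Degenerate
inputs fail safe: flat or non-finite windows are gated out, pulses without a
usable notch contribute no systolic/diastolic split features, and sample
builders drop incomplete rows rather than imputing.

## Known limitations

* The SQI formula and the beat detector are reasonable reconstructions of
  standard practice, not a validated artifact classifier; heavily corrupted
  segments are only caught if they break beat-template correlation.
* AIx75's inflection point is a convention (APG d-wave by default); other
  instruments use different definitions, so AIx values are comparable only
  within a configuration.
* The trending analysis anchors each test subject at the first gated window;
  a different anchor policy changes the estimated-change series.
* Calibration-free results on the synthetic cohort depend strongly on the
  planted inter-subject offsets; they should be read as a relative
  comparison against the calibrated variant, not an absolute capability.
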