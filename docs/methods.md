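# Methods

## Scope and design

`pulsebp` implements a transit-time cuffless blood-pressure workflow:
signal synthesis with known truth, pulse-wave landmark detection,
feature extraction, linear calibration, and the agreement/clinical
statistics used to validate cuffless devices against cuff references.
The real patient recordings such studies rest on are never public, so
the package treats a fully specified synthetic cohort as a first-class
component: every downstream stage is validated by parameter recovery
against the generator's stored ground truth.

## Signal model

**PPG.** Each beat is a DC baseline plus three positive Gaussian
components: the systolic ejection wave (amplitude `a_sep`, default 1.0
a.u.), the reflected systolic wave (`a_srp`, constrained below
`a_sep`), and the diastolic wave (`a_dp`). Default centers/widths
(0.14/0.045, 0.30/0.070, 0.55/0.060 s for a 1 s beat, scaled linearly
with beat period) produce a waveform with a distinct ejection peak,
reflected peak, dicrotic notch and diastolic peak, so all eight
landmarks exist and are analytically known. The intersecting-tangent
foot of the composite wave is located numerically on a 20 kHz grid and
the component centers are shifted so that the foot falls exactly at
R-peak time + PTT; this makes "the foot is at R + PTT" a generator
invariant rather than an approximation. Ground-truth fiducials are the
mathematical landmarks of the continuous noise-free model (local
extrema, derivative peaks, inflections) extracted on the same dense
grid.

**ECG.** A flat baseline with one narrow Gaussian R deflection per beat
(width 8 ms, amplitude 1 mV). Only R timing feeds the algorithm, so
P/QRS/T morphology is deliberately omitted.

**Physiology coupling.** True PTT is affine and decreasing in true SBP
(`ptt_ms = 380 − 1.0·sbp`, giving ≈205–290 ms over the cohort range),
and the reflected-to-ejection amplitude ratio is affine and increasing
in true DBP (`ratio = 0.20 + 0.004·dbp`). Both maps are invertible, so
a noise-free cohort can be decoded exactly — the property the
noise-free recovery tests assert. The literature supports the existence
and sign of these couplings but not a specific functional form; the
affine choice is the simplest identifiable one.

## Cohort model

Subject pressures emulate a hypertension-clinic population: SBP with
observed mean 125, SD 18.8, range 90–175 mmHg; DBP with mean 76, SD
12.4, range 54–105 mmHg. Because those are *observed* (hence truncated)
moments, the parent normal location/scale are solved numerically so the
truncated draw reproduces the stated mean and SD. SBP is sampled
exactly from its truncated marginal by inverse CDF; DBP is sampled from
the conditional normal given SBP (correlation 0.6, a typical SBP–DBP
association) with rejection restricted to the DBP box and a minimum
pulse pressure of 10 mmHg. This construction leaves the SBP marginal
exact and keeps DBP distortion small (the conditional truncation
narrows the DBP SD by ≈0.2 mmHg at the default settings). Heart rate is
normal (70 ± 8 bpm, clipped to 45–110).

Cuff references are three independent readings per subject with i.i.d.
Gaussian error (default SD 3 mmHg — a conventional figure for
oscillometric devices; the underlying studies state no cuff error
model) whose arithmetic mean is the reference value, mirroring the
three-readings-30-s-apart protocol.

Default record length is 180 s at 1000 Hz (the acquisition protocol of
the emulated device class). Channel noise, beat-period jitter and
beat-level PTT jitter default to zero: the default configuration is the
"zero model misspecification" condition in which residual error comes
only from cuff noise and sampling/detection discretization. All
randomness descends from one `SeedSequence(seed)` spawned once per
subject in subject order.

## Fiducial detection

Derivatives are taken on a zero-phase low-pass-filtered beat
(4th-order Butterworth, cutoff 15 Hz) because 2nd/3rd derivatives
amplify noise; the cutoff is configurable. Landmarks:

* **B1** — intersecting tangents: the tangent at the maximum-upstroke
  point intersected with the pre-upstroke minimum level (the standard
  foot definition; the source convention says only "beginning of the
  wave").
* **B0** — argmax of the first derivative on the rising edge.
* **SEP** — first prominent maximum (prominence ≥ 25% of beat range).
* **DER3** — first positive third-derivative peak after B1.
* **SEPMAX** — interpreted as the first inflection (upward
  zero-crossing of the second derivative) after SEP. The naming is
  ambiguous in the field; the choice is isolated in one code path.
* **SRP** — next local maximum after SEP; when the reflected wave is a
  shoulder rather than a peak, the first local maximum of the first
  derivative on the descending limb; as a last resort the backward
  component of the two-wave decomposition.
* **DP** — first local maximum after the dicrotic notch; explicitly
  *absent* (NaN, flagged) when no diastolic peak exists rather than
  forced.
* **End** — the segment boundary at the next R peak. The generator's
  truth table stores the next pulse onset instead; the two conventions
  differ by one PTT and End is therefore never compared against truth.

The quality gate resamples every beat to 200 samples, builds the
record's median template, and scores each beat by Pearson correlation
with the template (threshold 0.9 by default). This is monotone in the
threshold by construction. A record whose every beat fails is rejected,
mirroring the exclusion of poor-quality recordings in practice.

The forward/backward decomposition fits two positive Gaussians plus a
constant baseline by bounded trust-region least squares over the
systolic window (pre-upstroke minimum to the notch preceding a
diastolic peak, full beat when no third peak exists). Fit failure or a
relative residual above 10% sets `reliable=False` instead of raising.
The decomposition is exact (residual ~1e-11) on beats that truly
contain two components. It is *not* run per beat inside the default
pipeline — shoulder detection covers SRP at a fraction of the cost of
~40k nonlinear fits per cohort — but it is a public operation with its
own recovery tests.

## Features

Per beat: PTT (R→B1, ms); landmark times relative to B1 (ms);
log-amplitudes at SEP/SRP/DP (natural log of the level minus the level
at B1, flagged missing when nonpositive — never −∞ and never imputed);
augmentation index 100·amp(SRP)/amp(SEP) (baseline-corrected;
conventions differ across the literature and this one is documented
rather than claimed canonical); perfusion index 100·AC/DC with AC the
beat's peak-to-peak amplitude and DC its mean level; normalized band
powers 0–2, 2–5, 5–10 Hz and the spectral centroid of the beat's
discrete spectrum; beat duration and systolic upstroke time. A record's
vector is the per-feature **median** over accepted beats (≥10 required)
— robust to residual artifacts, chosen over the mean deliberately.
Which spectral/time features the commercial estimators actually use is
undisclosed; this set is a plausible superset and is configurable.

## Calibration model

Separate linear models for SBP and DBP. Feature selection is forward
stepwise minimizing 5-fold cross-validated squared error with
deterministic seeded folds, accepting a candidate only when the paired
fold-wise improvement exceeds its own standard error (a one-SE rule).
The guard keeps the selected set near zero on pure-noise targets
(negative-control test: median selected size ≤ 1 over 20 repeats) while
a genuinely informative regressor is still picked first. The final fit
on the selected subset is ordinary least squares (statsmodels), with
coefficient standard errors and residual SD reported. Constant columns
are dropped with a warning; an unregularized fit with more features
than subjects is refused; rank deficiency raises an error naming the
offending columns. Predictions are affine evaluations clamped to
[40, 260] mmHg with a warning. Models serialize to versioned JSON and
round-trip exactly. A per-subject recalibration hook is deliberately
out of scope for the default pipeline.

## Evaluation statistics

Differences are always predicted − reference (cuffless − cuff), the
cuff mean being the reference method.

* **Bland–Altman**: bias, sample SD of differences, 95% CI of the bias
  and two-sided p via the one-sample t procedure, limits of agreement
  bias ± 1.96·SD, plus the per-pair (mean, difference) plot
  coordinates. Zero-variance differences degenerate gracefully (CI
  collapses to the bias, p reported null).
* **Spearman** rank correlation with mid-rank ties; null on constant
  input.
* **Zonal error grid**: zone of a pair from the exact relative
  deviation |pred − ref|/ref with fractions stored as rationals
  {1,2,4,5}/12 and upper edges inclusive. The printed percentages
  (8.3/16.6/33.3/41.6) are rounded forms of these fractions — the
  140 mmHg worked example (128.3, 151.7, …) is reproduced exactly only
  under the rational convention, which is why it is the default.
  Boundary values are presented with half-up rounding to one decimal;
  internal computation is full precision. The grid is applied to both
  SBP and DBP with the same fractions.
* **Subgroups**: <110/70 (both below), 110/70–140/90, >140/90 (either
  above), assigned from the reference values; per subgroup × target the
  mean ± SD, median [25%; 75%], and a one-sample Wilcoxon signed-rank p
  for zero median error. A one-sample test matches the
  single-sample-per-row table layout these studies report; empty
  subgroups yield null rows with a warning.
* **Classification**: hypertension (>140/90) and prehypertension
  (>130/85), positive when SBP *or* DBP exceeds its threshold, applied
  identically to both methods; sensitivity/specificity/accuracy from
  the confusion table. The AUC uses a continuous exceedance score
  max((SBP−s)/s, (DBP−d)/d) of the predicted values against reference
  labels — a fixed-threshold confusion table has no ROC of its own, so
  the score construction is documented rather than implicit. Its
  variance and 95% CI follow DeLong's placement-value method,
  implemented here and verified against R's pROC on a frozen fixture
  to 10 decimals.

## Pipeline and reproducibility

`run_pipeline` simulates, extracts, splits subjects (default 50/50,
seeded), calibrates on the training half, predicts the held-out half,
and evaluates. The effective configuration is written beside the
outputs; identical seed + configuration yields a byte-identical
`report.json` (sorted-key JSON, deterministic numerics). The
simulate+extract stage caches its tables with a configuration checksum;
`resume=True` reuses them only when the checksum matches. The default
configuration uses 60 subjects — enough for the 30-subject training
minimum of the calibration contract while keeping a full run around
half a minute on one core. Tests exercise reduced problem sizes
(shorter records, 500 Hz, smaller cohorts) where the property under
test is scale-free, and the full default configuration where
determinism end-to-end is the claim.

## Limitations

The synthetic cohort demonstrates *algorithmic* correctness (landmark
recovery, calibration identifiability, statistical procedures), not
clinical accuracy. Real PPG carries motion artifacts beyond additive
noise, respiration modulation, arrhythmic beats, morphology classes the
three-Gaussian family does not span, and a PTT–BP relationship that is
neither exactly affine nor stationary; none of these are modelled, so a
perfect zone-A score here says nothing about performance on patients.
Cuff-device error is modelled as i.i.d. Gaussian for lack of a stated
alternative. EDF export uses a minimal single-record 16-bit codec with
a documented quantization bound; it targets interchange, not archival
fidelity.
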