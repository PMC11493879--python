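# Methods

## Problem and pipeline

Aortic valve stenosis (AoS) narrows the valve orifice, which delays and
blunts the systolic pressure upstroke and prolongs ejection. Those changes
survive transmission into the peripheral arterial pressure waveform, so a
continuous non-invasive brachial pressure recording (200 Hz, at least
3 minutes) carries diagnostic information. The package implements the full
analysis chain:

1. **Segment selection** — the longest artefact-free window (samples inside
   20–300 mmHg, adjacent-sample jumps below 60 mmHg), truncated to the
   first 600 s.
2. **Smoothing** — Savitzky–Golay least-squares polynomial filtering
   (window 15 samples = 75 ms, order 3). Derivatives are obtained by SG
   differentiation rather than by differencing the smoothed trace; the
   second derivative uses a slightly wider window (21 samples) because
   double differentiation amplifies noise the most.
3. **Beat segmentation** — upstroke events are peaks of dP/dt above an
   adaptive threshold (40 % of the rolling 10-s 95th percentile, 0.3 s
   refractory period); the onset of each beat is the pressure foot, the
   last sample on the diastolic minimum plateau before the upstroke. An
   extra relative-interval rule rejects the weaker of two events closer
   than 55 % of the running beat interval, which suppresses occasional
   detections of the dicrotic upslope. Beats outside 0.3–2.0 s are
   excluded; fewer than 60 valid beats is an error.
4. **Per-beat features** — the 25 beat-level quantities among the 27 base
   features (pressures, timings, slopes, AUC fractions, pulse-contour
   surrogates; see below).
5. **xBRS** — cross-correlation baroreflex sensitivity from the beat-level
   systolic pressure (SAP) and interbeat interval (IBI) series.
6. **Summaries** — per recording, each feature series collapses into
   median, IQR, variance, and the 1st/9th decile of its beat-to-beat first
   differences (27 × 5 = 135 statistics), each divided by the patient's
   age.
7. **Detection model** — stratified 75/25 split, SMOTE oversampling of the
   minority class to parity, min–max normalization fitted on the balanced
   training set, and a grid search over five classifier families
   (logistic regression, k-NN, decision tree, SVM, random forest) under
   stratified 4-fold cross-validation scored by AUROC; held-out evaluation
   reports the confusion matrix at probability threshold 0.5 plus a
   Mann–Whitney AUROC.

## Dicrotic-notch algorithm

The notch time is the mean of the times of the *second* beat-wide local
maxima of dP/dt and d²P/dt². On any realistic beat the first maximum of
either derivative lies in the systolic upstroke — frequently at the beat's
leading edge, where it is not an interior extremum — so the second maximum
is located operationally as the first prominent interior maximum after the
systolic peak. Both must fall within 0.35 s after the peak or the beat is
marked notch-less. Derivative peaks below 10 % of the trace maximum (in
prominence) are treated as noise. Peak times are refined to sub-sample
precision with parabolic interpolation; the broad pressure/slope extrema
use a 7-point least-squares quadratic vertex instead, which is markedly
more robust to noise-induced flat-top bias.

Left ventricular ejection time (LVET) is defined as the onset-to-notch
interval: the published per-group ejection-time and notch-time medians are
numerically adjacent, confirming onset-referenced notch timing as the
ejection-time proxy when the monitor's internal estimate is unavailable.

## Pulse-contour surrogates

The monitor's stroke-volume algorithm is proprietary, so SV is a
calibrated systolic pressure–time integral, `SV = k ∫₀^LVET (P − DAP) dt`,
with a single global constant `k = 3.9 mL/(mmHg·s)` chosen once so the
synthetic control group's median SV is ≈ 77 mL. Downstream quantities
follow the clinical formulas: CO = SV·HR, SVR = 80·MAP/CO (dyn·s·cm⁻⁵ —
the unit consistent with the published magnitudes), and BSA-indexed forms
using the Du Bois body surface area. MAP is the trapezoidal time-average
of the sampled beat, not the one-third rule. These are documented
surrogates, not re-implementations of the device's internals; within a
min–max-normalized classifier a global rescaling of SV-derived columns is
inert, but absolute magnitudes matter for interpretability.

The "notch AUC" feature is implemented literally as the area above the
horizontal line at the notch pressure, as a percentage of the beat's total
area. The published percentages for this feature are hard to reconcile
with any literal area reading (they sit close to the notch-time fraction
of the beat); a `notch_auc_mode="time_fraction"` switch provides that
variant, and the feature is not used as a calibration anchor.

## xBRS

Beat series are step-interpolated to 1 Hz. In 10-s windows advanced in
1-s steps, IBI is shifted 0–5 s later than SAP (the physiological
direction); the delay maximizing the positive Pearson correlation is kept
and tested at two-sided α = 0.01 (|r| ≥ 0.765 at n = 10). Accepted windows
emit the regression slope of IBI on SAP in ms/mmHg (gain) and the delay
(tau). Windows containing detection gaps over 3 s, or zero-variance SAP,
are skipped. Because the best of six delays is selected, the null
acceptance rate is bounded by ≈ 6·α/2 ≈ 3 %, not α itself; the property
test asserts the ≤ 5 % bound. Regression dilution from uncorrelated
beat-to-beat SAP variability attenuates the recovered gain by roughly
10 %, which stays within the 20 % recovery tolerance.

## Synthetic cohort generator

Each patient is a beat template constructed in velocity space: dP/dt is a
chain of quintic-smoothstep ramps (foot upstroke, descent crossing zero
exactly at the systolic-peak time, a taper and flattening approach into
the notch, the dicrotic-wave upslope/downslope) plus a sharp symmetric
ejection spike at the steepest-upstroke time — arterial dP/dt peaks
briefly in early ejection and then rides a plateau while pressure keeps
climbing. The pressure curve is the integral, normalized so the peak sits
exactly PP above DAP; diastole is a smooth decay whose amplitude is solved
so pressure returns exactly to DAP at the nominal interbeat interval. The
curve is twice continuously differentiable everywhere except the onset
itself, where the foot ramp starts with nonzero dP/dt slope — the
valve-opening kink real waveforms show; without it the onset is
fundamentally unresolvable at 200 Hz. Ground-truth landmark times are
measured numerically from the dense template, not assumed.

Per-group template parameters (DAP, PP, peak/upstroke/ejection timings,
notch depth, heart period, baroreflex gain, demographics, recording
duration) are drawn from log-normals matched to the published group
medians and interquartile ranges — stenosis patients have a ~15 ms later
steepest upstroke, ~30 ms later peak, ~20 ms longer ejection, slightly
higher age and female fraction, and longer recordings (toward 600 s vs
400 s). Within a recording, beats get multiplicative time-scale jitter
(σ = 1.5 %) and amplitude jitter (σ = 2 %), a respiratory baseline
sinusoid (6 mmHg at ≈ 0.25 Hz), additive white observation noise
(σ = 1 mmHg), and a baroreflex coupling
`IBI_n = IBI₀ + G·(SAP_{n−d} − SAP₀)` with positive gain (higher pressure
lengthens the interval) and a 3-s delay rounded to whole beats.

What the generator does *not* emulate: the finger-to-brachial transfer
function, arrhythmias and ectopy (an excluded population), reflected-wave
fine structure, low-flow–low-gradient subphysiology, cuff recalibration
artefacts, or a decrease of stroke volume with stenosis (the surrogate
integral actually grows slightly with the longer ejection). Passing tests
therefore demonstrate that the pipeline recovers what the generator
encodes and that the published group contrasts are sufficient for
detection — not clinical performance on real waveforms.

## Numerical choices

* Quantiles use linear interpolation between order statistics; variance
  uses the n − 1 denominator. "Deciles of the change" are the 10th/90th
  percentiles of the first-difference series (a `deciles_of="level"`
  switch gives the level-distribution deciles instead).
* Integrals are trapezoidal, with a linear-interpolation fractional end
  segment so the systolic integral cuts at the sub-sample notch time.
* Derivative tie-breaks resolve to the earliest time; all estimators are
  deterministic given the input.
* The split allocates per-class training counts by largest-remainder
  rounding, reproducing the published 75 + 36 / 38 partition of 101 + 48.
* SMOTE is the standard formulation (uniform λ on segments to one of the
  k = 5 nearest minority neighbours, Euclidean metric, originals
  retained); k shrinks with a warning when the minority is tiny.
* All randomness — cohort draws, beat jitter, noise, split, SMOTE, CV
  folds, stochastic learners — funnels through explicit integer seeds.
* Grid candidates infeasible at a given sample size (e.g. more neighbours
  than fold members) are excluded from model selection rather than
  failing the search; ties break toward the earlier family and the
  earlier grid point, in the published listing order.

## Problem sizes

The end-to-end acceptance computation simulates the full 149-patient
cohort (101 stenosis / 48 controls, recordings 180–600 s at 200 Hz) for
ten seeds and averages the held-out AUROC; one seed takes roughly half a
minute to a minute on a single CPU. Unit and property tests run on
single recordings of 190–300 s or on small cohorts.

## Known limitations

* SMOTE is applied once before cross-validation, as the study orders the
  steps; this is optimistic for the *training* CV score (synthetic
  neighbours of a fold's test points can sit in its training folds) but
  does not touch the held-out test set.
* The decision threshold 0.5 is a convention; the study does not state
  its operating point.
* The 40-item best-feature list is honored as a given subset
  (`BEST_FEATURE_SUBSET`, which enumerates 41 names as printed); how it
  was derived is not described, so no selection procedure is implemented.
* Group contrasts in the generator are calibrated to reported medians and
  IQRs only; covariances between parameters are not modelled beyond the
  feasibility constraints on landmark ordering.
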