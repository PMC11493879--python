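# aosdetect

Detection of aortic valve stenosis (AoS) from non-invasive arterial
blood-pressure waveforms.

Aortic stenosis delays and blunts the systolic upstroke and prolongs
ejection, and those morphology changes survive into the peripheral
pressure wave. `aosdetect` implements the complete analysis chain for
continuous brachial pressure recordings (200 Hz, ≥ 3 min): artefact-aware
segment selection, Savitzky–Golay smoothing, beat segmentation at the
pressure foot, 27 per-beat/per-window hemodynamic features — including a
derivative-based dicrotic-notch locator (LVET), slope and AUC landmarks,
pulse-contour surrogates (SV, CO, SVR and BSA-indexed forms) and
cross-correlation baroreflex sensitivity (xBRS gain and delay) — then
per-recording summaries (median, IQR, variance, deciles of the
beat-to-beat change), age normalization, and an imbalance-corrected
classifier: stratified 75/25 split, SMOTE oversampling, min–max
normalization, and a grid search over five classifier families under
4-fold cross-validation optimizing AUROC.

Because the clinical recordings are not public, the package ships a
first-class synthetic cohort generator: twice-differentiable parametric
beat templates with directly controlled landmarks, respiratory
modulation, a baroreflex SAP→IBI coupling with known gain, observation
noise, and two patient groups whose parameter distributions are
calibrated to the published stenosis/control contrasts (later upstroke
and peak, longer ejection, lower dP/dt, older age, longer recordings).
Every simulated beat carries ground truth, so detection and feature
extraction are testable end to end.

## Core definitions

* Dicrotic notch: `t_notch = ½·(t₂[dP/dt] + t₂[d²P/dt²])`, the mean of
  the times of the second beat-wide maxima of the first and second
  pressure derivatives; `LVET = t_notch` (onset-referenced).
* Systolic/diastolic AUC: `100·∫₀^LVET P dt / ∫₀^IBI P dt` and its
  complement; notch AUC: area above the horizontal at the notch pressure.
* Pulse-contour stroke volume: `SV = k·∫₀^LVET (P − DAP) dt`,
  `k = 3.9 mL/(mmHg·s)`; `CO = SV·HR`, `SVR = 80·MAP/CO` (dyn·s·cm⁻⁵),
  indexed by the Du Bois body surface area.
* xBRS: in sliding 10-s windows, the regression slope (ms/mmHg) of the
  interbeat interval on systolic pressure at the 0–5 s delay maximizing
  their positive correlation, kept when significant at α = 0.01.
* AUROC by the Mann–Whitney formulation (ties count one half).

See `docs/methods.md` for the full model description, parameter defaults
and limitations.

## Worked example

```python
from aosdetect import CohortParams, simulate_cohort, run_study, PipelineConfig

patients = simulate_cohort(CohortParams(seed=1))           # 101 AoS / 48 controls
result = run_study([(p.recording, p.meta) for p in patients],
                   PipelineConfig(), seed=1)

print("winner:", result.detector.search_.family, result.detector.search_.params)
print("training CV AUROC: %.2f +- %.2f" % (result.detector.search_.mean_auroc,
                                           result.detector.search_.sd_auroc))
rep = result.report
print("test confusion matrix: tp=%d fp=%d tn=%d fn=%d" % (rep.tp, rep.fp, rep.tn, rep.fn))
print("test metrics:", rep.rounded())
```

prints

```
winner: random-forest {'max_depth': None, 'n_estimators': 100}
training CV AUROC: 0.92 +- 0.01
test confusion matrix: tp=23 fp=4 tn=8 fn=3
test metrics: {'sensitivity': 0.88, 'specificity': 0.67, 'accuracy': 0.82,
               'ppv': 0.85, 'npv': 0.73, 'auroc': 0.92}
```

The cohort of 149 simulated recordings splits into 75 + 36 training and
38 test patients; after SMOTE both training classes hold 75 rows. The
test-set sensitivity/specificity say how many stenosis and control
patients the model labels correctly at the 0.5 probability threshold,
and the AUROC is the probability that a random stenosis patient scores
above a random control.

`AoSDetector` (SMOTE → min–max → grid search) is a scikit-learn
classifier and `WaveformFeaturizer` a transformer, so both compose with
sklearn pipelines and model selection.

## Command line

```
aosdetect simulate --n-aos 101 --n-control 48 --seed 7 --out cohort/
aosdetect features --manifest cohort/manifest.csv --out features.csv
aosdetect train    --features features.csv --seed 7 --out model/
aosdetect evaluate --model model/ --features features.csv
aosdetect all      --seed 7 --out study/
```

Waveforms are two-column CSVs (`time_s,pressure_mmHg`); the manifest
carries demographics and labels; `train` writes a JSON model artifact,
metrics report and ROC points. Every tunable lives in a flat YAML config
(`--config`, overridable with `--set key=value`); identical invocations
with identical seeds produce byte-identical outputs.

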