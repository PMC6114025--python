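# oculobox

A tested, reusable pipeline for binocular box-pursuit eye-tracking analysis:
synthetic gaze recordings → trajectory preprocessing → 89 oculomotor metrics
→ univariate biomarker screening → classifier building with repeated
cross-validation → external validation with ROC/confusion reporting.

The stimulus model is an aperture circling the edges of a 4:3 monitor
(10 s per side, five 40 s cycles, 220 s total, sampled at 500 Hz). Controls
show conjugate pursuit; cases carry a slowly varying disconjugate offset on
one eye. Because no raw clinical recordings are public, the `synth` module
is a first-class, tested component: every downstream stage runs end-to-end
on simulated cohorts.

## Modules

| module | contents |
| --- | --- |
| `oculobox.synth` | `StimulusProtocol`, `stimulus_position`, `simulate_recording`, `simulate_cohort`, recording/cohort CSV I/O |
| `oculobox.preprocess` | trimming, blink detection + 200-sample margins, per-eye median centering, cycle segmentation, trial-triggered "box trajectory" averaging |
| `oculobox.metrics` | the 89-metric registry (32 left, 32 right, 25 conjugate): box geometry, per-side distance/velocity, disconjugacy variances, blink counts, composite BOX scores |
| `oculobox.cohort` | `SubjectRecord`, concussion case labeling (CT− ∧ SSS>40 ∧ SAC≤24), age/sex balancing, CT filtering |
| `oculobox.screen` | Wilcoxon rank-sum (exact for small groups), Bonferroni threshold, age/sex covariate screen, per-metric AUC, correlation dedup |
| `oculobox.models` | best-subset (AIC) and L1-penalized logistic classifiers, random forests with OOB error, repeated stratified 4-fold CV with in-fold selection |
| `oculobox.evaluate` | ROC/AUC, confusion statistics, external validation reports |
| `oculobox.cli` | `oculobox` command with `simulate`, `preprocess`, `metrics`, `screen`, `fit`, `validate`, `run` |

## CLI

Run the whole pipeline on synthetic cohorts (config keys are optional; the
defaults are a small demo):

```sh
oculobox run --config config.yaml --out results/ --seed 0
```

with, e.g.:

```yaml
train: {n_control: 34, n_case: 34}
validation: {n_control: 247, n_case: 7}
case_profile: {disconjugacy_sd: 1.5}
cv: {n_folds: 4, n_repeats: 50}
seed: 0
```

This writes cohort CSVs, recordings, the 89-column metric TSVs, the
screening table, model JSONs, validation reports, ROC point CSVs, and a
manifest; reruns with the same config are bit-identical. Individual stages
(`simulate`, `metrics`, `screen`, `fit`, `validate`, `preprocess`) operate
on files with the same formats.

## Notes

- Composite BOX scores and the full 89-name roster are documented
  reconstructions: only the significant subset of metric names and none of
  the composite formulas are public. See docstrings in `oculobox.metrics`.
- All stochastic operations take explicit seeds; cohorts derive per-subject
  seeds from a single master seed.
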