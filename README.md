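# mieeg

Motor-imagery EEG classification pipeline: multiscale-PCA wavelet denoising,
4-level wavelet-packet subband features (95 per trial), and Rotation-Forest /
Random-Subspace ensemble classifiers evaluated with stratified 10-fold
cross-validation. A synthetic two-class generator (mu/beta rhythms with
class-dependent, spatially lateralized band-power attenuation over 1/f
background noise) makes the entire pipeline runnable and testable without any
external recordings.

## Layout

| module | purpose |
| --- | --- |
| `mieeg.model` | domain types (`EEGSegment`, `EEGDataset`, `FeatureVector`, ...) and validation |
| `mieeg.io` | delimited trial dumps, minimal EDF reader/writer, feature tables |
| `mieeg.wavelets` | Daubechies filter banks, periodized DWT and wavelet-packet transforms |
| `mieeg.simulate` | seeded synthetic two-class EEG (`generate_dataset`, `generate_null_dataset`) |
| `mieeg.mspca` | multiscale PCA denoising (`pca_decompose`, `retain_components`, `denoise`) |
| `mieeg.features` | level-4 WPD subbands, 16x5 statistics + 15 adjacent-MAV ratios = 95 features |
| `mieeg.trees` | entropy decision trees (gain-ratio + confidence pruning, reduced-error pruning, random-feature) |
| `mieeg.ensembles` | base-learner registry (SVM, 1-NN, RF, trees), Rotation Forest, Random Subspace |
| `mieeg.evaluation` | confusion metrics, ROC AUC, stratified CV, per-subject / pooled experiment grid |
| `mieeg.cli` | `mieeg` command-line entry point |

The wavelet transforms are implemented in-package (square orthogonal,
periodized, odd lengths handled by a removable pad) so that perfect
reconstruction and Parseval energy conservation hold to 1e-8 and better.

## CLI

```sh
# synthetic dataset (seed is mandatory, explicitly)
mieeg simulate --config sim.json --seed 7 --out data/

# individual stages
mieeg denoise  --in data/dataset.csv --out data/denoised.csv
mieeg features --in data/denoised.csv --out data/features.csv

# full experiment: data -> denoise -> features -> classifier grid
mieeg run --config pipeline.json --out results/run1
mieeg report --in results/run1/summary.csv
```

A pipeline config contains exactly one of `simulation` or `input`, plus
optional `mspca`, `features`, `classifiers` and `evaluation` sections:

```json
{
  "simulation": {"n_subjects": 5, "trials_per_class_per_subject": 140,
                  "erd_factor": 0.5, "snr_db": 5.0, "seed": 7},
  "mspca": {"retention_rule": "kaiser"},
  "features": {"channel_aggregation": "mean"},
  "classifiers": {
    "bases": ["svm", "knn", "rf", "c45_like", "rep_tree", "random_tree"],
    "ensembles": {"rsm": {"method": "random_subspace"},
                   "rof": {"method": "rotation_forest"}}
  },
  "evaluation": {"n_folds": 10, "seed": 7}
}
```

`run` writes `features.csv`, `reports.json`, a Table-style `summary.csv`
(per-subject rows plus a pooled `ALL` row per classifier) and a
`provenance.json` echoing every resolved default.

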