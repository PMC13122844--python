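# motorsig

Individualized functional phenotyping of sensorimotor cortex in
amyotrophic lateral sclerosis (ALS) from block-design task fMRI.

ALS begins focally — in a hand, a foot, or the bulbar muscles — and
spreads. `motorsig` implements an analysis stack that asks whether the
functional signature of the disease in primary motor cortex is
*topographic* (concentrated in the first-affected body-part field) or
*distributed*, and whether connectivity or activation better tracks
clinical severity:

- **Dual-shared-space group classification.** Robust Shared Response
  Models (rSRM) are fitted separately to patients and controls; held-out
  subjects are projected through *both* group spaces and classified with a
  linear SVM under leave-one-subject-out cross-validation.
- **Connectivity mapping.** Voxel-wise eigenvector centrality (power
  iteration on a non-negative voxel-similarity matrix) and seed-based
  correlation maps, with patient-minus-matched-control contrasts
  aggregated by King's disease stage (the inverted-U profile:
  decreased / increased / decreased at stages 1 / 2 / 3).
- **Latent-variable clinical modelling.** Partial least squares regression
  (NIPALS) predicts ALSFRS-R and PUMNS from voxel features, with
  leave-one-out cross-validation, back-projection of model weights into
  voxel space, and region-wise weight statistics (repeated-measures ANOVA
  with Holm-corrected paired comparisons).

Because no public patient data exist for this problem, the package ships a
**synthetic cohort generator** with full ground truth (shared responses,
subject bases, somatotopic ROI clusters, stage-dependent connectivity
shifts, clinical scores tied to a severity latent). Every quantitative
claim in the test suite is established against this generator or against
independent numerical oracles. See [docs/methods.md](docs/methods.md) for
the model and the reasoning behind the defaults.

## Quick start (command line)

```sh
python -m motorsig.cli run-all --out demo_out --seed 7
python -m motorsig.cli report demo_out
```

```
motorsig 0.1.0  config 7c8627b951e637a2
stages: simulate, preprocess, localize, connectivity, classify, plsr
overall LOSO accuracy: 1.000
first-affected 1.000 vs non-first-affected 1.000 (t(68) = 0.00, p = 1)
PLSR ecm -> alsfrs: mean LOO MSE = 18.184
PLSR timeseries -> pumns: mean LOO MSE = 22.758
```

Each stage writes CSV/JSON artifacts (`clinical.csv`, `group_masks.json`,
`stage_contrast.csv`, `classification_summary.json`, `plsr_*.json`) plus a
`manifest.json` recording the version, the full configuration and its
hash; `replay_from_manifest` re-runs any output directory bit-identically.
Subcommands `simulate`, `preprocess`, `localize`, `connectivity`,
`classify` and `plsr` run the pipeline up to that stage; `--config`
accepts a JSON/YAML pipeline configuration.

## Quick start (library)

```python
import numpy as np
from motorsig import (
    CohortConfig, generate_cohort, bandpass, synchronize_blocks,
    loso_classify, overall_accuracy, ecm, run_plsr_analysis,
)

cfg = CohortConfig(seed=7, n_patients=6, n_controls=6, snr=10.0)
series, records, truth = generate_cohort(cfg)

proc = [
    (synchronize_blocks(bandpass(s), truth.design),
     "ALS" if s.subject_id.startswith("P") else "CTL")
    for s in series
]
folds = loso_classify(proc, truth.roi_masks(cfg.grid), k=5, seed=0)
print(overall_accuracy(folds))          # 1.0 at snr = 10

report = run_plsr_analysis(
    [s for s, g in proc if g == "ALS"], records,
    predictor="ecm", response="alsfrs",
    combined=truth.combined_mask(cfg.grid),
)
print(report.mean_mse, report.latent_table[0]["lv1"])
```

Real NIfTI volumes and clinical CSV tables are read with `read_bold` /
`read_clinical_table`; the packaged 14-patient reference clinical table is
available via `load_reference_clinical()`.

## Tests and acceptance

```sh
python -m pytest -o addopts= -p no:cacheprovider -q tests/
```

The suite covers every module against closed-form or independently
implemented oracles (dense eigendecomposition for centrality, SVD/OLS and
scikit-learn for PLSR, a hand-rolled alternating-Procrustes reference for
the rSRM, statsmodels/pingouin for the multiple-comparison and ANOVA
statistics), plus end-to-end pipeline determinism and manifest replay.
`tests/test_acceptance.py` pins the headline behaviors: clinical-table
statistics, chance-level calibration of the classifier under label
permutation, oracle equivalences, parameter recovery across seeds,
qualitative disease signatures, and GLM type-I calibration.

The acceptance targets can be recomputed standalone:

```sh
python scripts/acceptance.py --seed 123 --out results/acceptance.json
```

which writes the recomputed clinical-table statistics and the mean
permuted-label LOSO accuracy (chance level) as JSON.

## Repository layout

```
src/motorsig/
  core.py          volumes, masks, BOLD series, clinical records, NIfTI/CSV I/O
  synth.py         synthetic cohort generator + ground truth
  preprocess.py    band-pass, z-scoring, block synchronization, PSC
  localizer.py     per-voxel GLM, top-k / group / combined masks
  connectivity.py  eigenvector centrality, seed maps, stage contrasts
  srm.py           robust SRM, basis transfer, dual-space features
  classify.py      LOSO SVM classification, permutation nulls, contrasts
  plsr.py          NIPALS PLSR, LOO CV, back-projection, region stats
  pipeline.py      end-to-end orchestration with manifest
  cli.py           click command-line interface
docs/methods.md    model description and parameter rationale
scripts/acceptance.py
tests/
```
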