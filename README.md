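# icnpipe

A tested, desk-scale pipeline for multivariate pattern-recognition analysis
of resting-state fMRI:

- **synthgen** — synthetic cohorts with known ground truth: dispersed
  spatial component maps, band-limited orthogonal time courses, group
  effects planted on a designated *affected* component subset, follow-up
  scans whose loadings move back toward the control mean, and symptom
  scores whose improvement co-varies with that normalization.
- **preprocess** — volume discard, global intensity scaling, zero-phase
  band-pass (0.01–0.08 Hz), nuisance + trend regression, Gaussian smoothing.
- **icn** — temporal-concatenation group PCA + spatial FastICA, subject-
  specific component back-reconstruction (dual regression, plus a guided
  negentropy-ascent refinement), template matching against a-priori
  DMN/MTL anchors, and voxelwise Fisher-z connectivity maps.
- **classify** — nested leave-one-out SVM ensemble: per outer fold, forward
  component selection seeded with the anchor components (grid-searched SVM
  parameters inside every evaluation), one base classifier per inner
  leave-one-out subset, signed probability scores (s = 2p − 1, positive =
  patient), median aggregation, and follow-up scan scoring by each
  subject's own fold.
- **stats** — sign-flip permutation tests (voxelwise paired pseudo-t on
  connectivity changes; one-tailed score-decrease test), covariate-adjusted
  Spearman association between baseline scores and PANSS-normalized
  treatment response with Bonferroni correction and studentized-residual
  outlier screening.
- **io / cli / pipeline** — NIfTI-1 and CSV readers/writers, YAML
  configuration, seeded stage orchestration and run manifests.

Patient data for the original study are not publicly deposited, so every
stage is exercised end-to-end on the synthetic cohort generator, which is
first-class, tested code.

## Tests

```sh
python -m pytest -q
```

The suite includes unit tests per module, property tests for the declared
invariants, and `tests/test_acceptance.py` with one test per acceptance
criterion (metric arithmetic, ICA recovery, classifier calibration/power,
permutation calibration, treatment-response sign recovery, preprocessing
contracts). The full run takes a few minutes on one CPU.

## Command line

```sh
# everything, one seed
icnpipe run-all --seed 1 --out runs/demo

# or stage by stage (each stage reads the previous stage's directory)
icnpipe simulate   --config cfg.yaml
icnpipe preprocess --config cfg.yaml
icnpipe ica        --config cfg.yaml [--mode dual_regression|guided]
icnpipe classify   --config cfg.yaml
icnpipe stats      --config cfg.yaml
icnpipe report     --out runs/demo
```

`--config` takes a YAML snapshot of `icnpipe.pipeline.PipelineConfig`;
flags override the file; the effective config and per-stage output hashes
are recorded in `manifest.json`. A single `--seed` fans out to per-stage
seeds, so one flag reproduces a whole run. With the default configuration
(68 subjects, 240 volumes, 20 components, the full 15-point SVM grid) a
`run-all` is compute-heavy; the tests and examples use reduced cohorts and
grids.

Outputs: `metrics.json`, `scores.csv`, `selection_frequency.csv`,
`fold_selections.csv`, `roc.csv`, `associations.csv`, `stats.json`,
`group_maps.nii` and FC-change t/p/mask maps as NIfTI.

## Layout

```
src/icnpipe/
  synthgen.py    cohort generator (+ ComponentAtlas / CohortConfig / Cohort)
  preprocess.py  Scan/NuisanceSet and the cleaning chain
  icn.py         group ICA, subject ICNs, template matching, FC maps
  classify.py    feature sets, forward selection, LOO ensemble, metrics
  stats.py       permutation tests, residualization, associations, outliers
  io.py          NIfTI/CSV/TSV readers and writers
  pipeline.py    PipelineConfig, staged execution, run manifests
  cli.py         click entry points
tests/           pytest suite incl. test_acceptance.py
scripts/acceptance.py
```
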