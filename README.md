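# slopekit

Toolkit for estimating and predicting early-intervention *treatment slopes*
(per-subject rates of skill growth) from longitudinal outcome tables,
pre-treatment clinical measures and blood leukocyte gene expression, plus the
downstream annotation statistics. Everything runs on synthetic cohorts with
the study-like statistical structure, so no external data are needed.

## What it does

| module | purpose |
| --- | --- |
| `slopekit.synthetic` | cohort generator: visits with subject-specific random intercepts/slopes, early/late start groups (optional late-group slope-SD inflation), clinical table correlated with true slopes, expression matrix with batch/sex/RIN nuisance structure and a correlated causal gene module calibrated to a target predictive R², gene sets, interaction network, truth record |
| `slopekit.trajectory` | REML random-intercept/random-slope mixed model (from scratch, vectorized per-subject blocks), BLUP treatment-slope extraction, covariate-adjusted start-group model with Wald F tests, slope-SD-difference permutation test (add-one p) |
| `slopekit.preprocess` | quantile normalization (tie-averaged), top-fraction variance filter (ceiling count, n−1 variance), train-fit/test-apply residualization of batch + sex + RIN |
| `slopekit.lasso` | coordinate-descent LASSO (numba kernels, warm-started λ paths), leave-one-out outer CV with per-fold residualization/standardization and inner 10-fold λ selection, permutation null for the cross-validated MSE, full-data feature prioritization |
| `slopekit.enrichment` | 2×2 odds-ratio + hypergeometric enrichment, Benjamini–Hochberg FDR, network edge-count permutation test (uniform or degree-binned null) |
| `slopekit.spatial` | voxelwise one-sample t over stacks of per-gene maps with in-mask BH-FDR thresholding; NIfTI I/O |

## CLI

All commands live under a single entry point:

```bash
slopekit simulate --config cohort.yaml --outdir cohort/ --seed 7
slopekit slopes --visits cohort/visits.tsv --covariates cohort/subjects.tsv --out slopes.tsv
slopekit sdtest --slopes slopes.tsv --groups cohort/subjects.tsv --perms 10000 --seed 1
slopekit preprocess --expr cohort/expression.tsv --keep-fraction 0.5 --out filtered.tsv
slopekit predict --features filtered.tsv --slopes slopes.tsv \
    --covariates cohort/subjects.tsv --perms 1000 --seed 1 --out result.json
slopekit enrich --query genes.txt --lists lists.gmt --universe universe.txt --out table.tsv
slopekit edgetest --query genes.txt --network cohort/network.tsv --perms 1000 --seed 1
slopekit tmap --maps maps_dir/ --mask mask.nii --q 0.05 --out tmap.nii
```

`cohort.yaml` holds `CohortConfig` overrides (`n_subjects`, `n_probes`,
`target_r2`, ...); every file format is plain text (TSV/GMT/JSON) except the
optional NIfTI volumes.

## Python example

```python
from slopekit import synthetic, trajectory, lasso

cohort = synthetic.simulate_cohort(synthetic.CohortConfig(seed=1))
fit = trajectory.fit_trajectory_model(cohort.visits)
slopes = trajectory.extract_treatment_slopes(fit)

cv = lasso.loocv_predict(
    cohort.expression.T, slopes.to_numpy(),
    covariates=cohort.subjects[["batch", "sex", "rin"]], seed=1,
)
perm = lasso.permutation_test_mse(
    cohort.expression.T, slopes.to_numpy(),
    covariates=cohort.subjects[["batch", "sex", "rin"]], B=1000, seed=1,
)
print(cv.mse, cv.r2, perm.p)
```

## Notes

- Permutation p-values use the add-one convention `(1 + #extreme) / (B + 1)`
  throughout, so the smallest attainable p at `B = 1000` is `1/1001`.
- LOOCV never lets the held-out subject influence residualization,
  standardization, the λ grid or λ selection; the permutation null reruns the
  whole scheme on shuffled outcomes (feature-side preprocessing is
  outcome-free and therefore shared).
- Cross-validated R² is `1 − SSE/SST` on held-out predictions (can be
  negative); a squared-correlation variant is available via
  `r2_method="correlation"`.
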