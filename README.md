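# methclock

Sequencing-native DNA methylation age clocks for low-input methylomes.

Most epigenetic clocks are trained on microarray betas and assume a fixed
probe set with uniform quality. Methylation *sequencing* (EM-seq, WGBS,
capture panels) instead yields, per sample, a beta value and a read depth
at millions of CpGs, with coverage that varies by site and by sample.
`methclock` is a toolkit for building and evaluating age predictors
directly on such data: depth-aware quality filtering, feature
construction from single CpGs or from co-methylated regions, penalised
regression on a transformed age scale, and the evaluations that matter
for sequencing clocks — robustness to sequencing depth, longitudinal
repeatability, sensitivity to induced age reversal, and genomic-context
enrichment of the selected CpGs. A synthetic methylome generator with
known ground truth makes the whole pipeline testable end to end.

It is aimed at epigenomics researchers and method developers working
with skin or other low-input tissues where non-invasive sampling gives
shallow, uneven coverage.

## The model

For each sample with beta vector x (missing values mean-imputed,
features z-scored), the clock predicts

    F(age) = b0 + w · PCA(z(x))

where the elastic-net coefficients w are fitted by nested
cross-validation (inner CV selects the penalty (alpha, l1_ratio), outer
CV yields unbiased out-of-fold predictions), and F is the log-linear age
transform with adult-age knot at 20 years:

    F(a) = log(a + 1) - log(21),  a <= 20
    F(a) = (a - 20) / 21,         a > 20

Region features replace single-CpG betas by the mean beta over runs of
adjacent CpGs whose age correlations agree within a tolerance (default
0.075, minimum 3 CpGs) — averaging reads across a region buffers
sampling noise at low depth. Quality filters follow sequencing-clock
practice: samples need >= 15x mean depth and >= 90% of sites covered;
cells below 7x are masked; sites missing in > 70% of *training* samples
are dropped (fitted on the training split only, to avoid leakage);
chrX/Y/M are excluded.

Enrichment of clock CpGs in genomic feature classes (exons, CpG islands,
…) is assessed by Monte Carlo: 250 random CpG sets matched to the query's
per-chromosome composition, a one-sample t-test against the observed
overlap count, plus a calibrated empirical-rank p.

See `docs/methods.md` for assumptions, parameter defaults and
limitations.

## Worked example

```python
import numpy as np
import methclock as mc

# simulate a cohort with known ground truth
cfg = mc.SimConfig(n_samples=200, n_sites=1000, seed=11)
cohort, truth = mc.simulate_cohort(cfg)

# split, filter, train a single-CpG clock
train_mask, test_idx = mc.train_test_split_indices(cohort.n_samples, 0.2, seed=11)
train, test, qc_info = mc.apply_qc_pipeline(cohort, mc.QCConfig(), train_mask)
tc = mc.TrainConfig(seed=11, en_alpha_grid=tuple(np.logspace(-3, 1, 10)))
model, cv = mc.fit_clock(train.beta, train.ages, tc, feature_ids=train.universe.site_ids)

# evaluate on the held-out split
pred, coverage = mc.predict_cohort(model, test)
rep = mc.regression_metrics(pred, test.ages)
print(f"held-out n={rep.n}  MAE={rep.mae:.2f} y  RMSE={rep.rmse:.2f} y  "
      f"MAD={rep.mad:.2f} y  R2={rep.r2:.3f}")
print(f"clock features: {model.n_features}, mean coverage {coverage.mean():.1%}")

# region clock on the same training data
corr = mc.age_correlation(train)
regions = mc.build_regions(train.universe, corr, tolerance=0.075)
feats, _ = mc.region_betas(train, regions)
rmodel, _ = mc.fit_clock(feats, train.ages, tc,
                         feature_ids=regions.feature_ids(train.universe),
                         feature_kind="region",
                         feature_sites=regions.member_site_ids(train.universe))
rpred, _ = mc.predict_cohort(rmodel, test)
rrep = mc.regression_metrics(rpred, test.ages)
print(f"region clock: {len(regions)} regions, held-out MAE={rrep.mae:.2f} y  R2={rrep.r2:.3f}")
```

Output:

```
held-out n=40  MAE=5.27 y  RMSE=6.11 y  MAD=4.41 y  R2=0.924
clock features: 1000, mean coverage 98.0%
region clock: 91 regions, held-out MAE=6.10 y  R2=0.887
```

The held-out MAE of ~5 years at this small problem size (200 samples,
1000 sites) reflects the simulated biological noise plus 30x read
sampling; coverage is the fraction of clock features observed in each
test sample before imputation. At the default study size (375 samples,
2000 sites) the held-out MAE drops near 2 years with R² ≈ 0.98.

The same pipeline is scriptable from the shell:

```bash
methclock simulate --out sim --n-samples 100 --n-sites 500 --seed 3
methclock train --sheet sim/sample_sheet.tsv --calls sim/calls \
    --universe sim/universe.tsv --out model --seed 3
methclock predict --model model/model.json --sheet sim/sample_sheet.tsv \
    --calls sim/calls --universe sim/universe.tsv --out predictions.tsv
```

Other subcommands: `qc`, `regions`, `evaluate`, `depth-scan`,
`consistency`, `enrich`. Every run writes a resolved-config snapshot next
to its outputs, and identical inputs + seed reproduce outputs byte for
byte.

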