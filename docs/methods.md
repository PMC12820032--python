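# Methods

`methclock` trains and evaluates epigenetic age predictors directly on
per-CpG methylation calls from enzymatic or bisulfite sequencing, and
ships a synthetic methylome generator so every stage can be exercised and
validated without access to any cohort data.

## Data model and filtering

The coordinate frame is a `SiteUniverse`: the sorted, deduplicated list of
assayable CpG positions (0-based, C on the plus strand). Per-sample calls
are beta values derived strictly from read counts, `beta = m / (m + u)`;
a cell with zero reads is missing (NaN), never a sentinel value.
Chromosome aliases (`1`/`chr1`, `MT`/`chrM`) are normalized on read.

Quality filtering runs in a fixed order, mirroring standard practice for
capture-panel methylomes:

1. **Sample QC** — drop samples whose mean depth over all universe sites
   is below 15x or whose covered fraction (depth >= 1) is below 90%.
   All exclusion comparisons are strict, so exact-threshold samples stay.
2. **Chromosome filter** — remove chrX, chrY and chrM sites (sex- and
   copy-number-confounded).
3. **Low-depth masking** — per sample, set beta to missing where depth
   < 7x; the depth itself is retained for reporting and read thinning.
4. **Missingness filter** — keep sites missing in at most 70% of
   *training* samples. This filter is fitted on the training split only
   and the surviving site set is applied to both splits, so the test
   split never influences feature availability (leakage control).

The same per-sample preprocessing (steps 1–3) is applied to any cohort a
trained clock predicts on, including depth-thinned evaluation sets —
train/test feature processing parity.

## Co-methylated regions

Adjacent CpGs often drift with age coherently. Region features are built
from per-site Pearson correlations `r_i` of beta with chronological age
(computed on the training split only; undefined below `min_obs = 10`
observations or at zero variance). A single greedy left-to-right pass
merges consecutive sites while, for each joining site,

    |r_i - r_anchor| < tolerance   and   |r_i - r_prev| < tolerance

with `tolerance = 0.075` by default. Applying **both** constraints is the
package's reading of "coordinated correlation" merging: the anchor term
bounds drift across the region, the consecutive term enforces local
smoothness; `mode` exposes the single-constraint alternatives
(`anchor_only`, `consecutive_only`). Chromosome changes and undefined-r
sites always close the current run; runs shorter than 3 sites are
discarded. A region's feature value for a sample is the unweighted mean
of its observed member betas (missing only when all members are missing).
An optional `max_gap` can additionally split regions by genomic distance;
it defaults to unlimited because a capture panel already bounds gaps.

The greedy rule is deterministic and is verified in the test suite
against an independently written brute-force restatement on thousands of
random inputs.

## Clock training

Features (single CpGs, region means, or an externally restricted CpG
list) go through a pipeline fitted strictly inside each cross-validation
training part:

1. mean imputation of missing values (all-missing features fall back to
   beta 0.5),
2. z-score standardisation (population SD, floored at 1e-8 to tolerate
   near-constant features after imputation),
3. correlation pre-selection: top-K features by |Pearson r| with
   chronological age (default K = 20 000, i.e. inactive below that
   feature count) or a threshold,
4. PCA retaining 95% of variance by default (`svd_solver="full"` for
   determinism),
5. ElasticNet regression of transformed age on the PCA scores.

The regression target is the log-linear age transform with the adult-age
knot at 20 years:

    F(a) = log(a + 1) - log(21)   for a <= 20
    F(a) = (a - 20) / 21          for a >  20

so the model weights relative errors more heavily in early life; all
reported predictions and metrics are inverse-transformed to years.

Hyperparameters (alpha on a 20-point log grid over [1e-3, 1e2]; l1_ratio
in {0.1, 0.3, 0.5, 0.7, 0.9, 1.0}) are chosen per outer fold by an inner
5-fold CV minimising MSE on the transformed scale, with deterministic tie
breaks (smaller alpha, then larger l1_ratio). The final model refits on
all samples using the majority-vote hyperparameters across the 5 outer
folds, with the same tie break — the nested-CV literature does not
prescribe final-model assembly, so this package fixes it explicitly.
Identical data, configuration and seed reproduce the model bit for bit,
and the JSON model container round-trips predictions exactly.

Prediction imputes missing clock features with the stored training means
and reports the observed fraction as the clock-feature coverage. A
region model stores its member site lists so region means can be
recomputed on any new cohort.

## Evaluation

* **Accuracy** — MAE, MSE, RMSE, MAD (median absolute error) and R²
  (about the mean of actual). Δage is defined as actual minus predicted
  age; robustness analyses use |Δage|.
* **Depth robustness** — reads are binomially thinned (each read kept
  independently with probability p, or p = target/current mean depth);
  thinned samples are re-masked at 7x like training data before
  prediction. Mean |Δage| against realized depth is fitted with
  `m(d) = c + a·exp(-d/tau)` by bounded nonlinear least squares on
  depth-bin means (default edges 0/5/15/30/60/150/inf, chosen to include
  the conventional 5–15x and 15–150x summaries), with a deterministic
  multi-start over tau; `c` is the reported asymptote.
* **Longitudinal consistency** — for individuals with >= 2 timepoints,
  the absolute deviation of each timepoint's prediction from that
  individual's mean prediction; the cohort statistic pools all absolute
  deviations, and the SEM is the SD of that pool over the square root of
  its size (the pooling population is a package decision).
* **Rejuvenation delta** — mean(control predictions) minus the mean of
  per-condition treated means.

## Genomic-feature enrichment

Clock CpGs are intersected with annotation interval classes; per CpG a
class counts at most once. The null is 250 random CpG sets drawn from
the universe with the query's per-chromosome counts matched exactly
(sampling without replacement within each chromosome — the reproducible
reading of "similar chromosomal distribution"). Significance follows a
two-tailed one-sample t-test of the null counts against the observed
count, treating the null as normal, with Benjamini–Hochberg adjustment
across classes (raw p always reported).

Because that t statistic compares a single observed draw against the
standard error of the null *mean*, it grows with the square root of the
iteration count and is strongly anti-conservative as a test of the draw
itself: under a true null its rejection rate at alpha = 0.05 is near 1,
not 0.05 (the suite demonstrates this). A calibrated two-tailed
empirical-rank p, `2·(min(#null<=obs, #null>=obs)+1)/(n+1)`, is therefore
computed alongside and is the statistic used for calibration checks;
its type-I error sits at the nominal level (slightly conservative from
count discreteness).

## Synthetic methylome generator

The generator emulates the statistical structure the pipeline assumes,
with defaults fixed once as the package's study conditions:

* 2000 CpGs on 4 synthetic autosomes at 150 bp spacing; 375 samples with
  ages uniform on 18–90.
* baseline betas from the bimodal mixture 0.4·Beta(0.5,10) +
  0.4·Beta(10,0.5) + 0.2·Uniform(0,1) — the hypo/hyper-methylated
  landscape of real methylomes;
* 10% of sites carry linear age trends with slopes ±U(0.001, 0.004)
  beta/year, organised into blocks of geometric mean length 8 sharing a
  slope (per-site jitter SD 0.0005, baseline jitter SD 0.02) — the
  co-methylation structure region features exploit. Slopes are anchored
  at age 54 (the midpoint of the default range) independently of any
  evaluation cohort's donor ages, so all cohort kinds share one site
  truth;
* per-sample biological noise SD 0.03 on the true beta, clipped to
  [0, 1];
* per-sample mean depth uniform on 20–40x (≈30x mean), per-site depth
  Poisson, 2% dropout; methylated counts Binomial(depth, true beta);
* longitudinal replicates fix each individual's biological noise and add
  per-visit noise (SD 0.01) and fresh read sampling, with ages advancing
  0.375 years per visit; interventions generate treated samples at
  epigenetic age max(0, chronological − offset).

All randomness flows from one master seed through named substreams, so
the site-level truth is identical across cohort kinds and each stage is
independently reproducible.

What the generator does **not** emulate: overdispersed, site-biased
capture depth (real panels leave many CpGs uncovered at low mean depth;
Poisson depth at 10x leaves almost none), cell-composition mixtures, SNP
interference, nonlinear age trajectories (a logistic option exists but
linear is the default, matching Pearson-based feature selection), and
batch effects. Passing tests therefore demonstrate correctness and
internal consistency of the machinery, not clinical performance on real
methylomes.

## Numerical choices and known limitations

* Percent-style reports round half away from zero; model serialization
  uses shortest-repr floats (exact round trip).
* PCA component signs follow scikit-learn's deterministic convention.
* The depth-bin asymptote fit requires >= 6 points across >= 3 bins and
  errors (with diagnostics) rather than extrapolating from fewer.
* Predictions below the adult-age knot are structurally compressed:
  features vary linearly with age while the regression target is
  logarithmic below 20 years, and the penalised fit shrinks long
  extrapolations. Rejuvenation deltas into early childhood are therefore
  underestimated by several years — visible in the bundled
  intervention-recovery analysis.
* At low coverage the dominant error term is imputation shrinkage: cells
  masked below 7x are replaced by training means, which pulls PCA scores
  (and hence predictions) toward the training mean roughly in proportion
  to the missing fraction. Region features buffer this — a region mean
  survives as long as any member is observed — which is exactly the
  regime where the region clock outperforms the single-CpG clock in the
  bundled depth scan.

## Problem sizes

The default suite and the acceptance script run the full pipeline at
375 samples × 2000 sites (300/75 split), a 150-sample evaluation cohort
at 120x for thinning, 200 × 250 Monte-Carlo iterations for enrichment
calibration, and 32 replicates per intervention arm; these sizes give
stable estimates of every reported quantity on a single CPU in a few
minutes.
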