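"""PCA-ElasticNet epigenetic clocks on a log-linear transformed age scale.

Training pipeline, fitted strictly inside each cross-validation training
part to avoid leakage:

1. mean imputation of missing feature values,
2. z-score standardisation (population SD, epsilon-floored),
3. pre-selection of features by absolute Pearson correlation with
   chronological age (top-K or threshold),
4. PCA to a variance fraction (or fixed component count),
5. ElasticNet regression of transformed age on the PCA scores, with the
   penalty pair chosen by an inner cross-validation loop.

The regression target is F(age), the piecewise log/linear transform of
Horvath with the adult-age knot at 20 years:

    F(a) = log(a + 1) - log(adult + 1)    for a <= adult
    F(a) = (a - adult) / (adult + 1)      for a >  adult

Reported predictions and metrics are always inverse-transformed to years.
Final-model hyperparameters are the majority vote over the outer folds
(ties: smaller alpha, then larger l1_ratio); the final model is refit on
all samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from sklearn.decomposition import PCA
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet
from sklearn.model_selection import KFold

from .io import CohortMatrix, parse_site_id

SCALE_EPS = 1e-8

_DEFAULT_ALPHAS = tuple(float(a) for a in np.logspace(-3, 2, 20))
_DEFAULT_L1 = (0.1, 0.3, 0.5, 0.7, 0.9, 1.0)


@dataclass(frozen=True)
class AgeTransform:
    """Piecewise log/linear age transform; F(adult_age) = 0, continuous and
    strictly increasing."""

    adult_age: float = 20.0

    def forward(self, age):
        age = np.asarray(age, dtype=float)
        if np.any(age < 0):
            raise ValueError("age must be non-negative")
        adult = self.adult_age
        out = np.where(
            age <= adult,
            np.log(age + 1.0) - np.log(adult + 1.0),
            (age - adult) / (adult + 1.0),
        )
        return out if out.ndim else float(out)

    def inverse(self, y):
        y = np.asarray(y, dtype=float)
        adult = self.adult_age
        out = np.where(
            y <= 0,
            (adult + 1.0) * np.exp(y) - 1.0,
            y * (adult + 1.0) + adult,
        )
        return out if out.ndim else float(out)


def transform_age(age, adult_age: float = 20.0):
    return AgeTransform(adult_age).forward(age)


def inverse_transform_age(y, adult_age: float = 20.0):
    return AgeTransform(adult_age).inverse(y)


@dataclass
class TrainConfig:
    """Training hyperparameters and search grids.

    ``corr_select_top_k`` / ``corr_select_min_abs_r``: feature pre-selection
    by |Pearson r| with chronological age (top-K wins if both set; both None
    disables selection).  PCA retains ``pca_variance_fraction`` of variance
    unless ``pca_n_components`` fixes the count.
    """

    corr_select_top_k: int | None = 20000
    corr_select_min_abs_r: float | None = None
    pca_variance_fraction: float = 0.95
    pca_n_components: int | None = None
    en_alpha_grid: tuple[float, ...] = _DEFAULT_ALPHAS
    en_l1_ratio_grid: tuple[float, ...] = _DEFAULT_L1
    outer_folds: int = 5
    inner_folds: int = 5
    seed: int = 0
    adult_age: float = 20.0
    en_max_iter: int = 5000

    def __post_init__(self):
        if not self.en_alpha_grid or not self.en_l1_ratio_grid:
            raise ValueError("hyperparameter grids must be non-empty")
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("fold counts must be >= 2")

    def to_dict(self) -> dict:
        return {
            "corr_select_top_k": self.corr_select_top_k,
            "corr_select_min_abs_r": self.corr_select_min_abs_r,
            "pca_variance_fraction": self.pca_variance_fraction,
            "pca_n_components": self.pca_n_components,
            "en_alpha_grid": list(self.en_alpha_grid),
            "en_l1_ratio_grid": list(self.en_l1_ratio_grid),
            "outer_folds": self.outer_folds,
            "inner_folds": self.inner_folds,
            "seed": self.seed,
            "adult_age": self.adult_age,
            "en_max_iter": self.en_max_iter,
        }


@dataclass
class ClockModel:
    """Frozen artifact of training, sufficient to predict from raw features.

    ``feature_ids`` are the selected features; imputation means and scaling
    parameters are stored per selected feature.  For region clocks,
    ``feature_sites`` maps each region feature id to its member CpG ids so
    region means can be recomputed on new samples.
    """

    feature_kind: str  # 'cpg' | 'region' | 'restricted_cpg'
    feature_ids: list[str]
    impute_means: np.ndarray
    scale_means: np.ndarray
    scale_sds: np.ndarray
    pca_mean: np.ndarray
    pca_components: np.ndarray  # (k, p)
    en_intercept: float
    en_coefs: np.ndarray  # (k,)
    adult_age: float = 20.0
    training_config: dict = field(default_factory=dict)
    seed: int | None = None
    feature_sites: dict[str, list[str]] | None = None

    @property
    def transform(self) -> AgeTransform:
        return AgeTransform(self.adult_age)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)


@dataclass
class FoldRecord:
    test_indices: np.ndarray
    alpha: float
    l1_ratio: float
    impute_means: np.ndarray
    n_components: int


@dataclass
class CVResult:
    oof_pred_years: np.ndarray
    folds: list[FoldRecord]
    final_alpha: float
    final_l1_ratio: float


def _pearson_with_age(z: np.ndarray, ages: np.ndarray) -> np.ndarray:
    a = ages - ages.mean()
    sa = a.std()
    if sa == 0:
        raise ValueError("ages are constant: degenerate regression target")
    zc = z - z.mean(axis=0)
    sz = z.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (zc * a[:, None]).mean(axis=0) / (sz * sa)
    r[sz == 0] = 0.0
    return r


@dataclass
class _Pipeline:
    impute_means: np.ndarray  # over all input features
    scale_means: np.ndarray
    scale_sds: np.ndarray
    selected: np.ndarray  # indices into input features
    pca_mean: np.ndarray
    pca_components: np.ndarray
    intercept: float = 0.0
    coefs: np.ndarray | None = None

    def scores(self, x: np.ndarray) -> np.ndarray:
        x = np.where(np.isnan(x), self.impute_means, x)
        z = (x - self.scale_means) / self.scale_sds
        zsel = z[:, self.selected]
        return (zsel - self.pca_mean) @ self.pca_components.T

    def predict_transformed(self, x: np.ndarray) -> np.ndarray:
        return self.intercept + self.scores(x) @ self.coefs


def _fit_front_end(x: np.ndarray, ages: np.ndarray, cfg: TrainConfig) -> _Pipeline:
    """Impute, scale, correlation-select and PCA — on training rows only."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        col_means = np.nanmean(x, axis=0)
    col_means = np.where(np.isnan(col_means), 0.5, col_means)  # all-missing feature
    xi = np.where(np.isnan(x), col_means, x)
    mu = xi.mean(axis=0)
    sd = np.maximum(xi.std(axis=0), SCALE_EPS)
    z = (xi - mu) / sd

    if cfg.corr_select_top_k is not None or cfg.corr_select_min_abs_r is not None:
        r = _pearson_with_age(z, ages)
        if cfg.corr_select_top_k is not None:
            k = min(cfg.corr_select_top_k, z.shape[1])
            selected = np.sort(np.argsort(-np.abs(r), kind="stable")[:k])
        else:
            selected = np.flatnonzero(np.abs(r) >= cfg.corr_select_min_abs_r)
        if len(selected) == 0:
            raise ValueError("no features survive correlation pre-selection")
    else:
        selected = np.arange(z.shape[1])

    n_comp = cfg.pca_n_components
    if n_comp is None:
        n_comp = cfg.pca_variance_fraction
        max_comp = min(z.shape[0], len(selected))
        if max_comp < 2:
            n_comp = 1
    pca = PCA(n_components=n_comp, svd_solver="full")
    pca.fit(z[:, selected])
    return _Pipeline(
        impute_means=col_means,
        scale_means=mu,
        scale_sds=sd,
        selected=selected,
        pca_mean=pca.mean_,
        pca_components=pca.components_,
    )


def _fit_elasticnet(scores, y, alpha, l1_ratio, cfg) -> ElasticNet:
    en = ElasticNet(
        alpha=alpha, l1_ratio=l1_ratio, max_iter=cfg.en_max_iter, tol=1e-5
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        en.fit(scores, y)
    return en


def _inner_cv_select(scores, y, cfg: TrainConfig, seed: int) -> tuple[float, float]:
    """Pick (alpha, l1_ratio) minimising inner-CV MSE on the transformed scale.

    Ties resolve to the smaller alpha, then the larger l1_ratio (the grid
    is scanned in that preference order with strict improvement).
    """
    kf = KFold(n_splits=cfg.inner_folds, shuffle=True, random_state=seed)
    splits = list(kf.split(scores))
    best = None
    combos = sorted(
        ((a, l) for a in cfg.en_alpha_grid for l in cfg.en_l1_ratio_grid),
        key=lambda t: (t[0], -t[1]),
    )
    for alpha, l1 in combos:
        sse = 0.0
        n = 0
        for tr, va in splits:
            en = _fit_elasticnet(scores[tr], y[tr], alpha, l1, cfg)
            resid = en.predict(scores[va]) - y[va]
            sse += float(resid @ resid)
            n += len(va)
        mse = sse / n
        if best is None or mse < best[0] - 1e-15:
            best = (mse, alpha, l1)
    return best[1], best[2]


def _vote_hyperparams(picks: list[tuple[float, float]]) -> tuple[float, float]:
    counts: dict[tuple[float, float], int] = {}
    for p in picks:
        counts[p] = counts.get(p, 0) + 1
    top = max(counts.values())
    tied = [p for p, c in counts.items() if c == top]
    tied.sort(key=lambda t: (t[0], -t[1]))
    return tied[0]


def fit_clock(
    features: np.ndarray,
    ages: np.ndarray,
    cfg: TrainConfig | None = None,
    feature_ids: Sequence[str] | None = None,
    feature_kind: str = "cpg",
    feature_sites: dict[str, list[str]] | None = None,
) -> tuple[ClockModel, CVResult]:
    """Train a clock with nested cross-validation.

    Returns the final model (refit on all samples with the majority-vote
    hyperparameters) and the out-of-fold predictions in years.
    """
    cfg = cfg or TrainConfig()
    x = np.asarray(features, dtype=float)
    ages = np.asarray(ages, dtype=float)
    n = len(ages)
    if x.shape[0] != n:
        raise ValueError("feature matrix and ages disagree on sample count")
    if n < max(cfg.outer_folds, 10):
        raise ValueError(
            f"need at least max(outer_folds, 10) = {max(cfg.outer_folds, 10)} samples, got {n}"
        )
    if np.ptp(ages) == 0:
        raise ValueError("ages are constant: degenerate regression target")
    if feature_ids is None:
        feature_ids = [f"f{j}" for j in range(x.shape[1])]
    feature_ids = list(feature_ids)
    if len(feature_ids) != x.shape[1]:
        raise ValueError("feature_ids length does not match feature count")

    tf = AgeTransform(cfg.adult_age)
    y = np.asarray(tf.forward(ages))

    outer = KFold(n_splits=cfg.outer_folds, shuffle=True, random_state=cfg.seed)
    oof = np.full(n, np.nan)
    folds: list[FoldRecord] = []
    picks: list[tuple[float, float]] = []
    for fold_i, (tr, te) in enumerate(outer.split(x)):
        pipe = _fit_front_end(x[tr], ages[tr], cfg)
        scores_tr = pipe.scores(x[tr])
        alpha, l1 = _inner_cv_select(
            scores_tr, y[tr], cfg, seed=cfg.seed * 1000 + fold_i
        )
        en = _fit_elasticnet(scores_tr, y[tr], alpha, l1, cfg)
        pipe.intercept, pipe.coefs = float(en.intercept_), en.coef_
        oof[te] = tf.inverse(pipe.predict_transformed(x[te]))
        picks.append((alpha, l1))
        folds.append(
            FoldRecord(
                test_indices=te,
                alpha=alpha,
                l1_ratio=l1,
                impute_means=pipe.impute_means,
                n_components=pipe.pca_components.shape[0],
            )
        )

    alpha, l1 = _vote_hyperparams(picks)
    pipe = _fit_front_end(x, ages, cfg)
    en = _fit_elasticnet(pipe.scores(x), y, alpha, l1, cfg)

    sel = pipe.selected
    model = ClockModel(
        feature_kind=feature_kind,
        feature_ids=[feature_ids[j] for j in sel],
        impute_means=pipe.impute_means[sel],
        scale_means=pipe.scale_means[sel],
        scale_sds=pipe.scale_sds[sel],
        pca_mean=pipe.pca_mean,
        pca_components=pipe.pca_components,
        en_intercept=float(en.intercept_),
        en_coefs=en.coef_,
        adult_age=cfg.adult_age,
        training_config={
            **cfg.to_dict(),
            "final_alpha": alpha,
            "final_l1_ratio": l1,
            "n_training_samples": n,
        },
        seed=cfg.seed,
        feature_sites=(
            None
            if feature_sites is None
            else {feature_ids[j]: feature_sites[feature_ids[j]] for j in sel}
        ),
    )
    cv = CVResult(oof_pred_years=oof, folds=folds, final_alpha=alpha, final_l1_ratio=l1)
    return model, cv


def fit_restricted_clock(
    features: np.ndarray,
    ages: np.ndarray,
    allowed: Sequence[int],
    cfg: TrainConfig | None = None,
    feature_ids: Sequence[str] | None = None,
) -> tuple[ClockModel, CVResult]:
    """Train with the feature set restricted to an externally given site list
    (e.g. a microarray clock's markers); correlation pre-selection is skipped.
    """
    allowed = np.asarray(sorted(set(int(a) for a in allowed)), dtype=np.intp)
    if len(allowed) == 0:
        raise ValueError("restricted feature set is empty after intersection")
    cfg = replace(cfg or TrainConfig(), corr_select_top_k=None, corr_select_min_abs_r=None)
    x = np.asarray(features, dtype=float)[:, allowed]
    ids = None
    if feature_ids is not None:
        ids = [feature_ids[j] for j in allowed]
    return fit_clock(x, ages, cfg, feature_ids=ids, feature_kind="restricted_cpg")


def predict_age(
    model: ClockModel, features: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Predict age (years) and clock-feature coverage for feature rows aligned
    to ``model.feature_ids``.

    Missing features are imputed with the stored training means; coverage is
    the fraction of clock features observed per sample.
    """
    x = np.atleast_2d(np.asarray(features, dtype=float))
    if x.shape[1] != model.n_features:
        raise ValueError(
            f"expected {model.n_features} features, got {x.shape[1]}"
        )
    coverage = 1.0 - np.isnan(x).mean(axis=1)
    xi = np.where(np.isnan(x), model.impute_means, x)
    z = (xi - model.scale_means) / model.scale_sds
    scores = (z - model.pca_mean) @ model.pca_components.T
    years = model.transform.inverse(model.en_intercept + scores @ model.en_coefs)
    return np.atleast_1d(years), coverage


def features_for_model(model: ClockModel, cohort: CohortMatrix) -> np.ndarray:
    """Build the samples x model-features matrix from a cohort.

    CpG features are looked up by site id; region features are recomputed
    as the mean of observed member betas.  Features whose sites are absent
    from the cohort's universe come out missing (then imputed at predict
    time).
    """
    s = cohort.n_samples
    out = np.full((s, model.n_features), np.nan)
    if model.feature_kind in ("cpg", "restricted_cpg"):
        for j, fid in enumerate(model.feature_ids):
            ordinal = cohort.universe.ordinal(*parse_site_id(fid))
            if ordinal is not None:
                out[:, j] = cohort.beta[:, ordinal]
    elif model.feature_kind == "region":
        if not model.feature_sites:
            raise ValueError("region model lacks member site lists")
        for j, fid in enumerate(model.feature_ids):
            ords = [
                o
                for sid in model.feature_sites[fid]
                if (o := cohort.universe.ordinal(*parse_site_id(sid))) is not None
            ]
            if ords:
                block = cohort.beta[:, ords]
                obs = (~np.isnan(block)).sum(axis=1)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
                    means = np.nanmean(block, axis=1)
                out[:, j] = np.where(obs > 0, means, np.nan)
    else:
        raise ValueError(f"unknown feature kind {model.feature_kind!r}")
    return out


def predict_cohort(model: ClockModel, cohort: CohortMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Predict ages for every sample of a cohort (years, coverage)."""
    return predict_age(model, features_for_model(model, cohort))


def train_test_split_indices(
    n: int, test_fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic shuffled split; returns (train_mask, test_indices).

    The held-out count is round(test_fraction * n).
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_test = int(round(test_fraction * n))
    test_idx = np.sort(order[:n_test])
    mask = np.ones(n, dtype=bool)
    mask[test_idx] = False
    return mask, test_idx
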