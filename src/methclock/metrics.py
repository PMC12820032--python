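"""Evaluation of clock predictions.

Accuracy metrics (MAE, MSE, RMSE, MAD, R²), signed and absolute Δage
(defined as actual minus predicted age), intra-individual longitudinal
consistency, depth-robustness via binomial read thinning with an
exponential-plus-asymptote fit of |Δage| against coverage, and
rejuvenation deltas between control and treated groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .io import CohortMatrix, SampleMethylome

#: default depth-bin edges (x coverage); 5-15x and 15-150x appear as edges
#: because low-coverage robustness is conventionally summarised over them.
DEFAULT_DEPTH_BINS = (0.0, 5.0, 15.0, 30.0, 60.0, 150.0, np.inf)


@dataclass
class MetricsReport:
    mae: float
    mse: float
    rmse: float
    mad: float  # median absolute error
    r2: float | None  # None when actual is constant
    n: int
    group: str | None = None

    def to_dict(self) -> dict:
        return {
            "mae": self.mae,
            "mse": self.mse,
            "rmse": self.rmse,
            "mad": self.mad,
            "r2": self.r2,
            "n": self.n,
            "group": self.group,
        }


def regression_metrics(
    predicted: Sequence[float], actual: Sequence[float], group: str | None = None
) -> MetricsReport:
    """Standard regression metrics in years; R² about the mean of actual."""
    p = np.asarray(predicted, dtype=float)
    a = np.asarray(actual, dtype=float)
    if p.shape != a.shape or p.ndim != 1:
        raise ValueError("predicted and actual must be equal-length 1-D")
    if len(p) == 0:
        raise ValueError("empty input")
    resid = p - a
    mse = float(np.mean(resid**2))
    sstot = float(np.sum((a - a.mean()) ** 2))
    r2 = None if sstot == 0 else 1.0 - float(np.sum(resid**2)) / sstot
    return MetricsReport(
        mae=float(np.mean(np.abs(resid))),
        mse=mse,
        rmse=float(np.sqrt(mse)),
        mad=float(np.median(np.abs(resid))),
        r2=r2,
        n=len(p),
        group=group,
    )


def delta_age(
    predicted: Sequence[float], actual: Sequence[float]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample signed Δage = actual - predicted, plus its absolute value."""
    p = np.asarray(predicted, dtype=float)
    a = np.asarray(actual, dtype=float)
    if p.shape != a.shape:
        raise ValueError("predicted and actual must be paired")
    signed = a - p
    return signed, np.abs(signed)


@dataclass
class ConsistencyReport:
    """Intra-individual spread of repeated predictions.

    Each timepoint's prediction is compared with the individual's mean
    prediction; the cohort statistic pools the absolute deviations.
    Individuals with fewer than two timepoints are excluded.
    """

    per_individual: pd.DataFrame  # individual_id, n_timepoints, mean_abs_deviation
    mean_abs_deviation: float
    sem: float
    n_individuals: int
    n_observations: int


def longitudinal_consistency(
    predictions: pd.DataFrame,
    pred_col: str = "predicted_age",
    id_col: str = "individual_id",
) -> ConsistencyReport:
    """Deviation of each timepoint prediction from the individual's mean.

    SEM is the SD of the pooled absolute deviations divided by the square
    root of their count.
    """
    eligible = predictions.groupby(id_col)[pred_col].transform("size") >= 2
    df = predictions[eligible]
    if df.empty:
        raise ValueError("no individual has >= 2 timepoints")
    dev = (df[pred_col] - df.groupby(id_col)[pred_col].transform("mean")).abs()
    per_ind = (
        df.assign(_dev=dev)
        .groupby(id_col)
        .agg(n_timepoints=(pred_col, "size"), mean_abs_deviation=("_dev", "mean"))
        .reset_index()
    )
    pooled = dev.to_numpy()
    return ConsistencyReport(
        per_individual=per_ind,
        mean_abs_deviation=float(pooled.mean()),
        sem=float(pooled.std(ddof=0) / np.sqrt(len(pooled))),
        n_individuals=int(len(per_ind)),
        n_observations=int(len(pooled)),
    )


def downsample_depth(
    sample: SampleMethylome,
    retention: float | None = None,
    target_mean_depth: float | None = None,
    seed: int | np.random.Generator = 0,
) -> SampleMethylome:
    """Binomially thin reads: each read survives independently with
    probability p.

    ``retention`` gives p directly; ``target_mean_depth`` sets
    p = target / current mean depth, capped at 1.  Sites thinned to depth 0
    become missing.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if (retention is None) == (target_mean_depth is None):
        raise ValueError("give exactly one of retention or target_mean_depth")
    if retention is None:
        current = float(sample.depth.mean())
        if current <= 0:
            raise ValueError("sample has no reads to thin")
        retention = min(1.0, target_mean_depth / current)
    if not 0.0 <= retention <= 1.0:
        raise ValueError(f"retention probability {retention} outside [0, 1]")
    return SampleMethylome(
        sample_id=sample.sample_id,
        universe=sample.universe,
        n_meth=rng.binomial(sample.n_meth, retention),
        n_unmeth=rng.binomial(sample.n_unmeth, retention),
        meta=dict(sample.meta),
    )


def downsample_cohort(
    cohort: CohortMatrix,
    target_mean_depth: float,
    seed: int | np.random.Generator = 0,
) -> CohortMatrix:
    """Thin every sample of a cohort toward a target mean depth (per-sample
    retention probability), preserving metadata."""
    if cohort.meth is None:
        raise ValueError("cohort does not carry read counts; cannot thin")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    current = cohort.depth.mean(axis=1)
    p = np.minimum(1.0, target_mean_depth / np.maximum(current, 1e-12))
    meth = rng.binomial(cohort.meth, p[:, None])
    unmeth = rng.binomial(cohort.depth - cohort.meth, p[:, None])
    depth = meth + unmeth
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = meth / depth
    beta[depth == 0] = np.nan
    return CohortMatrix(
        universe=cohort.universe,
        beta=beta,
        depth=depth,
        samples=cohort.samples,
        meth=meth,
    )


@dataclass
class DepthCurveFit:
    """Exponential-decay-to-asymptote fit m(d) = c + a * exp(-d / tau)."""

    asymptote: float  # c, years
    amplitude: float  # a, years
    rate: float  # tau, depth units
    bin_means: pd.DataFrame  # mean_depth, mean_abs_delta_age, n per bin

    def curve(self, depth):
        depth = np.asarray(depth, dtype=float)
        return self.asymptote + self.amplitude * np.exp(-depth / self.rate)


def fit_depth_asymptote(
    depths: Sequence[float],
    abs_delta_age: Sequence[float],
    bins: Sequence[float] = DEFAULT_DEPTH_BINS,
) -> DepthCurveFit:
    """Fit m(d) = c + a exp(-d/tau) to depth-binned mean |Δage|.

    Points are first aggregated into depth bins; the nonlinear least
    squares runs on the (bin mean depth, bin mean |Δage|) pairs with a
    deterministic multi-start over tau and bounds c, a >= 0.
    """
    d = np.asarray(depths, dtype=float)
    m = np.asarray(abs_delta_age, dtype=float)
    if d.shape != m.shape or d.ndim != 1:
        raise ValueError("depths and |Δage| must be equal-length 1-D")
    if len(d) < 6:
        raise ValueError("need at least 6 (depth, |Δage|) points")
    edges = np.asarray(bins, dtype=float)
    which = np.digitize(d, edges[1:-1])
    rows = []
    for b in range(len(edges) - 1):
        sel = which == b
        if sel.any():
            rows.append((float(d[sel].mean()), float(m[sel].mean()), int(sel.sum())))
    if len(rows) < 3:
        raise ValueError("points span fewer than 3 depth bins")
    bd = np.array([r[0] for r in rows])
    bm = np.array([r[1] for r in rows])

    def resid(theta):
        c, a, tau = theta
        return c + a * np.exp(-bd / tau) - bm

    spread = max(bm.max() - bm.min(), 1e-6)
    best = None
    for tau0 in (1.0, 5.0, 20.0, 60.0):
        x0 = np.array([max(bm.min(), 1e-6), spread, tau0])
        try:
            sol = least_squares(
                resid, x0, bounds=([0.0, 0.0, 1e-6], [np.inf, np.inf, 1e6])
            )
        except Exception:
            continue
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise RuntimeError(
            f"asymptote fit failed from all starts (bins: {rows})"
        )
    c, a, tau = best.x
    return DepthCurveFit(
        asymptote=float(c),
        amplitude=float(a),
        rate=float(tau),
        bin_means=pd.DataFrame(
            rows, columns=["mean_depth", "mean_abs_delta_age", "n"]
        ),
    )


def rejuvenation_delta(
    control_predictions: Sequence[float],
    treated_predictions: Mapping[str, Sequence[float]],
) -> tuple[dict[str, float], float]:
    """Years of predicted-age reduction per treatment condition and overall.

    Condition delta = mean(control) - mean(treated); the overall delta
    compares the control mean with the mean of the condition means.
    """
    control = np.asarray(control_predictions, dtype=float)
    if len(control) == 0:
        raise ValueError("empty control group")
    per_condition: dict[str, float] = {}
    means = []
    for name, preds in treated_predictions.items():
        preds = np.asarray(preds, dtype=float)
        if len(preds) == 0:
            raise ValueError(f"empty treated group {name!r}")
        per_condition[name] = float(control.mean() - preds.mean())
        means.append(preds.mean())
    overall = float(control.mean() - np.mean(means))
    return per_condition, overall
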