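"""Synthetic methylome cohorts with known ground truth.

Emulates the statistical structure a sequencing-based clock pipeline
assumes: a bimodal baseline methylation landscape, a subset of CpGs whose
beta drifts linearly with age, blocks of adjacent co-methylated CpGs that
share an age slope (with small per-site jitter), per-sample biological
noise, binomial read sampling at Poisson-distributed per-site depths, and
random dropout.  Longitudinal replicates and an age-reversal intervention
reuse the same site-level truth so one trained clock can be evaluated on
all of them.

All randomness flows from one master seed through named substreams, so
site-level truth is identical across cohorts generated from the same
config, while sample-level draws differ per cohort kind.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .io import AnnotationSet, CohortMatrix, SiteUniverse

# substream labels (second entry of the seed sequence)
_STREAM_SITES = 0
_STREAM_COHORT = 1
_STREAM_EVAL = 2
_STREAM_LONGITUDINAL = 3
_STREAM_INTERVENTION = 4
_STREAM_ANNOTATIONS = 5


@dataclass
class SimConfig:
    """Generator parameters; defaults define the package's study conditions.

    Slopes are in beta units per year, anchored at ``age_anchor`` so that
    evaluation cohorts with a different donor age range still share the
    training cohort's site truth.
    """

    n_samples: int = 375
    n_sites: int = 2000
    chroms: tuple[str, ...] = ("chr1", "chr2", "chr3", "chr4")
    spacing: int = 150  # bp between adjacent CpGs
    first_pos: int = 10_000
    age_range: tuple[float, float] = (18.0, 90.0)
    age_anchor: float = 54.0  # midpoint of the default age range
    frac_age_sites: float = 0.10
    slope_low: float = 0.001
    slope_high: float = 0.004
    block_mean_length: float = 8.0  # geometric
    slope_jitter_sd: float = 0.0005
    baseline_jitter_sd: float = 0.02
    baseline_weights: tuple[float, float, float] = (0.4, 0.4, 0.2)  # lo/hi/uniform
    noise_sd: float = 0.03
    depth_lo: float = 20.0
    depth_hi: float = 40.0
    dropout: float = 0.02
    seed: int = 0

    def validate(self):
        errors = []
        if self.n_samples < 1 or self.n_sites < 1:
            errors.append("n_samples and n_sites must be positive")
        if not 0 <= self.frac_age_sites <= 1:
            errors.append("frac_age_sites must be in [0, 1]")
        if not 0 <= self.dropout <= 1:
            errors.append("dropout must be in [0, 1]")
        if self.age_range[0] < 0 or self.age_range[1] <= self.age_range[0]:
            errors.append("age_range must be non-negative and increasing")
        if self.slope_low < 0 or self.slope_high < self.slope_low:
            errors.append("slope bounds must satisfy 0 <= low <= high")
        if self.depth_lo < 0 or self.depth_hi < self.depth_lo:
            errors.append("depth bounds must satisfy 0 <= lo <= hi")
        if abs(sum(self.baseline_weights) - 1.0) > 1e-9:
            errors.append("baseline_weights must sum to 1")
        if self.noise_sd < 0 or self.block_mean_length < 1:
            errors.append("noise_sd must be >= 0 and block_mean_length >= 1")
        if errors:
            raise ValueError("invalid SimConfig: " + "; ".join(errors))


@dataclass
class SimTruth:
    """Ground truth behind a simulated cohort."""

    baseline: np.ndarray  # per-site baseline beta
    slope: np.ndarray  # per-site beta/year (0 for non-age sites)
    block_id: np.ndarray  # per-site block index, -1 outside blocks
    true_age: np.ndarray  # per-sample epigenetic age (years)
    true_beta: np.ndarray  # (S, N) noise-free expected beta per cell

    @property
    def age_site_mask(self) -> np.ndarray:
        return self.slope != 0


def _rng(cfg: SimConfig, *stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, *stream])


def _build_universe(cfg: SimConfig) -> SiteUniverse:
    per = np.full(len(cfg.chroms), cfg.n_sites // len(cfg.chroms))
    per[: cfg.n_sites % len(cfg.chroms)] += 1
    chroms, pos = [], []
    for c, k in zip(cfg.chroms, per):
        chroms.extend([c] * k)
        pos.extend(cfg.first_pos + cfg.spacing * np.arange(k))
    order = np.lexsort((pos, np.array(chroms, dtype=object)))
    return SiteUniverse(
        np.array(chroms, dtype=object)[order], np.array(pos, dtype=np.int64)[order]
    )


def _draw_baseline(rng: np.random.Generator, size: int, weights) -> np.ndarray:
    comp = rng.choice(3, size=size, p=list(weights))
    out = np.empty(size)
    out[comp == 0] = rng.beta(0.5, 10.0, size=int((comp == 0).sum()))
    out[comp == 1] = rng.beta(10.0, 0.5, size=int((comp == 1).sum()))
    out[comp == 2] = rng.uniform(0.0, 1.0, size=int((comp == 2).sum()))
    return out


def _site_truth(cfg: SimConfig, universe: SiteUniverse):
    """Per-site baseline, slope and block assignment; deterministic given
    cfg.seed regardless of which cohort kind is generated."""
    rng = _rng(cfg, _STREAM_SITES)
    n = len(universe)
    baseline = _draw_baseline(rng, n, cfg.baseline_weights)
    slope = np.zeros(n)
    block_id = np.full(n, -1, dtype=np.int64)

    target = int(round(cfg.frac_age_sites * n))
    # chromosome boundaries: a block never crosses one
    chrom_of = universe.chroms
    placed = 0
    bid = 0
    attempts = 0
    while placed < target and attempts < 50 * max(target, 1):
        attempts += 1
        length = min(int(rng.geometric(1.0 / cfg.block_mean_length)), target - placed)
        length = max(length, 1)
        start = int(rng.integers(0, n - length + 1))
        span = slice(start, start + length)
        if (block_id[span] != -1).any():
            continue
        if chrom_of[start] != chrom_of[start + length - 1]:
            continue
        block_slope = rng.choice([-1.0, 1.0]) * rng.uniform(cfg.slope_low, cfg.slope_high)
        block_base = _draw_baseline(rng, 1, cfg.baseline_weights)[0]
        slope[span] = block_slope + rng.normal(0.0, cfg.slope_jitter_sd, length)
        baseline[span] = np.clip(
            block_base + rng.normal(0.0, cfg.baseline_jitter_sd, length), 0.0, 1.0
        )
        block_id[span] = bid
        bid += 1
        placed += length
    return baseline, slope, block_id


def _read_sample(
    rng: np.random.Generator, true_beta: np.ndarray, cfg: SimConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Poisson depths, dropout, then binomial read counts per cell."""
    s, n = true_beta.shape
    mean_depth = rng.uniform(cfg.depth_lo, cfg.depth_hi, size=s)
    depth = rng.poisson(mean_depth[:, None], size=(s, n))
    if cfg.dropout > 0:
        depth[rng.random((s, n)) < cfg.dropout] = 0
    meth = rng.binomial(depth, true_beta)
    return depth.astype(np.int64), meth.astype(np.int64)


def _cohort_from_truth(
    cfg: SimConfig,
    universe: SiteUniverse,
    true_beta: np.ndarray,
    samples: pd.DataFrame,
    rng: np.random.Generator,
) -> CohortMatrix:
    depth, meth = _read_sample(rng, true_beta, cfg)
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = meth / depth
    beta[depth == 0] = np.nan
    return CohortMatrix(
        universe=universe, beta=beta, depth=depth, samples=samples, meth=meth
    )


def _expected_beta(
    cfg: SimConfig, baseline, slope, epigenetic_ages, noise: np.ndarray | None
) -> np.ndarray:
    mu = baseline[None, :] + slope[None, :] * (
        np.asarray(epigenetic_ages)[:, None] - cfg.age_anchor
    )
    if noise is not None:
        mu = mu + noise
    return np.clip(mu, 0.0, 1.0)


def simulate_cohort(
    cfg: SimConfig, stream: int = _STREAM_COHORT, id_prefix: str = "S"
) -> tuple[CohortMatrix, SimTruth]:
    """Generate a cross-sectional cohort plus its ground truth.

    ``stream`` selects the sample-level substream: the default gives the
    training/validation cohort; other values give fresh samples over the
    identical site truth (e.g. an evaluation cohort at different depth).
    """
    cfg.validate()
    universe = _build_universe(cfg)
    baseline, slope, block_id = _site_truth(cfg, universe)
    rng = _rng(cfg, stream)
    ages = rng.uniform(*cfg.age_range, size=cfg.n_samples)
    noise = rng.normal(0.0, cfg.noise_sd, size=(cfg.n_samples, len(universe)))
    true_beta = _expected_beta(cfg, baseline, slope, ages, noise)
    samples = pd.DataFrame(
        {
            "sample_id": [f"{id_prefix}{i:04d}" for i in range(cfg.n_samples)],
            "age": ages,
            "sex": np.where(rng.random(cfg.n_samples) < 0.5, "F", "M"),
        }
    )
    cohort = _cohort_from_truth(cfg, universe, true_beta, samples, rng)
    truth = SimTruth(
        baseline=baseline,
        slope=slope,
        block_id=block_id,
        true_age=ages,
        true_beta=true_beta,
    )
    return cohort, truth


def simulate_longitudinal(
    cfg: SimConfig,
    n_individuals: int,
    n_timepoints: int,
    visit_noise_sd: float = 0.01,
    spacing_years: float = 0.375,
) -> tuple[CohortMatrix, SimTruth]:
    """Repeated sampling of the same individuals over time.

    Each individual's biological noise pattern is fixed across visits;
    visits add fresh visit noise and fresh read sampling, and ages advance
    by ``spacing_years`` per timepoint.
    """
    cfg.validate()
    if n_timepoints < 2:
        raise ValueError("need at least 2 timepoints")
    universe = _build_universe(cfg)
    baseline, slope, block_id = _site_truth(cfg, universe)
    rng = _rng(cfg, _STREAM_LONGITUDINAL)
    base_ages = rng.uniform(*cfg.age_range, size=n_individuals)
    ind_noise = rng.normal(0.0, cfg.noise_sd, size=(n_individuals, len(universe)))

    rows = []
    betas = []
    for t in range(n_timepoints):
        ages_t = base_ages + t * spacing_years
        visit = rng.normal(0.0, visit_noise_sd, size=ind_noise.shape)
        betas.append(_expected_beta(cfg, baseline, slope, ages_t, ind_noise + visit))
        for i in range(n_individuals):
            rows.append(
                {
                    "sample_id": f"I{i:03d}_T{t}",
                    "age": ages_t[i],
                    "individual_id": f"I{i:03d}",
                    "timepoint": t,
                }
            )
    true_beta = np.concatenate(betas, axis=0)
    samples = pd.DataFrame(rows)
    cohort = _cohort_from_truth(cfg, universe, true_beta, samples, rng)
    truth = SimTruth(
        baseline=baseline,
        slope=slope,
        block_id=block_id,
        true_age=samples["age"].to_numpy(),
        true_beta=true_beta,
    )
    return cohort, truth


def simulate_intervention(
    cfg: SimConfig,
    age_offset: float,
    n_per_group: int = 6,
    donor_age_range: tuple[float, float] | None = None,
) -> tuple[CohortMatrix, CohortMatrix]:
    """Control vs rejuvenated cohorts over the same site truth.

    Treated samples are generated at epigenetic age max(0, chronological -
    offset); controls at chronological age.  Donor chronological ages come
    from ``donor_age_range`` (default: the config's age range).
    """
    cfg.validate()
    universe = _build_universe(cfg)
    baseline, slope, block_id = _site_truth(cfg, universe)
    rng = _rng(cfg, _STREAM_INTERVENTION)
    lo, hi = donor_age_range or cfg.age_range
    donor_ages = rng.uniform(lo, hi, size=n_per_group)

    cohorts = []
    for group, epi_ages in (
        ("control", donor_ages),
        ("treated", np.maximum(0.0, donor_ages - age_offset)),
    ):
        noise = rng.normal(0.0, cfg.noise_sd, size=(n_per_group, len(universe)))
        true_beta = _expected_beta(cfg, baseline, slope, epi_ages, noise)
        samples = pd.DataFrame(
            {
                "sample_id": [f"{group[:4].upper()}{i:02d}" for i in range(n_per_group)],
                "age": donor_ages,
                "group": group,
            }
        )
        cohorts.append(_cohort_from_truth(cfg, universe, true_beta, samples, rng))
    return cohorts[0], cohorts[1]


def simulate_annotations(
    universe: SiteUniverse,
    coverage: dict[str, float],
    enriched_class: str | None = None,
    query_ordinals: Sequence[int] | None = None,
    enriched_fraction: float = 0.5,
    window: int = 1500,
    seed: int = 0,
) -> AnnotationSet:
    """Random interval classes tiled at requested per-site coverage fractions.

    Each chromosome span is cut into fixed-width windows and each window is
    included in a class with probability equal to that class's coverage
    fraction.  Optionally, 1-bp intervals are added to ``enriched_class``
    over a random ``enriched_fraction`` of the query set, planting known
    enrichment.
    """
    rng = np.random.default_rng(seed)
    for name, f in coverage.items():
        if not 0.0 < f < 1.0:
            raise ValueError(f"class {name!r}: coverage fraction must be in (0, 1)")
    if enriched_class is not None and enriched_class not in coverage:
        raise ValueError(f"enriched class {enriched_class!r} not among classes")

    spans: list[tuple[str, int, int]] = []
    chroms = universe.chroms
    n = len(universe)
    start = 0
    for i in range(1, n + 1):
        if i == n or chroms[i] != chroms[start]:
            spans.append(
                (str(chroms[start]), int(universe.pos[start]), int(universe.pos[i - 1]) + 1)
            )
            start = i

    classes: dict[str, list[tuple[str, int, int]]] = {}
    for name, f in coverage.items():
        ivs = []
        for chrom, lo, hi in spans:
            edges = np.arange(lo, hi + window, window)
            include = rng.random(len(edges) - 1) < f
            for j in np.flatnonzero(include):
                ivs.append((chrom, int(edges[j]), int(min(edges[j + 1], hi))))
        classes[name] = ivs
    if enriched_class is not None and query_ordinals is not None:
        ords = np.asarray(query_ordinals, dtype=np.intp)
        k = int(round(enriched_fraction * len(ords)))
        chosen = rng.choice(ords, size=k, replace=False) if k else []
        for o in chosen:
            classes[enriched_class].append(
                (str(universe.chroms[o]), int(universe.pos[o]), int(universe.pos[o]) + 1)
            )
    return AnnotationSet(classes)


def eval_config(cfg: SimConfig, n_samples: int, depth: float) -> SimConfig:
    """Config for an evaluation cohort at a fixed depth over the same sites."""
    return replace(cfg, n_samples=n_samples, depth_lo=depth, depth_hi=depth)


EVAL_STREAM = _STREAM_EVAL
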