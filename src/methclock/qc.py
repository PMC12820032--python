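"""Sample- and site-level quality filters for sequencing methylomes.

The filter chain runs in a fixed order: sample QC (mean depth and covered
fraction), sex/mitochondrial chromosome removal, per-cell low-depth
masking, then a site missingness filter computed on the training split
only (the test split never informs which sites survive).

All thresholds mirror strict exclusion wording: a sample fails when its
mean depth is *less than* 15x, a cell is masked when its depth is *less
than* 7x, a site is dropped when missing in *more than* 70% of training
samples — exact-threshold values are kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CohortMatrix, SiteUniverse, normalize_chrom

DEFAULT_EXCLUDED = ("chrX", "chrY", "chrM")


@dataclass
class QCConfig:
    min_sample_mean_depth: float = 15.0
    min_sample_covered_fraction: float = 0.90
    min_site_depth: int = 7
    max_site_missing_fraction: float = 0.70
    excluded_chromosomes: frozenset[str] = field(
        default_factory=lambda: frozenset(DEFAULT_EXCLUDED)
    )

    def __post_init__(self):
        if self.min_sample_mean_depth < 0 or self.min_site_depth < 0:
            raise ValueError("depth thresholds must be non-negative")
        for frac in (self.min_sample_covered_fraction, self.max_site_missing_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fraction thresholds must lie in [0, 1]")
        # normalize aliases (X, MT, chrM, ...) once at construction
        object.__setattr__(
            self,
            "excluded_chromosomes",
            frozenset(normalize_chrom(c) for c in self.excluded_chromosomes),
        )


def sample_qc(cohort: CohortMatrix, cfg: QCConfig) -> tuple[np.ndarray, pd.DataFrame]:
    """Flag samples passing the mean-depth and covered-fraction criteria.

    A sample passes iff its mean depth over *all* universe sites is at
    least ``min_sample_mean_depth`` and the fraction of sites with depth
    >= 1 is at least ``min_sample_covered_fraction``.
    """
    if cohort.n_sites == 0:
        raise ValueError("cannot run sample QC against an empty site universe")
    mean_depth = cohort.depth.mean(axis=1)
    covered = (cohort.depth >= 1).mean(axis=1)
    passed = (mean_depth >= cfg.min_sample_mean_depth) & (
        covered >= cfg.min_sample_covered_fraction
    )
    report = pd.DataFrame(
        {
            "sample_id": cohort.samples["sample_id"],
            "mean_depth": mean_depth,
            "covered_fraction": covered,
            "pass": passed,
        }
    )
    return passed, report


def drop_excluded_chromosomes(
    universe: SiteUniverse, cfg: QCConfig
) -> tuple[SiteUniverse, np.ndarray]:
    """Remove sites on excluded chromosomes (default chrX/chrY/chrM).

    Returns the reduced universe and the ordinals (into the input universe)
    of the retained sites, in order.
    """
    keep = np.array(
        [c not in cfg.excluded_chromosomes for c in universe.chroms.tolist()],
        dtype=bool,
    )
    ordinals = np.flatnonzero(keep)
    return universe.subset(ordinals), ordinals


def mask_low_depth(cohort: CohortMatrix, cfg: QCConfig) -> CohortMatrix:
    """Set beta to missing wherever cell depth < min_site_depth.

    Depth values (and read counts) are retained for reporting and for
    later binomial thinning.
    """
    beta = cohort.beta.copy()
    beta[cohort.depth < cfg.min_site_depth] = np.nan
    return CohortMatrix(
        universe=cohort.universe,
        beta=beta,
        depth=cohort.depth,
        samples=cohort.samples,
        meth=cohort.meth,
    )


def missingness_filter(training_cohort: CohortMatrix, cfg: QCConfig) -> np.ndarray:
    """Ordinals of sites missing in at most ``max_site_missing_fraction``
    of *training* samples.

    Must be computed on the training split only; the returned subset is
    then applied to both splits downstream (leakage control).
    """
    if training_cohort.n_samples == 0:
        raise ValueError("missingness filter needs at least one training sample")
    missing_frac = np.isnan(training_cohort.beta).mean(axis=0)
    return np.flatnonzero(missing_frac <= cfg.max_site_missing_fraction)


def qc_summary(report: pd.DataFrame) -> dict:
    return {
        "n_samples": int(len(report)),
        "n_pass": int(report["pass"].sum()),
        "n_fail": int((~report["pass"]).sum()),
        "mean_depth_min": float(report["mean_depth"].min()),
        "mean_depth_max": float(report["mean_depth"].max()),
    }


def apply_qc_pipeline(
    cohort: CohortMatrix,
    cfg: QCConfig,
    train_mask: np.ndarray,
) -> tuple[CohortMatrix, CohortMatrix, dict]:
    """Run the full filter chain and return (train, test) filtered cohorts.

    Order: sample QC -> excluded-chromosome removal -> low-depth masking ->
    missingness filter fitted on the training split and applied to both.
    The chain is idempotent on already-filtered data.
    """
    train_mask = np.asarray(train_mask, dtype=bool)
    passed, report = sample_qc(cohort, cfg)
    cohort = cohort.subset_samples(passed)
    train_mask = train_mask[passed]

    _, kept = drop_excluded_chromosomes(cohort.universe, cfg)
    cohort = cohort.subset_sites(kept)
    cohort = mask_low_depth(cohort, cfg)

    train = cohort.subset_samples(train_mask)
    test = cohort.subset_samples(~train_mask)
    surviving = missingness_filter(train, cfg)
    info = {
        "sample_qc": qc_summary(report),
        "n_sites_after_chrom_filter": int(cohort.n_sites),
        "n_sites_after_missingness": int(len(surviving)),
    }
    return train.subset_sites(surviving), test.subset_sites(surviving), info
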