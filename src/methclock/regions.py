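"""Co-methylated region construction from per-CpG age correlations.

Adjacent CpGs (consecutive in the filtered site list, on one chromosome)
are merged into a region while each candidate site's age correlation stays
within a tolerance of both the region's first (anchor) site and the
immediately preceding site.  Regions need at least ``min_region_size``
members (default 3) to be kept; each region's feature value for a sample
is the unweighted mean of its observed member betas.

The dual anchor+consecutive constraint is the default reading of
"coordinated correlation" merging: the anchor term bounds drift across the
region, the consecutive term enforces local smoothness.  ``mode`` exposes
the single-constraint alternatives.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import CohortMatrix, SiteUniverse

MODES = ("both", "anchor_only", "consecutive_only")


@dataclass
class AgeCorrelations:
    """Per-site Pearson correlation of beta with chronological age.

    ``r`` is NaN (undefined) where fewer than ``min_obs`` samples are
    observed or the site's beta has zero variance.
    """

    r: np.ndarray
    n_obs: np.ndarray


@dataclass
class Region:
    chrom: str
    ordinals: np.ndarray  # consecutive ascending, into the filtered site list
    anchor_r: float

    @property
    def size(self) -> int:
        return len(self.ordinals)


@dataclass
class RegionSet:
    regions: list[Region]
    tolerance: float

    def __len__(self) -> int:
        return len(self.regions)

    def feature_ids(self, universe: SiteUniverse) -> list[str]:
        ids = []
        for reg in self.regions:
            first, last = reg.ordinals[0], reg.ordinals[-1]
            ids.append(f"{reg.chrom}:{universe.pos[first]}-{universe.pos[last] + 1}")
        return ids

    def member_site_ids(self, universe: SiteUniverse) -> dict[str, list[str]]:
        out = {}
        for fid, reg in zip(self.feature_ids(universe), self.regions):
            out[fid] = [universe.site_ids[i] for i in reg.ordinals]
        return out


def age_correlation(
    cohort: CohortMatrix,
    site_ordinals: np.ndarray | None = None,
    min_obs: int = 10,
) -> AgeCorrelations:
    """Pearson correlation of each site's observed betas with sample age.

    Missing cells are excluded pairwise per site.  Undefined (NaN) when
    fewer than ``min_obs`` observations remain or the observed betas (or
    the corresponding ages) have zero variance.
    """
    if cohort.n_samples < 2:
        raise ValueError("age correlation needs at least 2 samples")
    beta = cohort.beta
    if site_ordinals is not None:
        beta = beta[:, np.asarray(site_ordinals, dtype=np.intp)]
    ages = cohort.ages
    obs = ~np.isnan(beta)
    n = obs.sum(axis=0).astype(float)

    b = np.where(obs, beta, 0.0)
    a = ages[:, None] * obs
    with np.errstate(invalid="ignore", divide="ignore"):
        mb = b.sum(axis=0) / n
        ma = a.sum(axis=0) / n
        cov = ((b - mb) * (a - ma) * obs).sum(axis=0) / n
        vb = (((b - mb) ** 2) * obs).sum(axis=0) / n
        va = (((a - ma) ** 2) * obs).sum(axis=0) / n
        r = cov / np.sqrt(vb * va)
    r[(n < min_obs) | (vb <= 0) | (va <= 0)] = np.nan
    r = np.clip(r, -1.0, 1.0)
    return AgeCorrelations(r=r, n_obs=obs.sum(axis=0))


def build_regions(
    universe: SiteUniverse,
    corr: AgeCorrelations,
    tolerance: float = 0.075,
    min_region_size: int = 3,
    mode: str = "both",
    max_gap: int | None = None,
) -> RegionSet:
    """Greedy left-to-right single-pass merge of adjacent CpGs.

    A region opens at the first unassigned site with defined r.  The next
    site joins iff it is on the same chromosome, has defined r, satisfies
    the tolerance constraint(s) of ``mode`` (strict ``<``), and — when
    ``max_gap`` is set — lies within that many bases of the previous
    member.  Any failure closes the region (kept only if it has at least
    ``min_region_size`` members) and the failing site starts a new one.
    Undefined-r sites and chromosome changes always close the region.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    r = corr.r
    if len(r) != len(universe):
        raise ValueError("correlations not aligned to the site list")

    regions: list[Region] = []
    start = prev = anchor = None  # current run: start ordinal, prev ordinal

    def close(end_exclusive: int):
        nonlocal start
        if start is not None and end_exclusive - start >= min_region_size:
            ords = np.arange(start, end_exclusive)
            regions.append(
                Region(
                    chrom=str(universe.chroms[start]),
                    ordinals=ords,
                    anchor_r=float(r[start]),
                )
            )
        start = None

    for i in range(len(r)):
        if np.isnan(r[i]):
            close(i)
            continue
        if start is None:
            start = i
            continue
        ok = universe.chroms[i] == universe.chroms[start]
        if ok and max_gap is not None:
            ok = universe.pos[i] - universe.pos[i - 1] <= max_gap
        if ok and mode in ("both", "anchor_only"):
            ok = abs(r[i] - r[start]) < tolerance
        if ok and mode in ("both", "consecutive_only"):
            ok = abs(r[i] - r[i - 1]) < tolerance
        if not ok:
            close(i)
            start = i
    close(len(r))
    return RegionSet(regions=regions, tolerance=tolerance)


def region_betas(
    cohort: CohortMatrix, regions: RegionSet
) -> tuple[np.ndarray, np.ndarray]:
    """Samples x regions mean-beta matrix plus member-observation counts.

    A cell is the unweighted mean of the observed member betas; missing iff
    every member is missing in that sample.  An empty region set yields a
    zero-column matrix.
    """
    s = cohort.n_samples
    k = len(regions)
    out = np.full((s, k), np.nan)
    counts = np.zeros((s, k), dtype=np.int64)
    for j, reg in enumerate(regions.regions):
        block = cohort.beta[:, reg.ordinals]
        obs = (~np.isnan(block)).sum(axis=1)
        counts[:, j] = obs
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
            means = np.nanmean(block, axis=1)
        out[:, j] = np.where(obs > 0, means, np.nan)
    return out, counts


def write_regions_bed(regions: RegionSet, universe: SiteUniverse, path, members_path=None):
    """Export regions as BED6+ (chrom, start, end, id, size, anchor_r) with an
    optional member-list sidecar TSV."""
    ids = regions.feature_ids(universe)
    with open(path, "w") as fh:
        for fid, reg in zip(ids, regions.regions):
            first, last = reg.ordinals[0], reg.ordinals[-1]
            fh.write(
                f"{reg.chrom}\t{universe.pos[first]}\t{universe.pos[last] + 1}\t"
                f"{fid}\t{reg.size}\t{reg.anchor_r:.6f}\n"
            )
    if members_path is not None:
        with open(members_path, "w") as fh:
            fh.write("region_id\tsite_id\n")
            for fid, sites in regions.member_site_ids(universe).items():
                for sid in sites:
                    fh.write(f"{fid}\t{sid}\n")
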