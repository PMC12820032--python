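"""Monte Carlo enrichment of clock CpGs in genomic feature classes.

The observed overlap count of a query CpG set with each annotation class
is compared against 250 random CpG sets drawn from the site universe with
the query's per-chromosome counts matched exactly (sampling without
replacement within each chromosome).  Per CpG, overlap with a class is
counted at most once however many intervals it falls in.

Significance follows a two-tailed one-sample t-test of the null counts
against the observed count as hypothesised mean (the null distribution is
treated as normal).  Note this statistic scales with the square root of
the iteration count and is anti-conservative as a test of the single
observed draw; a calibrated empirical-rank p-value is therefore computed
alongside it, and Benjamini-Hochberg adjustment is applied across classes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import AnnotationSet, SiteUniverse

DEFAULT_N_ITER = 250


@dataclass
class EnrichmentResult:
    class_name: str
    observed_count: int
    null_counts: np.ndarray
    null_mean: float
    null_sd: float
    t_statistic: float | None
    p_two_tailed: float
    p_empirical: float
    p_adjusted: float | None
    direction: str  # 'enriched' | 'depleted' | 'neutral'
    degenerate: bool = False


def class_membership(universe: SiteUniverse, ann: AnnotationSet) -> np.ndarray:
    """Boolean (classes x sites) matrix: site falls in >= 1 interval of class.

    Intervals are merged per chromosome and membership resolved with a
    searchsorted sweep, so overlapping intervals of one class cannot double
    count.
    """
    n = len(universe)
    out = np.zeros((len(ann.classes), n), dtype=bool)
    chroms = universe.chroms
    pos = universe.pos
    # contiguous ordinal ranges per chromosome (universe is sorted)
    bounds: dict[str, tuple[int, int]] = {}
    start = 0
    for i in range(1, n + 1):
        if i == n or chroms[i] != chroms[start]:
            bounds[str(chroms[start])] = (start, i)
            start = i
    for ci, (name, ivs) in enumerate(ann.classes.items()):
        per_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, s, e in ivs:
            per_chrom.setdefault(chrom, []).append((s, e))
        for chrom, spans in per_chrom.items():
            if chrom not in bounds:
                continue
            lo, hi = bounds[chrom]
            spans.sort()
            merged = []
            for s, e in spans:
                if merged and s <= merged[-1][1]:
                    merged[-1] = (merged[-1][0], max(merged[-1][1], e))
                else:
                    merged.append((s, e))
            starts = np.array([s for s, _ in merged])
            ends = np.array([e for _, e in merged])
            p = pos[lo:hi]
            idx = np.searchsorted(starts, p, side="right") - 1
            hit = (idx >= 0) & (p < ends[np.maximum(idx, 0)])
            out[ci, lo:hi] = hit
    return out


def count_overlaps(
    universe: SiteUniverse,
    cpg_ordinals: Sequence[int],
    ann: AnnotationSet,
    membership: np.ndarray | None = None,
) -> dict[str, int]:
    """Per class, the number of query CpGs inside >= 1 interval of the class."""
    if membership is None:
        membership = class_membership(universe, ann)
    ords = np.asarray(cpg_ordinals, dtype=np.intp)
    counts = membership[:, ords].sum(axis=1)
    return {name: int(c) for name, c in zip(ann.classes, counts)}


def sample_matched_random_sets(
    universe: SiteUniverse,
    query_ordinals: Sequence[int],
    n_iter: int = DEFAULT_N_ITER,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Draw ``n_iter`` random CpG sets matching the query's per-chromosome
    counts exactly (without replacement within each chromosome).

    Returns an (n_iter, |query|) array of universe ordinals.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ords = np.asarray(query_ordinals, dtype=np.intp)
    chroms = universe.chroms
    n = len(universe)
    # per-chromosome ordinal ranges
    ranges: list[tuple[str, int, int]] = []
    start = 0
    for i in range(1, n + 1):
        if i == n or chroms[i] != chroms[start]:
            ranges.append((str(chroms[start]), start, i))
            start = i
    query_per_chrom = {}
    for o in ords:
        c = str(chroms[o])
        query_per_chrom[c] = query_per_chrom.get(c, 0) + 1

    pieces = []
    for chrom, lo, hi in ranges:
        k = query_per_chrom.pop(chrom, 0)
        if k == 0:
            continue
        avail = hi - lo
        if k > avail:
            raise ValueError(
                f"chromosome {chrom}: query needs {k} sites but universe has {avail}"
            )
        # rank-of-uniforms: first k columns of an argsort are a uniform
        # without-replacement draw, vectorised over iterations
        u = rng.random((n_iter, avail))
        take = np.argpartition(u, k - 1, axis=1)[:, :k] if k < avail else np.tile(
            np.arange(avail), (n_iter, 1)
        )
        pieces.append(take + lo)
    if query_per_chrom:
        missing = sorted(query_per_chrom)
        raise ValueError(f"query chromosomes absent from universe: {missing}")
    return np.concatenate(pieces, axis=1) if pieces else np.empty((n_iter, 0), dtype=np.intp)


def enrichment_test(
    observed_count: int,
    null_counts: Sequence[int],
    class_name: str = "",
) -> EnrichmentResult:
    """Two-tailed one-sample t-test of null counts vs the observed count,
    plus a calibrated empirical-rank p-value.

    Degenerate zero-variance nulls: p = 1 when the observed count equals
    the null value, otherwise reported as 1/n_iter with the degeneracy
    flag set.
    """
    null = np.asarray(null_counts, dtype=float)
    if len(null) < 2:
        raise ValueError("need at least 2 null counts")
    mean, sd = float(null.mean()), float(null.std(ddof=1))
    n = len(null)
    degenerate = sd == 0.0
    if degenerate:
        t = None
        p = 1.0 if observed_count == mean else 1.0 / n
    else:
        t_res = stats.ttest_1samp(null, popmean=observed_count)
        t, p = float(t_res.statistic), float(t_res.pvalue)
    # two-tailed empirical rank with add-one smoothing
    n_ge = int(np.sum(null >= observed_count))
    n_le = int(np.sum(null <= observed_count))
    p_emp = min(1.0, 2.0 * (min(n_ge, n_le) + 1) / (n + 1))
    if observed_count > mean:
        direction = "enriched"
    elif observed_count < mean:
        direction = "depleted"
    else:
        direction = "neutral"
    return EnrichmentResult(
        class_name=class_name,
        observed_count=int(observed_count),
        null_counts=null.astype(int),
        null_mean=mean,
        null_sd=sd,
        t_statistic=t,
        p_two_tailed=p,
        p_empirical=p_emp,
        p_adjusted=None,
        direction=direction,
        degenerate=degenerate,
    )


def enrichment_analysis(
    universe: SiteUniverse,
    query_ordinals: Sequence[int],
    ann: AnnotationSet,
    n_iter: int = DEFAULT_N_ITER,
    seed: int | np.random.Generator = 0,
    adjust: str = "fdr_bh",
) -> list[EnrichmentResult]:
    """Full enrichment scan: matched random sets, overlap counting, t-test
    and empirical p per class, BH adjustment across classes."""
    membership = class_membership(universe, ann)
    ords = np.asarray(query_ordinals, dtype=np.intp)
    observed = membership[:, ords].sum(axis=1)
    random_sets = sample_matched_random_sets(universe, ords, n_iter=n_iter, seed=seed)
    # counts: (classes, n_iter)
    null = membership[:, random_sets].sum(axis=2)
    results = [
        enrichment_test(int(observed[ci]), null[ci], class_name=name)
        for ci, name in enumerate(ann.classes)
    ]
    if adjust and results:
        _, padj, _, _ = multipletests([r.p_two_tailed for r in results], method=adjust)
        for r, pa in zip(results, padj):
            r.p_adjusted = float(pa)
    return results
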