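"""Readers and writers for the on-disk formats of the clock pipeline.

Handles MethylDackel-dialect methylation bedGraph files (chrom, start, end,
methylation percentage, count methylated, count unmethylated), TSV sample
sheets, BED annotation files, probe manifests, and the text-based clock
model container.  Also assembles per-sample call files into cohort matrices.

Coordinates are 0-based half-open throughout; a CpG is keyed by the
position of its C on the plus strand.  Beta values are always recomputed
from the read counts — the integer-rounded percentage column is used only
for a consistency warning.  Missingness is represented uniformly as depth 0
plus a missing (NaN) beta; there are no sentinel beta values.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MODEL_FORMAT = "methclock-model"
MODEL_FORMAT_VERSION = 1

SHEET_COLUMNS = ("sample_id", "age", "individual_id", "timepoint", "group", "sex")


class ParseError(ValueError):
    """Malformed row in an input file; carries the 1-based line number."""

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


class ModelFormatError(ValueError):
    """Model container unreadable, truncated, or of an unsupported version."""


def normalize_chrom(name: str) -> str:
    """Normalize chromosome aliases to chr-prefixed form (MT -> chrM)."""
    name = name.strip()
    bare = name[3:] if name.startswith("chr") else name
    if bare == "MT":
        bare = "M"
    return "chr" + bare


def round_half_up(x: float) -> int:
    """Round to nearest integer, halves away from zero (percent reporting)."""
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


@dataclass(frozen=True)
class SiteUniverse:
    """Ordered catalogue of assayable CpG sites: the row frame for all matrices.

    Sites are unique, sorted lexicographically by (chrom, pos); the ordinal
    index is a bijection onto ``0..N-1``.
    """

    chroms: np.ndarray  # str array, len N
    pos: np.ndarray  # int64 array, len N

    def __post_init__(self):
        chroms = np.asarray(self.chroms, dtype=object)
        pos = np.asarray(self.pos, dtype=np.int64)
        object.__setattr__(self, "chroms", chroms)
        object.__setattr__(self, "pos", pos)
        if chroms.shape != pos.shape:
            raise ValueError("chroms and pos must have equal length")
        if np.any(pos < 0):
            raise ValueError("site positions must be non-negative")
        keys = list(zip(chroms.tolist(), pos.tolist()))
        if any(keys[i] >= keys[i + 1] for i in range(len(keys) - 1)):
            raise ValueError("sites must be unique and sorted by (chrom, pos)")

    @classmethod
    def from_pairs(
        cls, pairs: Iterable[tuple[str, int]], normalize: bool = True
    ) -> "SiteUniverse":
        uniq = sorted(
            {(normalize_chrom(c) if normalize else c, int(p)) for c, p in pairs}
        )
        chroms = np.array([c for c, _ in uniq], dtype=object)
        pos = np.array([p for _, p in uniq], dtype=np.int64)
        return cls(chroms, pos)

    def __len__(self) -> int:
        return len(self.pos)

    @cached_property
    def index(self) -> dict[tuple[str, int], int]:
        return {
            (c, int(p)): i
            for i, (c, p) in enumerate(zip(self.chroms.tolist(), self.pos.tolist()))
        }

    @cached_property
    def site_ids(self) -> list[str]:
        return [f"{c}:{p}" for c, p in zip(self.chroms.tolist(), self.pos.tolist())]

    def ordinal(self, chrom: str, pos: int) -> int | None:
        return self.index.get((chrom, int(pos)))

    def subset(self, ordinals: Sequence[int]) -> "SiteUniverse":
        ordinals = np.asarray(ordinals, dtype=np.intp)
        if len(ordinals) > 1 and np.any(np.diff(ordinals) <= 0):
            raise ValueError("subset ordinals must be strictly increasing")
        return SiteUniverse(self.chroms[ordinals], self.pos[ordinals])

    def chrom_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for c in self.chroms.tolist():
            counts[c] = counts.get(c, 0) + 1
        return counts


def parse_site_id(site_id: str) -> tuple[str, int]:
    chrom, _, pos = site_id.rpartition(":")
    return chrom, int(pos)


@dataclass
class SampleMethylome:
    """Per-sample methylation calls aligned to a site universe.

    ``beta`` is derived from read counts and is missing (NaN) wherever
    depth is zero.
    """

    sample_id: str
    universe: SiteUniverse
    n_meth: np.ndarray  # int64, len N
    n_unmeth: np.ndarray  # int64, len N
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.n_meth = np.asarray(self.n_meth, dtype=np.int64)
        self.n_unmeth = np.asarray(self.n_unmeth, dtype=np.int64)
        n = len(self.universe)
        if self.n_meth.shape != (n,) or self.n_unmeth.shape != (n,):
            raise ValueError("count arrays must match universe length")
        if np.any(self.n_meth < 0) or np.any(self.n_unmeth < 0):
            raise ValueError("read counts must be non-negative")

    @property
    def depth(self) -> np.ndarray:
        return self.n_meth + self.n_unmeth

    @property
    def beta(self) -> np.ndarray:
        depth = self.depth
        with np.errstate(invalid="ignore", divide="ignore"):
            b = self.n_meth / depth
        b[depth == 0] = np.nan
        return b

    @property
    def age(self) -> float | None:
        a = self.meta.get("age")
        return None if a is None else float(a)


@dataclass
class CohortMatrix:
    """Samples x sites beta and depth matrices with sample metadata.

    Row order matches the (sorted) sample sheet; column order matches the
    universe.  ``beta`` is float with NaN for missing cells; ``meth`` keeps
    the methylated read counts when available so that read-level binomial
    thinning remains possible downstream.
    """

    universe: SiteUniverse
    beta: np.ndarray  # float (S, N), NaN = missing
    depth: np.ndarray  # int64 (S, N)
    samples: pd.DataFrame  # columns: sample_id, age, ...
    meth: np.ndarray | None = None  # int64 (S, N) methylated counts

    def __post_init__(self):
        s, n = self.beta.shape
        if self.depth.shape != (s, n) or len(self.universe) != n:
            raise ValueError("matrix shapes inconsistent with universe")
        if len(self.samples) != s:
            raise ValueError("sample sheet length does not match matrix rows")

    @property
    def n_samples(self) -> int:
        return self.beta.shape[0]

    @property
    def n_sites(self) -> int:
        return self.beta.shape[1]

    @property
    def ages(self) -> np.ndarray:
        return self.samples["age"].to_numpy(dtype=float)

    def subset_sites(self, ordinals: Sequence[int]) -> "CohortMatrix":
        ordinals = np.asarray(ordinals, dtype=np.intp)
        return CohortMatrix(
            universe=self.universe.subset(ordinals),
            beta=self.beta[:, ordinals],
            depth=self.depth[:, ordinals],
            samples=self.samples.reset_index(drop=True),
            meth=None if self.meth is None else self.meth[:, ordinals],
        )

    def subset_samples(self, idx: Sequence[int] | np.ndarray) -> "CohortMatrix":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CohortMatrix(
            universe=self.universe,
            beta=self.beta[idx],
            depth=self.depth[idx],
            samples=self.samples.iloc[idx].reset_index(drop=True),
            meth=None if self.meth is None else self.meth[idx],
        )

    def sample(self, i: int) -> SampleMethylome:
        if self.meth is None:
            raise ValueError("cohort does not carry read counts")
        n_meth = self.meth[i]
        return SampleMethylome(
            sample_id=str(self.samples["sample_id"].iloc[i]),
            universe=self.universe,
            n_meth=n_meth,
            n_unmeth=self.depth[i] - n_meth,
            meta={k: self.samples[k].iloc[i] for k in self.samples.columns},
        )


@dataclass
class AnnotationSet:
    """Named classes of genomic intervals (0-based half-open).

    Classes may overlap each other and themselves; intervals require
    start < end.
    """

    classes: dict[str, list[tuple[str, int, int]]]

    def __post_init__(self):
        for name, ivs in self.classes.items():
            for chrom, start, end in ivs:
                if start >= end:
                    raise ValueError(
                        f"class {name!r}: interval {chrom}:{start}-{end} has start >= end"
                    )

    @property
    def names(self) -> list[str]:
        return list(self.classes)


# ---------------------------------------------------------------------------
# methylation bedGraph


def read_methyldackel_bedgraph(
    path,
    universe: SiteUniverse | None = None,
    sample_id: str | None = None,
    meta: dict | None = None,
) -> SampleMethylome:
    """Read one MethylDackel-style bedGraph into a SampleMethylome.

    Beta is computed from the two count columns, never from the (rounded)
    percentage column.  With a universe supplied, sites absent from the file
    get depth 0 / missing beta, and file sites outside the universe are
    dropped with a logged count.  Without one, the universe is built from
    the file itself.
    """
    path = Path(path)
    rows: list[tuple[str, int, int, int, float]] = []
    pct_deviations = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#")):
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise ParseError(
                    path, lineno, f"expected 6 tab-separated columns, got {len(fields)}"
                )
            chrom = normalize_chrom(fields[0])
            try:
                start, end = int(fields[1]), int(fields[2])
                pct = float(fields[3])
                nm, nu = int(fields[4]), int(fields[5])
            except ValueError as exc:
                raise ParseError(path, lineno, f"non-numeric field: {exc}") from None
            if start >= end:
                raise ParseError(path, lineno, f"start {start} >= end {end}")
            if nm < 0 or nu < 0:
                raise ParseError(path, lineno, "negative read count")
            if nm + nu > 0 and abs(pct - 100.0 * nm / (nm + nu)) > 1.0:
                pct_deviations += 1
            rows.append((chrom, start, nm, nu, pct))
    if pct_deviations:
        logger.warning(
            "%s: percentage column deviates >1 point from counts at %d sites",
            path,
            pct_deviations,
        )

    if universe is None:
        universe = SiteUniverse.from_pairs(
            [(c, p) for c, p, _, _, _ in rows], normalize=False
        )

    n_meth = np.zeros(len(universe), dtype=np.int64)
    n_unmeth = np.zeros(len(universe), dtype=np.int64)
    seen = np.zeros(len(universe), dtype=bool)
    dropped = 0
    for chrom, start, nm, nu, _ in rows:
        i = universe.ordinal(chrom, start)
        if i is None:
            dropped += 1
            continue
        if seen[i]:
            raise ParseError(path, 0, f"duplicate site {chrom}:{start}")
        seen[i] = True
        n_meth[i] = nm
        n_unmeth[i] = nu
    if dropped:
        logger.info("%s: dropped %d sites outside the supplied universe", path, dropped)
    return SampleMethylome(
        sample_id=sample_id or path.stem,
        universe=universe,
        n_meth=n_meth,
        n_unmeth=n_unmeth,
        meta=dict(meta or {}),
    )


def write_bedgraph(sample: SampleMethylome, path, include_uncovered: bool = False):
    """Write a SampleMethylome back to MethylDackel-dialect bedGraph."""
    depth = sample.depth
    with open(path, "w") as fh:
        fh.write(f'track type="bedGraph" description="{sample.sample_id}"\n')
        for i in range(len(sample.universe)):
            d = int(depth[i])
            if d == 0 and not include_uncovered:
                continue
            nm = int(sample.n_meth[i])
            pct = round_half_up(100.0 * nm / d) if d else 0
            fh.write(
                f"{sample.universe.chroms[i]}\t{sample.universe.pos[i]}\t"
                f"{sample.universe.pos[i] + 1}\t{pct}\t{nm}\t{d - nm}\n"
            )


# ---------------------------------------------------------------------------
# sample sheets and cohort assembly


def read_sample_sheet(path) -> pd.DataFrame:
    """Read a TSV sample sheet (sample_id, age, + optional metadata columns)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns or "age" not in df.columns:
        raise ValueError(f"{path}: sample sheet must have sample_id and age columns")
    if df["sample_id"].duplicated().any():
        dups = df["sample_id"][df["sample_id"].duplicated()].tolist()
        raise ValueError(f"{path}: duplicate sample_id(s): {dups}")
    ages = pd.to_numeric(df["age"], errors="coerce")
    if ages.isna().any() or (ages < 0).any():
        bad = df["sample_id"][ages.isna() | (ages < 0)].tolist()
        raise ValueError(f"{path}: non-numeric or negative age for sample(s) {bad}")
    df["age"] = ages.astype(float)
    return df


def write_sample_sheet(df: pd.DataFrame, path):
    df.to_csv(path, sep="\t", index=False)


def assemble_cohort(
    sample_sheet, call_files: Mapping[str, Path | str], universe: SiteUniverse
) -> CohortMatrix:
    """Assemble per-sample call files into a CohortMatrix.

    Samples are sorted by sample_id (stable) so assembly is invariant to
    sheet row order.  Every sheet sample must have exactly one call file.
    """
    sheet = (
        read_sample_sheet(sample_sheet)
        if not isinstance(sample_sheet, pd.DataFrame)
        else sample_sheet.copy()
    )
    if sheet["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in sample sheet")
    if (sheet["age"] < 0).any():
        raise ValueError("negative age in sample sheet")
    missing = [s for s in sheet["sample_id"] if s not in call_files]
    if missing:
        raise ValueError(f"no call file for sample(s): {missing}")
    sheet = sheet.sort_values("sample_id", kind="stable").reset_index(drop=True)

    s, n = len(sheet), len(universe)
    beta = np.full((s, n), np.nan)
    depth = np.zeros((s, n), dtype=np.int64)
    meth = np.zeros((s, n), dtype=np.int64)
    for i, sid in enumerate(sheet["sample_id"]):
        sm = read_methyldackel_bedgraph(call_files[sid], universe, sample_id=sid)
        beta[i] = sm.beta
        depth[i] = sm.depth
        meth[i] = sm.n_meth
    return CohortMatrix(universe=universe, beta=beta, depth=depth, samples=sheet, meth=meth)


# ---------------------------------------------------------------------------
# probe manifests


@dataclass
class ProbeMapReport:
    total: int
    matched: int

    @property
    def percent_present(self) -> int | None:
        """Matched probes as a percent of requested, rounded to nearest integer;
        None (not applicable) for an empty request."""
        if self.total == 0:
            return None
        return round_half_up(100.0 * self.matched / self.total)


def read_probe_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chrom": str})
    for col in ("probe_id", "chrom", "pos"):
        if col not in df.columns:
            raise ValueError(f"{path}: probe manifest missing column {col!r}")
    df["chrom"] = df["chrom"].map(normalize_chrom)
    df["pos"] = df["pos"].astype(int)
    return df


def map_probes_to_sites(
    manifest, probe_ids: Sequence[str], universe: SiteUniverse
) -> tuple[dict[str, int], ProbeMapReport]:
    """Map array probe ids to universe site ordinals via a coordinate manifest.

    Probes absent from the manifest, or whose coordinate is not in the
    universe, count as unmatched (not an error).
    """
    df = manifest if isinstance(manifest, pd.DataFrame) else read_probe_manifest(manifest)
    coord = dict(zip(df["probe_id"], zip(df["chrom"], df["pos"])))
    mapping: dict[str, int] = {}
    for pid in probe_ids:
        loc = coord.get(pid)
        if loc is None:
            continue
        ordinal = universe.ordinal(*loc)
        if ordinal is not None:
            mapping[pid] = ordinal
    report = ProbeMapReport(total=len(probe_ids), matched=len(mapping))
    return mapping, report


# ---------------------------------------------------------------------------
# BED annotations


def read_bed_annotations(path) -> AnnotationSet:
    """Read BED3+name (4th column = feature class) into an AnnotationSet."""
    classes: dict[str, list[tuple[str, int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(path, lineno, "BED annotation needs >= 4 columns")
            chrom = normalize_chrom(fields[0])
            start, end = int(fields[1]), int(fields[2])
            if start >= end:
                raise ParseError(path, lineno, f"start {start} >= end {end}")
            classes.setdefault(fields[3], []).append((chrom, start, end))
    return AnnotationSet(classes)


def write_bed_annotations(ann: AnnotationSet, path):
    with open(path, "w") as fh:
        for name, ivs in ann.classes.items():
            for chrom, start, end in ivs:
                fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")


# ---------------------------------------------------------------------------
# model container (text JSON with format version)


def write_model(model, path):
    """Serialize a fitted ClockModel to a self-describing JSON text container.

    Floats survive bit-exactly (shortest-repr round trip), so a reloaded
    model reproduces predictions identically.
    """
    payload = {
        "format": MODEL_FORMAT,
        "version": MODEL_FORMAT_VERSION,
        "feature_kind": model.feature_kind,
        "feature_ids": list(model.feature_ids),
        "feature_sites": model.feature_sites,
        "impute_means": model.impute_means.tolist(),
        "scale_means": model.scale_means.tolist(),
        "scale_sds": model.scale_sds.tolist(),
        "pca_mean": model.pca_mean.tolist(),
        "pca_components": model.pca_components.tolist(),
        "en_intercept": float(model.en_intercept),
        "en_coefs": model.en_coefs.tolist(),
        "adult_age": float(model.adult_age),
        "training_config": model.training_config,
        "seed": model.seed,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")


def read_model(path):
    from .clock import ClockModel  # local import to avoid a cycle

    try:
        with open(path) as fh:
            payload = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ModelFormatError(f"{path}: not a parseable model container: {exc}")
    if payload.get("format") != MODEL_FORMAT:
        raise ModelFormatError(f"{path}: not a {MODEL_FORMAT} container")
    if payload.get("version") != MODEL_FORMAT_VERSION:
        raise ModelFormatError(
            f"{path}: unsupported model format version {payload.get('version')!r} "
            f"(supported: {MODEL_FORMAT_VERSION})"
        )
    required = (
        "feature_kind",
        "feature_ids",
        "impute_means",
        "scale_means",
        "scale_sds",
        "pca_mean",
        "pca_components",
        "en_intercept",
        "en_coefs",
        "adult_age",
    )
    for key in required:
        if key not in payload:
            raise ModelFormatError(f"{path}: missing section {key!r}")
    return ClockModel(
        feature_kind=payload["feature_kind"],
        feature_ids=list(payload["feature_ids"]),
        feature_sites=payload.get("feature_sites"),
        impute_means=np.asarray(payload["impute_means"], dtype=float),
        scale_means=np.asarray(payload["scale_means"], dtype=float),
        scale_sds=np.asarray(payload["scale_sds"], dtype=float),
        pca_mean=np.asarray(payload["pca_mean"], dtype=float),
        pca_components=np.asarray(payload["pca_components"], dtype=float),
        en_intercept=float(payload["en_intercept"]),
        en_coefs=np.asarray(payload["en_coefs"], dtype=float),
        adult_age=float(payload["adult_age"]),
        training_config=payload.get("training_config") or {},
        seed=payload.get("seed"),
    )
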