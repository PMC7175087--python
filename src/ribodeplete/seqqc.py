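"""Depletion QC on mapped reads: counting, RPKM, size factors, outliers.

These are the downstream computations used to evaluate how well a depletion
reaction worked from RNA-seq of depleted vs undepleted samples:

* per-gene counts by the *midpoint rule* — each read contributes one count at
  the middle of its mapped interval, to the region containing that point;
* RPKM normalization (reads per kilobase of region per million mapped);
* per-position coverage of rRNA loci, with median-of-ratios size factors
  (geometric-mean reference pseudo-sample) to correct sequencing depth;
* the rRNA read fraction — summed rRNA-locus counts over total mapped reads;
* outlier calling between two samples as points further than a
  standard-deviation threshold from the least-squares line in log-log space
  (perpendicular distance by default; vertical residuals behind a flag);
* log2 fold-change comparison between two depletion methods with RPKM/count
  floors, summarized as squared Pearson correlation.

All coordinates are 0-based half-open.  Read strand is ignored for counting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from scipy import stats

from .errors import InputError, ParameterError

RRNA_CLASS = "rRNA"


@dataclass(frozen=True)
class ReadSet:
    """Mapped-read intervals: parallel arrays of reference, start, end, strand."""

    references: np.ndarray
    starts: np.ndarray
    ends: np.ndarray
    strands: np.ndarray

    def __post_init__(self):
        n = len(self.references)
        if not (len(self.starts) == len(self.ends) == len(self.strands) == n):
            raise InputError("ReadSet arrays must have equal length")
        if np.any(self.starts >= self.ends):
            raise InputError("read intervals must satisfy start < end")

    @property
    def total_mapped(self) -> int:
        return len(self.references)

    @staticmethod
    def from_arrays(references, starts, ends, strands=None) -> "ReadSet":
        n = len(starts)
        return ReadSet(
            references=np.asarray(references, dtype=object),
            starts=np.asarray(starts, dtype=np.int64),
            ends=np.asarray(ends, dtype=np.int64),
            strands=(np.asarray(strands, dtype=object) if strands is not None
                     else np.full(n, "+", dtype=object)),
        )

    @staticmethod
    def from_bed(path) -> "ReadSet":
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        if df.shape[1] < 3:
            raise InputError("BED needs at least 3 columns")
        strands = df[5] if df.shape[1] > 5 else None
        return ReadSet.from_arrays(df[0], df[1], df[2], strands)

    @staticmethod
    def from_sam(path) -> "ReadSet":
        refs, starts, ends, strands = [], [], [], []
        with pysam.AlignmentFile(str(path), "r") as sam:
            for rec in sam.fetch(until_eof=True):
                if rec.is_unmapped:
                    continue
                refs.append(rec.reference_name)
                starts.append(rec.reference_start)
                ends.append(rec.reference_end)
                strands.append("-" if rec.is_reverse else "+")
        if not refs:
            raise InputError(f"no mapped reads in {path}")
        return ReadSet.from_arrays(refs, starts, ends, strands)

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for i in range(self.total_mapped):
                fh.write(f"{self.references[i]}\t{self.starts[i]}\t{self.ends[i]}"
                         f"\tread{i}\t0\t{self.strands[i]}\n")


@dataclass(frozen=True)
class RegionSet:
    """Annotated genomic regions (genes / rRNA loci); overlap is allowed."""

    regions: pd.DataFrame  # columns: name, reference, start, end, cls

    def __post_init__(self):
        required = {"name", "reference", "start", "end", "cls"}
        missing = required - set(self.regions.columns)
        if missing:
            raise InputError(f"RegionSet missing columns: {sorted(missing)}")
        if (self.regions["start"] >= self.regions["end"]).any():
            raise InputError("regions must satisfy start < end")

    @staticmethod
    def from_records(records) -> "RegionSet":
        return RegionSet(pd.DataFrame(
            records, columns=["name", "reference", "start", "end", "cls"]
        ))

    @staticmethod
    def from_bed(path) -> "RegionSet":
        """BED with name in column 4 and region class (CDS/rRNA) in column 5."""
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        if df.shape[1] < 5:
            raise InputError("region BED needs columns: ref start end name class")
        return RegionSet.from_records(
            list(zip(df[3], df[0], df[1], df[2], df[4]))
        )

    def __len__(self) -> int:
        return len(self.regions)


@dataclass
class CountTable:
    """Per-region counts (and optionally RPKM) for one or more samples."""

    regions: RegionSet
    counts: pd.DataFrame          # region name x sample
    total_mapped: dict[str, int]
    rpkm: pd.DataFrame | None = None

    def join(self, other: "CountTable") -> "CountTable":
        """Combine samples of two tables over identical region sets."""
        if not self.regions.regions["name"].equals(other.regions.regions["name"]):
            raise InputError("cannot join tables over different region sets")
        return CountTable(
            regions=self.regions,
            counts=pd.concat([self.counts, other.counts], axis=1),
            total_mapped={**self.total_mapped, **other.total_mapped},
            rpkm=(pd.concat([self.rpkm, other.rpkm], axis=1)
                  if self.rpkm is not None and other.rpkm is not None else None),
        )


def _check_references(reads: ReadSet, regions: RegionSet) -> None:
    read_refs = set(reads.references.tolist())
    unmatched = sorted(set(regions.regions["reference"]) - read_refs)
    if unmatched and read_refs:
        raise InputError(f"region references not present in reads: {unmatched}")


def count_midpoints(reads: ReadSet, regions: RegionSet,
                    sample: str = "sample",
                    check_references: bool = True) -> CountTable:
    """Midpoint-rule counting: one count at floor((start + end) / 2) per read.

    A read is assigned to every region containing its midpoint (half-open:
    a midpoint equal to the region end is outside).
    """
    if check_references:
        _check_references(reads, regions)
    mids = (reads.starts + reads.ends) // 2
    by_ref: dict[str, np.ndarray] = {}
    for ref in np.unique(reads.references.astype(str)):
        sel = reads.references == ref
        by_ref[ref] = np.sort(mids[sel])
    out = np.zeros(len(regions), dtype=np.int64)
    for i, row in enumerate(regions.regions.itertuples(index=False)):
        pts = by_ref.get(row.reference)
        if pts is None:
            continue
        out[i] = np.searchsorted(pts, row.end, side="left") - \
            np.searchsorted(pts, row.start, side="left")
    counts = pd.DataFrame({sample: out}, index=regions.regions["name"].values)
    return CountTable(regions=regions, counts=counts,
                      total_mapped={sample: reads.total_mapped})


def rpkm(ct: CountTable) -> CountTable:
    """Fill in RPKM = count / (region_kb * total_mapped / 1e6) per sample."""
    lengths = (ct.regions.regions["end"] - ct.regions.regions["start"]).values
    cols = {}
    for sample in ct.counts.columns:
        total = ct.total_mapped[sample]
        if total <= 0:
            raise InputError(f"sample {sample!r} has no mapped reads")
        cols[sample] = ct.counts[sample].values * 1e9 / (lengths * total)
    return CountTable(regions=ct.regions, counts=ct.counts,
                      total_mapped=dict(ct.total_mapped),
                      rpkm=pd.DataFrame(cols, index=ct.counts.index))


def coverage_profile(reads: ReadSet, region) -> np.ndarray:
    """Per-position read coverage over a region (both read ends inclusive).

    ``region`` is (reference, start, end) or a RegionSet row; returns an array
    of length ``end - start`` where position p counts the reads overlapping p.
    """
    if hasattr(region, "reference"):
        ref, start, end = region.reference, region.start, region.end
    else:
        ref, start, end = region
    n = end - start
    delta = np.zeros(n + 1, dtype=np.int64)
    sel = reads.references == ref
    for s, e in zip(reads.starts[sel], reads.ends[sel]):
        lo = max(s, start)
        hi = min(e, end)
        if lo < hi:
            delta[lo - start] += 1
            delta[hi - start] -= 1
    return np.cumsum(delta[:-1])


def size_factors(count_matrix: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors against a geometric-mean pseudo-sample.

    Regions with a zero geometric mean (any zero count) are excluded; the
    size factor of sample j is the median over remaining regions of
    ``count[r, j] / geomean_r``.
    """
    if count_matrix.shape[1] < 2:
        raise InputError("size factors need at least 2 samples")
    vals = count_matrix.values.astype(float)
    ok = np.all(vals > 0, axis=1)
    if not ok.any():
        raise InputError("no region has nonzero counts in every sample")
    logs = np.log(vals[ok])
    log_ref = logs.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logs - log_ref, axis=0))
    return pd.Series(factors, index=count_matrix.columns)


def rrna_fraction(ct: CountTable) -> pd.Series:
    """Fraction of mapped reads whose midpoint falls in rRNA-class regions."""
    is_rrna = (ct.regions.regions["cls"] == RRNA_CLASS).values
    out = {}
    for sample in ct.counts.columns:
        out[sample] = float(ct.counts[sample].values[is_rrna].sum()
                            / ct.total_mapped[sample])
    return pd.Series(out)


@dataclass(frozen=True)
class OutlierResult:
    """Log-log fit summary plus per-region outlier flags."""

    slope: float
    intercept: float
    distances: pd.Series      # signed distance from the fitted line
    mean_distance: float
    sd_distance: float
    flags: pd.Series          # True where |d - mean| > threshold * sd
    side: pd.Series           # 'more_depleted_in_a' / 'more_depleted_in_b'


def loglog_outliers(rpkm_a: pd.Series, rpkm_b: pd.Series,
                    sd_threshold: float = 2.0,
                    distance: str = "perpendicular") -> OutlierResult:
    """Flag regions far from the log10-log10 least-squares line.

    Distances are measured perpendicular to the fitted line in Cartesian
    log-log coordinates (``distance="vertical"`` uses plain residuals).
    Points below the line are lower in sample b, i.e. more depleted in b.
    """
    if distance not in ("perpendicular", "vertical"):
        raise ParameterError(f"unknown distance mode {distance!r}")
    if not rpkm_a.index.equals(rpkm_b.index):
        rpkm_a, rpkm_b = rpkm_a.align(rpkm_b, join="inner")
    if len(rpkm_a) < 3:
        raise InputError("need at least 3 regions for a log-log fit")
    if (rpkm_a <= 0).any() or (rpkm_b <= 0).any():
        raise InputError("log-log fit requires strictly positive values; "
                         "filter zeros upstream")
    x = np.log10(rpkm_a.values.astype(float))
    y = np.log10(rpkm_b.values.astype(float))
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    d = resid / math_hypot(slope) if distance == "perpendicular" else resid
    mean, sd = float(d.mean()), float(d.std())
    flags = np.abs(d - mean) > sd_threshold * sd
    side = np.where(d < mean, "more_depleted_in_b", "more_depleted_in_a")
    idx = rpkm_a.index
    return OutlierResult(
        slope=float(slope), intercept=float(intercept),
        distances=pd.Series(d, index=idx),
        mean_distance=mean, sd_distance=sd,
        flags=pd.Series(flags, index=idx),
        side=pd.Series(side, index=idx),
    )


def math_hypot(slope: float) -> float:
    return float(np.sqrt(1.0 + slope * slope))


@dataclass(frozen=True)
class FoldChangeComparison:
    lfc: pd.DataFrame      # columns: method_a, method_b (log2 fold changes)
    r_squared: float
    n: int


def fold_change_compare(treated_a: pd.Series, untreated_a: pd.Series,
                        treated_b: pd.Series, untreated_b: pd.Series,
                        min_untreated: float = 64.0,
                        min_all: float = 0.0) -> FoldChangeComparison:
    """Compare expression fold changes measured under two depletion methods.

    Regions are kept when both *untreated* samples reach ``min_untreated``
    (RPKM floor) and all four samples reach ``min_all`` (e.g. a 1-count or
    5-RPKM floor); log2(treated/untreated) is computed per method and the
    squared Pearson correlation between the two methods returned.
    """
    df = pd.DataFrame({
        "ta": treated_a, "ua": untreated_a, "tb": treated_b, "ub": untreated_b,
    }).dropna()
    keep = (df["ua"] >= min_untreated) & (df["ub"] >= min_untreated)
    keep &= (df[["ta", "ua", "tb", "ub"]] >= min_all).all(axis=1)
    keep &= (df[["ta", "ua", "tb", "ub"]] > 0).all(axis=1)
    df = df[keep]
    if len(df) < 2:
        raise InputError("fewer than 2 regions pass the expression filters")
    lfc = pd.DataFrame({
        "method_a": np.log2(df["ta"] / df["ua"]),
        "method_b": np.log2(df["tb"] / df["ub"]),
    })
    r, _ = stats.pearsonr(lfc["method_a"], lfc["method_b"])
    return FoldChangeComparison(lfc=lfc, r_squared=float(r ** 2), n=len(df))
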