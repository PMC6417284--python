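"""Mappability masking and merged multi-sample WGS background counts.

Error measurement is restricted to uniquely mappable regions: intervals
with a mappability score of exactly 1 and length > 300 bp, shrunk by
50 bp at each end against edge effects.  For a whole-genome background,
per-sample count tables are merged into a single collapsed count file:
a sample contributes a locus only when it covers it at >= 20X with the
reference allele above 95% (the binomial chance of a heterozygote
producing so few non-reference reads is ~4e-5 at 20X), any sample with
a heterozygous call (no allele above 95%) vetoes the locus outright,
and only loci reaching >= 20,000X collapsed coverage are kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .read_qc import BASES

__all__ = [
    "MergedBackground",
    "RegionMask",
    "build_region_mask",
    "heterozygote_pvalue",
    "intervals_from_bigwig",
    "merge_wgs_background",
]

BED_COLUMNS = ["chrom", "start", "end"]


@dataclass
class RegionMask:
    """Sorted, non-overlapping genomic intervals (0-based half-open)."""

    intervals: pd.DataFrame  # columns chrom, start, end
    provenance: str = ""

    def __post_init__(self) -> None:
        df = self.intervals.reset_index(drop=True)[BED_COLUMNS]
        if (df["end"] <= df["start"]).any():
            raise ValueError("mask contains empty or inverted intervals")
        for _, grp in df.groupby("chrom"):
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            order = np.argsort(starts)
            if (starts[order][1:] < ends[order][:-1]).any():
                raise ValueError("mask intervals overlap")
        self.intervals = df.sort_values(["chrom", "start"], kind="stable").reset_index(
            drop=True
        )

    def __len__(self) -> int:
        return len(self.intervals)

    def total_length(self) -> int:
        return int((self.intervals["end"] - self.intervals["start"]).sum())

    def contains(self, chrom: str, pos: int) -> bool:
        """Membership of a 1-based position."""
        df = self.intervals
        sel = (df["chrom"] == chrom) & (df["start"] < pos) & (pos <= df["end"])
        return bool(sel.any())

    def write_bed(self, path) -> None:
        self.intervals.to_csv(path, sep="\t", index=False, header=False)

    @classmethod
    def read_bed(cls, path, provenance: str = "") -> "RegionMask":
        df = pd.read_csv(
            path, sep="\t", header=None, usecols=[0, 1, 2], names=BED_COLUMNS,
            dtype={"chrom": str},
        )
        return cls(intervals=df, provenance=provenance or str(path))


def build_region_mask(
    track,
    min_score: float = 1.0,
    min_length: int = 301,
    edge_trim: int = 50,
    provenance: str = "",
) -> RegionMask:
    """Uniquely-mappable region mask from a scored interval track.

    ``track`` is a DataFrame (chrom, start, end, score; 0-based
    half-open) or a path to a 4-column BED.  Intervals are kept iff
    their score is exactly ``min_score`` (mappability 1 by default) and
    their length is >= ``min_length`` (301, i.e. strictly more than
    300 bp); survivors are shrunk by ``edge_trim`` bases at each end,
    and any interval left without positive length is dropped.
    """
    if not isinstance(track, pd.DataFrame):
        track = pd.read_csv(
            track, sep="\t", header=None, usecols=[0, 1, 2, 3],
            names=BED_COLUMNS + ["score"], dtype={"chrom": str},
        )
    required = set(BED_COLUMNS + ["score"])
    if not required.issubset(track.columns):
        raise ValueError(f"track lacks columns: {sorted(required - set(track.columns))}")
    if track[["start", "end"]].isna().any().any():
        raise ValueError("malformed track: missing coordinates")
    length = track["end"] - track["start"]
    kept = track.loc[(track["score"] == min_score) & (length >= min_length)].copy()
    kept["start"] = kept["start"] + edge_trim
    kept["end"] = kept["end"] - edge_trim
    kept = kept.loc[kept["end"] > kept["start"], BED_COLUMNS]
    return RegionMask(intervals=kept.reset_index(drop=True), provenance=provenance)


def intervals_from_bigwig(path, chroms: Sequence[str] | None = None) -> pd.DataFrame:
    """Collapse a per-base bigWig track into constant-score intervals.

    Returns a (chrom, start, end, score) frame consumable by
    :func:`build_region_mask`.  Requires the optional pyBigWig
    dependency.
    """
    import pyBigWig  # optional extra

    rows = []
    with pyBigWig.open(str(path)) as bw:
        for chrom in chroms or bw.chroms():
            for start, end, score in bw.intervals(chrom) or []:
                rows.append((chrom, int(start), int(end), float(score)))
    return pd.DataFrame(rows, columns=BED_COLUMNS + ["score"])


def heterozygote_pvalue(
    n_reads: int, n_nonref: int, p: float = 0.5, two_sided: bool = True
) -> float:
    """Binomial probability that a true heterozygote shows so few
    non-reference reads: P(X <= n_nonref | n_reads, p), doubled for the
    two-sided version.  Justifies the >95% dominant-allele gates."""
    tail = float(stats.binom.cdf(n_nonref, n_reads, p))
    return min(1.0, 2.0 * tail) if two_sided else tail


@dataclass
class MergedBackground:
    """Collapsed multi-sample background counts.

    ``counts`` has the standard count-table layout plus ``n_samples``,
    the number of samples contributing at each locus; ``depth`` is the
    collapsed coverage (sum of included per-sample depths).
    """

    counts: pd.DataFrame
    n_input_samples: int

    def write(self, path) -> None:
        self.counts.to_csv(path, sep="\t", index=False)


def merge_wgs_background(
    tables: Sequence[pd.DataFrame],
    sample_depth_min: int = 20,
    dominant_frac: float = 0.95,
    collapsed_depth_min: int = 20000,
) -> MergedBackground:
    """Merge per-sample count tables into one background count set.

    Gates, applied in order per locus: (1) per-sample inclusion — a
    sample's counts enter the sum only where that sample has depth >=
    ``sample_depth_min`` and reference-allele fraction >
    ``dominant_frac``; samples below the depth floor are silent
    (neither include nor veto); (2) heterozygote veto — a locus is
    excluded everywhere if any sample covers it at >=
    ``sample_depth_min`` with no allele exceeding ``dominant_frac``;
    (3) collapsed coverage — merged loci must reach
    ``collapsed_depth_min`` summed depth.  All tables must share
    coordinates and reference alleles.
    """
    if not tables:
        raise ValueError("no count tables to merge")
    base = tables[0][["chrom", "pos", "ref"]].reset_index(drop=True)
    for i, t in enumerate(tables[1:], start=2):
        other = t[["chrom", "pos", "ref"]].reset_index(drop=True)
        if len(other) != len(base) or not other.equals(base):
            raise ValueError(f"count table {i} disagrees on coordinates/reference")

    n_loci = len(base)
    allele_sum = np.zeros((n_loci, 4), dtype=np.int64)
    n_samples = np.zeros(n_loci, dtype=np.int64)
    veto = np.zeros(n_loci, dtype=bool)
    ref_idx = base["ref"].map({b: i for i, b in enumerate(BASES)}).to_numpy()
    valid_ref = ~pd.isna(ref_idx)
    ref_idx = np.where(valid_ref, ref_idx, 0).astype(np.int64)

    for t in tables:
        counts = t[list(BASES)].to_numpy(dtype=np.int64)
        depth = t["depth"].to_numpy(dtype=np.int64)
        covered = depth >= sample_depth_min
        with np.errstate(divide="ignore", invalid="ignore"):
            dominant = np.where(depth > 0, counts.max(axis=1) / np.maximum(depth, 1), 0)
            ref_frac = np.where(
                depth > 0,
                counts[np.arange(n_loci), ref_idx] / np.maximum(depth, 1),
                0,
            )
        veto |= covered & (dominant <= dominant_frac)
        include = covered & (ref_frac > dominant_frac) & valid_ref
        allele_sum[include] += counts[include]
        n_samples += include.astype(np.int64)

    merged = base.copy()
    for j, b in enumerate(BASES):
        merged[b] = allele_sum[:, j]
    merged["depth"] = allele_sum.sum(axis=1)
    merged["n_samples"] = n_samples
    keep = (~veto) & (merged["depth"] >= collapsed_depth_min) & valid_ref
    merged = merged.loc[keep].reset_index(drop=True)
    return MergedBackground(counts=merged, n_input_samples=len(tables))
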