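"""Fragment-aware allele counting over genomic sites.

Short-insert paired-end sequencing (e.g. 130-170 bp amplicons read at
2x101 cycles) produces mate pairs that overlap over much of the
fragment, so a naive pileup counts the same template molecule twice and
lets a miscall in a single mate masquerade as an allele.  The counting
core here reconciles the two readouts a fragment produces at a site so
that every DNA fragment contributes at most one allele:

(i)  a position read by only one mate is counted iff its Phred score is
     >= the base-quality threshold (default 30);
(ii) a position read by both mates is counted once if the readouts are
     concordant and both are >= the threshold, or if exactly one
     readout reaches the threshold (that readout's allele is counted);
     discordant readouts that are both high-quality are discarded.

A ``naive_pileup`` mode reproduces quality-30/MAPQ-55 per-base counting
without fragment collapsing, trimming, or read-level suppression, for
comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .read_qc import (
    BASES,
    AlignedReadRecord,
    FilterConfig,
    countable_mask,
    filter_keep_arrays,
    passes_read_filters,
)

__all__ = [
    "COUNT_COLUMNS",
    "SiteCounts",
    "downsample_counts",
    "downsample_reads",
    "export_strand_halved_counts",
    "fragment_allele",
    "is_countable_site",
    "countable_sites",
    "pileup_counts",
    "pileup_counts_batch",
    "read_counts",
    "write_counts",
]

COUNT_COLUMNS = ["chrom", "pos", "ref", "A", "C", "G", "T", "depth"]

COUNTING_MODES = ("cleandeepseq", "naive_pileup")

_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass
class SiteCounts:
    """Per-site fragment-level allele counts; the unit of error measurement."""

    chrom: str
    pos: int
    ref: str
    counts: np.ndarray  # A, C, G, T

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (4,):
            raise ValueError("counts must be a length-4 A/C/G/T vector")
        if (self.counts < 0).any():
            raise ValueError("allele counts must be non-negative")

    @property
    def depth(self) -> int:
        return int(self.counts.sum())

    def count(self, base: str) -> int:
        return int(self.counts[_BASE_INDEX[base]])

    @classmethod
    def from_row(cls, row) -> "SiteCounts":
        return cls(
            chrom=row["chrom"],
            pos=int(row["pos"]),
            ref=row["ref"],
            counts=np.array([row[b] for b in BASES], dtype=np.int64),
        )


def fetch_reference(reference, chrom: str, start: int, end: int) -> str:
    """Reference bases for a 1-based inclusive interval.

    ``reference`` may be a ``{chrom: sequence}`` mapping or a
    ``pyfaidx.Fasta``-like object.
    """
    seg = reference[chrom][start - 1: end]
    return str(getattr(seg, "seq", seg)).upper()


def fragment_allele(
    readouts: Sequence[tuple[str, int]],
    base_qual_min: int = 30,
    strict_concordance: bool = False,
) -> str | None:
    """Resolve one fragment's readouts at one site into at most one allele.

    ``readouts`` holds the (base, phred) observations the fragment's
    mates made at the site (1 outside the mate overlap, 2 inside).  With
    ``strict_concordance`` the lone-high-quality rescue of a discordant
    pair is disabled: discordant readouts are never counted.
    Returns the counted allele, or ``None`` if the fragment contributes
    nothing.  More than two readouts indicate malformed pairing.
    """
    if len(readouts) > 2:
        raise ValueError(f"fragment produced {len(readouts)} readouts at one site")
    if not readouts:
        return None

    def informative(base: str, qual: int) -> bool:
        return qual >= base_qual_min and base in _BASE_INDEX

    if len(readouts) == 1:
        base, qual = readouts[0]
        return base if informative(base, qual) else None
    (b0, q0), (b1, q1) = readouts
    hi0, hi1 = informative(b0, q0), informative(b1, q1)
    if hi0 and hi1:
        return b0 if b0 == b1 else None
    if hi0 != hi1:
        lone = b0 if hi0 else b1
        if strict_concordance and b0 != b1:
            return None
        return lone
    return None


def _check_sorted(reads: Sequence[AlignedReadRecord]) -> None:
    last: dict[str, int] = {}
    seen: list[str] = []
    for r in reads:
        if r.chrom in last and r.pos < last[r.chrom]:
            raise ValueError("input reads are not coordinate-sorted")
        if r.chrom not in last:
            if r.chrom in seen:
                raise ValueError("input reads are not coordinate-sorted")
            seen.append(r.chrom)
        last[r.chrom] = r.pos
    return None


def pileup_counts(
    reads: Sequence[AlignedReadRecord],
    region: tuple[str, int, int],
    reference,
    cfg: FilterConfig | None = None,
    mode: str = "cleandeepseq",
    strict_concordance: bool = False,
) -> pd.DataFrame:
    """Per-site allele counts over a 1-based inclusive region.

    ``cleandeepseq`` mode applies the read gates, end trimming, and the
    fragment overlap-consensus rules; ``naive_pileup`` counts every base
    with Phred >= ``cfg.base_qual_min`` from every read passing the
    MAPQ gate, independently.  Fragments whose mates map to different
    chromosomes are excluded in cleandeepseq mode.
    """
    if mode not in COUNTING_MODES:
        raise ValueError(f"unknown counting mode {mode!r}")
    cfg = cfg or FilterConfig()
    chrom, start, end = region
    if end < start:
        return pd.DataFrame(columns=COUNT_COLUMNS)
    _check_sorted(reads)
    n_sites = end - start + 1
    counts = np.zeros((n_sites, 4), dtype=np.int64)

    if mode == "naive_pileup":
        for read in reads:
            if read.chrom != chrom:
                continue
            if read.mapq < cfg.mapq_min:
                continue
            if cfg.discard_missing_mapq and read.mapq == cfg.mapq_missing:
                continue
            for qidx, rpos in read.aligned_pairs():
                if start <= rpos <= end:
                    base = read.seq[qidx]
                    if base in _BASE_INDEX and read.qual[qidx] >= cfg.base_qual_min:
                        counts[rpos - start, _BASE_INDEX[base]] += 1
    else:
        cross_chrom: set[str] = set()
        fragments: dict[str, list[AlignedReadRecord]] = {}
        for read in reads:
            if read.mate_chrom is not None and read.mate_chrom != read.chrom:
                cross_chrom.add(read.qname)
            if read.chrom != chrom:
                cross_chrom.add(read.qname)
                continue
            fragments.setdefault(read.qname, []).append(read)
        for qname, frag_reads in fragments.items():
            if qname in cross_chrom:
                continue
            if len(frag_reads) > 2:
                raise ValueError(f"fragment {qname}: more than two reads")
            readouts: dict[int, list[tuple[str, int]]] = {}
            for read in frag_reads:
                if not passes_read_filters(read, cfg).passed:
                    continue
                mask = countable_mask(read, cfg)
                for qidx, rpos in read.aligned_pairs():
                    if mask[qidx] and start <= rpos <= end:
                        readouts.setdefault(rpos, []).append(
                            (read.seq[qidx], int(read.qual[qidx]))
                        )
            for rpos, obs in readouts.items():
                allele = fragment_allele(obs, cfg.base_qual_min, strict_concordance)
                if allele is not None:
                    counts[rpos - start, _BASE_INDEX[allele]] += 1

    ref_seq = fetch_reference(reference, chrom, start, end)
    return _counts_frame(chrom, start, ref_seq, counts)


def _counts_frame(chrom: str, start: int, ref_seq: str, counts: np.ndarray) -> pd.DataFrame:
    n = counts.shape[0]
    df = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.arange(start, start + n, dtype=np.int64),
            "ref": list(ref_seq),
            "A": counts[:, 0],
            "C": counts[:, 1],
            "G": counts[:, 2],
            "T": counts[:, 3],
        }
    )
    df["depth"] = counts.sum(axis=1)
    return df


def pileup_counts_batch(
    batch,
    region: tuple[str, int, int],
    reference,
    cfg: FilterConfig | None = None,
    mode: str = "cleandeepseq",
    strict_concordance: bool = False,
    counts_out: np.ndarray | None = None,
) -> np.ndarray:
    """Vectorized counting over a simulated read batch (see ``sim_reads.ReadBatch``).

    Semantically identical to :func:`pileup_counts` on the equivalent
    records (cross-checked by the test suite's brute-force oracle), but
    operates on the batch's struct-of-arrays layout so that depths of
    1e6 fragments per site are tractable.  Accumulates into
    ``counts_out`` (n_sites x 4) when given, enabling streamed chunks.
    Reads with non-match CIGARs are excluded in cleandeepseq mode by the
    CIGAR gate and handled read-by-read in naive mode.
    """
    if mode not in COUNTING_MODES:
        raise ValueError(f"unknown counting mode {mode!r}")
    cfg = cfg or FilterConfig()
    chrom, start, end = region
    n_sites = end - start + 1
    counts = counts_out if counts_out is not None else np.zeros((n_sites, 4), np.int64)
    if batch.chrom != chrom or len(batch) == 0:
        return counts
    L = batch.read_len
    positions = np.arange(start, end + 1)

    if mode == "naive_pileup":
        keep = batch.mapq >= cfg.mapq_min
        if cfg.discard_missing_mapq:
            keep &= batch.mapq != cfg.mapq_missing
        keep_match = keep & batch.match_cigar
        qual_ok = (batch.qual >= cfg.base_qual_min) & (batch.seq < 4)
        for k, p in enumerate(positions):
            j = p - batch.pos  # (n_frag, 2)
            inwin = (j >= 0) & (j < L) & keep_match
            jc = np.clip(j, 0, L - 1)
            b = np.take_along_axis(batch.seq, jc[:, :, None], axis=2)[:, :, 0]
            ok = inwin & np.take_along_axis(qual_ok, jc[:, :, None], axis=2)[:, :, 0]
            counts[k] += np.bincount(b[ok], minlength=4)[:4]
        # non-match reads (few): literal per-read fallback
        for fi, mi in zip(*np.nonzero(keep & ~batch.match_cigar)):
            rec = batch.record(fi, mi)
            for qidx, rpos in rec.aligned_pairs():
                if start <= rpos <= end:
                    base = rec.seq[qidx]
                    if base in _BASE_INDEX and rec.qual[qidx] >= cfg.base_qual_min:
                        counts[rpos - start, _BASE_INDEX[base]] += 1
        return counts

    if not cfg.match_only_cigar and not batch.match_cigar.all():
        raise ValueError(
            "batch cleandeepseq counting with indel reads requires the CIGAR "
            "gate; use the record-based pileup_counts instead"
        )
    flat_keep = filter_keep_arrays(
        batch.mapq.reshape(-1),
        batch.qual.reshape(-1, L),
        batch.seq.reshape(-1, L),
        batch.match_cigar.reshape(-1),
        cfg,
    ).reshape(-1, 2)
    lo, hi_cut = cfg.trim_bp, L - cfg.trim_bp
    for k, p in enumerate(positions):
        j = p - batch.pos
        has = (j >= lo) & (j < hi_cut) & flat_keep
        jc = np.clip(j, 0, L - 1)
        b = np.take_along_axis(batch.seq, jc[:, :, None], axis=2)[:, :, 0]
        q = np.take_along_axis(batch.qual, jc[:, :, None], axis=2)[:, :, 0]
        hi = has & (q >= cfg.base_qual_min) & (b < 4)
        h0, h1 = has[:, 0], has[:, 1]
        hi0, hi1 = hi[:, 0], hi[:, 1]
        b0, b1 = b[:, 0], b[:, 1]
        single = h0 ^ h1
        ok_single = single & np.where(h0, hi0, hi1)
        allele_single = np.where(h0, b0, b1)
        both = h0 & h1
        concordant = b0 == b1
        lone = hi0 ^ hi1
        if strict_concordance:
            lone = lone & concordant
        ok_both = both & ((concordant & hi0 & hi1) | lone)
        allele_both = np.where(hi0 & ~hi1, b0, np.where(hi1 & ~hi0, b1, b0))
        alleles = np.concatenate([allele_single[ok_single], allele_both[ok_both]])
        counts[k] += np.bincount(alleles, minlength=4)[:4]
    return counts


def counts_frame_from_batch(batch, region, reference, counts: np.ndarray) -> pd.DataFrame:
    chrom, start, end = region
    ref_seq = fetch_reference(reference, chrom, start, end)
    return _counts_frame(chrom, start, ref_seq, counts)


def is_countable_site(
    counts: SiteCounts, depth_min: int = 500, dominant_frac: float = 0.95
) -> bool:
    """Site eligibility for error measurement: strictly more than
    ``depth_min`` counted fragments and a dominant allele at strictly
    more than ``dominant_frac`` frequency."""
    depth = counts.depth
    if depth <= depth_min:
        return False
    return counts.counts.max() / depth > dominant_frac


def countable_sites(
    df: pd.DataFrame, depth_min: int = 500, dominant_frac: float = 0.95
) -> pd.Series:
    """Vectorized :func:`is_countable_site` over a counts table."""
    allele = df[list(BASES)].to_numpy()
    depth = df["depth"].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        dom = np.where(depth > 0, allele.max(axis=1) / np.maximum(depth, 1), 0.0)
    return pd.Series((depth > depth_min) & (dom > dominant_frac), index=df.index)


def downsample_reads(
    reads: Sequence[AlignedReadRecord], fraction: float, seed: int
) -> list[AlignedReadRecord]:
    """Retain each *fragment* independently with probability ``fraction``.

    Both mates of a fragment are kept or dropped together so that
    fragment-aware counting stays consistent.  Deterministic for a fixed
    seed and input order.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    if fraction == 1.0:
        return list(reads)
    rng = np.random.default_rng(seed)
    decision: dict[str, bool] = {}
    kept = []
    for read in reads:
        if read.qname not in decision:
            decision[read.qname] = bool(rng.random() < fraction)
        if decision[read.qname]:
            kept.append(read)
    return kept


def downsample_counts(df: pd.DataFrame, fraction: float, seed: int) -> pd.DataFrame:
    """Binomially thin each allele count; equivalent in expectation to
    retaining fragments with probability ``fraction``."""
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    out = df.copy()
    if fraction == 1.0:
        return out
    rng = np.random.default_rng(seed)
    for base in BASES:
        out[base] = rng.binomial(df[base].to_numpy(), fraction)
    out["depth"] = out[list(BASES)].sum(axis=1)
    return out


def export_strand_halved_counts(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split fragment counts into two pseudo-strand halves.

    Fragment-aware counts carry no strand, but strand-specific callers
    require per-strand tables; each allele count c is split into
    ceil(c/2) (forward table) + floor(c/2) (reverse table).
    """
    fwd = df.copy()
    rev = df.copy()
    for base in BASES:
        c = df[base].to_numpy()
        fwd[base] = (c + 1) // 2
        rev[base] = c // 2
    for part, strand in ((fwd, "+"), (rev, "-")):
        part["depth"] = part[list(BASES)].sum(axis=1)
        part["strand"] = strand
    return fwd, rev


def write_counts(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str})
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"count table {path} lacks columns: {missing}")
    return df
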