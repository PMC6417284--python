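"""Read-level quality gating for deep-sequencing error suppression.

Ultra-deep sequencing can measure substitution error rates down to the
1e-5 regime, but only after the small minority of badly mapped or
low-quality reads — which carry a disproportionate share of mismatches —
is suppressed.  The gates implemented here act on whole reads before any
allele is counted:

* a stringent mapping-quality cutoff (default MAPQ >= 55; the SAM
  sentinel 255, "mapping quality unavailable", is always discarded);
* a match-only CIGAR gate (``^\\d+M$``) that drops reads whose alignment
  contains indels or clips, since those carry alignment ambiguity;
* a cap on the fraction of low-quality base calls per read (default:
  reads with >= 5% of bases below Phred 20 are suppressed);
* masking of the first and last sequencing cycles (default 5 bp per
  end), where base quality decays and residual adapter/primer sequence
  may survive.

The module also provides the read-quality diagnostics used to justify
these gates: the per-cycle fraction of Q30 bases and the distribution of
reads over mutually exclusive quality categories.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AlignedReadRecord",
    "FilterConfig",
    "FilterReason",
    "FilterVerdict",
    "ReadQualityStats",
    "countable_mask",
    "passes_read_filters",
    "read_quality_profile",
]

_MATCH_ONLY_CIGAR = re.compile(r"^\d+M$")
_CIGAR_OP = re.compile(r"(\d+)([MIDNSHP=X])")

#: Canonical order of the 12 substitution types used throughout the package.
SUBSTITUTION_TYPES = (
    "A>C", "A>G", "A>T",
    "C>A", "C>G", "C>T",
    "G>A", "G>C", "G>T",
    "T>A", "T>C", "T>G",
)

BASES = "ACGT"


@dataclass
class AlignedReadRecord:
    """One mapped read: the unit of read-level filtering.

    Sequence and qualities are stored in reference orientation (as in
    SAM); ``is_reverse`` records the sequencing strand so that per-cycle
    statistics can be computed in machine-cycle order.
    """

    qname: str
    chrom: str
    pos: int  # 1-based leftmost aligned reference position
    mapq: int
    cigar: str
    seq: str
    qual: np.ndarray  # per-base Phred scores, same length as seq
    is_reverse: bool = False
    mate_chrom: str | None = None
    mate_pos: int | None = None

    def __post_init__(self) -> None:
        self.qual = np.asarray(self.qual, dtype=np.int64)
        if len(self.seq) != len(self.qual):
            raise ValueError(
                f"read {self.qname}: sequence length {len(self.seq)} != "
                f"quality length {len(self.qual)}"
            )
        if self.pos < 1:
            raise ValueError(f"read {self.qname}: position {self.pos} < 1")

    def __len__(self) -> int:
        return len(self.seq)

    def aligned_pairs(self) -> list[tuple[int, int]]:
        """(query index, 1-based reference position) for every aligned base.

        Only M/=/X columns are emitted; insertions and soft clips consume
        query, deletions and skips consume reference.
        """
        pairs: list[tuple[int, int]] = []
        qidx, rpos = 0, self.pos
        for n_str, op in _CIGAR_OP.findall(self.cigar):
            n = int(n_str)
            if op in "M=X":
                pairs.extend((qidx + i, rpos + i) for i in range(n))
                qidx += n
                rpos += n
            elif op in "IS":
                qidx += n
            elif op in "DN":
                rpos += n
            # H and P consume neither
        return pairs


class FilterReason(str, Enum):
    """Why a read was kept or suppressed (first failing gate wins)."""

    ok = "ok"
    low_mapq = "low_mapq"
    mapq_missing = "mapq_missing"
    non_match_cigar = "non_match_cigar"
    too_many_lowq_bases = "too_many_lowq_bases"


@dataclass(frozen=True)
class FilterVerdict:
    passed: bool
    reason: FilterReason

    def __post_init__(self) -> None:
        if self.passed != (self.reason is FilterReason.ok):
            raise ValueError("passed flag inconsistent with reason")


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the read-suppression and counting gates.

    ``lowq_count_max`` switches the low-quality-read rule from the
    fractional form (suppress when the low-quality fraction is
    >= ``lowq_frac_max``) to an absolute form (suppress when the count
    is >= ``lowq_count_max``); for 101 bp reads the defaults coincide
    (5 bases ~ 5%).
    """

    trim_bp: int = 5
    mapq_min: int = 55
    mapq_missing: int = 255
    discard_missing_mapq: bool = True
    lowq_phred: int = 20  # a base is low-quality iff phred < lowq_phred
    lowq_frac_max: float = 0.05  # suppress read iff lowq fraction >= this
    lowq_count_max: int | None = None  # absolute-count variant, off by default
    base_qual_min: int = 30  # per-base counting threshold
    match_only_cigar: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.lowq_frac_max <= 1.0):
            raise ValueError("lowq_frac_max must be in [0, 1]")
        if self.trim_bp < 0 or self.mapq_min < 0 or self.lowq_phred < 0:
            raise ValueError("thresholds must be non-negative")

    @classmethod
    def no_filter(cls) -> "FilterConfig":
        """Pass-everything configuration used for pileup-equivalence checks."""
        return cls(
            trim_bp=0,
            mapq_min=0,
            discard_missing_mapq=False,
            lowq_frac_max=1.0,
            match_only_cigar=False,
            base_qual_min=0,
        )

    def evolve(self, **kwargs) -> "FilterConfig":
        return replace(self, **kwargs)


def _lowq_base_mask(seq: str, qual: np.ndarray, lowq_phred: int) -> np.ndarray:
    """Low-quality call mask; N bases count as low-quality regardless of score."""
    mask = qual < lowq_phred
    if "N" in seq:
        mask = mask | (np.frombuffer(seq.encode(), dtype=np.uint8) == ord("N"))
    return mask


def _too_many_lowq(seq: str, qual: np.ndarray, cfg: FilterConfig) -> bool:
    n_low = int(_lowq_base_mask(seq, qual, cfg.lowq_phred).sum())
    if cfg.lowq_count_max is not None:
        return n_low >= cfg.lowq_count_max
    if cfg.lowq_frac_max >= 1.0:  # ceiling of 1 disables the rule (no-filter mode)
        return False
    return n_low / len(seq) >= cfg.lowq_frac_max


def passes_read_filters(read: AlignedReadRecord, cfg: FilterConfig) -> FilterVerdict:
    """Apply the read-suppression gates in fixed order, reporting the first hit.

    Order: low MAPQ, missing MAPQ (255), non-match CIGAR, excess
    low-quality bases.  The low-quality fraction is computed on the
    untrimmed read.
    """
    if len(read) == 0:
        raise ValueError(f"read {read.qname}: empty sequence")
    if read.mapq < cfg.mapq_min:
        return FilterVerdict(False, FilterReason.low_mapq)
    if cfg.discard_missing_mapq and read.mapq == cfg.mapq_missing:
        return FilterVerdict(False, FilterReason.mapq_missing)
    if cfg.match_only_cigar and not _MATCH_ONLY_CIGAR.match(read.cigar):
        return FilterVerdict(False, FilterReason.non_match_cigar)
    if _too_many_lowq(read.seq, read.qual, cfg):
        return FilterVerdict(False, FilterReason.too_many_lowq_bases)
    return FilterVerdict(True, FilterReason.ok)


def countable_mask(read: AlignedReadRecord, cfg: FilterConfig) -> np.ndarray:
    """Per-base countability mask after end trimming.

    Trimming is by sequenced-read coordinate (cycles), independent of
    strand: the motivation is per-cycle quality decay, and the first
    ``trim_bp`` machine cycles of a reverse read are its *last* stored
    bases — but since the mask is symmetric the stored orientation can
    be used directly.  A read shorter than ``2*trim_bp`` contributes
    nothing (all-False mask).
    """
    n = len(read)
    mask = np.zeros(n, dtype=bool)
    if n > 2 * cfg.trim_bp:
        mask[cfg.trim_bp: n - cfg.trim_bp] = True
    return mask


# Category labels of the cumulative read-quality distribution, in the
# priority order used for assignment (each read lands in exactly one bin).
QUALITY_CATEGORIES = (
    "low_mapq",
    "non_match_cigar",
    ">=16_lowq_bases",
    ">=12_lowq_bases",
    ">=8_lowq_bases",
    ">=5_lowq_bases",
    ">=1_lowq_bases",
    "0_lowq_bases",
)
_LOWQ_BINS = (16, 12, 8, 5, 1)


@dataclass
class ReadQualityStats:
    """Per-cycle Q30 fractions and the read-category distribution."""

    per_cycle_q30: np.ndarray  # fraction of bases with phred >= 30, by cycle
    per_cycle_n: np.ndarray  # number of reads contributing to each cycle
    category_fractions: pd.Series  # indexed by QUALITY_CATEGORIES, sums to 1
    n_reads: int


def read_quality_profile(
    reads: Iterable[AlignedReadRecord],
    cfg: FilterConfig | None = None,
    q30: int = 30,
) -> ReadQualityStats:
    """Diagnostics motivating the read gates.

    Cycle statistics are computed in machine-cycle order (reverse reads
    are flipped back).  Categories are assigned with priority: low or
    missing MAPQ first, then non-match CIGAR, then binned by the number
    of low-quality bases.
    """
    cfg = cfg or FilterConfig()
    q30_by_cycle: dict[int, int] = {}
    n_by_cycle: dict[int, int] = {}
    counts = {c: 0 for c in QUALITY_CATEGORIES}
    n_reads = 0
    for read in reads:
        n_reads += 1
        qual = read.qual[::-1] if read.is_reverse else read.qual
        for cycle, q in enumerate(qual):
            n_by_cycle[cycle] = n_by_cycle.get(cycle, 0) + 1
            if q >= q30:
                q30_by_cycle[cycle] = q30_by_cycle.get(cycle, 0) + 1
        if read.mapq < cfg.mapq_min or (
            cfg.discard_missing_mapq and read.mapq == cfg.mapq_missing
        ):
            counts["low_mapq"] += 1
        elif cfg.match_only_cigar and not _MATCH_ONLY_CIGAR.match(read.cigar):
            counts["non_match_cigar"] += 1
        else:
            n_low = int(_lowq_base_mask(read.seq, read.qual, cfg.lowq_phred).sum())
            for threshold in _LOWQ_BINS:
                if n_low >= threshold:
                    counts[f">={threshold}_lowq_bases"] += 1
                    break
            else:
                counts["0_lowq_bases"] += 1
    if n_reads == 0:
        raise ValueError("read_quality_profile requires a non-empty read set")
    n_cycles = max(n_by_cycle) + 1
    per_n = np.array([n_by_cycle.get(c, 0) for c in range(n_cycles)], dtype=float)
    per_q30 = np.array([q30_by_cycle.get(c, 0) for c in range(n_cycles)], dtype=float)
    fractions = pd.Series(
        {c: counts[c] / n_reads for c in QUALITY_CATEGORIES}, name="fraction"
    )
    return ReadQualityStats(
        per_cycle_q30=np.divide(per_q30, per_n, out=np.zeros_like(per_q30), where=per_n > 0),
        per_cycle_n=per_n.astype(int),
        category_fractions=fractions,
        n_reads=n_reads,
    )


# ---------------------------------------------------------------------------
# Vectorized gate evaluation for batches of equal-length, all-match reads.
# Used by the simulator-facing fast counting path; semantics identical to
# passes_read_filters.


def filter_keep_arrays(
    mapq: np.ndarray,
    qual: np.ndarray,
    seq_codes: np.ndarray,
    match_cigar: np.ndarray,
    cfg: FilterConfig,
) -> np.ndarray:
    """Vectorized read-gate evaluation.

    Parameters are parallel arrays over reads: ``mapq`` (n,), ``qual``
    (n, L), ``seq_codes`` (n, L) with A/C/G/T/N coded 0-4, and
    ``match_cigar`` (n,) flagging all-match alignments.  Returns a
    boolean keep mask equivalent to ``passes_read_filters`` per read.
    """
    keep = mapq >= cfg.mapq_min
    if cfg.discard_missing_mapq:
        keep &= mapq != cfg.mapq_missing
    if cfg.match_only_cigar:
        keep = keep & match_cigar
    lowq = (qual < cfg.lowq_phred) | (seq_codes == 4)
    n_low = lowq.sum(axis=1)
    if cfg.lowq_count_max is not None:
        keep &= n_low < cfg.lowq_count_max
    elif cfg.lowq_frac_max < 1.0:
        keep &= n_low / qual.shape[1] < cfg.lowq_frac_max
    return keep
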