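"""Expected mutant-allele fractions in cancer/normal spike-in designs.

Mixing cancer DNA into matched normal DNA at a known ratio produces
markers of known expected mutant-allele fraction (MAF), which anchor the
limit-of-detection analysis.  For a somatic SNV carried on ``a`` of the
``c`` copies of its locus per cancer cell, diluted 1:d into a normal
with 2 copies of the locus, the expected MAF is

    exact:        a / (c + 2 d)
    approximate:  a / (2 d)          (d >> c)

e.g. a marker with a=4 mutant alleles on a 6-copy locus has expected MAF
0.002 at 1:1000 and 0.0004 at 1:5000.  A spike-in design with mutant
allele counts {1, 2, 4} over two dilution arms {1000, 5000} yields six
distinct MAF levels after rounding to one significant figure.

The undiluted cancer specimen provides a powerful false-positive check:
a true variant's MAF must rise roughly d-fold in the undiluted sample,
whereas a recurrent artifact stays flat.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DilutionArm",
    "DilutionMarker",
    "FalsePositiveCall",
    "benchmark_detection",
    "expected_maf",
    "flag_false_positive",
    "maf_ladder",
    "read_markers",
    "round_to_sig",
    "write_markers",
]


@dataclass(frozen=True)
class DilutionMarker:
    """A known somatic SNV used as a spike-in truth marker.

    ``a`` is the number of mutant alleles per cancer cell and ``c`` the
    total copy number of the locus per cancer cell (e.g. a=4, c=6 for a
    hotspot on a locus with 4 of 6 copies mutated).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    a: int
    c: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.a < 0 or self.c < 1:
            raise ValueError("need a >= 0 and c >= 1")
        if self.a > self.c:
            raise ValueError(f"marker {self.label or self.pos}: a={self.a} > c={self.c}")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")


@dataclass(frozen=True)
class DilutionArm:
    """One arm of the dilution series: d normal cells per cancer cell."""

    d: int
    normal_copies: int = 2

    def __post_init__(self) -> None:
        if self.d < 1:
            raise ValueError("dilution factor d must be >= 1")
        if self.normal_copies < 1:
            raise ValueError("normal locus copy number must be >= 1")


def expected_maf(
    marker: DilutionMarker, arm: DilutionArm, approximate: bool = False
) -> float:
    """Expected mutant-allele fraction of ``marker`` under dilution ``arm``.

    Exact mode uses a / (c + d * normal_copies); approximate mode drops
    the cancer-cell copies from the denominator (a / (d * normal_copies)),
    the usual shorthand when d >> c.
    """
    if approximate:
        return marker.a / (arm.d * arm.normal_copies)
    return marker.a / (marker.c + arm.d * arm.normal_copies)


def round_to_sig(x: float, digits: int = 1) -> float:
    """Round to ``digits`` significant figures (0 stays 0)."""
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + digits - 1)


def maf_ladder(
    markers: Iterable[DilutionMarker], arms: Iterable[DilutionArm]
) -> list[float]:
    """Distinct expected-MAF levels of a design, ascending.

    Uses the approximate MAF rounded to one significant figure, matching
    how designed ladder levels are reported (e.g. 0.01% ... 0.2%).
    """
    markers = list(markers)
    arms = list(arms)
    if not markers or not arms:
        raise ValueError("need at least one marker and one arm")
    levels = {
        round_to_sig(expected_maf(m, arm, approximate=True))
        for m in markers
        for arm in arms
    }
    return sorted(levels)


class FalsePositiveCall(str, Enum):
    consistent_variant = "consistent_variant"
    false_positive = "false_positive"
    indeterminate = "indeterminate"


def flag_false_positive(
    maf_diluted: float,
    maf_undiluted: float,
    d: int,
    min_fold_frac: float = 0.1,
    depth_diluted: int | None = None,
    depth_undiluted: int | None = None,
    depth_min: int = 0,
) -> FalsePositiveCall:
    """Diluted-vs-undiluted consistency test for a candidate variant.

    A true variant diluted 1:d must show roughly a d-fold MAF increase
    in the undiluted specimen; the call is ``consistent_variant`` iff
    maf_undiluted >= min_fold_frac * d * maf_diluted (i.e. the undiluted
    MAF reaches at least 10% of the dilution-predicted fold by default).
    A site with zero diluted MAF, or with inadequate depth in either
    specimen, is ``indeterminate``.
    """
    if d < 1:
        raise ValueError("dilution factor d must be >= 1")
    for depth in (depth_diluted, depth_undiluted):
        if depth is not None and depth < depth_min:
            return FalsePositiveCall.indeterminate
    if maf_diluted == 0:
        return FalsePositiveCall.indeterminate
    if maf_undiluted >= min_fold_frac * d * maf_diluted:
        return FalsePositiveCall.consistent_variant
    return FalsePositiveCall.false_positive


def benchmark_detection(
    counts_diluted: pd.DataFrame,
    markers: Sequence[DilutionMarker],
    arm: DilutionArm,
    profile=None,
    depth_min: int = 500,
    dominant_frac: float = 0.95,
) -> pd.DataFrame:
    """Per-marker detection table against a background error profile.

    For every truth marker, reports the observed MAF in the diluted
    counts, the expected MAF under the dilution model, and whether the
    observation is separated from background noise — i.e. strictly
    above the profile's 99.9th-percentile error rate for the marker's
    substitution type (and trinucleotide context when the profile is
    context-stratified).  Markers whose site fails the depth/dominance
    eligibility gate are flagged ``ineligible`` rather than dropped.

    ``profile`` is an :class:`~cleandeepseq.error_profile.ErrorProfile`
    (or ``None``, treated as an all-zero noise floor, appropriate for
    zero-error simulations).
    """
    from .allele_counter import SiteCounts, is_countable_site
    from .error_profile import substitution_type

    by_pos = {
        (row["chrom"], int(row["pos"])): row for _, row in counts_diluted.iterrows()
    }
    rows = []
    for m in markers:
        key = (m.chrom, m.pos)
        row = by_pos.get(key)
        if row is None:
            raise ValueError(f"marker {m.label or m.pos} outside the counted region")
        sc = SiteCounts.from_row(row)
        depth = sc.depth
        observed = sc.count(m.alt) / depth if depth > 0 else float("nan")
        expected = expected_maf(m, arm)
        eligible = is_countable_site(sc, depth_min, dominant_frac)
        sub = substitution_type(m.ref, m.alt)
        noise = 0.0
        if profile is not None:
            noise = profile.lookup(sub, default=float("nan"))
        separated = bool(eligible and depth > 0 and observed > noise)
        rows.append(
            {
                "chrom": m.chrom,
                "pos": m.pos,
                "ref": m.ref,
                "alt": m.alt,
                "label": m.label,
                "type": sub,
                "depth": depth,
                "observed_maf": observed,
                "expected_maf": expected,
                "noise_p999": noise,
                "eligible": eligible,
                "separated": separated,
            }
        )
    return pd.DataFrame(rows)


MARKER_COLUMNS = ["chrom", "pos", "ref", "alt", "a", "c", "label"]


def write_markers(markers: Sequence[DilutionMarker], path) -> None:
    pd.DataFrame([m.__dict__ for m in markers])[MARKER_COLUMNS].to_csv(
        path, sep="\t", index=False
    )


def read_markers(path) -> list[DilutionMarker]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "label": str})
    df["label"] = df.get("label", "").fillna("")
    return [
        DilutionMarker(
            chrom=r["chrom"], pos=int(r["pos"]), ref=r["ref"], alt=r["alt"],
            a=int(r["a"]), c=int(r["c"]), label=str(r.get("label", "")),
        )
        for _, r in df.iterrows()
    ]
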