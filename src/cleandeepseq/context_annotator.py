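"""High/low error-rate context classification of variant lists.

C>T errors are strongly elevated in G-flanked trinucleotide contexts
(G(C>T)N or N(C>T)G, peaking at G(C>T)G), and G>A errors mirror this in
reverse complement (N(G>A)C or C(G>A)N).  Substitutions in these
contexts sit on a high background error floor and are hard to call at
low allele fraction; everything else lives in low-error contexts where
deep sequencing can reach 0.01-0.1% sensitivity.  This module applies
that classification to external variant or hotspot lists (tab-delimited
chrom, pos, ref, alt with flanks given or fetched from a reference) and
summarizes the fraction of a list that is detectable at low frequency.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .allele_counter import fetch_reference
from .read_qc import BASES

__all__ = [
    "VariantRecord",
    "annotate_variant_list",
    "classify_error_context",
    "read_variants",
]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class VariantRecord:
    """One substitution with its reference-strand flanking bases."""

    chrom: str
    pos: int
    ref: str
    alt: str
    flank5: str
    flank3: str
    recurrence: int | None = None
    population_af: float | None = None

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"{self.chrom}:{self.pos}: ref == alt")

    def reverse_complement(self) -> "VariantRecord":
        """The same event reported on the opposite strand."""
        return VariantRecord(
            chrom=self.chrom,
            pos=self.pos,
            ref=_COMPLEMENT[self.ref],
            alt=_COMPLEMENT[self.alt],
            flank5=_COMPLEMENT[self.flank3],
            flank3=_COMPLEMENT[self.flank5],
            recurrence=self.recurrence,
            population_af=self.population_af,
        )


def classify_error_context(variant: VariantRecord) -> str:
    """Classify a substitution as ``"high"`` or ``"low"`` error context.

    High iff the change is C>T with a G on either flank, or G>A with a
    C on either flank (the reverse-complement mirror); every other
    substitution is low.  Unknown flanks are rejected.
    """
    for name, flank in (("flank5", variant.flank5), ("flank3", variant.flank3)):
        if flank not in BASES:
            raise ValueError(
                f"{variant.chrom}:{variant.pos}: {name} base {flank!r} unknown"
            )
    sub = f"{variant.ref}>{variant.alt}"
    if sub == "C>T" and ("G" in (variant.flank5, variant.flank3)):
        return "high"
    if sub == "G>A" and ("C" in (variant.flank5, variant.flank3)):
        return "high"
    return "low"


def annotate_variant_list(
    variants: Sequence[VariantRecord],
    max_population_af: float = 0.001,
    min_recurrence: int = 1,
) -> tuple[pd.DataFrame, dict]:
    """Filter and classify a variant list.

    Variants with population allele fraction above ``max_population_af``
    (presumed germline contamination of the list) or recurrence below
    ``min_recurrence`` are removed before classification; a missing
    annotation never removes a variant.  Returns the per-variant table
    and a summary with the high/low-context fractions (``None``
    fractions when nothing survives the filters).
    """
    kept = []
    for v in variants:
        if v.population_af is not None and v.population_af > max_population_af:
            continue
        if v.recurrence is not None and v.recurrence < min_recurrence:
            continue
        kept.append(v)
    table = pd.DataFrame(
        [
            {
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "flank5": v.flank5,
                "flank3": v.flank3,
                "recurrence": v.recurrence,
                "population_af": v.population_af,
                "error_context": classify_error_context(v),
            }
            for v in kept
        ]
    )
    n = len(table)
    n_high = int((table["error_context"] == "high").sum()) if n else 0
    summary = {
        "n_total": n,
        "n_high": n_high,
        "n_low": n - n_high,
        "fraction_high": (n_high / n) if n else None,
        "fraction_low": ((n - n_high) / n) if n else None,
    }
    return table, summary


def read_variants(path, reference=None) -> list[VariantRecord]:
    """Load a tab-delimited variant list.

    Expects columns chrom, pos, ref, alt and optionally flank5, flank3,
    recurrence, population_af.  Missing flanks are fetched from
    ``reference`` when given, otherwise an error is raised.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    out = []
    for _, row in df.iterrows():
        chrom, pos = str(row["chrom"]), int(row["pos"])
        flank5 = row.get("flank5")
        flank3 = row.get("flank3")
        if (pd.isna(flank5) or pd.isna(flank3)) and reference is not None:
            flank5 = fetch_reference(reference, chrom, pos - 1, pos - 1)
            flank3 = fetch_reference(reference, chrom, pos + 1, pos + 1)
        if pd.isna(flank5) or pd.isna(flank3):
            raise ValueError(
                f"{chrom}:{pos}: flanks absent and no reference supplied"
            )
        rec = row.get("recurrence")
        af = row.get("population_af")
        out.append(
            VariantRecord(
                chrom=chrom,
                pos=pos,
                ref=str(row["ref"]),
                alt=str(row["alt"]),
                flank5=str(flank5),
                flank3=str(flank3),
                recurrence=None if pd.isna(rec) else int(rec),
                population_af=None if pd.isna(af) else float(af),
            )
        )
    return out
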