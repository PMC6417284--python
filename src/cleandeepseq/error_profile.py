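"""Substitution error rates, context stratification, and profile summaries.

The substitution error rate of genomic site i for the change g>m is

    rate_i(g>m) = (# fragments with nucleotide m at i) / (total # fragments at i)

measured at sites known to be devoid of real variation (deep coverage
and a dominant allele above 95%).  Per-site rates are stratified by the
12 substitution types and, optionally, by the 16 trinucleotide contexts
(one 5' and one 3' reference base), where C>T/G>A errors show strong
context dependence.  Profiles summarize the per-site rates with a
chosen statistic — median for ultra-deep data, or a high percentile
(99th/99.9th) when most sites have zero observed errors — and can be
compared between datasets by a through-origin linear fit, which is how
fold-changes such as the enrichment-PCR error increase are estimated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .allele_counter import countable_sites, fetch_reference
from .read_qc import BASES, SUBSTITUTION_TYPES

__all__ = [
    "ErrorProfile",
    "ProfileComparison",
    "SummarySpec",
    "attach_context",
    "compare_profiles",
    "damage_correlation",
    "nearest_rank",
    "profile_heatmap_matrix",
    "sample_error_rate",
    "site_error_rates",
    "substitution_type",
]

RATE_COLUMNS = ["chrom", "pos", "ref", "alt", "type", "rate", "depth"]

_STATISTIC_Q = {"median": 0.5, "p99": 0.99, "p999": 0.999}
# Default minimum sites per group: chosen so that > 20 sites lie above
# the requested percentile (1 for the median, which needs no tail).
_DEFAULT_MIN_SITES = {"median": 1, "p99": 2000, "p999": 20000}


def substitution_type(ref: str, alt: str) -> str:
    if ref not in BASES or alt not in BASES or ref == alt:
        raise ValueError(f"invalid substitution {ref}>{alt}")
    return f"{ref}>{alt}"


def site_error_rates(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-site substitution error rates, one row per non-reference allele.

    Expects a counts table already restricted to eligible sites (see
    ``allele_counter.countable_sites``); rows with reference N or zero
    depth yield no records.  For each site the three error rates plus
    the reference fraction sum to 1 exactly.
    """
    keep = counts["ref"].isin(list(BASES)) & (counts["depth"] > 0)
    df = counts.loc[keep]
    if df.empty:
        return pd.DataFrame(columns=RATE_COLUMNS)
    frames = []
    for alt in BASES:
        sel = df["ref"] != alt
        sub = df.loc[sel]
        frames.append(
            pd.DataFrame(
                {
                    "chrom": sub["chrom"],
                    "pos": sub["pos"],
                    "ref": sub["ref"],
                    "alt": alt,
                    "type": sub["ref"] + ">" + alt,
                    "rate": sub[alt] / sub["depth"],
                    "depth": sub["depth"],
                }
            )
        )
    out = pd.concat(frames).sort_values(["chrom", "pos", "alt"], kind="stable")
    return out.reset_index(drop=True)[RATE_COLUMNS]


def attach_context(
    records: pd.DataFrame,
    reference,
    counts: pd.DataFrame | None = None,
    dominant_frac: float = 0.95,
    depth_min: int = 0,
) -> pd.DataFrame:
    """Add 5'/3' reference flanks and a context-eligibility flag.

    ``context5``/``context3`` are the reference-strand flanking bases.
    A record is flagged ``context_ok=False`` — excluded from
    context-stratified analyses but retained unstratified — when a
    flank is undefined (contig edge or non-ACGT base) or, if a counts
    table is supplied, when a flanking site lacks a dominant allele at
    frequency > ``dominant_frac``.
    """
    out = records.copy()
    five, three, ok = [], [], []
    flank_ok: dict[tuple[str, int], bool] = {}
    if counts is not None:
        eligible = countable_sites(counts, depth_min=depth_min, dominant_frac=dominant_frac)
        flank_ok = {
            (row["chrom"], int(row["pos"])): bool(good)
            for (_, row), good in zip(counts.iterrows(), eligible)
        }
    chrom_len: dict[str, int] = {}
    for _, row in out.iterrows():
        chrom, pos = row["chrom"], int(row["pos"])
        if chrom not in chrom_len:
            seg = reference[chrom]
            chrom_len[chrom] = len(getattr(seg, "seq", seg))
        n = chrom_len[chrom]
        if pos <= 1 or pos >= n:
            five.append("N")
            three.append("N")
            ok.append(False)
            continue
        f5 = fetch_reference(reference, chrom, pos - 1, pos - 1)
        f3 = fetch_reference(reference, chrom, pos + 1, pos + 1)
        good = f5 in BASES and f3 in BASES
        if counts is not None:
            good = good and flank_ok.get((chrom, pos - 1), False)
            good = good and flank_ok.get((chrom, pos + 1), False)
        five.append(f5)
        three.append(f3)
        ok.append(good)
    out["context5"] = five
    out["context3"] = three
    out["context_ok"] = ok
    return out


@dataclass(frozen=True)
class SummarySpec:
    """Which statistic summarizes per-site rates, and its site floor.

    ``min_sites_per_type`` defaults by statistic: 20,000 for the 99.9th
    percentile (ensuring > 20 sites above it), 2,000 for the 99th, and
    1 for the median.  Groups below the floor are reported unavailable.
    """

    statistic: str = "median"
    min_sites_per_type: int | None = None

    def __post_init__(self) -> None:
        if self.statistic not in _STATISTIC_Q:
            raise ValueError(f"unknown statistic {self.statistic!r}")

    @property
    def quantile(self) -> float:
        return _STATISTIC_Q[self.statistic]

    @property
    def min_sites(self) -> int:
        if self.min_sites_per_type is not None:
            return self.min_sites_per_type
        return _DEFAULT_MIN_SITES[self.statistic]


def nearest_rank(values: Sequence[float], q: float) -> float:
    """Nearest-rank quantile: the ceil(q*n)-th smallest value."""
    arr = np.sort(np.asarray(values, dtype=float))
    if arr.size == 0:
        raise ValueError("nearest_rank of an empty collection")
    k = max(1, math.ceil(q * arr.size))
    return float(arr[k - 1])


@dataclass
class ErrorProfile:
    """Per-sample summary of error rates by substitution type (and context).

    ``table`` is indexed by type — or by (type, context5, context3)
    when context-stratified — with columns ``value`` (the statistic;
    NaN when unavailable), ``n_sites`` and ``available``.
    """

    sample_id: str
    statistic: str
    table: pd.DataFrame
    by_context: bool = False

    def lookup(
        self,
        sub: str,
        context: tuple[str, str] | None = None,
        default: float = float("nan"),
    ) -> float:
        key = (sub, *context) if (self.by_context and context is not None) else sub
        try:
            row = self.table.loc[key]
        except KeyError:
            return default
        if isinstance(row, pd.DataFrame):  # context profile queried by type only
            row = row.loc[row["available"], "value"]
            return float(row.max()) if len(row) else default
        return float(row["value"]) if bool(row["available"]) else default

    def values_by_type(self) -> pd.Series:
        if self.by_context:
            raise ValueError("profile is context-stratified")
        return self.table["value"]

    def write(self, path) -> None:
        self.table.reset_index().assign(
            sample=self.sample_id, statistic=self.statistic
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path) -> "ErrorProfile":
        df = pd.read_csv(path, sep="\t")
        by_context = "context5" in df.columns
        sample = str(df["sample"].iloc[0]) if len(df) else ""
        statistic = str(df["statistic"].iloc[0]) if len(df) else "median"
        idx = ["type", "context5", "context3"] if by_context else ["type"]
        table = df.set_index(idx)[["value", "n_sites", "available"]]
        return cls(sample_id=sample, statistic=statistic, table=table, by_context=by_context)


def summarize_profile(
    records: pd.DataFrame,
    spec: SummarySpec | None = None,
    by_context: bool = False,
    sample_id: str = "sample",
) -> ErrorProfile:
    """Summarize per-site rate records into an :class:`ErrorProfile`.

    All 12 substitution types (x16 contexts if requested) are always
    present in the output; a group with fewer than ``spec.min_sites``
    contributing sites — or none at all — is marked unavailable with a
    NaN value rather than being reported.
    """
    spec = spec or SummarySpec()
    df = records
    if by_context:
        if "context_ok" in df.columns:
            df = df.loc[df["context_ok"]]
        keys = [
            (t, f5, f3) for t in SUBSTITUTION_TYPES for f5 in BASES for f3 in BASES
        ]
        index = pd.MultiIndex.from_tuples(keys, names=["type", "context5", "context3"])
        grouped = df.groupby(["type", "context5", "context3"])["rate"]
    else:
        index = pd.Index(SUBSTITUTION_TYPES, name="type")
        grouped = df.groupby("type")["rate"]
    values = pd.Series(np.nan, index=index, name="value")
    n_sites = pd.Series(0, index=index, name="n_sites", dtype=np.int64)
    for key, rates in grouped:
        if key not in index:
            continue
        n_sites[key] = len(rates)
        if len(rates) >= spec.min_sites:
            values[key] = nearest_rank(rates.to_numpy(), spec.quantile)
    table = pd.DataFrame(
        {"value": values, "n_sites": n_sites, "available": values.notna()}
    )
    return ErrorProfile(
        sample_id=sample_id, statistic=spec.statistic, table=table, by_context=by_context
    )


def sample_error_rate(
    counts: pd.DataFrame, depth_min: int = 50, dominant_frac: float = 0.95
) -> float | None:
    """Sample-level error rate: total mismatch bases / total counted bases.

    Computed over well-covered sites (depth >= ``depth_min`` with the
    *reference* allele dominant at fraction > ``dominant_frac``) — the
    summary used when per-site rates are unmeasurable at moderate
    depth.  Returns ``None`` when no site is eligible.
    """
    df = counts.loc[counts["ref"].isin(list(BASES)) & (counts["depth"] >= depth_min)]
    if df.empty:
        return None
    ref_counts = np.array(
        [row[row["ref"]] for _, row in df.iterrows()], dtype=np.int64
    )
    depth = df["depth"].to_numpy()
    eligible = ref_counts / depth > dominant_frac
    if not eligible.any():
        return None
    mismatches = depth[eligible] - ref_counts[eligible]
    return float(mismatches.sum() / depth[eligible].sum())


@dataclass(frozen=True)
class ProfileComparison:
    """Through-origin fit of profile A's statistics against profile B's."""

    slope: float
    r2: float
    n_types: int
    slope_with_intercept: float
    intercept: float
    r2_with_intercept: float


def compare_profiles(
    profile_a: ErrorProfile, profile_b: ErrorProfile, min_pairs: int = 6
) -> ProfileComparison:
    """Fold-change between two per-type profiles.

    Fits A = slope * B by least squares through the origin over the
    substitution types available in both profiles (a fold-change claim
    is a ratio, so no intercept); the fit with intercept is reported
    alongside.  r-squared for the origin fit is the uncentered
    1 - SS_res/SS_tot with SS_tot = sum(A^2).
    """
    if profile_a.statistic != profile_b.statistic:
        raise ValueError("profiles use different summary statistics")
    a = profile_a.values_by_type()
    b = profile_b.values_by_type()
    ok = a.notna() & b.notna()
    if int(ok.sum()) < min_pairs:
        raise ValueError(
            f"only {int(ok.sum())} substitution types available in both profiles "
            f"(minimum {min_pairs})"
        )
    x = b[ok].to_numpy(dtype=float)
    y = a[ok].to_numpy(dtype=float)
    slope = float(np.dot(x, y) / np.dot(x, x))
    ss_res = float(np.sum((y - slope * x) ** 2))
    ss_tot = float(np.sum(y**2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    fit = stats.linregress(x, y)
    return ProfileComparison(
        slope=slope,
        r2=r2,
        n_types=int(ok.sum()),
        slope_with_intercept=float(fit.slope),
        intercept=float(fit.intercept),
        r2_with_intercept=float(fit.rvalue**2),
    )


#: Row ordering of the context heatmap: panels by reference base, three
#: substitutions per panel, 16 contexts each sorted by (5', 3') flank.
_PANEL_REF_ORDER = ("C", "G", "A", "T")


def profile_heatmap_matrix(profiles: Mapping[str, ErrorProfile]) -> pd.DataFrame:
    """Samples-by-(type, context) matrix with deterministic ordering.

    Rows follow the heatmap convention: positions grouped by reference
    base (C, G, A, T panels), the three substitutions of each reference
    base grouped, and contexts sorted by flanking bases.  Columns are
    samples in the mapping's order; cells are the profiles' statistics
    (MAF scale, NaN where unavailable).
    """
    if not profiles:
        raise ValueError("need at least one sample profile")
    rows = [
        (f"{g}>{m}", f5, f3)
        for g in _PANEL_REF_ORDER
        for m in BASES
        if m != g
        for f5 in BASES
        for f3 in BASES
    ]
    index = pd.MultiIndex.from_tuples(rows, names=["type", "context5", "context3"])
    data = {}
    for sample, prof in profiles.items():
        if not prof.by_context:
            raise ValueError(f"profile for {sample!r} is not context-stratified")
        aligned = prof.table["value"].reindex(index)
        data[sample] = aligned
    return pd.DataFrame(data, index=index)


def damage_correlation(rates_by_sample: pd.DataFrame) -> pd.DataFrame:
    """Per-type linear fit of error rate against the C>A damage surrogate.

    ``rates_by_sample`` holds one row per sample and one column per
    substitution type.  Each non-C>A type is regressed (OLS) on the
    per-sample C>A rate; returns slope, r-squared and p-value per type,
    NaN rows where the fit is unavailable (constant predictor).
    Requires at least three samples.
    """
    if "C>A" not in rates_by_sample.columns:
        raise ValueError("rates table lacks the C>A predictor column")
    if len(rates_by_sample) < 3:
        raise ValueError("damage correlation requires at least 3 samples")
    x = rates_by_sample["C>A"].to_numpy(dtype=float)
    out = []
    for sub in rates_by_sample.columns:
        if sub == "C>A":
            continue
        y = rates_by_sample[sub].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.isnan(x).any() or np.isnan(y).any():
            out.append({"type": sub, "slope": np.nan, "r2": np.nan, "pvalue": np.nan})
            continue
        fit = stats.linregress(x, y)
        out.append(
            {
                "type": sub,
                "slope": float(fit.slope),
                "r2": float(fit.rvalue**2),
                "pvalue": float(fit.pvalue),
            }
        )
    return pd.DataFrame(out).set_index("type")
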