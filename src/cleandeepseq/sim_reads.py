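"""Synthetic paired-end aligned reads with known error processes.

Every downstream stage of the error-suppression pipeline is validated
against simulations with known ground truth.  The generator emulates
amplicon-style paired-end sequencing of short inserts (130-170 bp read
at 2x101 cycles, so mates overlap over much of the fragment) with:

* per-substitution-type base error rates, modulated by trinucleotide
  context multipliers and a per-sample damage factor acting on C>A/G>T
  (optionally coupled into other types);
* two injection modes: ``per_mate`` (sequencer-like; each mate errs
  independently, so mate concordance can rescue the error) and
  ``per_fragment`` (damage-like; the template itself carries the
  error, so both mates report it concordantly);
* a per-base Phred quality model with decay over the first/last
  sequencing cycles, a quality penalty on sequencer miscalls, and an
  admixture of low-quality reads whose errors are *not* flagged by
  quality (miscalibration) — the reads the read-level gates exist for;
* two-component cancer/normal spike-in mixtures: truth markers enter
  fragments at their dilution-expected mutant-allele fraction;
* configurable fractions of low-MAPQ, missing-MAPQ (255) and
  indel-CIGAR reads to exercise the alignment gates.

A single seed drives all randomness.  Stream order per chunk: fragment
lengths, (shotgun starts,) marker alleles, template errors, per-mate
errors, base qualities, degraded-base positions, MAPQ/CIGAR flags.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .dilution_model import DilutionArm, DilutionMarker, expected_maf
from .read_qc import BASES, SUBSTITUTION_TYPES, AlignedReadRecord

__all__ = [
    "ErrorModel",
    "QualityModel",
    "ReadBatch",
    "ReferenceSeq",
    "SpikeDesign",
    "TruthTable",
    "default_error_model",
    "iter_simulated_batches",
    "random_reference",
    "read_alignments",
    "simulate_fragments",
    "write_alignments",
]

_CODE = {b: i for i, b in enumerate(BASES + "N")}
_DECODE = np.array(list(BASES + "N"))


def encode_seq(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.uint8)
    for base, code in _CODE.items():
        out[arr == ord(base)] = code
    return out


def decode_seq(codes: np.ndarray) -> str:
    return "".join(_DECODE[codes])


@dataclass(frozen=True)
class ReferenceSeq:
    """A named reference contig held in memory."""

    chrom: str
    seq: str

    def __len__(self) -> int:
        return len(self.seq)

    def as_mapping(self) -> Mapping[str, str]:
        return {self.chrom: self.seq.upper()}

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f">{self.chrom}\n")
            for i in range(0, len(self.seq), 60):
                fh.write(self.seq[i: i + 60] + "\n")

    @classmethod
    def from_fasta(cls, path, chrom: str | None = None) -> "ReferenceSeq":
        import pyfaidx

        fasta = pyfaidx.Fasta(str(path))
        name = chrom or list(fasta.keys())[0]
        return cls(chrom=name, seq=str(fasta[name][:]).upper())


def random_reference(length: int, seed: int, chrom: str = "amp1") -> ReferenceSeq:
    rng = np.random.default_rng(seed)
    return ReferenceSeq(chrom, "".join(rng.choice(list(BASES), size=length)))


@dataclass(frozen=True)
class QualityModel:
    """Per-base Phred score model.

    ``end_decay`` lowers the mean over the first/last ``end_cycles``
    sequencing cycles (instrument defaults here are illustrative, not
    calibrated to any particular sequencer).  ``error_penalty`` is
    subtracted from the drawn quality of sequencer (per-mate) miscalls:
    in well-behaved reads the base caller flags its own errors.  Bases
    degraded inside low-quality reads draw from the ``lowq_base_*``
    component instead.
    """

    mean: float = 36.0
    sd: float = 4.0
    end_decay: float = 4.0
    end_cycles: int = 5
    error_penalty: float = 10.0
    lowq_base_mean: float = 10.0
    lowq_base_sd: float = 3.0
    qmin: int = 2
    qmax: int = 41


@dataclass(frozen=True)
class ErrorModel:
    """Substitution-error process of one simulated sample.

    ``base_rate_by_type`` maps the 12 substitution types (e.g. "C>T")
    to per-base error probabilities; missing types default to 0.
    ``context_multiplier`` maps (type, 5' base, 3' base) to a factor
    >= 0 applied on top of the base rate (evaluated on the reference
    trinucleotide).  ``sample_damage_factor`` multiplies C>A/G>T rates;
    ``damage_coupling`` lets other types co-vary with damage as
    rate * (1 + coupling * (factor - 1)).

    ``mode`` selects sequencer-like per-mate injection or damage-like
    per-fragment (template) injection.  Low-quality-read admixture:
    each read independently becomes an LQRead with probability
    ``lowq_read_frac``; LQReads carry ``lowq_read_error_mult``-fold
    error on all bases (not quality-flagged) and a ``lowq_base_prob``
    chance per base of a degraded quality score.
    """

    base_rate_by_type: Mapping[str, float] = field(default_factory=dict)
    context_multiplier: Mapping[tuple[str, str, str], float] = field(default_factory=dict)
    sample_damage_factor: float = 1.0
    damage_coupling: Mapping[str, float] = field(default_factory=dict)
    mode: str = "per_mate"
    quality: QualityModel = field(default_factory=QualityModel)
    lowq_read_frac: float = 0.0
    lowq_read_error_mult: float = 10.0
    lowq_base_prob: float = 0.15
    low_mapq_frac: float = 0.0
    missing_mapq_frac: float = 0.0
    indel_cigar_frac: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("per_mate", "per_fragment"):
            raise ValueError(f"unknown injection mode {self.mode!r}")
        for t, r in self.base_rate_by_type.items():
            if t not in SUBSTITUTION_TYPES:
                raise ValueError(f"unknown substitution type {t!r}")
            if not (0.0 <= r <= 1.0):
                raise ValueError(f"rate for {t} outside [0, 1]")
        for key, m in self.context_multiplier.items():
            if m < 0:
                raise ValueError(f"context multiplier for {key} must be >= 0")
        for frac in (
            self.lowq_read_frac, self.lowq_base_prob,
            self.low_mapq_frac, self.missing_mapq_frac, self.indel_cigar_frac,
        ):
            if not (0.0 <= frac <= 1.0):
                raise ValueError("read-class fractions must be in [0, 1]")

    def type_rate(self, sub: str) -> float:
        rate = float(self.base_rate_by_type.get(sub, 0.0))
        if sub in ("C>A", "G>T"):
            rate *= self.sample_damage_factor
        elif sub in self.damage_coupling:
            rate *= 1.0 + self.damage_coupling[sub] * (self.sample_damage_factor - 1.0)
        return rate

    def evolve(self, **kwargs) -> "ErrorModel":
        return replace(self, **kwargs)


def default_error_model(seed_quality: QualityModel | None = None) -> ErrorModel:
    """Error process with type- and context-dependence of realistic magnitude.

    Base rates span 1e-5 (A>C/T>G, C>A/G>T, C>G/G>C) to 1e-4 (A>G/T>C
    and C>T/G>A); C>T errors are elevated in G-flanked contexts with the
    G(C>T)G context highest, mirrored onto G>A by reverse complement.
    """
    rates = {
        "A>C": 1e-5, "A>G": 1e-4, "A>T": 1e-5,
        "C>A": 1e-5, "C>G": 1e-5, "C>T": 1e-4,
        "G>A": 1e-4, "G>C": 1e-5, "G>T": 1e-5,
        "T>A": 1e-5, "T>C": 1e-4, "T>G": 1e-5,
    }
    mult: dict[tuple[str, str, str], float] = {}
    for five in BASES:
        for three in BASES:
            # G(C>T)N or N(C>T)G elevated; G(C>T)G highest
            if five == "G" and three == "G":
                mult[("C>T", five, three)] = 5.0
            elif five == "G" or three == "G":
                mult[("C>T", five, three)] = 3.0
            # mirror for G>A: N(G>A)C or C(G>A)N, C(G>A)C highest
            if five == "C" and three == "C":
                mult[("G>A", five, three)] = 5.0
            elif five == "C" or three == "C":
                mult[("G>A", five, three)] = 3.0
    return ErrorModel(
        base_rate_by_type=rates,
        context_multiplier=mult,
        quality=seed_quality or QualityModel(),
    )


@dataclass(frozen=True)
class SpikeDesign:
    """Layout of one simulated sequencing run.

    ``depth`` is the number of fragments.  In ``amplicon`` layout every
    fragment starts at ``region_start`` (primer-anchored) with a length
    drawn from ``fragment_length_range``; in ``shotgun`` layout starts
    are uniform over the reference.
    """

    markers: tuple[DilutionMarker, ...] = ()
    dilution_factor: int = 1000
    depth: int = 1000
    fragment_length_range: tuple[int, int] = (130, 170)
    read_length: int = 101
    seed: int = 0
    region_start: int = 1
    layout: str = "amplicon"

    def __post_init__(self) -> None:
        if self.dilution_factor < 1:
            raise ValueError("dilution factor must be >= 1")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        lmin, lmax = self.fragment_length_range
        if not (0 < lmin <= lmax):
            raise ValueError("invalid fragment length range")
        if self.read_length < 11:  # 2 x default trim width + 1
            raise ValueError("read length must cover at least 2 x trim + 1 bases")
        if lmin < self.read_length:
            raise ValueError("fragment length below read length is not modelled")
        if self.layout not in ("amplicon", "shotgun"):
            raise ValueError(f"unknown layout {self.layout!r}")

    @property
    def arm(self) -> DilutionArm:
        return DilutionArm(d=self.dilution_factor)


@dataclass
class ReadBatch:
    """Struct-of-arrays view of paired reads from ``n`` fragments.

    Mates are indexed 0 (forward, leftmost) and 1 (reverse); sequences
    and qualities are stored in reference orientation, as in SAM.
    Arrays: ``pos`` (n, 2) 1-based leftmost positions, ``seq``/``qual``
    (n, 2, L), ``mapq`` (n, 2), ``match_cigar`` (n, 2).  Fragment ids
    are ``frag_id_start + arange(n)``.
    """

    chrom: str
    pos: np.ndarray
    seq: np.ndarray
    qual: np.ndarray
    mapq: np.ndarray
    match_cigar: np.ndarray
    frag_id_start: int = 0

    def __len__(self) -> int:
        return self.pos.shape[0]

    @property
    def read_len(self) -> int:
        return self.seq.shape[2]

    def _cigar(self, fi: int, mi: int) -> str:
        L = self.read_len
        if self.match_cigar[fi, mi]:
            return f"{L}M"
        mid = L // 2
        return f"{mid + 1}M1I{L - mid - 2}M"

    def record(self, fi: int, mi: int) -> AlignedReadRecord:
        return AlignedReadRecord(
            qname=f"frag{self.frag_id_start + fi}",
            chrom=self.chrom,
            pos=int(self.pos[fi, mi]),
            mapq=int(self.mapq[fi, mi]),
            cigar=self._cigar(fi, mi),
            seq=decode_seq(self.seq[fi, mi]),
            qual=self.qual[fi, mi].astype(np.int64),
            is_reverse=bool(mi == 1),
            mate_chrom=self.chrom,
            mate_pos=int(self.pos[fi, 1 - mi]),
        )

    def to_records(self) -> list[AlignedReadRecord]:
        """All reads as records, coordinate-sorted."""
        order = sorted(
            ((int(self.pos[fi, mi]), fi, mi) for fi in range(len(self)) for mi in (0, 1))
        )
        return [self.record(fi, mi) for _, fi, mi in order]

    @classmethod
    def concat(cls, batches: Sequence["ReadBatch"]) -> "ReadBatch":
        if not batches:
            raise ValueError("no batches to concatenate")
        first = batches[0]
        return cls(
            chrom=first.chrom,
            pos=np.concatenate([b.pos for b in batches]),
            seq=np.concatenate([b.seq for b in batches]),
            qual=np.concatenate([b.qual for b in batches]),
            mapq=np.concatenate([b.mapq for b in batches]),
            match_cigar=np.concatenate([b.match_cigar for b in batches]),
            frag_id_start=first.frag_id_start,
        )


@dataclass
class TruthTable:
    """Ground truth of a simulation chunk.

    ``errors`` registers every injected miscall, one row per covering
    mate: (chrom, pos, fragment_id, mate, true_base, emitted_base,
    phred).  ``marker_truth`` summarizes spike-in alleles per marker
    site; ``mutant_fragment_ids`` lists which fragments carry each
    marker's mutant allele.  For reads flagged with an indel CIGAR the
    registry describes the pre-indel readout.
    """

    n_fragments: int
    errors: pd.DataFrame
    marker_truth: pd.DataFrame
    mutant_fragment_ids: dict[int, np.ndarray] = field(default_factory=dict)

    ERROR_COLUMNS = (
        "chrom", "pos", "fragment_id", "mate", "true_base", "emitted_base", "phred"
    )
    MARKER_COLUMNS = ("chrom", "pos", "ref", "alt", "n_covering", "n_mutant")

    @classmethod
    def empty(cls) -> "TruthTable":
        return cls(
            n_fragments=0,
            errors=pd.DataFrame(columns=list(cls.ERROR_COLUMNS)),
            marker_truth=pd.DataFrame(columns=list(cls.MARKER_COLUMNS)),
        )

    @classmethod
    def concat(cls, tables: Sequence["TruthTable"]) -> "TruthTable":
        if not tables:
            return cls.empty()
        merged_ids: dict[int, list[np.ndarray]] = {}
        marker = None
        for t in tables:
            for pos, ids in t.mutant_fragment_ids.items():
                merged_ids.setdefault(pos, []).append(ids)
        frames = [t.marker_truth for t in tables if len(t.marker_truth)]
        if frames:
            marker = (
                pd.concat(frames)
                .groupby(["chrom", "pos", "ref", "alt"], as_index=False)[
                    ["n_covering", "n_mutant"]
                ]
                .sum()
            )
        else:
            marker = tables[0].marker_truth
        return cls(
            n_fragments=sum(t.n_fragments for t in tables),
            errors=pd.concat([t.errors for t in tables], ignore_index=True),
            marker_truth=marker,
            mutant_fragment_ids={
                pos: np.concatenate(chunks) for pos, chunks in merged_ids.items()
            },
        )

    def write_errors(self, path) -> None:
        self.errors.to_csv(path, sep="\t", index=False)

    def write_marker_truth(self, path) -> None:
        self.marker_truth.to_csv(path, sep="\t", index=False)


def effective_rate_matrix(ref_codes: np.ndarray, model: ErrorModel) -> np.ndarray:
    """Per-position, per-alt effective error probabilities.

    Returns (len(ref), 4): entry [i, j] is the probability that the base
    at reference position i is misread as allele j (0 on the reference
    allele itself and on N positions).  Context multipliers use the
    reference trinucleotide; positions at contig edges get no
    multiplier.  Rejects configurations whose total per-base error
    probability exceeds 0.5.
    """
    n = len(ref_codes)
    rates = np.zeros((n, 4))
    five = np.full(n, 4, dtype=np.uint8)
    three = np.full(n, 4, dtype=np.uint8)
    five[1:] = ref_codes[:-1]
    three[:-1] = ref_codes[1:]
    for gi, g in enumerate(BASES):
        at_g = ref_codes == gi
        if not at_g.any():
            continue
        for m in BASES:
            if m == g:
                continue
            sub = f"{g}>{m}"
            base_rate = model.type_rate(sub)
            if base_rate == 0.0:
                continue
            col = np.full(n, base_rate)
            for (t, f5, f3), mult in model.context_multiplier.items():
                if t != sub:
                    continue
                sel = at_g & (five == _CODE[f5]) & (three == _CODE[f3])
                col[sel] = base_rate * mult
            rates[at_g, _CODE[m]] = col[at_g]
    total = rates.sum(axis=1)
    worst = total.max() if n else 0.0
    if worst * max(model.lowq_read_error_mult if model.lowq_read_frac > 0 else 1.0, 1.0) > 0.5:
        raise ValueError(
            f"effective per-base error probability {worst:.3g} (x LQRead "
            "multiplier) exceeds 0.5; rejecting configuration"
        )
    return rates


def _draw_alts(rates_rows: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Choose alt alleles for error events, proportional to per-alt rates."""
    cum = np.cumsum(rates_rows, axis=1)
    cum /= cum[:, -1:]
    return np.argmax(u[:, None] < cum, axis=1).astype(np.uint8)


def _inject(
    seq: np.ndarray,
    ref_index: np.ndarray,
    rate_matrix: np.ndarray,
    total_rate: np.ndarray,
    mult: np.ndarray | float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, ...]:
    """Inject errors into ``seq`` (modified in place).

    ``ref_index`` maps each seq entry to its 0-based reference position;
    ``mult`` scales the total rate (scalar or broadcastable).  Returns
    the index tuple of error positions and the original base codes.
    """
    p = total_rate[ref_index] * mult
    hit = rng.random(seq.shape) < p
    idx = np.nonzero(hit)
    if idx[0].size == 0:
        return idx, np.empty(0, dtype=np.uint8)
    rows = rate_matrix[ref_index[idx]]
    alts = _draw_alts(rows, rng.random(idx[0].size))
    original = seq[idx].copy()
    seq[idx] = alts
    return idx, original


def iter_simulated_batches(
    reference: ReferenceSeq,
    model: ErrorModel,
    design: SpikeDesign,
    chunk_fragments: int = 100_000,
) -> Iterator[tuple[ReadBatch, TruthTable]]:
    """Stream the simulation in chunks of fragments.

    Chunks come from a single seeded generator, so the concatenation of
    any chunking equals ``simulate_fragments`` output only for the same
    ``chunk_fragments``; determinism is per (seed, chunk size).
    """
    ref_codes = encode_seq(reference.seq)
    n_ref = len(ref_codes)
    lmin, lmax = design.fragment_length_range
    if n_ref < lmax:
        raise ValueError("reference shorter than the maximum fragment length")
    if design.layout == "amplicon" and design.region_start + lmax - 1 > n_ref:
        raise ValueError("amplicon window extends past the reference end")
    for m in design.markers:
        if m.chrom != reference.chrom or not (1 <= m.pos <= n_ref):
            raise ValueError(f"marker {m.label or m.pos} outside the reference")
        if BASES[ref_codes[m.pos - 1]] != m.ref:
            raise ValueError(
                f"marker {m.label or m.pos}: ref allele {m.ref} does not match "
                f"reference base {BASES[ref_codes[m.pos - 1]]}"
            )

    rate_matrix = effective_rate_matrix(ref_codes, model)
    total_rate = rate_matrix.sum(axis=1)
    q = model.quality
    R = design.read_length
    rng = np.random.default_rng(design.seed)
    remaining = design.depth
    frag_id = 0

    while remaining > 0:
        n = min(chunk_fragments, remaining)
        remaining -= n
        lengths = rng.integers(lmin, lmax + 1, size=n)
        if design.layout == "amplicon":
            starts = np.full(n, design.region_start, dtype=np.int64)
        else:
            starts = 1 + rng.integers(0, n_ref - lengths + 1)

        # fragment templates, padded to lmax; invalid tail masked
        offsets = np.arange(lmax)
        tmpl_idx = (starts - 1)[:, None] + offsets[None, :]
        tmpl_valid = offsets[None, :] < lengths[:, None]
        tmpl_idx_c = np.minimum(tmpl_idx, n_ref - 1)
        template = ref_codes[tmpl_idx_c].copy()

        # spike-in marker alleles (fragment-level, like a real variant)
        marker_rows = []
        mutant_ids: dict[int, np.ndarray] = {}
        for m in design.markers:
            p_mut = expected_maf(m, design.arm)
            covering = (starts <= m.pos) & (m.pos <= starts + lengths - 1)
            mutant = covering & (rng.random(n) < p_mut)
            tcol = m.pos - starts
            rows = np.nonzero(mutant)[0]
            template[rows, tcol[rows]] = _CODE[m.alt]
            marker_rows.append(
                {
                    "chrom": m.chrom, "pos": m.pos, "ref": m.ref, "alt": m.alt,
                    "n_covering": int(covering.sum()), "n_mutant": int(mutant.sum()),
                }
            )
            mutant_ids[m.pos] = frag_id + rows

        # template (damage-like) errors, shared by both mates
        tmpl_err_idx: tuple[np.ndarray, ...] = (np.empty(0, int),) * 2
        tmpl_err_true = np.empty(0, dtype=np.uint8)
        if model.mode == "per_fragment":
            hit_rate = np.where(tmpl_valid, 1.0, 0.0)
            idx, original = _inject(
                template, tmpl_idx_c, rate_matrix, total_rate, hit_rate, rng
            )
            tmpl_err_idx, tmpl_err_true = idx, original

        # mate views of the template (reference orientation)
        r_off = np.arange(R)
        pos0 = starts
        pos1 = starts + lengths - R
        seq = np.empty((n, 2, R), dtype=np.uint8)
        seq[:, 0, :] = np.take_along_axis(template, r_off[None, :], axis=1)
        idx1 = (lengths - R)[:, None] + r_off[None, :]
        seq[:, 1, :] = np.take_along_axis(template, idx1, axis=1)

        # low-quality-read admixture (independent per read)
        lq_read = rng.random((n, 2)) < model.lowq_read_frac

        # sequencer-like errors, independent per mate
        mate_err_idx: tuple[np.ndarray, ...] = (np.empty(0, int),) * 3
        mate_err_true = np.empty(0, dtype=np.uint8)
        ref_index = np.empty((n, 2, R), dtype=np.int64)
        ref_index[:, 0, :] = (pos0 - 1)[:, None] + r_off[None, :]
        ref_index[:, 1, :] = (pos1 - 1)[:, None] + r_off[None, :]
        if model.mode == "per_mate":
            mult = np.where(lq_read, model.lowq_read_error_mult, 1.0)[:, :, None]
            idx3, original = _inject(
                seq, ref_index, rate_matrix, total_rate, mult, rng
            )
            mate_err_idx, mate_err_true = idx3, original

        # qualities: normal draw, end decay, miscall penalty, LQ degradation
        qual = rng.normal(q.mean, q.sd, size=(n, 2, R))
        if q.end_cycles > 0:
            qual[:, :, : q.end_cycles] -= q.end_decay
            qual[:, :, R - q.end_cycles:] -= q.end_decay
        if model.mode == "per_mate" and mate_err_idx[0].size:
            is_lq_err = lq_read[mate_err_idx[0], mate_err_idx[1]]
            # LQRead miscalls are miscalibrated: no quality penalty
            qual[mate_err_idx] -= np.where(is_lq_err, 0.0, q.error_penalty)
        if model.lowq_read_frac > 0:
            degraded = lq_read[:, :, None] & (
                rng.random((n, 2, R)) < model.lowq_base_prob
            )
            qual[degraded] = rng.normal(
                q.lowq_base_mean, q.lowq_base_sd, size=int(degraded.sum())
            )
        qual = np.clip(np.rint(qual), q.qmin, q.qmax).astype(np.uint8)

        # mapping artifacts
        u = rng.random((n, 2))
        mapq = np.full((n, 2), 60, dtype=np.int16)
        mapq[u < model.low_mapq_frac] = 30
        band = model.low_mapq_frac + model.missing_mapq_frac
        mapq[(u >= model.low_mapq_frac) & (u < band)] = 255
        indel = rng.random((n, 2)) < model.indel_cigar_frac
        if indel.any():
            mid = R // 2
            rows = np.nonzero(indel)
            for fi, mi in zip(*rows):
                seq[fi, mi, mid + 1:] = seq[fi, mi, mid:-1].copy()
                qual[fi, mi, mid + 1:] = qual[fi, mi, mid:-1].copy()

        batch = ReadBatch(
            chrom=reference.chrom,
            pos=np.stack([pos0, pos1], axis=1),
            seq=seq,
            qual=qual,
            mapq=mapq,
            match_cigar=~indel,
            frag_id_start=frag_id,
        )
        truth = _build_truth(
            reference.chrom, frag_id, n, starts, lengths, pos0, pos1, R,
            tmpl_err_idx, tmpl_err_true, mate_err_idx, mate_err_true,
            template, seq, qual, marker_rows, mutant_ids,
        )
        frag_id += n
        yield batch, truth


def _build_truth(
    chrom, frag_id, n, starts, lengths, pos0, pos1, R,
    tmpl_err_idx, tmpl_err_true, mate_err_idx, mate_err_true,
    template, seq, qual, marker_rows, mutant_ids,
) -> TruthTable:
    rows = {c: [] for c in TruthTable.ERROR_COLUMNS}

    def add(frags, mates, js, refpos, true_codes, emitted_codes):
        rows["chrom"].extend([chrom] * len(frags))
        rows["pos"].extend(refpos.tolist())
        rows["fragment_id"].extend((frag_id + frags).tolist())
        rows["mate"].extend(mates.tolist())
        rows["true_base"].extend(_DECODE[true_codes].tolist())
        rows["emitted_base"].extend(_DECODE[emitted_codes].tolist())
        rows["phred"].extend(qual[frags, mates, js].tolist())

    if tmpl_err_idx[0].size:
        f, t = tmpl_err_idx
        refpos = starts[f] + t
        emitted = template[f, t]
        for mate, mate_pos in ((0, pos0), (1, pos1)):
            j = refpos - mate_pos[f]
            inside = (j >= 0) & (j < R)
            add(
                f[inside], np.full(inside.sum(), mate), j[inside],
                refpos[inside], tmpl_err_true[inside], emitted[inside],
            )
    if mate_err_idx[0].size:
        f, m, j = mate_err_idx
        refpos = np.where(m == 0, pos0[f], pos1[f]) + j
        add(f, m, j, refpos, mate_err_true, seq[f, m, j])

    errors = pd.DataFrame(rows, columns=list(TruthTable.ERROR_COLUMNS))
    return TruthTable(
        n_fragments=n,
        errors=errors,
        marker_truth=pd.DataFrame(
            marker_rows, columns=list(TruthTable.MARKER_COLUMNS)
        ),
        mutant_fragment_ids=mutant_ids,
    )


def simulate_fragments(
    reference: ReferenceSeq, model: ErrorModel, design: SpikeDesign
) -> tuple[ReadBatch, TruthTable]:
    """Simulate the full design in memory.

    Convenience wrapper over :func:`iter_simulated_batches`; for depths
    around 1e6 fragments prefer streaming the chunks directly into
    :func:`~cleandeepseq.allele_counter.pileup_counts_batch`.
    """
    batches, truths = [], []
    for batch, truth in iter_simulated_batches(reference, model, design):
        batches.append(batch)
        truths.append(truth)
    return ReadBatch.concat(batches), TruthTable.concat(truths)


# ---------------------------------------------------------------------------
# Alignment round-trip (SAM)


def write_alignments(
    records: Iterable[AlignedReadRecord] | ReadBatch,
    path,
    chrom_lengths: Mapping[str, int],
) -> None:
    """Write records as a coordinate-sorted SAM file with header.

    Records are sorted before writing; a record whose chromosome is
    absent from ``chrom_lengths`` is rejected by field name.
    """
    if isinstance(records, ReadBatch):
        records = records.to_records()
    records = sorted(records, key=lambda r: (r.chrom, r.pos, r.qname, r.is_reverse))
    names = list(chrom_lengths)
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": c, "LN": int(chrom_lengths[c])} for c in names],
        }
    )
    tid = {c: i for i, c in enumerate(names)}
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for rec in records:
            if rec.chrom not in tid:
                raise ValueError(f"record {rec.qname}: unknown chrom {rec.chrom!r}")
            seg = pysam.AlignedSegment(header)
            seg.query_name = rec.qname
            seg.query_sequence = rec.seq
            seg.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(int(qv) + 33) for qv in rec.qual)
            )
            flag = 0x1 | 0x2  # paired, proper pair
            flag |= 0x10 if rec.is_reverse else 0x20
            flag |= 0x80 if rec.is_reverse else 0x40
            seg.flag = flag
            seg.reference_id = tid[rec.chrom]
            seg.reference_start = rec.pos - 1
            seg.mapping_quality = rec.mapq
            seg.cigarstring = rec.cigar
            if rec.mate_chrom is not None:
                seg.next_reference_id = tid[rec.mate_chrom]
                seg.next_reference_start = (rec.mate_pos or rec.pos) - 1
            out.write(seg)


def read_alignments(path) -> list[AlignedReadRecord]:
    """Read a SAM/BAM file back into records (mapped reads only)."""
    records = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for seg in fh:
            if seg.is_unmapped:
                continue
            records.append(
                AlignedReadRecord(
                    qname=seg.query_name,
                    chrom=seg.reference_name,
                    pos=seg.reference_start + 1,
                    mapq=seg.mapping_quality,
                    cigar=seg.cigarstring or "",
                    seq=seg.query_sequence or "",
                    qual=np.asarray(seg.query_qualities, dtype=np.int64),
                    is_reverse=seg.is_reverse,
                    mate_chrom=(
                        seg.next_reference_name
                        if seg.next_reference_id >= 0
                        else None
                    ),
                    mate_pos=(
                        seg.next_reference_start + 1
                        if seg.next_reference_id >= 0
                        else None
                    ),
                )
            )
    return records
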