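"""Literal brute-force implementations of the counting rules.

These oracles restate the suppression and counting procedure as plainly
as possible — nested loops over fragments, positions and readouts, with
every threshold written out — and stay independent of the package's
implementation so that equivalence tests are meaningful.
"""

import re

TRIM = 5
MAPQ_MIN = 55
MAPQ_MISSING = 255
LOWQ_PHRED = 20
LOWQ_FRAC = 0.05
BASE_QUAL_MIN = 30


def _read_passes(read) -> bool:
    if read.mapq < MAPQ_MIN:
        return False
    if read.mapq == MAPQ_MISSING:
        return False
    if not re.fullmatch(r"\d+M", read.cigar):
        return False
    n_low = sum(
        1 for b, q in zip(read.seq, read.qual) if q < LOWQ_PHRED or b == "N"
    )
    if n_low / len(read.seq) >= LOWQ_FRAC:
        return False
    return True


def _informative(base, qual) -> bool:
    return qual >= BASE_QUAL_MIN and base in "ACGT"


def clean_counts(reads, region):
    """CleanDeepSeq counting: trimming + read gates + overlap rules (i)/(ii)."""
    chrom, start, end = region
    counts = {p: {b: 0 for b in "ACGT"} for p in range(start, end + 1)}
    fragments = {}
    for read in reads:
        fragments.setdefault(read.qname, []).append(read)
    for frag_reads in fragments.values():
        if any(r.chrom != chrom for r in frag_reads):
            continue
        readouts = {}
        for read in frag_reads:
            if not _read_passes(read):
                continue
            for i in range(len(read.seq)):
                if i < TRIM or i >= len(read.seq) - TRIM:
                    continue
                p = read.pos + i
                if start <= p <= end:
                    readouts.setdefault(p, []).append(
                        (read.seq[i], int(read.qual[i]))
                    )
        for p, obs in readouts.items():
            if len(obs) == 1:
                base, qual = obs[0]
                if _informative(base, qual):
                    counts[p][base] += 1
            elif len(obs) == 2:
                (b0, q0), (b1, q1) = obs
                hi0, hi1 = _informative(b0, q0), _informative(b1, q1)
                if hi0 and hi1:
                    if b0 == b1:
                        counts[p][b0] += 1
                elif hi0:
                    counts[p][b0] += 1
                elif hi1:
                    counts[p][b1] += 1
    return counts


def naive_counts(reads, region):
    """Per-base Q30/MAPQ-55 counting without fragment collapsing or trimming."""
    chrom, start, end = region
    counts = {p: {b: 0 for b in "ACGT"} for p in range(start, end + 1)}
    for read in reads:
        if read.chrom != chrom:
            continue
        if read.mapq < MAPQ_MIN or read.mapq == MAPQ_MISSING:
            continue
        qidx, rpos = 0, read.pos
        for n_str, op in re.findall(r"(\d+)([MIDNSHP=X])", read.cigar):
            n = int(n_str)
            if op in "M=X":
                for k in range(n):
                    p = rpos + k
                    base, qual = read.seq[qidx + k], read.qual[qidx + k]
                    if start <= p <= end and base in "ACGT" and qual >= BASE_QUAL_MIN:
                        counts[p][base] += 1
                qidx += n
                rpos += n
            elif op in "IS":
                qidx += n
            elif op in "DN":
                rpos += n
    return counts


def random_instance(rng, max_fragments=20, region_len=50, chrom="amp1"):
    """One random small counting instance: reads + region + reference.

    Fragments get 1-2 mates with arbitrary overlap; reads carry random
    MAPQs (including 255), occasional indel CIGARs, random bases with N
    sprinkled in, and qualities spanning the low-quality threshold.
    """
    from cleandeepseq.read_qc import AlignedReadRecord  # data container only

    start = 11
    end = start + region_len - 1
    reads = []
    n_frag = int(rng.integers(1, max_fragments + 1))
    for fi in range(n_frag):
        n_mates = int(rng.integers(1, 3))
        for mi in range(n_mates):
            length = int(rng.integers(12, 21))
            pos = int(rng.integers(1, end + 5))
            bases = rng.choice(list("ACGTN"), size=length, p=[0.24, 0.24, 0.24, 0.24, 0.04])
            qual = rng.integers(2, 41, size=length)
            mapq = int(rng.choice([10, 55, 60, 255], p=[0.15, 0.2, 0.55, 0.1]))
            if rng.random() < 0.15:
                k = length // 2
                cigar = f"{k}M1I{length - k - 1}M"
            else:
                cigar = f"{length}M"
            reads.append(
                AlignedReadRecord(
                    qname=f"frag{fi}", chrom=chrom, pos=pos, mapq=mapq,
                    cigar=cigar, seq="".join(bases), qual=qual,
                    is_reverse=bool(mi == 1), mate_chrom=chrom, mate_pos=pos,
                )
            )
    reads.sort(key=lambda r: r.pos)
    return reads, (chrom, start, end)
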