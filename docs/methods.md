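# Methods

This note documents the models and procedures the package implements,
the tunable parameters and their defaults, what the synthetic-data
generator does and does not emulate, the numerical conventions, and the
design choices made where the design was genuinely open.

## Read-level suppression

A read is suppressed if any gate fails; gates are evaluated in a fixed
order and the first failure is reported, so per-reason tallies over a
read set sum to the total.

| gate | default | semantics |
|------|---------|-----------|
| mapping quality | `mapq_min = 55` | keep iff MAPQ ≥ 55; MAPQ = 255 ("unavailable") always discarded while `discard_missing_mapq` |
| alignment shape | `match_only_cigar = True` | CIGAR must match `^\d+M$`; indels and clips imply alignment ambiguity |
| low-quality load | `lowq_phred = 20`, `lowq_frac_max = 0.05` | a base is low-quality iff Phred < 20 (strict); suppress iff the low-quality fraction is ≥ 5% (inclusive). N bases count as low-quality regardless of stored score |
| end trimming | `trim_bp = 5` | first/last 5 sequencing cycles masked from counting (quality decay, residual adapter/primer); by cycle, not reference position, and computed on the untrimmed read |

An absolute-count variant (`lowq_count_max`, suppress iff ≥ k
low-quality bases) is provided; for 101-bp reads the fractional and
absolute forms coincide (5 bases ≈ 5%). The fractional rule is the
operative default. A fraction ceiling of 1.0 disables the rule, which
gives a true pass-everything configuration (`FilterConfig.no_filter()`)
used for pileup-equivalence checks. The read-quality diagnostics
(per-cycle Q30 fraction; category distribution over low MAPQ, non-match
CIGAR, and low-quality-base bins ≥16/≥12/≥8/≥5/≥1/0) use the same
priority order.

## Fragment-aware counting

Fragments are identified by query name; mates mapping to different
chromosomes are excluded (a short-insert design implies proper pairs).
At each site a fragment has 1 or 2 readouts (more indicates malformed
pairing and is rejected):

* single readout: counted iff Phred ≥ `base_qual_min` (default 30);
* double readout: counted once if concordant with both ≥ Q30, or if
  exactly one readout is ≥ Q30 (that allele); a discordant pair with
  both readouts ≥ Q30 is discarded — the two stated counting
  conditions exclude this case and discarding is the conservative
  reading. Whether a lone high-quality readout should be counted when
  its low-quality mate disagrees is ambiguous; both behaviours are
  implemented (`strict_concordance`), default permissive.

`naive_pileup` mode reproduces per-base counting with a Q30 base
threshold and the MAPQ-55 gate, no trimming, no read-level
low-quality-fraction rule, no fragment collapsing: the comparator for
quantifying what suppression buys. By construction cleandeepseq counts
never exceed naive counts at the same thresholds.

Two equivalent counting paths exist: a record-based pure-Python path
(arbitrary SAM input, CIGAR-aware) and a vectorized struct-of-arrays
path for simulated batches, needed to reach ~1e6 fragments per site in
seconds. Both are cross-checked against a literal brute-force oracle on
randomized small instances, and against each other on simulated reads
including MAPQ/CIGAR defects.

Site eligibility for error measurement: depth strictly > `depth_min`
with a dominant allele strictly > 95%. Depth cutoffs are per-dataset
configuration values, not constants: 500,000X (ultra-deep amplicon),
15,000X (hybridization capture), 20,000X (merged WGS), 50X
(sample-level WES). The 95% threshold assumes error rates rarely exceed
5%; unrecognized low-level true variants can only inflate the measured
background, so reported rates are conservative upper bounds.

## Error rates, contexts, summaries

Per eligible site, the error rate of g>m is count(m)/depth; the three
non-reference rates plus the reference fraction sum to 1 exactly. The
12 substitution types are kept unfolded (complementary pairing is a
presentation grouping only — context dependence mirrors between
strands and is only visible unfolded). Trinucleotide context is the
reference-strand 5'/3' flank pair; a record is excluded from
context-stratified output (but retained unstratified) when a flank is
undefined (contig edge, non-ACGT) or, when flank counts are supplied,
when a flanking site lacks a >95% dominant allele.

Summary statistics use nearest-rank quantiles (the ceil(q·n)-th
smallest value; for the median this is the lower median at even n).
Nearest-rank makes the site floors exact: requiring > 20,000 sites per
type guarantees > 20 sites above the 99.9th percentile; the analogous
floor for the 99th percentile is 2,000 and the median needs only 1.
Groups below the floor are reported unavailable (NaN), never silently
dropped or extrapolated.

The sample-level error rate is Σ(non-reference counts)/Σ(depth) over
sites with depth ≥ 50 and the *reference* allele (not merely any
allele) dominant at > 95% — the summary used when per-site rates are
unmeasurable at moderate depth.

Profile comparison fits A = slope·B through the origin over the types
available in both profiles (≥ 6 pairs required); a fold-change claim is
a ratio and no intercept is printed for it, so the origin fit is
primary and the fit with intercept is reported alongside. r² for the
origin fit is uncentered (1 − SS_res/Σa²). The context heatmap matrix
orders rows by reference-base panel (C, G, A, T), then substitution,
then flank pair, deterministically. Damage correlation regresses each
other type's per-sample rate on the per-sample C>A rate (the damage
surrogate) by OLS, requiring ≥ 3 samples; a constant predictor yields
an unavailable (NaN) fit.

## Dilution model

A marker with `a` mutant alleles among `c` locus copies per cancer
cell, diluted 1:d into a normal with 2 copies, has expected MAF
a/(c + 2d) exactly, a/(2d) approximately; the approximation error is
a·c/(2d(c+2d)) < a·c/(2d)². Designed ladder levels are the approximate
MAFs rounded to one significant figure (how such levels are quoted),
deduplicated and sorted. The diluted-vs-undiluted false-positive test
calls a candidate consistent iff maf_undiluted ≥ 0.1·d·maf_diluted:
the qualitative expectation "a true variant rises ~d-fold undiluted"
needs a numeric operationalization, and requiring 10% of the predicted
fold (`min_fold_frac = 0.1`, configurable and logged) tolerates copy-
number and sampling distortion while still rejecting flat artifacts.
Zero diluted MAF, or inadequate depth in either specimen, is
indeterminate. Benchmark tables flag a marker as separated from noise
iff its observed MAF strictly exceeds the background profile's 99.9th
percentile for its substitution type; ineligible marker sites are
flagged, not dropped.

## Regions and merged background

Mappability masks keep intervals with score exactly 1 and length > 300
bp, then shrink each end by 50 bp; emptied intervals are dropped. The
merged WGS background applies, per locus: per-sample inclusion (depth
≥ 20X and reference fraction > 95%; shallower samples are silent —
a veto requires enough coverage to call), a global heterozygote veto
(any sample with ≥ 20X and no allele > 95% excludes the locus
everywhere), and a final collapsed-coverage gate (≥ 20,000X summed).
The collapsed gate is applied last; order does not change membership.
The dominance thresholds are justified by binomial tails for a true
heterozygote (e.g. 2·P(X≤1 | 20, 0.5) ≈ 4e-5), exposed as
`heterozygote_pvalue`.

## The synthetic-read generator

The generator emulates amplicon-style paired-end sequencing of short
inserts — 130–170 bp fragments read at 2×101 cycles, so mates overlap
over 30–70 bp of the insert — with all randomness driven by one seed.
Per chunk, the draw order is: fragment lengths, (shotgun starts,)
marker alleles, template errors, per-mate errors, base qualities,
degraded-base positions, MAPQ/CIGAR assignment; chunked streaming is
deterministic per (seed, chunk size).

Error injection distinguishes two processes:

* `per_fragment` (damage-like): the template itself carries the error
  before sequencing — deamination- or oxidation-type lesions — so both
  mates report it concordantly and the error passes overlap consensus.
  These errors carry no base-quality penalty: the sequencer reads a
  damaged template confidently. This is why the counting pipeline
  recovers injected template-level rates without bias.
* `per_mate` (sequencer-like): each mate errs independently; overlap
  concordance can rescue the error. Miscalls in well-behaved reads
  draw a reduced quality (`error_penalty`, default −10 from a base
  quality of N(36, 4)): base callers flag their own uncertainty.

Effective per-site rates are base rate × context multiplier (evaluated
on the reference trinucleotide; no multiplier at contig edges) ×
sample-damage factor on C>A/G>T, with optional coupling of other types
(rate × (1 + coupling·(factor − 1))). Configurations whose total
per-base error probability could exceed 0.5 are rejected.

Low-quality reads are drawn independently per read
(`lowq_read_frac`): they carry a 10× error multiplier on *all* their
bases and a 15% per-base chance of a degraded quality score (N(10, 3)),
but their miscalls are *not* quality-flagged — in degraded reads the
quality string is miscalibrated and does not explain the excess error.
That miscalibration is the reason read-level suppression buys more than
per-base quality thresholds alone, and it is what makes the
naive-vs-suppressed contrast large (~15× per-type median in the
default contrast simulation) rather than a wash. The per-base
degradation probability is set so that essentially every low-quality
read trips the ≥5% rule (P(fewer than 6 of 101 bases degraded) ≈ 0.2%).

Spike-in markers enter each covering fragment with probability equal to
the exact expected MAF a/(c + 2d). Fractions of reads receive MAPQ 30,
MAPQ 255, or an indel CIGAR (a duplicated mid-read base recorded as a
1-bp insertion, alignment-consistent) to exercise the gates. Quality
scores are N(mean, sd) with a mean penalty over the first/last 5
cycles, rounded and clipped to [2, 41].

What the generator does not emulate — and hence what passing tests do
not show about real data: realistic indel/SV processes, adapter
read-through, flow-cell optics and duplicate clusters, GC or strand
bias, instrument-calibrated quality distributions (the defaults are
illustrative), PCR jackpotting/duplicate structure, and multi-contig
genomes (one contig per simulated run). The truth registry describes
pre-indel readouts for the few reads flagged with indel CIGARs (those
reads are excluded by the CIGAR gate in suppressed counting).

## Numerical conventions and degenerate inputs

Coordinates are 1-based inclusive internally; BED I/O is 0-based
half-open, matching SAM and BED conventions. Strand-halved count export
splits each allele count c into ceil(c/2) (forward) + floor(c/2)
(reverse). Ladder levels round to 1 significant figure. Reads shorter
than 2×trim contribute nothing (all-false mask), not an error. Empty
regions return empty tables; an empty read set is rejected where a
profile is meaningless. Downsampling retains whole fragments (both
mates together) with the given probability, seeded; count-table
downsampling is the equivalent binomial thinning. N readouts are never
informative: they cannot be counted and cannot veto a concordant mate.

## Problem sizes used by the test suite

Chosen to make binomial error bars decisively smaller than the effects
under test while keeping the suite fast: 1e6 fragments (~1e6 counted
depth per site) for injected-rate recovery at rates 1e-5–1e-4 with a 3
standard-error band; 3e5 fragments for the naive-vs-suppressed
contrast; 5e6-depth binomial count simulation over 2,000 sites for the
six-fold profile-comparison recovery; 1,000 randomized small instances
for brute-force counting equivalence.

## Known limitations

No UMI support (the modelled workflow has none); no base-quality
recalibration (reported not to change pileup results materially); no
variant caller — the package measures backgrounds, and its strand-
halved export exists precisely to feed strand-aware callers; the
false-positive rule's 0.1 fold-fraction is a declared convention, not a
fitted constant; mappability is consumed, never computed.
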