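"""Simulator ground truth: injection fidelity, round trips, determinism."""

import numpy as np
import pytest

from cleandeepseq.allele_counter import pileup_counts_batch
from cleandeepseq.dilution_model import DilutionMarker
from cleandeepseq.read_qc import BASES
from cleandeepseq.sim_reads import (
    ErrorModel,
    QualityModel,
    ReadBatch,
    ReferenceSeq,
    SpikeDesign,
    TruthTable,
    default_error_model,
    iter_simulated_batches,
    random_reference,
    read_alignments,
    simulate_fragments,
    write_alignments,
)

_CODE = {b: i for i, b in enumerate(BASES + "N")}


def _ref_codes(ref):
    return np.array([_CODE[b] for b in ref.seq], dtype=np.uint8)


class TestZeroErrorIdentity:
    def test_reads_equal_reference_and_registry_empty(self):
        ref = random_reference(300, seed=8)
        batch, truth = simulate_fragments(
            ref, ErrorModel(), SpikeDesign(depth=200, seed=1)
        )
        assert truth.errors.empty
        codes = _ref_codes(ref)
        for fi in range(0, len(batch), 17):
            for mi in (0, 1):
                p0 = batch.pos[fi, mi] - 1
                assert np.array_equal(batch.seq[fi, mi], codes[p0: p0 + 101])

    def test_downstream_rates_exactly_zero(self):
        ref = random_reference(300, seed=12)
        batch, _ = simulate_fragments(ref, ErrorModel(), SpikeDesign(depth=300, seed=2))
        counts = pileup_counts_batch(batch, ("amp1", 1, 250), ref.as_mapping())
        ref_idx = _ref_codes(ref)[:250]
        nonref = counts.sum(axis=1) - counts[np.arange(250), ref_idx]
        assert (nonref == 0).all()


class TestMarkerSpikeIn:
    def test_marker_mafs_within_binomial_noise(self):
        """Spiked markers with a in {1,2,4} at d=1000 come out at a/(2d)."""
        ref = random_reference(300, seed=21)
        markers = []
        for pos, a in ((40, 1), (60, 2), (80, 4)):
            r = ref.seq[pos - 1]
            alt = "A" if r != "A" else "C"
            markers.append(DilutionMarker("amp1", pos, r, alt, a=a, c=4))
        design = SpikeDesign(
            markers=tuple(markers), dilution_factor=1000, depth=150_000, seed=5
        )
        batch, truth = simulate_fragments(ref, ErrorModel(), design)
        counts = pileup_counts_batch(batch, ("amp1", 30, 90), ref.as_mapping())
        for m in markers:
            row = counts[m.pos - 30]
            depth = row.sum()
            maf = row[_CODE[m.alt]] / depth
            p = m.a / 2000
            assert abs(maf - p) < 3 * np.sqrt(p * (1 - p) / depth)
            ids = truth.mutant_fragment_ids[m.pos]
            assert len(ids) == int(
                truth.marker_truth.set_index("pos").loc[m.pos, "n_mutant"]
            )

    def test_marker_outside_reference_rejected(self):
        ref = random_reference(300, seed=1)
        bad = DilutionMarker("amp1", 999, "A", "C", a=1, c=2)
        with pytest.raises(ValueError, match="outside"):
            simulate_fragments(ref, ErrorModel(), SpikeDesign(markers=(bad,)))

    def test_marker_ref_mismatch_rejected(self):
        ref = ReferenceSeq("amp1", "A" * 300)
        bad = DilutionMarker("amp1", 50, "G", "T", a=1, c=2)
        with pytest.raises(ValueError, match="does not match"):
            simulate_fragments(ref, ErrorModel(), SpikeDesign(markers=(bad,)))


class TestErrorInjection:
    def test_context_multiplier_scales_rate(self):
        # C>T at 2e-3 with a 5x G_G context multiplier: the GCG site runs at 1e-2
        seq = "ATTA" * 10 + "GCG" + "ATTA" * 10 + "TCA" + "ATTA" * 25
        ref = ReferenceSeq("amp1", seq)
        gcg_pos = 42  # 1-based position of the C in GCG
        tca_pos = 85  # C with T/A flanks: base rate applies
        assert ref.seq[gcg_pos - 1] == "C" and ref.seq[tca_pos - 1] == "C"
        model = ErrorModel(
            base_rate_by_type={"C>T": 2e-3},
            context_multiplier={("C>T", "G", "G"): 5.0},
            mode="per_fragment",
        )
        design = SpikeDesign(depth=30_000, seed=4, fragment_length_range=(130, 143))
        batch, _ = simulate_fragments(ref, model, design)
        counts = pileup_counts_batch(batch, ("amp1", 40, 90), ref.as_mapping())
        for pos, rate in ((gcg_pos, 1e-2), (tca_pos, 2e-3)):
            row = counts[pos - 40]
            depth = row.sum()
            got = row[_CODE["T"]] / depth
            assert abs(got - rate) < 3 * np.sqrt(rate * (1 - rate) / depth)

    def test_damage_factor_doubles_c_to_a_only(self):
        ref = random_reference(300, seed=33)
        base = {"C>A": 2e-3, "A>T": 2e-3}
        region = ("amp1", 20, 120)
        rates = {}
        for damage in (1.0, 2.0):
            model = ErrorModel(
                base_rate_by_type=base, sample_damage_factor=damage, mode="per_fragment"
            )
            batch, _ = simulate_fragments(
                ref, model, SpikeDesign(depth=30_000, seed=13)
            )
            counts = pileup_counts_batch(batch, region, ref.as_mapping())
            codes = _ref_codes(ref)[19:120]
            for sub, gi, mi_ in (("C>A", 1, 0), ("A>T", 0, 3)):
                at = codes == gi
                n = counts[at].sum()
                errs = counts[at, mi_].sum()
                rates[(sub, damage)] = (errs / n, n)
        for sub, factor in (("C>A", 2.0), ("A>T", 1.0)):
            expected = 2e-3 * factor
            got, n = rates[(sub, 2.0)]
            assert abs(got - expected) < 3 * np.sqrt(expected / n)
            got1, n1 = rates[(sub, 1.0)]
            assert abs(got1 - 2e-3) < 3 * np.sqrt(2e-3 / n1)

    def test_per_fragment_errors_shared_by_mates(self):
        ref = random_reference(300, seed=40)
        model = ErrorModel(base_rate_by_type={"A>G": 0.02}, mode="per_fragment")
        batch, truth = simulate_fragments(ref, model, SpikeDesign(depth=300, seed=6))
        # wherever both mates cover an error position, both report it
        by_key = truth.errors.groupby(["fragment_id", "pos"])
        n_double = 0
        for (fid, pos), grp in by_key:
            fi = fid - batch.frag_id_start
            j0, j1 = pos - batch.pos[fi, 0], pos - batch.pos[fi, 1]
            if 0 <= j0 < 101 and 0 <= j1 < 101:
                assert set(grp["mate"]) == {0, 1}
                assert batch.seq[fi, 0, j0] == batch.seq[fi, 1, j1]
                n_double += 1
        assert n_double > 10  # overlap zone is wide; plenty of shared errors

    def test_per_mate_errors_independent(self):
        ref = random_reference(300, seed=41)
        model = ErrorModel(base_rate_by_type={"A>G": 0.02}, mode="per_mate")
        batch, truth = simulate_fragments(ref, model, SpikeDesign(depth=300, seed=7))
        both = truth.errors.groupby(["fragment_id", "pos"])["mate"].nunique()
        # coincident same-site errors on both mates are rare at 2% per base
        assert (both == 2).mean() < 0.15
        # registry rows match the emitted batch content
        for _, row in truth.errors.head(50).iterrows():
            fi = int(row["fragment_id"]) - batch.frag_id_start
            mi = int(row["mate"])
            j = int(row["pos"]) - batch.pos[fi, mi]
            assert BASES[batch.seq[fi, mi, j]] == row["emitted_base"]
            assert row["true_base"] != row["emitted_base"]

    def test_excessive_rate_rejected(self):
        ref = random_reference(300, seed=2)
        model = ErrorModel(base_rate_by_type={"A>C": 0.3, "A>G": 0.3})
        with pytest.raises(ValueError, match="0.5"):
            simulate_fragments(ref, model, SpikeDesign(depth=10))

    def test_lq_multiplier_counts_toward_rate_cap(self):
        ref = random_reference(300, seed=2)
        model = ErrorModel(
            base_rate_by_type={"A>C": 0.1}, lowq_read_frac=0.2, lowq_read_error_mult=10
        )
        with pytest.raises(ValueError, match="0.5"):
            simulate_fragments(ref, model, SpikeDesign(depth=10))


class TestModelValidation:
    def test_unknown_type_rejected(self):
        with pytest.raises(ValueError, match="unknown substitution"):
            ErrorModel(base_rate_by_type={"A>A": 0.1})

    def test_bad_mode_rejected(self):
        with pytest.raises(ValueError, match="injection mode"):
            ErrorModel(mode="sideways")

    def test_fragment_shorter_than_read_rejected(self):
        with pytest.raises(ValueError, match="fragment length"):
            SpikeDesign(fragment_length_range=(80, 170))

    def test_default_model_magnitudes(self):
        model = default_error_model()
        assert model.type_rate("C>T") == pytest.approx(1e-4)
        assert model.type_rate("A>C") == pytest.approx(1e-5)
        assert model.context_multiplier[("C>T", "G", "G")] == 5.0
        assert model.context_multiplier[("G>A", "C", "C")] == 5.0


class TestAlignmentRoundTrip:
    def test_empty_collection(self, tmp_path):
        path = tmp_path / "empty.sam"
        write_alignments([], path, {"amp1": 400})
        assert path.read_text().startswith("@HD")
        assert read_alignments(path) == []

    def test_single_fragment_pairing_preserved(self, tmp_path):
        ref = random_reference(300, seed=3)
        batch, _ = simulate_fragments(ref, ErrorModel(), SpikeDesign(depth=1, seed=4))
        path = tmp_path / "pair.sam"
        write_alignments(batch, path, {"amp1": 300})
        back = read_alignments(path)
        assert len(back) == 2
        assert back[0].qname == back[1].qname == "frag0"
        assert {r.is_reverse for r in back} == {False, True}
        assert back[0].mate_pos == back[1].pos

    def test_round_trip_identity_on_all_fields(self, tmp_path):
        ref = random_reference(300, seed=9)
        model = ErrorModel(
            base_rate_by_type={"A>G": 0.01},
            low_mapq_frac=0.1, missing_mapq_frac=0.05, indel_cigar_frac=0.1,
            lowq_read_frac=0.2,
        )
        batch, _ = simulate_fragments(ref, model, SpikeDesign(depth=60, seed=10))
        path = tmp_path / "rt.sam"
        write_alignments(batch, path, {"amp1": 300})
        back = read_alignments(path)
        original = sorted(
            batch.to_records(), key=lambda r: (r.pos, r.qname, r.is_reverse)
        )
        back = sorted(back, key=lambda r: (r.pos, r.qname, r.is_reverse))
        assert len(back) == len(original) == 120
        for a, b in zip(original, back):
            assert (a.qname, a.chrom, a.pos, a.mapq, a.cigar, a.seq, a.is_reverse) == (
                b.qname, b.chrom, b.pos, b.mapq, b.cigar, b.seq, b.is_reverse
            )
            assert np.array_equal(a.qual, b.qual)

    def test_byte_stable_under_fixed_seed(self, tmp_path):
        ref = random_reference(300, seed=14)
        model = default_error_model()
        outputs = []
        for run in (0, 1):
            batch, _ = simulate_fragments(ref, model, SpikeDesign(depth=500, seed=77))
            path = tmp_path / f"run{run}.sam"
            write_alignments(batch, path, {"amp1": 300})
            outputs.append(path.read_bytes())
        assert outputs[0] == outputs[1]

    def test_unknown_chrom_rejected(self, tmp_path):
        from conftest import make_read

        with pytest.raises(ValueError, match="chrom"):
            write_alignments(
                [make_read(chrom="chrX")], tmp_path / "x.sam", {"amp1": 400}
            )


class TestStreaming:
    def test_chunked_truth_totals_match(self):
        ref = random_reference(300, seed=30)
        m = DilutionMarker("amp1", 60, ref.seq[59], "A" if ref.seq[59] != "A" else "C", a=2, c=4)
        model = ErrorModel(base_rate_by_type={"C>T": 1e-3})
        design = SpikeDesign(markers=(m,), dilution_factor=100, depth=5000, seed=11)
        whole_batch, whole_truth = simulate_fragments(ref, model, design)
        chunks = list(iter_simulated_batches(ref, model, design, chunk_fragments=999))
        assert sum(len(b) for b, _ in chunks) == 5000
        merged = TruthTable.concat([t for _, t in chunks])
        assert merged.n_fragments == whole_truth.n_fragments == 5000
        # same generator stream, different chunking: totals agree statistically
        assert merged.marker_truth["n_covering"].sum() > 0
        rebuilt = ReadBatch.concat([b for b, _ in chunks])
        assert len(rebuilt) == len(whole_batch)
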