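"""Error-rate records, context stratification, summaries, comparisons."""

import numpy as np
import pandas as pd
import pytest

from cleandeepseq.error_profile import (
    ErrorProfile,
    SummarySpec,
    attach_context,
    compare_profiles,
    damage_correlation,
    nearest_rank,
    profile_heatmap_matrix,
    sample_error_rate,
    site_error_rates,
    substitution_type,
    summarize_profile,
)
from cleandeepseq.read_qc import SUBSTITUTION_TYPES


def counts_frame(rows):
    df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "A", "C", "G", "T"])
    df["depth"] = df[list("ACGT")].sum(axis=1)
    return df


class TestSiteErrorRates:
    def test_printed_formula_arithmetic(self):
        df = counts_frame([("amp1", 10, "A", 9990, 4, 3, 3)])
        rec = site_error_rates(df).set_index("type")
        assert rec.loc["A>C", "rate"] == pytest.approx(4e-4)
        assert rec.loc["A>G", "rate"] == pytest.approx(3e-4)
        assert rec.loc["A>T", "rate"] == pytest.approx(3e-4)
        # three error rates + reference fraction sum to 1 exactly
        assert rec["rate"].sum() + 9990 / 10000 == pytest.approx(1.0)

    def test_all_reference_site(self):
        rec = site_error_rates(counts_frame([("amp1", 1, "C", 0, 1000, 0, 0)]))
        assert len(rec) == 3
        assert (rec["rate"] == 0).all()

    def test_zero_depth_and_n_ref_yield_nothing(self):
        df = counts_frame([("amp1", 1, "A", 0, 0, 0, 0), ("amp1", 2, "N", 5, 5, 0, 0)])
        assert site_error_rates(df).empty

    def test_rate_recovery_binomial(self, rng):
        # C>T at 1e-4, depth 1e7: estimate within 3 binomial SDs
        depth = 10**7
        n_err = rng.binomial(depth, 1e-4)
        df = counts_frame([("amp1", 5, "C", 0, depth - n_err, 0, n_err)])
        rec = site_error_rates(df).set_index("type")
        se = np.sqrt(1e-4 * (1 - 1e-4) / depth)
        assert abs(rec.loc["C>T", "rate"] - 1e-4) < 3 * se

    def test_substitution_type_validation(self):
        assert substitution_type("C", "T") == "C>T"
        with pytest.raises(ValueError):
            substitution_type("C", "C")


class TestAttachContext:
    REF = {"amp1": "TGCGA"}

    def test_flanks_from_reference(self):
        df = counts_frame([("amp1", 3, "C", 0, 995, 0, 5)])
        rec = attach_context(site_error_rates(df), self.REF)
        assert (rec["context5"] == "G").all() and (rec["context3"] == "G").all()
        assert rec["context_ok"].all()

    def test_contig_edges_excluded(self):
        df = counts_frame(
            [("amp1", 1, "T", 0, 0, 5, 995), ("amp1", 5, "A", 995, 0, 5, 0)]
        )
        rec = attach_context(site_error_rates(df), self.REF)
        assert not rec["context_ok"].any()  # both ends lack a flank
        assert len(rec) == 6  # retained unstratified

    def test_non_dominant_flank_excluded(self):
        counts = counts_frame(
            [
                ("amp1", 2, "G", 0, 0, 800, 200),  # 80% dominant flank
                ("amp1", 3, "C", 0, 995, 0, 5),
                ("amp1", 4, "G", 0, 0, 1000, 0),
            ]
        )
        target = counts.iloc[[1]]
        rec = attach_context(site_error_rates(target), self.REF, counts=counts)
        assert not rec["context_ok"].any()
        rec_ok = attach_context(
            site_error_rates(target), self.REF,
            counts=counts_frame(
                [("amp1", 2, "G", 0, 0, 1000, 0), ("amp1", 3, "C", 0, 995, 0, 5),
                 ("amp1", 4, "G", 0, 0, 1000, 0)]
            ),
        )
        assert rec_ok["context_ok"].all()


class TestSummaries:
    def test_median_of_mostly_zero_rates(self):
        rates = [0.0] * 99 + [1e-3]
        df = pd.DataFrame({"type": "A>C", "rate": rates})
        prof = summarize_profile(df, SummarySpec("median"))
        assert prof.lookup("A>C") == 0.0

    def test_nearest_rank_forced_by_definition(self):
        values = np.arange(1, 101) / 1000.0
        assert nearest_rank(values, 0.99) == pytest.approx(0.099)  # 99th smallest
        assert nearest_rank(values, 0.5) == pytest.approx(0.050)

    def test_nearest_rank_matches_numpy_inverted_cdf(self, rng):
        for _ in range(50):
            n = int(rng.integers(1, 200))
            vals = rng.random(n)
            q = float(rng.choice([0.5, 0.9, 0.99, 0.999]))
            want = np.percentile(vals, q * 100, method="inverted_cdf")
            assert nearest_rank(vals, q) == pytest.approx(float(want))

    def test_min_sites_floor_makes_group_unavailable(self):
        df = pd.DataFrame({"type": "C>T", "rate": np.zeros(10_000)})
        prof = summarize_profile(df, SummarySpec("p999"))
        assert not prof.table.loc["C>T", "available"]
        assert np.isnan(prof.lookup("C>T"))
        prof99 = summarize_profile(df, SummarySpec("p99"))
        assert prof99.table.loc["C>T", "available"]

    def test_empty_group_unavailable(self):
        df = pd.DataFrame({"type": [], "rate": []})
        prof = summarize_profile(df, SummarySpec("median"))
        assert not prof.table["available"].any()
        assert set(prof.table.index) == set(SUBSTITUTION_TYPES)

    def test_order_invariance(self, rng):
        rates = rng.random(500)
        types = rng.choice(SUBSTITUTION_TYPES, size=500)
        df = pd.DataFrame({"type": types, "rate": rates})
        shuffled = df.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = summarize_profile(df, SummarySpec("p99", min_sites_per_type=1))
        b = summarize_profile(shuffled, SummarySpec("p99", min_sites_per_type=1))
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_profile_round_trip(self, tmp_path):
        df = pd.DataFrame({"type": ["A>C"] * 5, "rate": [0.1, 0.2, 0.3, 0.4, 0.5]})
        prof = summarize_profile(df, SummarySpec("median"), sample_id="s1")
        path = tmp_path / "prof.tsv"
        prof.write(path)
        back = ErrorProfile.read(path)
        assert back.sample_id == "s1" and back.statistic == "median"
        pd.testing.assert_frame_equal(
            back.table.astype({"available": bool}), prof.table
        )


class TestSampleErrorRate:
    def test_direct_arithmetic(self):
        df = counts_frame([("amp1", 1, "A", 10**6 - 100, 40, 30, 30)])
        assert sample_error_rate(df) == pytest.approx(1e-4)

    def test_zero_error(self):
        df = counts_frame([("amp1", i, "A", 1000, 0, 0, 0) for i in range(1, 11)])
        assert sample_error_rate(df) == 0.0

    def test_eligibility_gates(self):
        df = counts_frame(
            [
                ("amp1", 1, "A", 49, 0, 0, 0),  # below 50X: out
                ("amp1", 2, "A", 60, 40, 0, 0),  # ref fraction 60%: out
                ("amp1", 3, "C", 0, 100, 0, 0),
            ]
        )
        assert sample_error_rate(df) == 0.0  # only pos 3 counted
        none_eligible = counts_frame([("amp1", 1, "A", 10, 0, 0, 0)])
        assert sample_error_rate(none_eligible) is None

    def test_recovery_of_uniform_error(self, rng):
        depth, rate, n_sites = 100, 1e-4, 10**5
        errs = rng.binomial(depth, rate, size=n_sites)
        df = counts_frame(
            [("amp1", i + 1, "A", depth - e, e, 0, 0) for i, e in enumerate(errs)]
        )
        got = sample_error_rate(df)
        se = np.sqrt(rate / (depth * n_sites))
        assert abs(got - rate) < 3 * se


def _profile_from_values(values, statistic="p99", sample_id="s"):
    table = pd.DataFrame(
        {
            "value": pd.Series(values, index=pd.Index(SUBSTITUTION_TYPES, name="type")),
            "n_sites": 10**5,
        }
    )
    table["available"] = table["value"].notna()
    return ErrorProfile(sample_id=sample_id, statistic=statistic, table=table)


class TestCompareProfiles:
    def test_identical_profiles(self, rng):
        vals = rng.random(12) * 1e-3
        cmp = compare_profiles(_profile_from_values(vals), _profile_from_values(vals))
        assert cmp.slope == pytest.approx(1.0)
        assert cmp.r2 == pytest.approx(1.0)

    def test_exact_sixfold(self, rng):
        vals = rng.random(12) * 1e-4
        cmp = compare_profiles(
            _profile_from_values(vals * 6), _profile_from_values(vals)
        )
        assert cmp.slope == pytest.approx(6.0)
        assert cmp.r2 == pytest.approx(1.0)
        assert cmp.slope_with_intercept == pytest.approx(6.0)
        assert cmp.intercept == pytest.approx(0.0, abs=1e-12)

    def test_unavailable_types_excluded_min_pairs(self, rng):
        vals = rng.random(12) * 1e-4
        sparse = vals.copy()
        sparse[:7] = np.nan
        with pytest.raises(ValueError, match="minimum"):
            compare_profiles(_profile_from_values(sparse), _profile_from_values(vals))

    def test_statistic_mismatch_rejected(self, rng):
        vals = rng.random(12)
        with pytest.raises(ValueError, match="statistic"):
            compare_profiles(
                _profile_from_values(vals, "p99"), _profile_from_values(vals, "p999")
            )


class TestHeatmapMatrix:
    def _context_profile(self, value_fn, sample_id="s"):
        rows = []
        for t in SUBSTITUTION_TYPES:
            for f5 in "ACGT":
                for f3 in "ACGT":
                    rows.append(
                        {
                            "type": t, "context5": f5, "context3": f3,
                            "value": value_fn(t, f5, f3), "n_sites": 100,
                            "available": True,
                        }
                    )
        table = pd.DataFrame(rows).set_index(["type", "context5", "context3"])
        return ErrorProfile(sample_id, "median", table, by_context=True)

    def test_constant_matrix_and_ordering(self):
        prof = self._context_profile(lambda *a: 1e-4)
        mat = profile_heatmap_matrix({"s1": prof})
        assert mat.shape == (192, 1)
        assert (mat["s1"] == 1e-4).all()
        # panels ordered by reference base C, G, A, T
        ref_order = [t[0] for t, _, _ in mat.index]
        first_c = ref_order.index("C")
        first_t = len(ref_order) - 1 - ref_order[::-1].index("T")
        assert first_c == 0 and first_t == 191

    def test_sample_specific_damage_is_column_confined(self):
        base = self._context_profile(lambda *a: 1e-5, "clean")
        damaged = self._context_profile(
            lambda t, f5, f3: 1e-3 if t in ("C>A", "G>T") else 1e-5, "damaged"
        )
        mat = profile_heatmap_matrix({"clean": base, "damaged": damaged})
        ca_rows = mat.index.get_level_values("type").isin(["C>A", "G>T"])
        assert (mat.loc[ca_rows, "damaged"] == 1e-3).all()
        assert (mat.loc[ca_rows, "clean"] == 1e-5).all()
        assert (mat.loc[~ca_rows, "damaged"] == 1e-5).all()

    def test_context_dependent_type_is_row_wide(self):
        f = lambda t, f5, f3: 5e-4 if (t == "C>T" and "G" in (f5, f3)) else 1e-5
        mat = profile_heatmap_matrix(
            {"s1": self._context_profile(f, "s1"), "s2": self._context_profile(f, "s2")}
        )
        hot = [
            (t == "C>T" and "G" in (f5, f3)) for t, f5, f3 in mat.index
        ]
        assert (mat.loc[hot] == 5e-4).all().all()  # across all samples


class TestDamageCorrelation:
    def test_recovers_coupled_slope(self, rng):
        n = 30
        ca = rng.uniform(1e-5, 1e-3, size=n)
        cg = 0.5 * ca + rng.normal(0, 1e-6, size=n)
        at = rng.uniform(1e-5, 2e-5, size=n)  # independent type
        df = pd.DataFrame({"C>A": ca, "C>G": cg, "A>T": at})
        fits = damage_correlation(df)
        assert fits.loc["C>G", "slope"] == pytest.approx(0.5, abs=0.05)
        assert fits.loc["C>G", "r2"] > 0.95
        assert fits.loc["A>T", "r2"] < 0.2

    def test_too_few_samples(self):
        df = pd.DataFrame({"C>A": [1e-4, 2e-4], "C>G": [1e-5, 2e-5]})
        with pytest.raises(ValueError, match="3 samples"):
            damage_correlation(df)

    def test_constant_predictor_unavailable(self):
        df = pd.DataFrame({"C>A": [1e-4] * 5, "C>G": np.linspace(1e-5, 5e-5, 5)})
        fits = damage_correlation(df)
        assert np.isnan(fits.loc["C>G", "slope"])
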