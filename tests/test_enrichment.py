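import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metacomp.annotations import CategoryMap, SampleTable
from metacomp.enrichment import (
    EnrichmentConfig,
    FunctionalEnrichment,
    compare_categories,
    d_rank_table,
    d_score,
    d_score_table,
)
from metacomp.profiling import FunctionCountMatrix, build_count_matrix
from metacomp.simulate import SyntheticConfig, simulate_table


def reference_two_proportion_z(x1, n1, x2, n2):
    """Independent hand-coded pooled two-proportion z-statistic."""
    f1, f2 = x1 / n1, x2 / n2
    p = (x1 + x2) / (n1 + n2)
    q = 1.0 - p
    var = p * q * (1.0 / n1 + 1.0 / n2)
    if var == 0.0:
        return 0.0
    return (f1 - f2) / math.sqrt(var)


def make_matrix(counts: dict, totals: dict) -> FunctionCountMatrix:
    frame = pd.DataFrame(counts).T.fillna(0).astype(int)
    return FunctionCountMatrix(
        counts=frame, sample_totals=pd.Series(totals), namespace="COG"
    )


class TestDScore:
    def test_equal_frequencies_give_zero(self):
        assert d_score(10, 500, 10, 500).d == 0.0

    def test_hand_computed_example(self):
        # f1=0.03, f2=0.01, p=0.02, q=0.98, se=sqrt(0.02*0.98*2/1000)=0.0062610
        e = d_score(30, 1000, 10, 1000)
        assert e.d == pytest.approx(0.02 / math.sqrt(0.02 * 0.98 * 0.002), abs=1e-12)
        assert e.d == pytest.approx(3.1944, abs=1e-4)
        assert e.p_value < 0.05 and e.significant

    def test_degenerate_pooled_probability_returns_zero(self):
        assert d_score(0, 100, 0, 200).d == 0.0          # p = 0
        assert d_score(100, 100, 200, 200).d == 0.0      # p = 1
        assert d_score(0, 100, 0, 200).p_value == 1.0

    def test_intermediate_quantities_are_exact(self):
        e = d_score(30, 1000, 10, 1000)
        assert (e.f1, e.f2) == (0.03, 0.01)
        assert e.p == 0.02 and e.q == 1.0 - e.p

    @pytest.mark.parametrize("args", [(5, 0, 1, 10), (1, 10, 5, 0), (11, 10, 0, 10),
                                      (-1, 10, 0, 10)])
    def test_invalid_inputs_rejected(self, args):
        with pytest.raises(ValueError):
            d_score(*args)

    def test_matches_independent_oracles_on_random_tuples(self):
        """1,000 random count tuples vs a hand-coded z and statsmodels."""
        from statsmodels.stats.proportion import proportions_ztest

        rng = np.random.default_rng(42)
        for _ in range(1000):
            n1, n2 = rng.integers(10, 5000, size=2)
            x1 = int(rng.integers(0, n1 + 1))
            x2 = int(rng.integers(0, n2 + 1))
            d = d_score(x1, n1, x2, n2).d
            assert d == pytest.approx(reference_two_proportion_z(x1, n1, x2, n2),
                                      abs=1e-12)
            if 0 < x1 + x2 < n1 + n2:
                z, _ = proportions_ztest([x1, x2], [n1, n2])
                assert d == pytest.approx(float(z), abs=1e-9)

    @settings(max_examples=200, derandomize=True)
    @given(st.integers(1, 2000), st.integers(1, 2000),
           st.integers(0, 2000), st.integers(0, 2000))
    def test_antisymmetry(self, n1, n2, x1, x2):
        x1, x2 = min(x1, n1), min(x2, n2)
        assert d_score(x1, n1, x2, n2).d == -d_score(x2, n2, x1, n1).d

    @settings(max_examples=200, derandomize=True)
    @given(st.integers(1, 2000), st.integers(1, 2000),
           st.integers(0, 2000), st.integers(0, 2000))
    def test_sign_follows_frequency_difference(self, n1, n2, x1, x2):
        x1, x2 = min(x1, n1), min(x2, n2)
        e = d_score(x1, n1, x2, n2)
        assert np.sign(e.d) == np.sign(e.f1 - e.f2)


class TestDScoreTable:
    def test_family_only_in_query_is_positive(self):
        m = make_matrix({"COG0001": {"Q": 5, "R": 0}, "COG0002": {"Q": 5, "R": 10}},
                        {"Q": 10, "R": 10})
        entries = d_score_table(m, "Q", "R")
        by_fam = {e.family_id: e for e in entries}
        assert by_fam["COG0001"].d > 0

    def test_equal_frequency_matrix_is_all_zero(self):
        m = make_matrix({"COG0001": {"Q": 5, "R": 5}, "COG0002": {"Q": 7, "R": 7}},
                        {"Q": 12, "R": 12})
        assert all(e.d == 0.0 for e in d_score_table(m, "Q", "R"))

    def test_query_equal_reference_rejected(self):
        m = make_matrix({"COG0001": {"Q": 5, "R": 5}}, {"Q": 5, "R": 5})
        with pytest.raises(ValueError):
            d_score_table(m, "Q", "Q")

    def test_order_is_abs_d_descending_then_lexicographic(self):
        m = make_matrix(
            {"COG0003": {"Q": 0, "R": 20}, "COG0001": {"Q": 20, "R": 0},
             "COG0002": {"Q": 30, "R": 30}},
            {"Q": 50, "R": 50})
        fams = [e.family_id for e in d_score_table(m, "Q", "R")]
        assert fams == ["COG0001", "COG0003", "COG0002"]  # tie broken by name

    def test_bh_adjustment_only_raises_p_values(self):
        cfg = SyntheticConfig.null_two_sample(n_families=50, n_occurrences=2000, seed=8)
        m = build_count_matrix(simulate_table(cfg), "COG")
        raw = FunctionalEnrichment(m, "Q", "R").fit().dscores
        bh = FunctionalEnrichment(
            m, "Q", "R", config=EnrichmentConfig(multiple_testing="BH")
        ).fit().dscores
        merged = raw.merge(bh, on="family_id", suffixes=("_raw", "_bh"))
        assert (merged["p_adjusted_bh"] >= merged["p_value_raw"] - 1e-15).all()
        assert bh["significant"].sum() <= raw["significant"].sum()

    def test_null_type_one_error_near_alpha(self):
        """~5% of families cross P<0.05 under a 200-family multinomial null."""
        rng = np.random.default_rng(12)
        hits = trials = 0
        for rep in range(100):
            cfg = SyntheticConfig.null_two_sample(
                n_families=200, n_occurrences=10000, seed=int(rng.integers(2**31)))
            m = build_count_matrix(simulate_table(cfg), "COG")
            ds = FunctionalEnrichment(m, "Q", "R").fit().dscores
            hits += int(ds["significant"].sum())
            trials += len(ds)
        rate = hits / trials
        assert rate == pytest.approx(0.05, abs=0.01)


class TestDRank:
    @staticmethod
    def entries_with_scores(scores: dict[str, float]):
        from metacomp.enrichment import DScoreEntry

        return [
            DScoreEntry(family_id=f, x1=1, x2=1, n1=100, n2=100,
                        f1=0.01, f2=0.01, p=0.01, q=0.99,
                        d=d, p_value=1.0, significant=False)
            for f, d in scores.items()
        ]

    @staticmethod
    def k25_map(member_families):
        entries = {f: "A" for f in member_families}
        for i in range(24):  # pad to K = 25 with singleton categories
            entries[f"PAD{i:02d}"] = f"X{i:02d}"
        return CategoryMap(entries)

    def test_arithmetic_example(self):
        """Member scores {1.0, 2.0, -0.5} with K=25 aggregate to 2.5/5 = 0.5."""
        scores = {"F1": 1.0, "F2": 2.0, "F3": -0.5}
        cmap = self.k25_map(scores)
        ranks = {e.category_id: e for e in
                 d_rank_table(self.entries_with_scores(scores), cmap)}
        entry = ranks["A"]
        assert entry.d_rank == 0.5
        assert entry.sum_d == 2.5 and entry.K == 25
        assert entry.d_rank * math.sqrt(entry.K) == entry.sum_d

    def test_drank_from_model_matches_manual_sum(self, toy_cmap):
        m = make_matrix(
            {"COG0039": {"Q": 30, "R": 10}, "COG0538": {"Q": 5, "R": 20},
             "COG1131": {"Q": 15, "R": 15}},
            {"Q": 1000, "R": 1000})
        res = FunctionalEnrichment(m, "Q", "R", category_map=toy_cmap).fit()
        ds = res.dscores.set_index("family_id")["d"]
        dr = res.dranks.set_index("category_id")
        K = toy_cmap.K
        assert dr.loc["C", "d_rank"] == pytest.approx(
            (ds["COG0039"] + ds["COG0538"]) / math.sqrt(K), abs=1e-12)
        assert dr.loc["V", "d_rank"] == pytest.approx(ds["COG1131"] / math.sqrt(K),
                                                      abs=1e-12)
        # invariant: d_rank * sqrt(K) == sum_d
        assert (dr["d_rank"] * math.sqrt(K)).values == pytest.approx(
            dr["sum_d"].values, abs=1e-12)

    def test_quadrupling_K_halves_every_drank(self):
        cfg = SyntheticConfig.null_two_sample(n_families=80, n_occurrences=4000,
                                              n_categories=10, seed=13)
        m = build_count_matrix(simulate_table(cfg), "COG")
        small = cfg.categories
        big_entries = dict(small.entries)
        # 30 extra singleton categories -> K goes 10 -> 40
        for i in range(30):
            big_entries[f"PAD{i:02d}"] = f"X{i:02d}"
        big = CategoryMap(big_entries)
        r_small = FunctionalEnrichment(m, "Q", "R", category_map=small).fit().dranks
        r_big = FunctionalEnrichment(m, "Q", "R", category_map=big).fit().dranks
        a = r_small.set_index("category_id")["d_rank"]
        b = r_big.set_index("category_id")["d_rank"]
        shared = a.index.intersection(b.index)
        assert len(shared) == 10
        assert b[shared].values == pytest.approx((a[shared] / 2.0).values, abs=1e-12)

    def test_all_zero_scores_nothing_significant(self, toy_cmap):
        m = make_matrix(
            {"COG0039": {"Q": 5, "R": 5}, "COG1131": {"Q": 3, "R": 3}},
            {"Q": 10, "R": 10})
        res = FunctionalEnrichment(m, "Q", "R", category_map=toy_cmap).fit()
        assert (res.dranks["d_rank"] == 0).all()
        assert not res.dranks["enriched"].any()
        assert not res.dranks["under_represented"].any()

    def test_unmapped_families_fall_into_uncategorized_bucket(self, toy_cmap):
        m = make_matrix(
            {"COG0039": {"Q": 5, "R": 9}, "COG9999": {"Q": 9, "R": 2}},
            {"Q": 14, "R": 11})
        res = FunctionalEnrichment(m, "Q", "R", category_map=toy_cmap).fit()
        dr = res.dranks.set_index("category_id")
        assert "uncategorized" in dr.index
        assert dr.loc["uncategorized", "member_families"] == ("COG9999",)
        # K counts only mapped categories
        assert (dr["K"] == toy_cmap.K).all()

    def test_empty_entry_list_rejected(self, toy_cmap):
        with pytest.raises(ValueError):
            d_rank_table([], toy_cmap)

    def test_wrapper_agrees_with_model(self, toy_cmap):
        m = make_matrix(
            {"COG0039": {"Q": 30, "R": 10}, "COG1131": {"Q": 5, "R": 20}},
            {"Q": 500, "R": 500})
        entries = d_score_table(m, "Q", "R")
        via_wrapper = {e.category_id: e.d_rank for e in d_rank_table(entries, toy_cmap)}
        via_model = FunctionalEnrichment(
            m, "Q", "R", category_map=toy_cmap).fit().dranks
        for r in via_model.itertuples(index=False):
            assert via_wrapper[r.category_id] == pytest.approx(r.d_rank, abs=1e-12)

    def test_permutation_threshold_close_to_normal_on_simulated_null(self):
        """On a 25-category 2,000-family null the empirical permutation
        threshold and the z*sqrt(m_c/K) normal approximation agree."""
        cfg = SyntheticConfig.null_two_sample(
            n_families=2000, n_occurrences=10000, uniform=False, seed=17)
        m = build_count_matrix(simulate_table(cfg), "COG")
        perm = FunctionalEnrichment(
            m, "Q", "R", category_map=cfg.categories,
            config=EnrichmentConfig(null_mode="permutation",
                                    n_permutations=4000, seed=5),
        ).fit().dranks.set_index("category_id")["threshold"]
        norm = FunctionalEnrichment(
            m, "Q", "R", category_map=cfg.categories,
        ).fit().dranks.set_index("category_id")["threshold"]
        ratio = (perm / norm).to_numpy()
        assert (np.abs(ratio - 1.0) < 0.10).all()

    def test_permutation_threshold_is_seed_deterministic(self, toy_cmap):
        m = make_matrix(
            {"COG0039": {"Q": 30, "R": 10}, "COG1131": {"Q": 50, "R": 60}},
            {"Q": 500, "R": 500})
        cfg = EnrichmentConfig(null_mode="permutation", n_permutations=500, seed=99)
        a = FunctionalEnrichment(m, "Q", "R", category_map=toy_cmap, config=cfg).fit()
        b = FunctionalEnrichment(m, "Q", "R", category_map=toy_cmap, config=cfg).fit()
        assert a.dranks.equals(b.dranks)


class TestCompareCategories:
    @pytest.fixture
    def three_sample_table(self):
        cfg = SyntheticConfig.null_two_sample(n_families=60, n_occurrences=3000, seed=23)
        frames = []
        for label, seed in (("GH", 1), ("CW", 2), ("TM", 3)):
            sub = SyntheticConfig.null_two_sample(
                n_families=60, n_occurrences=3000, seed=seed)
            t = simulate_table(sub)
            f = t.frame[t.frame["sample_id"] == "Q"].copy()
            f["sample_id"] = label
            frames.append(f)
        return SampleTable(pd.concat(frames, ignore_index=True)), cfg.categories

    def test_all_pairs_of_three_samples_is_three(self, three_sample_table):
        table, cmap = three_sample_table
        report = compare_categories(table, cmap)
        assert len(report.pairs) == 3
        assert set(report.results) == set(report.pairs)

    def test_swapping_a_pair_negates_dranks(self, three_sample_table):
        table, cmap = three_sample_table
        fwd = compare_categories(table, cmap, pairs=[("GH", "CW")])
        rev = compare_categories(table, cmap, pairs=[("CW", "GH")])
        a = fwd.wide["GH_vs_CW.d_rank"]
        b = rev.wide["CW_vs_GH.d_rank"]
        assert a.values == pytest.approx((-b[a.index]).values, abs=1e-12)

    def test_unknown_sample_rejected(self, three_sample_table):
        table, cmap = three_sample_table
        with pytest.raises(ValueError):
            compare_categories(table, cmap, pairs=[("GH", "nope")])

    def test_vs_reference_mode(self, three_sample_table):
        table, cmap = three_sample_table
        report = compare_categories(table, cmap, mode="vs_reference:TM")
        assert sorted(report.pairs) == [("CW", "TM"), ("GH", "TM")]
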