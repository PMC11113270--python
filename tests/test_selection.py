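"""ANOVA F ranking, Spearman screens, correlation ranges, gene sets, overlaps."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import breakclock as bc
from breakclock.selection import DEFAULT_GENE_SET_SIZES, f_scores_array


def _fm(df: pd.DataFrame) -> bc.FeatureMatrix:
    return bc.FeatureMatrix("TPM", "exon", df)


class TestAnovaFScores:
    def test_two_group_hand_case(self):
        # groups [1,2] and [3,4]: MSB=4, MSE=0.5, F=8 exactly
        X = np.array([[1.0], [2.0], [3.0], [4.0]])
        labels = np.array([0, 0, 1, 1])
        assert f_scores_array(X, labels)[0] == 8.0

    def test_constant_gene_is_zero(self):
        X = np.full((6, 1), 3.3)
        assert f_scores_array(X, np.array([0, 0, 1, 1, 2, 2]))[0] == 0.0

    def test_equal_group_means_zero_f(self):
        X = np.array([[1.0], [3.0], [1.0], [3.0]])
        assert f_scores_array(X, np.array([0, 0, 1, 1]))[0] == 0.0

    def test_perfect_separation_is_inf_and_outranks(self):
        df = pd.DataFrame(
            {
                "s1": [0.0, 5.0], "s2": [0.0, 6.0],
                "s3": [1.0, 50.0], "s4": [1.0, 49.0],
            },
            index=["sep", "strong"],
        )
        ranking = bc.anova_f_scores(_fm(df), ["a", "a", "b", "b"])
        assert np.isinf(ranking.table.loc["sep", "F"])
        assert ranking.table.loc["sep", "rank"] == 1

    def test_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 200))
        labels = np.repeat(np.arange(5), 6)
        ours = f_scores_array(X, labels)
        ref = np.array([stats.f_oneway(*(X[labels == g, j] for g in range(5))).statistic
                        for j in range(200)])
        np.testing.assert_allclose(ours, ref, rtol=1e-9)

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        X = rng.gamma(2, size=(20, 50))
        labels = np.repeat([0, 1, 2, 3], 5)
        np.testing.assert_allclose(
            f_scores_array(X, labels), f_scores_array(X * 37.5, labels), rtol=1e-12
        )

    def test_rank_is_permutation_with_gene_id_tiebreak(self):
        df = pd.DataFrame(
            np.array([[1.0, 2.0, 1.0, 2.0]] * 3), index=["z", "a", "m"],
            columns=["s1", "s2", "s3", "s4"],
        )
        ranking = bc.anova_f_scores(_fm(df), ["x", "y", "x", "y"])
        ranks = ranking.table["rank"]
        assert sorted(ranks) == [1, 2, 3]
        # all F equal -> ascending gene_id order
        assert list(ranking.table.sort_values("rank").index) == ["a", "m", "z"]

    def test_labels_treated_categorically(self):
        # swapping numeric label values does not change F (only grouping matters)
        rng = np.random.default_rng(2)
        X = rng.normal(size=(15, 20))
        lab1 = np.repeat([3, 12, 19], 5)
        lab2 = np.repeat([19, 3, 12], 5)
        np.testing.assert_allclose(f_scores_array(X, lab1), f_scores_array(X, lab2))


class TestAnovaFScoreSelector:
    def test_sklearn_contract_and_nesting(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 40))
        y = np.repeat(np.arange(5), 6)
        sel15 = bc.AnovaFScoreSelector(k=15).fit(X, y)
        sel25 = bc.AnovaFScoreSelector(k=25).fit(X, y)
        kept15 = set(np.flatnonzero(sel15.get_support()))
        kept25 = set(np.flatnonzero(sel25.get_support()))
        assert kept15 < kept25
        assert sel15.transform(X).shape == (30, 15)
        assert sorted(sel15.ranks_) == list(range(1, 41))

    def test_matches_function_api(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.normal(size=(25, 12)),
                          index=[f"g{i:02d}" for i in range(25)])
        y = np.repeat([0, 1, 2], 4)
        ranking = bc.anova_f_scores(df, y)
        sel = bc.AnovaFScoreSelector(k=5).fit(df.T.to_numpy(), y)
        np.testing.assert_allclose(ranking.table["F"].to_numpy(), sel.f_scores_)
        np.testing.assert_array_equal(ranking.table["rank"].to_numpy(), sel.ranks_)

    def test_pipeline_compatibility(self):
        from sklearn.linear_model import LogisticRegression
        from sklearn.pipeline import Pipeline

        rng = np.random.default_rng(5)
        X = rng.normal(size=(40, 30))
        y = np.repeat([0, 1], 20)
        X[:, 3] += y * 3  # informative feature
        pipe = Pipeline([("sel", bc.AnovaFScoreSelector(k=3)),
                         ("clf", LogisticRegression(max_iter=1000))])
        pipe.fit(X, y)
        assert pipe.score(X, y) > 0.8
        assert 3 in np.flatnonzero(pipe.named_steps["sel"].get_support())


class TestSpearmanScreen:
    @staticmethod
    def _meta(n_per_age=4, ages=(3, 12, 19, 22, 24)):
        rows = [(f"s{a}_{i}", float(a), "brain") for a in ages for i in range(n_per_age)]
        return pd.DataFrame(rows, columns=["sample_id", "age_months", "tissue"]).set_index("sample_id")

    def test_monotone_gene_has_rho_one(self):
        meta = self._meta()
        values = pd.DataFrame([np.arange(len(meta), dtype=float)], index=["mono"],
                              columns=meta.index)
        screen = bc.spearman_age_screen(_fm(values), meta)
        # ties in age ranks cap rho below 1 for a strictly increasing gene only
        # when ages repeat; against the sample order rho is driven by age ranks
        assert screen.table.loc["mono", "rho"] > 0.9
        assert screen.table.loc["mono", "sign"] == "positive"

    def test_constant_gene_sign_none(self):
        meta = self._meta()
        values = pd.DataFrame([np.ones(len(meta))], index=["flat"], columns=meta.index)
        screen = bc.spearman_age_screen(_fm(values), meta)
        assert screen.table.loc["flat", "sign"] == "none"
        assert screen.table.loc["flat", "p"] == 1.0
        assert screen.significant_fraction == 0.0

    def test_matches_scipy_per_gene(self):
        rng = np.random.default_rng(6)
        meta = self._meta()
        values = pd.DataFrame(rng.normal(size=(20, len(meta))),
                              index=[f"g{i}" for i in range(20)], columns=meta.index)
        screen = bc.spearman_age_screen(values, meta)
        age = meta["age_months"].to_numpy()
        for g in values.index:
            rho, p = stats.spearmanr(values.loc[g].to_numpy(), age)
            assert screen.table.loc[g, "rho"] == pytest.approx(rho, rel=1e-9)
            assert screen.table.loc[g, "p"] == pytest.approx(p, rel=1e-6)

    def test_requires_three_distinct_ages(self):
        meta = self._meta(ages=(3, 12))
        values = pd.DataFrame(np.ones((1, len(meta))), index=["g"], columns=meta.index)
        with pytest.raises(ValueError, match="3 distinct age"):
            bc.spearman_age_screen(_fm(values), meta)


class TestPerTissueRange:
    @staticmethod
    def _meta():
        rows = []
        for t in ("brain", "heart"):
            for a in (3, 12, 19, 22, 24):
                for r in range(2):
                    rows.append((f"{t}{a}_{r}", float(a), t))
        return pd.DataFrame(rows, columns=["sample_id", "age_months", "tissue"]).set_index("sample_id")

    def test_identical_per_tissue_rho_gives_zero_range(self):
        meta = self._meta()
        age_rank = meta["age_months"].to_numpy()
        values = pd.DataFrame([age_rank], index=["g"], columns=meta.index)
        rng = bc.per_tissue_correlation_range(_fm(values), meta)
        assert rng["g"] == pytest.approx(0.0)

    def test_hand_range(self):
        # per-tissue rho {1, -1} -> range 2
        meta = self._meta()
        vals = np.where(meta["tissue"] == "brain", meta["age_months"], -meta["age_months"])
        values = pd.DataFrame([vals.astype(float)], index=["g"], columns=meta.index)
        rng = bc.per_tissue_correlation_range(values, meta)
        assert rng["g"] == pytest.approx(2.0)

    def test_single_tissue_warns_and_returns_zero(self):
        meta = self._meta()
        meta = meta[meta["tissue"] == "brain"]
        values = pd.DataFrame(np.random.default_rng(0).normal(size=(3, len(meta))),
                              index=list("abc"), columns=meta.index)
        rng = bc.per_tissue_correlation_range(values, meta)
        assert (rng == 0).all()


class TestCompareRanges:
    def test_identical_groups_degenerate_convention(self):
        out = bc.compare_ranges({"a": [1, 1], "b": [1, 1], "c": [1, 1]})
        assert out["anova_p"] == 1.0
        assert all(p == 1.0 for p in out["tukey"].values())

    def test_closed_form_f(self):
        # groups {1,2},{3,4},{5,6}: MSB=8, MSE=0.5, F=16
        groups = {"a": [1, 2], "b": [3, 4], "c": [5, 6]}
        f, p = stats.f_oneway(*groups.values())
        assert f == pytest.approx(16.0)
        out = bc.compare_ranges(groups)
        assert out["anova_p"] == pytest.approx(p)

    def test_tukey_pairs_upper_triangle(self):
        out = bc.compare_ranges({"a": [1, 2, 1.5], "b": [3, 4, 3.5], "c": [5, 6, 5.5]})
        assert set(out["tukey"]) == {("a", "b"), ("a", "c"), ("b", "c")}
        assert out["tukey"][("a", "c")] <= out["tukey"][("a", "b")]


class TestGeneSetsAndOverlap:
    @staticmethod
    def _ranking(n=600):
        ids = [f"g{i:04d}" for i in range(n)]
        f = pd.Series(np.linspace(100, 1, n), index=ids)
        table = pd.DataFrame({"F": f, "rank": np.arange(1, n + 1)})
        return bc.GeneRanking("age", "TPM", table)

    def test_default_schedule_is_nested(self):
        sets = bc.top_k_gene_sets(self._ranking())
        assert list(sets) == list(DEFAULT_GENE_SET_SIZES)
        prev: set = set()
        for k, genes in sets.items():
            assert len(genes) == k
            assert prev < set(genes) or not prev
            prev = set(genes)

    def test_size_beyond_universe_rejected(self):
        with pytest.raises(ValueError, match="only 20"):
            bc.top_k_gene_sets(self._ranking(20), (15, 25))

    def test_full_list(self):
        sets = bc.top_k_gene_sets(self._ranking(30), (30,))
        assert sets[30] == self._ranking(30).ranked_genes

    def test_disjoint_sets(self):
        k, p = bc.overlap_test(["a", "b"], ["c", "d"], 100)
        assert (k, p) == (0, 1.0)

    def test_identical_sets_brute_force(self):
        # A == B, |A|=10, universe 100: p = 1/C(100,10)
        genes = [f"g{i}" for i in range(10)]
        k, p = bc.overlap_test(genes, genes, 100)
        from math import comb

        assert k == 10
        assert p == pytest.approx(1 / comb(100, 10), rel=1e-9)

    def test_whole_universe_overlap_is_certain(self):
        universe = [f"g{i}" for i in range(20)]
        k, p = bc.overlap_test(universe, universe[:7], 20)
        assert (k, p) == (7, 1.0)

    def test_hypergeometric_matches_enumeration(self):
        # small enough to enumerate: universe 8, |A|=3, |B|=4
        from itertools import combinations

        universe = list(range(8))
        b = {0, 1, 2, 3}
        total = 0
        hits = 0
        for a in combinations(universe, 3):
            total += 1
            if len(set(a) & b) >= 2:
                hits += 1
        _, p = bc.overlap_test(["g0", "g1", "g9"], ["g0", "g1", "g2", "g3"], 8)
        assert p == pytest.approx(hits / total, rel=1e-12)


def test_planted_negative_genes_have_negative_sign(planted_dataset, planted_lpkm):
    screen = bc.spearman_age_screen(planted_lpkm, planted_dataset.metadata)
    neg = planted_dataset.manifest.genes_with_role("age_neg")
    signs = screen.table.loc[neg, "sign"]
    assert (signs == "negative").mean() >= 0.8
    assert not (signs == "positive").any()
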