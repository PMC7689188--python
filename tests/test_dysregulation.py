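"""Dysregulation scores, the permutation null, and DMTN construction."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import mirdysnet as md
from mirdysnet.dysregulation import ConstantVectorError


def _matrices(x_rows, y_rows, n_tumor, n_normal):
    """Build miRNA/gene matrices plus groups from per-feature value rows."""
    samples = [f"T{i}" for i in range(n_tumor)] + [f"N{i}" for i in range(n_normal)]
    em_m = md.ExpressionMatrix(
        pd.DataFrame(x_rows, index=[f"m{i}" for i in range(len(x_rows))],
                     columns=samples, dtype=float), "miRNA")
    em_g = md.ExpressionMatrix(
        pd.DataFrame(y_rows, index=[f"g{i}" for i in range(len(y_rows))],
                     columns=samples, dtype=float), "mRNA")
    groups = md.GroupAssignment(
        {s: ("tumor" if s.startswith("T") else "normal") for s in samples})
    return em_m, em_g, groups


class TestRankCorrelation:
    def test_monotone_identity(self):
        assert md.rank_correlation([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)

    def test_hand_formula_without_ties(self):
        # d^2 = (4, 1, 1): 1 - 6*6 / (3*8) = -0.5
        assert md.rank_correlation([1, 2, 3], [3, 1, 2]) == pytest.approx(-0.5)

    def test_average_ranks_for_ties_match_hand_computation(self):
        x, y = [1.0, 1.0, 2.0], [1.0, 2.0, 3.0]
        # ranks(x) = (1.5, 1.5, 3), ranks(y) = (1, 2, 3): Pearson by hand
        rx, ry = np.array([1.5, 1.5, 3.0]), np.array([1.0, 2.0, 3.0])
        expected = np.corrcoef(rx, ry)[0, 1]
        assert md.rank_correlation(x, y) == pytest.approx(expected)

    def test_constant_vector_raises(self):
        with pytest.raises(ConstantVectorError):
            md.rank_correlation([1, 1, 1], [1, 2, 3])


class TestDysregulationScores:
    def test_identical_relation_in_both_conditions_scores_zero(self):
        x = [[1, 2, 3, 4, 1, 2, 3, 4]]
        y = [[2, 3, 4, 5, 2, 3, 4, 5]]
        em_m, em_g, groups = _matrices(x, y, 4, 4)
        pairs = pd.DataFrame({"miRNA": ["m0"], "gene": ["g0"]})
        rec = md.dysregulation_scores(em_m, em_g, pairs, groups)
        assert rec.loc[0, "rho_tumor"] == pytest.approx(1.0)
        assert rec.loc[0, "score"] == pytest.approx(0.0)

    def test_opposite_monotone_relations_score_two(self):
        x = [[1, 2, 3, 4, 1, 2, 3, 4]]
        y = [[2, 3, 4, 5, 5, 4, 3, 2]]  # increasing in tumor, decreasing in normal
        em_m, em_g, groups = _matrices(x, y, 4, 4)
        pairs = pd.DataFrame({"miRNA": ["m0"], "gene": ["g0"]})
        rec = md.dysregulation_scores(em_m, em_g, pairs, groups)
        assert rec.loc[0, "score"] == pytest.approx(2.0)

    def test_seeded_pairs_match_per_pair_spearmanr(self):
        rng = np.random.default_rng(3)
        n_t, n_n = 15, 12
        x = rng.lognormal(0, 1, (20, n_t + n_n))
        y = rng.lognormal(0, 1, (20, n_t + n_n))
        em_m, em_g, groups = _matrices(x, y, n_t, n_n)
        pairs = pd.DataFrame({"miRNA": [f"m{i}" for i in range(20)],
                              "gene": [f"g{i}" for i in range(20)]})
        rec = md.dysregulation_scores(em_m, em_g, pairs, groups)
        for i in range(20):
            rt = stats.spearmanr(x[i, :n_t], y[i, :n_t]).statistic
            rn = stats.spearmanr(x[i, n_t:], y[i, n_t:]).statistic
            assert rec.loc[i, "rho_tumor"] == pytest.approx(rt)
            assert rec.loc[i, "score"] == pytest.approx(abs(rt - rn))

    def test_score_symmetric_under_condition_swap(self):
        rng = np.random.default_rng(4)
        x = rng.lognormal(0, 1, (5, 20))
        y = rng.lognormal(0, 1, (5, 20))
        em_m, em_g, groups = _matrices(x, y, 10, 10)
        swapped = md.GroupAssignment(
            {s: ("normal" if c == "tumor" else "tumor")
             for s, c in groups.condition.items()})
        pairs = pd.DataFrame({"miRNA": [f"m{i}" for i in range(5)],
                              "gene": [f"g{i}" for i in range(5)]})
        a = md.dysregulation_scores(em_m, em_g, pairs, groups)
        b = md.dysregulation_scores(em_m, em_g, pairs, swapped)
        np.testing.assert_allclose(a["score"], b["score"], atol=1e-12)

    def test_missing_id_pairs_are_skipped(self):
        x = [[1, 2, 3, 4, 5, 6, 1, 3, 2, 5]]
        em_m, em_g, groups = _matrices(x, x, 5, 5)
        pairs = pd.DataFrame({"miRNA": ["m0", "ghost"], "gene": ["g0", "g0"]})
        rec = md.dysregulation_scores(em_m, em_g, pairs, groups)
        assert len(rec) == 1


class TestPermutationPvalues:
    def test_zero_observed_score_gives_p_one(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, (1, 12)) ** 0 + np.arange(12)  # strictly increasing
        y = x.copy()
        em_m, em_g, groups = _matrices(x, y, 6, 6)
        pairs = pd.DataFrame({"miRNA": ["m0"], "gene": ["g0"]})
        rec = md.dysregulation_scores(em_m, em_g, pairs, groups)
        assert rec.loc[0, "score"] == pytest.approx(0.0)
        rec = md.permutation_pvalues(rec, em_m, em_g, groups, n_perm=200, seed=0)
        assert rec.loc[0, "p_perm"] == 1.0

    def test_exhaustive_enumerates_all_partitions_of_3_plus_3(self):
        rng = np.random.default_rng(6)
        x = rng.lognormal(0, 1, (4, 6))
        y = rng.lognormal(0, 1, (4, 6))
        em_m, em_g, groups = _matrices(x, y, 3, 3)
        pairs = pd.DataFrame({"miRNA": [f"m{i}" for i in range(4)],
                              "gene": [f"g{i}" for i in range(4)]})
        rec = md.dysregulation_scores(em_m, em_g, pairs, groups)
        ex = md.permutation_pvalues(rec, em_m, em_g, groups, exhaustive=True)
        assert (ex["n_perm"] == 20).all()
        # p is a multiple of 1/20 and at least 1/20 (the observed partition)
        assert np.allclose(ex["p_perm"] * 20, np.round(ex["p_perm"] * 20))
        assert (ex["p_perm"] >= 1 / 20).all()

    def test_monte_carlo_agrees_with_exhaustive_within_3_se(self):
        rng = np.random.default_rng(7)
        x = rng.lognormal(0, 1, (6, 6))
        y = rng.lognormal(0, 1, (6, 6))
        em_m, em_g, groups = _matrices(x, y, 3, 3)
        pairs = pd.DataFrame({"miRNA": [f"m{i}" for i in range(6)],
                              "gene": [f"g{i}" for i in range(6)]})
        rec = md.dysregulation_scores(em_m, em_g, pairs, groups)
        ex = md.permutation_pvalues(rec, em_m, em_g, groups, exhaustive=True)
        mc = md.permutation_pvalues(rec, em_m, em_g, groups, n_perm=10_000, seed=1)
        se = np.sqrt(ex["p_perm"] * (1 - ex["p_perm"]) / 10_000)
        assert (np.abs(mc["p_perm"] - ex["p_perm"]) <= 3 * se + 1e-12).all()

    def test_monte_carlo_converges_to_exhaustive(self):
        rng = np.random.default_rng(8)
        x = rng.lognormal(0, 1, (10, 6))
        y = rng.lognormal(0, 1, (10, 6))
        em_m, em_g, groups = _matrices(x, y, 3, 3)
        pairs = pd.DataFrame({"miRNA": [f"m{i}" for i in range(10)],
                              "gene": [f"g{i}" for i in range(10)]})
        rec = md.dysregulation_scores(em_m, em_g, pairs, groups)
        ex = md.permutation_pvalues(rec, em_m, em_g, groups, exhaustive=True)
        mc = md.permutation_pvalues(rec, em_m, em_g, groups, n_perm=5000, seed=2)
        assert np.abs(mc["p_perm"] - ex["p_perm"]).mean() < 0.02

    def test_exhaustive_cap_enforced(self):
        rng = np.random.default_rng(9)
        x = rng.lognormal(0, 1, (1, 12))
        em_m, em_g, groups = _matrices(x, x + rng.lognormal(0, 1, (1, 12)), 6, 6)
        pairs = pd.DataFrame({"miRNA": ["m0"], "gene": ["g0"]})
        rec = md.dysregulation_scores(em_m, em_g, pairs, groups)
        with pytest.raises(ValueError, match="cap"):
            md.permutation_pvalues(rec, em_m, em_g, groups, exhaustive=True,
                                   max_partitions=10)

    def test_same_seed_reproduces_pvalues(self, null_perm_records):
        cfg = md.ScenarioConfig(
            n_tumor=50, n_normal=50, n_mirna=100, n_gene=400, n_pairs=1000,
            n_dysreg=100, rho_tumor=0.0, rho_normal=0.0, risk_log2_fc=0.0,
            seed=101,
        )
        em_m, em_g, groups, pairs, _ = md.gen_paired_expression(cfg)
        rec = md.dysregulation_scores(em_m, em_g, pairs, groups)
        again = md.permutation_pvalues(rec.head(25), em_m, em_g, groups,
                                       n_perm=1000, seed=101)
        np.testing.assert_array_equal(
            again["p_perm"].to_numpy(), null_perm_records["p_perm"].to_numpy()[:25])

    def test_null_pvalues_are_uniform(self, null_perm_records):
        ks = stats.kstest(null_perm_records["p_perm"], "uniform").statistic
        assert ks < 0.05


class TestBuildDmtn:
    @staticmethod
    def _records(pvals):
        return pd.DataFrame(
            {"miRNA": [f"m{i}" for i in range(len(pvals))],
             "gene": [f"g{i}" for i in range(len(pvals))],
             "p_perm": pvals})

    def test_boundary_p_excluded_by_strict_rule(self):
        net = md.build_dmtn(self._records([0.05, 0.049]))
        assert net.edges == {("m1", "g1")}

    def test_all_insignificant_gives_empty_network(self):
        net = md.build_dmtn(self._records([1.0, 1.0]))
        assert not net.edges and not net.mirnas

    def test_edge_count_matches_recount(self):
        rng = np.random.default_rng(10)
        p = rng.random(500)
        net = md.build_dmtn(self._records(p), alpha=0.05)
        assert len(net.edges) == int((p < 0.05).sum())

    def test_requires_permutation_pvalues(self):
        with pytest.raises(ValueError, match="p_perm"):
            md.build_dmtn(pd.DataFrame({"miRNA": [], "gene": []}))
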