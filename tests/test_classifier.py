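"""TP/TN label construction, network features, AUC, and the GA-tuned SVM."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

import mirdysnet as md
from mirdysnet.classifier import FEATURE_NAMES, _build_xy, _cv_auc


def _em(values, samples, features):
    return md.ExpressionMatrix(
        pd.DataFrame(values, index=features, columns=samples, dtype=float), "miRNA")


def _groups(samples):
    return md.GroupAssignment(
        {s: ("tumor" if s.startswith("T") else "normal") for s in samples})


class TestLabelConstruction:
    def test_true_positives_are_union_intersect_network(self):
        net = md.BipartiteNetwork.from_edges(
            [("B", "g1"), ("C", "g2"), ("D", "g3")])
        assert md.select_true_positives([{"A", "B"}, {"B", "C"}], net) == {"B", "C"}

    def test_disjoint_lists_give_empty_set_with_warning(self, caplog):
        net = md.BipartiteNetwork.from_edges([("X", "g1")])
        with caplog.at_level("WARNING"):
            tp = md.select_true_positives([{"A"}], net)
        assert tp == set() and "empty" in caplog.text.lower()

    def test_seeded_instance_matches_set_expression(self):
        rng = np.random.default_rng(21)
        ids = [f"m{i}" for i in range(50)]
        lists = [set(rng.choice(ids, 15)) for _ in range(3)]
        net_mirnas = set(rng.choice(ids, 25))
        net = md.BipartiteNetwork.from_edges([(m, "g") for m in net_mirnas])
        assert md.select_true_positives(lists, net) == (
            (lists[0] | lists[1] | lists[2]) & net_mirnas)

    def test_finalize_negatives_set_expression_and_order(self):
        net = md.BipartiteNetwork.from_edges([("A", "g"), ("C", "g"), ("D", "g")])
        assert md.finalize_negatives(["A", "B", "C"], {"B"}, net) == ["A", "C"]
        assert md.finalize_negatives(["A", "C"], {"A", "C"}, net) == []


class TestRankSumNegatives:
    SAMPLES = [f"T{i}" for i in range(4)] + [f"N{i}" for i in range(4)]

    def test_dominant_low_mirna_always_selected(self):
        rng = np.random.default_rng(22)
        vals = rng.lognormal(2, 0.5, (10, 8))
        vals[3] = 1e-6 * rng.random(8)  # smallest mean and variance everywhere
        em = _em(vals, self.SAMPLES, [f"m{i}" for i in range(10)])
        for k in (1, 3, 5):
            assert "m3" in md.rank_sum_negatives(em, _groups(self.SAMPLES), k=k)

    def test_hand_ranked_six_by_eight_table(self):
        # identical tumor and normal halves, so each of the six rankings
        # repeats one hand-computed (mean rank, var rank) pattern:
        #   mean ranks: F=1 A=2 B=3 C=4 D=5 E=6
        #   var ranks:  A=B=E=2 (three-way tie at 0), D=4, F=5, C=6
        #   rank sums:  A=12 B=15 F=18 E=24 D=27 C=30
        half = {
            "A": [1, 1, 1, 1], "B": [2, 2, 2, 2], "C": [0, 1, 2, 9],
            "D": [3, 3, 3, 4], "E": [10, 10, 10, 10], "F": [0, 0, 0, 2],
        }
        vals = np.array([half[m] + half[m] for m in "ABCDEF"], dtype=float)
        em = _em(vals, self.SAMPLES, list("ABCDEF"))
        assert md.rank_sum_negatives(em, _groups(self.SAMPLES), k=2) == ["A", "B"]
        assert md.rank_sum_negatives(em, _groups(self.SAMPLES), k=3) == ["A", "B", "F"]

    def test_identical_rows_fall_back_to_lexicographic_ids(self):
        vals = np.ones((4, 8))
        em = _em(vals, self.SAMPLES, ["d", "b", "c", "a"])
        assert md.rank_sum_negatives(em, _groups(self.SAMPLES), k=2) == ["a", "b"]

    def test_k_larger_than_mirna_count_rejected(self):
        em = _em(np.ones((2, 8)), self.SAMPLES, ["a", "b"])
        with pytest.raises(ValueError, match="exceeds"):
            md.rank_sum_negatives(em, _groups(self.SAMPLES), k=5)


class TestComputeFeatures:
    SAMPLES = [f"T{i}" for i in range(3)] + [f"N{i}" for i in range(3)]

    def _em_for(self, net):
        mirnas = sorted(net.mirnas)
        return _em(np.ones((len(mirnas), 6)), self.SAMPLES, mirnas)

    def test_toy_graph_hand_trace(self, toy_net):
        feats = md.compute_features(
            toy_net, self._em_for(toy_net), _groups(self.SAMPLES), {"m2"})
        m1 = feats.loc["m1"]
        assert m1["out_degree"] == 1
        assert m1["n_coreg"] == 1
        assert m1["pct_coreg_disease"] == 1.0
        assert m1["n_genes_disease_reg"] == 1
        # m2 co-regulates with m1 only, which is not a disease miRNA
        assert feats.loc["m2", "pct_coreg_disease"] == 0.0
        assert feats.loc["m2", "n_genes_disease_reg"] == 0

    def test_unique_targets_mean_no_coregulation(self, toy_net):
        feats = md.compute_features(
            toy_net, self._em_for(toy_net), _groups(self.SAMPLES), {"m2"})
        m3 = feats.loc["m3"]
        assert m3["n_coreg"] == 0
        assert m3["pct_coreg_disease"] == 0.0
        assert m3["n_genes_disease_reg"] == 0

    def test_equal_condition_means_give_zero_fold_change(self, toy_net):
        feats = md.compute_features(
            toy_net, self._em_for(toy_net), _groups(self.SAMPLES), set())
        assert (feats["log2_fc"] == 0.0).all()

    def test_missing_mirna_is_named_in_the_error(self, toy_net):
        em = _em(np.ones((2, 6)), self.SAMPLES, ["m1", "m2"])
        with pytest.raises(ValueError, match="m3"):
            md.compute_features(toy_net, em, _groups(self.SAMPLES), set())

    @pytest.mark.parametrize("seed", range(10))
    def test_disease_regulated_targets_never_exceed_out_degree(self, seed):
        rng = np.random.default_rng([23, seed])
        mirnas = [f"m{i}" for i in range(15)]
        genes = [f"g{i}" for i in range(20)]
        edges = {(m, g) for m, g in zip(rng.choice(mirnas, 60), rng.choice(genes, 60))}
        net = md.BipartiteNetwork.from_edges(edges)
        present = sorted(net.mirnas)
        em = _em(rng.lognormal(0, 1, (len(present), 6)), self.SAMPLES, present)
        disease = set(rng.choice(present, 5))
        feats = md.compute_features(net, em, _groups(self.SAMPLES), disease)
        assert (feats["n_genes_disease_reg"] <= feats["out_degree"]).all()
        assert ((feats["n_coreg"] > 0) | (feats["pct_coreg_disease"] == 0)).all()


class TestEvaluateAuc:
    def test_perfect_separation(self):
        assert md.evaluate_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_all_tied_scores_give_half(self):
        assert md.evaluate_auc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_enumerated_pairs(self):
        # pos {0.9, 0.2} vs neg {0.5, 0.1}: 3 of 4 pairs concordant
        assert md.evaluate_auc([0.9, 0.2, 0.5, 0.1], [1, 1, 0, 0]) == 0.75

    def test_negation_antisymmetry_and_sklearn_agreement(self):
        rng = np.random.default_rng(24)
        scores = rng.normal(0, 1, 200)
        labels = rng.integers(0, 2, 200)
        labels[0], labels[1] = 0, 1  # both classes guaranteed
        auc = md.evaluate_auc(scores, labels)
        assert auc + md.evaluate_auc(-scores, labels) == pytest.approx(1.0)
        assert auc == pytest.approx(roc_auc_score(labels, scores))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            md.evaluate_auc([0.1, 0.2], [1, 1])


def _cluster_features(seed=25, n=50, gap=4.0):
    rng = np.random.default_rng(seed)
    pos = rng.normal(gap, 1.0, (n, 5))
    neg = rng.normal(0.0, 1.0, (n, 5))
    ids = [f"p{i}" for i in range(n)] + [f"n{i}" for i in range(n)]
    feats = pd.DataFrame(np.vstack([pos, neg]), index=ids, columns=FEATURE_NAMES)
    labels = md.LabelSets(tp={f"p{i}" for i in range(n)},
                          tn={f"n{i}" for i in range(n)})
    return feats, labels


class TestTrainClassifier:
    def test_separable_clusters_reach_high_cv_auc(self):
        feats, labels = _cluster_features()
        model = md.train_classifier(
            feats, labels, ga=md.GAConfig(population=8, generations=4), seed=1)
        assert model.cv_auc >= 0.95

    def test_single_class_rejected(self):
        feats, labels = _cluster_features()
        with pytest.raises(ValueError):
            md.train_classifier(feats, md.LabelSets(tp=labels.tp, tn=set()), seed=1)

    def test_same_seed_gives_identical_model(self):
        feats, labels = _cluster_features()
        ga = md.GAConfig(population=6, generations=3)
        a = md.train_classifier(feats, labels, ga=ga, seed=7)
        b = md.train_classifier(feats, labels, ga=ga, seed=7)
        assert (a.log_c, a.log_gamma, a.cv_auc) == (b.log_c, b.log_gamma, b.cv_auc)

    def test_ga_matches_or_beats_a_coarse_grid(self, risk_run):
        ids, X, y = _build_xy(risk_run.features, risk_run.labels)
        splits = list(StratifiedKFold(5, shuffle=True, random_state=11).split(X, y))
        grid_best = max(
            _cv_auc(X, y, lc, lg, splits)[1]
            for lc in (-1.0, 1.0, 3.0)
            for lg in (-3.0, -1.0, 1.0)
        )
        assert risk_run.model.cv_auc >= grid_best - 0.02


class TestRecognitionThresholdAndPrediction:
    def test_no_tn_scores_above_threshold_across_seeded_draws(self):
        feats, labels = _cluster_features(seed=26, n=20)
        model = md.train_classifier(
            feats, labels, ga=md.GAConfig(population=6, generations=2), seed=2)
        rng = np.random.default_rng(27)
        for _ in range(100):
            tbl = pd.DataFrame(rng.normal(1.0, 2.0, (15, 5)), columns=FEATURE_NAMES)
            thr = md.recognition_threshold(model, tbl)
            assert (model.predict_score(tbl) > thr).sum() == 0

    def test_threshold_one_predicts_nothing(self, risk_run):
        preds = md.predict_risk(risk_run.model, risk_run.features, 1.0)
        assert preds["risk"].sum() == 0

    def test_threshold_zero_predicts_everything_with_positive_scores(self, risk_run):
        preds = md.predict_risk(risk_run.model, risk_run.features, 0.0)
        assert preds["risk"].sum() == (preds["score"] > 0).sum() == len(preds)

    def test_predictions_sorted_by_descending_score(self, risk_run):
        s = risk_run.predictions["score"].to_numpy()
        assert (np.diff(s) <= 1e-15).all()

    def test_feature_name_mismatch_rejected(self, risk_run):
        bad = risk_run.features.rename(columns={"out_degree": "degree"})
        with pytest.raises(ValueError, match="missing"):
            risk_run.model.predict_score(bad)
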