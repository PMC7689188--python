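"""Shared fixtures: the three expensive simulation scenarios are computed
once per session and reused by the unit and acceptance tests."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
import pytest

import mirdysnet as md


@dataclass
class RiskScenarioRun:
    """Default risk scenario pushed through the whole classifier chain."""

    scenario: md.Scenario
    records: pd.DataFrame
    net: md.BipartiteNetwork
    labels: md.LabelSets
    features: pd.DataFrame
    model: md.ModelBundle
    threshold: float
    predictions: pd.DataFrame


@pytest.fixture(scope="session")
def null_perm_records() -> pd.DataFrame:
    """Permutation p-values for 1,000 truly null pairs at n = 50+50.

    The generator plants no rewiring (rho_tumor = rho_normal = 0) and no
    fold change, so every candidate pair satisfies the permutation null.
    """
    cfg = md.ScenarioConfig(
        n_tumor=50, n_normal=50, n_mirna=100, n_gene=400, n_pairs=1000,
        n_dysreg=100, rho_tumor=0.0, rho_normal=0.0, risk_log2_fc=0.0,
        seed=101,
    )
    em_m, em_g, groups, pairs, _ = md.gen_paired_expression(cfg)
    rec = md.dysregulation_scores(em_m, em_g, pairs, groups)
    return md.permutation_pvalues(rec, em_m, em_g, groups, n_perm=1000, seed=101)


@pytest.fixture(scope="session")
def planted_perm_records() -> pd.DataFrame:
    """Permutation p-values for 200 pairs rewired (0.6 vs 0.0) at n = 100+100."""
    cfg = md.ScenarioConfig(
        n_tumor=100, n_normal=100, n_mirna=50, n_gene=200, n_pairs=200,
        n_dysreg=200, seed=102,
    )
    em_m, em_g, groups, pairs, _ = md.gen_paired_expression(cfg)
    rec = md.dysregulation_scores(em_m, em_g, pairs, groups)
    return md.permutation_pvalues(rec, em_m, em_g, groups, n_perm=1000, seed=102)


@pytest.fixture(scope="session")
def risk_run() -> RiskScenarioRun:
    """The default synthetic risk scenario run end to end."""
    cfg = md.ScenarioConfig(seed=11)
    scn = md.generate_scenario(cfg)
    rec = md.dysregulation_scores(scn.em_mirna, scn.em_gene, scn.pairs, scn.groups)
    rec = md.permutation_pvalues(
        rec, scn.em_mirna, scn.em_gene, scn.groups, n_perm=cfg.n_perm, seed=cfg.seed
    )
    net = md.build_dmtn(rec)
    tp = md.select_true_positives(scn.disease_lists, net)
    tn = md.finalize_negatives(
        md.rank_sum_negatives(scn.em_mirna, scn.groups, k=95), tp, net
    )
    disease = set().union(*map(set, scn.disease_lists))
    features = md.compute_features(net, scn.em_mirna, scn.groups, disease)
    labels = md.LabelSets(tp=tp, tn=set(tn))
    model = md.train_classifier(features, labels, seed=cfg.seed)
    threshold = md.recognition_threshold(model, features.loc[sorted(labels.tn)])
    predictions = md.predict_risk(model, features, threshold)
    return RiskScenarioRun(
        scenario=scn, records=rec, net=net, labels=labels, features=features,
        model=model, threshold=threshold, predictions=predictions,
    )


@pytest.fixture()
def toy_net() -> md.BipartiteNetwork:
    """m1 and m2 share g1; m3 regulates g2 alone."""
    return md.BipartiteNetwork.from_edges(
        [("m1", "g1"), ("m2", "g1"), ("m3", "g2")]
    )
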