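"""Train the GA-tuned SVM risk classifier on the default synthetic scenario.

Curated disease lists intersected with the network give true positives;
lowly/stably expressed network miRNAs picked by the six-ranking sum give
true negatives.  Five network/expression features feed the classifier,
and the recognition threshold is set so that no TN miRNA is called risk.
"""

import mirdysnet as md

cfg = md.ScenarioConfig(seed=11)
scn = md.generate_scenario(cfg)
rec = md.dysregulation_scores(scn.em_mirna, scn.em_gene, scn.pairs, scn.groups)
rec = md.permutation_pvalues(rec, scn.em_mirna, scn.em_gene, scn.groups,
                             n_perm=cfg.n_perm, seed=cfg.seed)
net = md.build_dmtn(rec)

tp = md.select_true_positives(scn.disease_lists, net)
tn = md.finalize_negatives(
    md.rank_sum_negatives(scn.em_mirna, scn.groups, k=95), tp, net)
labels = md.LabelSets(tp=tp, tn=set(tn))
disease = set().union(*map(set, scn.disease_lists))
features = md.compute_features(net, scn.em_mirna, scn.groups, disease)

model = md.train_classifier(features, labels, seed=cfg.seed)
threshold = md.recognition_threshold(model, features.loc[sorted(labels.tn)])
preds = md.predict_risk(model, features, threshold)

risk = set(preds.index[preds["risk"]])
planted = scn.truth.risk_mirnas & net.mirnas
print(f"{len(net.mirnas)} network miRNAs; {len(tp)} TP, {len(tn)} TN labels")
print(f"cross-validated AUC {model.cv_auc:.3f} "
      f"(per fold: {[round(a, 3) for a in model.fold_aucs]})")
print(f"recognition threshold {threshold:.3f} -> {len(risk)} risk miRNAs, "
      f"{len(risk & labels.tn)} of them TN (must be 0)")
print(f"recovered {len(risk & planted)}/{len(planted)} planted risk miRNAs")
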