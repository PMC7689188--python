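# mirdysnet

Dysregulated miRNA–target network analysis: infer which miRNA→mRNA
regulatory relations are *rewired* between tumor and normal tissue,
classify "risk" miRNAs from network-derived features, and screen the
results against survival, immune-infiltration and drug-response data.

Most differential miRNA-network methods score the expression change of
the miRNAs and genes themselves. `mirdysnet` instead scores the change in
the *relation*: for a candidate miRNA *i* / mRNA *j* pair the
dysregulation score is

    S_ij = | rho_ij(tumor) − rho_ij(normal) |,    S ∈ [0, 2]

where rho is the Spearman rank correlation across the samples of each
condition. Significance comes from a permutation null that shuffles the
tumor/normal partition of the samples (group sizes fixed) and recomputes
S; the p-value is the fraction of permutations whose score is at least
the observed one. Pairs with p < 0.05 form a directed bipartite
miRNA→gene network (the dysregulated miRNA-target network, DMTN).

On top of the network the package provides:

- **Risk-miRNA classification** — true positives are curated disease
  miRNAs present in the network; true negatives are network miRNAs with
  the lowest combined ranks of mean expression and variance over all,
  tumor-only and normal-only samples (six rankings). Five features per
  miRNA (out-degree, number of co-regulating miRNAs, percentage of
  disease co-regulators, number of targets shared with disease miRNAs,
  log2 fold change of condition means) feed an RBF-kernel SVM whose
  hyperparameters a small genetic algorithm tunes to maximize mean
  cross-validated AUC. The recognition threshold is placed just above
  the highest score of any true negative, so no TN is ever called risk.
- **Set statistics** — hypergeometric upper-tail overlap tests
  P(X ≥ x), GMT-style annotation enrichment, Benjamini–Hochberg FDR.
- **Survival screens** — median-split Kaplan–Meier curves with two-group
  log-rank tests per feature.
- **Phenotype associations** — Spearman screens against immune-cell
  abundances and Pearson screens against drug log-IC50 across cell
  lines, with the |r| ≥ 0.2 and BH q < 0.05 significance rule.
- **Synthetic data** — Gaussian-copula generators that plant rewired
  pairs, a risk-miRNA block, survival drivers and phenotype
  correlations with machine-readable ground truth, so the entire
  pipeline is testable end to end without any downloads.

## Worked example

`examples/` contains one short script per capability. Building the
network on synthetic data (`examples/01_dysregulation_network.py`):

```text
scored 300 candidate pairs (60 with planted rewiring)
network: 27 miRNAs, 62 genes, 66 edges at p < 0.05
planted-edge detection rate 0.83; false-positive rate on null pairs 0.067 (nominal 0.05)
out-degree histogram {1: 13, 2: 8, 4: 2, 6: 1, 7: 1, 8: 2}; log-log slope -1.23 (negative = heavy-tailed)
miRNA-miRNA shortest paths {2: 4, 4: 2, 6: 1}, 344 unreachable pairs (even lengths: paths go via genes)
```

At this desk scale (40+40 samples) 83% of the planted rewired edges are
recovered while null pairs are flagged at roughly the nominal 5% rate;
the out-degree histogram is heavy-tailed (few hub miRNAs, many leaves).
Training the classifier on the default scenario
(`examples/02_risk_classifier.py`):

```text
105 network miRNAs; 15 TP, 64 TN labels
cross-validated AUC 1.000 (per fold: [1.0, 1.0, 1.0, 1.0, 1.0])
recognition threshold 0.089 -> 15 risk miRNAs, 0 of them TN (must be 0)
recovered 15/15 planted risk miRNAs
```

The planted risk block is fully recovered with no true negative called
risk. `examples/06_full_pipeline.py` runs every stage through the
orchestrator and prints the manifest; the same flow is available from
the shell:

```sh
mirdysnet simulate --out inputs/ --seed 7
mirdysnet run --config pipeline.yaml --seed 7
```

Stage outputs are TSV/JSON files with sha256 checksums recorded in
`run_manifest.json`; a rerun with the same seed is checksum-identical,
and `--resume` recomputes only stages whose outputs are missing.

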