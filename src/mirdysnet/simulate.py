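"""Synthetic data with known ground truth for every pipeline stage.

The generator emulates the statistical structure the pipeline assumes:

* paired tumor/normal expression in which each candidate miRNA-mRNA pair
  follows a per-condition bivariate Gaussian copula with log-normal
  marginals — dysregulated pairs change their rank correlation between
  conditions, null pairs do not;
* a planted "risk" block of miRNAs with many dysregulated targets, a
  disease-list analog naming them, and a disjoint low-mean/low-variance
  block that the rank-sum negative-selection procedure should find;
* exponential survival times whose log-hazard is linear in the
  standardized expression of chosen driver features, with independent
  exponential censoring tuned to roughly 30%;
* compositional immune-cell abundances (rows sum to one) rank-coupled to
  chosen features, and a cell-line log-IC50 matrix with planted Pearson
  correlations and ~10% missing entries.

Spearman targets are hit through the bivariate-normal relation
r_pearson = 2 sin(pi * rho_spearman / 6) on the latent scale; monotone
marginal transforms then preserve the rank correlation.  All generators
are pure functions of (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm, rankdata

from .io import ExpressionMatrix, GroupAssignment

__all__ = [
    "ScenarioConfig",
    "GroundTruth",
    "Scenario",
    "spearman_to_pearson",
    "gen_paired_expression",
    "gen_risk_scenario",
    "gen_survival",
    "gen_abundance_and_drugs",
    "generate_scenario",
    "write_scenario",
]


def spearman_to_pearson(rho_s: float) -> float:
    """Latent Pearson parameter giving Spearman ``rho_s`` for a bivariate normal."""
    if abs(rho_s) >= 1:
        raise ValueError("infeasible Spearman target")
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


@dataclass
class ScenarioConfig:
    """Desk-scale study conditions for the full synthetic scenario.

    Defaults give a complete pipeline run in minutes on one CPU while
    keeping each stage's signal at realistic strength: moderate tumor
    rewiring (rho 0.6 vs 0.0), a ~10% risk block, hazard coefficient 0.8,
    planted phenotype correlations of 0.5 (immune, Spearman) and 0.6
    (drug, Pearson).
    """

    n_tumor: int = 60
    n_normal: int = 60
    n_mirna: int = 150
    n_gene: int = 600
    n_pairs: int = 2000
    n_dysreg: int = 200
    rho_tumor: float = 0.6
    rho_normal: float = 0.0
    rho_null: float = 0.0
    # log-normal marginals: exp(mu + sigma*z)
    lognorm_mu: float = 2.0
    lognorm_mu_jitter: float = 0.3
    lognorm_sigma: float = 0.6
    risk_fraction: float = 0.10
    risk_log2_fc: float = 1.0
    risk_degree_range: tuple[int, int] = (6, 12)
    tn_block_size: int = 20
    tn_mu: float = -1.5
    tn_sigma: float = 0.1
    hazard_coef: float = 0.8
    baseline_hazard: float = 1.0 / 1000.0  # per day
    censor_target: float = 0.30
    n_celltypes: int = 8
    n_planted_immune: int = 5
    rho_immune: float = 0.5
    n_drugs: int = 30
    n_lines: int = 400
    n_planted_drug: int = 10
    rho_drug: float = 0.6
    drug_missing_frac: float = 0.10
    n_perm: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_dysreg > self.n_pairs:
            raise ValueError("n_dysreg exceeds n_pairs")
        if self.n_dysreg > self.n_gene:
            raise ValueError("n_dysreg exceeds n_gene (one planted gene per pair)")
        if min(self.n_tumor, self.n_normal) < 3:
            raise ValueError("group sizes must be >= 3")
        for rho in (self.rho_tumor, self.rho_normal, self.rho_null):
            if abs(rho) >= 1:
                raise ValueError("correlation targets must lie in (-1, 1)")
        n_risk = round(self.risk_fraction * self.n_mirna)
        if n_risk + self.tn_block_size >= self.n_mirna:
            raise ValueError("risk fraction too large for the miRNA count")


@dataclass
class GroundTruth:
    """Machine-readable planted structure accompanying every scenario."""

    dysreg_pairs: set[tuple[str, str]] = field(default_factory=set)
    risk_mirnas: set[str] = field(default_factory=set)
    tn_block: set[str] = field(default_factory=set)
    survival_drivers: set[str] = field(default_factory=set)
    immune_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    drug_pairs: list[tuple[str, str, float]] = field(default_factory=list)


@dataclass
class Scenario:
    """All generated inputs plus the ground truth."""

    config: ScenarioConfig
    em_mirna: ExpressionMatrix
    em_gene: ExpressionMatrix
    groups: GroupAssignment
    pairs: pd.DataFrame
    disease_lists: list[list[str]]
    clinical: pd.DataFrame
    abundance: pd.DataFrame
    drugs: pd.DataFrame
    em_lines: ExpressionMatrix
    truth: GroundTruth


def _ids(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i:04d}" for i in range(1, n + 1)]


def gen_paired_expression(cfg: ScenarioConfig):
    """Paired tumor/normal expression with planted correlation rewiring.

    Returns ``(em_mirna, em_gene, groups, pairs, truth)``.  Dysregulated
    pairs follow (rho_tumor, rho_normal); null pairs use rho_null in both
    conditions.  The planted risk block receives many dysregulated
    targets and a tumor-vs-normal fold change; the TN block receives one
    edge each plus strictly lower marginal mean and variance than every
    other miRNA.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    mirnas = _ids("hsa-mir-", cfg.n_mirna)
    genes = _ids("gene-", cfg.n_gene)
    samples = _ids("T", cfg.n_tumor) + _ids("N", cfg.n_normal)
    n_s = len(samples)
    cond = np.array(["tumor"] * cfg.n_tumor + ["normal"] * cfg.n_normal)

    n_risk = round(cfg.risk_fraction * cfg.n_mirna)
    roles = rng.permutation(cfg.n_mirna)
    risk_idx = roles[:n_risk]
    tn_idx = roles[n_risk : n_risk + cfg.tn_block_size]
    other_idx = roles[n_risk + cfg.tn_block_size :]
    truth = GroundTruth(
        risk_mirnas={mirnas[i] for i in risk_idx},
        tn_block={mirnas[i] for i in tn_idx},
    )

    # --- allocate dysregulated edges: risk-heavy, one each for the TN block
    budget = cfg.n_dysreg - cfg.tn_block_size
    lo, hi = cfg.risk_degree_range
    owners: list[int] = []
    for i in risk_idx:
        d = int(rng.integers(lo, hi + 1))
        owners.extend([i] * min(d, max(budget - len(owners), 0)))
    leftover = budget - len(owners)
    if leftover > 0:
        owners.extend(rng.choice(other_idx, size=leftover, replace=True).tolist())
    owners.extend(tn_idx.tolist())
    gene_perm = rng.permutation(cfg.n_gene)
    dysreg = [(int(m), int(gene_perm[j])) for j, m in enumerate(owners)]
    truth.dysreg_pairs = {(mirnas[m], genes[g]) for m, g in dysreg}

    # --- null candidate pairs (no planted rewiring)
    taken = set(dysreg)
    null_pairs: list[tuple[int, int]] = []
    while len(null_pairs) < cfg.n_pairs - cfg.n_dysreg:
        m = int(rng.integers(0, cfg.n_mirna))
        g = int(rng.integers(0, cfg.n_gene))
        if (m, g) not in taken:
            taken.add((m, g))
            null_pairs.append((m, g))

    # --- latent Gaussian layer
    z_mir = rng.standard_normal((cfg.n_mirna, n_s))
    z_gene = rng.standard_normal((cfg.n_gene, n_s))
    t_mask = cond == "tumor"

    def couple(gi: int, mi: int, rho_t: float, rho_n: float) -> None:
        eps = z_gene[gi]
        for mask, rho in ((t_mask, rho_t), (~t_mask, rho_n)):
            r = spearman_to_pearson(rho)
            z_gene[gi, mask] = r * z_mir[mi, mask] + math.sqrt(1 - r * r) * eps[mask]

    for m, g in dysreg:
        couple(g, m, cfg.rho_tumor, cfg.rho_normal)
    if cfg.rho_null != 0.0:
        claimed = {g for _, g in dysreg}
        for m, g in null_pairs:
            if g not in claimed:
                claimed.add(g)
                couple(g, m, cfg.rho_null, cfg.rho_null)

    # --- log-normal marginals
    mu_mir = cfg.lognorm_mu + rng.normal(0, cfg.lognorm_mu_jitter, cfg.n_mirna)
    sig_mir = np.full(cfg.n_mirna, cfg.lognorm_sigma)
    mu_mir[tn_idx] = cfg.tn_mu
    sig_mir[tn_idx] = cfg.tn_sigma
    shift = np.zeros((cfg.n_mirna, n_s))
    shift[np.ix_(risk_idx, np.where(t_mask)[0])] = cfg.risk_log2_fc * math.log(2)
    expr_mir = np.exp(mu_mir[:, None] + shift + sig_mir[:, None] * z_mir)
    mu_gene = cfg.lognorm_mu + rng.normal(0, cfg.lognorm_mu_jitter, cfg.n_gene)
    expr_gene = np.exp(mu_gene[:, None] + cfg.lognorm_sigma * z_gene)

    em_mirna = ExpressionMatrix(pd.DataFrame(expr_mir, index=mirnas, columns=samples), "miRNA")
    em_gene = ExpressionMatrix(pd.DataFrame(expr_gene, index=genes, columns=samples), "mRNA")
    groups = GroupAssignment(dict(zip(samples, cond)))
    all_pairs = dysreg + null_pairs
    order = rng.permutation(len(all_pairs))
    pairs = pd.DataFrame(
        [(mirnas[all_pairs[i][0]], genes[all_pairs[i][1]]) for i in order],
        columns=["miRNA", "gene"],
    )
    return em_mirna, em_gene, groups, pairs, truth


def gen_risk_scenario(cfg: ScenarioConfig, truth: GroundTruth):
    """Disease-list analogs naming the planted risk miRNAs.

    Two overlapping curated lists whose union covers the risk set, padded
    with decoy ids absent from the expression matrices (so the
    intersection-with-network step has work to do).  Returns
    ``(disease_lists, disease_set)``.
    """
    rng = np.random.default_rng([cfg.seed, 2])
    risk = sorted(truth.risk_mirnas)
    if not risk:
        raise ValueError("no planted risk miRNAs; risk fraction too small")
    cut = max(1, int(0.6 * len(risk)))
    decoys = [f"hsa-mir-decoy-{i:03d}" for i in range(1, 9)]
    list1 = risk[:cut] + decoys[:4]
    list2 = risk[max(0, cut - len(risk) // 4):] + decoys[4:]
    for lst in (list1, list2):
        rng.shuffle(lst)
    return [list1, list2], set(risk) | set(decoys)


def gen_survival(
    em: ExpressionMatrix,
    drivers,
    hazard_coef: float,
    seed: int,
    censor_target: float = 0.30,
    baseline_hazard: float = 1.0 / 1000.0,
) -> pd.DataFrame:
    """Exponential survival times driven by the chosen features.

    The per-sample hazard is ``baseline * exp(coef * z)`` with ``z`` the
    mean standardized log-expression of the driver features; censoring is
    an independent exponential tuned so the expected censored fraction
    matches ``censor_target``.  Returns a clinical table indexed by
    sample with ``time`` (days) and ``event`` columns.
    """
    rng = np.random.default_rng([seed, 3])
    drivers = list(drivers)
    if drivers:
        logx = np.log(em.data.loc[drivers].to_numpy(dtype=float) + 1e-12)
        z = (logx - logx.mean(axis=1, keepdims=True)) / logx.std(axis=1, keepdims=True)
        z = z.mean(axis=0)
    else:
        z = np.zeros(em.n_samples)
    lam = baseline_hazard * np.exp(hazard_coef * z)
    t_event = rng.exponential(1.0 / lam)

    def censored_frac(mu: float) -> float:
        return float(np.mean(mu / (mu + lam)))

    mu = brentq(
        lambda m: censored_frac(m) - censor_target,
        baseline_hazard * 1e-6,
        baseline_hazard * 1e6,
    )
    t_cens = rng.exponential(1.0 / mu, size=em.n_samples)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return pd.DataFrame({"time": time, "event": event}, index=em.sample_ids)


def gen_abundance_and_drugs(cfg: ScenarioConfig, em: ExpressionMatrix, truth: GroundTruth):
    """Immune abundances and a drug-response screen with planted signal.

    Abundance rows are exact compositions: the last cell type is a
    dominant filler absorbing the remainder, the others are bounded
    fractions; planted cell types are rank-coupled to chosen features by
    reordering their values along a Gaussian-copula latent.  The drug
    block generates cell-line expression (Gaussian log-scale marginals),
    log-IC50 columns with planted Pearson correlations, and ~10% missing
    entries.  Returns ``(abundance, drugs, em_lines)`` and records the
    planted pairs in ``truth``.
    """
    rng = np.random.default_rng([cfg.seed, 4])
    samples = em.sample_ids
    n = len(samples)
    k = cfg.n_celltypes
    if cfg.n_planted_immune > k - 1:
        raise ValueError("need at least one unplanted filler cell type")
    for rho in (cfg.rho_immune, cfg.rho_drug):
        if abs(rho) >= 0.95:
            raise ValueError("infeasible planted correlation magnitude")

    feats = sorted(truth.risk_mirnas) or em.feature_ids
    immune_feats = [feats[i % len(feats)] for i in range(cfg.n_planted_immune)]
    celltypes = [f"celltype_{i:02d}" for i in range(1, k + 1)]
    cols = np.empty((n, k))
    cap = 0.8 / (k - 1)
    r_lat = spearman_to_pearson(cfg.rho_immune)
    truth.immune_pairs = []
    for j in range(k - 1):
        draws = cap * rng.beta(2.0, 5.0, n)
        if j < len(immune_feats):
            v = em.data.loc[immune_feats[j], samples].to_numpy(dtype=float)
            u = norm.ppf((rankdata(v) - 0.5) / n)
            z = r_lat * u + math.sqrt(1 - r_lat * r_lat) * rng.standard_normal(n)
            col = np.empty(n)
            col[np.argsort(z)] = np.sort(draws)
            cols[:, j] = col
            truth.immune_pairs.append((immune_feats[j], celltypes[j], cfg.rho_immune))
        else:
            cols[:, j] = draws
    cols[:, k - 1] = 1.0 - cols[:, : k - 1].sum(axis=1)
    abundance = pd.DataFrame(cols, index=samples, columns=celltypes)

    # --- cell-line expression (log-scale Gaussian marginals) and IC50s
    lines = _ids("line-", cfg.n_lines)
    expr = np.clip(rng.normal(5.0, 1.0, (em.n_features, cfg.n_lines)), 0.0, None)
    em_lines = ExpressionMatrix(
        pd.DataFrame(expr, index=em.feature_ids, columns=lines), em.kind
    )
    drug_names = [f"drug-{i:03d}" for i in range(1, cfg.n_drugs + 1)]
    drug_feats = [feats[i % len(feats)] for i in range(cfg.n_planted_drug)]
    ic50 = rng.normal(2.5, 1.2, (cfg.n_lines, cfg.n_drugs))
    truth.drug_pairs = []
    for j in range(min(cfg.n_planted_drug, cfg.n_drugs)):
        x = em_lines.data.loc[drug_feats[j]].to_numpy(dtype=float)
        zx = (x - x.mean()) / x.std()
        r = cfg.rho_drug
        ic50[:, j] = 2.5 + 1.2 * (
            r * zx + math.sqrt(1 - r * r) * rng.standard_normal(cfg.n_lines)
        )
        truth.drug_pairs.append((drug_feats[j], drug_names[j], r))
    mask = rng.random((cfg.n_lines, cfg.n_drugs)) < cfg.drug_missing_frac
    ic50[mask] = np.nan
    drugs = pd.DataFrame(ic50, index=lines, columns=drug_names)
    return abundance, drugs, em_lines


def generate_scenario(cfg: ScenarioConfig) -> Scenario:
    """Generate every pipeline input with a shared ground truth."""
    em_mirna, em_gene, groups, pairs, truth = gen_paired_expression(cfg)
    disease_lists, _ = gen_risk_scenario(cfg, truth)
    drivers = sorted(truth.risk_mirnas)[:3]
    truth.survival_drivers = set(drivers)
    clinical = gen_survival(
        em_mirna, drivers, cfg.hazard_coef, cfg.seed,
        censor_target=cfg.censor_target, baseline_hazard=cfg.baseline_hazard,
    )
    abundance, drugs, em_lines = gen_abundance_and_drugs(cfg, em_mirna, truth)
    return Scenario(
        config=cfg,
        em_mirna=em_mirna,
        em_gene=em_gene,
        groups=groups,
        pairs=pairs,
        disease_lists=disease_lists,
        clinical=clinical,
        abundance=abundance,
        drugs=drugs,
        em_lines=em_lines,
        truth=truth,
    )


def write_scenario(scn: Scenario, outdir) -> dict[str, str]:
    """Write every input table, the truth files and the resolved config.

    Returns a name -> path mapping of everything written.
    """
    import os
    import yaml

    from .io import write_expression, write_groups, write_pairs

    os.makedirs(outdir, exist_ok=True)
    paths: dict[str, str] = {}

    def p(name: str) -> str:
        paths[name] = os.path.join(outdir, name)
        return paths[name]

    write_expression(scn.em_mirna, p("mirna_expression.tsv"))
    write_expression(scn.em_gene, p("gene_expression.tsv"))
    write_groups(scn.groups, p("groups.tsv"))
    write_pairs(scn.pairs, p("candidate_pairs.tsv"))
    for i, lst in enumerate(scn.disease_lists, start=1):
        with open(p(f"disease_list_{i}.txt"), "w") as fh:
            fh.write("\n".join(lst) + "\n")
    scn.clinical.rename_axis("sample").to_csv(p("clinical.tsv"), sep="\t",
                                              float_format="%.10g")
    scn.abundance.rename_axis("sample").to_csv(p("immune_abundance.tsv"), sep="\t",
                                               float_format="%.10g")
    scn.drugs.rename_axis("cell_line").to_csv(p("drug_ic50.tsv"), sep="\t",
                                              float_format="%.10g")
    write_expression(scn.em_lines, p("cellline_expression.tsv"))

    t = scn.truth
    pd.DataFrame(sorted(t.dysreg_pairs), columns=["miRNA", "gene"]).to_csv(
        p("truth_dysreg_pairs.tsv"), sep="\t", index=False)
    pd.DataFrame({"miRNA": sorted(t.risk_mirnas)}).to_csv(
        p("truth_risk_mirnas.tsv"), sep="\t", index=False)
    pd.DataFrame({"miRNA": sorted(t.tn_block)}).to_csv(
        p("truth_tn_block.tsv"), sep="\t", index=False)
    pd.DataFrame({"feature": sorted(t.survival_drivers)}).to_csv(
        p("truth_survival_drivers.tsv"), sep="\t", index=False)
    pd.DataFrame(t.immune_pairs, columns=["feature", "celltype", "rho"]).to_csv(
        p("truth_immune_pairs.tsv"), sep="\t", index=False)
    pd.DataFrame(t.drug_pairs, columns=["feature", "drug", "rho"]).to_csv(
        p("truth_drug_pairs.tsv"), sep="\t", index=False)

    cfg = asdict(scn.config)
    cfg["risk_degree_range"] = list(cfg["risk_degree_range"])
    with open(p("config.yaml"), "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return paths
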