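"""Dysregulation scores with a permutation null, and the dysregulated
miRNA-target network (DMTN) built from them.

For a candidate miRNA-mRNA pair the dysregulation score is

    S = | rho_tumor - rho_normal |

where each rho is the Spearman rank correlation of the pair's expression
across the samples of that condition.  S lies in [0, 2]; large S means the
regulatory relation itself (not merely the expression level) differs
between conditions.  Significance comes from permuting the tumor/normal
partition of the samples: the p-value is the fraction of permutations
whose recomputed score meets or exceeds the observed one.  Pairs with
p < alpha form the directed bipartite miRNA->gene network.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, GroupAssignment

logger = logging.getLogger(__name__)

__all__ = [
    "ConstantVectorError",
    "rank_correlation",
    "dysregulation_scores",
    "permutation_pvalues",
    "BipartiteNetwork",
    "build_dmtn",
    "out_degree_distribution",
    "mirna_shortest_paths",
]


class ConstantVectorError(ValueError):
    """Correlation of a constant vector is undefined."""


def rank_correlation(x, y) -> float:
    """Spearman rank correlation (average ranks for ties).

    Requires equal lengths >= 3 and non-constant vectors; a constant
    vector raises :class:`ConstantVectorError` so the caller may drop the
    pair.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("vectors must be 1-D and of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantVectorError("constant vector: correlation undefined")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def _paired_corr(xm: np.ndarray, ym: np.ndarray, method: str) -> np.ndarray:
    """Row-wise correlation of two equally shaped 2-D arrays.

    Each row of ``xm`` is correlated with the matching row of ``ym``.
    Spearman is Pearson on average ranks.  Rows where either side is
    constant yield NaN.
    """
    if method == "spearman":
        xm = stats.rankdata(xm, axis=-1)
        ym = stats.rankdata(ym, axis=-1)
    xc = xm - xm.mean(axis=-1, keepdims=True)
    yc = ym - ym.mean(axis=-1, keepdims=True)
    denom = np.sqrt((xc * xc).sum(axis=-1) * (yc * yc).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc * yc).sum(axis=-1) / denom
    return r


def _group_indices(em: ExpressionMatrix, groups: GroupAssignment):
    groups.check_covers(em)
    cond = np.array([groups.condition[s] for s in em.sample_ids])
    idx_t = np.where(cond == "tumor")[0]
    idx_n = np.where(cond == "normal")[0]
    return idx_t, idx_n


def dysregulation_scores(
    em_mirna: ExpressionMatrix,
    em_gene: ExpressionMatrix,
    pairs: pd.DataFrame,
    groups: GroupAssignment,
    method: str = "spearman",
) -> pd.DataFrame:
    """Per-pair condition correlations and dysregulation scores.

    Pairs whose miRNA or gene is absent from the matrices, or whose
    expression is constant within a condition, are skipped with a logged
    count.  Returns a DataFrame with columns ``miRNA``, ``gene``,
    ``rho_tumor``, ``rho_normal`` and ``score``.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown correlation method {method!r}")
    if em_mirna.sample_ids != em_gene.sample_ids:
        # align gene matrix onto the miRNA sample order
        em_gene = em_gene.subset_samples(em_mirna.sample_ids)
    idx_t, idx_n = _group_indices(em_mirna, groups)
    if len(idx_t) < 3 or len(idx_n) < 3:
        raise ValueError("need at least 3 tumor and 3 normal samples")

    mir_pos = {m: i for i, m in enumerate(em_mirna.feature_ids)}
    gene_pos = {g: i for i, g in enumerate(em_gene.feature_ids)}
    rows = pairs[["miRNA", "gene"]].to_numpy()
    keep = np.array([(m in mir_pos) and (g in gene_pos) for m, g in rows])
    n_missing = int((~keep).sum())
    if n_missing:
        logger.info("skipped %d pairs with ids missing from the matrices", n_missing)
    rows = rows[keep]
    if len(rows) == 0:
        raise ValueError("no evaluable pair")

    X = em_mirna.values[[mir_pos[m] for m, _ in rows]]
    Y = em_gene.values[[gene_pos[g] for _, g in rows]]
    rho_t = _paired_corr(X[:, idx_t], Y[:, idx_t], method)
    rho_n = _paired_corr(X[:, idx_n], Y[:, idx_n], method)
    ok = np.isfinite(rho_t) & np.isfinite(rho_n)
    n_const = int((~ok).sum())
    if n_const:
        logger.info("skipped %d pairs with a constant within-condition vector", n_const)
    out = pd.DataFrame(
        {
            "miRNA": rows[ok, 0],
            "gene": rows[ok, 1],
            "rho_tumor": rho_t[ok],
            "rho_normal": rho_n[ok],
        }
    )
    out["score"] = np.abs(out["rho_tumor"] - out["rho_normal"])
    if len(out) == 0:
        raise ValueError("no evaluable pair")
    return out


# Comparison guard for the permutation count: ties in S count against the
# observed score; the epsilon only absorbs float round-off between two
# computations of the same quantity.
_TIE_EPS = 1e-12


def _pair_perm_p(
    x: np.ndarray,
    y: np.ndarray,
    n_t: int,
    s_obs: float,
    rng: np.random.Generator,
    n_perm: int,
    method: str,
) -> float:
    """Monte-Carlo permutation p for one pair (vectorized over permutations)."""
    n = len(x)
    u = rng.random((n_perm, n))
    order = np.argsort(u, axis=1)
    xt = x[order[:, :n_t]]
    yt = y[order[:, :n_t]]
    xn = x[order[:, n_t:]]
    yn = y[order[:, n_t:]]
    rt = _paired_corr(xt, yt, method)
    rn = _paired_corr(xn, yn, method)
    s_perm = np.abs(np.nan_to_num(rt) - np.nan_to_num(rn))
    return float(np.mean(s_perm >= s_obs - _TIE_EPS))


def _pair_exhaustive_p(
    x: np.ndarray, y: np.ndarray, n_t: int, s_obs: float, method: str
) -> float:
    n = len(x)
    parts = list(combinations(range(n), n_t))
    count = 0
    for t in parts:
        t = np.array(t)
        comp = np.setdiff1d(np.arange(n), t, assume_unique=True)
        rt = _paired_corr(x[t][None, :], y[t][None, :], method)[0]
        rn = _paired_corr(x[comp][None, :], y[comp][None, :], method)[0]
        s = abs(np.nan_to_num(rt) - np.nan_to_num(rn))
        if s >= s_obs - _TIE_EPS:
            count += 1
    return count / len(parts)


def permutation_pvalues(
    records: pd.DataFrame,
    em_mirna: ExpressionMatrix,
    em_gene: ExpressionMatrix,
    groups: GroupAssignment,
    n_perm: int = 10_000,
    seed: int = 0,
    exhaustive: bool = False,
    max_partitions: int = 50_000,
    method: str = "spearman",
    pseudocount: bool = False,
) -> pd.DataFrame:
    """Attach permutation p-values to a dysregulation-score table.

    The tumor/normal partition of the samples is shuffled jointly for the
    miRNA and mRNA vectors (sample identity is preserved, group sizes are
    kept fixed) and the score recomputed; ``p_perm`` is the fraction of
    permutations with a score at least as large as the observed one.  Each
    pair draws its permutations from an independent stream derived from
    ``(seed, pair index)``, so results are reproducible regardless of
    evaluation order.

    ``exhaustive`` enumerates every distinct partition instead (only
    allowed when their number is at most ``max_partitions``).
    ``pseudocount`` switches to the (b+1)/(n+1) estimator, which cannot
    return an exact zero.
    """
    if not exhaustive and n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if em_mirna.sample_ids != em_gene.sample_ids:
        em_gene = em_gene.subset_samples(em_mirna.sample_ids)
    idx_t, idx_n = _group_indices(em_mirna, groups)
    n = len(idx_t) + len(idx_n)
    order = np.concatenate([idx_t, idx_n])
    n_t = len(idx_t)

    if exhaustive:
        n_part = math.comb(n, n_t)
        if n_part > max_partitions:
            raise ValueError(
                f"{n_part} partitions exceed the exhaustive cap {max_partitions}"
            )

    mir = em_mirna.data.to_numpy(dtype=float)
    gene = em_gene.data.to_numpy(dtype=float)
    mir_pos = {m: i for i, m in enumerate(em_mirna.feature_ids)}
    gene_pos = {g: i for i, g in enumerate(em_gene.feature_ids)}

    out = records.copy()
    pvals = np.empty(len(out))
    for i, (m, g) in enumerate(zip(out["miRNA"], out["gene"])):
        # samples reordered tumor-first so the first n_t slots are "tumor"
        x = mir[mir_pos[m]][order]
        y = gene[gene_pos[g]][order]
        rt = _paired_corr(x[:n_t][None, :], y[:n_t][None, :], method)[0]
        rn = _paired_corr(x[n_t:][None, :], y[n_t:][None, :], method)[0]
        s_obs = abs(np.nan_to_num(rt) - np.nan_to_num(rn))
        if exhaustive:
            pvals[i] = _pair_exhaustive_p(x, y, n_t, s_obs, method)
        else:
            rng = np.random.default_rng([seed, i])
            p = _pair_perm_p(x, y, n_t, s_obs, rng, n_perm, method)
            if pseudocount:
                p = (p * n_perm + 1) / (n_perm + 1)
            pvals[i] = p
    out["p_perm"] = pvals
    out["n_perm"] = math.comb(n, n_t) if exhaustive else n_perm
    return out


@dataclass
class BipartiteNetwork:
    """Directed bipartite miRNA -> gene network (the DMTN).

    Wraps a :class:`networkx.DiGraph` whose nodes carry a ``side``
    attribute (``"miRNA"`` or ``"gene"``).  Edge duplication is impossible
    by construction; isolated nodes are never stored.
    """

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)

    @classmethod
    def from_edges(cls, edges) -> "BipartiteNetwork":
        g = nx.DiGraph()
        for m, t in edges:
            g.add_node(m, side="miRNA")
            g.add_node(t, side="gene")
            g.add_edge(m, t)
        return cls(g)

    @property
    def mirnas(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d["side"] == "miRNA"}

    @property
    def genes(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d["side"] == "gene"}

    @property
    def edges(self) -> set[tuple[str, str]]:
        return set(self.graph.edges())

    def targets(self, mirna: str) -> set[str]:
        return set(self.graph.successors(mirna))

    def regulators(self, gene: str) -> set[str]:
        return set(self.graph.predecessors(gene))

    def out_degree(self, mirna: str) -> int:
        return self.graph.out_degree(mirna)

    def neighbor_genes(self, mirnas) -> set[str]:
        """One-step neighbor genes of a set of miRNAs."""
        out: set[str] = set()
        for m in mirnas:
            if m in self.graph:
                out |= self.targets(m)
        return out

    def to_frame(self) -> pd.DataFrame:
        e = sorted(self.graph.edges())
        return pd.DataFrame(e, columns=["miRNA", "gene"])


def build_dmtn(records: pd.DataFrame, alpha: float = 0.05) -> BipartiteNetwork:
    """Keep edges with permutation p strictly below ``alpha``."""
    if "p_perm" not in records.columns:
        raise ValueError("records carry no p_perm column; run permutation_pvalues first")
    sig = records[records["p_perm"] < alpha]
    return BipartiteNetwork.from_edges(zip(sig["miRNA"], sig["gene"]))


def out_degree_distribution(net: BipartiteNetwork):
    """Out-degree histogram of the miRNA nodes and a log-log OLS slope.

    Returns ``(hist, slope)`` where ``hist`` maps degree -> number of
    miRNAs and ``slope`` is the ordinary-least-squares slope of
    log10(count) on log10(degree) over degrees with nonzero count (a
    descriptive statistic only; NaN when fewer than two distinct degrees).
    """
    mirnas = net.mirnas
    if not mirnas:
        raise ValueError("empty network")
    degs = [net.out_degree(m) for m in mirnas]
    hist: dict[int, int] = {}
    for d in degs:
        hist[d] = hist.get(d, 0) + 1
    pts = [(d, c) for d, c in sorted(hist.items()) if d > 0]
    if len(pts) < 2:
        slope = float("nan")
    else:
        lx = np.log10([d for d, _ in pts])
        ly = np.log10([c for _, c in pts])
        slope = float(np.polyfit(lx, ly, 1)[0])
    return hist, slope


def mirna_shortest_paths(net: BipartiteNetwork):
    """Histogram of pairwise shortest-path lengths between miRNA nodes.

    Path length is counted in edges on the undirected view of the
    bipartite graph, so two miRNAs sharing a target are at distance 2.
    Returns ``(hist, n_unreachable)``; unreachable pairs are counted
    separately, never as a histogram bin.
    """
    und = net.graph.to_undirected(as_view=True)
    mirnas = sorted(net.mirnas)
    hist: dict[int, int] = {}
    unreachable = 0
    for i, src in enumerate(mirnas):
        dist = nx.single_source_shortest_path_length(und, src)
        for dst in mirnas[i + 1 :]:
            if dst in dist:
                d = dist[dst]
                hist[d] = hist.get(d, 0) + 1
            else:
                unreachable += 1
    return hist, unreachable
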