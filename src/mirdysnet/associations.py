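"""Correlation screens linking feature expression to phenotypes.

Two screens share one machinery:

* immune infiltration — Spearman correlation between each feature's
  expression and each immune-cell abundance across shared samples;
* drug response — Pearson correlation between each feature's expression
  and each drug's log-IC50 across shared cell lines, with a significance
  rule of |r| >= 0.2 (inclusive) and BH-adjusted p < 0.05.

A negative drug-screen correlation means high expression tracks lower
IC50, i.e. more drug-sensitive lines.  Missing IC50 entries are handled
pairwise-complete with a minimum-n guard.  q-values are adjusted across
the whole screen, never pooled across screens.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix
from .setstats import bh_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "read_abundance",
    "read_drug_response",
    "immune_associations",
    "drug_associations",
    "group_compare",
]


def read_abundance(path, fractional: bool = True) -> pd.DataFrame:
    """Read a samples-by-cell-types abundance TSV (CIBERSORT-like).

    When ``fractional`` each row must sum to 1 within 1e-6.
    """
    df = pd.read_csv(path, sep="\t", index_col=0).astype(float)
    if (df.to_numpy() < 0).any():
        raise ValueError("negative abundance")
    if fractional:
        sums = df.sum(axis=1).to_numpy()
        if np.abs(sums - 1.0).max() > 1e-6:
            raise ValueError("abundance rows do not sum to 1")
    return df


def read_drug_response(path) -> pd.DataFrame:
    """Read a cell-lines-by-drugs log-IC50 TSV; empty cells are missing."""
    return pd.read_csv(path, sep="\t", index_col=0).astype(float)


def _screen(
    em: ExpressionMatrix,
    pheno: pd.DataFrame,
    method: str,
    r_min: float,
    alpha: float,
    min_n: int,
) -> pd.DataFrame:
    shared = [s for s in em.sample_ids if s in pheno.index]
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared samples")
    expr = em.data[shared]
    ph = pheno.loc[shared]
    corr = stats.spearmanr if method == "spearman" else stats.pearsonr
    rows = []
    for feat, fv in expr.iterrows():
        fvals = fv.to_numpy(dtype=float)
        for col in ph.columns:
            pv = ph[col].to_numpy(dtype=float)
            mask = np.isfinite(pv) & np.isfinite(fvals)
            n = int(mask.sum())
            if n < max(min_n, 3):
                logger.info("pair (%s, %s) skipped: n=%d below minimum", feat, col, n)
                continue
            x, y = fvals[mask], pv[mask]
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                logger.info("pair (%s, %s) skipped: constant vector", feat, col)
                continue
            res = corr(x, y)
            rows.append(
                {
                    "feature": feat,
                    "phenotype": col,
                    "method": method,
                    "n": n,
                    "r": float(res.statistic),
                    "p": float(res.pvalue),
                }
            )
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = bh_adjust(out["p"].to_numpy())
        # the magnitude threshold is inclusive; the epsilon only absorbs
        # float round-off for correlations constructed exactly at r_min
        out["significant"] = (out["r"].abs() >= r_min - 1e-12) & (out["q"] < alpha)
    return out


def immune_associations(
    em: ExpressionMatrix,
    abundance: pd.DataFrame,
    alpha: float = 0.05,
    method: str = "spearman",
) -> pd.DataFrame:
    """Feature-expression vs immune-cell-abundance Spearman screen.

    One record per (feature, cell type) over shared samples; q-values are
    BH-adjusted across the whole screen; significance is q < alpha (no
    magnitude threshold for the immune screen).
    """
    return _screen(em, abundance, method=method, r_min=0.0, alpha=alpha, min_n=3)


def drug_associations(
    em: ExpressionMatrix,
    drugs: pd.DataFrame,
    method: str = "pearson",
    r_min: float = 0.2,
    alpha: float = 0.05,
    min_n: int = 20,
) -> pd.DataFrame:
    """Feature-expression vs drug log-IC50 correlation screen.

    Pairwise-complete over shared cell lines; pairs with fewer than
    ``min_n`` paired observations are skipped.  Significant iff
    |r| >= r_min (inclusive) and BH q < alpha.
    """
    return _screen(em, drugs, method=method, r_min=r_min, alpha=alpha, min_n=min_n)


def group_compare(values, groups):
    """Two-sided Wilcoxon rank-sum comparison of values across two groups.

    ``groups`` is a boolean vector (True = first group); both groups need
    at least 3 members.  Returns ``(statistic, p)``.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups, dtype=bool)
    a, b = values[groups], values[~groups]
    if len(a) < 3 or len(b) < 3:
        raise ValueError("both groups need at least 3 members")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)
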