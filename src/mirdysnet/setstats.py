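"""Hypergeometric set-overlap tests, Benjamini-Hochberg adjustment, and
generic annotation enrichment.

The overlap model: a universe of N ids, an investigated set of size K, an
"interesting" set of size M, observed overlap x.  The upper-tail
probability P(X >= x) under Hypergeometric(N, M, K) scores the surprise
of the overlap; it is computed in log space for stability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "OverlapResult",
    "hypergeom_upper_tail",
    "overlap_test",
    "bh_adjust",
    "enrich",
    "read_gmt",
]


@dataclass
class OverlapResult:
    """Overlap of an investigated set (K) with an interesting set (M)."""

    universe_size: int
    set_size: int
    interest_size: int
    overlap: int
    expected: float
    fold_enrichment: float
    p_upper: float
    overlap_percent: float


def _check_overlap_input(N: int, K: int, M: int, x: int) -> None:
    if min(N, K, M, x) < 0:
        raise ValueError("negative count")
    if K > N or M > N:
        raise ValueError("set larger than universe")
    if x > min(K, M):
        raise ValueError("overlap larger than the smaller set")


def hypergeom_upper_tail(N: int, K: int, M: int, x: int) -> float:
    """P(X >= x) for X ~ Hypergeometric(N, M, K).

    The tail includes x itself (the enrichment convention).  x = 0 covers
    the whole support, so the result is exactly 1.
    """
    _check_overlap_input(N, K, M, x)
    if x == 0:
        return 1.0
    hi = min(K, M)
    t = np.arange(x, hi + 1)
    logp = hypergeom.logpmf(t, N, M, K)
    p = float(np.exp(logsumexp(logp)))
    return min(p, 1.0)


def overlap_test(set_a, set_b, universe) -> OverlapResult:
    """Hypergeometric overlap test of two id sets within a universe.

    Elements of either set absent from the universe are dropped with a
    logged count (they do not enlarge N).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    a, b = set(set_a), set(set_b)
    stray = len(a - universe) + len(b - universe)
    if stray:
        logger.warning("dropped %d set elements absent from the universe", stray)
    a &= universe
    b &= universe
    N, K, M = len(universe), len(a), len(b)
    x = len(a & b)
    expected = K * M / N
    return OverlapResult(
        universe_size=N,
        set_size=K,
        interest_size=M,
        overlap=x,
        expected=expected,
        fold_enrichment=(x / expected) if expected > 0 else float("nan"),
        p_upper=hypergeom_upper_tail(N, K, M, x),
        overlap_percent=100.0 * x / K if K else float("nan"),
    )


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(query, annotation: dict, universe, alpha: float = 0.05) -> pd.DataFrame:
    """Hypergeometric enrichment of a query set against named annotation sets.

    One overlap test per term; q-values are BH-adjusted across the terms
    of this run only.  Returns a DataFrame sorted by p with columns
    ``term, overlap, set_size, interest_size, expected, p, q, significant``.
    """
    if not annotation:
        raise ValueError("empty annotation")
    universe = set(universe)
    rows = []
    for term, members in annotation.items():
        res = overlap_test(query, members, universe)
        rows.append(
            {
                "term": term,
                "overlap": res.overlap,
                "set_size": res.set_size,
                "interest_size": res.interest_size,
                "expected": res.expected,
                "p": res.p_upper,
            }
        )
    table = pd.DataFrame(rows)
    table["q"] = bh_adjust(table["p"].to_numpy())
    table["significant"] = table["q"] < alpha
    return table.sort_values("p", kind="stable").reset_index(drop=True)


def read_gmt(path) -> dict[str, set[str]]:
    """Read a GMT file (term, description, members...) into term -> id set."""
    out: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            out[parts[0]] = {m for m in parts[2:] if m}
    if not out:
        raise ValueError(f"no annotation sets in {path}")
    return out
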