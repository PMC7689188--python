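"""Tabular input/output and the low-expression filter.

Expression tables are plain TSV: a header row of sample ids, the first
column holding feature ids, and a non-negative numeric body (normalized
expression, unitless).  Matching group-assignment, candidate-pair and
clinical tables use small two/three-column TSV dialects documented on the
respective readers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TUMOR = "tumor"
NORMAL = "normal"


class ExpressionError(ValueError):
    """Raised when an expression table violates a structural invariant."""


@dataclass
class ExpressionMatrix:
    """A features-by-samples matrix of non-negative normalized expression.

    Parameters
    ----------
    data
        DataFrame with feature ids as the index and sample ids as columns.
    kind
        Feature kind tag, ``"miRNA"`` or ``"mRNA"``.
    """

    data: pd.DataFrame
    kind: str = "miRNA"

    def __post_init__(self) -> None:
        if self.kind not in ("miRNA", "mRNA"):
            raise ExpressionError(f"unknown feature kind {self.kind!r}")
        idx = self.data.index
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise ExpressionError(f"duplicate feature ids: {dups[:5]}")
        cols = self.data.columns
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise ExpressionError(f"duplicate sample ids: {dups[:5]}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ExpressionError("non-numeric cell in expression table")
        if np.isnan(values).any():
            raise ExpressionError("missing value in expression table")
        if (values < 0).any():
            raise ExpressionError("negative expression")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_features(self, feature_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[list(feature_ids)], self.kind)

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data[list(sample_ids)], self.kind)


@dataclass
class GroupAssignment:
    """Per-sample condition labels (``tumor`` / ``normal``)."""

    condition: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {c for c in self.condition.values() if c not in (TUMOR, NORMAL)}
        if bad:
            raise ValueError(f"unknown condition labels: {sorted(bad)}")

    @property
    def tumor_samples(self) -> list[str]:
        return [s for s, c in self.condition.items() if c == TUMOR]

    @property
    def normal_samples(self) -> list[str]:
        return [s for s, c in self.condition.items() if c == NORMAL]

    def check_covers(self, em: ExpressionMatrix) -> None:
        missing = [s for s in em.sample_ids if s not in self.condition]
        if missing:
            raise ValueError(f"samples without condition label: {missing[:5]}")


def read_expression(path, kind: str = "miRNA") -> ExpressionMatrix:
    """Read a features-by-samples TSV into a validated :class:`ExpressionMatrix`.

    Duplicated feature ids are an error, never silently collapsed.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise ExpressionError(f"non-numeric cell in {path}: {exc}") from exc
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(df, kind)


def write_expression(em: ExpressionMatrix, path) -> None:
    em.data.to_csv(path, sep="\t", float_format="%.10g")


def read_groups(path) -> GroupAssignment:
    """Read a two-column TSV (``sample``, ``condition``)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample", "condition"} <= set(df.columns):
        raise ValueError("group table must have columns 'sample' and 'condition'")
    if df["sample"].duplicated().any():
        raise ValueError("duplicate sample in group table")
    return GroupAssignment(dict(zip(df["sample"], df["condition"])))


def write_groups(groups: GroupAssignment, path) -> None:
    pd.DataFrame(
        {"sample": list(groups.condition), "condition": list(groups.condition.values())}
    ).to_csv(path, sep="\t", index=False)


def read_pairs(path) -> pd.DataFrame:
    """Read a candidate miRNA-mRNA pair list (columns ``miRNA``, ``gene``
    and optional ``support``), de-duplicating pairs."""
    df = pd.read_csv(path, sep="\t", dtype={"miRNA": str, "gene": str})
    if not {"miRNA", "gene"} <= set(df.columns):
        raise ValueError("pair table must have columns 'miRNA' and 'gene'")
    if (df["miRNA"].str.len() == 0).any() or (df["gene"].str.len() == 0).any():
        raise ValueError("empty id in pair table")
    n0 = len(df)
    df = df.drop_duplicates(subset=["miRNA", "gene"]).reset_index(drop=True)
    if len(df) < n0:
        logger.info("dropped %d duplicate candidate pairs", n0 - len(df))
    if "support" in df.columns and (df["support"].astype(int) < 0).any():
        raise ValueError("negative support count")
    return df


def write_pairs(pairs: pd.DataFrame, path) -> None:
    pairs.to_csv(path, sep="\t", index=False)


def filter_zero_fraction(
    em: ExpressionMatrix,
    groups: GroupAssignment,
    max_zero_frac: float = 0.10,
    on_all_samples: bool = False,
) -> ExpressionMatrix:
    """Drop features with too many exact zeros among normal samples.

    A feature is removed iff the fraction of normal samples in which its
    value is exactly 0.0 exceeds ``max_zero_frac`` (strict inequality: a
    feature with exactly that fraction of zeros is kept).  Tumor samples
    never influence the decision unless ``on_all_samples`` is set.  The
    order of surviving features is preserved.
    """
    groups.check_covers(em)
    if on_all_samples:
        ref = em.data
    else:
        normals = [s for s in em.sample_ids if groups.condition[s] == NORMAL]
        if not normals:
            raise ValueError("zero normal samples: cannot apply the zero-fraction filter")
        ref = em.data[normals]
    zero_frac = (ref.to_numpy() == 0.0).mean(axis=1)
    keep = zero_frac <= max_zero_frac
    if not keep.all():
        logger.info(
            "zero-fraction filter removed %d of %d %s features",
            int((~keep).sum()), em.n_features, em.kind,
        )
    return ExpressionMatrix(em.data.loc[keep], em.kind)
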