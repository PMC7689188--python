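"""Risk-miRNA classification from network features.

The training labels are built from the network itself: true positives
(TP) are curated disease miRNAs that appear in the dysregulated network;
true negatives (TN) are network miRNAs with the lowest combined ranks of
mean expression and variance (computed over all, tumor-only and
normal-only samples — six rankings in total), i.e. miRNAs that are both
lowly and stably expressed and therefore unlikely to be functional.

Five per-miRNA features feed an RBF-kernel support-vector machine whose
cost and kernel-width hyperparameters are tuned by a small real-coded
genetic algorithm maximizing mean cross-validated AUC:

* out-degree in the network,
* number of co-regulating miRNAs (sharing at least one target),
* percentage of those co-regulators that are disease miRNAs,
* number of own targets also targeted by a disease miRNA,
* log2 fold change of mean tumor vs normal expression (pseudo-count 1).

Scores are mapped to [0, 1] with a Platt-style sigmoid fitted within
cross-validation, and the recognition threshold is set just above the
highest score of any TN miRNA, so no TN is ever called risk.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.calibration import CalibratedClassifierCV
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .dysregulation import BipartiteNetwork
from .io import ExpressionMatrix, GroupAssignment

logger = logging.getLogger(__name__)

FEATURE_NAMES = [
    "out_degree",
    "n_coreg",
    "pct_coreg_disease",
    "n_genes_disease_reg",
    "log2_fc",
]

__all__ = [
    "FEATURE_NAMES",
    "LabelSets",
    "GAConfig",
    "ModelBundle",
    "select_true_positives",
    "rank_sum_negatives",
    "finalize_negatives",
    "compute_features",
    "train_classifier",
    "recognition_threshold",
    "predict_risk",
    "evaluate_auc",
]


@dataclass
class LabelSets:
    """Disjoint TP/TN miRNA id sets, both inside the network."""

    tp: set[str]
    tn: set[str]

    def __post_init__(self) -> None:
        self.tp = set(self.tp)
        self.tn = set(self.tn)
        if self.tp & self.tn:
            raise ValueError("TP and TN sets overlap")


@dataclass
class GAConfig:
    """Real-coded GA over (log10 C, log10 gamma) for the RBF SVM."""

    population: int = 20
    generations: int = 15
    log_c_range: tuple[float, float] = (-2.0, 3.0)
    log_gamma_range: tuple[float, float] = (-3.0, 1.0)
    tournament: int = 3
    crossover_prob: float = 0.5
    mutation_sigma: float = 0.3
    mutation_prob: float = 0.5
    elitism: int = 2


@dataclass
class ModelBundle:
    """A fitted, Platt-calibrated SVM plus its tuning record."""

    pipeline: Pipeline
    feature_names: list[str]
    log_c: float
    log_gamma: float
    fold_aucs: list[float]
    cv_auc: float
    recognition_threshold: float | None = None
    kernel: str = "rbf"

    def predict_score(self, features: pd.DataFrame) -> pd.Series:
        """Probability-like risk score in [0, 1] per miRNA."""
        missing = [c for c in self.feature_names if c not in features.columns]
        if missing:
            raise ValueError(f"feature columns missing: {missing}")
        X = features[self.feature_names].to_numpy(dtype=float)
        scores = self.pipeline.predict_proba(X)[:, 1]
        return pd.Series(scores, index=features.index, name="score")

    def summary(self) -> dict:
        return {
            "kernel": self.kernel,
            "C": 10.0 ** self.log_c,
            "gamma": 10.0 ** self.log_gamma,
            "fold_aucs": list(self.fold_aucs),
            "cv_auc": self.cv_auc,
            "recognition_threshold": self.recognition_threshold,
            "feature_names": list(self.feature_names),
        }


def select_true_positives(curated_lists, net: BipartiteNetwork) -> set[str]:
    """Union of curated disease-miRNA lists, restricted to network miRNAs."""
    lists = [set(l) for l in curated_lists]
    if not lists or all(not l for l in lists):
        raise ValueError("curated lists are empty")
    merged = set().union(*lists)
    tp = merged & net.mirnas
    if not tp:
        logger.warning("no curated miRNA appears in the network; TP set is empty")
    return tp


def rank_sum_negatives(
    em_mirna: ExpressionMatrix, groups: GroupAssignment, k: int = 95
) -> list[str]:
    """The k miRNAs with the lowest sum of six expression ranks.

    For each of three sample sets (all, tumor-only, normal-only) the
    miRNAs are ranked by mean expression and by variance across samples
    (rank 1 = smallest, average ranks for ties); the selection score is
    the sum of the six ranks.  Ties in the sum are broken by miRNA id.
    """
    groups.check_covers(em_mirna)
    if k > em_mirna.n_features:
        raise ValueError(f"k={k} exceeds the {em_mirna.n_features} available miRNAs")
    sample_sets = {
        "all": em_mirna.sample_ids,
        "tumor": [s for s in em_mirna.sample_ids if groups.condition[s] == "tumor"],
        "normal": [s for s in em_mirna.sample_ids if groups.condition[s] == "normal"],
    }
    total = np.zeros(em_mirna.n_features)
    for samples in sample_sets.values():
        sub = em_mirna.data[samples].to_numpy(dtype=float)
        total += rankdata(sub.mean(axis=1)) + rankdata(sub.var(axis=1))
    order = sorted(zip(total, em_mirna.feature_ids))
    return [m for _, m in order[:k]]


def finalize_negatives(candidates, tp: set[str], net: BipartiteNetwork) -> list[str]:
    """Drop TP members and miRNAs outside the network; order preserved."""
    mirnas = net.mirnas
    out = [c for c in candidates if c not in tp and c in mirnas]
    if not out:
        logger.warning("finalize_negatives produced an empty TN set")
    return out


def compute_features(
    net: BipartiteNetwork,
    em_mirna: ExpressionMatrix,
    groups: GroupAssignment,
    disease_set: set[str],
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """The five classifier features for every miRNA in the network."""
    groups.check_covers(em_mirna)
    disease_set = set(disease_set)
    mirnas = sorted(net.mirnas)
    missing = [m for m in mirnas if m not in em_mirna.data.index]
    if missing:
        raise ValueError(f"miRNA missing from expression matrix: {missing[0]}")

    tumor = [s for s in em_mirna.sample_ids if groups.condition[s] == "tumor"]
    normal = [s for s in em_mirna.sample_ids if groups.condition[s] == "normal"]
    mean_t = em_mirna.data.loc[mirnas, tumor].mean(axis=1)
    mean_n = em_mirna.data.loc[mirnas, normal].mean(axis=1)

    targets = {m: net.targets(m) for m in mirnas}
    rows = []
    for m in mirnas:
        tgt = targets[m]
        coreg = {
            other
            for g in tgt
            for other in net.regulators(g)
            if other != m
        }
        n_coreg = len(coreg)
        pct = len(coreg & disease_set) / n_coreg if n_coreg else 0.0
        n_dis_genes = sum(
            1
            for g in tgt
            if any(r != m and r in disease_set for r in net.regulators(g))
        )
        rows.append(
            {
                "miRNA": m,
                "out_degree": len(tgt),
                "n_coreg": n_coreg,
                "pct_coreg_disease": pct,
                "n_genes_disease_reg": n_dis_genes,
                "log2_fc": math.log2(
                    (mean_t[m] + pseudocount) / (mean_n[m] + pseudocount)
                ),
            }
        )
    return pd.DataFrame(rows).set_index("miRNA")


def evaluate_auc(scores, labels) -> float:
    """Area under the ROC curve via the Mann-Whitney U statistic.

    Equals P(score_pos > score_neg) + 0.5 P(tie) over all positive/negative
    pairs.  Both classes must be present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("single class: AUC undefined")
    r = rankdata(scores)
    u = r[labels == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def _build_xy(features: pd.DataFrame, labels: LabelSets):
    ids = sorted(labels.tp) + sorted(labels.tn)
    missing = [m for m in ids if m not in features.index]
    if missing:
        raise ValueError(f"labeled miRNA without features: {missing[0]}")
    X = features.loc[ids, FEATURE_NAMES].to_numpy(dtype=float)
    y = np.array([1] * len(labels.tp) + [0] * len(labels.tn))
    return ids, X, y


def _cv_auc(X, y, log_c, log_gamma, splits) -> tuple[list[float], float]:
    """Mean cross-validated AUC with per-fold standardization (no leakage)."""
    fold_aucs = []
    for tr, te in splits:
        clf = Pipeline(
            [
                ("scale", StandardScaler()),
                ("svm", SVC(kernel="rbf", C=10.0 ** log_c, gamma=10.0 ** log_gamma)),
            ]
        )
        clf.fit(X[tr], y[tr])
        fold_aucs.append(evaluate_auc(clf.decision_function(X[te]), y[te]))
    return fold_aucs, float(np.mean(fold_aucs))


def train_classifier(
    features: pd.DataFrame,
    labels: LabelSets,
    folds: int = 5,
    ga: GAConfig | None = None,
    seed: int = 0,
) -> ModelBundle:
    """GA-tuned RBF SVM with stratified k-fold cross-validation.

    The GA evolves (log10 C, log10 gamma) with tournament selection,
    uniform crossover, Gaussian mutation and elitism; fitness is the mean
    cross-validated AUC on fixed stratified folds.  The returned model is
    refit on all labeled miRNAs with Platt-calibrated probability output.
    Deterministic given ``seed``.
    """
    ga = ga or GAConfig()
    if folds < 2:
        raise ValueError("folds must be >= 2")
    ids, X, y = _build_xy(features, labels)
    if len(set(y)) < 2:
        raise ValueError("single class: cannot train")
    if min((y == 1).sum(), (y == 0).sum()) < folds:
        raise ValueError("each class needs at least `folds` members")

    rng = np.random.default_rng([seed, 0xC1A55])
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed % (2**31))
    splits = list(skf.split(X, y))

    lo = np.array([ga.log_c_range[0], ga.log_gamma_range[0]])
    hi = np.array([ga.log_c_range[1], ga.log_gamma_range[1]])
    pop = rng.uniform(lo, hi, size=(ga.population, 2))
    cache: dict[tuple[float, float], float] = {}

    def fitness(ind) -> float:
        key = (round(ind[0], 6), round(ind[1], 6))
        if key not in cache:
            cache[key] = _cv_auc(X, y, ind[0], ind[1], splits)[1]
        return cache[key]

    fits = np.array([fitness(ind) for ind in pop])
    for _ in range(ga.generations):
        elite_idx = np.argsort(fits)[::-1][: ga.elitism]
        children = [pop[i].copy() for i in elite_idx]
        while len(children) < ga.population:
            # tournament selection of two parents
            parents = []
            for _ in range(2):
                contenders = rng.integers(0, ga.population, ga.tournament)
                parents.append(pop[contenders[np.argmax(fits[contenders])]])
            child = np.where(
                rng.random(2) < ga.crossover_prob, parents[0], parents[1]
            ).astype(float)
            mutate = rng.random(2) < ga.mutation_prob
            child = child + mutate * rng.normal(0.0, ga.mutation_sigma, 2)
            children.append(np.clip(child, lo, hi))
        pop = np.array(children)
        fits = np.array([fitness(ind) for ind in pop])

    best = pop[int(np.argmax(fits))]
    fold_aucs, cv_auc = _cv_auc(X, y, best[0], best[1], splits)
    # Platt-style sigmoid fitted within cross-validation maps the margin
    # to a probability-like score in [0, 1].
    calib_cv = min(folds, int((y == 1).sum()), int((y == 0).sum()))
    final = Pipeline(
        [
            ("scale", StandardScaler()),
            (
                "svm",
                CalibratedClassifierCV(
                    SVC(kernel="rbf", C=10.0 ** best[0], gamma=10.0 ** best[1]),
                    method="sigmoid",
                    cv=calib_cv,
                    ensemble=False,
                ),
            ),
        ]
    )
    final.fit(X, y)
    return ModelBundle(
        pipeline=final,
        feature_names=list(FEATURE_NAMES),
        log_c=float(best[0]),
        log_gamma=float(best[1]),
        fold_aucs=fold_aucs,
        cv_auc=cv_auc,
    )


def recognition_threshold(model: ModelBundle, tn_features: pd.DataFrame) -> float:
    """Smallest score cutoff at which no TN miRNA is called risk.

    Defined as the maximum score assigned to any TN example, nudged up by
    one representable float so that a strict ``score > threshold`` rule
    labels zero TN positive.
    """
    if len(tn_features) == 0:
        raise ValueError("tn_features is empty")
    scores = model.predict_score(tn_features)
    thr = float(np.nextafter(scores.max(), np.inf))
    model.recognition_threshold = thr
    return thr


def predict_risk(
    model: ModelBundle, features: pd.DataFrame, threshold: float
) -> pd.DataFrame:
    """Score every miRNA; risk iff score > threshold (sorted by score)."""
    scores = model.predict_score(features)
    out = pd.DataFrame({"score": scores})
    out["risk"] = out["score"] > threshold
    return out.sort_values("score", ascending=False, kind="stable")
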