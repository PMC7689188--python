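"""Median-split survival screens: Kaplan-Meier curves and log-rank tests.

Each feature's samples are split at the median expression value (ties go
to the low group), and the survival experience of the two groups is
compared with the standard one-degree-of-freedom log-rank test.  The
product-limit estimation and the log-rank statistic are delegated to
lifelines.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from lifelines.utils import restricted_mean_survival_time

from .io import ExpressionMatrix
from .setstats import bh_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "read_clinical",
    "median_split",
    "km_curve",
    "logrank_test",
    "survival_screen",
]


def read_clinical(path) -> pd.DataFrame:
    """Read a clinical TSV (``sample``, ``time`` in days, ``event`` 0/1)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str})
    if not {"sample", "time", "event"} <= set(df.columns):
        raise ValueError("clinical table needs columns sample, time, event")
    df = df.set_index("sample")
    if (df["time"] < 0).any():
        raise ValueError("negative survival time")
    if not df["event"].isin((0, 1)).all():
        raise ValueError("event must be 0 (censored) or 1 (death)")
    return df


def median_split(values) -> np.ndarray:
    """Boolean labels: True = low group (value <= median).

    The median is the average of the middle order statistics for even n.
    All-identical values raise a degenerate-split error.
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("need at least 2 samples to split")
    if np.ptp(v) == 0:
        raise ValueError("degenerate split: all values identical")
    return v <= np.median(v)


def km_curve(times, events):
    """Kaplan-Meier product-limit estimate.

    Returns ``(t, s)`` arrays forming the step function, starting at
    (0, 1).  Censored times reduce the risk set without a step; ties
    between events and censorings at the same time are resolved with
    events first (the lifelines convention).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) == 0:
        raise ValueError("empty survival data")
    if (times < 0).any() or not np.isfinite(times).all():
        raise ValueError("times must be finite and non-negative")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    sf = kmf.survival_function_
    return sf.index.to_numpy(dtype=float), sf.iloc[:, 0].to_numpy(dtype=float)


def logrank_test(times_a, events_a, times_b, events_b):
    """Two-group log-rank test; returns ``(chi2, p)``.

    With no events in either group the test is undefined; by convention
    the result is ``(0.0, 1.0)`` with a warning.
    """
    times_a = np.asarray(times_a, dtype=float)
    times_b = np.asarray(times_b, dtype=float)
    events_a = np.asarray(events_a, dtype=int)
    events_b = np.asarray(events_b, dtype=int)
    if len(times_a) == 0 or len(times_b) == 0:
        raise ValueError("both groups must be non-empty")
    if events_a.sum() + events_b.sum() == 0:
        logger.warning("no events in either group; log-rank undefined, returning p=1")
        return 0.0, 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = _ll_logrank(times_a, times_b, event_observed_A=events_a,
                          event_observed_B=events_b)
    chi2 = float(res.test_statistic)
    if not np.isfinite(chi2):  # identical groups can yield 0/0
        return 0.0, 1.0
    return chi2, float(res.p_value)


def _direction(times_lo, events_lo, times_hi, events_hi) -> str:
    """Compare restricted mean survival time between groups."""
    tau = float(min(times_lo.max(), times_hi.max()))
    if tau <= 0:
        return "none"
    kl, kh = KaplanMeierFitter(), KaplanMeierFitter()
    kl.fit(times_lo, events_lo)
    kh.fit(times_hi, events_hi)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rl = restricted_mean_survival_time(kl, t=tau)
        rh = restricted_mean_survival_time(kh, t=tau)
    if np.isclose(rl, rh):
        return "none"
    return "high_worse" if rh < rl else "high_better"


def survival_screen(em: ExpressionMatrix, clinical: pd.DataFrame) -> pd.DataFrame:
    """Median-split log-rank screen over every feature of the matrix.

    Only samples present in both the expression matrix and the clinical
    table are used.  Features with a degenerate split, or leaving fewer
    than 2 samples in a group, are skipped with a logged reason.  Returns
    columns ``feature, n_low, n_high, chi2, p, q, direction`` with q the
    BH adjustment across the screened features.
    """
    shared = [s for s in em.sample_ids if s in clinical.index]
    if len(shared) < 4:
        raise ValueError("fewer than 4 samples shared with the clinical table")
    times = clinical.loc[shared, "time"].to_numpy(dtype=float)
    events = clinical.loc[shared, "event"].to_numpy(dtype=int)
    expr = em.data[shared]
    rows = []
    for feat, vals in expr.iterrows():
        v = vals.to_numpy(dtype=float)
        try:
            low = median_split(v)
        except ValueError:
            logger.info("survival screen: %s skipped (degenerate split)", feat)
            continue
        if low.sum() < 2 or (~low).sum() < 2:
            logger.info("survival screen: %s skipped (group < 2 after split)", feat)
            continue
        chi2, p = logrank_test(times[low], events[low], times[~low], events[~low])
        rows.append(
            {
                "feature": feat,
                "n_low": int(low.sum()),
                "n_high": int((~low).sum()),
                "chi2": chi2,
                "p": p,
                "direction": _direction(times[low], events[low],
                                        times[~low], events[~low]),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = bh_adjust(out["p"].to_numpy())
        out = out[["feature", "n_low", "n_high", "chi2", "p", "q", "direction"]]
    return out
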