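"""Comparison statistics shared across the study.

Cohen's kappa for agreement between two risk classifiers, Stouffer's
weighted combination of one-sided p-values across cohorts, Harrell's
concordance index for censored outcomes, and Kaplan-Meier survival
proportions with the log-rank test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from sksurv.metrics import concordance_index_censored

__all__ = [
    "cohens_kappa",
    "stouffer_weighted",
    "concordance_index",
    "km_logrank",
]


def cohens_kappa(table) -> float:
    """Chance-corrected agreement (p_o - p_e) / (1 - p_e) of a square
    contingency table of two classifiers' labels."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] != t.shape[1] or t.shape[0] < 2:
        raise ValueError("need a square table with >= 2 categories")
    if (t < 0).any() or t.sum() == 0:
        raise ValueError("cells must be nonnegative with positive total")
    n = t.sum()
    p_o = np.trace(t) / n
    p_e = float((t.sum(axis=1) / n) @ (t.sum(axis=0) / n))
    if p_e >= 1.0:
        raise ValueError("expected agreement is 1: kappa undefined")
    return float((p_o - p_e) / (1.0 - p_e))


def stouffer_weighted(p_values, weights=None) -> float:
    """Weighted Stouffer combination of one-sided p-values.

    ``Z_i = Phi^{-1}(1 - p_i)``, combined ``Z = sum(w_i Z_i) / sqrt(sum
    w_i^2)``, combined p = 1 - Phi(Z).  Weights default to equal; for
    unbalanced cohorts pass ``sqrt(n_i)``.  Exact 0/1 inputs are clipped to
    the machine-safe range.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("need a 1-d nonempty array of p-values")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    tiny = np.finfo(float).tiny
    p = np.clip(p, tiny, 1.0 - 1e-16)
    w = np.ones_like(p) if weights is None else np.asarray(weights, dtype=float)
    if (w <= 0).any() or len(w) != len(p):
        raise ValueError("weights must be positive and match p-values")
    z = stats.norm.isf(p)
    combined = float(w @ z / np.sqrt(w @ w))
    return float(stats.norm.sf(combined))


def concordance_index(scores, time, event) -> float:
    """Harrell's c-index: fraction of comparable pairs in which the higher
    score has the earlier event; ties in score count 1/2."""
    event = np.asarray(event, dtype=bool)
    time = np.asarray(time, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if not event.any():
        raise ValueError("no comparable pairs (no events)")
    c, *_ = concordance_index_censored(event, time, scores)
    return float(c)


def km_logrank(
    groups, time, event, eval_time: float
) -> tuple[dict[str, float], float]:
    """Kaplan-Meier survival proportion per group at ``eval_time`` (the
    step-function value at the largest event time <= eval_time) and the
    two-sided log-rank p across groups."""
    groups = pd.Series(np.asarray(groups), name="group")
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    labels = groups.unique()
    if len(labels) < 2 and len(labels) != 1:
        raise ValueError("no groups")
    surv: dict[str, float] = {}
    for lab in labels:
        mask = (groups == lab).to_numpy()
        if mask.sum() == 0:
            raise ValueError(f"group {lab!r} is empty")
        kmf = KaplanMeierFitter()
        kmf.fit(time[mask], event[mask])
        surv[str(lab)] = float(kmf.predict(eval_time))
    if len(labels) >= 2:
        res = multivariate_logrank_test(time, groups, event)
        p = float(res.p_value)
    else:
        p = float("nan")
    return surv, p
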