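"""Performance and survival evaluation.

ROC/AUC (midrank tie handling, so AUC equals the Mann-Whitney statistic),
confusion matrices, Kaplan-Meier recurrence-free-survival curves per risk
group, and k-group log-rank tests.  Survival machinery is delegated to
lifelines; ROC to scikit-learn.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from sklearn.metrics import roc_auc_score, roc_curve

__all__ = [
    "roc_auc",
    "multiclass_auc",
    "km_curve",
    "km_by_group",
    "logrank",
    "confusion",
    "temporal_strata",
]


def roc_auc(scores, labels) -> tuple[pd.DataFrame, float]:
    """Empirical ROC points and trapezoidal AUC for a binary problem.

    Raises ``ValueError`` unless both classes are present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC requires both classes in `labels`")
    fpr, tpr, thr = roc_curve(labels, scores)
    auc = float(roc_auc_score(labels, scores))
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr}), auc


def multiclass_auc(proba: pd.DataFrame, labels) -> dict[str, float]:
    """One-vs-rest AUC per class plus the macro average.

    ``proba`` columns are class names; ``labels`` the true class per row.
    """
    labels = pd.Series(labels).astype(str).to_numpy()
    out: dict[str, float] = {}
    aucs = []
    for cls in proba.columns:
        y = (labels == str(cls)).astype(int)
        if len(np.unique(y)) < 2:
            continue
        a = float(roc_auc_score(y, proba[cls]))
        out[str(cls)] = a
        aucs.append(a)
    out["macro"] = float(np.mean(aucs)) if aucs else float("nan")
    return out


def km_curve(times, events) -> pd.DataFrame:
    """Product-limit estimate; columns ``time`` and ``survival``.

    S(0) = 1 and the curve is a right-continuous step function dropping at
    event times; censored subjects leave the risk set at their time.
    """
    kmf = KaplanMeierFitter()
    kmf.fit(np.asarray(times, dtype=float), np.asarray(events, dtype=bool))
    sf = kmf.survival_function_
    return pd.DataFrame({"time": sf.index.to_numpy(dtype=float),
                         "survival": sf.iloc[:, 0].to_numpy(dtype=float)})


def survival_at(times, events, t: float) -> float:
    """S(t) from the product-limit estimator."""
    curve = km_curve(times, events)
    past = curve[curve["time"] <= t]
    return float(past["survival"].iloc[-1]) if len(past) else 1.0


def km_by_group(df: pd.DataFrame, group_col: str) -> dict[str, pd.DataFrame]:
    """Per-group KM curves from a table with time_months / event columns."""
    out = {}
    for g, sub in df.groupby(group_col, sort=True):
        if len(sub) == 0:
            continue
        out[str(g)] = km_curve(sub["time_months"], sub["event"])
    return out


def logrank(times, events, groups) -> tuple[float, float, int]:
    """k-group log-rank test: (chi-square statistic, p, degrees of freedom)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if len(uniq) < 2:
        raise ValueError("log-rank requires at least 2 groups")
    if not events.any():
        raise ValueError("log-rank requires at least one event")
    res = multivariate_logrank_test(times, groups, events)
    return float(res.test_statistic), float(res.p_value), len(uniq) - 1


def confusion(preds, labels, classes) -> pd.DataFrame:
    """Count matrix with rows = truth, columns = prediction."""
    classes = [str(c) for c in classes]
    preds = pd.Series(preds).astype(str)
    labels = pd.Series(labels).astype(str)
    unknown = set(preds) | set(labels)
    unknown -= set(classes)
    if unknown:
        raise ValueError(f"labels outside the declared classes: {sorted(unknown)}")
    mat = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for t, p in zip(labels, preds):
        mat.loc[t, p] += 1
    return mat


def temporal_strata(risk: pd.DataFrame) -> pd.Series:
    """Predicted temporal stratum per case for survival display.

    Cases flagged by the early-recurrence (gray) rule form the '<=2y'
    stratum; among the rest, a red/orange 3-5-year unit suggests later
    recurrence, and everything else is '>5y/none'.
    """
    def stratum(row) -> str:
        if row["early_recurrence"]:
            return "le2y"
        if row.get("color_rec3_3to5y", "blue") in ("red", "orange"):
            return "3to5y"
        return "gt5y_none"

    return risk.apply(stratum, axis=1)
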