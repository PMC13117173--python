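"""Ensemble risk scoring: colors, points, AI score, stage score, total score.

Every scoring unit pairs an SVM likelihood with an RF likelihood for the
same prediction target.  A unit is *red* (2 points) when both are at or
above the 0.5 positivity threshold, *orange* (1 point) when exactly one is,
and *blue* (0 points) otherwise; the boundary value 0.5 counts as positive.
The AI score is the point sum over the units and is banded into
high- (6-10), middle- (3-5) and low-risk (0-2) groups.  Adding the
pathologic stage score (I = 1, II = 2, III = 3) gives the total score,
banded at >= 7 (high), 3-6 (middle) and <= 2 (low).

The default schema uses five units — the 2-year pair, the 5-year pair and
the three class pairs of the three-category task (<= 2 y class, 3-5 y
class, and "any recurrence" = 1 - likelihood of the no/late-recurrence
class) — so the maximum AI score is 10, matching the published band limits.
A case whose 2-year unit is red carries an early-recurrence flag used only
for temporal stratification in survival plots; it never alters the points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "ScoringSchema",
    "DEFAULT_SCHEMA",
    "unit_color",
    "color_points",
    "ai_score",
    "ai_group",
    "stage_score",
    "total_score",
    "total_group",
    "early_recurrence_flag",
    "unit_likelihoods_from_table",
    "RiskScorer",
]

COLOR_POINTS = {"red": 2, "orange": 1, "blue": 0}
STAGE_SCORES = {"I": 1, "II": 2, "III": 3}


@dataclass(frozen=True)
class ScoringSchema:
    units: tuple[str, ...] = ("rec2", "rec5", "rec3_le2y", "rec3_3to5y", "rec3_any_rec")
    threshold: float = 0.5
    points: dict = field(default_factory=lambda: dict(COLOR_POINTS))
    ai_high_min: int = 6
    ai_middle_min: int = 3
    total_high_min: int = 7
    total_middle_min: int = 3

    @property
    def max_ai_score(self) -> int:
        return max(self.points.values()) * len(self.units)


DEFAULT_SCHEMA = ScoringSchema()


def unit_color(svm_lik: float, rf_lik: float, threshold: float = 0.5) -> str:
    """'red' if both likelihoods >= threshold, 'orange' if exactly one, else 'blue'."""
    for name, v in (("svm", svm_lik), ("rf", rf_lik)):
        if not np.isfinite(v) or v < 0.0 or v > 1.0:
            raise ValueError(f"{name} likelihood {v!r} outside [0, 1]")
    n_pos = int(svm_lik >= threshold) + int(rf_lik >= threshold)
    return ("blue", "orange", "red")[n_pos]


def color_points(color: str, schema: ScoringSchema = DEFAULT_SCHEMA) -> int:
    return schema.points[color]


def ai_score(
    unit_likelihoods: dict[str, tuple[float, float]],
    schema: ScoringSchema = DEFAULT_SCHEMA,
) -> tuple[int, str, dict[str, str]]:
    """Sum unit points into the AI score.

    ``unit_likelihoods`` maps unit name -> (svm likelihood, rf likelihood).
    Returns ``(score, group, colors)``; a missing unit raises ``KeyError``
    naming it.
    """
    missing = [u for u in schema.units if u not in unit_likelihoods]
    if missing:
        raise KeyError(f"missing likelihoods for scoring unit(s): {missing}")
    colors = {
        u: unit_color(*unit_likelihoods[u], threshold=schema.threshold)
        for u in schema.units
    }
    score = sum(schema.points[c] for c in colors.values())
    return score, ai_group(score, schema), colors


def ai_group(score: int, schema: ScoringSchema = DEFAULT_SCHEMA) -> str:
    if score < 0 or score > schema.max_ai_score:
        raise ValueError(f"AI score {score} outside 0..{schema.max_ai_score}")
    if score >= schema.ai_high_min:
        return "high"
    if score >= schema.ai_middle_min:
        return "middle"
    return "low"


def stage_score(stage: str) -> int:
    try:
        return STAGE_SCORES[stage]
    except KeyError:
        raise ValueError(f"unknown pathologic stage {stage!r}; expected I, II or III") from None


def total_score(
    ai: int, stage: str, schema: ScoringSchema = DEFAULT_SCHEMA
) -> tuple[int, str]:
    total = int(ai) + stage_score(stage)
    return total, total_group(total, schema)


def total_group(total: int, schema: ScoringSchema = DEFAULT_SCHEMA) -> str:
    if total >= schema.total_high_min:
        return "high"
    if total >= schema.total_middle_min:
        return "middle"
    return "low"


def early_recurrence_flag(
    unit_likelihoods: dict[str, tuple[float, float]],
    schema: ScoringSchema = DEFAULT_SCHEMA,
) -> bool:
    """True when the 2-year unit is red (both models call early recurrence)."""
    if "rec2" not in unit_likelihoods:
        raise KeyError("missing likelihoods for scoring unit(s): ['rec2']")
    return unit_color(*unit_likelihoods["rec2"], threshold=schema.threshold) == "red"


def unit_likelihoods_from_table(likelihoods: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long (case, task, learner, class, likelihood) table to units.

    Output: one row per case, columns ``<unit>_svm`` and ``<unit>_rf`` for
    the five default units.
    """
    def grab(task, cls):
        sub = likelihoods[(likelihoods["task"] == task) & (likelihoods["class"] == cls)]
        return sub.pivot(index="case_id", columns="learner", values="likelihood")

    rec2 = grab("REC2", "1")
    rec5 = grab("REC5", "1")
    le2y = grab("REC3CAT", "le2y")
    mid = grab("REC3CAT", "3to5y")
    none = grab("REC3CAT", "gt5y_none")
    out = pd.DataFrame(index=rec2.index)
    for name, tab in (("rec2", rec2), ("rec5", rec5), ("rec3_le2y", le2y), ("rec3_3to5y", mid)):
        out[f"{name}_svm"] = tab["svm"]
        out[f"{name}_rf"] = tab["rf"]
    out["rec3_any_rec_svm"] = 1.0 - none["svm"]
    out["rec3_any_rec_rf"] = 1.0 - none["rf"]
    return out


class RiskScorer(TransformerMixin, BaseEstimator):
    """Transform case likelihood tables into full risk assessments.

    Stateless transformer: ``transform(likelihoods, stages)`` consumes the
    long likelihood table produced by the model ensemble plus a case -> stage
    mapping, and emits one row per case with unit colors, AI score and
    group, stage score, total score and group, and the early-recurrence
    flag.
    """

    def __init__(self, schema: ScoringSchema = DEFAULT_SCHEMA) -> None:
        self.schema = schema

    def fit(self, X=None, y=None) -> "RiskScorer":
        return self

    def transform(self, likelihoods: pd.DataFrame, stages: pd.Series | None = None) -> pd.DataFrame:
        units = unit_likelihoods_from_table(likelihoods)
        rows = []
        for case_id, row in units.iterrows():
            ul = {u: (row[f"{u}_svm"], row[f"{u}_rf"]) for u in self.schema.units}
            score, group, colors = ai_score(ul, self.schema)
            rec: dict[str, object] = {"case_id": case_id}
            for u in self.schema.units:
                rec[f"color_{u}"] = colors[u]
            rec["ai_score"] = score
            rec["ai_group"] = group
            rec["early_recurrence"] = early_recurrence_flag(ul, self.schema)
            if stages is not None:
                st = stages.loc[case_id]
                rec["stage"] = st
                rec["stage_score"] = stage_score(st)
                rec["total_score"], rec["total_group"] = total_score(score, st, self.schema)
            rows.append(rec)
        return pd.DataFrame(rows)
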