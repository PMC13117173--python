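"""Case-level study design: stratified hold-out split and task labels.

The split is stratified over the eight recurrence/follow-up categories and
performed strictly at the case level, so no ROI of a patient can appear in
both the training and test sets.  Three prediction tasks are defined over
the recurrence horizon: recurrence within 2 years (REC2), within 5 years
(REC5), and a three-category task (<=2 years / 3-5 years / >5 years or no
recurrence, REC3CAT).  Non-recurrent cases whose follow-up is shorter than
5 years are informative for the 2-year task but ambiguous for the 5-year
ones; they are used for REC2 only — the reason three separate models exist.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["TASKS", "stratified_split", "make_labels", "task_label_table"]

logger = logging.getLogger(__name__)

TASKS = ("REC2", "REC5", "REC3CAT")

REC3_CLASSES = ("le2y", "3to5y", "gt5y_none")


def stratified_split(
    cases: pd.DataFrame, test_fraction: float = 0.25, seed: int = 0
) -> pd.DataFrame:
    """Assign each case to 'train' or 'test', stratified by category.

    Per category, ``round(test_fraction * n)`` cases (round half up) are
    drawn without replacement into the test set; singleton categories go to
    training.  Returns a copy of ``cases`` with a ``split`` column; the
    assignment is a partition and reproducible for a given seed.
    """
    if not 0 < test_fraction < 1:
        raise ValueError(f"test_fraction must lie in (0, 1), got {test_fraction!r}")
    if "category" not in cases.columns:
        raise ValueError("cases must carry a 'category' column")
    rng = np.random.default_rng(seed)
    out = cases.copy()
    out["split"] = "train"
    for cat in sorted(out["category"].unique()):
        ids = out.index[out["category"] == cat].to_numpy()
        n = len(ids)
        if n == 0:
            continue
        if n == 1:
            logger.info("category %s has a single case; kept in training", cat)
            continue
        n_test = int(np.floor(test_fraction * n + 0.5))
        n_test = min(n_test, n - 1)  # never empty the training side of a stratum
        if n_test == 0:
            continue
        chosen = rng.choice(ids, size=n_test, replace=False)
        out.loc[chosen, "split"] = "test"
    return out


def write_split(cases: pd.DataFrame, path: str | Path) -> None:
    """Persist the case -> train/test assignment as JSON."""
    mapping = dict(zip(cases["case_id"], cases["split"]))
    Path(path).write_text(json.dumps(mapping, indent=1, sort_keys=True))


def make_labels(event: bool, time_months: float, task: str) -> tuple[object, bool]:
    """Label and task eligibility for one case.

    Returns ``(label, eligible)``.  REC2: recurrence at <= 24 months (the
    24-month boundary counts as "within 2 years"); REC5: recurrence at
    <= 60 months; REC3CAT: 'le2y' / '3to5y' / 'gt5y_none'.  Non-recurrent
    cases with follow-up below 60 months are ineligible for REC5 and
    REC3CAT (their 5-year status is unknown); every included case is
    eligible for REC2.
    """
    if time_months <= 0 or not np.isfinite(time_months):
        raise ValueError(f"time_months must be positive, got {time_months!r}")
    if not event and time_months < 24.0:
        raise ValueError("non-recurrent case with follow-up < 24 months violates inclusion")
    if task == "REC2":
        return int(event and time_months <= 24.0), True
    if task == "REC5":
        eligible = event or time_months >= 60.0
        return int(event and time_months <= 60.0), eligible
    if task == "REC3CAT":
        eligible = event or time_months >= 60.0
        if event and time_months <= 24.0:
            return "le2y", True
        if event and time_months <= 60.0:
            return "3to5y", True
        return "gt5y_none", eligible
    raise ValueError(f"unknown task {task!r}; expected one of {TASKS}")


def task_label_table(cases: pd.DataFrame) -> pd.DataFrame:
    """Vectorized labels/eligibility for all tasks.

    Adds ``label_REC2``, ``label_REC5``, ``label_REC3CAT`` and matching
    ``eligible_*`` columns to a copy of ``cases``.
    """
    out = cases.copy()
    ev = out["event"].to_numpy(dtype=bool)
    t = out["time_months"].to_numpy(dtype=float)
    out["label_REC2"] = (ev & (t <= 24.0)).astype(int)
    out["eligible_REC2"] = True
    out["label_REC5"] = (ev & (t <= 60.0)).astype(int)
    out["eligible_REC5"] = ev | (t >= 60.0)
    rec3 = np.where(
        ev & (t <= 24.0), "le2y", np.where(ev & (t <= 60.0), "3to5y", "gt5y_none")
    )
    out["label_REC3CAT"] = rec3
    out["eligible_REC3CAT"] = out["eligible_REC5"]
    return out
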