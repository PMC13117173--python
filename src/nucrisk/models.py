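"""Per-task SVM / random-forest classifiers over ROI feature vectors.

Each of the three recurrence tasks is fitted twice — a linear-kernel SVM
(with per-feature z-standardization and Platt-type probability calibration,
one-vs-one for the three-class task) and a 500-tree random forest on raw
features — giving the six-model ensemble.  Models are trained on ROI-level
rows; a case's likelihood is the arithmetic mean of its ROI likelihoods.
Internal validation is 5-fold cross-validation with folds drawn over CASES
(never ROIs, to avoid within-patient leakage) for the SVM and the
out-of-bag error for the forest.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import accuracy_score, roc_auc_score
from sklearn.model_selection import KFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .design import TASKS, task_label_table
from .registry import ROI_FEATURE_NAMES, roi_feature_blocks

__all__ = [
    "RecurrenceTaskModel",
    "RecurrenceEnsemble",
    "case_likelihoods",
    "cross_validate_cases",
    "feature_importance",
    "block_shares",
]


class RecurrenceTaskModel(ClassifierMixin, BaseEstimator):
    """One (task, learner) classifier over 960-entry ROI vectors.

    Parameters
    ----------
    task
        'REC2', 'REC5' or 'REC3CAT' (used in error messages and metadata).
    learner
        'svm' — linear-kernel SVC behind a StandardScaler, probabilities by
        Platt-type sigmoid calibration, one-vs-one in the multiclass case;
        'rf' — RandomForestClassifier, 500 trees, sqrt-p features per split,
        out-of-bag score enabled.
    """

    def __init__(
        self,
        task: str = "REC2",
        learner: str = "svm",
        n_estimators: int = 500,
        random_state: int | None = 0,
        oob_score: bool = True,
    ) -> None:
        self.task = task
        self.learner = learner
        self.n_estimators = n_estimators
        self.random_state = random_state
        self.oob_score = oob_score

    def _build(self):
        if self.learner == "svm":
            svc = SVC(
                kernel="linear",
                decision_function_shape="ovo",
                random_state=self.random_state,
            )
            calibrated = CalibratedClassifierCV(
                svc, method="sigmoid", cv=5, ensemble=False
            )
            return Pipeline([("scale", StandardScaler()), ("svc", calibrated)])
        if self.learner == "rf":
            return RandomForestClassifier(
                n_estimators=self.n_estimators,
                max_features="sqrt",
                oob_score=self.oob_score,
                random_state=self.random_state,
                n_jobs=1,
            )
        raise ValueError(f"unknown learner {self.learner!r}; expected 'svm' or 'rf'")

    def fit(self, X, y) -> "RecurrenceTaskModel":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError(
                f"task {self.task}: training set holds a single class {classes!r}"
            )
        self.model_ = self._build().fit(X, y)
        self.classes_ = self.model_.classes_ if hasattr(self.model_, "classes_") else (
            self.model_[-1].classes_
        )
        if self.learner == "rf" and self.oob_score:
            self.oob_score_ = float(self.model_.oob_score_)
            self.oob_error_ = 1.0 - self.oob_score_
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        return self.model_.predict_proba(np.asarray(X, dtype=float))

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        return self.model_.predict(np.asarray(X, dtype=float))

    @property
    def coef_importance_(self) -> np.ndarray:
        """Per-feature importance: |SVM weights| (mean over class pairs) or RF impurity."""
        check_is_fitted(self, "model_")
        return feature_importance(self)


def feature_importance(model: RecurrenceTaskModel) -> np.ndarray:
    """Non-negative per-feature importance vector of a fitted task model."""
    if model.learner == "svm":
        # weights of the underlying linear SVC on standardized features
        coef = model.model_[-1].calibrated_classifiers_[0].estimator.coef_
        return np.abs(np.atleast_2d(coef)).mean(axis=0)
    return np.asarray(model.model_.feature_importances_, dtype=float)


def block_shares(
    importances: np.ndarray, feature_names: list[str] | tuple[str, ...] = ROI_FEATURE_NAMES
) -> dict[str, float]:
    """Aggregate per-feature importance into block percentages summing to 100."""
    blocks = roi_feature_blocks()
    imp = np.asarray(importances, dtype=float)
    if imp.shape[0] != len(feature_names):
        raise ValueError("importance length does not match feature names")
    totals: dict[str, float] = {}
    for name, v in zip(feature_names, imp):
        b = blocks.get(name, "other")
        totals[b] = totals.get(b, 0.0) + float(v)
    grand = sum(totals.values())
    if grand <= 0:
        return {b: 0.0 for b in totals}
    return {b: 100.0 * v / grand for b, v in totals.items()}


def case_likelihoods(
    model: RecurrenceTaskModel, X: np.ndarray, case_ids: np.ndarray
) -> pd.DataFrame:
    """Case-level class likelihoods: arithmetic mean over each case's ROIs.

    Order-invariant in the ROI rows; raises on an empty input.
    """
    X = np.asarray(X, dtype=float)
    case_ids = np.asarray(case_ids)
    if len(X) == 0:
        raise ValueError("no ROI rows to score")
    proba = model.predict_proba(X)
    df = pd.DataFrame(proba, columns=[str(c) for c in model.classes_])
    df["case_id"] = case_ids
    out = df.groupby("case_id", sort=True).mean()
    # means of a simplex stay on the simplex
    assert np.allclose(out.sum(axis=1), 1.0, atol=1e-6)
    return out


def cross_validate_cases(
    model: RecurrenceTaskModel,
    X: np.ndarray,
    y_roi: np.ndarray,
    case_ids: np.ndarray,
    y_case: pd.Series,
    k: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """k-fold cross-validation with folds partitioning cases, not ROIs.

    Returns one row per fold with case-level accuracy and AUC (binary: the
    positive-class likelihood; multiclass: macro one-vs-rest).
    """
    X = np.asarray(X, dtype=float)
    case_ids = np.asarray(case_ids)
    cases = np.unique(case_ids)
    if k > len(cases):
        raise ValueError(f"k={k} exceeds the number of cases ({len(cases)})")
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    rows = []
    for fold, (tr_idx, te_idx) in enumerate(kf.split(cases)):
        tr_cases, te_cases = set(cases[tr_idx]), cases[te_idx]
        tr_mask = np.fromiter((c in tr_cases for c in case_ids), dtype=bool, count=len(case_ids))
        fold_model = clone(model)
        if getattr(fold_model, "learner", None) == "rf":
            fold_model.set_params(oob_score=False)  # redundant inside CV folds
        fitted = fold_model.fit(X[tr_mask], y_roi[tr_mask])
        lik = case_likelihoods(fitted, X[~tr_mask], case_ids[~tr_mask])
        lik = lik.loc[[c for c in te_cases if c in lik.index]]
        truth = y_case.loc[lik.index]
        pred = lik.columns[np.argmax(lik.to_numpy(), axis=1)]
        acc = accuracy_score(truth.astype(str), pred)
        try:
            if lik.shape[1] == 2:
                pos = str(fitted.classes_[-1])
                auc = roc_auc_score((truth.astype(str) == pos).astype(int), lik[pos])
            else:
                auc = roc_auc_score(
                    truth.astype(str), lik, multi_class="ovr", average="macro"
                )
        except ValueError:  # a fold may hold a single truth class
            auc = np.nan
        rows.append({"fold": fold, "n_cases": len(lik), "accuracy": acc, "auc": auc})
    return pd.DataFrame(rows)


class RecurrenceEnsemble(BaseEstimator):
    """The six-model ensemble: {REC2, REC5, REC3CAT} x {svm, rf}.

    ``fit`` takes the ROI feature table (with ``case_id`` and the 960
    registry columns) and the case table (``case_id``, ``event``,
    ``time_months``); task eligibility rules are applied per task.
    ``predict_likelihoods`` returns the long per-case likelihood table that
    the risk-scoring stage consumes.
    """

    def __init__(
        self,
        tasks: tuple[str, ...] = TASKS,
        n_estimators: int = 500,
        random_state: int = 0,
        oob_score: bool = True,
    ) -> None:
        self.tasks = tasks
        self.n_estimators = n_estimators
        self.random_state = random_state
        self.oob_score = oob_score

    def fit(self, roi_features: pd.DataFrame, cases: pd.DataFrame) -> "RecurrenceEnsemble":
        labeled = task_label_table(cases).set_index("case_id")
        X_all = roi_features[list(ROI_FEATURE_NAMES)].to_numpy(dtype=float)
        case_ids = roi_features["case_id"].to_numpy()
        self.models_: dict[tuple[str, str], RecurrenceTaskModel] = {}
        for task in self.tasks:
            eligible = labeled.index[labeled[f"eligible_{task}"]]
            mask = np.fromiter(
                (c in set(eligible) for c in case_ids), dtype=bool, count=len(case_ids)
            )
            y = labeled.loc[case_ids[mask], f"label_{task}"].to_numpy()
            for learner in ("svm", "rf"):
                m = RecurrenceTaskModel(
                    task=task,
                    learner=learner,
                    n_estimators=self.n_estimators,
                    random_state=self.random_state,
                    oob_score=self.oob_score,
                )
                self.models_[(task, learner)] = m.fit(X_all[mask], y)
        return self

    def predict_likelihoods(self, roi_features: pd.DataFrame) -> pd.DataFrame:
        """Long table: case_id, task, learner, class, likelihood."""
        check_is_fitted(self, "models_")
        X = roi_features[list(ROI_FEATURE_NAMES)].to_numpy(dtype=float)
        ids = roi_features["case_id"].to_numpy()
        frames = []
        for (task, learner), model in self.models_.items():
            lik = case_likelihoods(model, X, ids)
            long = lik.reset_index().melt(
                id_vars="case_id", var_name="class", value_name="likelihood"
            )
            long["task"] = task
            long["learner"] = learner
            frames.append(long)
        return pd.concat(frames, ignore_index=True)[
            ["case_id", "task", "learner", "class", "likelihood"]
        ]

    def save(self, path) -> None:
        """Persist the fitted ensemble (joblib blob + JSON metadata sidecar)."""
        import json
        from pathlib import Path

        import joblib

        check_is_fitted(self, "models_")
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        joblib.dump(self, path)
        meta = {
            "tasks": list(self.tasks),
            "n_estimators": self.n_estimators,
            "random_state": self.random_state,
            "models": [f"{t}_{l}" for t, l in self.models_],
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path) -> "RecurrenceEnsemble":
        import joblib

        obj = joblib.load(path)
        if not isinstance(obj, cls):
            raise TypeError(f"{path} does not hold a {cls.__name__}")
        return obj
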