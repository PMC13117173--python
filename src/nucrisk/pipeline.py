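"""End-to-end orchestration: simulate -> features -> split -> train -> score -> evaluate.

A single ``RunConfig`` (YAML-loadable) drives every stage; all tabular
outputs are CSV/JSON under one output directory, and a run manifest records
seeds, per-stage row counts and content hashes so that silent changes in
intermediate files are detectable and identical configurations reproduce
identical manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cflcm import ROIFeaturizer
from .design import stratified_split, task_label_table, write_split
from .evaluate import km_by_group, logrank, multiclass_auc, roc_auc, temporal_strata
from .models import RecurrenceEnsemble, block_shares, feature_importance
from .plots import plot_km, plot_risk_table, plot_roc
from .scoring import RiskScorer
from .synth import CohortParams, generate_cohort

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "runs/demo"
    cohort: dict = field(default_factory=dict)
    cflcm: dict = field(default_factory=dict)
    test_fraction: float = 0.25
    n_estimators: int = 500

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        CohortParams(seed=self.seed, **self.cohort)  # raises on bad fields
        if not 0 < self.test_fraction < 1:
            raise ValueError(f"test_fraction must lie in (0, 1), got {self.test_fraction!r}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage; returns (and writes) the run manifest."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "stages": {},
    }

    def record(stage: str, files: list[Path], **counts) -> None:
        manifest["stages"][stage] = {
            "files": {f.name: _sha256(f) for f in files},
            **counts,
        }

    try:
        # --- simulate -----------------------------------------------------
        params = CohortParams(seed=config.seed, **config.cohort)
        cohort = generate_cohort(params)
        cohort_path = out / "cohort.csv"
        cohort.cases.to_csv(cohort_path, index=False)
        record("simulate", [cohort_path], n_cases=len(cohort.cases), n_nuclei=len(cohort.nuclei))

        # --- ROI features -------------------------------------------------
        featurizer = ROIFeaturizer(**config.cflcm)
        roi_features = featurizer.fit().transform(cohort.nuclei)
        feat_path = out / "roi_features.csv"
        roi_features.to_csv(feat_path, index=False)
        record("cflcm", [feat_path], n_rois=len(roi_features))

        # --- split + labels ----------------------------------------------
        cases = stratified_split(cohort.cases, config.test_fraction, seed=config.seed)
        cases = task_label_table(cases)
        split_path = out / "split.json"
        write_split(cases, split_path)
        n_test = int((cases["split"] == "test").sum())
        if n_test == 0 or n_test == len(cases):
            raise RuntimeError("degenerate split: empty train or test set")
        record("split", [split_path], n_train=len(cases) - n_test, n_test=n_test)

        # --- train --------------------------------------------------------
        train_ids = set(cases.loc[cases["split"] == "train", "case_id"])
        train_rois = roi_features[roi_features["case_id"].isin(train_ids)]
        ensemble = RecurrenceEnsemble(
            n_estimators=config.n_estimators, random_state=config.seed
        ).fit(train_rois, cases[cases["split"] == "train"])
        likelihoods = ensemble.predict_likelihoods(roi_features)
        likelihoods = likelihoods.merge(cases[["case_id", "split"]], on="case_id")
        lik_path = out / "likelihoods.csv"
        likelihoods.to_csv(lik_path, index=False)
        importance = {
            f"{task}_{learner}": block_shares(feature_importance(m))
            for (task, learner), m in ensemble.models_.items()
        }
        imp_path = out / "feature_importance.json"
        imp_path.write_text(json.dumps(importance, indent=1))
        ensemble.save(out / "models" / "ensemble.joblib")
        record("train", [lik_path, imp_path], n_models=len(ensemble.models_))

        # --- score --------------------------------------------------------
        test_cases = cases[cases["split"] == "test"].set_index("case_id")
        test_lik = likelihoods[likelihoods["split"] == "test"]
        risk = RiskScorer().transform(test_lik, stages=test_cases["stage"])
        risk_path = out / "risk_scores.csv"
        risk.to_csv(risk_path, index=False)
        plot_risk_table(risk, out / "risk_table.png")
        record("score", [risk_path], n_cases=len(risk))

        # --- evaluate -----------------------------------------------------
        summary = _evaluate(cases, likelihoods, risk, out)
        auc_path = out / "auc_summary.json"
        auc_path.write_text(json.dumps(summary, indent=1))
        record("evaluate", [auc_path])
    except Exception as exc:  # annotate which stage failed, keep partial outputs
        done = list(manifest["stages"])
        stage_names = ["simulate", "cflcm", "split", "train", "score", "evaluate"]
        failed = next((s for s in stage_names if s not in done), "evaluate")
        raise RuntimeError(f"pipeline stage '{failed}' failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


# ---------------------------------------------------------------------------
# file-based single stages (CLI resume path)
# ---------------------------------------------------------------------------

def _load_cases_with_split(out: Path) -> pd.DataFrame:
    cases = pd.read_csv(out / "cohort.csv")
    mapping = json.loads((out / "split.json").read_text())
    cases["split"] = cases["case_id"].map(mapping)
    return task_label_table(cases)


def train_stage(outdir: str | Path, seed: int = 0, n_estimators: int = 500) -> pd.DataFrame:
    """Fit the six-model ensemble from files under ``outdir``; writes likelihoods.csv."""
    out = Path(outdir)
    cases = _load_cases_with_split(out)
    roi_features = pd.read_csv(out / "roi_features.csv")
    train_ids = set(cases.loc[cases["split"] == "train", "case_id"])
    ensemble = RecurrenceEnsemble(n_estimators=n_estimators, random_state=seed).fit(
        roi_features[roi_features["case_id"].isin(train_ids)],
        cases[cases["split"] == "train"],
    )
    likelihoods = ensemble.predict_likelihoods(roi_features)
    likelihoods = likelihoods.merge(cases[["case_id", "split"]], on="case_id")
    likelihoods.to_csv(out / "likelihoods.csv", index=False)
    return likelihoods


def score_stage(outdir: str | Path) -> pd.DataFrame:
    """Score test cases from likelihoods.csv; writes risk_scores.csv."""
    out = Path(outdir)
    cases = _load_cases_with_split(out)
    likelihoods = pd.read_csv(out / "likelihoods.csv", dtype={"class": str})
    test_cases = cases[cases["split"] == "test"].set_index("case_id")
    risk = RiskScorer().transform(
        likelihoods[likelihoods["split"] == "test"], stages=test_cases["stage"]
    )
    risk.to_csv(out / "risk_scores.csv", index=False)
    return risk


def evaluate_stage(outdir: str | Path) -> dict:
    """Recompute AUC / survival summaries from files under ``outdir``."""
    out = Path(outdir)
    cases = _load_cases_with_split(out)
    likelihoods = pd.read_csv(out / "likelihoods.csv", dtype={"class": str})
    risk = pd.read_csv(out / "risk_scores.csv")
    summary = _evaluate(cases, likelihoods, risk, out)
    (out / "auc_summary.json").write_text(json.dumps(summary, indent=1))
    return summary


def _evaluate(cases: pd.DataFrame, likelihoods: pd.DataFrame, risk: pd.DataFrame, out: Path) -> dict:
    """Test-set AUCs per model, plus survival stratification summaries."""
    test = cases[cases["split"] == "test"].set_index("case_id")
    summary: dict = {"auc": {}, "km": {}}
    for task in ("REC2", "REC5"):
        truth = test[f"label_{task}"]
        for learner in ("svm", "rf"):
            sub = likelihoods[
                (likelihoods["task"] == task)
                & (likelihoods["learner"] == learner)
                & (likelihoods["class"] == "1")
                & (likelihoods["split"] == "test")
            ].set_index("case_id")
            eligible = truth.index.intersection(sub.index)
            y = truth.loc[eligible]
            if len(y.unique()) < 2:
                continue
            curve, auc = roc_auc(sub.loc[eligible, "likelihood"], y)
            curve.to_csv(out / f"roc_{task}_{learner}.csv", index=False)
            plot_roc(curve, auc, f"{task} ({learner})", out / f"roc_{task}_{learner}.png")
            summary["auc"][f"{task}_{learner}"] = auc
    for learner in ("svm", "rf"):
        sub = likelihoods[
            (likelihoods["task"] == "REC3CAT")
            & (likelihoods["learner"] == learner)
            & (likelihoods["split"] == "test")
        ]
        if len(sub) == 0:
            continue
        proba = sub.pivot(index="case_id", columns="class", values="likelihood")
        eligible = test.index[test["eligible_REC3CAT"]].intersection(proba.index)
        if len(eligible) >= 2:
            summary["auc"][f"REC3CAT_{learner}"] = multiclass_auc(
                proba.loc[eligible], test.loc[eligible, "label_REC3CAT"]
            )

    surv = risk.merge(
        cases[["case_id", "time_months", "event"]], on="case_id", how="left"
    )
    surv["temporal_stratum"] = temporal_strata(risk)
    for col in ("stage", "ai_group", "total_group"):
        curves = km_by_group(surv, col)
        for g, c in curves.items():
            c.to_csv(out / f"km_{col}_{g}.csv", index=False)
        if curves:
            plot_km(curves, f"RFS by {col} (test set)", out / f"km_{col}.png")
        if surv[col].nunique() >= 2 and surv["event"].any():
            stat, p, dof = logrank(surv["time_months"], surv["event"], surv[col])
            summary["km"][col] = {"logrank_stat": stat, "p": p, "df": dof}
    return summary
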