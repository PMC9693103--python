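"""End-to-end orchestration of the six-model comparison.

Ties the stages together the way the emulated study was run: feature-set
selection, model fitting and threshold choice happen on the training
cohort only; the frozen model is then evaluated once on the test cohort.
Three feature families (radiomics-only, Pmap, combined), each with and
without SMOTE, give six models.

Blinding is enforced by interface: the selection/threshold code receives
only the training partition.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CohortConfig, generate_cohort
from .features import (
    CLINICAL_FEATURES,
    DEFAULT_DVH_SPEC,
    RADIOMIC_FEATURES,
    extract_feature_table,
)
from .metrics import (
    calibration_curve,
    confusion_from_predictions,
    decision_curve,
    precision_recall_curve,
    roc_auc,
)
from .pipeline import (
    PipelineConfig,
    ThresholdedClassifier,
    decremental_selection,
    train_classifier,
    youden_threshold,
)

__all__ = ["RunConfig", "family_features", "run_experiment", "fit_thresholded"]

RAD_FEATURES = tuple(name for name, _, _ in RADIOMIC_FEATURES)
PMAP_FEATURES = (
    "DMean_Pmap", "DMean_2Lungs", "DMean_LungH", "V5_LungH", "V10_LungH",
    "V30_2Lungs", "V40_Heart", "AJCC_stage", "COPD", "MEVS", "smoking",
)
DVH_FEATURES = tuple(name for name, *_ in DEFAULT_DVH_SPEC)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one experiment run."""

    endpoint: str = "apt2"
    families: tuple[str, ...] = ("rad", "pmap", "combined")
    smote: tuple[bool, ...] = (False, True)
    train: CohortConfig = field(default_factory=lambda: CohortConfig(n_patients=165, seed=11))
    test: CohortConfig = field(default_factory=lambda: CohortConfig(n_patients=42, seed=12))
    pipeline: PipelineConfig = field(default_factory=PipelineConfig)
    select_features: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.endpoint not in ("apt2", "apt3"):
            raise ValueError("endpoint must be 'apt2' or 'apt3'")
        unknown = set(self.families) - {"rad", "pmap", "combined"}
        if unknown:
            raise ValueError(f"unknown model families: {sorted(unknown)}")
        if not self.families:
            raise ValueError("at least one model family is required")


def family_features(family: str, table: pd.DataFrame) -> list[str]:
    """Feature columns of one model family, in deterministic order."""
    if family == "rad":
        cols = RAD_FEATURES
    elif family == "pmap":
        cols = PMAP_FEATURES
    elif family == "combined":
        cols = DVH_FEATURES + RAD_FEATURES + CLINICAL_FEATURES
    else:
        raise ValueError(f"unknown family {family!r}")
    return [c for c in cols if c in table.columns]


def fit_thresholded(
    X_train: pd.DataFrame,
    y_train: np.ndarray,
    config: PipelineConfig,
    select: bool = True,
):
    """Train on the training partition only; freeze features + threshold.

    Returns (classifier, trace-or-None). With ``select=False`` the full
    feature set is used without the decremental search.
    """
    trace = None
    if select and X_train.shape[1] >= 2:
        trace = decremental_selection(X_train, y_train, config)
        model = trace.final_model
        X_used = X_train[trace.chosen_features]
    else:
        if config.use_smote:
            from .pipeline import smote_oversample

            Xs, ys = smote_oversample(
                X_train.to_numpy(dtype=float), y_train, k=config.smote_k,
                seed=config.seed,
            )
            Xs = pd.DataFrame(Xs, columns=X_train.columns)
            model = train_classifier(Xs, ys, config)
        else:
            model = train_classifier(X_train, y_train, config)
        X_used = X_train
    p_train = model.predict_proba(X_used)
    if np.unique(p_train).size < 2:
        # degenerate model: constant probability on every training row.
        # No cut can separate anything; classify everyone low-risk.
        threshold = float(p_train[0])
    else:
        threshold = youden_threshold(p_train, y_train)
    return ThresholdedClassifier(model=model, threshold=threshold), trace


def _evaluate(clf: ThresholdedClassifier, X: pd.DataFrame, y: np.ndarray) -> dict:
    X_used = X[clf.model.feature_names]
    p = clf.model.predict_proba(X_used)
    pred = (p > clf.threshold).astype(int)
    cm = confusion_from_predictions(y, pred)
    printed = cm.printed()
    dca = decision_curve(p, y)
    return {
        "metrics": {
            "auc": roc_auc(p, y),
            "threshold": clf.threshold,
            "tp": cm.tp, "fp": cm.fp, "tn": cm.tn, "fn": cm.fn,
            "se": printed["se"], "sp": printed["sp"], "bacc": printed["bacc"],
            "ppv": printed["ppv"], "npv": printed["npv"], "f1": printed["f1"],
        },
        "confusion": cm,
        "probabilities": p,
        "decision_curve": {
            "threshold": dca.thresholds,
            "nb_model": dca.nb_model,
            "nb_all": dca.nb_all,
            "nb_none": dca.nb_none,
        },
        "precision_recall": {
            c: v for c, v in zip(
                ("threshold", "precision", "recall"),
                precision_recall_curve(p, y).T,
            )
        },
        "calibration": {
            c: v for c, v in zip(
                ("bin_center", "mean_predicted", "observed_rate", "count"),
                calibration_curve(p, y).T,
            )
        },
    }


def run_experiment(
    config: RunConfig,
    train_cohort=None,
    test_cohort=None,
) -> dict:
    """Run the requested model comparison end to end.

    Cohorts are generated from ``config.train`` / ``config.test`` unless
    passed in (e.g. loaded from disk via :func:`aptox.io.load_cohort`).
    Returns a report bundle: per-model training/testing metrics and curves
    plus the echoed configuration.
    """
    if train_cohort is None:
        train_cohort = generate_cohort(config.train)
    if test_cohort is None:
        test_cohort = generate_cohort(config.test)
    train_table = extract_feature_table(train_cohort)
    test_table = extract_feature_table(test_cohort)
    if list(train_table.columns) != list(test_table.columns):
        raise ValueError("training and testing tables have different columns")

    y_train = train_table[config.endpoint].to_numpy()
    y_test = test_table[config.endpoint].to_numpy()

    models: dict[str, dict] = {}
    for family in config.families:
        cols = family_features(family, train_table)
        for use_smote in config.smote:
            name = f"{family}_{'smote' if use_smote else 'nosmote'}"
            pipe = dataclasses.replace(
                config.pipeline,
                use_smote=use_smote,
                seed=config.pipeline.seed + config.seed,
            )
            clf, trace = fit_thresholded(
                train_table[cols], y_train, pipe, select=config.select_features
            )
            res_train = _evaluate(clf, train_table, y_train)
            res_test = _evaluate(clf, test_table, y_test)
            models[name] = {
                "classifier": clf,
                "chosen_features": list(clf.model.feature_names),
                "trace": trace,
                "metrics": {
                    **{f"train_{k}": v for k, v in res_train["metrics"].items()},
                    **{f"test_{k}": v for k, v in res_test["metrics"].items()},
                },
                "train": res_train,
                "test": res_test,
                "decision_curve": res_test["decision_curve"],
                "precision_recall": res_test["precision_recall"],
                "calibration": res_test["calibration"],
            }
    return {
        "config": dataclasses.asdict(config),
        "endpoint": config.endpoint,
        "models": models,
    }
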