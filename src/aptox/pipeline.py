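"""Imbalance-corrected neural-network model building.

The procedure mirrors a clinical modelling workflow for a rare (~20%)
binary toxicity endpoint:

1. optional SMOTE oversampling of the minority class to parity;
2. a single-hidden-layer feedforward classifier on standardized inputs;
3. permutation-based feature importances;
4. decremental feature elimination — drop the least important feature,
   retrain, repeat down to one feature — with each candidate set scored by
   the mean out-of-bag balanced accuracy over B bootstrap replications;
5. retention of the set with the highest mean bootstrap score;
6. a probability cut-off maximizing the Youden index Se + Sp - 1.

SMOTE, when enabled, is applied inside each bootstrap replication to the
in-bag rows only, never to evaluation rows.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import accuracy_score, balanced_accuracy_score
from sklearn.neighbors import NearestNeighbors
from sklearn.neural_network import MLPClassifier

__all__ = [
    "PipelineConfig",
    "TrainedModel",
    "SelectionStep",
    "SelectionTrace",
    "ThresholdedClassifier",
    "smote_oversample",
    "train_classifier",
    "predictor_importance",
    "decremental_selection",
    "youden_threshold",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Knobs of the model-building procedure.

    ``bootstrap_B`` follows the source workflow's 1000 replications by
    default; desk-scale analyses lower it. ``hidden_units="auto"`` sizes
    the hidden layer as ceil((n_features + 2) / 2).
    """

    use_smote: bool = False
    smote_k: int = 5
    bootstrap_B: int = 1000
    hidden_units: int | str = "auto"
    max_epochs: int = 500
    alpha: float = 1e-2  # L2 penalty of the network weights
    balanced_accuracy: bool = True
    importance_repeats: int = 10
    redraw_cap: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bootstrap_B < 1:
            raise ValueError("bootstrap_B must be >= 1")
        if self.smote_k < 1:
            raise ValueError("smote_k must be >= 1")


@dataclass
class TrainedModel:
    """Fitted network + the input standardization frozen from training data."""

    feature_names: list[str]
    net: MLPClassifier
    mean_: np.ndarray
    scale_: np.ndarray
    seed: int

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean_) / self.scale_

    def predict_proba(self, X) -> np.ndarray:
        """Probability of the positive (toxicity) class per row.

        A DataFrame is subset to the model's own feature columns, so a
        wider table than the model was trained on is fine.
        """
        if isinstance(X, pd.DataFrame):
            X = X[self.feature_names].to_numpy(dtype=float)
        X = _check_matrix(np.asarray(X, dtype=float))
        return self.net.predict_proba(self._standardize(X))[:, 1]


@dataclass
class SelectionStep:
    feature_names: list[str]
    replication_scores: np.ndarray
    mean_score: float
    dropped: str | None  # feature removed after this step


@dataclass
class SelectionTrace:
    """Ledger of the decremental search and its retained feature set."""

    steps: list[SelectionStep]
    chosen_features: list[str]
    chosen_mean_score: float
    final_model: TrainedModel
    importances: dict[str, float]


@dataclass
class ThresholdedClassifier:
    """A trained model plus a probability cut-off (classify when p > threshold)."""

    model: TrainedModel
    threshold: float

    def predict(self, X) -> np.ndarray:
        return (self.model.predict_proba(X) > self.threshold).astype(int)

    @property
    def threshold_percent(self) -> float:
        """Cut-off on the percent scale as clinical reports print it."""
        return round(100.0 * self.threshold)


def _check_matrix(X: np.ndarray) -> np.ndarray:
    if not np.all(np.isfinite(X)):
        bad = np.argwhere(~np.isfinite(X))[0]
        raise ValueError(
            f"non-finite feature value at row {bad[0]}, column {bad[1]}"
        )
    return X


def smote_oversample(
    X: np.ndarray,
    y: np.ndarray,
    k: int = 5,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic minority oversampling to class parity.

    Each synthetic row is x_i + lambda (x_nn - x_i) with lambda ~ U(0, 1)
    and x_nn one of the k nearest minority neighbours of x_i (Euclidean
    distance on standardized features). Original rows are preserved and
    returned first.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError("smote_oversample needs exactly two classes")
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    if n_min == n_maj:
        return X.copy(), y.copy()
    if n_min < 2:
        raise ValueError("minority class needs >= 2 members for SMOTE")
    k_eff = min(k, n_min - 1)

    Xm = X[y == minority]
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Zm = (Xm - X.mean(axis=0)) / sd
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(Zm)
    _, idx = nn.kneighbors(Zm)  # column 0 is the point itself

    rng = np.random.default_rng(seed)
    n_new = n_maj - n_min
    base = rng.integers(0, n_min, size=n_new)
    pick = rng.integers(1, k_eff + 1, size=n_new)
    lam = rng.random(n_new)
    neigh = idx[base, pick]
    X_new = Xm[base] + lam[:, None] * (Xm[neigh] - Xm[base])
    return (
        np.vstack([X, X_new]),
        np.concatenate([y, np.full(n_new, minority, dtype=int)]),
    )


def _hidden_units(config: PipelineConfig, n_features: int) -> int:
    if config.hidden_units == "auto":
        return math.ceil((n_features + 2) / 2)
    return int(config.hidden_units)


def train_classifier(
    X,
    y,
    config: PipelineConfig,
    seed: int | None = None,
) -> TrainedModel:
    """Fit the feedforward classifier on standardized inputs.

    One hidden layer (logistic-output MLP, L-BFGS training: deterministic
    given the seed and fast at cohort-scale n); features are z-scored with
    training-set statistics stored on the model.
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        names = [f"x{i}" for i in range(X.shape[1])]
    y = np.asarray(y).astype(int)
    _check_matrix(X)
    if np.unique(y).size < 2 or min(np.bincount(y)) < 2:
        raise ValueError("need >= 2 rows of each class")

    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    Z = (X - mean) / scale
    net = MLPClassifier(
        hidden_layer_sizes=(_hidden_units(config, X.shape[1]),),
        activation="relu",
        solver="lbfgs",
        alpha=config.alpha,
        max_iter=config.max_epochs,
        random_state=config.seed if seed is None else seed,
    )
    # the iteration cap is a deliberate compute bound for bootstrap loops;
    # hitting it is not an error worth surfacing per fit
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        net.fit(Z, y)
    return TrainedModel(
        feature_names=names, net=net, mean_=mean, scale_=scale,
        seed=config.seed if seed is None else seed,
    )


def _score(y_true, y_pred, balanced: bool) -> float:
    if balanced:
        return float(balanced_accuracy_score(y_true, y_pred))
    return float(accuracy_score(y_true, y_pred))


def predictor_importance(
    model: TrainedModel,
    X,
    y,
    seed: int | None = None,
    repeats: int = 10,
    balanced: bool = True,
) -> dict[str, float]:
    """Permutation importances, floored at 0 and normalized to sum 1.

    Importance of a feature is the mean drop in (balanced) accuracy when
    its column is shuffled, over ``repeats`` shuffles. If every drop is
    non-positive (no feature carries signal) importances fall back to
    uniform.
    """
    if isinstance(X, pd.DataFrame):
        X = X[model.feature_names].to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    rng = np.random.default_rng(seed)
    base = _score(y, (model.predict_proba(X) > 0.5).astype(int), balanced)
    drops = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        acc = 0.0
        for _ in range(repeats):
            Xp = X.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            acc += _score(y, (model.predict_proba(Xp) > 0.5).astype(int), balanced)
        drops[j] = base - acc / repeats
    drops = np.clip(drops, 0.0, None)
    total = drops.sum()
    if total == 0:
        drops = np.ones_like(drops)
        total = drops.sum()
    return dict(zip(model.feature_names, drops / total))


def _bootstrap_scores(
    X: pd.DataFrame,
    y: np.ndarray,
    config: PipelineConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Out-of-bag (balanced) accuracy over B bootstrap replications.

    A replication whose in-bag or out-of-bag rows are single-class is
    redrawn, up to ``redraw_cap`` attempts.
    """
    n = len(y)
    scores = np.empty(config.bootstrap_B)
    for b in range(config.bootstrap_B):
        for _ in range(config.redraw_cap):
            boot = rng.integers(0, n, size=n)
            oob = np.setdiff1d(np.arange(n), boot)
            if oob.size == 0:
                continue
            yb, yo = y[boot], y[oob]
            if np.unique(yb).size == 2 and min(np.bincount(yb)) >= 2 \
                    and np.unique(yo).size == 2:
                break
        else:
            raise RuntimeError("could not draw a two-class bootstrap sample")
        Xb, Xo = X.iloc[boot], X.iloc[oob]
        if config.use_smote:
            Xb_arr, yb = smote_oversample(
                Xb.to_numpy(dtype=float), yb, k=config.smote_k,
                seed=int(rng.integers(2**31)),
            )
            Xb = pd.DataFrame(Xb_arr, columns=X.columns)
        model = train_classifier(
            Xb, yb, config, seed=int(rng.integers(2**31))
        )
        pred = (model.predict_proba(Xo) > 0.5).astype(int)
        scores[b] = _score(yo, pred, config.balanced_accuracy)
    return scores


def decremental_selection(
    X,
    y,
    config: PipelineConfig,
) -> SelectionTrace:
    """Decremental feature elimination with bootstrap stabilization.

    At each step the current feature set is scored by the mean out-of-bag
    (balanced) accuracy over ``bootstrap_B`` replications, a model is
    trained on the full training rows (SMOTE-balanced when enabled) and
    the least important feature is removed; this repeats until one feature
    remains. The retained set maximizes the mean bootstrap score, ties
    resolved toward the smaller set.
    """
    if isinstance(X, pd.DataFrame):
        Xdf = X.copy()
    else:
        X = np.asarray(X, dtype=float)
        Xdf = pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])
    y = np.asarray(y).astype(int)
    if Xdf.shape[1] < 2:
        raise ValueError("decremental selection needs >= 2 features")

    rng = np.random.default_rng(config.seed)
    current = list(Xdf.columns)
    steps: list[SelectionStep] = []
    while current:
        Xc = Xdf[current]
        scores = _bootstrap_scores(Xc, y, config, rng)
        if config.use_smote:
            Xs, ys = smote_oversample(
                Xc.to_numpy(dtype=float), y, k=config.smote_k,
                seed=int(rng.integers(2**31)),
            )
            Xs = pd.DataFrame(Xs, columns=current)
        else:
            Xs, ys = Xc, y
        model = train_classifier(Xs, ys, config, seed=int(rng.integers(2**31)))
        dropped = None
        if len(current) > 1:
            imp = predictor_importance(
                model, Xc, y, seed=int(rng.integers(2**31)),
                repeats=config.importance_repeats,
                balanced=config.balanced_accuracy,
            )
            dropped = min(current, key=lambda f: (imp[f], current.index(f)))
        steps.append(
            SelectionStep(
                feature_names=list(current),
                replication_scores=scores,
                mean_score=float(scores.mean()),
                dropped=dropped,
            )
        )
        if dropped is None:
            break
        current = [f for f in current if f != dropped]

    # highest mean score; ties -> fewest features (later steps are smaller)
    best = max(steps, key=lambda s: (s.mean_score, -len(s.feature_names)))
    Xc = Xdf[best.feature_names]
    if config.use_smote:
        Xs, ys = smote_oversample(
            Xc.to_numpy(dtype=float), y, k=config.smote_k,
            seed=int(rng.integers(2**31)),
        )
        Xs = pd.DataFrame(Xs, columns=best.feature_names)
    else:
        Xs, ys = Xc, y
    final = train_classifier(Xs, ys, config, seed=int(rng.integers(2**31)))
    importances = predictor_importance(
        final, Xc, y, seed=int(rng.integers(2**31)),
        repeats=config.importance_repeats,
        balanced=config.balanced_accuracy,
    )
    return SelectionTrace(
        steps=steps,
        chosen_features=list(best.feature_names),
        chosen_mean_score=best.mean_score,
        final_model=final,
        importances=importances,
    )


def youden_threshold(probabilities, labels) -> float:
    """Probability cut-off maximizing the Youden index Se + Sp - 1.

    Candidates are midpoints between adjacent distinct predicted
    probabilities (classification rule: positive when p > threshold);
    ties resolve to the lowest threshold, favouring sensitivity.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels).astype(int)
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present")
    distinct = np.unique(p)
    if distinct.size < 2:
        raise ValueError("need more than one distinct predicted probability")
    cands = (distinct[:-1] + distinct[1:]) / 2.0
    n_pos, n_neg = (y == 1).sum(), (y == 0).sum()
    best_t, best_yi = cands[0], -np.inf
    for t in cands:
        pred = p > t
        se = (pred & (y == 1)).sum() / n_pos
        sp = (~pred & (y == 0)).sum() / n_neg
        yi = se + sp - 1.0
        if yi > best_yi + 1e-12:
            best_yi, best_t = yi, t
    return float(best_t)
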