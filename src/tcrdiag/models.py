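"""Classifier benchmark: ten model families under stratified 5-fold CV.

Seven classical families (random forest, logistic regression, KNN, decision
tree, Gaussian naive Bayes, gradient boosting, AdaBoost — all via
scikit-learn) and three neural families (MLP, 1-D CNN, Transformer — NumPy
implementations in :mod:`tcrdiag.nets`).  For each family an exhaustive
grid search is scored by stratified 5-fold cross-validated AUC; the winning
hyperparameters are refit on the full training partition and evaluated on
the held-out set with accuracy, AUC, recall and F1 (CRC is the positive
class; the classification threshold is 0.5 on the probability scale).

AUC is computed by the rank/pair-counting formulation (ties count ½), which
the test suite checks against the trapezoidal area under the constructed
ROC curve.  Standardization (z-scoring on training statistics) is applied
by default for the KNN, logistic-regression and neural families; tree
ensembles see raw frequencies.

Per-family seeds are derived from one master seed by hashing the family
name, so adding a family never perturbs another's randomness.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import (
    AdaBoostClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import ParameterGrid, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.tree import DecisionTreeClassifier

from .features import FeatureMatrix
from .nets import CNNNet, MLPNet, TransformerNet

logger = logging.getLogger("tcrdiag")

FAMILIES = (
    "random_forest",
    "logistic_regression",
    "knn",
    "decision_tree",
    "naive_bayes",
    "gradient_boosting",
    "adaboost",
    "mlp",
    "cnn",
    "transformer",
)

#: families whose inputs are z-scored on training statistics by default
STANDARDIZED_FAMILIES = frozenset(
    {"knn", "logistic_regression", "mlp", "cnn", "transformer"}
)

#: compact grids for desk-scale runs (2–3 values per tunable); the full
#: search spaces are available as :data:`FULL_GRIDS`.
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "random_forest": {"n_estimators": [200], "max_depth": [None, 8]},
    "logistic_regression": {"C": [0.1, 1.0, 10.0]},
    "knn": {"n_neighbors": [5, 11], "weights": ["uniform", "distance"]},
    "decision_tree": {"max_depth": [4, None], "min_samples_split": [2, 8]},
    "naive_bayes": {},
    "gradient_boosting": {"n_estimators": [100], "learning_rate": [0.1],
                          "max_depth": [2, 3]},
    "adaboost": {"n_estimators": [100], "learning_rate": [0.5, 1.0]},
    "mlp": {"hidden_sizes": [(64,)], "dropout": [0.1]},
    "cnn": {"filters": [8], "kernel_size": [5], "pooling": ["max"]},
    "transformer": {"d_model": [16], "nhead": [2], "num_layers": [1]},
}

FULL_GRIDS: dict[str, dict[str, list]] = {
    "random_forest": {
        "n_estimators": [100, 200, 500],
        "max_depth": [None, 4, 8, 16],
        "max_features": ["sqrt", "log2"],
        "class_weight": [None, "balanced"],
    },
    "logistic_regression": {
        "C": [0.01, 0.1, 1.0, 10.0, 100.0],
        "penalty": ["l2"],
        "solver": ["lbfgs", "liblinear"],
    },
    "knn": {"n_neighbors": [3, 5, 7, 11, 15], "weights": ["uniform", "distance"]},
    "decision_tree": {
        "max_depth": [None, 4, 8, 16],
        "min_samples_split": [2, 4, 8],
        "class_weight": [None, "balanced"],
    },
    "naive_bayes": {},
    "gradient_boosting": {
        "n_estimators": [100, 200],
        "learning_rate": [0.01, 0.1, 0.3],
        "max_depth": [2, 3, 5],
    },
    "adaboost": {"n_estimators": [50, 100, 200], "learning_rate": [0.1, 0.5, 1.0]},
    "mlp": {
        "hidden_sizes": [(64,), (128,), (64, 32)],
        "dropout": [0.0, 0.1, 0.3],
        "learning_rate": [1e-3, 3e-3],
        "epochs": [40, 80],
        "batch_size": [16, 32],
    },
    "cnn": {
        "conv_layers": [1, 2],
        "filters": [8, 16],
        "kernel_size": [3, 5, 7],
        "pooling": ["max", "avg"],
        "dropout": [0.0, 0.1],
        "learning_rate": [1e-3, 3e-3],
        "epochs": [40, 80],
        "batch_size": [16, 32],
    },
    "transformer": {
        "d_model": [16, 32],
        "nhead": [2, 4],
        "num_layers": [1, 2],
        "dropout": [0.0, 0.1],
        "learning_rate": [1e-3, 3e-3],
        "epochs": [40, 80],
        "batch_size": [16, 32],
    },
}


def derive_seed(master_seed: int, tag: str) -> int:
    """Stable per-component seed below 2^31, hashed from a master seed and a
    component tag."""
    digest = hashlib.sha256(f"{master_seed}:{tag}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class ModelSpec:
    """One classifier family with its hyperparameter grid."""

    family: str
    grid: dict[str, list] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        if not self.grid:
            self.grid = {k: list(v) for k, v in DEFAULT_GRIDS[self.family].items()}
        if self.family == "naive_bayes" and self.grid:
            raise ValueError("naive_bayes runs with default settings (empty grid)")
        allowed = set(FULL_GRIDS[self.family])
        bad = set(self.grid) - allowed
        if bad:
            raise ValueError(f"invalid hyperparameters for {self.family}: {sorted(bad)}")

    def grid_points(self) -> list[dict]:
        if not self.grid:
            return [{}]
        return list(ParameterGrid(self.grid))


def build_estimator(family: str, params: Mapping[str, Any], seed: int):
    """Instantiate an unfitted estimator for one grid point."""
    p = dict(params)
    if family == "random_forest":
        return RandomForestClassifier(random_state=seed, **p)
    if family == "logistic_regression":
        p.setdefault("max_iter", 2000)
        return LogisticRegression(random_state=seed, **p)
    if family == "knn":
        return KNeighborsClassifier(**p)
    if family == "decision_tree":
        return DecisionTreeClassifier(random_state=seed, **p)
    if family == "naive_bayes":
        return GaussianNB()
    if family == "gradient_boosting":
        return GradientBoostingClassifier(random_state=seed, **p)
    if family == "adaboost":
        return AdaBoostClassifier(random_state=seed, **p)
    if family == "mlp":
        return MLPNet(seed=seed, **p)
    if family == "cnn":
        return CNNNet(seed=seed, **p)
    if family == "transformer":
        return TransformerNet(seed=seed, **p)
    raise ValueError(f"unknown family {family!r}")


class TrainedModel:
    """A fitted family + standardization wrapper exposing class-1 scores."""

    def __init__(self, family: str, params: dict, estimator,
                 mean: np.ndarray | None, std: np.ndarray | None):
        self.family = family
        self.params = params
        self.estimator = estimator
        self._mean = mean
        self._std = std

    def _transform(self, X: np.ndarray) -> np.ndarray:
        if self._mean is None:
            return X
        return (X - self._mean) / self._std

    def score_samples(self, X: np.ndarray) -> np.ndarray:
        """Class-1 (CRC) probability per sample."""
        Z = self._transform(np.asarray(X, dtype=float))
        proba = self.estimator.predict_proba(Z)
        return np.clip(proba[:, 1], 0.0, 1.0)


def _fit_one(
    family: str,
    params: Mapping[str, Any],
    X: np.ndarray,
    y: np.ndarray,
    seed: int,
    standardize: bool | None = None,
) -> TrainedModel:
    if standardize is None:
        standardize = family in STANDARDIZED_FAMILIES
    mean = std = None
    Z = X
    if standardize:
        mean = X.mean(axis=0)
        std = X.std(axis=0)
        std = np.where(std > 0, std, 1.0)
        Z = (X - mean) / std
    est = build_estimator(family, params, seed)
    est.fit(Z, y)
    return TrainedModel(family, dict(params), est, mean, std)


# ---------------------------------------------------------------------------
# metrics

def auc_score(y_true: Sequence[int], scores: Sequence[float]) -> float:
    """AUC by pair counting via midranks: the probability that a random
    positive outscores a random negative, ties counting ½."""
    from scipy.stats import rankdata

    y = np.asarray(y_true)
    s = np.asarray(scores, dtype=float)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: evaluation set has a single class")
    ranks = rankdata(s)
    return float(
        (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    )


def roc_points(y_true: Sequence[int], scores: Sequence[float]) -> np.ndarray:
    """Ordered (FPR, TPR) points from (0,0) to (1,1), one step per distinct
    score threshold (descending)."""
    y = np.asarray(y_true)
    s = np.asarray(scores, dtype=float)
    order = np.argsort(-s, kind="mergesort")
    y_sorted = y[order]
    s_sorted = s[order]
    n_pos = max(int((y == 1).sum()), 1)
    n_neg = max(int((y == 0).sum()), 1)
    tps = np.cumsum(y_sorted == 1)
    fps = np.cumsum(y_sorted == 0)
    # keep the last index of each distinct score
    distinct = np.r_[np.diff(s_sorted) != 0, True]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    return np.column_stack([fpr, tpr])


@dataclass
class EvalReport:
    """Held-out evaluation of one trained model."""

    family: str
    accuracy: float
    auc: float
    recall: float
    f1: float
    roc: np.ndarray
    scores: np.ndarray
    n_features: int
    note: str = ""


def evaluate(
    model: TrainedModel, fm_eval: FeatureMatrix, threshold: float = 0.5
) -> EvalReport:
    """Score an evaluation set: pair-counting AUC plus thresholded accuracy,
    recall and F1 with CRC (label 1) as the positive class."""
    scores = model.score_samples(fm_eval.X)
    y = fm_eval.y
    auc = auc_score(y, scores)
    pred = (scores >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    accuracy = float((pred == y).mean())
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall)
        else 0.0
    )
    return EvalReport(
        family=model.family,
        accuracy=accuracy,
        auc=auc,
        recall=float(recall),
        f1=float(f1),
        roc=roc_points(y, scores),
        scores=scores,
        n_features=fm_eval.n_features,
    )


# ---------------------------------------------------------------------------
# cross-validation and grid search

def stratified_kfold(
    fm: FeatureMatrix, k: int = 5, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Disjoint stratified folds covering every sample exactly once."""
    _, counts = np.unique(fm.y, return_counts=True)
    if counts.min() < k:
        raise ValueError(f"smallest class has {counts.min()} samples; need >= {k}")
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [
        (train, val) for train, val in splitter.split(fm.X, fm.y)
    ]


@dataclass
class CVResult:
    """Grid-search outcome: per-point fold metrics and the winner."""

    family: str
    grid_points: list[dict]
    fold_aucs: list[list[float]]
    fold_accuracies: list[list[float]]
    mean_aucs: list[float]
    sd_aucs: list[float]
    mean_accuracies: list[float]
    best_index: int
    failures: list[int] = field(default_factory=list)

    @property
    def best_params(self) -> dict:
        return self.grid_points[self.best_index]

    @property
    def best_mean_auc(self) -> float:
        return self.mean_aucs[self.best_index]


def grid_search_cv(
    spec: ModelSpec, fm_train: FeatureMatrix, k: int = 5
) -> CVResult:
    """Exhaustive grid evaluation by stratified k-fold CV; the winner
    maximizes mean validation AUC (ties break toward earlier grid order).
    A grid point whose training fails on a fold scores AUC 0.5 there and is
    flagged, never silently dropped.
    """
    points = spec.grid_points()
    folds = stratified_kfold(fm_train, k=k, seed=derive_seed(spec.seed, "cv"))
    fold_aucs, fold_accs, failures = [], [], []
    for gi, params in enumerate(points):
        aucs, accs = [], []
        for fi, (tr, va) in enumerate(folds):
            try:
                model = _fit_one(
                    spec.family,
                    params,
                    fm_train.X[tr],
                    fm_train.y[tr],
                    seed=derive_seed(spec.seed, f"fold{fi}"),
                )
                scores = model.score_samples(fm_train.X[va])
                aucs.append(auc_score(fm_train.y[va], scores))
                accs.append(float(((scores >= 0.5).astype(int) == fm_train.y[va]).mean()))
            except Exception as exc:  # noqa: BLE001 — flagged, not dropped
                logger.warning(
                    "%s grid point %d failed on fold %d: %s",
                    spec.family, gi, fi, exc,
                )
                if gi not in failures:
                    failures.append(gi)
                aucs.append(0.5)
                accs.append(0.5)
        fold_aucs.append(aucs)
        fold_accs.append(accs)
    mean_aucs = [float(np.mean(a)) for a in fold_aucs]
    sd_aucs = [float(np.std(a)) for a in fold_aucs]
    mean_accs = [float(np.mean(a)) for a in fold_accs]
    best = int(np.argmax(mean_aucs))  # argmax takes the first maximum
    return CVResult(
        family=spec.family,
        grid_points=points,
        fold_aucs=fold_aucs,
        fold_accuracies=fold_accs,
        mean_aucs=mean_aucs,
        sd_aucs=sd_aucs,
        mean_accuracies=mean_accs,
        best_index=best,
        failures=failures,
    )


def fit_final(
    spec: ModelSpec, params: Mapping[str, Any], fm_train: FeatureMatrix
) -> TrainedModel:
    """Refit the winning hyperparameters on the full training partition."""
    return _fit_one(
        spec.family, params, fm_train.X, fm_train.y,
        seed=derive_seed(spec.seed, "final"),
    )


def benchmark_all(
    specs: Sequence[ModelSpec],
    fm_train: FeatureMatrix,
    fm_test: FeatureMatrix,
    k: int = 5,
) -> tuple[pd.DataFrame, dict[str, TrainedModel], dict[str, EvalReport]]:
    """Grid search + refit + held-out evaluation for every family.

    Returns the metrics table ranked by test AUC, the trained models, and
    the per-family evaluation reports.  Per-family failures become flagged
    rows; the table is never aborted.
    """
    if not specs:
        raise ValueError("benchmark_all requires at least one model spec")
    rows = []
    models: dict[str, TrainedModel] = {}
    reports: dict[str, EvalReport] = {}
    for spec in specs:
        try:
            cv = grid_search_cv(spec, fm_train, k=k)
            model = fit_final(spec, cv.best_params, fm_train)
            report = evaluate(model, fm_test)
            models[spec.family] = model
            reports[spec.family] = report
            rows.append(
                {
                    "family": spec.family,
                    "cv_mean_auc": cv.best_mean_auc,
                    "cv_sd_auc": cv.sd_aucs[cv.best_index],
                    "test_auc": report.auc,
                    "test_accuracy": report.accuracy,
                    "test_recall": report.recall,
                    "test_f1": report.f1,
                    "best_params": str(cv.best_params),
                    "failed": bool(cv.failures),
                }
            )
        except Exception as exc:  # noqa: BLE001 — flagged row
            logger.error("family %s failed: %s", spec.family, exc)
            rows.append(
                {
                    "family": spec.family,
                    "cv_mean_auc": np.nan,
                    "cv_sd_auc": np.nan,
                    "test_auc": np.nan,
                    "test_accuracy": np.nan,
                    "test_recall": np.nan,
                    "test_f1": np.nan,
                    "best_params": "",
                    "failed": True,
                }
            )
    table = pd.DataFrame(rows).sort_values(
        "test_auc", ascending=False, na_position="last"
    )
    return table.reset_index(drop=True), models, reports


def default_specs(
    master_seed: int, families: Sequence[str] = FAMILIES
) -> list[ModelSpec]:
    """One spec per family with the desk-scale default grid and a
    family-hashed seed."""
    return [
        ModelSpec(family=f, seed=derive_seed(master_seed, f)) for f in families
    ]
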