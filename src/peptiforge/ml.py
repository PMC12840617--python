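"""Classifier harness for DPP-IV inhibitory peptide prediction.

Peptides are labeled active (1) when IC50 < 2000 uM, featurized with the
27-component PseAAC representation, standardized with a training-time
standardizer, and classified with one of four tree-ensemble algorithms
(GBDT, random forest, LightGBM, XGBoost) behind a thin adapter
interface.  Hyperparameters are chosen by grid search with stratified
5-fold cross-validation, AUC being the primary selection metric and
accuracy the tie-breaker.  High-confidence predictions (probability
above a configurable threshold, default 0.9) are flagged as screening
candidates.
"""

from __future__ import annotations

import itertools
import json
import logging
import warnings
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.metrics import (
    accuracy_score,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold

from .features import (
    FEATURE_NAMES,
    N_FEATURES,
    PropertyScales,
    Standardizer,
    default_scales,
    featurize,
)
from .residues import InvalidResidueError, validate_sequence

log = logging.getLogger(__name__)

ACTIVITY_THRESHOLD_UM = 2000.0


def _predict_proba(estimator, X) -> np.ndarray:
    """predict_proba with lightgbm's spurious feature-name warning silenced.

    The wrapper records feature names at fit time even for plain arrays and
    then warns on every array predict; features always flow through the
    identical featurize -> standardize path here, so the warning is noise.
    """
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="X does not have valid feature names")
        return estimator.predict_proba(X)

ALGORITHMS = ("gbdt", "rf", "lightgbm", "xgboost")

#: Default 3x3x3 hyperparameter grids (not taken from any publication;
#: chosen as conventional tree-ensemble search ranges).
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "gbdt": {"n_estimators": [50, 100, 200], "learning_rate": [0.05, 0.1, 0.2], "max_depth": [2, 3, 5]},
    "rf": {"n_estimators": [100, 200, 400], "max_depth": [4, 8, 16], "max_features": ["sqrt", 0.5, 1.0]},
    "lightgbm": {"n_estimators": [50, 100, 200], "learning_rate": [0.05, 0.1, 0.2], "max_depth": [2, 3, 5]},
    "xgboost": {"n_estimators": [50, 100, 200], "learning_rate": [0.05, 0.1, 0.2], "max_depth": [2, 3, 5]},
}


@dataclass(frozen=True)
class LabeledPeptide:
    """A training example: sequence, optional IC50 (uM) and binary label."""

    sequence: str
    label: int
    ic50: float | None = None

    def __post_init__(self):
        validate_sequence(self.sequence, "peptide")
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")
        if self.ic50 is not None:
            if self.ic50 <= 0:
                raise ValueError("ic50 must be positive")
            expected = 1 if self.ic50 < ACTIVITY_THRESHOLD_UM else 0
            if self.label != expected:
                raise ValueError(
                    f"label {self.label} inconsistent with ic50 {self.ic50} uM "
                    f"under the {ACTIVITY_THRESHOLD_UM:g} uM rule"
                )


def label_by_ic50(values, threshold: float = ACTIVITY_THRESHOLD_UM) -> np.ndarray:
    """Binary activity labels: 1 iff IC50 < threshold (strict; 2000 -> 0)."""
    arr = np.asarray(values, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("IC50 values must be positive")
    return (arr < threshold).astype(int)


def compute_metrics(y_true, y_pred, y_score=None) -> dict[str, float]:
    """Accuracy, recall, precision, F1 and rank-based ROC-AUC.

    AUC is the probability that a positive outranks a negative, ties
    counting one half.  With a single-class truth vector the AUC is
    undefined and reported as NaN with a warning.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("length mismatch between truth and prediction")
    metrics = {
        "accuracy": float(accuracy_score(y_true, y_pred)),
        "recall": float(recall_score(y_true, y_pred, zero_division=0)),
        "precision": float(precision_score(y_true, y_pred, zero_division=0)),
        "f1": float(f1_score(y_true, y_pred, zero_division=0)),
    }
    if y_score is not None:
        if len(np.unique(y_true)) < 2:
            warnings.warn("AUC undefined for single-class truth; reporting NaN")
            metrics["auc"] = float("nan")
        else:
            metrics["auc"] = float(roc_auc_score(y_true, np.asarray(y_score, dtype=float)))
    return metrics


def _make_estimator(algorithm: str, params: dict, seed: int):
    """Adapter: one constructor per supported library, uniformly seeded."""
    if algorithm == "gbdt":
        from sklearn.ensemble import GradientBoostingClassifier

        return GradientBoostingClassifier(random_state=seed, **params)
    if algorithm == "rf":
        from sklearn.ensemble import RandomForestClassifier

        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if algorithm == "lightgbm":
        from lightgbm import LGBMClassifier

        return LGBMClassifier(random_state=seed, n_jobs=1, verbosity=-1, **params)
    if algorithm == "xgboost":
        from xgboost import XGBClassifier

        return XGBClassifier(
            random_state=seed, n_jobs=1, verbosity=0, eval_metric="logloss", **params
        )
    raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")


@dataclass
class TrainedModel:
    """A fitted classifier bundled with its featurization state.

    Prediction reuses exactly the training-time path: same PseAAC weight
    ``w``, same property scales, same standardizer.
    """

    algorithm: str
    params: dict
    seed: int
    w: float
    standardizer: Standardizer
    estimator: object
    scales: PropertyScales

    def _features(self, sequences) -> np.ndarray:
        X = np.vstack([featurize(s, w=self.w, scales=self.scales) for s in sequences])
        return self.standardizer.transform(X)

    def predict_proba(self, sequences) -> np.ndarray:
        """Probability of the active class for each sequence."""
        return _predict_proba(self.estimator, self._features(sequences))[:, 1]

    def save(self, path) -> None:
        """Persist as a joblib artifact plus a self-describing JSON sidecar."""
        joblib.dump(self, path)
        meta = {
            "algorithm": self.algorithm,
            "params": self.params,
            "seed": self.seed,
            "w": self.w,
            "n_features": N_FEATURES,
            "feature_names": list(FEATURE_NAMES),
            "standardizer": self.standardizer.to_dict(),
            "scales_fingerprint": joblib.hash(self.scales.table.to_numpy()),
        }
        with open(f"{path}.json", "w") as fh:
            json.dump(meta, fh, indent=1)

    @classmethod
    def load(cls, path) -> "TrainedModel":
        model = joblib.load(path)
        if not isinstance(model, cls):
            raise TypeError(f"{path} does not contain a TrainedModel")
        return model


@dataclass
class CVResult:
    """Outcome of grid-searched stratified cross-validation."""

    algorithm: str
    best_params: dict
    fold_metrics: list[dict]
    mean_metrics: dict
    feature_importances: np.ndarray
    seed: int
    grid_results: list[dict] = field(default_factory=list)
    model: TrainedModel | None = None


def _grid_points(grid: dict[str, list]) -> list[dict]:
    keys = list(grid)
    return [dict(zip(keys, combo)) for combo in itertools.product(*(grid[k] for k in keys))]


def _dataset_arrays(dataset, w, scales):
    seqs = [p.sequence for p in dataset]
    y = np.array([p.label for p in dataset], dtype=int)
    X = np.vstack([featurize(s, w=w, scales=scales) for s in seqs])
    return X, y


def cross_validate(
    dataset,
    algorithm: str,
    grid: dict[str, list] | None = None,
    k: int = 5,
    seed: int = 0,
    w: float = 0.05,
    scales: PropertyScales | None = None,
) -> CVResult:
    """Grid search with stratified k-fold cross-validation.

    For every grid point, out-of-fold metrics are computed with the
    standardizer refitted on each training split.  The best point
    maximizes mean AUC, ties broken by mean accuracy and then by grid
    order.  The returned result carries the per-fold and mean metrics of
    the winner, a model refitted on the full dataset, and its normalized
    feature-importance vector.  Deterministic given ``seed``.
    """
    scales = scales or default_scales()
    if grid is None:
        grid = DEFAULT_GRIDS[algorithm]
    points = _grid_points(grid)
    if not points:
        raise ValueError("empty hyperparameter grid")
    X, y = _dataset_arrays(dataset, w, scales)
    class_counts = np.bincount(y, minlength=2)
    if np.any(class_counts < k):
        raise ValueError(f"need at least k={k} samples per class, got {class_counts.tolist()}")

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))

    evaluated = []
    for point in points:
        fold_metrics = []
        for train_idx, test_idx in splits:
            std = Standardizer().fit(X[train_idx])
            clf = _make_estimator(algorithm, point, seed)
            clf.fit(std.transform(X[train_idx]), y[train_idx])
            scores = _predict_proba(clf, std.transform(X[test_idx]))[:, 1]
            preds = (scores >= 0.5).astype(int)
            fold_metrics.append(compute_metrics(y[test_idx], preds, scores))
        mean = {m: float(np.nanmean([f[m] for f in fold_metrics])) for m in fold_metrics[0]}
        evaluated.append({"params": point, "fold_metrics": fold_metrics, "mean_metrics": mean})

    best_idx = max(
        range(len(evaluated)),
        key=lambda i: (
            evaluated[i]["mean_metrics"]["auc"],
            evaluated[i]["mean_metrics"]["accuracy"],
            -i,
        ),
    )
    best = evaluated[best_idx]

    model = train(dataset, algorithm, params=best["params"], seed=seed, w=w, scales=scales)
    importances = np.asarray(model.estimator.feature_importances_, dtype=float)
    total = importances.sum()
    if total > 0:
        importances = importances / total
    else:
        importances = np.full(N_FEATURES, 1.0 / N_FEATURES)

    return CVResult(
        algorithm=algorithm,
        best_params=best["params"],
        fold_metrics=best["fold_metrics"],
        mean_metrics=best["mean_metrics"],
        feature_importances=importances,
        seed=seed,
        grid_results=[{"params": e["params"], "mean_metrics": e["mean_metrics"]} for e in evaluated],
        model=model,
    )


def train(
    dataset,
    algorithm: str,
    params: dict | None = None,
    seed: int = 0,
    w: float = 0.05,
    scales: PropertyScales | None = None,
) -> TrainedModel:
    """Fit a classifier on the full dataset (featurize -> standardize -> fit)."""
    scales = scales or default_scales()
    params = params or {}
    X, y = _dataset_arrays(dataset, w, scales)
    std = Standardizer().fit(X)
    clf = _make_estimator(algorithm, params, seed)
    clf.fit(std.transform(X), y)
    return TrainedModel(algorithm, dict(params), seed, w, std, clf, scales)


def rank_feature_importance(result: CVResult) -> list[tuple[str, float]]:
    """Features by descending normalized importance; ties break by index."""
    weights = np.asarray(result.feature_importances, dtype=float)
    total = weights.sum()
    if total > 0:
        weights = weights / total
    order = np.lexsort((np.arange(len(weights)), -weights))
    return [(FEATURE_NAMES[i], float(weights[i])) for i in order]


def predict_candidates(model: TrainedModel, peptides, threshold: float = 0.9) -> pd.DataFrame:
    """Score peptides and flag high-confidence candidate inhibitors.

    Rows with invalid residues are skipped with a log entry.  Returns a
    DataFrame with columns ``sequence``, ``probability`` and
    ``high_confidence`` (probability >= threshold).
    """
    valid = []
    for seq in peptides:
        try:
            validate_sequence(seq, "peptide")
        except InvalidResidueError as exc:
            log.error("skipping peptide: %s", exc)
            continue
        valid.append(seq)
    if not valid:
        return pd.DataFrame(columns=["sequence", "probability", "high_confidence"])
    probs = model.predict_proba(valid)
    return pd.DataFrame(
        {
            "sequence": valid,
            "probability": probs,
            "high_confidence": probs >= threshold,
        }
    )
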