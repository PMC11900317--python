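"""Kinase-family classifiers: grid search, repeated-holdout CV, validation.

Three algorithm families are supported — random forest, Gaussian naive
Bayes, and a multi-layer perceptron — each paired with one of the three
fingerprint kinds. Hyperparameters are selected by exhaustive grid search
under 3-fold stratified CV scored by mean MCC; model robustness is then
assessed by repeated stratified 70/30 holdout resampling ("n-fold CV" in
the repeated-subsampling sense).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier

from .curation import LabeledDataset
from .featurize import FP_LENGTH, FeatureMatrix
from .metrics import (
    ConfusionMetrics,
    MetricSummary,
    metrics_from_predictions,
    summarize_repeats,
)

ALGORITHMS = ("random_forest", "gaussian_nb", "mlp")

#: Canonical hyperparameter grids; order is the documented tie-break order.
RF_GRID = [
    {"n_estimators": n, "max_features": mf}
    for n in (100, 500)
    for mf in ("sqrt", None, "log2")
]
GNB_GRID = [{"var_smoothing": v} for v in (1e-9, 1e-8, 1e-7, 1e-6)]
#: 1-2 hidden layers over widths {100, 200, 1000}; all width combinations.
MLP_WIDTHS = (100, 200, 1000)
MLP_GRID = [{"hidden_layer_sizes": (w,)} for w in MLP_WIDTHS] + [
    {"hidden_layer_sizes": (w1, w2)} for w1 in MLP_WIDTHS for w2 in MLP_WIDTHS
]

DEFAULT_GRIDS = {"random_forest": RF_GRID, "gaussian_nb": GNB_GRID, "mlp": MLP_GRID}


@dataclass(frozen=True)
class ModelSpec:
    """Algorithm + fingerprint kind + hyperparameters + seed."""

    algorithm: str
    fingerprint_kind: str
    hyperparams: tuple[tuple[str, object], ...]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.fingerprint_kind not in FP_LENGTH:
            raise ValueError(f"unknown fingerprint kind {self.fingerprint_kind!r}")

    @classmethod
    def make(cls, algorithm, fingerprint_kind, hyperparams: dict, seed=0):
        return cls(algorithm, fingerprint_kind, tuple(sorted(hyperparams.items())), seed)

    @property
    def params(self) -> dict:
        return dict(self.hyperparams)


@dataclass
class CVProtocol:
    """Repeated stratified random-holdout evaluation protocol."""

    n_repeats: int = 10
    test_fraction: float = 0.3
    stratified: bool = True
    scoring: str = "mcc"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0, 1)")
        from .metrics import METRIC_NAMES

        if self.scoring not in METRIC_NAMES:
            raise ValueError(f"unknown scoring metric {self.scoring!r}")


@dataclass
class TrainedModel:
    """A fitted estimator plus the metadata needed to use it safely."""

    spec: ModelSpec
    estimator: object
    decision_threshold: float = 0.5
    training_smiles: frozenset[str] = frozenset()
    training_hash: str = ""

    @property
    def fingerprint_kind(self) -> str:
        return self.spec.fingerprint_kind


def build_estimator(spec: ModelSpec):
    """Instantiate the scikit-learn estimator for a spec (unfitted)."""
    params = spec.params
    if spec.algorithm == "random_forest":
        return RandomForestClassifier(
            n_estimators=params.get("n_estimators", 100),
            max_features=params.get("max_features", "sqrt"),
            class_weight=params.get("class_weight"),
            random_state=spec.seed,
            n_jobs=1,
        )
    if spec.algorithm == "gaussian_nb":
        return GaussianNB(var_smoothing=params.get("var_smoothing", 1e-9))
    # MLP: rectifier units, adaptive-moment optimizer, early stopping on a
    # 10% validation split, at most 200 epochs
    return MLPClassifier(
        hidden_layer_sizes=params.get("hidden_layer_sizes", (100,)),
        activation="relu",
        solver="adam",
        early_stopping=True,
        validation_fraction=0.1,
        max_iter=200,
        random_state=spec.seed,
    )


def _check_features(features: FeatureMatrix, kind: str) -> np.ndarray:
    if features.kind != kind:
        raise ValueError(
            f"fingerprint kind mismatch: model expects {kind!r}, "
            f"features are {features.kind!r}"
        )
    return np.asarray(features.matrix, dtype=np.float64)


def grid_search(
    algorithm: str,
    features: FeatureMatrix,
    labels: Sequence[int],
    seed: int = 0,
    grid: list[dict] | None = None,
    n_folds: int = 3,
) -> tuple[ModelSpec, list[tuple[dict, float]]]:
    """Exhaustive grid search under stratified k-fold CV scored by mean MCC.

    Returns the winning spec and the full (params, score) log. Ties break
    toward the first-listed grid point. Repeats in which MCC is undefined
    contribute a score of 0 for ranking purposes (logged as-is).
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("grid_search requires both classes present")
    if counts.min() < 2:
        raise ValueError("grid_search requires >= 2 examples per class")
    grid = grid if grid is not None else DEFAULT_GRIDS[algorithm]
    if not grid:
        raise ValueError("empty hyperparameter grid")

    X = np.asarray(features.matrix, dtype=np.float64)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(X, labels))

    log: list[tuple[dict, float]] = []
    best_spec: ModelSpec | None = None
    best_score = -np.inf
    for params in grid:
        spec = ModelSpec.make(algorithm, features.kind, params, seed=seed)
        scores = []
        for train_idx, test_idx in folds:
            est = build_estimator(spec)
            est.fit(X[train_idx], labels[train_idx])
            pred = est.predict(X[test_idx])
            cm = metrics_from_predictions(labels[test_idx], pred)
            scores.append(cm.mcc if cm.mcc is not None else 0.0)
        mean_score = float(np.mean(scores))
        log.append((params, mean_score))
        if mean_score > best_score:
            best_score = mean_score
            best_spec = spec
    return best_spec, log


def fit(
    spec: ModelSpec,
    features: FeatureMatrix,
    labels: Sequence[int],
    decision_threshold: float = 0.5,
    training_smiles: Sequence[str] | None = None,
) -> TrainedModel:
    """Fit an estimator for the spec on the full feature matrix."""
    X = _check_features(features, spec.fingerprint_kind)
    y = np.asarray(labels)
    est = build_estimator(spec)
    est.fit(X, y)
    smiles = frozenset(training_smiles or [])
    digest = hashlib.sha256(
        ("\n".join(sorted(smiles)) + repr(spec)).encode()
    ).hexdigest()
    return TrainedModel(
        spec=spec,
        estimator=est,
        decision_threshold=decision_threshold,
        training_smiles=smiles,
        training_hash=digest,
    )


def predict_proba(model: TrainedModel, features: FeatureMatrix) -> np.ndarray:
    """Probability of the positive (active) class per row."""
    X = _check_features(features, model.fingerprint_kind)
    est = model.estimator
    if not hasattr(est, "classes_"):
        raise ValueError("model is not fitted")
    proba = est.predict_proba(X)
    pos_col = int(np.flatnonzero(est.classes_ == 1)[0])
    return proba[:, pos_col]


def classify(model: TrainedModel, features: FeatureMatrix) -> np.ndarray:
    """Binary labels: probability >= decision_threshold."""
    return (predict_proba(model, features) >= model.decision_threshold).astype(int)


def cross_validate(
    spec: ModelSpec,
    features: FeatureMatrix,
    labels: Sequence[int],
    protocol: CVProtocol,
    decision_threshold: float = 0.5,
) -> MetricSummary:
    """Repeated stratified random 70/30 (by default) holdout evaluation.

    Each repeat refits from scratch on its training partition and scores
    the held-out partition; per-repeat confusion metrics are summarized
    as mean +/- population sd. Repeats with a class missing from the test
    partition yield undefined rates which the summary records, never
    silently drops.
    """
    X = _check_features(features, spec.fingerprint_kind)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("cross_validate requires both classes present")
    rng = np.random.default_rng(protocol.seed)
    repeats: list[ConfusionMetrics] = []
    for rep in range(protocol.n_repeats):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        train_idx, test_idx = _holdout_indices(
            y, protocol.test_fraction, rep_seed, protocol.stratified
        )
        rep_spec = ModelSpec.make(
            spec.algorithm, spec.fingerprint_kind, spec.params, seed=rep_seed
        )
        est = build_estimator(rep_spec)
        est.fit(X[train_idx], y[train_idx])
        proba = est.predict_proba(X[test_idx])
        pos_col = int(np.flatnonzero(est.classes_ == 1)[0])
        pred = (proba[:, pos_col] >= decision_threshold).astype(int)
        repeats.append(metrics_from_predictions(y[test_idx], pred))
    return summarize_repeats(repeats)


def _holdout_indices(
    y: np.ndarray, test_fraction: float, seed: int, stratified: bool
) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(seed)
    n = len(y)
    if stratified:
        train: list[int] = []
        test: list[int] = []
        for c in np.unique(y):
            idx = np.flatnonzero(y == c)
            rng.shuffle(idx)
            n_test = int(round(test_fraction * len(idx)))
            test.extend(idx[:n_test].tolist())
            train.extend(idx[n_test:].tolist())
        return np.array(sorted(train)), np.array(sorted(test))
    idx = rng.permutation(n)
    n_test = int(round(test_fraction * n))
    return np.sort(idx[n_test:]), np.sort(idx[:n_test])


def external_validate(
    model: TrainedModel,
    external: LabeledDataset,
    features: FeatureMatrix,
) -> ConfusionMetrics:
    """Single-pass confusion metrics on an untouched external dataset.

    Refuses any structural overlap with the training set (checked on
    standardized SMILES).
    """
    if len(external) == 0:
        raise ValueError("external dataset is empty")
    if model.training_smiles:
        overlap = [
            rec.compound_id
            for rec, _ in external.records
            if rec.smiles_std in model.training_smiles
        ]
        if overlap:
            raise ValueError(
                f"external set overlaps training set: {overlap[:10]}"
                + ("..." if len(overlap) > 10 else "")
            )
    pred = classify(model, features)
    return metrics_from_predictions(external.labels, pred)


# ---------------------------------------------------------------------------
# model card serialization
# ---------------------------------------------------------------------------


def write_model_card(
    model: TrainedModel,
    path: str | Path,
    grid_log: list[tuple[dict, float]] | None = None,
    cv_summary: MetricSummary | None = None,
    model_path: str | None = None,
) -> None:
    card = {
        "algorithm": model.spec.algorithm,
        "fingerprint_kind": model.spec.fingerprint_kind,
        "hyperparams": model.spec.params,
        "seed": model.spec.seed,
        "decision_threshold": model.decision_threshold,
        "training_hash": model.training_hash,
        "n_training_structures": len(model.training_smiles),
        "model_path": model_path,
    }
    if grid_log is not None:
        card["grid_log"] = [{"params": p, "mean_mcc": s} for p, s in grid_log]
    if cv_summary is not None:
        card["cv_mean"] = cv_summary.mean
        card["cv_sd"] = cv_summary.sd
        card["cv_n_undefined"] = cv_summary.n_undefined
    Path(path).write_text(json.dumps(card, indent=2, default=str))


def save_model(model: TrainedModel, path: str | Path) -> None:
    import joblib

    joblib.dump(model, path)


def load_model(path: str | Path) -> TrainedModel:
    import joblib

    return joblib.load(path)
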