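"""Supervised classification of reads as erroneous (1) or correct (0).

Five classifier families are supported, each with fixed default
hyperparameters: multinomial naive Bayes (alpha = 0.1), linear SVM (C = 1),
random forest (100 trees, min_samples_split = 2, min_samples_leaf = 1),
L2-penalized logistic regression (C = 1, lbfgs), and gradient-boosted trees
(XGBoost, max_depth = 3, 300 rounds, learning rate 0.1, binary logistic
objective, no early stopping).

The decision rule is: score > threshold predicts 1, with ties broken toward
label 1 (flagging a read as erroneous is the conservative failure mode). The
threshold is 0.5 on a probability and 0 on an SVM decision value.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import scipy.sparse as sp
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.naive_bayes import MultinomialNB
from sklearn.svm import LinearSVC
from xgboost import XGBClassifier

from .evaluate import MetricsReport, evaluate_predictions
from .features import Vocabulary

ALGORITHMS = ("nb", "svm", "rf", "lr", "xgb")

_DEFAULT_HYPERPARAMETERS: dict[str, dict] = {
    "nb": {"alpha": 0.1},
    "svm": {"C": 1.0},
    "rf": {"n_estimators": 100, "min_samples_split": 2, "min_samples_leaf": 1},
    "lr": {"C": 1.0, "penalty": "l2", "solver": "lbfgs"},
    "xgb": {"max_depth": 3, "n_estimators": 300, "learning_rate": 0.1},
}


@dataclass
class ModelConfig:
    """Algorithm choice plus hyperparameter overrides and a seed."""

    algorithm: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(
                f"unknown algorithm {self.algorithm!r}; choose from {ALGORITHMS}"
            )
        merged = dict(_DEFAULT_HYPERPARAMETERS[self.algorithm])
        merged.update(self.hyperparameters)
        self.hyperparameters = merged

    def build_estimator(self):
        hp = self.hyperparameters
        if self.algorithm == "nb":
            return MultinomialNB(alpha=hp["alpha"])
        if self.algorithm == "svm":
            return LinearSVC(C=hp["C"], random_state=self.seed)
        if self.algorithm == "rf":
            return RandomForestClassifier(
                n_estimators=hp["n_estimators"],
                min_samples_split=hp["min_samples_split"],
                min_samples_leaf=hp["min_samples_leaf"],
                random_state=self.seed,
                n_jobs=1,
            )
        if self.algorithm == "lr":
            if hp["penalty"].lower() != "l2":
                raise ValueError("only the L2 penalty is supported for LR")
            # TF-IDF entries are O(IDF / L); with 10^6+ columns the lbfgs
            # gradient per coordinate starts below the library's default
            # stopping tolerance and the solver would quit at iteration 0,
            # so the tolerance is tightened here.
            return LogisticRegression(
                C=hp["C"],
                solver=hp["solver"],
                random_state=self.seed,
                max_iter=5000,
                tol=1e-8,
            )
        return XGBClassifier(
            max_depth=hp["max_depth"],
            n_estimators=hp["n_estimators"],
            learning_rate=hp["learning_rate"],
            objective="binary:logistic",
            random_state=self.seed,
            n_jobs=1,
            verbosity=0,
        )


@dataclass
class SplitPlan:
    """Train/test read-id split with a k-fold partition of the training ids."""

    train_ids: list[str]
    test_ids: list[str]
    folds: list[list[str]]
    seed: int

    def __post_init__(self) -> None:
        overlap = set(self.train_ids) & set(self.test_ids)
        if overlap:
            raise ValueError(f"train/test overlap: {sorted(overlap)[:5]} ...")


@dataclass
class TrainedClassifier:
    """A fitted estimator bound to the vocabulary its features came from."""

    config: ModelConfig
    estimator: object
    vocabulary: Vocabulary | None = None

    @property
    def k(self) -> int | None:
        return self.vocabulary.k if self.vocabulary is not None else None


def make_split(
    read_ids: list[str],
    labels: np.ndarray | list[int],
    n_train: int,
    n_test: int,
    seed: int,
    cv_folds: int = 5,
) -> SplitPlan:
    """Stratified train/test split plus a stratified k-fold plan.

    The split is deterministic under ``seed``. Labels must contain both
    classes and the training set must be large enough for ``cv_folds``.
    """
    labels = np.asarray(labels)
    if len(read_ids) != labels.size:
        raise ValueError("read_ids and labels must have equal length")
    if n_train + n_test > len(read_ids):
        raise ValueError(
            f"n_train + n_test = {n_train + n_test} exceeds dataset size {len(read_ids)}"
        )
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present for a stratified split")
    if n_train < cv_folds:
        raise ValueError(
            f"cannot form {cv_folds} folds from {n_train} training reads"
        )
    ids = np.asarray(read_ids)
    idx = np.arange(len(ids))
    train_idx, rest_idx = train_test_split(
        idx, train_size=n_train, stratify=labels, random_state=seed, shuffle=True
    )
    if n_test < rest_idx.size:
        test_idx, _ = train_test_split(
            rest_idx,
            train_size=n_test,
            stratify=labels[rest_idx],
            random_state=seed,
            shuffle=True,
        )
    else:
        test_idx = rest_idx
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    folds = [
        list(ids[train_idx[fold]])
        for _, fold in skf.split(train_idx, labels[train_idx])
    ]
    return SplitPlan(
        train_ids=list(ids[train_idx]),
        test_ids=list(ids[test_idx]),
        folds=folds,
        seed=seed,
    )


def _check_X_y(X: sp.spmatrix, y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    if X.shape[0] != y.size:
        raise ValueError(f"X has {X.shape[0]} rows but y has {y.size} labels")
    if np.isnan(X.data if sp.issparse(X) else X).any():
        raise ValueError("feature matrix contains NaN")
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    return y


def train(
    config: ModelConfig,
    X: sp.spmatrix,
    y: np.ndarray | list[int],
    vocabulary: Vocabulary | None = None,
) -> TrainedClassifier:
    y = _check_X_y(X, np.asarray(y))
    est = config.build_estimator()
    est.fit(X, y)
    return TrainedClassifier(config=config, estimator=est, vocabulary=vocabulary)


def _check_columns(model: TrainedClassifier, X: sp.spmatrix) -> None:
    n_expected = getattr(model.estimator, "n_features_in_", None)
    if n_expected is not None and X.shape[1] != n_expected:
        raise ValueError(
            f"feature matrix has {X.shape[1]} columns; model expects {n_expected}"
        )


def predict_scores(model: TrainedClassifier, X: sp.spmatrix) -> np.ndarray:
    """Continuous scores monotone in the predicted class.

    Probability of class 1 where available; signed decision value for the
    linear SVM (positive favors label 1).
    """
    _check_columns(model, X)
    if X.shape[0] == 0:
        return np.empty(0)
    est = model.estimator
    if hasattr(est, "predict_proba"):
        return est.predict_proba(X)[:, 1]
    return est.decision_function(X)


def decision_threshold(model: TrainedClassifier) -> float:
    """0.5 for probabilistic scores, 0 for SVM decision values."""
    return 0.0 if model.config.algorithm == "svm" else 0.5


def predict_labels(model: TrainedClassifier, X: sp.spmatrix) -> np.ndarray:
    """Binary labels; score >= threshold maps to 1 (ties flagged erroneous)."""
    scores = predict_scores(model, X)
    return (scores >= decision_threshold(model)).astype(np.int64)


def cross_validate(
    config: ModelConfig,
    X: sp.spmatrix,
    y: np.ndarray | list[int],
    n_folds: int = 5,
    seed: int = 0,
) -> tuple[list[MetricsReport], dict[str, float]]:
    """Stratified k-fold cross-validation; per-fold reports plus mean/sd.

    Folds whose training part is single-class are flagged (report ``None``)
    and excluded from the summary.
    """
    y = _check_X_y(X, np.asarray(y))
    if n_folds < 2:
        raise ValueError(f"cross-validation requires >= 2 folds, got {n_folds}")
    X = sp.csr_matrix(X)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    reports: list[MetricsReport | None] = []
    for tr, va in skf.split(X, y):
        if len(np.unique(y[tr])) < 2 or len(np.unique(y[va])) < 2:
            reports.append(None)
            continue
        model = train(config, X[tr], y[tr])
        y_pred = predict_labels(model, X[va])
        scores = predict_scores(model, X[va])
        reports.append(evaluate_predictions(y[va], y_pred, scores=scores))
    valid = [r for r in reports if r is not None]
    summary: dict[str, float] = {}
    if valid:
        for name in ("accuracy", "precision", "recall", "f1", "mcc", "roc_auc"):
            vals = [getattr(r, name) for r in valid if getattr(r, name) is not None]
            if vals:
                summary[f"{name}_mean"] = float(np.mean(vals))
                summary[f"{name}_sd"] = float(np.std(vals))
    return reports, summary


def save_bundle(model: TrainedClassifier, directory: str | Path) -> None:
    """Persist a model as {config.json, vocabulary.tsv, model.joblib}."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cfg = {
        "algorithm": model.config.algorithm,
        "hyperparameters": model.config.hyperparameters,
        "seed": model.config.seed,
        "k": model.k,
    }
    (directory / "config.json").write_text(json.dumps(cfg, indent=2) + "\n")
    if model.vocabulary is not None:
        model.vocabulary.to_tsv(directory / "vocabulary.tsv")
    joblib.dump(model.estimator, directory / "model.joblib")


def load_bundle(directory: str | Path) -> TrainedClassifier:
    directory = Path(directory)
    cfg = json.loads((directory / "config.json").read_text())
    config = ModelConfig(
        algorithm=cfg["algorithm"],
        hyperparameters=cfg["hyperparameters"],
        seed=cfg["seed"],
    )
    vocab_path = directory / "vocabulary.tsv"
    vocabulary = Vocabulary.from_tsv(vocab_path) if vocab_path.exists() else None
    estimator = joblib.load(directory / "model.joblib")
    return TrainedClassifier(config=config, estimator=estimator, vocabulary=vocabulary)
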