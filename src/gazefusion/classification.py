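"""Base classifier zoo: exhaustive grid search with variable-k CV, held-out
confidence scoring and threshold-based candidate selection.

Every (parameter combination, k) pair in a spec's grid x k-range is scored by
stratified k-fold CV mean accuracy on the training rows; the winner (first in
enumeration order on ties: grid declaration order, smaller k first within a
combination) is refit on all training rows.  Held-out scores are two-class
confidence vectors normalized to sum to 1; families without a probability
output have their decision margins squashed through a logistic sigmoid.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.base import clone
from sklearn.ensemble import (AdaBoostClassifier, BaggingClassifier,
                              GradientBoostingClassifier, RandomForestClassifier)
from sklearn.linear_model import SGDClassifier
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .errors import ConfigurationError, DataError, PreconditionError
from .features import FeatureTable

#: Fixed family precedence used for all tie-breaking.
FAMILY_ORDER = ("decision_tree", "random_forest", "bagging", "adaboost",
                "gradient_boosting", "knn", "svm", "sgd")

_FAMILY_FACTORIES = {
    "decision_tree": DecisionTreeClassifier,
    "random_forest": RandomForestClassifier,
    "bagging": BaggingClassifier,
    "adaboost": AdaBoostClassifier,
    "gradient_boosting": GradientBoostingClassifier,
    "knn": KNeighborsClassifier,
    "svm": lambda **kw: SVC(probability=True, **kw),
    "sgd": lambda **kw: SGDClassifier(loss="log_loss", **kw),
}

DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "decision_tree": {"max_depth": [3, 5, None]},
    "random_forest": {"n_estimators": [50, 100], "max_depth": [5, None]},
    "bagging": {"n_estimators": [10, 30]},
    "adaboost": {"n_estimators": [30, 50]},
    "gradient_boosting": {"n_estimators": [50, 100]},
    "knn": {"n_neighbors": [3, 5, 7]},
    "svm": {"C": [0.1, 1.0, 10.0]},
    "sgd": {"alpha": [1e-4, 1e-3]},
}

#: One-point grids for fast experiments and tests.
SMALL_GRIDS: dict[str, dict[str, list]] = {
    "decision_tree": {"max_depth": [5]},
    "random_forest": {"n_estimators": [100]},
    "bagging": {"n_estimators": [10]},
    "adaboost": {"n_estimators": [30]},
    "gradient_boosting": {"n_estimators": [50]},
    "knn": {"n_neighbors": [5]},
    "svm": {"C": [1.0]},
    "sgd": {"alpha": [1e-4]},
}


@dataclass(frozen=True)
class ClassifierSpec:
    family: str
    parameter_grid: dict[str, list] = field(default_factory=dict)
    k_range: tuple[int, ...] = tuple(range(2, 11))

    def __post_init__(self) -> None:
        if self.family not in _FAMILY_FACTORIES:
            raise ConfigurationError("family", f"unknown family {self.family!r}")
        if not self.parameter_grid or any(not v for v in self.parameter_grid.values()):
            raise ConfigurationError("parameter_grid", "grid must be non-empty")
        if any(k < 2 or k > 10 for k in self.k_range):
            raise ConfigurationError("k_range", f"must lie within [2, 10], got {self.k_range}")

    def combinations(self):
        """Parameter combinations in grid declaration order."""
        keys = list(self.parameter_grid)
        for values in itertools.product(*(self.parameter_grid[k] for k in keys)):
            yield dict(zip(keys, values))


def default_specs(small: bool = False, k_range: Sequence[int] | None = None,
                  families: Sequence[str] | None = None) -> list[ClassifierSpec]:
    grids = SMALL_GRIDS if small else DEFAULT_GRIDS
    ks = tuple(k_range) if k_range is not None else tuple(range(2, 11))
    families = families or FAMILY_ORDER
    return [ClassifierSpec(family=f, parameter_grid=dict(grids[f]), k_range=ks)
            for f in families]


@dataclass
class ScoreSet:
    """Per-test-sample confidence vectors from one trained classifier."""

    family: str
    params: dict
    k: int
    sample_ids: np.ndarray
    scores: np.ndarray  # (n_samples, 2), rows sum to 1
    class_labels: tuple[str, str]  # column order; positive class is index 1
    test_accuracy: float
    cv_accuracy: float

    @property
    def name(self) -> str:
        return f"{self.family}(k={self.k})"

    @property
    def predictions(self) -> np.ndarray:
        return np.asarray(self.class_labels)[np.argmax(self.scores, axis=1)]


def _make_estimator(family: str, params: dict, seed: int):
    est = _FAMILY_FACTORIES[family](**params)
    if "random_state" in est.get_params():
        est.set_params(random_state=seed)
    return est


def split_dataset(table: FeatureTable, ratio: float, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Seeded stratified split; ``ratio`` is the train fraction."""
    if len(table) == 0:
        raise DataError("empty feature table")
    if not 0.0 < ratio < 1.0:
        raise ConfigurationError("ratio", f"must be in (0, 1), got {ratio}")
    y = table.labels
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < 2:
        raise DataError("every class needs at least 2 rows to split")
    idx = np.arange(len(table))
    train_idx, test_idx = train_test_split(idx, train_size=ratio, random_state=seed,
                                           stratify=y, shuffle=True)
    return np.sort(train_idx), np.sort(test_idx)


def _cv_mean_accuracy(family: str, params: dict, k: int,
                      X: np.ndarray, y: np.ndarray, seed: int) -> float:
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    accs = []
    for train, val in skf.split(X, y):
        if len(np.unique(y[train])) < 2:
            warnings.warn(f"skipping degenerate single-class fold (k={k})")
            continue
        est = _make_estimator(family, params, seed)
        try:
            est.fit(X[train], y[train])
            accs.append(float(np.mean(est.predict(X[val]) == y[val])))
        except ValueError as exc:  # e.g. boosting on uninformative features,
            # or a neighbor count exceeding a tiny fold
            warnings.warn(f"{family} could not score a fold ({exc}); scoring it 0")
            accs.append(0.0)
    if not accs:
        raise DataError(f"all folds degenerate for k={k}")
    return float(np.mean(accs))


def tune_and_train(spec: ClassifierSpec, table: FeatureTable,
                   train_index: Sequence[int], seed: int = 0):
    """Exhaustive (params x k) search by k-fold CV accuracy; returns
    ``(fitted_model, best_params, best_k, cv_accuracy)``."""
    train_index = np.asarray(train_index, dtype=int)
    X = table.features()[train_index]
    y = table.labels[train_index]
    if len(np.unique(y)) < 2:
        raise DataError("training rows must cover both classes")

    best: Optional[tuple[dict, int, float]] = None
    for params in spec.combinations():
        for k in sorted(spec.k_range):
            if k > np.bincount(np.unique(y, return_inverse=True)[1]).min():
                continue  # fewer members than folds
            try:
                acc = _cv_mean_accuracy(spec.family, params, k, X, y, seed)
            except DataError:
                continue
            if best is None or acc > best[2]:
                best = (params, k, acc)
    if best is None:
        raise DataError("no evaluable (params, k) pair")
    params, k, cv_acc = best
    model = _make_estimator(spec.family, params, seed)
    try:
        model.fit(X, y)
    except ValueError as exc:
        # degenerate training data (e.g. constant features); fall back to a
        # prior-based majority predictor so downstream fusion stays total
        from sklearn.dummy import DummyClassifier
        warnings.warn(f"{spec.family} could not fit ({exc}); "
                      "using a majority-prior fallback")
        model = DummyClassifier(strategy="prior")
        model.fit(X, y)
    return model, params, k, cv_acc


def _confidences(model, X: np.ndarray, class_labels: tuple[str, str]) -> np.ndarray:
    if hasattr(model, "predict_proba"):
        proba = model.predict_proba(X)
        cols = list(model.classes_)
        out = np.zeros((len(X), 2))
        for j, label in enumerate(class_labels):
            if label in cols:
                out[:, j] = proba[:, cols.index(label)]
    else:  # margin -> logistic squashing, documented fallback
        margin = model.decision_function(X)
        pos = 1.0 / (1.0 + np.exp(-margin))
        out = np.column_stack([1.0 - pos, pos])
    total = out.sum(axis=1, keepdims=True)
    total[total == 0] = 1.0
    return out / total


def score_heldout(model, table: FeatureTable, test_index: Sequence[int],
                  params: dict | None = None, k: int = 0,
                  cv_accuracy: float = float("nan"),
                  family: str | None = None) -> ScoreSet:
    """Score the held-out rows; accuracy is argmax-vs-truth with ties going to
    the first label in sorted order."""
    test_index = np.asarray(test_index, dtype=int)
    X = table.features()[test_index]
    y = table.labels[test_index]
    class_labels = tuple(sorted(np.unique(table.labels)))
    if len(class_labels) != 2:
        raise DataError(f"binary task expected, got labels {class_labels}")
    scores = _confidences(model, X, class_labels)
    preds = np.asarray(class_labels)[np.argmax(scores, axis=1)]
    sample_ids = (table.frame["subject_id"].astype(str) + "/"
                  + table.frame["stimulus_id"].astype(str)).to_numpy()[test_index]
    sample_ids = np.array([f"{sid}#{i}" for i, sid in zip(test_index, sample_ids)])
    return ScoreSet(
        family=family or type(model).__name__, params=params or {}, k=k,
        sample_ids=sample_ids, scores=scores, class_labels=class_labels,
        test_accuracy=float(np.mean(preds == y)), cv_accuracy=cv_accuracy,
    )


def train_zoo(specs: Sequence[ClassifierSpec], table: FeatureTable,
              train_index: Sequence[int], test_index: Sequence[int],
              seed: int = 0) -> list[ScoreSet]:
    """Tune, train and score every spec on the same split."""
    out = []
    for spec in specs:
        model, params, k, cv_acc = tune_and_train(spec, table, train_index, seed=seed)
        out.append(score_heldout(model, table, test_index, params=params, k=k,
                                 cv_accuracy=cv_acc, family=spec.family))
    return out


def select_candidates(scoresets: Sequence[ScoreSet], threshold: float) -> list[ScoreSet]:
    """Keep score sets with ``test_accuracy > threshold``, sorted by
    decreasing accuracy; ties follow :data:`FAMILY_ORDER`."""
    if not scoresets:
        raise DataError("no score sets given")
    ids0 = scoresets[0].sample_ids
    for ss in scoresets[1:]:
        if not np.array_equal(ss.sample_ids, ids0):
            raise PreconditionError("score sets do not share sample ids")
    chosen = [ss for ss in scoresets if ss.test_accuracy > threshold]
    if not chosen:
        raise DataError(
            f"no classifier exceeded accuracy threshold {threshold}; lower the threshold")
    rank = {f: i for i, f in enumerate(FAMILY_ORDER)}
    chosen.sort(key=lambda ss: (-ss.test_accuracy, rank.get(ss.family, len(rank))))
    return chosen
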