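"""Transformation- and classifier-based score-level fusion.

Three algebraic rules operate on aligned per-sample confidence vectors from
member classifiers:

* weighted sum     ``S_c = sum_i w_i * s_ic``
* weighted product ``S_c = prod_i s_ic ** w_i``
* pairwise Bayes   ``S = (t_a t_b) / ((1 - t_a)(1 - t_b) + t_a t_b)``
  on the two members' positive-class scores, one of which is pre-multiplied
  by a down-weighting factor.

Weights come from the brute-force grid {w/10 : w = 1..10}, enumerated in a
fixed order (member subsets lexicographic by candidate rank, weight tuples
ascending) so tie-broken optima are reproducible.  Classifier-based fusion
re-learns the decision from the concatenated confidence vectors of the two
best members on a fresh 70:30 split.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .classification import (ClassifierSpec, ScoreSet, score_heldout,
                             split_dataset, tune_and_train)
from .errors import AlignmentError, ConfigurationError, DataError
from .features import FeatureTable

WEIGHT_GRID: tuple[float, ...] = tuple(w / 10.0 for w in range(1, 11))


@dataclass(frozen=True)
class FusionWeights:
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        for w in self.weights:
            if not 0.0 < w <= 1.0:
                raise ConfigurationError("weights", f"each weight must be in (0, 1], got {w}")


@dataclass
class ScoreMatrix:
    """Aligned member scores with shape (n_members, n_samples, n_classes)."""

    members: list[str]
    sample_ids: np.ndarray
    scores: np.ndarray
    class_labels: tuple[str, str]

    @classmethod
    def from_scoresets(cls, scoresets: Sequence[ScoreSet]) -> "ScoreMatrix":
        if not scoresets:
            raise DataError("no score sets")
        ids0 = scoresets[0].sample_ids
        for ss in scoresets[1:]:
            if not np.array_equal(ss.sample_ids, ids0):
                raise AlignmentError("score sets do not share sample ids")
            if ss.class_labels != scoresets[0].class_labels:
                raise AlignmentError("score sets do not share class label order")
        return cls(members=[ss.name for ss in scoresets], sample_ids=ids0.copy(),
                   scores=np.stack([ss.scores for ss in scoresets]),
                   class_labels=scoresets[0].class_labels)

    @property
    def n_members(self) -> int:
        return self.scores.shape[0]


@dataclass
class FusedScores:
    rule: str  # sum | product | bayes | classifier
    members: list[str]
    weights: Optional[tuple[float, ...]]
    scores: np.ndarray  # (n_samples, 2)
    predictions: np.ndarray  # label strings
    class_labels: tuple[str, str]
    accuracy: float = float("nan")
    improves_single: Optional[bool] = None
    extra: dict = field(default_factory=dict)


def _check_weights(matrix: ScoreMatrix, weights: FusionWeights) -> np.ndarray:
    if len(weights.weights) != matrix.n_members:
        raise ConfigurationError("weights", f"need one weight per member "
                                 f"({matrix.n_members}), got {len(weights.weights)}")
    return np.asarray(weights.weights, dtype=float)


def _finalize(rule: str, matrix: ScoreMatrix, weights, fused: np.ndarray,
              labels: Optional[np.ndarray]) -> FusedScores:
    preds = np.asarray(matrix.class_labels)[np.argmax(fused, axis=1)]
    acc = float(np.mean(preds == labels)) if labels is not None else float("nan")
    return FusedScores(rule=rule, members=list(matrix.members),
                       weights=tuple(weights) if weights is not None else None,
                       scores=fused, predictions=preds,
                       class_labels=matrix.class_labels, accuracy=acc)


def weighted_sum_fuse(matrix: ScoreMatrix, weights: FusionWeights,
                      labels: Optional[np.ndarray] = None) -> FusedScores:
    """Per-class weighted sum of member scores; argmax prediction (ties go to
    the first class in label order)."""
    w = _check_weights(matrix, weights)
    fused = np.tensordot(w, matrix.scores, axes=(0, 0))
    return _finalize("sum", matrix, w, fused, labels)


def weighted_product_fuse(matrix: ScoreMatrix, weights: FusionWeights,
                          labels: Optional[np.ndarray] = None) -> FusedScores:
    """Per-class weighted product ``prod_i s_i^{w_i}``; any zero member score
    annihilates that class's fused score."""
    w = _check_weights(matrix, weights)
    if np.any(matrix.scores < 0):
        raise DataError("weighted product requires non-negative scores")
    fused = np.prod(matrix.scores ** w[:, None, None], axis=0)
    return _finalize("product", matrix, w, fused, labels)


def bayes_pair_scores(t_a: np.ndarray, t_b: np.ndarray) -> np.ndarray:
    """S = t_a t_b / ((1-t_a)(1-t_b) + t_a t_b), with the doubly-singular
    input (1, 0) mapped to 0.5 (warned)."""
    t_a = np.asarray(t_a, dtype=float)
    t_b = np.asarray(t_b, dtype=float)
    num = t_a * t_b
    den = (1.0 - t_a) * (1.0 - t_b) + num
    singular = den == 0.0
    if np.any(singular):
        warnings.warn("Bayes fusion hit singular score pair(s); defining S = 0.5")
    out = np.where(singular, 0.5, num / np.where(singular, 1.0, den))
    return out


def bayes_fuse(matrix: ScoreMatrix, weight_on: Optional[str] = None,
               weight: float = 1.0,
               labels: Optional[np.ndarray] = None) -> FusedScores:
    """Pairwise Bayes fusion of the two members' positive-class scores.

    The member named by ``weight_on`` has its score pre-multiplied by
    ``weight`` (a down-weighting factor in (0, 1]).  Prediction is the
    positive class (index 1 in label order) iff S >= 0.5.
    """
    if matrix.n_members != 2:
        raise DataError(f"Bayes fusion takes exactly 2 members, got {matrix.n_members}")
    if not 0.0 < weight <= 1.0:
        raise ConfigurationError("weight", f"must be in (0, 1], got {weight}")
    if np.any(matrix.scores < 0) or np.any(matrix.scores > 1):
        raise DataError("Bayes fusion requires scores in [0, 1]")
    t = matrix.scores[:, :, 1].copy()  # positive-class scores, shape (2, n)
    if weight_on is not None:
        if weight_on not in matrix.members:
            raise ConfigurationError("weight_on", f"unknown member {weight_on!r}")
        t[matrix.members.index(weight_on)] *= weight
    s = bayes_pair_scores(t[0], t[1])
    fused = np.column_stack([1.0 - s, s])
    preds = np.where(s >= 0.5, matrix.class_labels[1], matrix.class_labels[0])
    acc = float(np.mean(preds == labels)) if labels is not None else float("nan")
    return FusedScores(rule="bayes", members=list(matrix.members),
                       weights=(weight,) if weight_on is not None else None,
                       scores=fused, predictions=preds,
                       class_labels=matrix.class_labels, accuracy=acc,
                       extra={"weight_on": weight_on})


@dataclass
class SearchResult:
    rule: str
    best_by_size: dict[int, FusedScores]
    n_evaluations: int
    best_single_accuracy: float


def search_weights_and_combinations(candidates: Sequence[ScoreSet], rule: str,
                                    sizes: Sequence[int], labels: np.ndarray,
                                    weight_grid: Sequence[float] = WEIGHT_GRID,
                                    ) -> SearchResult:
    """Exhaustive search over member subsets and the w/10 weight grid.

    For each requested size, every subset of that size (lexicographic in the
    candidates' given order) and every weight assignment from the grid is
    evaluated; the maximum-accuracy configuration wins, first-found on ties.
    For the Bayes rule only pairs are searched: each choice of down-weighted
    member times each grid weight.  ``improves_single`` flags whether the
    winner strictly beats the best single candidate's accuracy.
    """
    if len(candidates) < 2:
        raise DataError("need at least 2 candidate score sets")
    if rule not in ("sum", "product", "bayes"):
        raise ConfigurationError("rule", f"unknown rule {rule!r}")
    sizes = sorted(set(int(s) for s in sizes))
    if rule == "bayes" and sizes != [2]:
        raise ConfigurationError("sizes", "Bayes fusion searches pairs only (sizes = {2})")
    if any(s < 2 or s > len(candidates) for s in sizes):
        raise ConfigurationError("sizes", f"sizes must lie in [2, {len(candidates)}]")
    labels = np.asarray(labels)
    best_single = max(ss.test_accuracy for ss in candidates)
    grid = tuple(weight_grid)

    n_evals = 0
    best_by_size: dict[int, FusedScores] = {}
    for size in sizes:
        best: Optional[FusedScores] = None
        for combo in itertools.combinations(range(len(candidates)), size):
            matrix = ScoreMatrix.from_scoresets([candidates[i] for i in combo])
            if rule in ("sum", "product"):
                weight_tuples = np.array(list(itertools.product(grid, repeat=size)))
                accs = _grid_accuracies(matrix, weight_tuples, rule, labels)
                n_evals += len(weight_tuples)
                j = int(np.argmax(accs))
                if best is None or accs[j] > best.accuracy:
                    fuse = weighted_sum_fuse if rule == "sum" else weighted_product_fuse
                    best = fuse(matrix, FusionWeights(tuple(weight_tuples[j])), labels)
            else:  # bayes
                for member in matrix.members:
                    for w in grid:
                        with warnings.catch_warnings():
                            warnings.simplefilter("ignore")
                            fused = bayes_fuse(matrix, weight_on=member, weight=w,
                                               labels=labels)
                        n_evals += 1
                        if best is None or fused.accuracy > best.accuracy:
                            best = fused
        assert best is not None
        best.improves_single = best.accuracy > best_single
        best_by_size[size] = best
    return SearchResult(rule=rule, best_by_size=best_by_size,
                        n_evaluations=n_evals, best_single_accuracy=best_single)


def _grid_accuracies(matrix: ScoreMatrix, weight_tuples: np.ndarray, rule: str,
                     labels: np.ndarray) -> np.ndarray:
    """Vectorized accuracy of every weight tuple (rows) for one subset."""
    if rule == "sum":
        fused = np.tensordot(weight_tuples, matrix.scores, axes=(1, 0))
    else:
        logs = np.log(np.maximum(matrix.scores, 1e-300))
        fused = np.exp(np.tensordot(weight_tuples, logs, axes=(1, 0)))
        fused[:, np.any(matrix.scores == 0, axis=0)] = 0.0  # exact annihilation
    preds = np.argmax(fused, axis=2)
    truth = np.asarray(labels) == matrix.class_labels[1]
    return np.mean(preds == truth[None, :], axis=1)


def classifier_score_fusion(scoresets: Sequence[ScoreSet], labels: np.ndarray,
                            specs: Sequence[ClassifierSpec], split_seed: int,
                            ratio: float = 0.7) -> dict[str, FusedScores]:
    """Second-stage classifiers on the concatenated confidence vectors of the
    two top members, re-split 70:30 (stratified, seeded)."""
    if len(scoresets) < 2:
        raise DataError("classifier-based fusion needs two score sets")
    top_two = scoresets[:2]
    matrix = ScoreMatrix.from_scoresets(top_two)
    X = np.hstack([ss.scores for ss in top_two])  # (n, 4)
    labels = np.asarray(labels)

    frame = pd.DataFrame(X, columns=[f"score__{i}" for i in range(X.shape[1])])
    frame["subject_id"] = matrix.sample_ids
    frame["stimulus_id"] = "derived"
    frame["gender_label"] = labels
    frame["age_label"] = labels
    derived = FeatureTable(frame=frame,
                           modality_blocks={"score": list(frame.columns[:X.shape[1]])},
                           task="gender")
    train_idx, test_idx = split_dataset(derived, ratio, split_seed)

    out: dict[str, FusedScores] = {}
    for spec in specs:
        model, params, k, cv_acc = tune_and_train(spec, derived, train_idx, seed=split_seed)
        ss = score_heldout(model, derived, test_idx, params=params, k=k,
                           cv_accuracy=cv_acc, family=spec.family)
        out[spec.family] = FusedScores(
            rule="classifier", members=[m for m in matrix.members],
            weights=None, scores=ss.scores, predictions=ss.predictions,
            class_labels=ss.class_labels, accuracy=ss.test_accuracy,
            extra={"family": spec.family, "params": params, "k": k},
        )
    return out
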