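"""End-to-end experiment orchestration and report generation.

``run_experiment`` wires the full pipeline: simulate (or load) a cohort,
filter and segment every session, build the labeled feature table, then
either fuse the modality features by concatenation before training the
classifier zoo (``with_concatenation=True``) or train the zoo per modality
and pool its score sets.  Candidates above the selection threshold enter the
weighted-sum / weighted-product / Bayes searches and the classifier-based
fusion of the two top members.  Every stage is seeded from one master seed,
failures carry the stage name, and reports serialize deterministically.
"""

from __future__ import annotations

import json
import logging
import warnings
from contextlib import contextmanager
from dataclasses import dataclass, field
from itertools import product as _product
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from . import classification, features, preprocessing, score_fusion, synthetic_data
from .classification import ClassifierSpec, ScoreSet
from .errors import DataError, GazeFusionError, StageError
from .features import FeatureTable
from .synthetic_data import CohortConfig

logger = logging.getLogger(__name__)

REPORT_PRECISION = 4  # decimal places in serialized reports


def accuracy_of(predictions: Sequence, labels: Sequence) -> float:
    """Fraction of exact matches."""
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if predictions.shape != labels.shape or predictions.size == 0:
        raise DataError(f"predictions/labels shape mismatch or empty: "
                        f"{predictions.shape} vs {labels.shape}")
    return float(np.mean(predictions == labels))


def mean_cross_modality_spearman(table: FeatureTable, modality_a: str,
                                 modality_b: str) -> float:
    """Mean Spearman rank correlation over all cross pairs of one column from
    each modality block; constant columns contribute 0 (warned)."""
    for m in (modality_a, modality_b):
        if m not in table.modality_blocks:
            raise DataError(f"modality {m!r} not in table")
    if len(table) < 3:
        raise DataError("need at least 3 rows for rank correlation")
    cols_a = table.modality_blocks[modality_a]
    cols_b = table.modality_blocks[modality_b]
    values = []
    for ca, cb in _product(cols_a, cols_b):
        a = table.frame[ca].to_numpy(dtype=float)
        b = table.frame[cb].to_numpy(dtype=float)
        if np.all(a == a[0]) or np.all(b == b[0]):
            warnings.warn(f"constant column in pair ({ca}, {cb}); contributing 0")
            values.append(0.0)
            continue
        rho = stats.spearmanr(a, b).statistic
        values.append(0.0 if np.isnan(rho) else float(rho))
    return float(np.mean(values))


@dataclass
class ExperimentConfig:
    task: str = "gender"
    with_concatenation: bool = True
    per_modality: bool = True  # also train the zoo on each modality alone
    train_ratio: float = 0.8
    fusion_ratio: float = 0.7
    select_threshold: float = 0.75
    max_candidates: int = 5  # cap after thresholding, for tractable searches
    sizes: tuple[int, ...] = (2, 3)
    small_grids: bool = True
    k_range: tuple[int, ...] = (2, 3)
    families: Optional[tuple[str, ...]] = None
    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    dispersion_threshold_px: float = preprocessing.DEFAULT_DISPERSION_PX
    min_fixation_ms: float = preprocessing.DEFAULT_MIN_FIX_MS

    def validate(self) -> None:
        if self.task not in ("gender", "age"):
            raise DataError(f"task must be gender/age, got {self.task!r}")
        if not (0 < self.train_ratio < 1 and 0 < self.fusion_ratio < 1):
            raise DataError("split ratios must lie in (0, 1)")
        if any(s < 2 for s in self.sizes):
            raise DataError("fusion sizes must be >= 2")


@dataclass
class ExperimentReport:
    task: str
    with_concatenation: bool
    seed: int
    n_rows: int
    n_train: int
    n_test: int
    modality_accuracies: dict[str, dict[str, float]]
    best_per_modality: dict[str, float]
    base_accuracies: dict[str, float]  # zoo used as fusion candidates
    selected: list[str]
    fusion: dict[str, dict[str, dict]]  # rule -> size -> summary
    classifier_fusion: dict[str, float]
    spearman: dict[str, float]
    best_single_accuracy: float
    best_fused_accuracy: float

    def to_dict(self) -> dict:
        def r(x: float) -> float:
            return round(float(x), REPORT_PRECISION)

        return {
            "task": self.task,
            "with_concatenation": self.with_concatenation,
            "seed": self.seed,
            "n_rows": self.n_rows,
            "n_train": self.n_train,
            "n_test": self.n_test,
            "modality_accuracies": {m: {f: r(a) for f, a in fams.items()}
                                    for m, fams in self.modality_accuracies.items()},
            "best_per_modality": {m: r(a) for m, a in self.best_per_modality.items()},
            "base_accuracies": {f: r(a) for f, a in self.base_accuracies.items()},
            "selected": list(self.selected),
            "fusion": self.fusion,
            "classifier_fusion": {f: r(a) for f, a in self.classifier_fusion.items()},
            "spearman": {p: r(v) for p, v in self.spearman.items()},
            "best_single_accuracy": r(self.best_single_accuracy),
            "best_fused_accuracy": r(self.best_fused_accuracy),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def study_cohort(n_subjects: int = 60, n_stimuli: int = 18,
                 session_duration_s: float = 10.0) -> CohortConfig:
    """Reference synthetic regime for the gender study: a strong pupil
    effect, weak blink/fixation effects, and a shared per-session arousal
    state coupling all three channels (what makes feature concatenation pay
    off over per-trait score fusion)."""
    return CohortConfig(
        n_subjects=n_subjects, gender_ratio=0.5, n_stimuli=n_stimuli,
        session_duration_s=session_duration_s,
        pupil_gender_delta_mm=0.45, pupil_subject_sd=0.15,
        pupil_session_sd=0.05, pupil_noise_sd=0.15,
        blink_rate_by_gender={"male": 12.0, "female": 15.2},
        blink_rate_subject_sd=0.8,
        fixation_gender_delta_s=0.015, fixation_subject_sd_s=0.03,
        session_state_pupil_mm=0.25, session_state_blink_rate=3.0,
        session_state_fixation_s=0.05,
        corrupt_fraction=0.02,
    )


def study_config(seed: int, with_concatenation: bool,
                 n_subjects: int = 60) -> "ExperimentConfig":
    """Experiment configuration for the reference study regime.  The
    with-concatenation run searches subsets of 2-5 members; the per-trait run
    has at most 3 members (one per modality) by construction."""
    return ExperimentConfig(
        task="gender", with_concatenation=with_concatenation, per_modality=True,
        select_threshold=0.5, seed=seed, cohort=study_cohort(n_subjects),
        sizes=(2, 3, 4, 5) if with_concatenation else (2, 3), k_range=(3,),
    )


@contextmanager
def _stage(name: str):
    try:
        yield
    except StageError:
        raise
    except GazeFusionError as exc:
        raise StageError(name, str(exc)) from exc


def _derived_seeds(master: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(master).generate_state(n)]


def build_feature_table(config: ExperimentConfig) -> FeatureTable:
    """Simulate the cohort, preprocess every session and assemble the
    labeled, class-balanced feature table."""
    seeds = _derived_seeds(config.seed, 4)
    cohort_cfg = config.cohort.with_(seed=seeds[0])
    rows = []
    metadata = []
    with _stage("simulate+preprocess"):
        subjects = synthetic_data.generate_cohort(cohort_cfg)
        metadata = subjects
        session_seeds = synthetic_data.session_seeds(cohort_cfg, len(subjects),
                                                     cohort_cfg.n_stimuli)
        for si, subject in enumerate(subjects):
            for ti in range(cohort_cfg.n_stimuli):
                records = synthetic_data.simulate_session(
                    subject, f"I{ti:02d}", cohort_cfg, int(session_seeds[si, ti]))
                events = preprocessing.process_session(
                    records, cohort_cfg.sampling_rate_hz,
                    config.dispersion_threshold_px, config.min_fixation_ms)
                try:
                    rows.append(features.extract_modality_features(events))
                except DataError as exc:
                    logger.warning("dropping session %s/%s: %s",
                                   subject.subject_id, ti, exc)
    with _stage("assemble_dataset"):
        return features.assemble_dataset(rows, metadata, config.task,
                                         balance_seed=seeds[1])


def run_experiment(config: ExperimentConfig,
                   table: Optional[FeatureTable] = None) -> ExperimentReport:
    config.validate()
    seeds = _derived_seeds(config.seed + 1, 6)
    if table is None:
        table = build_feature_table(config)

    with _stage("split_dataset"):
        train_idx, test_idx = classification.split_dataset(
            table, config.train_ratio, seeds[0])

    specs = classification.default_specs(small=config.small_grids,
                                         k_range=config.k_range,
                                         families=config.families)

    with _stage("spearman"):
        spearman = {}
        for ma, mb in (("pupil", "blink"), ("pupil", "fixation"), ("blink", "fixation")):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                spearman[f"{ma}~{mb}"] = mean_cross_modality_spearman(table, ma, mb)

    modality_accuracies: dict[str, dict[str, float]] = {}
    modality_scoresets: dict[str, list[ScoreSet]] = {}
    if config.per_modality or not config.with_concatenation:
        with _stage("per_modality_zoo"):
            for modality in features.MODALITIES:
                sub = features.fuse_features(table, [modality], train_idx)
                sets = classification.train_zoo(specs, sub, train_idx, test_idx,
                                                seed=seeds[1])
                modality_scoresets[modality] = sets
                modality_accuracies[modality] = {s.family: s.test_accuracy for s in sets}
    best_per_modality = {m: max(a.values()) for m, a in modality_accuracies.items()}

    with _stage("base_zoo"):
        if config.with_concatenation:
            fused_table = features.fuse_features(table, list(features.MODALITIES),
                                                 train_idx)
            base_sets = classification.train_zoo(specs, fused_table, train_idx,
                                                 test_idx, seed=seeds[2])
            base_accuracies = {s.family: s.test_accuracy for s in base_sets}
        else:
            # one member per trait: each modality is represented by its best
            # classifier, and fusion combines the traits' score sets
            rank = {f: i for i, f in enumerate(classification.FAMILY_ORDER)}
            base_sets = [max(modality_scoresets[m],
                             key=lambda s: (s.test_accuracy, -rank[s.family]))
                         for m in features.MODALITIES]
            base_accuracies = {f"{m}:{s.family}": s.test_accuracy
                               for m, s in zip(features.MODALITIES, base_sets)}

    y_test = table.labels[test_idx]

    with _stage("select_candidates"):
        if config.with_concatenation:
            candidates = classification.select_candidates(base_sets,
                                                          config.select_threshold)
            candidates = candidates[:config.max_candidates]
        else:
            # the per-trait members all enter the fusion regardless of the
            # selection threshold; order them by decreasing accuracy
            candidates = classification.select_candidates(base_sets, 0.0)

    fusion_summary: dict[str, dict[str, dict]] = {}
    best_fused = max(c.test_accuracy for c in candidates)
    with _stage("score_fusion_search"):
        sizes = [s for s in config.sizes if s <= len(candidates)]
        for rule in ("sum", "product"):
            if len(candidates) >= 2 and sizes:
                result = score_fusion.search_weights_and_combinations(
                    candidates, rule, sizes, y_test)
                fusion_summary[rule] = _summarize_search(result)
                best_fused = max(best_fused, *(f.accuracy
                                               for f in result.best_by_size.values()))
        if len(candidates) >= 2:
            result = score_fusion.search_weights_and_combinations(
                candidates, "bayes", [2], y_test)
            fusion_summary["bayes"] = _summarize_search(result)
            best_fused = max(best_fused, *(f.accuracy
                                           for f in result.best_by_size.values()))

    with _stage("classifier_fusion"):
        clf_fusion = score_fusion.classifier_score_fusion(
            candidates, y_test, specs, split_seed=seeds[3], ratio=config.fusion_ratio)
        classifier_fusion = {f: fs.accuracy for f, fs in clf_fusion.items()}
        best_fused = max(best_fused, *classifier_fusion.values())

    best_single = max(s.test_accuracy for s in base_sets)
    return ExperimentReport(
        task=config.task, with_concatenation=config.with_concatenation,
        seed=config.seed, n_rows=len(table), n_train=len(train_idx),
        n_test=len(test_idx),
        modality_accuracies=modality_accuracies,
        best_per_modality=best_per_modality,
        base_accuracies=base_accuracies,
        selected=[c.name for c in candidates],
        fusion=fusion_summary, classifier_fusion=classifier_fusion,
        spearman=spearman, best_single_accuracy=best_single,
        best_fused_accuracy=best_fused,
    )


def _summarize_search(result: score_fusion.SearchResult) -> dict[str, dict]:
    out = {}
    for size, fused in result.best_by_size.items():
        out[str(size)] = {
            "members": fused.members,
            "weights": list(fused.weights) if fused.weights else None,
            "accuracy": round(fused.accuracy, REPORT_PRECISION),
            "improves_single": bool(fused.improves_single),
        }
    return out
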