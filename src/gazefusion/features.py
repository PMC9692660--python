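"""Per-session statistical descriptors, dataset assembly and feature-level fusion.

For every (subject, stimulus) session three modality blocks are built:

* ``pupil`` — dispersion/position indices (mean, median, std, min, max, Q1,
  Q3) of the per-sample left/right average diameter over both-eyes-valid
  samples;
* ``blink`` — event count, fast-blink count and duration statistics of the
  timed blinks;
* ``fixation`` — event count and duration statistics.

Standard deviations use the population convention (divide by n).  Sessions
without timed events get zero duration statistics plus a presence flag so
blink-free viewings are kept rather than dropped.  Feature-level fusion is
column-wise concatenation of modality blocks followed by max-absolute-value
scaling fitted on training rows only, which maps training values into
[-1, 1] while keeping zero entries exactly zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .preprocessing import OcularEvents
from .synthetic_data import SubjectMetadata, age_group_of

logger = logging.getLogger(__name__)

MODALITIES = ("pupil", "blink", "fixation")

PUPIL_FEATURES = ("mean", "median", "std", "min", "max", "q1", "q3")
BLINK_FEATURES = ("count", "n_fast", "dur_mean", "dur_std", "dur_min", "dur_max", "has_timed")
FIXATION_FEATURES = ("count", "dur_mean", "dur_std", "dur_min", "dur_max", "has_events")


@dataclass(frozen=True)
class FeatureRow:
    subject_id: str
    stimulus_id: str
    pupil_features: dict[str, float]
    blink_features: dict[str, float]
    fixation_features: dict[str, float]
    gender_label: Optional[str] = None
    age_label: Optional[str] = None

    def block(self, modality: str) -> dict[str, float]:
        return getattr(self, f"{modality}_features")


def _duration_stats(durations: Sequence[float]) -> tuple[dict[str, float], float]:
    """(dur_mean/std/min/max, presence flag); zeros when no timed events."""
    if len(durations) == 0:
        return {"dur_mean": 0.0, "dur_std": 0.0, "dur_min": 0.0, "dur_max": 0.0}, 0.0
    arr = np.asarray(durations, dtype=float)
    return {
        "dur_mean": float(arr.mean()),
        "dur_std": float(arr.std()),  # population std
        "dur_min": float(arr.min()),
        "dur_max": float(arr.max()),
    }, 1.0


def extract_modality_features(events: OcularEvents) -> FeatureRow:
    """Build one unlabeled :class:`FeatureRow` from a session's events.

    Raises :class:`DataError` when the session has no both-eyes-(0,0)
    samples, in which case the caller should drop (and log) the session.
    """
    valid = [r for r in events.retained_records
             if r.validity_left == 0 and r.validity_right == 0]
    if not valid:
        raise DataError("session has no (0,0) records; row rejected")
    subject_id = valid[0].subject_id
    stimulus_id = valid[0].stimulus_id

    diam = np.array([(r.pupil_left_mm + r.pupil_right_mm) / 2.0 for r in valid])
    diam = diam[~np.isnan(diam)]
    if diam.size == 0:
        raise DataError("session has no defined pupil diameters; row rejected")
    pupil = {
        "mean": float(diam.mean()),
        "median": float(np.median(diam)),
        "std": float(diam.std()),  # population std
        "min": float(diam.min()),
        "max": float(diam.max()),
        "q1": float(np.percentile(diam, 25)),
        "q3": float(np.percentile(diam, 75)),
    }

    timed = [b.duration_ms for b in events.blinks if not b.is_fast]
    blink_stats, has_timed = _duration_stats(timed)
    blink = {"count": float(len(events.blinks)), "n_fast": float(events.n_fast_blinks),
             **blink_stats, "has_timed": has_timed}

    fix_durs = [f.duration_ms for f in events.fixations]
    fix_stats, has_fix = _duration_stats(fix_durs)
    fixation = {"count": float(len(events.fixations)), **fix_stats, "has_events": has_fix}

    return FeatureRow(subject_id=subject_id, stimulus_id=stimulus_id,
                      pupil_features=pupil, blink_features=blink,
                      fixation_features=fixation)


@dataclass
class FeatureTable:
    """Labeled feature matrix with named modality column blocks."""

    frame: pd.DataFrame
    modality_blocks: dict[str, list[str]]
    task: str  # "gender" or "age"
    scaling_state: dict[str, float] = field(default_factory=dict)

    @property
    def label_column(self) -> str:
        return f"{self.task}_label"

    @property
    def labels(self) -> np.ndarray:
        return self.frame[self.label_column].to_numpy()

    @property
    def feature_columns(self) -> list[str]:
        return [c for cols in self.modality_blocks.values() for c in cols]

    def features(self) -> np.ndarray:
        return self.frame[self.feature_columns].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.frame)


def _rows_to_frame(rows: Sequence[FeatureRow]) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    data = []
    for row in rows:
        rec: dict[str, object] = {"subject_id": row.subject_id, "stimulus_id": row.stimulus_id,
                                  "gender_label": row.gender_label, "age_label": row.age_label}
        for modality in MODALITIES:
            for name, value in row.block(modality).items():
                rec[f"{modality}__{name}"] = value
        data.append(rec)
    frame = pd.DataFrame(data)
    blocks = {
        "pupil": [f"pupil__{f}" for f in PUPIL_FEATURES],
        "blink": [f"blink__{f}" for f in BLINK_FEATURES],
        "fixation": [f"fixation__{f}" for f in FIXATION_FEATURES],
    }
    return frame, blocks


def assemble_dataset(rows: Sequence[FeatureRow],
                     metadata: Iterable[SubjectMetadata] | Mapping[str, SubjectMetadata],
                     task: str, balance_seed: int) -> FeatureTable:
    """Attach labels and down-sample the majority class to exact parity.

    ``age_label`` is ``under30`` iff age <= 30.  Balancing is a seeded random
    subset of the majority class's rows; row order is otherwise preserved.
    """
    if task not in ("gender", "age"):
        raise ConfigurationError("task", f"must be 'gender' or 'age', got {task!r}")
    if not isinstance(metadata, Mapping):
        metadata = {s.subject_id: s for s in metadata}
    orphans = sorted({r.subject_id for r in rows} - set(metadata))
    if orphans:
        raise DataError(f"missing metadata for subjects: {', '.join(orphans)}")

    labeled = []
    for row in rows:
        meta = metadata[row.subject_id]
        labeled.append(FeatureRow(
            subject_id=row.subject_id, stimulus_id=row.stimulus_id,
            pupil_features=row.pupil_features, blink_features=row.blink_features,
            fixation_features=row.fixation_features,
            gender_label=meta.gender, age_label=age_group_of(meta.age),
        ))
    frame, blocks = _rows_to_frame(labeled)

    label_col = f"{task}_label"
    counts = frame[label_col].value_counts()
    if len(counts) < 2:
        raise DataError(f"task {task!r} needs both classes, found {list(counts.index)}")
    n_min = int(counts.min())
    rng = np.random.default_rng(balance_seed)
    keep: list[np.ndarray] = []
    for label in sorted(counts.index):
        idx = frame.index[frame[label_col] == label].to_numpy()
        if len(idx) > n_min:
            idx = np.sort(rng.choice(idx, size=n_min, replace=False))
        keep.append(idx)
    frame = frame.loc[np.sort(np.concatenate(keep))].reset_index(drop=True)
    return FeatureTable(frame=frame, modality_blocks=blocks, task=task)


def fuse_features(table: FeatureTable, modalities: Sequence[str],
                  train_index: Sequence[int]) -> FeatureTable:
    """Concatenate the selected modality blocks and max-abs scale each feature.

    Scale factors are fitted on ``train_index`` rows only and applied to all
    rows; an all-zero training column gets factor 1 so zeros pass through.
    A single-modality call performs scaling only.
    """
    modalities = list(modalities)
    if not modalities:
        raise ConfigurationError("modalities", "must be non-empty")
    unknown = [m for m in modalities if m not in table.modality_blocks]
    if unknown:
        raise ConfigurationError("modalities", f"unknown modalities {unknown}")
    train_index = np.asarray(train_index, dtype=int)
    if train_index.size == 0:
        raise ConfigurationError("train_index", "must be non-empty")

    frame = table.frame.copy()
    blocks = {m: list(table.modality_blocks[m]) for m in modalities}
    scaling: dict[str, float] = {}
    for cols in blocks.values():
        for col in cols:
            max_abs = float(np.abs(frame.loc[train_index, col].to_numpy(dtype=float)).max())
            factor = max_abs if max_abs > 0 else 1.0
            scaling[col] = factor
            frame[col] = frame[col].to_numpy(dtype=float) / factor
    id_cols = ["subject_id", "stimulus_id", "gender_label", "age_label"]
    keep_cols = id_cols + [c for cols in blocks.values() for c in cols]
    return FeatureTable(frame=frame[keep_cols], modality_blocks=blocks,
                        task=table.task, scaling_state=scaling)


def write_feature_csv(table: FeatureTable, path) -> None:
    table.frame.to_csv(path, index=False)


def read_feature_csv(path, task: str) -> FeatureTable:
    frame = pd.read_csv(path)
    blocks: dict[str, list[str]] = {}
    for col in frame.columns:
        if "__" in col:
            modality = col.split("__", 1)[0]
            blocks.setdefault(modality, []).append(col)
    return FeatureTable(frame=frame, modality_blocks=blocks, task=task)
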