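"""Plain-text I/O for gaze logs, subject metadata and event tables."""

from __future__ import annotations

import csv
import math
from pathlib import Path
from typing import Iterable, Sequence

from .errors import DataError
from .synthetic_data import GazeRecord, SubjectMetadata

GAZE_HEADER = [
    "timestamp_ms", "validity_left", "validity_right",
    "pupil_left_mm", "pupil_right_mm", "gaze_x", "gaze_y",
    "stimulus_id", "subject_id",
]


def _fmt(x: float) -> str:
    return "" if math.isnan(x) else f"{x:.6g}"


def write_gaze_tsv(records: Iterable[GazeRecord], path: str | Path) -> None:
    """Tab-separated gaze log; undefined pupil diameters become empty fields."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        fh.write("\t".join(GAZE_HEADER) + "\n")
        for r in records:
            fh.write("\t".join([
                _fmt(r.timestamp_ms), str(r.validity_left), str(r.validity_right),
                _fmt(r.pupil_left_mm), _fmt(r.pupil_right_mm),
                _fmt(r.gaze_x), _fmt(r.gaze_y), r.stimulus_id, r.subject_id,
            ]) + "\n")


def read_gaze_tsv(path: str | Path) -> list[GazeRecord]:
    path = Path(path)
    records: list[GazeRecord] = []
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != GAZE_HEADER:
            raise DataError(f"{path}: unexpected gaze header {header}")
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(GAZE_HEADER):
                raise DataError(f"{path}:{lineno}: expected {len(GAZE_HEADER)} fields")
            records.append(GazeRecord(
                timestamp_ms=float(parts[0]),
                validity_left=int(parts[1]),
                validity_right=int(parts[2]),
                pupil_left_mm=float(parts[3]) if parts[3] else float("nan"),
                pupil_right_mm=float(parts[4]) if parts[4] else float("nan"),
                gaze_x=float(parts[5]) if parts[5] else float("nan"),
                gaze_y=float(parts[6]) if parts[6] else float("nan"),
                stimulus_id=parts[7],
                subject_id=parts[8],
            ))
    return records


def write_metadata_csv(subjects: Sequence[SubjectMetadata], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["subject_id", "age", "gender"])
        for s in subjects:
            writer.writerow([s.subject_id, s.age, s.gender])


def read_metadata_csv(path: str | Path) -> list[SubjectMetadata]:
    subjects = []
    with Path(path).open() as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            subjects.append(SubjectMetadata(
                subject_id=row["subject_id"], age=int(row["age"]), gender=row["gender"],
            ))
    return subjects
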