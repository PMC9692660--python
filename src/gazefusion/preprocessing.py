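"""Validity filtering and blink / fixation segmentation.

The retention rule keeps only samples where both eyes carry validity code 0
(certainly found) or both carry 4 (not found); anything involving codes 1-3
or a mismatched pair is discarded.  On the filtered stream, a maximal run of
both-eyes-4 samples followed by a return to both-eyes-0 is a blink; a
single-sample run is a "fast" blink whose duration cannot be computed.
Fixations are segmented with a dispersion-threshold (I-DT) pass over the
code-0 gaze points.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigurationError, DataError, PreconditionError
from .synthetic_data import GazeRecord

DEFAULT_DISPERSION_PX = 100.0
DEFAULT_MIN_FIX_MS = 100.0


@dataclass(frozen=True, slots=True)
class BlinkEvent:
    start_ms: float
    end_ms: float
    duration_ms: Optional[float]  # None for fast blinks
    is_fast: bool


@dataclass(frozen=True, slots=True)
class FixationEvent:
    start_ms: float
    end_ms: float
    centroid_x: float
    centroid_y: float

    @property
    def duration_ms(self) -> float:
        return self.end_ms - self.start_ms


@dataclass(frozen=True)
class OcularEvents:
    """All events extracted from one session plus the filtered record stream."""

    blinks: list[BlinkEvent]
    n_fast_blinks: int
    fixations: list[FixationEvent]
    retained_records: list[GazeRecord]


def _validity_arrays(records: Sequence[GazeRecord]) -> tuple[np.ndarray, np.ndarray]:
    vl = np.fromiter((r.validity_left for r in records), dtype=int, count=len(records))
    vr = np.fromiter((r.validity_right for r in records), dtype=int, count=len(records))
    return vl, vr


def filter_validity(records: Sequence[GazeRecord]) -> list[GazeRecord]:
    """Keep only both-eyes-(0,0) and both-eyes-(4,4) samples, in order."""
    if len(records) == 0:
        return []
    vl, vr = _validity_arrays(records)
    bad = (vl < 0) | (vl > 4) | (vr < 0) | (vr > 4)
    if bad.any():
        idx = int(np.flatnonzero(bad)[0])
        raise DataError(f"record {idx}: validity code outside 0-4 "
                        f"({records[idx].validity_left}, {records[idx].validity_right})")
    keep = ((vl == 0) & (vr == 0)) | ((vl == 4) & (vr == 4))
    return [records[i] for i in np.flatnonzero(keep)]


def detect_blinks(records: Sequence[GazeRecord],
                  sampling_rate_hz: float) -> tuple[list[BlinkEvent], int]:
    """Segment blinks from a validity-filtered stream.

    A maximal run of (4,4) samples followed by at least one (0,0) sample is
    one blink; its duration is ``run_length / sampling_rate_hz`` for runs of
    two or more samples.  Length-1 runs are fast blinks (no duration).  A
    trailing run at end-of-stream yields no event.
    """
    if sampling_rate_hz <= 0:
        raise ConfigurationError("sampling_rate_hz", "must be > 0")
    if len(records) == 0:
        return [], 0
    vl, vr = _validity_arrays(records)
    if np.any((vl > 0) & (vl < 4)) or np.any((vr > 0) & (vr < 4)):
        raise PreconditionError("detect_blinks requires validity-filtered input "
                                "(codes 1-3 present)")
    closed = vl == 4  # filtered input: (4,4) xor (0,0)
    dt_ms = 1000.0 / sampling_rate_hz
    blinks: list[BlinkEvent] = []
    n_fast = 0
    n = len(records)
    i = 0
    while i < n:
        if not closed[i]:
            i += 1
            continue
        j = i
        while j < n and closed[j]:
            j += 1
        if j < n:  # followed by a (0,0) sample -> a real blink
            run = j - i
            if run == 1:
                blinks.append(BlinkEvent(records[i].timestamp_ms, records[i].timestamp_ms,
                                         None, True))
                n_fast += 1
            else:
                blinks.append(BlinkEvent(records[i].timestamp_ms, records[j - 1].timestamp_ms,
                                         run * dt_ms, False))
        i = j
    return blinks, n_fast


def detect_fixations(records: Sequence[GazeRecord], sampling_rate_hz: float,
                     dispersion_threshold_px: float = DEFAULT_DISPERSION_PX,
                     min_duration_ms: float = DEFAULT_MIN_FIX_MS) -> list[FixationEvent]:
    """Dispersion-threshold (I-DT) fixation segmentation over (0,0) samples.

    A window of consecutive valid points is a fixation when
    ``(max-min x) + (max-min y) <= dispersion_threshold_px`` and its time span
    is at least ``min_duration_ms``; windows are grown greedily to maximal
    extent and never overlap.  Gaps in the valid stream (blinks, dropped
    samples) break the point sequence so fixations cannot span them.
    """
    if dispersion_threshold_px <= 0:
        raise ConfigurationError("dispersion_threshold_px", "must be > 0")
    if min_duration_ms <= 0:
        raise ConfigurationError("min_duration_ms", "must be > 0")
    if sampling_rate_hz <= 0:
        raise ConfigurationError("sampling_rate_hz", "must be > 0")
    valid = [r for r in records if r.validity_left == 0 and r.validity_right == 0]
    if not valid:
        return []
    dt_ms = 1000.0 / sampling_rate_hz
    ts = np.array([r.timestamp_ms for r in valid])
    xs = np.array([r.gaze_x for r in valid])
    ys = np.array([r.gaze_y for r in valid])

    # split at temporal discontinuities
    breaks = np.flatnonzero(np.diff(ts) > 1.5 * dt_ms)
    segments = np.split(np.arange(len(valid)), breaks + 1)

    fixations: list[FixationEvent] = []
    for seg in segments:
        fixations.extend(_idt_segment(ts[seg], xs[seg], ys[seg],
                                      dispersion_threshold_px, min_duration_ms))
    return fixations


def _idt_segment(ts: np.ndarray, xs: np.ndarray, ys: np.ndarray,
                 threshold: float, min_duration_ms: float) -> list[FixationEvent]:
    n = len(ts)
    out: list[FixationEvent] = []
    i = 0
    while i < n:
        # grow [i, j] while dispersion stays under threshold
        xmin = xmax = xs[i]
        ymin = ymax = ys[i]
        j = i
        while j + 1 < n:
            nx, ny = xs[j + 1], ys[j + 1]
            nxmin, nxmax = min(xmin, nx), max(xmax, nx)
            nymin, nymax = min(ymin, ny), max(ymax, ny)
            if (nxmax - nxmin) + (nymax - nymin) > threshold:
                break
            xmin, xmax, ymin, ymax = nxmin, nxmax, nymin, nymax
            j += 1
        if ts[j] - ts[i] >= min_duration_ms:
            out.append(FixationEvent(
                start_ms=float(ts[i]), end_ms=float(ts[j]),
                centroid_x=float(xs[i:j + 1].mean()), centroid_y=float(ys[i:j + 1].mean()),
            ))
            i = j + 1
        else:
            i += 1
    return out


def process_session(records: Sequence[GazeRecord], sampling_rate_hz: float,
                    dispersion_threshold_px: float = DEFAULT_DISPERSION_PX,
                    min_duration_ms: float = DEFAULT_MIN_FIX_MS) -> OcularEvents:
    """Filter + segment one session into an :class:`OcularEvents` bundle."""
    retained = filter_validity(records)
    blinks, n_fast = detect_blinks(retained, sampling_rate_hz)
    fixations = detect_fixations(retained, sampling_rate_hz,
                                 dispersion_threshold_px, min_duration_ms)
    return OcularEvents(blinks=blinks, n_fast_blinks=n_fast,
                        fixations=fixations, retained_records=retained)
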