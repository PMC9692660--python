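import numpy as np
import pytest

from gazefusion.preprocessing import OcularEvents, filter_validity
from gazefusion.synthetic_data import (CohortConfig, GazeRecord,
                                       SubjectMetadata)


def make_records(codes, rate_hz=50.0, pupil=4.0, xy=None, subject="S000",
                 stimulus="I00"):
    """Build a GazeRecord sequence from per-record (left, right) validity
    codes.  ``codes`` may also be a list of single ints, applied to both eyes.
    ``xy`` is an optional list of (x, y) gaze positions."""
    dt = 1000.0 / rate_hz
    records = []
    for i, code in enumerate(codes):
        vl, vr = code if isinstance(code, tuple) else (code, code)
        x, y = xy[i] if xy is not None else (100.0, 100.0)
        p = float("nan") if vl == 4 else pupil
        records.append(GazeRecord(
            timestamp_ms=i * dt, validity_left=vl, validity_right=vr,
            pupil_left_mm=p, pupil_right_mm=p, gaze_x=x, gaze_y=y,
            stimulus_id=stimulus, subject_id=subject,
        ))
    return records


def quiet_config(**overrides):
    """A generator config with every stochastic effect switched off."""
    base = dict(
        n_subjects=2, gender_ratio=0.5, n_stimuli=1, session_duration_s=2.0,
        pupil_subject_sd=0.0, pupil_session_sd=0.0, pupil_noise_sd=0.0,
        blink_rate_by_gender={"male": 0.0, "female": 0.0},
        fixation_duration_sd_s=0.0, gaze_noise_sd=0.0, corrupt_fraction=0.0,
    )
    base.update(overrides)
    return CohortConfig(**base)


@pytest.fixture
def subject_20():
    return SubjectMetadata(subject_id="S000", age=20, gender="male")


@pytest.fixture
def subject_70():
    return SubjectMetadata(subject_id="S001", age=70, gender="male")


def events_from_codes(codes, rate_hz=50.0, **kw):
    from gazefusion.preprocessing import process_session
    return process_session(make_records(codes, rate_hz=rate_hz, **kw), rate_hz)
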