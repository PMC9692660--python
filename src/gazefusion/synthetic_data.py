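"""Synthetic eye-tracking cohort generator.

Emits Tobii-style gaze records (per-eye validity codes 0-4, per-eye pupil
diameter, gaze position) for configurable cohorts with demographic effect
structure: an age-dependent pupil baseline, gender-dependent blink rates and
a fixation/saccade alternation of the gaze point.  Blinks are rendered with
the canonical validity signature: a run of both-eyes code-4 samples flanked
by both-eyes code-0 samples, with a configurable fraction collapsed to a
single sample ("fast" blinks).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigurationError

UNDER30 = "under30"
OVER30 = "over30"
MALE = "male"
FEMALE = "female"

#: Default age structure: (age range inclusive, weight).
DEFAULT_AGE_DISTRIBUTION: tuple[tuple[tuple[int, int], float], ...] = (
    ((17, 18), 11 / 112),
    ((21, 30), 58 / 112),
    ((31, 40), 9 / 112),
    ((41, 50), 16 / 112),
    ((51, 60), 8 / 112),
    ((61, 70), 9 / 112),
    ((71, 80), 1 / 112),
)


def age_group_of(age: int) -> str:
    """Binary age binning: ``under30`` iff age <= 30."""
    return UNDER30 if age <= 30 else OVER30


@dataclass(frozen=True, slots=True)
class SubjectMetadata:
    subject_id: str
    age: int
    gender: str

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ConfigurationError("age", f"must be >= 0, got {self.age}")
        if self.gender not in (MALE, FEMALE):
            raise ConfigurationError("gender", f"must be male/female, got {self.gender!r}")

    @property
    def age_group(self) -> str:
        return age_group_of(self.age)


@dataclass(frozen=True, slots=True)
class GazeRecord:
    """One eye-tracker sample.  Pupil diameters are NaN when the eye is not found."""

    timestamp_ms: float
    validity_left: int
    validity_right: int
    pupil_left_mm: float
    pupil_right_mm: float
    gaze_x: float
    gaze_y: float
    stimulus_id: str
    subject_id: str


@dataclass(frozen=True)
class CohortConfig:
    """All knobs of the generator.  Defaults mirror the emulated cohort
    (112 subjects, 73 male / 39 female, 18 stimuli, 50 Hz)."""

    n_subjects: int = 112
    gender_ratio: float = 73 / 112  # fraction male
    age_distribution: tuple[tuple[tuple[int, int], float], ...] = DEFAULT_AGE_DISTRIBUTION
    n_stimuli: int = 18
    sampling_rate_hz: float = 50.0
    session_duration_s: float = 10.0

    # pupil effects (mm)
    pupil_base_mm: float = 5.0
    pupil_age_slope: float = -0.3  # per decade of age; negative = shrinks with age
    pupil_gender_delta_mm: float = 0.0  # added to female baseline
    pupil_subject_sd: float = 0.2  # between-subject baseline spread
    pupil_session_sd: float = 0.0  # session-to-session baseline drift
    pupil_noise_sd: float = 0.15  # per-sample, per-eye

    # blink effects (events/minute)
    blink_rate_by_gender: Mapping[str, float] = field(
        default_factory=lambda: {MALE: 13.3, FEMALE: 15.2}
    )
    blink_rate_age_delta: float = 0.0  # added for over-30 subjects
    blink_rate_subject_sd: float = 0.0
    blink_duration_mean_ms: float = 150.0
    blink_duration_sd_ms: float = 40.0
    fast_blink_fraction: float = 0.1  # rendered as single-sample runs

    # fixation/saccade alternation (seconds / pixels)
    fixation_duration_mean_s: float = 0.3
    fixation_duration_sd_s: float = 0.1
    fixation_gender_delta_s: float = 0.0  # added to female mean duration
    fixation_age_delta_s: float = 0.0  # added to over-30 mean duration
    fixation_subject_sd_s: float = 0.0
    saccade_samples: int = 2
    screen_width_px: int = 1280
    screen_height_px: int = 1024
    gaze_noise_sd: float = 3.0

    # shared per-session latent state (arousal): one N(0,1) draw per session
    # shifts all three channels by these couplings (default: decoupled)
    session_state_pupil_mm: float = 0.0
    session_state_blink_rate: float = 0.0
    session_state_fixation_s: float = 0.0

    corrupt_fraction: float = 0.0  # fraction of samples given validity codes 1-3
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects <= 0:
            raise ConfigurationError("n_subjects", f"must be > 0, got {self.n_subjects}")
        if not 0.0 <= self.gender_ratio <= 1.0:
            raise ConfigurationError("gender_ratio", f"must be in [0,1], got {self.gender_ratio}")
        if self.n_stimuli <= 0:
            raise ConfigurationError("n_stimuli", f"must be > 0, got {self.n_stimuli}")
        if self.sampling_rate_hz <= 0:
            raise ConfigurationError("sampling_rate_hz", f"must be > 0, got {self.sampling_rate_hz}")
        if self.session_duration_s <= 0:
            raise ConfigurationError("session_duration_s", f"must be > 0, got {self.session_duration_s}")
        for g, rate in self.blink_rate_by_gender.items():
            if rate < 0:
                raise ConfigurationError("blink_rate_by_gender", f"rate for {g} must be >= 0, got {rate}")
        if not self.age_distribution:
            raise ConfigurationError("age_distribution", "must be non-empty")
        total = sum(w for _, w in self.age_distribution)
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError("age_distribution", f"weights must sum to 1, got {total}")
        if not 0.0 <= self.fast_blink_fraction <= 1.0:
            raise ConfigurationError("fast_blink_fraction", f"must be in [0,1], got {self.fast_blink_fraction}")
        if not 0.0 <= self.corrupt_fraction <= 1.0:
            raise ConfigurationError("corrupt_fraction", f"must be in [0,1], got {self.corrupt_fraction}")
        for name in ("pupil_noise_sd", "pupil_subject_sd", "gaze_noise_sd",
                     "blink_duration_mean_ms", "fixation_duration_mean_s"):
            if getattr(self, name) < 0:
                raise ConfigurationError(name, "must be >= 0")

    def with_(self, **kw) -> "CohortConfig":
        return replace(self, **kw)


def generate_cohort(config: CohortConfig) -> list[SubjectMetadata]:
    """Generate ``n_subjects`` subjects with deterministic gender counts and
    ages drawn from ``age_distribution`` (seeded)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_male = int(round(config.gender_ratio * config.n_subjects))
    genders = [MALE] * n_male + [FEMALE] * (config.n_subjects - n_male)
    ranges = [r for r, _ in config.age_distribution]
    weights = np.array([w for _, w in config.age_distribution], dtype=float)
    weights /= weights.sum()
    subjects = []
    for i in range(config.n_subjects):
        lo, hi = ranges[rng.choice(len(ranges), p=weights)]
        age = int(rng.integers(lo, hi + 1))
        subjects.append(SubjectMetadata(subject_id=f"S{i:03d}", age=age, gender=genders[i]))
    return subjects


def _subject_rng(config_seed: int, subject_id: str) -> np.random.Generator:
    # stable per-subject stream so traits persist across sessions
    return np.random.default_rng([config_seed, zlib.crc32(subject_id.encode())])


def _subject_traits(subject: SubjectMetadata, config: CohortConfig) -> dict[str, float]:
    rng = _subject_rng(config.seed, subject.subject_id)
    pupil_offset = rng.normal(0.0, config.pupil_subject_sd) if config.pupil_subject_sd else 0.0
    blink_offset = rng.normal(0.0, config.blink_rate_subject_sd) if config.blink_rate_subject_sd else 0.0
    fix_offset = rng.normal(0.0, config.fixation_subject_sd_s) if config.fixation_subject_sd_s else 0.0
    return {"pupil": pupil_offset, "blink": blink_offset, "fixation": fix_offset}


def pupil_baseline_mm(subject: SubjectMetadata, config: CohortConfig,
                      include_subject_offset: bool = True) -> float:
    """Linear-in-age baseline: base + slope * (age / 10), plus the gender
    delta for females and (optionally) the per-subject offset."""
    base = config.pupil_base_mm + config.pupil_age_slope * (subject.age / 10.0)
    if subject.gender == FEMALE:
        base += config.pupil_gender_delta_mm
    if include_subject_offset:
        base += _subject_traits(subject, config)["pupil"]
    return base


def blink_rate_per_min(subject: SubjectMetadata, config: CohortConfig,
                       include_subject_offset: bool = True) -> float:
    try:
        rate = float(config.blink_rate_by_gender[subject.gender])
    except KeyError:
        raise ConfigurationError("blink_rate_by_gender", f"no rate for gender {subject.gender!r}")
    if subject.age_group == OVER30:
        rate += config.blink_rate_age_delta
    if include_subject_offset:
        rate += _subject_traits(subject, config)["blink"]
    return max(rate, 0.0)


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given arithmetic mean and sd."""
    if sd <= 0:
        return np.log(mean), 0.0
    sigma2 = np.log(1.0 + (sd / mean) ** 2)
    return np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2)


def _place_blinks(rng: np.random.Generator, n: int, n_blinks: int,
                  run_lengths: Sequence[int]) -> list[tuple[int, int]]:
    """Place non-overlapping (start, length) runs, keeping one flanking sample
    clear on each side and never touching the session edges."""
    placed: list[tuple[int, int]] = []
    for length in run_lengths[:n_blinks]:
        for _ in range(200):
            hi = n - 1 - length
            if hi <= 1:
                break
            start = int(rng.integers(1, hi))
            if all(start + length + 1 <= s or start >= s + l + 1 for s, l in placed):
                placed.append((start, length))
                break
    placed.sort()
    return placed


def simulate_session(subject: SubjectMetadata, stimulus_id: str,
                     config: CohortConfig, seed: int) -> list[GazeRecord]:
    """Simulate one viewing session for one subject and stimulus.

    Record count is ``session_duration_s * sampling_rate_hz``; blinks arrive
    as a Poisson count at the subject's rate; gaze alternates fixations and
    linear saccade sweeps; a ``corrupt_fraction`` of non-blink samples gets
    validity codes 1-3 to exercise downstream filtering.
    """
    config.validate()
    if config.session_duration_s <= 0 or config.sampling_rate_hz <= 0:
        raise ConfigurationError("session_duration_s", "must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(config.session_duration_s * config.sampling_rate_hz))
    dt_ms = 1000.0 / config.sampling_rate_hz
    timestamps = np.arange(n) * dt_ms

    state = rng.standard_normal()  # shared latent session state

    # --- pupil channel ---------------------------------------------------
    baseline = pupil_baseline_mm(subject, config)
    if config.pupil_session_sd > 0:
        baseline += rng.normal(0.0, config.pupil_session_sd)
    baseline += config.session_state_pupil_mm * state
    pupil_l = baseline + rng.normal(0.0, config.pupil_noise_sd, n) if config.pupil_noise_sd else np.full(n, baseline)
    pupil_r = baseline + rng.normal(0.0, config.pupil_noise_sd, n) if config.pupil_noise_sd else np.full(n, baseline)

    # --- blink events ----------------------------------------------------
    rate = max(blink_rate_per_min(subject, config)
               + config.session_state_blink_rate * state, 0.0)
    n_blinks = int(rng.poisson(rate * config.session_duration_s / 60.0)) if rate > 0 else 0
    run_lengths = []
    for _ in range(n_blinks):
        if rng.random() < config.fast_blink_fraction:
            run_lengths.append(1)
        else:
            dur = rng.normal(config.blink_duration_mean_ms, config.blink_duration_sd_ms)
            run_lengths.append(max(2, int(round(dur / dt_ms))))
    blink_runs = _place_blinks(rng, n, n_blinks, run_lengths)

    validity = np.zeros(n, dtype=int)
    blink_mask = np.zeros(n, dtype=bool)
    guard_mask = np.zeros(n, dtype=bool)  # blink samples + flanks: never corrupted
    for start, length in blink_runs:
        validity[start:start + length] = 4
        blink_mask[start:start + length] = True
        guard_mask[max(0, start - 1):min(n, start + length + 1)] = True

    # --- corrupt samples (codes 1-3, either eye) -------------------------
    vleft = validity.copy()
    vright = validity.copy()
    if config.corrupt_fraction > 0:
        eligible = np.flatnonzero(~guard_mask)
        k = int(round(config.corrupt_fraction * eligible.size))
        if k > 0:
            idx = rng.choice(eligible, size=k, replace=False)
            vleft[idx] = rng.integers(1, 4, size=k)
            vright[idx] = rng.integers(1, 4, size=k)

    # pupil undefined while the eye is not found
    pupil_l[vleft == 4] = np.nan
    pupil_r[vright == 4] = np.nan

    # --- gaze: fixation / saccade alternation ----------------------------
    mean_fix = config.fixation_duration_mean_s
    if subject.gender == FEMALE:
        mean_fix += config.fixation_gender_delta_s
    if subject.age_group == OVER30:
        mean_fix += config.fixation_age_delta_s
    mean_fix += _subject_traits(subject, config)["fixation"]
    mean_fix += config.session_state_fixation_s * state
    mean_fix = max(mean_fix, 2.0 * dt_ms / 1000.0)
    mu, sigma = _lognormal_params(mean_fix, config.fixation_duration_sd_s)

    gaze_x = np.empty(n)
    gaze_y = np.empty(n)
    pos = np.array([rng.uniform(0, config.screen_width_px),
                    rng.uniform(0, config.screen_height_px)])
    i = 0
    while i < n:
        dur_s = float(rng.lognormal(mu, sigma)) if sigma > 0 else mean_fix
        k = max(2, int(round(dur_s * config.sampling_rate_hz)))
        k = min(k, n - i)
        gaze_x[i:i + k] = pos[0]
        gaze_y[i:i + k] = pos[1]
        i += k
        if i >= n:
            break
        nxt = np.array([rng.uniform(0, config.screen_width_px),
                        rng.uniform(0, config.screen_height_px)])
        m = min(config.saccade_samples, n - i)
        for j in range(m):
            frac = (j + 1) / (m + 1)
            gaze_x[i + j] = pos[0] + frac * (nxt[0] - pos[0])
            gaze_y[i + j] = pos[1] + frac * (nxt[1] - pos[1])
        i += m
        pos = nxt
    if config.gaze_noise_sd > 0:
        gaze_x = gaze_x + rng.normal(0.0, config.gaze_noise_sd, n)
        gaze_y = gaze_y + rng.normal(0.0, config.gaze_noise_sd, n)

    return [
        GazeRecord(
            timestamp_ms=float(timestamps[i]),
            validity_left=int(vleft[i]),
            validity_right=int(vright[i]),
            pupil_left_mm=float(pupil_l[i]),
            pupil_right_mm=float(pupil_r[i]),
            gaze_x=float(gaze_x[i]),
            gaze_y=float(gaze_y[i]),
            stimulus_id=stimulus_id,
            subject_id=subject.subject_id,
        )
        for i in range(n)
    ]


def session_seeds(config: CohortConfig, n_subjects: int, n_stimuli: int) -> np.ndarray:
    """Deterministic per-(subject, stimulus) session seeds derived from the
    cohort seed."""
    ss = np.random.SeedSequence(config.seed)
    return ss.generate_state(n_subjects * n_stimuli).reshape(n_subjects, n_stimuli)


def simulate_cohort(config: CohortConfig):
    """Yield (subject, stimulus_id, records) for the whole cohort."""
    subjects = generate_cohort(config)
    seeds = session_seeds(config, len(subjects), config.n_stimuli)
    for si, subject in enumerate(subjects):
        for ti in range(config.n_stimuli):
            stimulus_id = f"I{ti:02d}"
            yield subject, stimulus_id, simulate_session(
                subject, stimulus_id, config, int(seeds[si, ti])
            )
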