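"""Seeded synthetic subject-nights with stage-conditioned movement and cardiac structure.

The generator stands in for an access-controlled PSG/actigraphy cohort.  It
produces, per subject, a first-order-Markov hypnogram over the five PSG
stages, a per-epoch activity-count channel (zero-inflated negative binomial,
high-mean and overdispersed in wake, mostly-zero with rare bursts in sleep,
mimicking PIM-mode counts), an RR-interval series whose stage-conditional
structure carries the physiological contrasts sleep scorers exploit — mean
HR highest in wake, lowest in NREM, intermediate in REM; beat-to-beat
variability shrinking from wake through deep NREM; an HF oscillation at the
respiratory frequency; and an LF oscillation whose amplitude is elevated in
REM so that the measured LF/HF ratio is higher in REM than NREM — plus an
SpO2 sample-coverage channel used downstream for record-bound detection.

All randomness flows from a single integer seed; identical parameters give
bit-identical cohorts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .records import EpochGrid, RRSeries, SubjectRecord
from .stages import EPOCH_LEN_S, N1, N2, N3, REM, STAGES5, WAKE, StageSequence

LF_FREQ_HZ = 0.1  # center of the sympathetic/baroreflex (LF) oscillation


@dataclass(frozen=True)
class StageActivity:
    """Zero-inflated negative-binomial parameters for one stage's counts."""

    burst_prob: float  # probability an epoch has any movement at all
    mean: float  # NB mean given a burst
    dispersion: float = 2.0  # NB size r; smaller = more overdispersed


@dataclass(frozen=True)
class StageCardiac:
    """Piecewise-stationary RR model parameters for one stage."""

    hr_bpm: float  # mean heart rate -> baseline interval 60000/hr ms
    sdnn_ms: float  # white beat-to-beat jitter SD
    lf_amp_ms: float  # amplitude of the 0.1-Hz LF sinusoid
    hf_amp_ms: float  # amplitude of the respiratory (HF) sinusoid
    resp_hz: float = 0.25  # respiratory frequency

    def __post_init__(self):
        if min(self.hr_bpm, self.sdnn_ms, self.lf_amp_ms, self.hf_amp_ms, self.resp_hz) < 0:
            raise ValueError("cardiac rates and amplitudes must be >= 0")
        if self.hr_bpm <= 0:
            raise ValueError("mean HR must be positive")


def _default_transitions() -> np.ndarray:
    # Row-stochastic over (W, N1, N2, N3, REM).  Diagonals are set from
    # typical adult bout lengths (mean bout = 30 s / (1 - p_stay)): wake and
    # N1 bouts of a few minutes, consolidated N2/N3 bouts of ~10 min, REM
    # periods of ~12 min.
    return np.array(
        [
            [0.90, 0.08, 0.02, 0.00, 0.00],
            [0.05, 0.70, 0.24, 0.005, 0.005],
            [0.01, 0.02, 0.95, 0.01, 0.01],
            [0.005, 0.005, 0.04, 0.95, 0.00],
            [0.01, 0.02, 0.01, 0.00, 0.96],
        ]
    )


def _default_activity() -> dict:
    return {
        WAKE: StageActivity(burst_prob=0.95, mean=150.0, dispersion=2.0),
        N1: StageActivity(burst_prob=0.20, mean=25.0),
        N2: StageActivity(burst_prob=0.05, mean=10.0),
        N3: StageActivity(burst_prob=0.02, mean=5.0),
        REM: StageActivity(burst_prob=0.05, mean=10.0),
    }


def _default_cardiac() -> dict:
    # HR: wake > REM > NREM; SDNN shrinking W -> N3; LF amplitude elevated
    # in REM (drives LF/HF(REM) > LF/HF(NREM)); HF at 0.25 Hz.
    return {
        WAKE: StageCardiac(hr_bpm=70.0, sdnn_ms=30.0, lf_amp_ms=20.0, hf_amp_ms=15.0),
        N1: StageCardiac(hr_bpm=62.0, sdnn_ms=25.0, lf_amp_ms=15.0, hf_amp_ms=20.0),
        N2: StageCardiac(hr_bpm=58.0, sdnn_ms=20.0, lf_amp_ms=10.0, hf_amp_ms=25.0),
        N3: StageCardiac(hr_bpm=55.0, sdnn_ms=15.0, lf_amp_ms=5.0, hf_amp_ms=25.0),
        REM: StageCardiac(hr_bpm=64.0, sdnn_ms=25.0, lf_amp_ms=35.0, hf_amp_ms=12.0),
    }


@dataclass(frozen=True)
class SimulationParams:
    """Full parameterization of a synthetic cohort.

    Defaults describe a night-time recording: 8-h records (960 epochs),
    lights off 5 min in, stage-conditional distributions as above.
    """

    n_subjects: int = 20
    n_epochs: int = 960
    transitions: np.ndarray = field(default_factory=_default_transitions)
    activity: dict = field(default_factory=_default_activity)
    cardiac: dict = field(default_factory=_default_cardiac)
    spo2_dropout: float = 0.0  # fraction of epochs at EACH end with no SpO2
    lights_off_epoch: int = 10
    seed: int = 0

    def __post_init__(self):
        t = np.asarray(self.transitions, dtype=float)
        if t.shape != (5, 5):
            raise ValueError("transition matrix must be 5x5 over (W, N1, N2, N3, REM)")
        if np.any(t < 0) or np.any(np.abs(t.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("transition matrix rows must be non-negative and sum to 1")
        object.__setattr__(self, "transitions", t)
        if self.n_epochs < 1 or self.n_subjects < 1:
            raise ValueError("n_epochs and n_subjects must be >= 1")
        if not 0.0 <= self.spo2_dropout < 0.5:
            raise ValueError("spo2_dropout must lie in [0, 0.5)")
        for st in STAGES5:
            a = self.activity[st]
            if not 0.0 <= a.burst_prob <= 1.0 or a.mean < 0 or a.dispersion <= 0:
                raise ValueError(f"invalid activity parameters for stage {st}")
            self.cardiac[st]  # KeyError if a stage is missing

    def replace(self, **kw) -> "SimulationParams":
        return dataclasses.replace(self, **kw)


def stationary_distribution(transitions: np.ndarray) -> np.ndarray:
    """Stationary distribution of the stage chain by eigen-analysis."""
    t = np.asarray(transitions, dtype=float)
    vals, vecs = np.linalg.eig(t.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def simulate_hypnogram(params: SimulationParams, rng=None) -> StageSequence:
    """Realize the first-order Markov stage chain, starting in wake."""
    rng = np.random.default_rng(params.seed) if rng is None else rng
    cum = np.cumsum(params.transitions, axis=1)
    labels = np.empty(params.n_epochs, dtype=object)
    state = 0  # W
    labels[0] = STAGES5[0]
    for i in range(1, params.n_epochs):
        state = int(np.searchsorted(cum[state], rng.random(), side="right"))
        state = min(state, 4)  # guard against cum[-1] = 1 - eps
        labels[i] = STAGES5[state]
    return StageSequence(labels)


def simulate_activity(stages: StageSequence, params: SimulationParams, rng=None) -> np.ndarray:
    """Draw per-epoch activity counts conditional on stage."""
    rng = np.random.default_rng(params.seed) if rng is None else rng
    n = len(stages)
    counts = np.zeros(n, dtype=float)
    for i, st in enumerate(stages.labels):
        a = params.activity[str(st)]
        if rng.random() < a.burst_prob and a.mean > 0:
            r = a.dispersion
            p = r / (r + a.mean)
            counts[i] = rng.negative_binomial(r, p)
    return counts


def simulate_rr(stages: StageSequence, params: SimulationParams, rng=None) -> RRSeries:
    """Generate the RR series as a piecewise-stationary stage-modulated process.

    Each interval is the stage's baseline 60000/HR plus an LF sinusoid at
    0.1 Hz, an HF sinusoid at the stage's respiratory frequency, and white
    jitter; intervals are floored at 250 ms.  Beat times accumulate until
    the record end is passed, so the series spans the full epoch grid.
    """
    rng = np.random.default_rng(params.seed) if rng is None else rng
    total_s = len(stages) * stages.epoch_len
    beat_times: list[float] = []
    intervals: list[float] = []
    t = 0.0
    n = len(stages)
    while t < total_s:
        st = str(stages.labels[min(int(t // stages.epoch_len), n - 1)])
        c = params.cardiac[st]
        rr = 60000.0 / c.hr_bpm
        rr += c.lf_amp_ms * np.sin(2 * np.pi * LF_FREQ_HZ * t)
        rr += c.hf_amp_ms * np.sin(2 * np.pi * c.resp_hz * t)
        if c.sdnn_ms > 0:
            rr += rng.normal(0.0, c.sdnn_ms)
        rr = max(rr, 250.0)
        t += rr / 1000.0
        beat_times.append(t)
        intervals.append(rr)
    return RRSeries(np.array(beat_times), np.array(intervals))


def simulate_spo2_coverage(n_epochs: int, dropout: float, rng) -> np.ndarray:
    """SpO2 coverage seconds per epoch; optional leading/trailing dropout."""
    cov = np.clip(30.0 - rng.exponential(0.5, size=n_epochs), 0.0, 30.0)
    k = int(round(dropout * n_epochs))
    if k > 0:
        cov[:k] = 0.0
        cov[-k:] = 0.0
    return cov


def simulate_subject(subject: str, params: SimulationParams, seed: int) -> SubjectRecord:
    """One subject-night from a single derived seed."""
    rng = np.random.default_rng(seed)
    stages = simulate_hypnogram(params, rng)
    activity = simulate_activity(stages, params, rng)
    rr = simulate_rr(stages, params, rng)
    cov = simulate_spo2_coverage(params.n_epochs, params.spo2_dropout, rng)
    grid = EpochGrid(activity=activity, spo2_coverage=cov, stages=stages)
    return SubjectRecord(
        subject=subject,
        grid=grid,
        rr=rr,
        lights_off_s=params.lights_off_epoch * EPOCH_LEN_S,
        meta={"seed": int(seed)},
    )


def simulate_cohort(params: SimulationParams) -> list[SubjectRecord]:
    """A cohort of independent subject-nights; per-subject seeds derive
    deterministically from the master seed."""
    ss = np.random.SeedSequence(params.seed)
    seeds = ss.generate_state(params.n_subjects) % (2**31)
    return [
        simulate_subject(f"S{i:03d}", params, int(seeds[i]))
        for i in range(params.n_subjects)
    ]


def train_test_split_subjects(subjects: list, seed: int, train_frac: float = 0.65):
    """Seeded subject-level split: round(train_frac * N) to training, rest test."""
    subjects = list(subjects)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(subjects))
    n_train = int(round(train_frac * len(subjects)))
    train = [subjects[i] for i in order[:n_train]]
    test = [subjects[i] for i in order[n_train:]]
    return train, test
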