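"""Core data containers shared across the pipeline.

A subject-night is a :class:`SubjectRecord`: an :class:`EpochGrid` of
per-30-s-epoch channels (activity count, SpO2 coverage seconds, optional
reference PSG stage), an :class:`RRSeries` of heart-beat intervals, and a
lights-off time.  Epoch 0 starts at t = 0 s; epoch *i* covers the half-open
interval [30 i, 30 (i+1)).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .stages import EPOCH_LEN_S, StageSequence

#: physiological plausibility guard on RR intervals (flags, never errors)
RR_PHYSIO_MIN_MS = 200.0
RR_PHYSIO_MAX_MS = 3000.0


@dataclass(frozen=True)
class RRSeries:
    """Beat-to-beat (RR) interval series.

    ``beat_times`` and ``intervals`` have equal length: ``beat_times[i]`` is
    the time (seconds from record start) of the beat that *terminates*
    interval ``i``, whose duration is ``intervals[i]`` in milliseconds.
    Interval ``i`` therefore spans ``(beat_times[i] - intervals[i]/1000,
    beat_times[i]]``.

    Intervals outside the physiological guard band [200, 3000] ms are
    recorded in ``physio_flags`` but are not rejected: artifact handling is
    the caller's decision (see :func:`hypnoscore.hrv.artifact_fraction`).
    """

    beat_times: np.ndarray  # s, strictly increasing
    intervals: np.ndarray  # ms, > 0

    def __post_init__(self):
        bt = np.asarray(self.beat_times, dtype=float)
        rr = np.asarray(self.intervals, dtype=float)
        if bt.shape != rr.shape or bt.ndim != 1:
            raise ValueError("beat_times and intervals must be equal-length 1-D arrays")
        if bt.size == 0:
            raise ValueError("empty RR series")
        if np.any(np.diff(bt) <= 0):
            raise ValueError("beat times must be strictly increasing")
        if np.any(rr <= 0):
            raise ValueError("RR intervals must be positive")
        object.__setattr__(self, "beat_times", bt)
        object.__setattr__(self, "intervals", rr)

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def physio_flags(self) -> np.ndarray:
        return (self.intervals < RR_PHYSIO_MIN_MS) | (self.intervals > RR_PHYSIO_MAX_MS)

    @property
    def span(self) -> tuple[float, float]:
        """(start, end) of the beat record in seconds."""
        return float(self.beat_times[0] - self.intervals[0] / 1000.0), float(self.beat_times[-1])


@dataclass(frozen=True)
class EpochGrid:
    """Aligned per-30-s-epoch channels for one record."""

    activity: np.ndarray  # non-negative counts (PIM mode)
    spo2_coverage: np.ndarray  # seconds of valid SpO2 per epoch, in [0, 30]
    stages: Optional[StageSequence] = None  # reference PSG labels, if any
    epoch_len: float = EPOCH_LEN_S

    def __post_init__(self):
        act = np.asarray(self.activity, dtype=float)
        cov = np.asarray(self.spo2_coverage, dtype=float)
        if act.ndim != 1 or act.size < 1:
            raise ValueError("activity must be a non-empty 1-D array")
        if np.any(act < 0):
            raise ValueError("activity counts must be non-negative")
        if cov.shape != act.shape:
            raise ValueError("spo2_coverage must align with activity")
        if np.any((cov < 0) | (cov > self.epoch_len)):
            raise ValueError(f"spo2 coverage must lie in [0, {self.epoch_len}] s")
        if self.stages is not None and len(self.stages) != act.size:
            raise ValueError("stage labels must align with the epoch grid")
        object.__setattr__(self, "activity", act)
        object.__setattr__(self, "spo2_coverage", cov)

    @property
    def n_epochs(self) -> int:
        return int(self.activity.size)

    @property
    def t_start(self) -> np.ndarray:
        """Start time (s) of each epoch."""
        return np.arange(self.n_epochs) * self.epoch_len

    @property
    def t_end(self) -> np.ndarray:
        """End time (s) of each epoch; the HRV window for epoch i ends here."""
        return self.t_start + self.epoch_len


@dataclass
class SubjectRecord:
    """One subject-night: epoch channels, RR series, lights-off, metadata."""

    subject: str
    grid: EpochGrid
    rr: RRSeries
    lights_off_s: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.lights_off_s < 0:
            raise ValueError("lights_off_s must be >= 0")
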