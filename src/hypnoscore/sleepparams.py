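"""Record-bound detection and sleep-parameter derivation.

The PSG record's start and end are not annotated; the SpO2 channel serves as
a surrogate: the record runs from the first 5-min block (consecutive,
non-overlapping 10-epoch spans from recording start) containing at least
30 s of SpO2 samples to the end of the last such block.

From any hypnogram restricted to those bounds the standard parameters are
derived: SPT (sleep period time, the bounded recording span), TST (0.5 min
per sleep epoch), SE = TST/SPT x 100, SOL (lights-off to sleep onset), WASO
(wake minutes after onset) and REM/NREM minutes.  Sleep onset is the first
epoch of the first 10-min span in which at least half the epochs are scored
sleep; by default the span slides epoch-by-epoch (a fixed 20-epoch block
variant is available, the definition being ambiguous in common usage).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stages import EPOCH_LEN_S, NREM, REM, Hypnogram

BLOCK_EPOCHS = 10  # 5-min SpO2 blocks
MIN_COVERAGE_S = 30.0
ONSET_SPAN_EPOCHS = 20  # 10-min sleep-onset span
ONSET_MIN_SLEEP = 10  # >= 50% of the span scored sleep


@dataclass(frozen=True)
class RecordBounds:
    start_s: float
    end_s: float

    def __post_init__(self):
        if self.start_s >= self.end_s:
            raise ValueError("record bounds must satisfy start < end")
        for v in (self.start_s, self.end_s):
            if v % EPOCH_LEN_S:
                raise ValueError("bounds must lie on the 30-s epoch grid")

    @property
    def start_epoch(self) -> int:
        return int(self.start_s // EPOCH_LEN_S)

    @property
    def end_epoch(self) -> int:
        """One past the last in-bounds epoch."""
        return int(self.end_s // EPOCH_LEN_S)


def detect_record_bounds(spo2_coverage: np.ndarray, epoch_len: float = EPOCH_LEN_S) -> RecordBounds:
    """Bounds from SpO2 coverage: first/last 5-min block with >= 30 s of samples."""
    cov = np.asarray(spo2_coverage, dtype=float)
    if np.any((cov < 0) | (cov > epoch_len)):
        raise ValueError(f"coverage values must lie in [0, {epoch_len}] s")
    n_blocks = cov.size // BLOCK_EPOCHS
    qualifying = [
        b
        for b in range(n_blocks)
        if cov[b * BLOCK_EPOCHS : (b + 1) * BLOCK_EPOCHS].sum() >= MIN_COVERAGE_S
    ]
    if not qualifying:
        raise ValueError("no 5-min block holds >= 30 s of SpO2 samples; bounds undetectable")
    start = qualifying[0] * BLOCK_EPOCHS * epoch_len
    end = (qualifying[-1] + 1) * BLOCK_EPOCHS * epoch_len
    return RecordBounds(start, end)


@dataclass(frozen=True)
class SleepParameters:
    """Per-record sleep parameters, all durations in minutes, SE in percent."""

    SPT: float
    TST: float
    SE: float
    SOL: float  # NaN when no sleep onset occurs
    WASO: float  # NaN when no sleep onset occurs
    REM: float
    NREM: float

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in ("SPT", "TST", "SE", "SOL", "WASO", "REM", "NREM")}


def find_sleep_onset(
    sleep_mask: np.ndarray,
    from_epoch: int = 0,
    sliding: bool = True,
) -> int | None:
    """First epoch of the first qualifying 10-min span, or None.

    A span qualifies when >= 10 of its 20 epochs are scored sleep.  With
    ``sliding`` (default) spans start at every epoch >= ``from_epoch``;
    otherwise only at fixed 20-epoch block boundaries counted from
    ``from_epoch``.
    """
    s = np.asarray(sleep_mask, dtype=bool)
    starts = (
        range(from_epoch, s.size - ONSET_SPAN_EPOCHS + 1)
        if sliding
        else range(from_epoch, s.size - ONSET_SPAN_EPOCHS + 1, ONSET_SPAN_EPOCHS)
    )
    for i in starts:
        if s[i : i + ONSET_SPAN_EPOCHS].sum() >= ONSET_MIN_SLEEP:
            return i
    return None


def derive_parameters(
    hyp: Hypnogram,
    bounds: RecordBounds,
    lights_off_s: float | None = None,
    sliding_onset: bool = True,
) -> SleepParameters:
    """Derive the sleep parameters of one record within its bounds.

    The hypnogram is indexed on the full epoch grid (epoch 0 at t = 0);
    epochs outside the bounds never contribute.  ``lights_off_s`` defaults
    to the bound start and must lie within the bounds.
    """
    lo_s = bounds.start_s if lights_off_s is None else float(lights_off_s)
    if not bounds.start_s <= lo_s < bounds.end_s:
        raise ValueError("lights_off must lie within the record bounds")
    i0, i1 = bounds.start_epoch, bounds.end_epoch
    if len(hyp) < i1:
        raise ValueError("hypnogram does not cover the record bounds")
    labels = hyp.labels[i0:i1]
    sleep = labels != "W"
    epoch_min = hyp.epoch_len / 60.0
    spt = (bounds.end_s - bounds.start_s) / 60.0
    tst = epoch_min * float(sleep.sum())
    se = 100.0 * tst / spt
    rem = epoch_min * float(np.sum(labels == REM))
    nrem = epoch_min * float(np.sum(labels == NREM))
    lo_epoch = int(lo_s // hyp.epoch_len) - i0  # relative to bounds
    onset = find_sleep_onset(sleep, from_epoch=lo_epoch, sliding=sliding_onset)
    if onset is None:
        sol = waso = float("nan")
    else:
        sol = (onset - lo_epoch) * epoch_min
        # WASO counts wake from the first epoch actually scored sleep at or
        # after the onset span's start (latency inside the span is SOL-side,
        # not wakefulness after sleep onset)
        first_sleep = onset + int(np.argmax(sleep[onset:]))
        waso = epoch_min * float(np.sum(~sleep[first_sleep:]))
    return SleepParameters(SPT=spt, TST=tst, SE=se, SOL=sol, WASO=waso, REM=rem, NREM=nrem)
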