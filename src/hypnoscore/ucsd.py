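"""The UCSD interpretative algorithm: weighted 7-min actigraphy sleep/wake scoring.

The scorer rates each successive minute as wake or sleep from a weighted sum
of activity over a 7-min span — the current minute, the 4 preceding and the
2 following minutes.  The decision statistic for minute *t* is

    D(t) = sum_{k=-4}^{+2} w_k * A(t + k)

and the minute is scored **sleep** when ``D(t) < threshold``.  Coefficients
and threshold live in a versioned YAML config (PIM-mode defaults from the
original UCSD publication); the source 30-s epoch grid is aggregated to
minutes by pairwise summation and each minute's label is expanded back to
its two 30-s epochs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from .stages import Hypnogram

KERNEL_OFFSETS = tuple(range(-4, 3))  # minutes -4 ... +2


@dataclass(frozen=True)
class UCSDConfig:
    weights: np.ndarray  # 7 coefficients for minutes -4 ... +2
    threshold: float
    count_mode: str = "PIM"
    name: str = "ucsd-pim-2001"

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (7,):
            raise ValueError("UCSD kernel requires exactly 7 weights (minutes -4 ... +2)")
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.count_mode not in ("PIM", "ZCM", "TAT"):
            raise ValueError("count_mode must be one of PIM, ZCM, TAT")
        object.__setattr__(self, "weights", w)

    @classmethod
    def from_yaml(cls, path=None) -> "UCSDConfig":
        """Load a config; defaults to the packaged PIM coefficients."""
        if path is None:
            text = resources.files("hypnoscore.data").joinpath("ucsd_default.yaml").read_text()
        else:
            with open(path) as fh:
                text = fh.read()
        cfg = yaml.safe_load(text)
        return cls(
            weights=np.asarray(cfg["weights"], dtype=float),
            threshold=float(cfg["threshold"]),
            count_mode=cfg.get("count_mode", "PIM"),
            name=cfg.get("name", "custom"),
        )


def counts_to_minutes(counts_30s: np.ndarray) -> tuple[np.ndarray, bool]:
    """Pairwise-sum 30-s counts into per-minute counts.

    Odd-length records carry the trailing 30-s epoch as a half-minute (its
    count summed alone), flagged via the returned boolean and a warning.
    """
    c = np.asarray(counts_30s, dtype=float)
    odd = bool(c.size % 2)
    if odd:
        warnings.warn("odd number of 30-s epochs: trailing half-minute carried as-is",
                      stacklevel=2)
        minutes = np.concatenate([c[:-1].reshape(-1, 2).sum(axis=1), c[-1:]])
    else:
        minutes = c.reshape(-1, 2).sum(axis=1)
    return minutes, odd


def score_minutes(counts_per_min: np.ndarray, cfg: UCSDConfig) -> tuple[np.ndarray, np.ndarray]:
    """Per-minute sleep mask and decision statistic D(t); edges zero-padded."""
    a = np.asarray(counts_per_min, dtype=float)
    pad = np.concatenate([np.zeros(4), a, np.zeros(2)])
    d = np.zeros(a.size)
    for j, k in enumerate(KERNEL_OFFSETS):
        d += cfg.weights[j] * pad[4 + k : 4 + k + a.size]
    return d < cfg.threshold, d


def ucsd_score(counts_30s: np.ndarray, cfg: UCSDConfig | None = None) -> Hypnogram:
    """Score a 30-s activity-count series as a binary (W / sleep) hypnogram."""
    cfg = cfg or UCSDConfig.from_yaml()
    minutes, odd = counts_to_minutes(counts_30s)
    sleep_min, d = score_minutes(minutes, cfg)
    sleep_epochs = np.repeat(sleep_min, 2)
    if odd:
        sleep_epochs = sleep_epochs[:-1]  # trailing half-minute -> one epoch
    n = np.asarray(counts_30s).size
    sleep_epochs = sleep_epochs[:n]
    flags = {"edge_padded": True, "odd_trailing_half_minute": odd,
             "decision_statistic": d}
    return Hypnogram.from_sleep_mask(sleep_epochs, flags=flags)
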