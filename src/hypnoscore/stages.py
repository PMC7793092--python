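"""Sleep-stage alphabets and hypnogram containers.

Polysomnography (PSG) is scored in 30-s epochs on a five-symbol alphabet
(wake, NREM stages 1-3, REM).  Everything downstream of the scorer works
on one of two deterministic collapses of that alphabet:

* three classes  ``{W, NREM, REM}`` — the stage-scoring task, and
* two classes    ``{wake, sleep}``  — the classic actigraphy task,
  where sleep = NREM + REM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

EPOCH_LEN_S = 30.0

WAKE = "W"
N1 = "N1"
N2 = "N2"
N3 = "N3"
REM = "REM"
NREM = "NREM"

STAGES5 = (WAKE, N1, N2, N3, REM)
STAGES3 = (WAKE, NREM, REM)

_COLLAPSE3 = {WAKE: WAKE, N1: NREM, N2: NREM, N3: NREM, REM: REM, NREM: NREM}


def collapse_to_3(labels) -> np.ndarray:
    """Map five-stage labels onto {W, NREM, REM}. Idempotent on 3-class input."""
    return np.array([_COLLAPSE3[str(s)] for s in labels], dtype=object)


@dataclass(frozen=True)
class StageSequence:
    """A per-30-s-epoch sequence of five-stage PSG labels."""

    labels: np.ndarray  # dtype=object, values in STAGES5
    epoch_len: float = EPOCH_LEN_S

    def __post_init__(self):
        labels = np.asarray(self.labels, dtype=object)
        if labels.size < 1:
            raise ValueError("stage sequence must contain at least one epoch")
        bad = set(map(str, labels)) - set(STAGES5)
        if bad:
            raise ValueError(f"unknown stage labels: {sorted(bad)}")
        object.__setattr__(self, "labels", labels)

    def __len__(self) -> int:
        return len(self.labels)

    def to_hypnogram(self) -> "Hypnogram":
        return Hypnogram(collapse_to_3(self.labels))


@dataclass(frozen=True)
class Hypnogram:
    """Per-epoch stage labels on the {W, NREM, REM} alphabet.

    ``sleep_mask`` gives the binary sleep/wake view (sleep = NREM + REM).
    """

    labels: np.ndarray
    epoch_len: float = EPOCH_LEN_S
    flags: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        labels = np.asarray(self.labels, dtype=object)
        if labels.size < 1:
            raise ValueError("hypnogram must contain at least one epoch")
        bad = set(map(str, labels)) - set(STAGES3)
        if bad:
            raise ValueError(f"labels outside {{W, NREM, REM}}: {sorted(bad)}")
        object.__setattr__(self, "labels", labels)

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def sleep_mask(self) -> np.ndarray:
        """Boolean per-epoch array, True where the epoch is scored sleep."""
        return self.labels != WAKE

    @classmethod
    def from_sleep_mask(cls, mask, flags=None) -> "Hypnogram":
        """Binary scorers (e.g. UCSD) produce W/NREM-only hypnograms."""
        labels = np.where(np.asarray(mask, dtype=bool), NREM, WAKE).astype(object)
        return cls(labels, flags=flags or {})

    def slice_epochs(self, start: int, stop: int) -> "Hypnogram":
        return Hypnogram(self.labels[start:stop], self.epoch_len, dict(self.flags))
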