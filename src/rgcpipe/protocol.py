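"""Stimulus protocol: epoch layout of one recording session.

A session consists of two spontaneous epochs (before and after CNO wash-in),
repeated trials of a full-field chirp stimulus (contrast steps, a 1-15 Hz
frequency sweep and a contrast-modulation sweep), and repeated trials of a
moving bar presented in several directions.  Spike times are stored per
epoch, relative to epoch onset; the protocol object is the single source of
truth for epoch identities, durations and bar directions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError

#: default chirp segmentation (label, start s, end s); 1-s analysis windows
#: after the ON and OFF contrast steps are taken from these anchors
DEFAULT_CHIRP_SEGMENTS: tuple[tuple[str, float, float], ...] = (
    ("baseline", 0.0, 2.0),
    ("step_on", 2.0, 5.0),
    ("step_off", 5.0, 8.0),
    ("freq_sweep", 8.0, 16.0),  # 1 -> 15 Hz linear chirp
    ("pause", 16.0, 17.0),
    ("contrast_sweep", 17.0, 25.0),  # 2 Hz, amplitude ramp
    ("tail", 25.0, 27.0),
)

DEFAULT_BAR_DIRECTIONS: tuple[float, ...] = tuple(float(d) for d in range(0, 360, 30))


@dataclass(frozen=True)
class Epoch:
    """One contiguous recording epoch.

    ``kind`` is one of ``spont_pre``, ``spont_cno``, ``chirp``, ``bar``;
    ``direction_deg`` is NaN except for bar epochs.
    """

    epoch_id: int
    kind: str
    trial: int
    direction_deg: float
    duration_s: float

    @property
    def is_cno(self) -> bool:
        return self.kind == "spont_cno"


@dataclass(frozen=True)
class StimulusProtocol:
    chirp_segments: tuple[tuple[str, float, float], ...] = DEFAULT_CHIRP_SEGMENTS
    n_chirp_trials: int = 5
    bar_directions: tuple[float, ...] = DEFAULT_BAR_DIRECTIONS
    n_bar_trials: int = 5
    bar_epoch_duration_s: float = 2.0
    spont_pre_duration_s: float = 300.0
    spont_cno_duration_s: float = 300.0

    def __post_init__(self) -> None:
        prev_end = None
        for label, start, end in self.chirp_segments:
            if end <= start:
                raise ConfigurationError(f"chirp segment {label!r} has end <= start")
            if prev_end is not None and start < prev_end:
                raise ConfigurationError(f"chirp segment {label!r} overlaps its predecessor")
            prev_end = end
        dirs = np.asarray(self.bar_directions, dtype=float) % 360.0
        if len(np.unique(dirs)) != len(dirs):
            raise ConfigurationError("bar directions must be distinct modulo 360")
        for name in ("bar_epoch_duration_s", "spont_pre_duration_s", "spont_cno_duration_s"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.n_chirp_trials < 0 or self.n_bar_trials < 0:
            raise ConfigurationError("trial counts must be nonnegative")

    @property
    def chirp_duration_s(self) -> float:
        return self.chirp_segments[-1][2]

    def segment(self, label: str) -> tuple[float, float]:
        for seg_label, start, end in self.chirp_segments:
            if seg_label == label:
                return start, end
        raise KeyError(label)

    def epochs(self, kinds: tuple[str, ...] | None = None) -> list[Epoch]:
        """Enumerate epochs in session order with stable integer ids."""
        out: list[Epoch] = []
        eid = 0
        out.append(Epoch(eid, "spont_pre", 0, np.nan, self.spont_pre_duration_s))
        eid += 1
        out.append(Epoch(eid, "spont_cno", 0, np.nan, self.spont_cno_duration_s))
        eid += 1
        for trial in range(self.n_chirp_trials):
            out.append(Epoch(eid, "chirp", trial, np.nan, self.chirp_duration_s))
            eid += 1
        for trial in range(self.n_bar_trials):
            for direction in self.bar_directions:
                out.append(Epoch(eid, "bar", trial, float(direction), self.bar_epoch_duration_s))
                eid += 1
        if kinds is not None:
            out = [e for e in out if e.kind in kinds]
        return out

    def epoch_ids(self, kind: str) -> list[int]:
        return [e.epoch_id for e in self.epochs() if e.kind == kind]
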