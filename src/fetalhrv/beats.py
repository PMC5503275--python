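"""Core beat-series containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FLAGS", "VALID", "MISSED", "FALSE_POSITIVE", "ECTOPIC", "INTERPOLATED",
           "BeatSeries", "UniformSeries", "RR_MIN_MS", "RR_MAX_MS"]

VALID = "valid"
MISSED = "missed"
FALSE_POSITIVE = "false_positive"
ECTOPIC = "ectopic"
INTERPOLATED = "interpolated"
FLAGS = frozenset({VALID, MISSED, FALSE_POSITIVE, ECTOPIC, INTERPOLATED})

# physiologic guard band for cleaned R-R intervals
RR_MIN_MS = 100.0
RR_MAX_MS = 3000.0


@dataclass
class BeatSeries:
    """Irregular beat-to-beat record.

    Attributes
    ----------
    beat_time : ndarray
        Beat times in seconds from record start, strictly increasing.
    rr : ndarray
        R-R interval ending at each beat, in milliseconds, > 0.
    flag : ndarray of str
        Per-beat quality flag, one of :data:`FLAGS`.
    """

    beat_time: np.ndarray
    rr: np.ndarray
    flag: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.beat_time = np.asarray(self.beat_time, dtype=float)
        self.rr = np.asarray(self.rr, dtype=float)
        if self.flag is None:
            self.flag = np.full(self.rr.size, VALID, dtype="<U14")
        else:
            self.flag = np.asarray(self.flag, dtype="<U14")
        if self.beat_time.ndim != 1 or self.beat_time.shape != self.rr.shape:
            raise ValueError("beat_time and rr must be 1-D arrays of equal length")
        if self.flag.shape != self.rr.shape:
            raise ValueError("flag length mismatch")
        if self.rr.size and np.any(np.diff(self.beat_time) <= 0):
            raise ValueError("beat_time must be strictly increasing")
        if np.any(self.rr <= 0):
            bad = int(np.flatnonzero(self.rr <= 0)[0])
            raise ValueError(f"non-positive rr at beat {bad}")
        unknown = set(np.unique(self.flag)) - FLAGS
        if unknown:
            raise ValueError(f"unknown flags: {sorted(unknown)}")

    def __len__(self) -> int:
        return int(self.rr.size)

    @classmethod
    def from_rr(cls, rr, start_time: float = 0.0) -> "BeatSeries":
        """Build a series from consecutive R-R intervals (ms).

        Beat *i* is placed at ``start_time + cumsum(rr)[i] / 1000`` — each
        interval ends at its beat.
        """
        rr = np.asarray(rr, dtype=float)
        return cls(beat_time=start_time + np.cumsum(rr) / 1000.0, rr=rr)

    @property
    def duration(self) -> float:
        """Span in seconds between the first and last beat."""
        return float(self.beat_time[-1] - self.beat_time[0]) if len(self) else 0.0

    def copy(self) -> "BeatSeries":
        return BeatSeries(self.beat_time.copy(), self.rr.copy(), self.flag.copy())


@dataclass
class UniformSeries:
    """R-R signal resampled on a fixed-rate grid."""

    start_time: float
    rate: float
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.rate <= 0:
            raise ValueError("rate must be positive")

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.values.size) / self.rate

    @property
    def duration(self) -> float:
        return (self.values.size - 1) / self.rate
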