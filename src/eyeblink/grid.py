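"""Discrete time grid and binary event trains.

All model computations run on a fixed grid (2 ms by default, the step used by
the real-time implementation).  Events are binary: a channel either has a
detection in a given step or it does not, and times are stored as integer step
indices.  Binning is half-open, ``[k*dt, (k+1)*dt)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TimeGrid", "EventTrain", "PN", "IO"]

PN = "PN"
IO = "IO"


@dataclass(frozen=True)
class TimeGrid:
    """A uniform discretization of session time.

    Parameters
    ----------
    dt : float
        Seconds per step (default 0.002).
    horizon : int
        Session length in steps.
    """

    dt: float = 0.002
    horizon: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.horizon < 0:
            raise ValueError("horizon must be non-negative")

    def to_steps(self, seconds: float | np.ndarray) -> int | np.ndarray:
        """Convert seconds to step indices with round-half-up."""
        k = np.floor(np.asarray(seconds, dtype=float) / self.dt + 0.5).astype(np.int64)
        return int(k) if k.ndim == 0 else k

    def to_seconds(self, steps: int | np.ndarray) -> float | np.ndarray:
        out = np.asarray(steps, dtype=float) * self.dt
        return float(out) if out.ndim == 0 else out

    @property
    def duration(self) -> float:
        return self.horizon * self.dt


@dataclass
class EventTrain:
    """Timestamped binary events for one channel on a fixed grid.

    ``steps`` holds strictly increasing, non-negative integer step indices
    (< grid horizon); multiplicities collapse, i.e. the train is binary.
    """

    channel: str
    steps: np.ndarray
    grid: TimeGrid = field(default_factory=TimeGrid)

    def __post_init__(self) -> None:
        steps = np.unique(np.asarray(self.steps, dtype=np.int64))
        if steps.size and steps[0] < 0:
            raise ValueError("event steps must be non-negative")
        if steps.size and self.grid.horizon and steps[-1] >= self.grid.horizon:
            raise ValueError("event step beyond grid horizon")
        self.steps = steps

    def __len__(self) -> int:
        return int(self.steps.size)

    @property
    def times(self) -> np.ndarray:
        """Event times in seconds."""
        return self.steps * self.grid.dt

    def to_binary(self) -> np.ndarray:
        """Dense 0/1 vector over the grid horizon."""
        vec = np.zeros(self.grid.horizon, dtype=np.int8)
        vec[self.steps] = 1
        return vec

    @classmethod
    def from_times(cls, channel: str, times_s, grid: TimeGrid) -> "EventTrain":
        return cls(channel, grid.to_steps(np.asarray(times_s, dtype=float)), grid)

    @classmethod
    def from_binary(cls, channel: str, vec, grid: TimeGrid) -> "EventTrain":
        return cls(channel, np.flatnonzero(np.asarray(vec) != 0), grid)

    def restricted(self, start: int, stop: int) -> np.ndarray:
        """Event steps falling in the half-open window [start, stop)."""
        lo, hi = np.searchsorted(self.steps, [start, stop])
        return self.steps[lo:hi]
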