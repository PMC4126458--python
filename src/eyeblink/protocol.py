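"""Stimulus schedules for classical-conditioning protocols.

A session is a sequence of trials.  Each trial has a CS trigger, optionally a
US trigger (paired trials, ``us = cs + ISI``), and a condition label.  Trial
windows are half-open and partition the session, so every event belongs to
exactly one trial; the window of trial *k* opens ``pre_s`` seconds before its
CS trigger and closes where the next one opens.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import TimeGrid

__all__ = ["Trial", "StimulusSchedule", "make_schedule", "concatenate_schedules"]

#: condition labels (mirroring the acquisition/extinction/stability conditions)
PAIRED = "paired"
CS_ALONE = "cs_alone"
UNPAIRED = "unpaired"


@dataclass(frozen=True)
class Trial:
    cs_step: int
    us_step: int | None
    condition: str


@dataclass
class StimulusSchedule:
    """Trial list plus the grid and the nominal ISI (seconds)."""

    trials: list[Trial]
    grid: TimeGrid
    isi: float
    pre_s: float = 1.0

    def __post_init__(self) -> None:
        cs = self.cs_steps
        if cs.size > 1 and np.any(np.diff(cs) <= 0):
            raise ValueError("CS triggers must be strictly increasing")
        for t in self.trials:
            if t.us_step is not None and t.us_step <= t.cs_step:
                raise ValueError("US trigger must follow the CS trigger")

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def cs_steps(self) -> np.ndarray:
        return np.array([t.cs_step for t in self.trials], dtype=np.int64)

    @property
    def us_steps(self) -> np.ndarray:
        """US trigger steps; CS-alone trials get the virtual US ``cs + ISI``.

        The virtual trigger keeps extinction-phase CRs classifiable by the same
        20-ms anticipation criterion used on paired trials.
        """
        isi_steps = self.grid.to_steps(self.isi)
        return np.array(
            [t.us_step if t.us_step is not None else t.cs_step + isi_steps for t in self.trials],
            dtype=np.int64,
        )

    @property
    def trial_starts(self) -> np.ndarray:
        """Half-open trial window boundaries (length ``n_trials + 1``)."""
        pre = self.grid.to_steps(self.pre_s)
        starts = np.maximum(self.cs_steps - pre, 0)
        starts[0] = 0
        end = self.grid.horizon if self.grid.horizon else int(self.cs_steps[-1] + pre)
        return np.append(starts, end)

    def trial_of(self, steps: np.ndarray) -> np.ndarray:
        """Trial index of each step (events in ITIs belong to the enclosing trial)."""
        return np.clip(np.searchsorted(self.trial_starts, steps, side="right") - 1, 0, len(self) - 1)


def make_schedule(
    n_trials: int,
    isi_s: float = 0.3,
    iti_s: float | tuple[float, float] = (10.0, 15.0),
    condition: str = PAIRED,
    grid_dt: float = 0.002,
    rng: np.random.Generator | None = None,
    start_s: float = 2.0,
    tail_s: float = 2.0,
) -> StimulusSchedule:
    """Build a schedule with fixed or uniformly randomized CS-to-CS intervals.

    ``iti_s`` is the CS-onset-to-CS-onset interval, either a constant or a
    ``(low, high)`` range sampled uniformly per trial (10-15 s by default).
    ``condition`` of ``"paired"`` schedules a US at ``cs + isi``; any other
    label leaves the US out (a virtual one is still used for CR timing).
    """
    if n_trials < 1:
        raise ValueError("need at least one trial")
    if isinstance(iti_s, (tuple, list)):
        lo, hi = iti_s
        if rng is None:
            rng = np.random.default_rng()
        itis = rng.uniform(lo, hi, size=max(n_trials - 1, 0))
    else:
        itis = np.full(max(n_trials - 1, 0), float(iti_s))
    cs_times = start_s + np.concatenate([[0.0], np.cumsum(itis)])
    grid = TimeGrid(grid_dt, 0)
    cs_steps = grid.to_steps(cs_times)
    isi_steps = grid.to_steps(isi_s)
    horizon = int(cs_steps[-1] + grid.to_steps(max(tail_s, isi_s + 1.0)))
    grid = TimeGrid(grid_dt, horizon)
    trials = [
        Trial(int(c), int(c + isi_steps) if condition == PAIRED else None, condition)
        for c in cs_steps
    ]
    return StimulusSchedule(trials, grid, isi_s)


def concatenate_schedules(first: StimulusSchedule, second: StimulusSchedule, gap_s: float = 12.0) -> StimulusSchedule:
    """Append ``second`` after ``first`` (e.g. acquisition then extinction)."""
    if first.grid.dt != second.grid.dt:
        raise ValueError("schedules must share a grid step")
    offset = first.grid.horizon + first.grid.to_steps(gap_s)
    trials = list(first.trials) + [
        Trial(t.cs_step + offset, None if t.us_step is None else t.us_step + offset, t.condition)
        for t in second.trials
    ]
    grid = TimeGrid(first.grid.dt, offset + second.grid.horizon)
    return StimulusSchedule(trials, grid, first.isi)
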