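"""Synthetic detection-train generators.

Real recordings behind the detection front-end are summarized by two
statistics per channel: the true-detection ratio TDR (probability that a
stimulus raises at least one detection inside its stimulus-locked window) and
the false-alarm rate FAR (detections per second elsewhere).  This module
turns those statistics back into event trains so every other stage of the
package can be exercised without animal data: stationary or slowly drifting
Poisson-like background, stimulus-locked true detections, within-trial
shuffling (the unpaired control) and post-CR artifact masking.

Two true-detection latency models are provided.  ``per_step`` converts the
TDR to an independent per-step Bernoulli probability ``1 - (1-TDR)^(1/n)``
(the conversion used for pure simulation studies) and may yield several
detections per stimulus; ``draw`` emits at most one detection per stimulus
(probability TDR, latency uniform in the window), which is what a threshold
detector with a refractory period produces and is the right emulation of
recorded detection trains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._engine import merge_intervals
from .exceptions import ConfigurationError, InputError
from .grid import IO, PN, EventTrain, TimeGrid
from .protocol import StimulusSchedule

__all__ = [
    "DetectionStats",
    "RateProfile",
    "tdr_to_step_prob",
    "far_to_step_prob",
    "simulate_channel",
    "simulate_background",
    "shuffle_io_within_trials",
    "apply_cr_mask",
    "drifting_rate_profile",
    "PN_WINDOW",
    "IO_WINDOW",
]

#: a-priori true-detection windows after the trigger (s)
PN_WINDOW = (0.010, 0.150)
IO_WINDOW = (0.005, 0.205)


@dataclass(frozen=True)
class DetectionStats:
    """TDR/FAR operating point plus the stimulus-locked window for a channel."""

    channel: str
    tdr: float
    far: float
    td_window: tuple[float, float] = PN_WINDOW
    latency_model: str = "per_step"

    def __post_init__(self) -> None:
        if not (0.0 <= self.tdr <= 1.0):
            raise ConfigurationError("tdr must lie in [0, 1]")
        if self.far < 0:
            raise ConfigurationError("far must be non-negative")
        if self.td_window[0] >= self.td_window[1]:
            raise ConfigurationError("td window start must precede its end")
        if self.latency_model not in ("per_step", "draw"):
            raise ConfigurationError(f"unknown latency model {self.latency_model!r}")

    def window_steps(self, grid: TimeGrid) -> tuple[int, int]:
        return grid.to_steps(self.td_window[0]), grid.to_steps(self.td_window[1])


@dataclass(frozen=True)
class RateProfile:
    """Background rate as a function of time, on a coarse (1 s) grid, Hz."""

    knots_s: np.ndarray
    rates_hz: np.ndarray
    bounds: tuple[float, float]

    def rate(self, times_s: np.ndarray) -> np.ndarray:
        return np.interp(np.asarray(times_s, dtype=float), self.knots_s, self.rates_hz)

    def mean_rate(self, t0: float, t1: float) -> float:
        tt = np.linspace(t0, t1, 65)
        return float(np.trapezoid(self.rate(tt), tt) / (t1 - t0))


def tdr_to_step_prob(tdr: float, n_steps: int) -> float:
    """Per-step probability p with ``1 - (1-p)^n = TDR``.

    TDR = 1 has no finite per-step probability and is rejected.
    """
    if not (0.0 <= tdr < 1.0):
        raise ConfigurationError("tdr must lie in [0, 1) for the per-step conversion")
    if n_steps < 1:
        raise ConfigurationError("window must span at least one step")
    return 1.0 - (1.0 - tdr) ** (1.0 / n_steps)


def far_to_step_prob(far: float, grid: TimeGrid) -> float:
    """Per-step background probability ``FAR * dt``."""
    p = far * grid.dt
    if p >= 1.0:
        raise ConfigurationError("far * dt must be below 1")
    return p


def simulate_background(
    far: float | RateProfile,
    grid: TimeGrid,
    rng: np.random.Generator,
    channel: str = IO,
) -> EventTrain:
    """Per-step Bernoulli background over the whole grid (rate possibly drifting)."""
    if isinstance(far, RateProfile):
        p = far.rate(np.arange(grid.horizon) * grid.dt) * grid.dt
        if np.any(p >= 1.0):
            raise ConfigurationError("far * dt must be below 1")
        steps = np.flatnonzero(rng.random(grid.horizon) < p)
    else:
        p = far_to_step_prob(far, grid)
        steps = np.flatnonzero(rng.random(grid.horizon) < p) if p > 0 else np.empty(0, np.int64)
    return EventTrain(channel, steps, grid)


def simulate_channel(
    schedule: StimulusSchedule,
    stats: DetectionStats,
    grid: TimeGrid | None = None,
    rng: np.random.Generator | None = None,
    profile: RateProfile | None = None,
    seed: int | None = None,
) -> EventTrain:
    """Generate one channel's event train for a stimulus schedule.

    Background false alarms are drawn per-step at ``far(t) * dt``; each
    stimulus adds true detections inside its TD window according to the
    latency model.  PN channels lock to the CS trigger, IO channels to the US
    trigger (CS-alone trials therefore get background only on IO).
    Reproducible given the same generator state.
    """
    grid = grid or schedule.grid
    if grid.dt != schedule.grid.dt:
        raise InputError("grid and schedule must share dt")
    if rng is None:
        rng = np.random.default_rng(seed)
    bg = simulate_background(profile if profile is not None else stats.far, grid, rng, stats.channel)

    s0, s1 = stats.window_steps(grid)
    n_win = s1 - s0
    triggers = []
    for t in schedule.trials:
        trig = t.cs_step if stats.channel == PN else t.us_step
        if trig is not None:
            triggers.append(trig)
    triggers = np.asarray(triggers, dtype=np.int64)
    if triggers.size > 1 and np.any(np.diff(np.sort(triggers)) < n_win):
        raise InputError("stimulus TD windows overlap; schedule too dense")

    evoked: list[np.ndarray] = []
    if stats.tdr > 0 and triggers.size:
        if stats.latency_model == "per_step":
            p = tdr_to_step_prob(stats.tdr, n_win)
            for trig in triggers:
                hits = np.flatnonzero(rng.random(n_win) < p)
                evoked.append(trig + s0 + hits)
        else:  # one draw per stimulus: detected with prob TDR, latency uniform
            detected = rng.random(triggers.size) < stats.tdr
            lat = rng.integers(0, n_win, size=triggers.size)
            evoked.append((triggers + s0 + lat)[detected])
    steps = np.concatenate([bg.steps] + evoked) if evoked else bg.steps
    steps = steps[steps < grid.horizon]
    return EventTrain(stats.channel, steps, grid)


def shuffle_io_within_trials(
    io: EventTrain, schedule: StimulusSchedule, rng: np.random.Generator | None = None, seed: int | None = None
) -> EventTrain:
    """Redraw each trial's IO event positions uniformly within the trial window.

    Per-trial counts are preserved exactly; the CS-US contingency is
    destroyed while marginal rates survive.  This is the unpaired-stimulation
    control.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    bounds = schedule.trial_starts.copy()
    bounds[-1] = max(bounds[-1], int(io.steps[-1]) + 1 if len(io) else 0)
    out = []
    for k in range(len(schedule)):
        lo, hi = int(bounds[k]), int(bounds[k + 1])
        n = io.restricted(lo, hi).size
        if k == len(schedule) - 1:  # tail events belong to the last trial
            n = len(io) - np.searchsorted(io.steps, lo)
        if n:
            out.append(rng.choice(hi - lo, size=min(n, hi - lo), replace=False) + lo)
    steps = np.concatenate(out) if out else np.empty(0, np.int64)
    return EventTrain(io.channel, steps, io.grid)


def apply_cr_mask(
    io: EventTrain,
    cr_steps: np.ndarray,
    mask_duration_s: float,
    replacement_rate_hz: float | None = None,
    rng: np.random.Generator | None = None,
) -> EventTrain:
    """Remove IO events within ``mask_duration_s`` after each CR trigger.

    Emulates the stimulation artifact blanking of the acquisition stage
    (half-open windows ``[cr, cr + mask)``).  With ``replacement_rate_hz``
    set, the blanked spans are refilled with Bernoulli background at that
    rate (the replace-with-spontaneous control); ``rng`` is then required.
    """
    if mask_duration_s < 0:
        raise ConfigurationError("mask duration must be non-negative")
    grid = io.grid
    n = grid.to_steps(mask_duration_s)
    starts = np.asarray(cr_steps, dtype=np.int64)
    ms, me = merge_intervals(starts, np.minimum(starts + n, grid.horizon))
    keep = np.ones(len(io), dtype=bool)
    for a, b in zip(ms, me):
        lo, hi = np.searchsorted(io.steps, [a, b])
        keep[lo:hi] = False
    steps = io.steps[keep]
    if replacement_rate_hz is not None:
        if rng is None:
            raise InputError("replacement mode needs a random generator")
        p = replacement_rate_hz * grid.dt
        fills = [a + np.flatnonzero(rng.random(b - a) < p) for a, b in zip(ms, me)]
        steps = np.concatenate([steps] + fills) if fills else steps
    return EventTrain(io.channel, steps, grid)


def drifting_rate_profile(
    kind: str,
    bounds: tuple[float, float] = (0.5, 2.0),
    period_s: float = 1200.0,
    duration_s: float = 5400.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> RateProfile:
    """Slow baseline-rate drift within the physiological band.

    ``kind``: ``constant`` (at the band midpoint... use ``bounds[0]==bounds[1]``
    for an exact level), ``sinusoid`` (full swing across the band with period
    ``period_s``) or ``random_walk`` (smoothed reflected walk on a 1-s grid,
    clipped to the band).
    """
    lo, hi = bounds
    if lo > hi:
        raise ConfigurationError("rate bounds inverted")
    if lo < 0:
        raise ConfigurationError("rates must be non-negative")
    knots = np.arange(0.0, duration_s + 1.0)
    if kind == "constant":
        rates = np.full_like(knots, (lo + hi) / 2.0)
    elif kind == "sinusoid":
        mid, amp = (lo + hi) / 2.0, (hi - lo) / 2.0
        phase = 0.0
        if rng is None:
            rng = np.random.default_rng(seed)
        phase = rng.uniform(0, 2 * np.pi)
        rates = mid + amp * np.sin(2 * np.pi * knots / period_s + phase)
    elif kind == "random_walk":
        if rng is None:
            rng = np.random.default_rng(seed)
        # OU-like increments tuned so the band is explored over ~period_s
        sd = (hi - lo) / np.sqrt(period_s) if period_s > 0 else 0.0
        steps = rng.normal(0.0, sd, size=knots.size)
        walk = np.empty_like(knots)
        walk[0] = (lo + hi) / 2.0
        mid = (lo + hi) / 2.0
        for i in range(1, knots.size):
            walk[i] = walk[i - 1] + steps[i] - (walk[i - 1] - mid) / period_s
        rates = np.clip(walk, lo, hi)
    else:
        raise ConfigurationError(f"unknown profile kind {kind!r}")
    return RateProfile(knots, np.clip(rates, lo, hi), (lo, hi))
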