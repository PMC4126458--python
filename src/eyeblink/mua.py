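"""Low-complexity event detection on multi-unit-activity-like signals.

The front-end detects sustained variability increases in a band-passed 1-D
signal: subtract a running mean estimate, rectify, smooth to a short-term
average, and emit an event at each upward crossing of a detection threshold
(with a refractory period so a sustained burst yields one event, not one per
sample).  Detections are scored against a-priori stimulus-locked windows:
TDR is the fraction of stimuli with at least one in-window detection and FAR
the detection rate outside all windows; sweeping the threshold yields the
ROC curve used to pick operating points.

A synthetic MUA generator (Gaussian background whose variance steps up after
each trigger) serves as the module's test fixture; inputs are assumed
band-pass filtered upstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from scipy.signal import lfilter

from .exceptions import ConfigurationError, InputError
from .grid import EventTrain, TimeGrid

__all__ = [
    "MuaSignal",
    "DetectorParams",
    "DetectionScore",
    "RocCurve",
    "detect_events",
    "score_detections",
    "roc_curve",
    "synth_mua",
]


@dataclass
class MuaSignal:
    samples: np.ndarray
    fs: float
    channel: str = "MUA"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ConfigurationError("sampling rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ConfigurationError("signal contains non-finite values")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs


@dataclass(frozen=True)
class DetectorParams:
    """Detection pipeline parameters (all windows in seconds).

    ``mean_estimator``: "ema" (default) or "sma" for the running mean;
    ``variability``: "rectify" (default) or "square".
    """

    mean_window_s: float = 0.5
    smooth_window_s: float = 0.01
    threshold: float = 1.0
    refractory_s: float = 0.010
    mean_estimator: str = "ema"
    variability: str = "rectify"

    def __post_init__(self) -> None:
        if self.mean_window_s <= 0 or self.smooth_window_s <= 0:
            raise ConfigurationError("windows must be positive")
        if self.threshold <= 0:
            raise ConfigurationError("threshold must be positive")
        if self.mean_estimator not in ("ema", "sma") or self.variability not in ("rectify", "square"):
            raise ConfigurationError("unknown estimator flag")


@dataclass(frozen=True)
class DetectionScore:
    tdr: float
    far: float
    n_stimuli: int
    td_window: tuple[float, float]
    latencies_s: np.ndarray  # first in-window detection latency per detected stimulus


@dataclass
class RocCurve:
    thresholds: np.ndarray
    tdr: np.ndarray
    far: np.ndarray
    channel: str = "MUA"

    def as_stats(self, i: int) -> tuple[float, float]:
        return float(self.tdr[i]), float(self.far[i])


def _causal_moving_average(x: np.ndarray, n: int) -> np.ndarray:
    """Trailing-window mean (a real-time stage must be causal)."""
    if n <= 1:
        return x
    cs = np.concatenate([[0.0], np.cumsum(x)])
    out = np.empty_like(x)
    out[n - 1 :] = (cs[n:] - cs[:-n]) / n
    out[: n - 1] = cs[1:n] / np.arange(1, n)
    return out


def variability_signal(signal: MuaSignal, params: DetectorParams) -> np.ndarray:
    """Mean-subtracted, rectified, smoothed amplitude (the detection signal).

    All stages are causal, as a real-time front-end requires; the detection
    latency is therefore bounded by the smoothing window, not the mean one.
    """
    x = signal.samples
    n_mean = max(int(round(params.mean_window_s * signal.fs)), 1)
    if params.mean_estimator == "ema":
        alpha = 2.0 / (n_mean + 1)
        mean, _ = lfilter([alpha], [1.0, -(1.0 - alpha)], x, zi=[(1.0 - alpha) * x[0]])
    else:
        mean = _causal_moving_average(x, n_mean)
    dev = x - mean
    dev = np.abs(dev) if params.variability == "rectify" else dev**2
    n_smooth = max(int(round(params.smooth_window_s * signal.fs)), 1)
    return _causal_moving_average(dev, n_smooth)


def _events_from_variability(
    v: np.ndarray, fs: float, threshold: float, refractory_s: float, grid: TimeGrid, channel: str
) -> EventTrain:
    above = v > threshold
    crossings = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if above.size and above[0]:
        crossings = np.insert(crossings, 0, 0)
    refr = int(round(refractory_s * fs))
    kept = []
    last = -refr - 1
    for c in crossings:
        if c - last > refr:
            kept.append(c)
            last = c
    steps = np.floor(np.asarray(kept, dtype=float) / fs / grid.dt + 0.5).astype(np.int64)
    horizon = grid.horizon or int(np.ceil(v.size / fs / grid.dt))
    return EventTrain(channel, steps[steps < horizon], TimeGrid(grid.dt, horizon))


def detect_events(signal: MuaSignal, params: DetectorParams, grid: TimeGrid) -> EventTrain:
    """Threshold the variability signal and emit events at upward crossings.

    Crossings within ``refractory_s`` of the previous event are suppressed;
    events are mapped onto the model grid (round-half-up).  The sampling rate
    must be an integer multiple of the grid rate.
    """
    if signal.samples.size < max(params.mean_window_s, params.smooth_window_s) * signal.fs:
        raise InputError("signal shorter than the detector windows")
    ratio = signal.fs * grid.dt
    if abs(ratio - round(ratio)) > 1e-9:
        raise InputError("sampling rate incompatible with the model grid")
    v = variability_signal(signal, params)
    return _events_from_variability(v, signal.fs, params.threshold, params.refractory_s, grid, signal.channel)


def score_detections(
    events: EventTrain, triggers_s: np.ndarray, td_window: tuple[float, float]
) -> DetectionScore:
    """TDR/FAR of an event train against stimulus-locked windows.

    FAR is computed over the time outside all TD windows only, so evoked
    responses do not inflate the background rate.
    """
    t0, t1 = td_window
    if t1 <= t0:
        raise InputError("td window start must precede its end")
    triggers = np.sort(np.asarray(triggers_s, dtype=float))
    if triggers.size > 1 and np.any(np.diff(triggers) < (t1 - t0)):
        raise InputError("TD windows overlap")
    times = events.times
    hit = 0
    lat = []
    in_window = np.zeros(times.size, dtype=bool)
    for trig in triggers:
        lo, hi = np.searchsorted(times, [trig + t0, trig + t1])
        if hi > lo:
            hit += 1
            lat.append(times[lo] - trig)
            in_window[lo:hi] = True
    total = events.grid.duration
    quiet = total - triggers.size * (t1 - t0)
    far = float(np.count_nonzero(~in_window)) / quiet if quiet > 0 else np.nan
    tdr = hit / triggers.size if triggers.size else np.nan
    return DetectionScore(tdr, far, int(triggers.size), td_window, np.asarray(lat))


def roc_curve(
    signal: MuaSignal,
    triggers_s: np.ndarray,
    td_window: tuple[float, float],
    thresholds: np.ndarray,
    params: DetectorParams,
    grid: TimeGrid | None = None,
) -> RocCurve:
    """One detection score per threshold (thresholds sorted ascending).

    TDR and FAR are monotone non-increasing in the threshold up to the mild
    non-monotonicity the refractory period can introduce; the construction
    itself enforces nothing, the invariant is asserted by the tests.
    """
    thresholds = np.sort(np.asarray(thresholds, dtype=float))
    grid = grid or TimeGrid(0.002, int(np.ceil(signal.duration / 0.002)))
    v = variability_signal(signal, params)
    tdr, far = [], []
    for thr in thresholds:
        ev = _events_from_variability(v, signal.fs, float(thr), params.refractory_s, grid, signal.channel)
        score = score_detections(ev, triggers_s, td_window)
        tdr.append(score.tdr)
        far.append(score.far)
    return RocCurve(thresholds, np.asarray(tdr), np.asarray(far), signal.channel)


def synth_mua(
    triggers_s: np.ndarray,
    response_gain: float = 5.0,
    response_duration_s: float = 0.050,
    noise_sd: float = 1.0,
    fs: float = 10_000.0,
    duration_s: float | None = None,
    latency_s: float = 0.010,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    channel: str = "MUA",
) -> MuaSignal:
    """Synthetic MUA-like fixture: Gaussian background whose standard
    deviation is multiplied by ``sqrt(response_gain)`` (variance x gain) for
    ``response_duration_s`` after each trigger plus a fixed latency."""
    if fs < 1000:
        raise ConfigurationError("sampling rate must be at least 1 kHz")
    if response_gain <= 0:
        raise ConfigurationError("response gain must be positive")
    triggers = np.asarray(triggers_s, dtype=float)
    if duration_s is None:
        duration_s = (triggers.max(initial=0.0) + 1.0) if triggers.size else 1.0
    n = int(round(duration_s * fs))
    if rng is None:
        rng = np.random.default_rng(seed)
    sd = np.full(n, float(noise_sd))
    amp = np.sqrt(response_gain)
    for trig in triggers:
        a = int(round((trig + latency_s) * fs))
        b = int(round((trig + latency_s + response_duration_s) * fs))
        sd[max(a, 0):max(b, 0)] *= amp
    samples = rng.normal(0.0, 1.0, size=n) * sd
    return MuaSignal(samples, fs, channel)
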