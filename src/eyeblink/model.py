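"""The cerebellar microcircuit engine.

The model maps CS-pathway (PN) detections to conditioned-response triggers and
adapts a single memory parameter ``w`` by eligibility-gated coincidence
plasticity:

* each PN detection starts a decaying *trace*; a CR is triggered the first
  time the scaled trace ``w * trace(t)`` falls below the decision threshold
  ``theta_cr`` -- smaller ``w`` means an earlier CR;
* each PN detection also arms a delayed rectangular *eligibility window*
  (delay ``lambda_noi``, duration ``lambda_tau_elig``); every eligible step
  potentiates ``w`` by ``delta_p`` and every US-pathway (IO) detection that
  survives gating and lands on an eligible step depresses it by ``delta_d``;
* a CR trigger schedules a delayed *nucleo-olivary inhibition* (NOI) window
  that discards IO detections, closing the negative-feedback loop that
  stabilizes learning and sets CR anticipation.

The latency algebra (minimum learnable ISI, required NOI delay, internal CR
timing) lives here too, since those identities are what make the learned
timing adaptive rather than incidental.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._engine import run_engine
from .exceptions import ConfigurationError, InputError, UnlearnableISIError
from .grid import EventTrain, TimeGrid
from .protocol import StimulusSchedule

__all__ = [
    "TraceParams",
    "LatencyBudget",
    "ModelParams",
    "ModelState",
    "CrEvent",
    "SessionLog",
    "make_trace",
    "cr_trigger_time",
    "anticipation_weight",
    "min_isi",
    "required_noi_delay",
    "internal_timing",
    "classify_cr",
    "run_session",
]

WELL_TIMED = "well_timed"
LATE = "late"

#: minimum CR-to-US lead for a CR to count as well timed (s), boundary inclusive
WELL_TIMED_LEAD_S = 0.020


@dataclass(frozen=True)
class TraceParams:
    """CS trace: initial value ``tau0``, final value ``tau1``, duration
    ``lambda_tau`` seconds, with a pluggable decay family (linear default).

    The linear shape is the one consistent with the three printed anchors of
    the trace model (no CR above ``theta_cr/tau1``; 140 ms trigger at w=0.25;
    anticipation boundary 0.28 for a 300-ms ISI).
    """

    tau0: float = 1.0
    tau1: float = 0.5
    lambda_tau: float = 0.350
    shape: str = "linear"

    def __post_init__(self) -> None:
        if not (self.tau0 >= self.tau1 > 0):
            raise ConfigurationError("need tau0 >= tau1 > 0")
        if self.lambda_tau <= 0:
            raise ConfigurationError("trace duration must be positive")
        if self.shape not in ("linear", "exponential"):
            raise ConfigurationError(f"unknown trace shape {self.shape!r}")

    def value(self, t: float | np.ndarray) -> np.ndarray:
        """Trace value at time ``t`` (s) since the PN detection; 0 outside."""
        t = np.asarray(t, dtype=float)
        if self.shape == "linear":
            v = self.tau0 - (self.tau0 - self.tau1) * t / self.lambda_tau
        else:  # exponential, matched endpoints
            rate = np.log(self.tau0 / self.tau1) / self.lambda_tau
            v = self.tau0 * np.exp(-rate * t)
        return np.where((t >= 0) & (t < self.lambda_tau), v, 0.0)


@dataclass(frozen=True)
class LatencyBudget:
    """The transmission/mechanical latencies of the conditioning loop (s).

    ``omega_cs``: CS trigger to PN detection; ``omega_cr``: CR trigger to
    effective eyelid closure; ``omega_us``: US trigger to IO detection.
    Defaults use the measured mean detection latencies (96.2 / 68.5 ms) and a
    nominal effector latency.  Derived quantities are recomputed on demand.
    """

    omega_cs: float = 0.0962
    omega_cr: float = 0.0638
    omega_us: float = 0.0685
    isi: float = 0.300
    lambda_noi: float = 0.100
    cr_stim_duration: float = 0.150

    def __post_init__(self) -> None:
        for name in ("omega_cs", "omega_cr", "omega_us", "lambda_noi", "cr_stim_duration"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")


def min_isi(lat: LatencyBudget) -> float:
    """Minimum learnable ISI: ``omega_cs + omega_cr``.

    Below it the CS-to-US gap cannot be bridged: even an immediate CR comes
    after the US.
    """
    return lat.omega_cs + lat.omega_cr


def required_noi_delay(lat: LatencyBudget, midpoint: bool = False) -> float:
    """Smallest NOI delay giving anticipatory CRs: ``omega_cr + omega_us``.

    With ``midpoint=True``, add 75 ms (half the 150-ms CR stimulation train)
    so the US onset falls in the middle of the executed CR.
    """
    delay = lat.omega_cr + lat.omega_us
    if midpoint:
        delay += lat.cr_stim_duration / 2.0
    return delay


def internal_timing(lat: LatencyBudget) -> float:
    """Internal CR timing the model must acquire: ``ISI - (omega_cs + omega_cr)``."""
    t_cr = lat.isi - min_isi(lat)
    if -1e-12 < t_cr < 0:
        t_cr = 0.0
    if t_cr < 0:
        raise UnlearnableISIError(
            f"ISI {lat.isi:.3f}s below the minimum learnable ISI {min_isi(lat):.3f}s"
        )
    return t_cr


@dataclass(frozen=True)
class ModelParams:
    """All cerebellar constants.

    ``sigma_bar`` is the mean proportion of IO events *not* suppressed by the
    NOI, used only in the expectation formulas of the calibration (0 = full
    suppression).  ``cr_mask_s`` optionally emulates the acquisition-stage
    stimulation artifact that blanks the IO channel after each CR trigger
    (0 = off; the bio-hybrid rig blanked 2 s).
    """

    trace: TraceParams = field(default_factory=TraceParams)
    theta_cr: float = 0.2
    w0: float = 0.5
    delta_p: float = 0.0
    delta_d: float = 0.0
    lambda_noi: float = 0.100
    lambda_tau_elig: float = 0.300
    w_bounds: tuple[float, float] = (0.0, 1.0)
    sigma_bar: float = 0.0
    cr_mask_s: float = 0.0
    #: overrides decoupling the two delays that normally share lambda_noi
    #: (used to study a non-delayed NOI or a non-delayed plasticity trace)
    elig_delay_s: float | None = None
    noi_delay_s: float | None = None

    def __post_init__(self) -> None:
        if self.theta_cr <= 0:
            raise ConfigurationError("theta_cr must be positive")
        if self.delta_p < 0 or self.delta_d < 0:
            raise ConfigurationError("plasticity steps must be non-negative")
        if not (self.w_bounds[0] <= self.w0 <= self.w_bounds[1]):
            raise ConfigurationError("w0 outside w_bounds")
        if not (0.0 <= self.sigma_bar <= 1.0):
            raise ConfigurationError("sigma_bar must lie in [0, 1]")
        if self.lambda_noi < 0 or self.lambda_tau_elig <= 0 or self.cr_mask_s < 0:
            raise ConfigurationError("invalid window parameter")
        for v in (self.elig_delay_s, self.noi_delay_s):
            if v is not None and v < 0:
                raise ConfigurationError("delays must be non-negative")

    @property
    def elig_delay(self) -> float:
        return self.lambda_noi if self.elig_delay_s is None else self.elig_delay_s

    @property
    def noi_delay(self) -> float:
        return self.lambda_noi if self.noi_delay_s is None else self.noi_delay_s

    def with_steps(self, delta_p: float, delta_d: float) -> "ModelParams":
        return replace(self, delta_p=delta_p, delta_d=delta_d)


@dataclass
class ModelState:
    """Evolving state: the memory weight plus the transient windows."""

    w: float
    active_trace_start: int | None = None
    cr_fired_for_trace: bool = False
    noi_windows: list[tuple[int, int]] = field(default_factory=list)
    elig_windows: list[tuple[int, int]] = field(default_factory=list)


@dataclass(frozen=True)
class CrEvent:
    trigger_step: int
    trial_index: int
    timing_class: str
    lead_time: float  # seconds between trigger and US trigger (signed, + = early)


def make_trace(params: TraceParams, grid: TimeGrid) -> np.ndarray:
    """Per-step trace values over ``[0, lambda_tau)`` (monotone non-increasing)."""
    n = int(np.ceil(params.lambda_tau / grid.dt - 1e-9))
    if n < 1:
        raise ConfigurationError("trace shorter than one grid step")
    return params.value(np.arange(n) * grid.dt)


def cr_trigger_time(w: float, params: ModelParams) -> float | None:
    """CR trigger delay after a PN detection, or None if no crossing.

    Returns the earliest ``t`` in ``[0, lambda_tau)`` at which the scaled
    trace ``w * trace(t)`` crosses below ``theta_cr`` (closed form for the
    linear shape).  No crossing -- i.e. ``w * tau1 >= theta_cr`` -- is a valid
    outcome, not an error: the model simply stays silent.
    """
    if w < 0:
        raise ConfigurationError("w must be non-negative")
    tr, theta = params.trace, params.theta_cr
    if w * tr.tau0 < theta:
        return 0.0
    if w * tr.tau1 >= theta:
        return None
    if tr.shape == "linear":
        return tr.lambda_tau * (tr.tau0 - theta / w) / (tr.tau0 - tr.tau1)
    rate = np.log(tr.tau0 / tr.tau1) / tr.lambda_tau
    return float(np.log(w * tr.tau0 / theta) / rate)


def anticipation_weight(lat: LatencyBudget, params: ModelParams) -> float:
    """Largest ``w`` whose CR is still anticipatory (trigger not after the US).

    The trigger must come within ``ISI - omega_cs`` of the PN detection; for
    the default trace with a 300-ms ISI and the measured 96.2-ms PN latency
    this evaluates to w = 0.28.
    """
    budget = lat.isi - lat.omega_cs
    tr, theta = params.trace, params.theta_cr
    if budget <= 0:
        raise UnlearnableISIError("no anticipation budget: ISI <= omega_cs")
    if budget >= tr.lambda_tau:
        return params.w_bounds[1]
    return theta / float(tr.value(budget))


def classify_cr(trigger_step: int, us_trigger_step: int, grid: TimeGrid) -> str:
    """Well timed iff the trigger leads the US trigger by >= 20 ms (inclusive)."""
    lead = (us_trigger_step - trigger_step) * grid.dt
    return WELL_TIMED if lead >= WELL_TIMED_LEAD_S - 1e-12 else LATE


@dataclass
class SessionLog:
    """Per-trial record of a simulated session.

    ``trials`` is a DataFrame with one row per trial: detection counts, the
    first CR of the trial (step, latency, timing class) and the weight at the
    trial boundaries.  ``w_final`` is the weight at the session end, and
    ``recalibrations`` (adaptive sessions only) lists
    ``(time_s, io_far_hz, delta_p, delta_d)`` tuples.
    """

    trials: pd.DataFrame
    cr_events: list[CrEvent]
    w_final: float
    params: ModelParams
    schedule: StimulusSchedule
    seed: int | None = None
    recalibrations: list[tuple[float, float, float, float]] = field(default_factory=list)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def w_trajectory(self) -> np.ndarray:
        """Weight at the end of each trial (piecewise constant between events)."""
        return self.trials["w_end"].to_numpy()

    def first_trial_where(self, mask: np.ndarray) -> int | None:
        idx = np.flatnonzero(np.asarray(mask))
        return int(self.trials.index[idx[0]]) if idx.size else None


def run_session(
    pn: EventTrain,
    io: EventTrain,
    schedule: StimulusSchedule,
    params: ModelParams,
    state0: ModelState | None = None,
    seed: int | None = None,
    delta_p_per_trial: np.ndarray | None = None,
    delta_d_per_trial: np.ndarray | None = None,
    engine: str = "auto",
) -> SessionLog:
    """Run a full conditioning session and return its :class:`SessionLog`.

    Step semantics, in order within each 2-ms step: (a) a PN detection
    restarts the CS trace and schedules a delayed eligibility window; (b) if a
    trace is active, has not yet fired, and ``w*trace < theta_cr``, a CR is
    triggered and a delayed NOI window is scheduled (at most one CR per
    trace); (c) IO detections inside any NOI (or artifact-mask) window are
    discarded; (d) potentiation ``+delta_p`` for an eligible step and
    depression ``-delta_d`` per surviving coincident IO detection are summed
    and then ``w`` is clipped to ``w_bounds``.

    ``delta_*_per_trial`` override the constant steps (used by the adaptive
    recalibration); ``engine`` is ``"auto"`` (numba when available) or
    ``"python"``.
    """
    if pn.grid.dt != io.grid.dt or pn.grid.dt != schedule.grid.dt:
        raise InputError("event trains and schedule must share one grid")
    n_trials = len(schedule)
    dp = np.full(n_trials, params.delta_p) if delta_p_per_trial is None else np.asarray(delta_p_per_trial, float)
    dd = np.full(n_trials, params.delta_d) if delta_d_per_trial is None else np.asarray(delta_d_per_trial, float)
    if dp.shape != (n_trials,) or dd.shape != (n_trials,):
        raise InputError("per-trial step arrays must have one entry per trial")

    grid = schedule.grid
    trace = make_trace(params.trace, grid)
    w0 = params.w0 if state0 is None else state0.w
    res = run_engine(
        pn_steps=pn.steps,
        io_steps=io.steps,
        trial_starts=schedule.trial_starts,
        trace=trace,
        theta=params.theta_cr,
        w0=w0,
        w_lo=params.w_bounds[0],
        w_hi=params.w_bounds[1],
        dp=dp,
        dd=dd,
        elig_delay=grid.to_steps(params.elig_delay),
        elig_len=grid.to_steps(params.lambda_tau_elig),
        noi_delay=grid.to_steps(params.noi_delay),
        noi_len=grid.to_steps(params.lambda_tau_elig),
        mask_len=grid.to_steps(params.cr_mask_s),
        horizon=grid.horizon,
        use_numba=(engine != "python"),
    )

    us_steps = schedule.us_steps
    cr_events: list[CrEvent] = []
    first_cr = np.full(n_trials, -1, dtype=np.int64)
    for step, tr_idx in zip(res.cr_steps, res.cr_trials):
        lead = (us_steps[tr_idx] - step) * grid.dt
        cr_events.append(CrEvent(int(step), int(tr_idx), classify_cr(step, us_steps[tr_idx], grid), float(lead)))
        if first_cr[tr_idx] < 0:
            first_cr[tr_idx] = step

    cs_steps = schedule.cs_steps
    trials = pd.DataFrame(
        {
            "condition": [t.condition for t in schedule.trials],
            "cs_step": cs_steps,
            "us_step": us_steps,
            "n_pn": res.n_pn,
            "n_io": res.n_io,
            "n_io_gated": res.n_gated,
            "n_pot_steps": res.n_pot,
            "n_dep_events": res.n_dep,
            "cr_step": first_cr,
            "cr_time_s": np.where(first_cr >= 0, (first_cr - cs_steps) * grid.dt, np.nan),
            "lead_s": np.where(first_cr >= 0, (us_steps - first_cr) * grid.dt, np.nan),
            "timing_class": [
                classify_cr(s, u, grid) if s >= 0 else ""
                for s, u in zip(first_cr, us_steps)
            ],
            "w_start": res.w_trial_start,
            "w_end": res.w_trial_end,
            "delta_p": dp,
            "delta_d": dd,
        }
    )
    return SessionLog(trials, cr_events, float(res.w_final), params, schedule, seed)
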