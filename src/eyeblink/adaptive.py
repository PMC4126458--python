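"""Adaptive recalibration under a non-stationary IO baseline.

The static calibration assumes a stationary spontaneous IO rate; in vivo that
rate drifts (0.5-2 Hz band), which turns into a systematic, non-associative
drift of the memory weight.  The fix is periodic recalibration: every
``recalibration_period`` seconds (150 s, roughly 10 trials) the spontaneous
rate is re-estimated from the raw IO detection count -- the system is blind
to whether detections are spontaneous or evoked, so paired stimulation
slightly over-estimates it -- and only the stability row's depression count
``D3 = kappa * IO_far`` is updated before re-solving; the acquisition and
extinction rows carry no dependence on the IO rate.

Because only ``D3`` moves, the weighted-normal-equation solution is a ratio
of polynomials in ``IO_far`` whose coefficients depend on the training data
alone: ``delta_p`` is degree 2 over degree 2 and ``delta_d`` degree 1 over
the same degree-2 denominator.  Evaluating that rational form is the cheap,
fixed-cost update suitable for a low-power implementation; it agrees with
the direct re-solve to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calibration import (
    CalibrationConstraints,
    CalibrationResult,
    ConditionSummary,
    STABILITY,
    solve_plasticity,
)
from .exceptions import ConfigurationError, DegenerateCalibrationError, InputError
from .grid import EventTrain
from .model import ModelParams, ModelState, SessionLog, run_session
from .protocol import StimulusSchedule

__all__ = [
    "AdaptiveState",
    "RationalCoefficients",
    "estimate_io_far",
    "recalibrate_direct",
    "derive_rational_coefficients",
    "run_adaptive_session",
]


@dataclass
class AdaptiveState:
    """Frozen training summaries plus the evolving operating state.

    ``kappa`` is the mean eligible time per trial (s) fixed at calibration:
    the PN-rate dependence of the stability row is frozen at the training
    set's detections per trial, only the IO term is ever updated.
    """

    summaries: list[ConditionSummary]
    constraints: CalibrationConstraints
    kappa: float
    io_far: float
    delta_p: float
    delta_d: float
    recalibration_period: float = 150.0
    ewma_alpha: float | None = None  # optional smoothing of successive estimates
    history: list[tuple[float, float, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.recalibration_period <= 0:
            raise ConfigurationError("recalibration period must be positive")
        if self.kappa <= 0:
            raise ConfigurationError("kappa must be positive")
        if self.io_far < 0:
            raise ConfigurationError("io_far must be non-negative")

    @classmethod
    def from_calibration(
        cls, result: CalibrationResult, kappa: float, io_far: float, period_s: float = 150.0
    ) -> "AdaptiveState":
        return cls(
            summaries=list(result.summaries),
            constraints=result.constraints,
            kappa=kappa,
            io_far=io_far,
            delta_p=result.delta_p,
            delta_d=result.delta_d,
            recalibration_period=period_s,
        )


@dataclass(frozen=True)
class RationalCoefficients:
    """delta(io_far) = (a2 f^2 + a1 f + a0) / (b2 f^2 + b1 f + b0), per step."""

    alpha_p: np.ndarray  # numerator of delta_p, ascending powers (a0, a1, a2)
    alpha_d: np.ndarray
    beta: np.ndarray  # shared denominator, ascending powers
    valid_range: tuple[float, float] = (0.0, np.inf)

    def evaluate(self, io_far: float | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        f = np.asarray(io_far, dtype=float)
        den = self.beta[0] + self.beta[1] * f + self.beta[2] * f**2
        if np.any(den == 0):
            raise DegenerateCalibrationError("rational denominator vanishes on the requested rate")
        dp = (self.alpha_p[0] + self.alpha_p[1] * f + self.alpha_p[2] * f**2) / den
        dd = (self.alpha_d[0] + self.alpha_d[1] * f + self.alpha_d[2] * f**2) / den
        return np.maximum(dp, 0.0), np.maximum(dd, 0.0)


def estimate_io_far(io: EventTrain, window: tuple[float, float]) -> float:
    """Detections per second in the half-open time window (seconds).

    All detections count as spontaneous -- during paired stimulation this
    over-estimates the true baseline rate, an accepted bias that shrinks
    with longer inter-trial intervals.
    """
    t0, t1 = window
    if t1 <= t0:
        raise InputError("estimation window must have positive length")
    g = io.grid
    count = io.restricted(g.to_steps(t0), g.to_steps(t1)).size
    return count / (t1 - t0)


def _updated_summaries(state: AdaptiveState, io_far: float) -> list[ConditionSummary]:
    out = []
    for s in state.summaries:
        if s.condition_id == STABILITY:
            out.append(ConditionSummary(STABILITY, s.p_bar, state.kappa * io_far, s.n_trials))
        else:
            out.append(s)
    return out


def recalibrate_direct(state: AdaptiveState, io_far: float) -> tuple[float, float]:
    """Re-solve the WLS system with ``D3`` replaced by ``kappa * io_far``.

    At the initial rate estimate this is an exact fixed point of the original
    calibration.
    """
    if io_far < 0:
        raise ConfigurationError("io_far must be non-negative")
    result = solve_plasticity(_updated_summaries(state, io_far), state.constraints)
    return result.delta_p, result.delta_d


def derive_rational_coefficients(state: AdaptiveState) -> RationalCoefficients:
    """Closed-form coefficients of the recalibration as polynomials in IO_far.

    Writing the weighted normal equations ``M x = c`` with
    ``M12 = m0 + m1 f`` and ``M22 = q0 + q2 f^2`` (``f`` = IO_far, the only
    moving quantity, entering through ``D3 = kappa f``), Cramer's rule gives

        delta_p = (M22 c1 - M12 c2) / det(M),
        delta_d = (M11 c2 - M12 c1) / det(M),

    all polynomials of degree <= 2 in ``f`` whose coefficients are fixed by
    the training data.  The derivation is verified against
    :func:`recalibrate_direct` on a rate grid in the tests.
    """
    base = {s.condition_id: s for s in state.summaries}
    if len(base) != 3:
        raise DegenerateCalibrationError("need the three condition summaries")
    P = np.array([base[c].p_bar for c in ("acquisition", "extinction", "stability")])
    D = np.array([base[c].d_bar for c in ("acquisition", "extinction", "stability")])
    W = state.constraints.weights
    b = state.constraints.targets
    k = state.kappa

    m11 = float(np.sum(W * P**2))
    # M12 = -(w1 P1 D1 + w2 P2 D2) - w3 P3 k f
    m0 = -(W[0] * P[0] * D[0] + W[1] * P[1] * D[1])
    m1 = -W[2] * P[2] * k
    # M22 = (w1 D1^2 + w2 D2^2) + w3 k^2 f^2
    q0 = W[0] * D[0] ** 2 + W[1] * D[1] ** 2
    q2 = W[2] * k**2
    c1 = float(np.sum(W * P * b))
    c2 = -(W[0] * D[0] * b[0] + W[1] * D[1] * b[1])  # b3 = 0 keeps this constant

    beta = np.array([m11 * q0 - m0**2, -2.0 * m0 * m1, m11 * q2 - m1**2])
    alpha_p = np.array([q0 * c1 - m0 * c2, -m1 * c2, q2 * c1])
    alpha_d = np.array([m11 * c2 - m0 * c1, -m1 * c1, 0.0])
    if abs(beta[0]) < 1e-300 and abs(beta[2]) < 1e-300:
        raise DegenerateCalibrationError("degenerate summaries: denominator identically zero")
    return RationalCoefficients(alpha_p, alpha_d, beta)


def run_adaptive_session(
    pn: EventTrain,
    io: EventTrain,
    schedule: StimulusSchedule,
    params: ModelParams,
    adaptive: AdaptiveState,
    state0: ModelState | None = None,
    seed: int | None = None,
    engine: str = "auto",
) -> SessionLog:
    """Run a session with periodic recalibration of the plasticity steps.

    Every ``recalibration_period`` seconds the IO detection count of the
    elapsed window yields a rate estimate, the rational form is evaluated at
    it, and the new steps take effect at the first trial starting after the
    boundary (steps never change mid-trial).  The estimates depend only on
    the input train, so the whole per-trial step schedule is precomputed and
    the session runs in a single engine pass.  Recalibrations are logged as
    ``(time_s, io_far_hz, delta_p, delta_d)``.
    """
    coeffs = derive_rational_coefficients(adaptive)
    grid = schedule.grid
    period = adaptive.recalibration_period
    n_bounds = int(np.floor(grid.duration / period))
    dp = np.full(len(schedule), adaptive.delta_p)
    dd = np.full(len(schedule), adaptive.delta_d)
    trial_start_s = schedule.trial_starts[:-1] * grid.dt
    history: list[tuple[float, float, float, float]] = []
    f_smooth = adaptive.io_far
    for k in range(1, n_bounds + 1):
        t1 = k * period
        f_hat = estimate_io_far(io, (t1 - period, t1))
        if adaptive.ewma_alpha is not None:
            f_smooth = adaptive.ewma_alpha * f_hat + (1 - adaptive.ewma_alpha) * f_smooth
            f_hat = f_smooth
        new_p, new_d = (float(v) for v in coeffs.evaluate(f_hat))
        affected = trial_start_s >= t1
        dp[affected] = new_p
        dd[affected] = new_d
        history.append((t1, f_hat, new_p, new_d))
    log = run_session(
        pn, io, schedule, params, state0=state0, seed=seed,
        delta_p_per_trial=dp, delta_d_per_trial=dd, engine=engine,
    )
    log.recalibrations = history
    adaptive.history = history
    if history:
        adaptive.io_far = history[-1][1]
        adaptive.delta_p, adaptive.delta_d = history[-1][2], history[-1][3]
    return log
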