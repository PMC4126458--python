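"""Plasticity-step calibration.

The learning dynamics are governed by two linear steps: a potentiation
``delta_p`` applied at every eligible time step and a depression ``delta_d``
applied per IO detection coinciding with the eligibility trace.  Calibration
counts the expected plasticity events per trial in three experimental
conditions (acquisition, extinction, stability) and solves the weighted
least-squares system

    [ P1  -D1 ] [delta_p]   [ -Delta_a / T_a ]
    [ P2  -D2 ] [delta_d] = [ +Delta_e / T_e ]
    [ P3  -D3 ]             [        0       ]

with the stability row weighted dominant: zero mean drift of ``w`` under
spontaneous IO activity is what guarantees that paired stimulation yields
acquisition and CS-alone stimulation yields extinction; the first two rows
then set the learning rates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._engine import merge_intervals
from .exceptions import ConfigurationError, DegenerateCalibrationError, InputError
from .grid import EventTrain, TimeGrid
from .model import ModelParams
from .protocol import StimulusSchedule

__all__ = [
    "EligibilityVector",
    "PlasticityCounts",
    "ConditionSummary",
    "CalibrationConstraints",
    "CalibrationResult",
    "ACQUISITION",
    "EXTINCTION",
    "STABILITY",
    "eligibility_vector",
    "count_plasticity",
    "summarize_condition",
    "condition_summaries_from_training",
    "solve_plasticity",
    "select_operating_point",
]

ACQUISITION = "acquisition"
EXTINCTION = "extinction"
STABILITY = "stability"


@dataclass
class EligibilityVector:
    """Binary per-step indicator: 1 from ``lambda_noi`` after each PN
    detection for ``lambda_tau_elig`` seconds (overlaps unioned, values
    clipped to {0, 1})."""

    starts: np.ndarray  # merged half-open interval starts (steps)
    ends: np.ndarray
    grid: TimeGrid
    lambda_noi: float
    lambda_tau_elig: float

    @property
    def total_steps(self) -> int:
        return int(np.sum(self.ends - self.starts))

    def contains(self, steps: np.ndarray) -> np.ndarray:
        """Boolean mask: is each step eligible?"""
        steps = np.asarray(steps, dtype=np.int64)
        idx = np.searchsorted(self.ends, steps, side="right")
        ok = idx < self.starts.size
        out = np.zeros(steps.shape, dtype=bool)
        out[ok] = self.starts[idx[ok]] <= steps[ok]
        return out

    def to_binary(self) -> np.ndarray:
        vec = np.zeros(self.grid.horizon, dtype=np.int8)
        for a, b in zip(self.starts, self.ends):
            vec[a:b] = 1
        return vec

    def steps_in(self, lo: int, hi: int) -> int:
        """Number of eligible steps inside the half-open window [lo, hi)."""
        a = np.clip(self.starts, lo, hi)
        b = np.clip(self.ends, lo, hi)
        return int(np.sum(b - a))


@dataclass(frozen=True)
class PlasticityCounts:
    potentiation: int  # P = sum(Pi), eligible steps
    depression: float  # D = sigma_bar * Pi^T I
    sigma_bar: float


@dataclass(frozen=True)
class ConditionSummary:
    """Mean plasticity events per trial for one experimental condition."""

    condition_id: str
    p_bar: float
    d_bar: float
    n_trials: int


@dataclass(frozen=True)
class CalibrationConstraints:
    """Learning-rate targets: a weight change of ``delta_a`` over ``t_a``
    paired trials (acquisition), ``delta_e`` over ``t_e`` CS-alone trials
    (extinction), and a dominant zero-drift stability row."""

    delta_a: float = 0.2
    t_a: float = 40.0
    delta_e: float = 0.2
    t_e: float = 40.0
    stability_weight: float = 100.0

    def __post_init__(self) -> None:
        if min(self.delta_a, self.t_a, self.delta_e, self.t_e) <= 0:
            raise ConfigurationError("constraint targets must be positive")
        if self.stability_weight < 1:
            raise ConfigurationError("stability weight must be >= 1")

    @property
    def targets(self) -> np.ndarray:
        return np.array([-self.delta_a / self.t_a, self.delta_e / self.t_e, 0.0])

    @property
    def weights(self) -> np.ndarray:
        return np.array([1.0, 1.0, self.stability_weight])


@dataclass
class CalibrationResult:
    delta_p: float
    delta_d: float
    residuals: np.ndarray  # per-row achieved - target
    summaries: list[ConditionSummary]
    constraints: CalibrationConstraints
    clamped: bool = False
    operating_point: dict | None = None

    @property
    def magnitudes(self) -> tuple[float, float]:
        """(larger, smaller) of the two solved step magnitudes."""
        hi, lo = sorted((abs(self.delta_p), abs(self.delta_d)), reverse=True)
        return hi, lo


def eligibility_vector(
    pn: EventTrain, lambda_noi: float, lambda_tau_elig: float, grid: TimeGrid | None = None
) -> EligibilityVector:
    """Convolve the PN train with the delayed rectangular eligibility pulse.

    The result is binary: overlapping pulses from rapid PN detections union
    rather than add.
    """
    grid = grid or pn.grid
    if lambda_tau_elig <= 0 or lambda_noi < 0:
        raise ConfigurationError("eligibility parameters must be positive")
    d = grid.to_steps(lambda_noi)
    L = grid.to_steps(lambda_tau_elig)
    starts = pn.steps + d
    ends = np.minimum(starts + L, grid.horizon) if grid.horizon else starts + L
    s, e = merge_intervals(np.minimum(starts, ends), ends)
    return EligibilityVector(s, e, grid, lambda_noi, lambda_tau_elig)


def count_plasticity(elig: EligibilityVector, io: EventTrain, sigma_bar: float = 1.0) -> PlasticityCounts:
    """P = number of eligible steps; D = sigma_bar x (IO detections on
    eligible steps).  ``sigma_bar`` is the mean proportion of IO events not
    suppressed by the NOI: pass 1 for conditions without CRs."""
    if not (0.0 <= sigma_bar <= 1.0):
        raise ConfigurationError("sigma_bar must lie in [0, 1]")
    if elig.grid.dt != io.grid.dt:
        raise InputError("eligibility vector and IO train must share a grid")
    coincidences = int(np.count_nonzero(elig.contains(io.steps)))
    return PlasticityCounts(elig.total_steps, sigma_bar * coincidences, sigma_bar)


def summarize_condition(
    pn: EventTrain,
    io: EventTrain,
    schedule: StimulusSchedule,
    condition_id: str,
    params: ModelParams,
) -> ConditionSummary:
    """Per-trial mean plasticity counts for one condition's event trains.

    ``sigma_bar`` from ``params`` is applied only to the extinction condition
    (the one with CRs); acquisition and stability trains carry no CRs during
    estimation, so every coincidence counts.
    """
    n = len(schedule)
    if n == 0:
        raise InputError("condition must contain at least one trial")
    elig = eligibility_vector(pn, params.elig_delay, params.lambda_tau_elig, schedule.grid)
    sigma = params.sigma_bar if condition_id == EXTINCTION else 1.0
    counts = count_plasticity(elig, io, sigma)
    return ConditionSummary(condition_id, counts.potentiation / n, counts.depression / n, n)


@dataclass
class TrainingData:
    """A calibration training set: paired trials plus a spontaneous segment."""

    pn: EventTrain
    io: EventTrain
    schedule: StimulusSchedule
    io_spont: EventTrain
    spont_duration_s: float

    @property
    def spont_rate_hz(self) -> float:
        return len(self.io_spont) / self.spont_duration_s


def condition_summaries_from_training(
    data: TrainingData, params: ModelParams
) -> tuple[list[ConditionSummary], float]:
    """Build the three condition summaries from a single training set.

    Acquisition uses the paired trials directly.  The CS-alone conditions are
    synthesized by combining the paired-trial PN data with IO data from the
    spontaneous period (so the calibration phase need not be extended): the
    spontaneous depression count per trial is the rate estimate times the
    mean eligible time per trial, ``D3 = far_hat * kappa`` with
    ``kappa = P_bar * dt`` -- exactly the dependence the adaptive
    recalibration later updates.  Returns the summaries and ``kappa``.
    """
    n = len(data.schedule)
    acq = summarize_condition(data.pn, data.io, data.schedule, ACQUISITION, params)
    kappa = acq.p_bar * data.schedule.grid.dt
    d_spont = data.spont_rate_hz * kappa
    ext = ConditionSummary(EXTINCTION, acq.p_bar, params.sigma_bar * d_spont, n)
    stab = ConditionSummary(STABILITY, acq.p_bar, d_spont, n)
    return [acq, ext, stab], kappa


def estimate_sigma_bar(params: ModelParams, target_w: float = 0.3) -> float:
    """Empirical estimate of the unsuppressed IO fraction during CR trials.

    The NOI window is anchored to the CR trigger while the eligibility window
    is anchored to the CS, so early CRs gate more of the eligibility window
    than late ones.  Given the mean trigger delay expected at the acquired
    weight level ``target_w``, the unsuppressed fraction is the part of the
    eligibility window the NOI never covers,
    ``(t_trig + noi_delay - elig_delay) / lambda_tau_elig`` clipped to
    [0, 1]; with no crossing at ``target_w`` there are no CRs and nothing is
    suppressed (returns 1).
    """
    from .model import cr_trigger_time

    t_trig = cr_trigger_time(target_w, params)
    if t_trig is None:
        return 1.0
    frac = (t_trig + params.noi_delay - params.elig_delay) / params.lambda_tau_elig
    return float(np.clip(frac, 0.0, 1.0))


def solve_plasticity(
    summaries: list[ConditionSummary], constraints: CalibrationConstraints
) -> CalibrationResult:
    """Weighted least squares for (delta_p, delta_d).

    Solves the weighted normal equations of the 3x2 system exactly; a
    rank-deficient system (e.g. every depression count zero) raises
    :class:`DegenerateCalibrationError`.  A negative solution is clamped at
    zero and flagged, keeping the closed form used by the adaptive module
    exact for the un-clamped case.
    """
    if len(summaries) != 3:
        raise InputError("need exactly one summary per condition")
    A = np.array([[s.p_bar, -s.d_bar] for s in summaries])
    b = constraints.targets
    W = constraints.weights
    M = (A * W[:, None]).T @ A
    if np.linalg.matrix_rank(M, tol=1e-12 * max(1.0, float(np.abs(M).max()))) < 2:
        raise DegenerateCalibrationError("calibration system is rank deficient")
    x = np.linalg.solve(M, (A * W[:, None]).T @ b)
    clamped = bool(np.any(x < 0))
    x = np.maximum(x, 0.0)
    residuals = A @ x - b
    return CalibrationResult(float(x[0]), float(x[1]), residuals, list(summaries), constraints, clamped)


def calibrate_training(
    data: TrainingData, params: ModelParams, constraints: CalibrationConstraints
) -> tuple[CalibrationResult, float]:
    """Convenience: summaries from a training set, then the WLS solve.

    Returns the result and ``kappa`` (eligible seconds per trial), which the
    adaptive module needs to re-express the stability row at a new IO rate.
    """
    summaries, kappa = condition_summaries_from_training(data, params)
    return solve_plasticity(summaries, constraints), kappa


def select_operating_point(
    pn_candidates: list[tuple[float, TrainingData]],
    io_candidates: list[tuple[float, TrainingData]] | None,
    params: ModelParams,
    constraints: CalibrationConstraints,
) -> tuple[CalibrationResult, pd.DataFrame]:
    """Pick detection thresholds by minimizing the calibration residual.

    Each candidate pairs a threshold with the training data it produces.
    When ``io_candidates`` is given, PN candidates supply the PN train and IO
    candidates the IO trains, and the full grid is searched; otherwise each
    PN candidate is a complete training set.  For every configuration the
    summaries are rebuilt and the system re-solved; the configuration with
    the minimum weighted residual norm wins, ties broken toward the lower
    spontaneous IO rate (then lower PN threshold).  Returns the winning
    result (with ``operating_point`` filled in) and the residual surface.
    """
    if not pn_candidates or (io_candidates is not None and not io_candidates):
        raise InputError("empty threshold grid")
    rows = []
    best = None
    for thr_pn, pn_data in pn_candidates:
        io_iter = io_candidates if io_candidates is not None else [(thr_pn, pn_data)]
        for thr_io, io_data in io_iter:
            data = TrainingData(
                pn_data.pn, io_data.io, pn_data.schedule, io_data.io_spont, io_data.spont_duration_s
            )
            try:
                result, _ = calibrate_training(data, params, constraints)
            except DegenerateCalibrationError:
                continue
            err = float(np.sqrt(np.sum(constraints.weights * result.residuals**2)))
            far = data.spont_rate_hz
            rows.append({"thr_pn": thr_pn, "thr_io": thr_io, "residual": err, "io_far_hz": far})
            key = (err, far, thr_pn)
            if best is None or key < best[0]:
                result.operating_point = rows[-1]
                best = (key, result)
    if best is None:
        raise DegenerateCalibrationError("no threshold configuration yielded a solvable system")
    return best[1], pd.DataFrame(rows)
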