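"""Shared fixtures and the independent dense brute-force session oracle."""

from __future__ import annotations

import numpy as np
import pytest

from eyeblink.grid import EventTrain, TimeGrid
from eyeblink.model import ModelParams, TraceParams, make_trace
from eyeblink.protocol import StimulusSchedule, Trial


@pytest.fixture
def grid():
    return TimeGrid(0.002, 5000)


@pytest.fixture
def default_params():
    """Package defaults: tau0=1, tau1=0.5, 350-ms trace, theta=0.2, w0=0.5."""
    return ModelParams()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def single_trial_schedule(grid: TimeGrid, cs_step: int = 100, isi_s: float = 0.3, paired: bool = True):
    us = cs_step + grid.to_steps(isi_s) if paired else None
    return StimulusSchedule([Trial(cs_step, us, "paired" if paired else "cs_alone")], grid, isi_s)


def brute_force_session(pn_steps, io_steps, params: ModelParams, grid: TimeGrid, w0=None):
    """Dense reference simulation over every grid step.

    Implements the step semantics directly on full binary vectors and
    explicit window sets, independently of the interval-skipping engine:
    (a) PN restarts the trace, (b) strict threshold crossing of the scaled
    trace triggers one CR per trace and schedules a delayed NOI window,
    (c) gated IO detections are discarded, (d) potentiation per eligible
    step and depression per surviving coincidence are summed then clipped.
    Returns (w_final, n_pot, n_dep, cr_steps).
    """
    horizon = grid.horizon
    pn = np.zeros(horizon, dtype=bool)
    pn[np.asarray(pn_steps, dtype=int)] = True
    io = np.zeros(horizon, dtype=bool)
    io[np.asarray(io_steps, dtype=int)] = True

    d_elig = grid.to_steps(params.elig_delay)
    n_elig = grid.to_steps(params.lambda_tau_elig)
    d_noi = grid.to_steps(params.noi_delay)
    n_noi = grid.to_steps(params.lambda_tau_elig)
    n_mask = grid.to_steps(params.cr_mask_s)

    elig = np.zeros(horizon, dtype=bool)
    for p in np.flatnonzero(pn):
        elig[p + d_elig : p + d_elig + n_elig] = True

    trace = make_trace(params.trace, grid)
    w = params.w0 if w0 is None else w0
    lo, hi = params.w_bounds
    trace_start = None
    fired = True
    noi = np.zeros(horizon + d_noi + n_noi + n_mask + 1, dtype=bool)
    n_pot = 0
    n_dep = 0
    cr_steps = []
    for t in range(horizon):
        if pn[t]:
            trace_start = t
            fired = False
        if trace_start is not None and not fired:
            k = t - trace_start
            if k < trace.size and w * trace[k] < params.theta_cr:
                cr_steps.append(t)
                fired = True
                noi[t + d_noi : t + d_noi + n_noi] = True
                if n_mask > 0:
                    noi[t : t + n_mask] = True
        dw = 0.0
        if elig[t]:
            dw += params.delta_p
            n_pot += 1
        if io[t] and not noi[t]:
            if elig[t]:
                dw -= params.delta_d
                n_dep += 1
        w = min(hi, max(lo, w + dw))
    return w, n_pot, n_dep, cr_steps


def random_small_session(rng, horizon=2000, n_trials_max=5):
    """A random small scenario for oracle-equivalence checks."""
    grid = TimeGrid(0.002, horizon)
    n_trials = int(rng.integers(1, n_trials_max + 1))
    cs = np.sort(rng.choice(np.arange(50, horizon - 400), size=n_trials, replace=False))
    cs = cs[np.concatenate([[True], np.diff(cs) > 300])]
    trials = [Trial(int(c), int(c + 150), "paired") for c in cs]
    schedule = StimulusSchedule(trials, grid, 0.3)
    pn = np.unique(rng.choice(horizon - 1, size=rng.integers(0, 8)))
    io = np.unique(rng.choice(horizon - 1, size=rng.integers(0, 20)))
    params = ModelParams(
        trace=TraceParams(1.0, 0.5, float(rng.uniform(0.1, 0.4))),
        theta_cr=0.2,
        w0=float(rng.uniform(0.1, 0.9)),
        delta_p=float(rng.uniform(0, 2e-3)),
        delta_d=float(rng.uniform(0, 0.05)),
        lambda_noi=float(rng.choice([0.0, 0.05, 0.1])),
        lambda_tau_elig=float(rng.uniform(0.1, 0.35)),
        cr_mask_s=float(rng.choice([0.0, 0.0, 0.5])),
    )
    return grid, schedule, EventTrain("PN", pn, grid), EventTrain("IO", io, grid), params
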