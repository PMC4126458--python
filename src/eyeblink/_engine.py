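"""Low-level session engine.

The per-step semantics are exact, but the engine only iterates through steps
where something can happen: the spans opened by PN detections (trace,
eligibility, CR checks) plus every IO event step.  An IO detection outside
any eligibility window cannot change ``w`` -- gating it or not only affects
bookkeeping -- so skipping the quiet stretches of the inter-trial intervals
is lossless.

The kernel is written in a numba-compilable subset and is wrapped with
``numba.njit`` when numba is importable; the plain-python version is kept
callable (``use_numba=False``) and the two are interchangeable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["run_engine", "EngineResult", "merge_intervals"]


def merge_intervals(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Union of half-open intervals, returned sorted and disjoint."""
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    keep = ends > starts
    starts, ends = starts[keep], ends[keep]
    if starts.size == 0:
        return starts, ends
    order = np.argsort(starts, kind="stable")
    s, e = starts[order], np.maximum.accumulate(ends[order])
    new_group = np.empty(s.size, dtype=bool)
    new_group[0] = True
    new_group[1:] = s[1:] > e[:-1]
    idx = np.flatnonzero(new_group)
    merged_s = s[idx]
    merged_e = e[np.append(idx[1:] - 1, s.size - 1)]
    return merged_s, merged_e


def _kernel(
    hot_s, hot_e, elig_s, elig_e, pn_steps, io_steps, trial_starts,
    trace, theta, w0, w_lo, w_hi, dp, dd, noi_delay, noi_len, mask_len, horizon,
):
    n_trials = trial_starts.shape[0] - 1
    n_trace = trace.shape[0]
    n_pn_total = pn_steps.shape[0]
    n_io_total = io_steps.shape[0]

    w = w0
    w_start = np.empty(n_trials, dtype=np.float64)
    w_end = np.empty(n_trials, dtype=np.float64)
    n_pot = np.zeros(n_trials, dtype=np.int64)
    n_dep = np.zeros(n_trials, dtype=np.int64)
    n_gated = np.zeros(n_trials, dtype=np.int64)
    cr_steps = np.empty(n_pn_total + 1, dtype=np.int64)
    cr_trials = np.empty(n_pn_total + 1, dtype=np.int64)
    n_cr = 0
    noi_ws = np.empty(n_pn_total + 1, dtype=np.int64)
    noi_we = np.empty(n_pn_total + 1, dtype=np.int64)
    n_noi = 0
    noi_ptr = 0
    noi_cover = np.int64(-1)
    mask_ws = np.empty(n_pn_total + 1, dtype=np.int64)
    n_mask = 0
    mask_ptr = 0
    mask_cover = np.int64(-1)

    trace_start = np.int64(-(1 << 40))
    fired = True
    pn_ptr = 0
    io_ptr = 0
    elig_ptr = 0
    n_elig = elig_s.shape[0]
    trial_ptr = 0
    w_start[0] = w

    for h in range(hot_s.shape[0] + 1):
        if h < hot_s.shape[0]:
            a = hot_s[h]
            b = hot_e[h]
        else:
            a = horizon
            b = horizon
        # IO events in the quiet stretch before this interval: gating bookkeeping only
        while io_ptr < n_io_total and io_steps[io_ptr] < a:
            t = io_steps[io_ptr]
            while trial_ptr < n_trials - 1 and t >= trial_starts[trial_ptr + 1]:
                w_end[trial_ptr] = w
                trial_ptr += 1
                w_start[trial_ptr] = w
            while noi_ptr < n_noi and noi_ws[noi_ptr] <= t:
                if noi_we[noi_ptr] > noi_cover:
                    noi_cover = noi_we[noi_ptr]
                noi_ptr += 1
            while mask_ptr < n_mask and mask_ws[mask_ptr] <= t:
                if mask_ws[mask_ptr] + mask_len > mask_cover:
                    mask_cover = mask_ws[mask_ptr] + mask_len
                mask_ptr += 1
            if t < noi_cover or t < mask_cover:
                n_gated[trial_ptr] += 1
            io_ptr += 1
        for t in range(a, b):
            while trial_ptr < n_trials - 1 and t >= trial_starts[trial_ptr + 1]:
                w_end[trial_ptr] = w
                trial_ptr += 1
                w_start[trial_ptr] = w
            # (a) PN detection restarts the trace and re-arms the CR
            if pn_ptr < n_pn_total and pn_steps[pn_ptr] == t:
                trace_start = t
                fired = False
                pn_ptr += 1
            while noi_ptr < n_noi and noi_ws[noi_ptr] <= t:
                if noi_we[noi_ptr] > noi_cover:
                    noi_cover = noi_we[noi_ptr]
                noi_ptr += 1
            # (b) threshold crossing of the scaled trace -> CR trigger + NOI window
            k = t - trace_start
            if (not fired) and k >= 0 and k < n_trace and w * trace[k] < theta:
                cr_steps[n_cr] = t
                cr_trials[n_cr] = trial_ptr
                n_cr += 1
                fired = True
                noi_ws[n_noi] = t + noi_delay
                noi_we[n_noi] = t + noi_delay + noi_len
                n_noi += 1
                if mask_len > 0:
                    mask_ws[n_mask] = t
                    n_mask += 1
            while mask_ptr < n_mask and mask_ws[mask_ptr] <= t:
                if mask_ws[mask_ptr] + mask_len > mask_cover:
                    mask_cover = mask_ws[mask_ptr] + mask_len
                mask_ptr += 1
            while elig_ptr < n_elig and elig_e[elig_ptr] <= t:
                elig_ptr += 1
            eligible = elig_ptr < n_elig and elig_s[elig_ptr] <= t
            # (c) gating, (d) net plasticity then clip
            dw = 0.0
            if eligible:
                dw += dp[trial_ptr]
                n_pot[trial_ptr] += 1
            if io_ptr < n_io_total and io_steps[io_ptr] == t:
                io_ptr += 1
                if t < noi_cover or t < mask_cover:
                    n_gated[trial_ptr] += 1
                elif eligible:
                    dw -= dd[trial_ptr]
                    n_dep[trial_ptr] += 1
            if dw != 0.0:
                w += dw
                if w > w_hi:
                    w = w_hi
                if w < w_lo:
                    w = w_lo
    while trial_ptr < n_trials - 1:
        w_end[trial_ptr] = w
        trial_ptr += 1
        w_start[trial_ptr] = w
    w_end[n_trials - 1] = w
    return (
        w, w_start, w_end, n_pot, n_dep, n_gated,
        cr_steps[:n_cr].copy(), cr_trials[:n_cr].copy(),
    )


try:  # optional acceleration; the python kernel is the reference
    from numba import njit as _njit

    _kernel_numba = _njit(cache=False)(_kernel)
except Exception:  # pragma: no cover - numba simply absent
    _kernel_numba = None


@dataclass
class EngineResult:
    w_final: float
    w_trial_start: np.ndarray
    w_trial_end: np.ndarray
    n_pot: np.ndarray
    n_dep: np.ndarray
    n_gated: np.ndarray
    n_pn: np.ndarray
    n_io: np.ndarray
    cr_steps: np.ndarray
    cr_trials: np.ndarray


def run_engine(
    pn_steps: np.ndarray,
    io_steps: np.ndarray,
    trial_starts: np.ndarray,
    trace: np.ndarray,
    theta: float,
    w0: float,
    w_lo: float,
    w_hi: float,
    dp: np.ndarray,
    dd: np.ndarray,
    elig_delay: int,
    elig_len: int,
    noi_delay: int,
    noi_len: int,
    mask_len: int,
    horizon: int,
    use_numba: bool = True,
) -> EngineResult:
    pn_steps = np.asarray(pn_steps, dtype=np.int64)
    io_steps = np.asarray(io_steps, dtype=np.int64)
    trial_starts = np.asarray(trial_starts, dtype=np.int64)

    elig_start = pn_steps + elig_delay
    elig_end = elig_start + elig_len
    if elig_end.size and elig_end.max(initial=0) > horizon:
        warnings.warn("eligibility window truncated at the session horizon", stacklevel=2)
    elig_s, elig_e = merge_intervals(np.minimum(elig_start, horizon), np.minimum(elig_end, horizon))

    span = max(trace.shape[0], elig_delay + elig_len)
    hot_s, hot_e = merge_intervals(pn_steps, np.minimum(pn_steps + span, horizon))

    kern = _kernel_numba if (use_numba and _kernel_numba is not None) else _kernel
    (w, w_start, w_end, n_pot, n_dep, n_gated, cr_steps, cr_trials) = kern(
        hot_s, hot_e, elig_s, elig_e, pn_steps, io_steps, trial_starts,
        np.asarray(trace, dtype=np.float64), float(theta), float(w0),
        float(w_lo), float(w_hi),
        np.asarray(dp, dtype=np.float64), np.asarray(dd, dtype=np.float64),
        int(noi_delay), int(noi_len), int(mask_len), int(horizon),
    )
    n_pn = np.diff(np.searchsorted(pn_steps, trial_starts)).astype(np.int64)
    n_io = np.diff(np.searchsorted(io_steps, trial_starts)).astype(np.int64)
    # events beyond the last boundary belong to the last trial
    n_pn[-1] += pn_steps.size - np.searchsorted(pn_steps, trial_starts[-1])
    n_io[-1] += io_steps.size - np.searchsorted(io_steps, trial_starts[-1])
    return EngineResult(float(w), w_start, w_end, n_pot, n_dep, n_gated, n_pn, n_io, cr_steps, cr_trials)
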