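"""Calibration: eligibility counting, condition summaries, the WLS solve."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eyeblink.calibration import (
    ACQUISITION,
    EXTINCTION,
    STABILITY,
    CalibrationConstraints,
    ConditionSummary,
    count_plasticity,
    eligibility_vector,
    estimate_sigma_bar,
    select_operating_point,
    solve_plasticity,
    summarize_condition,
)
from eyeblink.exceptions import ConfigurationError, DegenerateCalibrationError, InputError
from eyeblink.experiments import bio_hybrid_stats, make_training_set
from eyeblink.grid import EventTrain, TimeGrid
from eyeblink.model import ModelParams
from eyeblink.calibration import calibrate_training


def dense_eligibility(pn_steps, d, L, horizon):
    """Brute-force convolution with the rectangular pulse, clipped to {0, 1}."""
    v = np.zeros(horizon, dtype=int)
    for p in pn_steps:
        v[p + d : p + d + L] += 1
    return np.clip(v, 0, 1)


class TestEligibility:
    def test_single_detection_block(self):
        grid = TimeGrid(0.002, 1000)
        pn = EventTrain("PN", [100], grid)
        ev = eligibility_vector(pn, 0.1, 0.3, grid)
        vec = ev.to_binary()
        assert vec.sum() == 150
        assert vec[150] == 1 and vec[149] == 0 and vec[299] == 1 and vec[300] == 0

    def test_empty_train(self):
        grid = TimeGrid(0.002, 500)
        ev = eligibility_vector(EventTrain("PN", [], grid), 0.1, 0.3, grid)
        assert ev.total_steps == 0

    def test_overlap_unioned_binary(self):
        grid = TimeGrid(0.002, 1000)
        pn = EventTrain("PN", [100, 150], grid)  # 100 ms apart
        ev = eligibility_vector(pn, 0.1, 0.3, grid)
        ref = dense_eligibility([100, 150], 50, 150, 1000)
        assert np.array_equal(ev.to_binary(), ref)
        assert ev.total_steps == ref.sum() == 200

    @given(st.lists(st.integers(0, 900), max_size=8), st.integers(10, 120), st.integers(0, 60))
    @settings(max_examples=50, deadline=None)
    def test_matches_dense_convolution(self, steps, length, delay):
        grid = TimeGrid(0.002, 1200)
        pn = EventTrain("PN", steps, grid)
        ev = eligibility_vector(pn, delay * 0.002, length * 0.002, grid)
        ref = dense_eligibility(sorted(set(steps)), delay, length, 1200)
        assert np.array_equal(ev.to_binary(), ref)


class TestCounts:
    def test_direct_count(self):
        grid = TimeGrid(0.002, 1000)
        ev = eligibility_vector(EventTrain("PN", [100], grid), 0.1, 0.3, grid)
        io = EventTrain("IO", [200], grid)
        counts = count_plasticity(ev, io, 1.0)
        assert counts.potentiation == 150 and counts.depression == 1.0

    def test_sigma_bar_scaling(self):
        grid = TimeGrid(0.002, 1000)
        ev = eligibility_vector(EventTrain("PN", [100], grid), 0.1, 0.3, grid)
        io = EventTrain("IO", [160, 200, 240, 280], grid)
        assert count_plasticity(ev, io, 0.5).depression == 2.0

    def test_sigma_bar_domain(self):
        grid = TimeGrid(0.002, 100)
        ev = eligibility_vector(EventTrain("PN", [], grid), 0.1, 0.1, grid)
        with pytest.raises(ConfigurationError):
            count_plasticity(ev, EventTrain("IO", [], grid), 1.5)

    @given(st.lists(st.integers(0, 999), max_size=10), st.lists(st.integers(0, 999), max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_exhaustive_per_step_oracle(self, pn_steps, io_steps):
        grid = TimeGrid(0.002, 1000)
        ev = eligibility_vector(EventTrain("PN", pn_steps, grid), 0.05, 0.2, grid)
        io = EventTrain("IO", io_steps, grid)
        counts = count_plasticity(ev, io, 1.0)
        pi = dense_eligibility(sorted(set(pn_steps)), 25, 100, 1000)
        i_vec = np.zeros(1000, dtype=int)
        i_vec[list(set(io_steps))] = 1
        assert counts.potentiation == pi.sum()
        assert counts.depression == pi @ i_vec


class TestSummaries:
    def test_stability_expectation(self, rng):
        """30 paired trials, IO FAR 1.14 Hz, 0.3-s eligibility, ~1 PN/trial
        gives ~0.31 spontaneous coincidences per trial in expectation."""
        pn_stats, io_stats = bio_hybrid_stats(training=True)
        d3 = []
        for k in range(40):
            data = make_training_set(np.random.default_rng(k), pn_stats, io_stats)
            from eyeblink.calibration import condition_summaries_from_training

            summaries, kappa = condition_summaries_from_training(data, ModelParams())
            d3.append(summaries[2].d_bar)
        # expectation: 1.14 Hz x 0.3 s x 0.914 detected trials = 0.3126
        assert np.mean(d3) == pytest.approx(1.14 * 0.3 * 0.914, rel=0.08)

    def test_zero_io_gives_zero_depression(self, grid):
        from eyeblink.protocol import StimulusSchedule, Trial

        sch = StimulusSchedule([Trial(100, 250, "paired")], grid, 0.3)
        s = summarize_condition(
            EventTrain("PN", [150], grid), EventTrain("IO", [], grid), sch, STABILITY, ModelParams()
        )
        assert s.d_bar == 0.0 and s.p_bar == 150

    def test_zero_trials_rejected(self, grid):
        from eyeblink.protocol import StimulusSchedule

        with pytest.raises(Exception):
            sch = StimulusSchedule([], grid, 0.3)
            summarize_condition(
                EventTrain("PN", [], grid), EventTrain("IO", [], grid), sch, STABILITY, ModelParams()
            )


def grid_search_oracle(summaries, constraints, lo=0.0, hi=None, n=400):
    """Dense 2-D minimization of the weighted objective."""
    A = np.array([[s.p_bar, -s.d_bar] for s in summaries])
    b = constraints.targets
    W = constraints.weights
    if hi is None:
        hi = (abs(b).max() + 0.01) / max(A[:, 0].max(), 1e-9), 2.0
    dps = np.linspace(lo, hi[0], n)
    dds = np.linspace(lo, hi[1], n)
    DP, DD = np.meshgrid(dps, dds, indexing="ij")
    obj = np.zeros_like(DP)
    for i in range(3):
        obj += W[i] * (A[i, 0] * DP + A[i, 1] * DD - b[i]) ** 2
    k = np.unravel_index(np.argmin(obj), obj.shape)
    return dps[k[0]], dds[k[1]]


class TestSolve:
    def test_recovers_constructed_steps(self):
        """Rows built from known steps are recovered to numerical precision."""
        dp_true, dd_true = 3e-5, 0.015
        P, D = 150.0, np.array([0.7, 0.0, 0.3])
        rows = [P * dp_true - d * dd_true for d in D]
        constraints = CalibrationConstraints(
            delta_a=-rows[0] * 40, t_a=40, delta_e=rows[1] * 40 + 1e-9, t_e=40
        )
        # make the system exactly consistent by choosing targets equal to rows
        summaries = [
            ConditionSummary(ACQUISITION, P, D[0], 30),
            ConditionSummary(EXTINCTION, P, D[1], 30),
            ConditionSummary(STABILITY, P, D[2] * 0, 30),  # placeholder, replaced below
        ]
        # stability row: P dp - D3 dd = 0 requires D3 = P dp / dd
        d3 = P * dp_true / dd_true
        summaries[2] = ConditionSummary(STABILITY, P, d3, 30)
        res = solve_plasticity(summaries, constraints)
        assert res.delta_p == pytest.approx(dp_true, rel=1e-6)
        assert res.delta_d == pytest.approx(dd_true, rel=1e-6)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_grid_search(self, seed):
        rng = np.random.default_rng(seed)
        summaries = [
            ConditionSummary(ACQUISITION, 150 * rng.uniform(0.5, 1.5), rng.uniform(0.4, 1.2), 30),
            ConditionSummary(EXTINCTION, 150 * rng.uniform(0.5, 1.5), 0.0, 30),
            ConditionSummary(STABILITY, 150 * rng.uniform(0.5, 1.5), rng.uniform(0.2, 0.5), 30),
        ]
        constraints = CalibrationConstraints()
        res = solve_plasticity(summaries, constraints)
        dp_g, dd_g = grid_search_oracle(summaries, constraints, hi=(4 * res.delta_p + 1e-6, 4 * res.delta_d + 1e-4))
        assert res.delta_p == pytest.approx(dp_g, abs=4 * res.delta_p / 400 + 1e-9)
        assert res.delta_d == pytest.approx(dd_g, abs=4 * res.delta_d / 400 + 1e-6)

    def test_heavy_weight_limit_ratio(self):
        """stability_weight -> inf forces delta_d / delta_p -> P3 / D3."""
        summaries = [
            ConditionSummary(ACQUISITION, 150.0, 0.8, 30),
            ConditionSummary(EXTINCTION, 150.0, 0.0, 30),
            ConditionSummary(STABILITY, 150.0, 0.31, 30),
        ]
        res = solve_plasticity(summaries, CalibrationConstraints(stability_weight=1e6))
        assert res.delta_d / res.delta_p == pytest.approx(150.0 / 0.31, rel=1e-4)

    def test_scale_equivariance(self):
        summaries = [
            ConditionSummary(ACQUISITION, 150.0, 0.8, 30),
            ConditionSummary(EXTINCTION, 150.0, 0.05, 30),
            ConditionSummary(STABILITY, 150.0, 0.31, 30),
        ]
        c = CalibrationConstraints()
        res1 = solve_plasticity(summaries, c)
        scaled = [ConditionSummary(s.condition_id, 3 * s.p_bar, 3 * s.d_bar, s.n_trials) for s in summaries]
        res3 = solve_plasticity(scaled, c)
        assert res3.delta_p == pytest.approx(res1.delta_p / 3)
        assert res3.delta_d == pytest.approx(res1.delta_d / 3)

    def test_degenerate_all_zero_depression(self):
        summaries = [
            ConditionSummary(ACQUISITION, 150.0, 0.0, 30),
            ConditionSummary(EXTINCTION, 150.0, 0.0, 30),
            ConditionSummary(STABILITY, 150.0, 0.0, 30),
        ]
        with pytest.raises(DegenerateCalibrationError):
            solve_plasticity(summaries, CalibrationConstraints())

    def test_negative_solution_clamped_with_flag(self):
        # acquisition asks for a *rise*, extinction for a *fall*: dp would go negative
        summaries = [
            ConditionSummary(ACQUISITION, 150.0, 2.5, 30),
            ConditionSummary(EXTINCTION, 0.5, 2.0, 30),
            ConditionSummary(STABILITY, 150.0, 0.31, 30),
        ]
        c = CalibrationConstraints(delta_e=2.0, t_e=10)
        res = solve_plasticity(summaries, c)
        if res.clamped:
            assert min(res.delta_p, res.delta_d) == 0.0
        assert res.delta_p >= 0 and res.delta_d >= 0

    def test_printed_magnitude_ordering(self, rng):
        """Bio-hybrid statistics give a large per-coincidence depression step
        and a small per-step potentiation step (the printed unordered pair)."""
        pn_stats, io_stats = bio_hybrid_stats(training=True)
        data = make_training_set(rng, pn_stats, io_stats)
        res, _ = calibrate_training(data, ModelParams(), CalibrationConstraints())
        assert res.delta_d > res.delta_p
        hi, lo = res.magnitudes
        assert hi == res.delta_d and lo == res.delta_p

    def test_table3_direction(self, rng):
        """With Table-3 statistics the calibrated steps give negative paired
        drift and ~zero stability drift (the design of the system)."""
        from eyeblink.experiments import simulation_stats

        pn_stats, io_stats = simulation_stats()
        data = make_training_set(rng, pn_stats, io_stats)
        res, _ = calibrate_training(data, ModelParams(), CalibrationConstraints())
        s = {x.condition_id: x for x in res.summaries}
        paired_drift = s[ACQUISITION].p_bar * res.delta_p - s[ACQUISITION].d_bar * res.delta_d
        stab_drift = s[STABILITY].p_bar * res.delta_p - s[STABILITY].d_bar * res.delta_d
        assert paired_drift < 0
        assert abs(stab_drift) < 0.2 / 40 / 10


class TestSigmaBarEstimator:
    def test_no_crossing_means_no_suppression(self):
        assert estimate_sigma_bar(ModelParams(), target_w=0.9) == 1.0

    def test_partial_coverage(self):
        # t_trig(0.3) = 0.2333; (0.2333 + 0.1 - 0.1) / 0.3
        assert estimate_sigma_bar(ModelParams(), target_w=0.3) == pytest.approx(0.2333 / 0.3, abs=1e-3)


class TestOperatingPoint:
    def _candidates(self, rng, far_values):
        pn_stats, _ = bio_hybrid_stats(training=True)
        out = []
        for far in far_values:
            io_stats = bio_hybrid_stats(training=True)[1]
            io_stats = type(io_stats)("IO", io_stats.tdr, far, io_stats.td_window, "draw")
            data = make_training_set(np.random.default_rng(rng.integers(2**31 - 1)), pn_stats, io_stats)
            out.append((far, data))
        return out

    def test_empty_grid_rejected(self):
        with pytest.raises(InputError):
            select_operating_point([], None, ModelParams(), CalibrationConstraints())

    def test_minimum_residual_selected(self, rng):
        cands = self._candidates(rng, [0.4, 1.1, 2.5])
        result, surface = select_operating_point(cands, None, ModelParams(), CalibrationConstraints())
        best_row = surface.loc[surface["residual"].idxmin()]
        assert result.operating_point["residual"] == pytest.approx(best_row["residual"])
        assert (result.operating_point["residual"] <= surface["residual"] + 1e-15).all()
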