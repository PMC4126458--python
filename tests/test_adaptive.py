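"""Adaptive recalibration: rate estimation, rational closed form, drift control."""

import numpy as np
import pytest

from eyeblink.adaptive import (
    AdaptiveState,
    derive_rational_coefficients,
    estimate_io_far,
    recalibrate_direct,
    run_adaptive_session,
)
from eyeblink.calibration import (
    ACQUISITION,
    EXTINCTION,
    STABILITY,
    CalibrationConstraints,
    ConditionSummary,
    calibrate_training,
)
from eyeblink.exceptions import DegenerateCalibrationError, InputError
from eyeblink.experiments import bio_hybrid_stats, make_training_set
from eyeblink.grid import EventTrain, TimeGrid
from eyeblink.model import ModelParams
from eyeblink.protocol import make_schedule
from eyeblink.synth import shuffle_io_within_trials, simulate_channel


@pytest.fixture
def calibrated_state(rng):
    pn_stats, io_stats = bio_hybrid_stats(training=True)
    data = make_training_set(rng, pn_stats, io_stats)
    result, kappa = calibrate_training(data, ModelParams(), CalibrationConstraints())
    return AdaptiveState.from_calibration(result, kappa, data.spont_rate_hz)


class TestEstimateIoFar:
    def test_counting(self):
        grid = TimeGrid(0.002, 100_000)  # 200 s
        times = np.linspace(1.0, 149.0, 171)
        io = EventTrain.from_times("IO", times, grid)
        assert estimate_io_far(io, (0.0, 150.0)) == pytest.approx(171 / 150.0)

    def test_zero_detections(self):
        grid = TimeGrid(0.002, 1000)
        assert estimate_io_far(EventTrain("IO", [], grid), (0.0, 2.0)) == 0.0

    def test_empty_window_rejected(self):
        grid = TimeGrid(0.002, 1000)
        with pytest.raises(InputError):
            estimate_io_far(EventTrain("IO", [], grid), (1.0, 1.0))

    def test_evoked_events_overestimate_rate(self, rng):
        """With paired stimulation present the blind estimate exceeds the
        true spontaneous rate."""
        pn_stats, io_stats = bio_hybrid_stats(training=True)
        ests = []
        for k in range(10):
            sch = make_schedule(12, iti_s=10.0, rng=np.random.default_rng(k))
            io = simulate_channel(sch, io_stats, rng=np.random.default_rng(100 + k))
            ests.append(estimate_io_far(io, (0.0, sch.grid.duration)))
        assert np.mean(ests) > io_stats.far


class TestRecalibration:
    def test_fixed_point_at_initial_rate(self, calibrated_state):
        dp, dd = recalibrate_direct(calibrated_state, calibrated_state.io_far)
        assert dp == pytest.approx(calibrated_state.delta_p, rel=1e-12)
        assert dd == pytest.approx(calibrated_state.delta_d, rel=1e-12)

    def test_doubled_rate_halves_depression_step(self):
        """In the heavy-stability-weight limit delta_d = P_bar*delta_p/(kappa*f),
        and with a consistent training set (evoked coincidences equal to the
        spontaneous ones) the potentiation scale is rate-independent, so a
        doubled rate halves delta_d."""
        kappa, f0 = 0.3, 1.0
        summaries = [
            ConditionSummary(ACQUISITION, 150.0, 2 * kappa * f0, 30),
            ConditionSummary(EXTINCTION, 150.0, 0.0, 30),
            ConditionSummary(STABILITY, 150.0, kappa * f0, 30),
        ]
        st = AdaptiveState(
            summaries=summaries,
            constraints=CalibrationConstraints(stability_weight=1e6),
            kappa=kappa,
            io_far=f0,
            delta_p=1e-5,
            delta_d=1e-2,
        )
        _, dd1 = recalibrate_direct(st, f0)
        _, dd2 = recalibrate_direct(st, 2 * f0)
        assert dd2 / dd1 == pytest.approx(0.5, abs=0.01)

    def test_rational_equals_direct_on_grid(self, calibrated_state):
        """The module's core correctness theorem: rational evaluation equals
        the direct WLS re-solve to near machine precision."""
        coeffs = derive_rational_coefficients(calibrated_state)
        for f in np.linspace(0.0, 3.0, 50):
            dp_ref, dd_ref = recalibrate_direct(calibrated_state, f)
            dp, dd = (float(x) for x in coeffs.evaluate(f))
            assert dp == pytest.approx(dp_ref, rel=1e-10, abs=1e-16)
            assert dd == pytest.approx(dd_ref, rel=1e-10, abs=1e-16)

    def test_rational_against_sympy_oracle(self, calibrated_state):
        """Independent symbolic solve of the weighted normal equations."""
        sympy = pytest.importorskip("sympy")
        st = calibrated_state
        base = {s.condition_id: s for s in st.summaries}
        P = [base[c].p_bar for c in (ACQUISITION, EXTINCTION, STABILITY)]
        D = [base[ACQUISITION].d_bar, base[EXTINCTION].d_bar, None]
        f = sympy.symbols("f", positive=True)
        dp, dd = sympy.symbols("dp dd")
        W = st.constraints.weights
        b = st.constraints.targets
        D3 = st.kappa * f
        rows = [
            (P[0] * dp - D[0] * dd - b[0], W[0]),
            (P[1] * dp - D[1] * dd - b[1], W[1]),
            (P[2] * dp - D3 * dd - b[2], W[2]),
        ]
        obj = sum(w * r**2 for r, w in rows)
        sol = sympy.solve([sympy.diff(obj, dp), sympy.diff(obj, dd)], [dp, dd], dict=True)[0]
        coeffs = derive_rational_coefficients(st)
        for fv in (0.3, 1.0, 1.7, 2.6):
            dp_sym = float(sol[dp].subs(f, fv))
            dd_sym = float(sol[dd].subs(f, fv))
            dp_r, dd_r = (float(x) for x in coeffs.evaluate(fv))
            assert dp_r == pytest.approx(dp_sym, rel=1e-9)
            assert dd_r == pytest.approx(dd_sym, rel=1e-9)

    def test_denominator_degree_two(self, calibrated_state):
        coeffs = derive_rational_coefficients(calibrated_state)
        assert coeffs.beta[2] != 0.0  # the closed form is degree 2, not 1
        assert coeffs.alpha_d[2] == 0.0  # delta_d numerator is degree 1

    def test_scale_invariance_of_solution(self, calibrated_state):
        """Scaling all summaries and kappa by c rescales steps by 1/c at any
        rate, so the rational forms agree after rescaling."""
        st = calibrated_state
        c = 2.5
        scaled = AdaptiveState(
            summaries=[
                ConditionSummary(s.condition_id, c * s.p_bar, c * s.d_bar, s.n_trials)
                for s in st.summaries
            ],
            constraints=st.constraints,
            kappa=c * st.kappa,
            io_far=st.io_far,
            delta_p=st.delta_p / c,
            delta_d=st.delta_d / c,
        )
        co1 = derive_rational_coefficients(st)
        co2 = derive_rational_coefficients(scaled)
        for fv in (0.5, 1.14, 2.0):
            dp1, dd1 = co1.evaluate(fv)
            dp2, dd2 = co2.evaluate(fv)
            assert float(dp2) == pytest.approx(float(dp1) / c, rel=1e-9)
            assert float(dd2) == pytest.approx(float(dd1) / c, rel=1e-9)

    def test_degenerate_summaries_rejected(self, calibrated_state):
        bad = AdaptiveState(
            summaries=[ConditionSummary(ACQUISITION, 1.0, 0.5, 30)] * 3,
            constraints=calibrated_state.constraints,
            kappa=1.0,
            io_far=1.0,
            delta_p=1e-5,
            delta_d=1e-2,
        )
        with pytest.raises(DegenerateCalibrationError):
            derive_rational_coefficients(bad)


class TestAdaptiveSession:
    def _session(self, rng, n_trials=40):
        pn_stats, io_stats = bio_hybrid_stats(training=True)
        sch = make_schedule(n_trials, iti_s=(10.0, 15.0), rng=rng)
        pn = simulate_channel(sch, pn_stats, rng=rng)
        io = simulate_channel(sch, io_stats, rng=rng)
        return sch, pn, io

    def test_stationary_matches_static_up_to_estimation_noise(self, rng, calibrated_state):
        from eyeblink.model import run_session

        sch, pn, io = self._session(rng)
        io_shuf = shuffle_io_within_trials(io, sch, rng=rng)
        params = ModelParams(delta_p=calibrated_state.delta_p, delta_d=calibrated_state.delta_d)
        log_a = run_adaptive_session(pn, io_shuf, sch, params, calibrated_state)
        log_s = run_session(pn, io_shuf, sch, params)
        assert log_a.recalibrations  # recalibrations did happen
        # stationary input: step trajectory stays near the initial value
        dds = np.array([r[3] for r in log_a.recalibrations])
        assert np.all(np.abs(dds / params.delta_d - 1) < 0.6)
        assert abs(log_a.w_final - log_s.w_final) < 0.1

    def test_recalibration_log_period(self, rng, calibrated_state):
        sch, pn, io = self._session(rng)
        params = ModelParams(delta_p=calibrated_state.delta_p, delta_d=calibrated_state.delta_d)
        log = run_adaptive_session(pn, io, sch, params, calibrated_state)
        times = np.array([r[0] for r in log.recalibrations])
        assert np.allclose(np.diff(times), calibrated_state.recalibration_period)

    def test_adaptive_tracks_drift_better_than_static(self, calibrated_state):
        """Under a strong sustained rate shift the static model drifts while
        the adaptive one stays near w0 (the associativity-preserving
        behavior)."""
        from eyeblink.model import run_session
        from eyeblink.synth import drifting_rate_profile

        rng = np.random.default_rng(77)
        pn_stats, io_stats = bio_hybrid_stats(training=True)
        diffs = []
        for k in range(4):
            sch = make_schedule(60, iti_s=(10.0, 15.0), rng=np.random.default_rng(200 + k))
            profile = drifting_rate_profile("constant", (2.2, 2.2), duration_s=sch.grid.duration)
            pn = simulate_channel(sch, pn_stats, rng=np.random.default_rng(300 + k))
            io = simulate_channel(sch, io_stats, rng=np.random.default_rng(400 + k), profile=profile)
            io_u = shuffle_io_within_trials(io, sch, rng=np.random.default_rng(500 + k))
            params = ModelParams(delta_p=calibrated_state.delta_p, delta_d=calibrated_state.delta_d)
            st = AdaptiveState(
                summaries=calibrated_state.summaries,
                constraints=calibrated_state.constraints,
                kappa=calibrated_state.kappa,
                io_far=calibrated_state.io_far,
                delta_p=calibrated_state.delta_p,
                delta_d=calibrated_state.delta_d,
            )
            log_a = run_adaptive_session(pn, io_u, sch, params, st)
            log_s = run_session(pn, io_u, sch, params)
            diffs.append(abs(log_s.w_final - 0.5) - abs(log_a.w_final - 0.5))
        # static drifts away from w0 by more than adaptive, on average
        assert np.mean(diffs) > 0
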