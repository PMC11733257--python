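"""Unit tests for the closed-loop stance model building blocks."""

import math

import numpy as np
import pytest
from scipy import signal

from hapticsway.errors import ConfigurationError, InvalidNumericError
from hapticsway.model_core import (
    STUDY_GAIN_GRID,
    BodyParams,
    ConflictParams,
    ControlParams,
    GainCondition,
    ModelConfig,
    NoiseParams,
    conflict_correction,
    linear_spectral_radius,
    noise_filter_coefficients,
    noise_step,
    plant_step,
    run_condition_battery,
    sensory_estimates,
    simulate_trial,
    stationary_noise_std,
)
from hapticsway.sway_metrics import integrate_spectrum, segmented_psd

DT = 1.0 / 1200.0


class TestPlantStep:
    def test_equilibrium_is_fixed_point(self, body):
        state = (0.0, 0.0)
        for _ in range(100):
            state = plant_step(state, 0.0, body, DT)
        assert state == (0.0, 0.0)

    def test_first_step_acceleration_matches_linearisation(self, body):
        theta0 = 0.01
        _, td = plant_step((theta0, 0.0), 0.0, body, DT)
        accel = td / DT
        assert accel == pytest.approx(68.5 * 9.81 * 0.96 * 0.01 / 76.4, rel=1e-12)

    def test_free_fall_matches_cosh_solution(self, body):
        # torque-free linear ODE: theta(t) = theta0 * cosh(t*sqrt(mgh/J))
        theta0 = 1e-3
        omega = math.sqrt(body.mgh / body.J)
        state = (theta0, 0.0)
        n = 600  # 0.5 s
        for _ in range(n):
            state = plant_step(state, 0.0, body, DT)
        expected = theta0 * math.cosh(n * DT * omega)
        # semi-implicit Euler is first-order: ~dt*omega/2 amplitude offset
        assert state[0] == pytest.approx(expected, rel=2e-3)

    def test_nonfinite_torque_rejected(self, body):
        with pytest.raises(InvalidNumericError):
            plant_step((0.0, 0.0), np.nan, body, DT)
        with pytest.raises(InvalidNumericError):
            plant_step((np.inf, 0.0), 0.0, body, DT)


class TestSensoryEstimates:
    @pytest.mark.parametrize(
        "G,expected_touch_factor",
        [(0.0, 1.0), (1.0, 0.0), (2.0, -1.0)],
        ids=["static-object", "free-floating", "reversed"],
    )
    def test_touch_geometry(self, body, G, expected_touch_factor):
        theta, theta_dot = 0.02, -0.01
        th_s, v_s, th_t, v_t = sensory_estimates(
            theta, theta_dot, GainCondition(G=G), (0.0, 0.0), body
        )
        assert th_s == theta and v_s == theta_dot
        assert th_t == pytest.approx(expected_touch_factor * theta, abs=1e-15)
        assert v_t == pytest.approx(expected_touch_factor * theta_dot, abs=1e-15)

    def test_same_noise_enters_both_channels(self, body):
        th_s, v_s, th_t, v_t = sensory_estimates(
            0.0, 0.0, GainCondition(G=0.0), (0.005, -0.002), body
        )
        assert th_s == th_t == 0.005
        assert v_s == v_t == -0.002

    def test_degenerate_body_rejected(self):
        with pytest.raises(ConfigurationError):
            BodyParams(h=0.0)


class TestConflictCorrection:
    @pytest.mark.parametrize(
        "v_touch,v_space,Te,mode,expected",
        [
            (0.10, 0.08, 0.05, "literal", 0.0),
            (0.30, 0.05, 0.10, "literal", 0.25),
            (0.30, 0.05, 0.10, "deadzone", 0.15),
            (-0.30, -0.05, 0.10, "literal", -0.25),
            (-0.30, -0.05, 0.10, "deadzone", -0.15),
            (0.30, 0.05, np.inf, "literal", 0.0),
        ],
    )
    def test_correction_forms(self, v_touch, v_space, Te, mode, expected):
        cp = ConflictParams(Te=Te, mode=mode)
        assert conflict_correction(v_touch, v_space, cp) == pytest.approx(
            expected, abs=1e-15
        )

    def test_invalid_mode_rejected(self):
        with pytest.raises(ConfigurationError):
            ConflictParams(mode="sometimes")


class TestNoise:
    def test_zero_gain_silences_process(self):
        params = NoiseParams(k_noise=0.0, seed=3)
        rng = np.random.default_rng(params.seed)
        state = 0.0
        for _ in range(50):
            state, (n, ndot) = noise_step(state, params, DT, rng)
            assert n == 0.0 and ndot == 0.0 and state == 0.0

    def test_seed_reproducibility(self):
        params = NoiseParams(seed=9)
        seqs = []
        for _ in range(2):
            rng = np.random.default_rng(params.seed)
            state, vals = 0.0, []
            for _ in range(200):
                state, (n, ndot) = noise_step(state, params, DT, rng)
                vals.append((n, ndot))
            seqs.append(vals)
        assert seqs[0] == seqs[1]

    def test_stationary_variance_matches_ar1_closed_form(self, rng):
        # same recurrence as noise_step, vectorised for one million steps;
        # short tau keeps the effective sample count high enough for 2%
        params = NoiseParams(k_noise=0.05, tau_noise=0.05)
        a, b = noise_filter_coefficients(params, DT)
        w = rng.standard_normal(1_000_000)
        n = signal.lfilter([b], [1, -a], w)
        expected = stationary_noise_std(params, DT)
        assert np.std(n[1000:]) == pytest.approx(expected, rel=0.02)

    def test_invalid_tau_rejected(self):
        with pytest.raises(ConfigurationError):
            NoiseParams(tau_noise=0.0)


class TestSimulateTrial:
    def test_zero_noise_zero_sway_all_gains(self, body, ctrl):
        for G in STUDY_GAIN_GRID:
            trace = simulate_trial(
                body,
                ctrl,
                ConflictParams(),
                NoiseParams(k_noise=0.0, seed=0),
                GainCondition(G=G),
                60.0,
            )
            assert not trace.diverged
            assert np.max(np.abs(trace.theta)) == 0.0

    def test_deterministic_given_seed(self, body, ctrl):
        runs = [
            simulate_trial(
                body, ctrl, ConflictParams(), NoiseParams(seed=5),
                GainCondition(G=0.5), 60.0,
            )
            for _ in range(2)
        ]
        assert np.array_equal(runs[0].theta, runs[1].theta)
        assert np.array_equal(runs[0].torque, runs[1].torque)

    def test_free_floating_touch_cue_is_noise_only(self, body, ctrl):
        # G=1, no device lag: hand-object distance is identically zero, so
        # the touch channel carries nothing but the shared noise source
        trace = simulate_trial(
            body, ctrl, ConflictParams(Te=np.inf), NoiseParams(seed=2),
            GainCondition(G=1.0), 60.0,
        )
        assert np.allclose(trace.theta_touch, trace.noise, atol=1e-12)

    def test_x_body_is_h_theta(self, quiet_trace, body):
        assert np.array_equal(quiet_trace.x_body, body.h * quiet_trace.theta)

    def test_trace_noise_matches_reference_recurrence(self, body, ctrl):
        # the in-loop noise process equals the documented AR(1) recurrence
        noisep = NoiseParams(seed=13)
        trace = simulate_trial(
            body, ctrl, ConflictParams(), noisep, GainCondition(G=0.0), 60.0,
        )
        a, b = noise_filter_coefficients(noisep, trace.dt)
        w = np.random.default_rng(noisep.seed).standard_normal(len(trace.t))
        ref = signal.lfilter([b], [1, -a], np.concatenate([[0.0], w[:-1]]))
        assert np.allclose(trace.noise, ref, atol=1e-15)

    def test_unstable_controller_aborts_with_diagnostic(self, body):
        bad = ControlParams(Kp=1.05 * body.mgh, Kd=0.0, delay=0.3)
        assert linear_spectral_radius(body, bad) > 1.0
        with pytest.raises(ConfigurationError, match="unstable"):
            simulate_trial(
                body, bad, ConflictParams(), NoiseParams(seed=0),
                GainCondition(G=0.0), 60.0,
            )

    def test_divergence_flagged_not_raised(self, body, ctrl):
        # conflict ablation at the destabilising gain: flag-and-return
        trace = simulate_trial(
            body, ctrl, ConflictParams(Te=np.inf), NoiseParams(seed=0),
            GainCondition(G=2.0), 120.0,
        )
        assert trace.diverged
        assert len(trace.theta) < int(120.0 / trace.dt)


class TestConditionBattery:
    def test_study_grid_and_determinism(self, default_config):
        import dataclasses

        cfg = dataclasses.replace(default_config, duration=60.0, discard_s=10.0)
        out1 = run_condition_battery(cfg, seeds=[0, 1])
        out2 = run_condition_battery(cfg, seeds=[0, 1])
        assert set(out1) == set(STUDY_GAIN_GRID)
        for G in out1:
            assert len(out1[G]) == 2
            for a, b in zip(out1[G], out2[G]):
                assert np.array_equal(a.theta, b.theta)

    def test_empty_gain_list_rejected(self, default_config):
        with pytest.raises(ConfigurationError):
            run_condition_battery(default_config, gains=[], seeds=[0])

    def test_seed_dispersion_at_full_duration(self, default_config):
        # integrated velocity power across independent 2810-s realisations
        cfg = default_config
        out = run_condition_battery(cfg, gains=[0.0], duration=2810.0,
                                    seeds=[0, 1, 2])
        powers = []
        for trace in out[0.0]:
            sl = trace.analysis_slice()
            spec = segmented_psd(trace.theta_dot[sl], trace.fs)
            powers.append(integrate_spectrum(spec))
        powers = np.asarray(powers)
        assert powers.std() / powers.mean() < 0.15
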