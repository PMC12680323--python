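"""Sensory-layer unit and property tests.

The recursive filters are checked against brute-force direct-summation
oracles; the dynamics are checked for causality, nonnegativity,
steady-state accuracy and the transient-sustained phenomenology.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dstn import (
    SensoryParams,
    StimulusSequence,
    TuningBank,
    exp_filter,
    pooling_matrix,
    simulate,
    single_pulse,
    step_response,
    suppressive_drive,
    tuned_drive,
)
from dstn.model import exp_filter_weights


def explicit_filter_oracle(signal, tau_ms, dt_ms, mode="gain"):
    """Brute-force double sum: y_t = sum_{T<=t} w[t-T] x_T."""
    signal = np.asarray(signal, dtype=float)
    w = exp_filter_weights(len(signal), tau_ms, dt_ms, mode)
    return np.array(
        [np.dot(w[: t + 1][::-1], signal[: t + 1]) for t in range(len(signal))]
    )


class TestTunedDrive:
    @pytest.mark.parametrize(
        "delta_deg, expected",
        [(0.0, 1.0), (90.0, 0.0), (15.0, np.abs(np.cos(np.deg2rad(15))) ** 23)],
    )
    def test_drive_at_offset_from_preferred(self, bank, delta_deg, expected):
        d = tuned_drive(np.deg2rad(delta_deg), 1.0, bank)
        assert d[0] == pytest.approx(expected, abs=1e-12)

    def test_circular_with_period_pi(self, bank):
        a = tuned_drive(0.3, 0.8, bank)
        b = tuned_drive(0.3 + np.pi, 0.8, bank)
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_nonnegative_and_scales_with_contrast(self, bank):
        d = tuned_drive(0.7, 0.5, bank)
        assert (d >= 0).all()
        np.testing.assert_allclose(d, 0.5 * tuned_drive(0.7, 1.0, bank))

    def test_invalid_contrast_rejected(self, bank):
        with pytest.raises(ValueError):
            tuned_drive(0.0, -0.1, bank)
        with pytest.raises(ValueError):
            tuned_drive(0.0, 1.5, bank)


class TestExpFilter:
    def test_tau_zero_is_identity(self, rng):
        x = rng.random(100)
        np.testing.assert_array_equal(exp_filter(x, 0.0), x)

    def test_sustained_input_converges_to_one(self):
        y = exp_filter(np.ones(5000), 400.0, dt_ms=2.0)
        assert y[-1] == pytest.approx(1.0, rel=1e-8)

    def test_negative_tau_rejected(self):
        with pytest.raises(ValueError):
            exp_filter(np.ones(5), -1.0)

    def test_impulse_matches_explicit_sum_at_one_tau(self):
        x = np.zeros(400)
        x[0] = 1.0
        y = exp_filter(x, 400.0, dt_ms=2.0)
        oracle = explicit_filter_oracle(x, 400.0, 2.0)
        # read out one time constant after the impulse
        assert y[200] == pytest.approx(oracle[200], rel=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 2**31 - 1),
        tau=st.sampled_from([50.0, 100.0, 400.0, 900.0]),
        mode=st.sampled_from(["gain", "literal"]),
    )
    def test_recursion_equals_explicit_double_sum(self, seed, tau, mode):
        x = np.random.default_rng(seed).random(300)
        y = exp_filter(x, tau, dt_ms=2.0, mode=mode)
        oracle = explicit_filter_oracle(x, tau, 2.0, mode)
        np.testing.assert_allclose(y, oracle, rtol=1e-10, atol=1e-13)


class TestPoolingMatrix:
    def test_uniform_at_infinite_exponent(self, bank):
        np.testing.assert_array_equal(pooling_matrix(bank, np.inf), np.ones((12, 12)))

    def test_identity_at_zero(self, bank):
        np.testing.assert_array_equal(pooling_matrix(bank, 0.0), np.eye(12))

    def test_cosine_weight_at_unit_exponent(self, bank):
        S = pooling_matrix(bank, 1.0)
        # channels 45 degrees apart (3 steps of pi/12)
        assert S[0, 3] == pytest.approx(np.cos(np.pi / 4), rel=1e-12)

    def test_symmetric_unit_diagonal_bounded(self, bank):
        for p in (0.1, 0.5, 1.0, 5.0):
            S = pooling_matrix(bank, p)
            np.testing.assert_allclose(S, S.T)
            np.testing.assert_allclose(np.diag(S), 1.0)
            assert (S >= 0).all() and (S <= 1).all()


class TestSuppressiveDrive:
    def test_zero_excitation_gives_zero(self):
        e = np.zeros((4, 50))
        s = suppressive_drive(e, np.ones((4, 4)), 100.0)
        np.testing.assert_array_equal(s, 0.0)

    def test_instantaneous_uniform_pool_is_sum(self, rng):
        e = rng.random((5, 80))
        s = suppressive_drive(e, np.ones((5, 5)), 0.0)
        np.testing.assert_allclose(s[0], e.sum(axis=0), rtol=1e-12)

    def test_impulse_decays_with_tau_s(self):
        e = np.zeros((1, 200))
        e[0, 0] = 1.0
        s = suppressive_drive(e, np.ones((1, 1)), 100.0, dt_ms=2.0)[0]
        oracle = explicit_filter_oracle(e[0], 100.0, 2.0)
        np.testing.assert_allclose(s, oracle, rtol=1e-10)
        assert s[50] / s[0] == pytest.approx(np.exp(-1.0), rel=1e-9)

    def test_pool_weighting_and_filter_commute(self, rng, bank):
        e = rng.random((12, 120))
        pool = pooling_matrix(bank, 1.0)
        filtered_then_pooled = pool @ exp_filter(e, 80.0, axis=-1)
        pooled_then_filtered = suppressive_drive(e, pool, 80.0)
        np.testing.assert_allclose(filtered_then_pooled, pooled_then_filtered, rtol=1e-10)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            suppressive_drive(np.ones((3, 10)), np.ones((4, 4)), 10.0)


class TestStepResponse:
    def test_rest_stays_at_rest(self, params):
        r = step_response(np.zeros(3), np.zeros(3), 0.0, params)
        np.testing.assert_array_equal(r, 0.0)

    def test_fixed_point_of_constant_drive(self, params):
        r_star = 1.0 / (0.5 + params.sigma_pow_n)
        r = step_response(np.array([r_star]), np.array([1.0]), 0.5, params)
        assert r[0] == pytest.approx(r_star, rel=1e-12)

    def test_single_euler_step_from_rest(self, params):
        r = step_response(np.array([0.0]), np.array([1.0]), 0.0, params)
        expected = (2.0 / 52.0) * (1.0 / 0.1**1.5)
        assert r[0] == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(1.2163, abs=5e-5)

    def test_unstable_dt_warns(self):
        with pytest.warns(RuntimeWarning):
            SensoryParams(tau_R_ms=1.0, dt_ms=2.0)


class TestSimulate:
    def test_zero_stimulus_zero_response(self, params):
        stim = StimulusSequence(np.zeros((1, 100)))
        trace = simulate(stim, params)
        np.testing.assert_array_equal(trace.response, 0.0)
        np.testing.assert_array_equal(trace.excitatory, 0.0)

    def test_nan_stimulus_rejected(self):
        X = np.zeros((1, 10))
        X[0, 3] = np.nan
        with pytest.raises(ValueError):
            StimulusSequence(X)

    def test_suppressive_window_makes_transient_sustained(self):
        """tau_S > 0, tau_E = 0: early peak, then decline to a stable plateau."""
        stim = single_pulse(2000.0, trial_duration_ms=8100.0)
        trace = simulate(stim, SensoryParams(tau_E_ms=0.0, tau_S_ms=100.0))
        r = trace.response[trace.unit_index(0.0)]
        i0, i1 = int(500 / 2), int(2500 / 2)
        within = r[i0:i1]
        peak_idx = int(np.argmax(within))
        assert peak_idx < (i1 - i0) / 4  # peak early in the window
        assert within[-1] < 0.6 * within.max()  # stable level well below peak
        # plateau reached before offset: last 200 ms nearly flat
        tail = within[-100:]
        assert np.ptp(tail) < 0.01 * within.max()

    def test_excitatory_window_preserves_stable_level(self):
        """tau_S = 0: all tau_E reach the same plateau; time-to-peak grows."""
        levels, t_peak = [], []
        for tau_e in (100.0, 400.0, 800.0):
            stim = single_pulse(2000.0, trial_duration_ms=8100.0)
            trace = simulate(stim, SensoryParams(tau_E_ms=tau_e, tau_S_ms=0.0))
            r = trace.response[trace.unit_index(0.0)]
            within = r[int(500 / 2) : int(2500 / 2)]
            levels.append(within[-1])
            t_peak.append(np.argmax(within >= 0.99 * within.max()))
        assert max(levels) - min(levels) < 0.01 * max(levels)
        assert t_peak[0] < t_peak[1] < t_peak[2]

    def test_steady_state_matches_normalization_equation(self):
        """Held stimulus >> all taus: r -> e/(s + sigma**n) within 0.1%."""
        params = SensoryParams(tau_E_ms=100.0, tau_S_ms=50.0)
        stim = single_pulse(6000.0, trial_duration_ms=7000.0, prestimulus_ms=200.0)
        trace = simulate(stim, params)
        i_end = int(6200 / 2) - 1
        e, s = trace.excitatory[:, i_end], trace.suppressive[:, i_end]
        expected = e / (s + params.sigma_pow_n)
        np.testing.assert_allclose(trace.response[:, i_end], expected, rtol=1e-3)

    def test_causality_under_truncation_is_bitwise(self, params):
        stim = single_pulse(400.0, trial_duration_ms=2000.0)
        full = simulate(stim, params)
        cut = 300
        truncated = StimulusSequence(
            stim.drive_matrix[:, :cut],
            dt_ms=stim.dt_ms,
            orientation_of_channel=stim.orientation_of_channel,
            location_of_channel=stim.location_of_channel,
        )
        part = simulate(truncated, params)
        np.testing.assert_array_equal(part.response, full.response[:, :cut])
        np.testing.assert_array_equal(part.suppressive, full.suppressive[:, :cut])

    def test_nonnegative_and_bounded(self, params):
        stim = single_pulse(500.0, trial_duration_ms=3000.0)
        trace = simulate(stim, params)
        assert (trace.response >= 0).all()
        assert trace.response.max() <= trace.excitatory.max() / params.sigma_pow_n

    def test_zero_at_start_when_stimulus_starts_at_zero(self, params):
        stim = single_pulse(100.0, trial_duration_ms=1000.0, prestimulus_ms=200.0)
        trace = simulate(stim, params)
        assert trace.excitatory[:, 0].max() == 0.0

    def test_instantaneous_limit_recovers_static_normalization(self, bank):
        """tau_E = tau_S = 0: e = d**n and s = sum_i e_i exactly."""
        params = SensoryParams(tau_E_ms=0.0, tau_S_ms=0.0)
        stim = single_pulse(100.0, contrast=0.64, trial_duration_ms=800.0)
        trace = simulate(stim, params, bank)
        d = np.zeros_like(trace.excitatory)
        i0, i1 = int(500 / 2), int(600 / 2)
        d[:, i0:i1] = tuned_drive(0.0, 0.64, bank)[:, None]
        np.testing.assert_array_equal(trace.excitatory, d**1.5)
        np.testing.assert_allclose(
            trace.suppressive[0], trace.excitatory.sum(axis=0), rtol=1e-12
        )

    def test_suppression_spreads_later_than_excitation(self):
        """Center of mass of the suppressive impulse response exceeds the
        excitatory one for any tau_S >= 0 with tau_E > 0."""
        impulse = np.zeros(4000)
        impulse[0] = 1.0
        t = np.arange(impulse.size)
        e = exp_filter(impulse, 400.0)
        com_e = (t * e).sum() / e.sum()
        for tau_s in (50.0, 400.0):
            s = exp_filter(e, tau_s)
            com_s = (t * s).sum() / s.sum()
            assert com_s > com_e
        # tau_S = 0 degenerates to the identity window: equal spread
        s0 = exp_filter(e, 0.0)
        assert (t * s0).sum() / s0.sum() == pytest.approx(com_e)

    def test_dt_mismatch_rejected(self, params):
        stim = StimulusSequence(np.zeros((1, 10)), dt_ms=1.0)
        with pytest.raises(ValueError):
            simulate(stim, params)


class TestTraceSerialization:
    def test_long_format_frame(self, params):
        stim = single_pulse(100.0, trial_duration_ms=600.0)
        trace = simulate(stim, params)
        df = trace.to_frame()
        assert list(df.columns) == [
            "unit", "location", "time_ms", "excitatory", "suppressive", "response",
        ]
        assert len(df) == trace.response.size

    def test_params_dict_roundtrip(self):
        p = SensoryParams(tau_E_ms=123.0, pooling_exponent=np.inf)
        q = SensoryParams.from_dict(p.to_dict())
        assert q == p
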