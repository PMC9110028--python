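"""Unit and property tests for the release/replenishment simulator."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from calyxstp import (
    ReleaseModelParams,
    StimulusProtocol,
    apply_spike,
    interval_update,
    simulate,
    steady_state_norm_amplitude,
)


def euler_interval(n, tau_r, delta, tau_b, tau_d, dt):
    """Independent fixed-step Euler oracle for the spike-free dynamics."""
    steps = int(round(delta / dt))
    for _ in range(steps):
        n += dt * (1.0 - n) / tau_r
        tau_r += dt * (tau_b - tau_r) / tau_d
    return n, tau_r


class TestIntervalUpdate:
    def test_constant_tau_closed_form(self):
        # tau_r == tau_b: deficit decays as e^(-delta/tau_b)
        p = ReleaseModelParams(pv=0.5, tau_b=100.0, tau_h=100.0, tau_d=500.0)
        n, tau_r = interval_update(0.5, 100.0, 100.0, p)
        assert n == pytest.approx(1.0 - 0.5 * math.exp(-1.0), abs=1e-12)
        assert tau_r == pytest.approx(100.0, abs=1e-12)

    def test_zero_interval_is_identity(self):
        p = ReleaseModelParams(pv=0.2, tau_b=5000.0, tau_h=60.0, tau_d=500.0)
        assert interval_update(0.3, 70.0, 0.0, p) == (0.3, 70.0)

    def test_matches_fine_euler_oracle(self):
        p = ReleaseModelParams(pv=0.2, tau_b=5000.0, tau_h=60.0, tau_d=500.0)
        n_exact, tr_exact = interval_update(0.8, 60.0, 10.0, p)
        n_euler, tr_euler = euler_interval(0.8, 60.0, 10.0, 5000.0, 500.0, 1e-4)
        assert abs(n_exact - n_euler) < 1e-6
        assert abs(tr_exact - tr_euler) / tr_exact < 1e-6

    @pytest.mark.parametrize(
        "n,tau_r,delta",
        [(0.5, -1.0, 10.0), (0.5, 0.0, 10.0), (0.5, 50.0, -1.0), (1.5, 50.0, 10.0)],
    )
    def test_invalid_arguments_raise(self, n, tau_r, delta):
        p = ReleaseModelParams(pv=0.2, tau_b=5000.0, tau_h=60.0, tau_d=500.0)
        with pytest.raises(ValueError):
            interval_update(n, tau_r, delta, p)


class TestApplySpike:
    def test_wildtype_release_probability(self):
        p = ReleaseModelParams(pv=0.13, tau_b=5000.0, tau_h=66.9, tau_d=500.0)
        epsc, n_after, tau_r_after = apply_spike(1.0, p)
        assert epsc == pytest.approx(0.13)
        assert n_after == pytest.approx(0.87)
        assert tau_r_after == 66.9

    def test_vanishing_release_leaves_pool(self):
        p = ReleaseModelParams(pv=1e-12, tau_b=5000.0, tau_h=66.9, tau_d=500.0)
        epsc, n_after, _ = apply_spike(0.5, p)
        assert epsc == pytest.approx(0.0, abs=1e-12)
        assert n_after == pytest.approx(0.5, abs=1e-12)

    def test_full_release_empties_pool(self):
        p = ReleaseModelParams(pv=1.0, tau_b=5000.0, tau_h=66.9, tau_d=500.0)
        epsc, n_after, _ = apply_spike(1.0, p)
        assert epsc == 1.0 and n_after == 0.0


class TestSimulate:
    def test_two_spike_paired_pulse_closed_form(self):
        # tau_h == tau_b: epsc_norm[1] = 1 - pv*exp(-delta/tau)
        p = ReleaseModelParams(pv=0.13, tau_b=66.9, tau_h=66.9, tau_d=500.0)
        proto = StimulusProtocol(spike_times=(0.0, 10.0))
        trace = simulate(proto, p)
        assert trace.epsc_norm[1] == pytest.approx(
            1.0 - 0.13 * math.exp(-10.0 / 66.9), abs=1e-12
        )

    def test_vanishing_pv_no_depression(self):
        p = ReleaseModelParams(pv=1e-9, tau_b=5000.0, tau_h=66.9, tau_d=500.0)
        trace = simulate(StimulusProtocol.regular_train(200.0, 100.0), p)
        assert np.allclose(trace.epsc_norm, 1.0, atol=1e-6)

    def test_first_norm_amplitude_is_exactly_one(self, wt_params):
        trace = simulate(StimulusProtocol.regular_train(100.0, 800.0), wt_params)
        assert trace.epsc_norm[0] == 1.0

    def test_exact_matches_euler(self, wt_params):
        proto = StimulusProtocol.regular_train(200.0, 800.0)
        exact = simulate(proto, wt_params)
        euler = simulate(proto, wt_params, method="euler", dt=1e-3)
        assert np.max(np.abs(exact.epsc_norm - euler.epsc_norm)) <= 1e-4

    def test_euler_dt_too_coarse_rejected(self, wt_params):
        proto = StimulusProtocol.regular_train(600.0, 100.0)
        with pytest.raises(ValueError, match="dt"):
            simulate(proto, wt_params, method="euler", dt=2.0)

    def test_empty_protocol_rejected(self):
        with pytest.raises(ValueError):
            StimulusProtocol(spike_times=())

    def test_trace_invariants(self, wt_params):
        proto = StimulusProtocol.train_with_recovery(100.0, 800.0, [50, 500, 5000])
        tr = simulate(proto, wt_params)
        assert np.all(tr.n_post <= tr.n_pre + 1e-15)
        assert np.all(tr.n_pre <= 1.0 + 1e-12) and np.all(tr.n_post >= 0.0)
        assert np.allclose(tr.n_post, tr.n_pre * (1 - wt_params.pv))
        lo = min(wt_params.tau_b, wt_params.tau_h)
        hi = max(wt_params.tau_b, wt_params.tau_h)
        assert np.all((tr.tau_r_pre >= lo - 1e-9) & (tr.tau_r_pre <= hi + 1e-9))


param_strategy = st.builds(
    ReleaseModelParams,
    pv=st.floats(0.02, 0.9),
    tau_b=st.floats(200.0, 20000.0),
    tau_h=st.floats(5.0, 150.0),
    tau_d=st.floats(20.0, 5000.0),
)


class TestModelProperties:
    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(params=param_strategy, freq=st.floats(50.0, 600.0))
    def test_pool_bounds_and_monotone_depression(self, params, freq):
        """Occupancy stays in [0,1] and a regular train from rest depresses
        monotonically (tau_r starts at tau_b >= tau_h)."""
        proto = StimulusProtocol.regular_train(freq, 400.0)
        tr = simulate(proto, params)
        assert np.all((tr.n_pre >= 0) & (tr.n_pre <= 1.0 + 1e-12))
        assert np.all(np.diff(tr.epsc_norm) <= 1e-12)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(params=param_strategy)
    def test_steady_state_decreases_with_frequency(self, params):
        freqs = [50.0, 100.0, 200.0, 400.0, 600.0]
        ss = [
            steady_state_norm_amplitude(f, params, constant_tau=True) for f in freqs
        ]
        assert all(a >= b - 1e-12 for a, b in zip(ss, ss[1:]))

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(params=param_strategy)
    def test_full_recovery_at_long_intervals(self, params):
        """A probe long after the train sees a refilled pool (epsc_norm -> 1)."""
        horizon = 20.0 * max(params.tau_b, params.tau_d)
        proto = StimulusProtocol.train_with_recovery(100.0, 200.0, [horizon])
        tr = simulate(proto, params)
        assert tr.epsc_norm[-1] == pytest.approx(1.0, abs=1e-6)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        params=param_strategy,
        fracs=st.lists(st.floats(0.05, 0.95), min_size=2, max_size=6, unique=True),
    )
    def test_tau_r_relaxes_monotonically_toward_background(self, params, fracs):
        """Between spikes tau_r moves monotonically from tau_h toward tau_b."""
        span = 3.0 * params.tau_d
        taus = []
        for frac in sorted(fracs):
            _, tau_r = interval_update(0.5, params.tau_h, frac * span, params)
            taus.append(tau_r)
        diffs = np.diff(taus)
        if params.tau_b >= params.tau_h:
            assert np.all(diffs >= -1e-9)
        else:
            assert np.all(diffs <= 1e-9)


class TestSteadyState:
    def test_constant_tau_fixed_point_value(self):
        p = ReleaseModelParams(pv=0.13, tau_b=66.9, tau_h=66.9, tau_d=500.0)
        ss = steady_state_norm_amplitude(100.0, p, constant_tau=True)
        E = math.exp(-10.0 / 66.9)
        assert ss == pytest.approx((1 - E) / (1 - 0.87 * E), abs=1e-12)
        assert ss == pytest.approx(0.5536121524916713, abs=1e-9)

    def test_vanishing_pv_no_depression(self):
        p = ReleaseModelParams(pv=1e-9, tau_b=66.9, tau_h=66.9, tau_d=500.0)
        assert steady_state_norm_amplitude(100.0, p, constant_tau=True) == pytest.approx(
            1.0, abs=1e-6
        )

    def test_constant_tau_agrees_with_simulated_when_tau_b_equals_tau_h(self):
        p = ReleaseModelParams(pv=0.2, tau_b=80.0, tau_h=80.0, tau_d=500.0)
        analytic = steady_state_norm_amplitude(150.0, p, constant_tau=True)
        simulated = steady_state_norm_amplitude(150.0, p, constant_tau=False)
        assert simulated == pytest.approx(analytic, rel=1e-8)

    def test_invalid_frequency_rejected(self, wt_params):
        with pytest.raises(ValueError):
            steady_state_norm_amplitude(0.0, wt_params)


class TestProtocolConstruction:
    @pytest.mark.parametrize(
        "freq,duration,expected",
        [(100.0, 800.0, 80), (600.0, 800.0, 480), (200.0, 800.0, 160)],
    )
    def test_regular_train_spike_count(self, freq, duration, expected):
        proto = StimulusProtocol.regular_train(freq, duration)
        assert len(proto) == expected
        assert proto.spike_times[0] == 0.0
        assert proto.spike_times[1] == pytest.approx(1000.0 / freq)

    def test_recovery_probes_offset_from_last_train_spike(self):
        proto = StimulusProtocol.train_with_recovery(100.0, 800.0, [50.0, 30000.0])
        assert len(proto) == 82
        assert proto.spike_times[80] == pytest.approx(790.0 + 50.0)
        assert proto.spike_times[-1] == pytest.approx(790.0 + 30000.0)
        assert proto.segment_tags[79] == "train"
        assert proto.segment_tags[80] == "recovery_probe"

    def test_unsorted_times_rejected(self):
        with pytest.raises(ValueError):
            StimulusProtocol(spike_times=(0.0, 10.0, 5.0))

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ReleaseModelParams(pv=0.0, tau_b=1.0, tau_h=1.0, tau_d=1.0)
        with pytest.raises(ValueError):
            ReleaseModelParams(pv=0.5, tau_b=-1.0, tau_h=1.0, tau_d=1.0)
        with pytest.raises(ValueError):
            ReleaseModelParams(pv=0.5, tau_b=100.0, tau_h=50.0, tau_d=1.0,
                               tau_r_init=200.0)
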