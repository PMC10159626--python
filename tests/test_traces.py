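"""Trace-processing operations against independently coded brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wormmem.datamodel import exchange_protocol
from wormmem.traces import (
    NormalizedTrace,
    bin_and_znorm,
    detect_ground_state,
    detect_ground_state_tail,
    integrate_post_switch,
    moving_average,
    normalize,
    resample_linear,
    time_derivative,
)

from oracles import (
    oracle_ground_state,
    oracle_integrate,
    oracle_moving_average,
)


class TestGroundState:
    def test_constant_trace_falls_back_to_quantile(self):
        assert detect_ground_state(np.full(50, 3.25)) == pytest.approx(3.25)

    def test_ramp_matches_oracle_exactly(self):
        trace = np.arange(1.0, 101.0)
        got = detect_ground_state(trace, kernel_frames=20, quantile=0.10)
        assert got == pytest.approx(oracle_ground_state(trace, 20, 0.10), abs=1e-12)

    def test_matches_oracle_on_many_random_traces(self, rng):
        for _ in range(200):
            n = int(rng.integers(20, 120))
            trace = rng.gamma(2.0, 50.0, size=n)
            k = int(rng.integers(1, min(n, 25)))
            q = float(rng.uniform(0.05, 0.5))
            assert detect_ground_state(trace, k, q) == pytest.approx(
                oracle_ground_state(trace, k, q), abs=1e-8
            )

    def test_short_trace_error_names_minimum(self):
        with pytest.raises(ValueError, match="kernel_frames=20"):
            detect_ground_state(np.ones(5))

    def test_tail_detector(self):
        trace = np.concatenate([np.arange(30.0), np.full(10, 2.0)])
        assert detect_ground_state_tail(trace) == pytest.approx(2.0)
        ten = np.arange(10.0)
        assert detect_ground_state_tail(ten, 10) == pytest.approx(ten.mean())
        with pytest.raises(ValueError):
            detect_ground_state_tail(np.ones(5), 10)


class TestNormalize:
    def test_gain_invariance(self):
        t = np.arange(10.0)
        f = 100 + 10 * np.sin(t)
        a = normalize(f, t, "ground_state", F_G=100.0)
        b = normalize(3.7 * f, t, "ground_state", F_G=370.0)
        np.testing.assert_allclose(a.values, b.values, rtol=1e-12)

    def test_trace_at_ground_state_is_all_ones(self):
        t = np.arange(5.0)
        out = normalize(np.full(5, 42.0), t, "ground_state", F_G=42.0)
        np.testing.assert_allclose(out.values, 1.0)

    def test_max_mode_maps_baseline_to_zero_peak_to_one(self):
        out = normalize(np.array([2.0, 4.0, 6.0]), np.arange(3.0), "max",
                        F_G=2.0, F_max=6.0)
        np.testing.assert_allclose(out.values, [0.0, 0.5, 1.0])

    @given(gain=st.floats(0.1, 100), offset=st.floats(-50, 50))
    @settings(max_examples=50, deadline=None)
    def test_max_mode_affine_invariance(self, gain, offset):
        f = np.array([10.0, 30.0, 50.0, 20.0])
        t = np.arange(4.0)
        a = normalize(f, t, "max", F_G=10.0, F_max=50.0)
        g = gain * f + offset
        b = normalize(g, t, "max", F_G=gain * 10.0 + offset, F_max=gain * 50.0 + offset)
        np.testing.assert_allclose(a.values, b.values, rtol=1e-9, atol=1e-9)

    def test_nonpositive_ground_state_rejected(self):
        with pytest.raises(ValueError, match="F_G"):
            normalize(np.ones(3), np.arange(3.0), "ground_state", F_G=0.0)


class TestResample:
    def test_native_rate_is_identity(self):
        t = np.arange(20) / 2.0
        tr = NormalizedTrace(np.sin(t), t, "ground_state", 1.0)
        (out,) = resample_linear([tr], target_rate=2.0)
        np.testing.assert_allclose(out.time, t)
        np.testing.assert_allclose(out.values, tr.values)

    def test_midpoint_interpolation(self):
        tr = NormalizedTrace([0.0, 1.0], [0.0, 1.0], "ground_state", 1.0)
        (out,) = resample_linear([tr], target_rate=2.0)
        assert out.values[1] == pytest.approx(0.5)
        assert out.time[-1] <= 1.0  # no extrapolation

    def test_mixed_rates_go_to_maximum(self):
        mk = lambda hz: NormalizedTrace(np.ones(int(10 * hz)), np.arange(int(10 * hz)) / hz,
                                        "ground_state", 1.0)
        out = resample_linear([mk(2), mk(3), mk(5)])
        for tr in out:
            assert tr.frame_rate == pytest.approx(5.0)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            resample_linear([NormalizedTrace([1.0], [0.0], "ground_state", 1.0)])


class TestDerivative:
    def test_constant_gives_zero(self):
        t = np.arange(10) / 2.0
        tr = NormalizedTrace(np.full(10, 2.0), t, "ground_state", 1.0)
        np.testing.assert_allclose(time_derivative(tr), 0.0)

    def test_linear_ramp_gives_slope(self):
        t = np.arange(50) / 5.0
        tr = NormalizedTrace(3.5 * t, t, "ground_state", 1.0)
        np.testing.assert_allclose(time_derivative(tr), 3.5, rtol=1e-9)

    def test_sine_derivative_is_cosine(self):
        t = np.arange(0, 20, 0.05)
        tr = NormalizedTrace(np.sin(t), t, "ground_state", 1.0)
        d = time_derivative(tr)
        np.testing.assert_allclose(d[1:-1], np.cos(t)[1:-1], atol=5e-4)

    def test_non_uniform_base_rejected(self):
        tr = NormalizedTrace([0, 1, 2.0], [0.0, 1.0, 3.0], "ground_state", 1.0)
        with pytest.raises(ValueError, match="resample"):
            time_derivative(tr)


class TestIntegration:
    def setup_method(self):
        self.schedule = exchange_protocol()
        self.t = np.arange(480) / 2.0  # 2 Hz over the 240 s protocol

    def test_all_ones_window_counts_samples(self):
        tr = NormalizedTrace(np.ones(480), self.t, "ground_state", 1.0)
        wins = integrate_post_switch(tr, self.schedule, window_s=10.0)
        assert len(wins) == 6
        for w in wins:
            assert w.integrated_activity == pytest.approx(20.0)

    def test_ramp_matches_loop_oracle(self):
        vals = np.linspace(0, 5, 480)
        tr = NormalizedTrace(vals, self.t, "ground_state", 1.0)
        wins = integrate_post_switch(tr, self.schedule, window_s=5.0)
        for w in wins:
            assert w.integrated_activity == pytest.approx(
                oracle_integrate(vals, self.t, w.start, 5.0), abs=1e-10
            )

    def test_additive_over_disjoint_windows(self):
        vals = np.cos(self.t / 7.0) + 2
        tr = NormalizedTrace(vals, self.t, "ground_state", 1.0)
        whole = integrate_post_switch(tr, self.schedule, window_s=10.0)
        first = integrate_post_switch(tr, self.schedule, window_s=5.0)
        for w10, w5 in zip(whole, first):
            tail = oracle_integrate(vals, self.t, w5.start + 5.0, 5.0)
            assert w10.integrated_activity == pytest.approx(
                w5.integrated_activity + tail, abs=1e-10
            )

    def test_window_exceeding_recording_names_switch(self):
        tr = NormalizedTrace(np.ones(480), self.t, "ground_state", 1.0)
        with pytest.raises(ValueError, match="switch 5"):
            integrate_post_switch(tr, self.schedule, window_s=40.0)

    def test_per_neuron_override_changes_window(self):
        tr = NormalizedTrace(np.ones(480), self.t, "ground_state", 1.0,
                             neuron_id="AWA")
        wins = integrate_post_switch(tr, self.schedule, window_s=10.0,
                                     per_neuron_overrides={"AWA": 15.0})
        assert wins[0].duration == 15.0
        assert wins[0].integrated_activity == pytest.approx(30.0)


class TestBinZnorm:
    def test_output_is_z_normalized(self, rng):
        v = rng.normal(size=100)
        out = bin_and_znorm(v, 20)
        assert out.size == 5
        assert out.mean() == pytest.approx(0.0, abs=1e-12)
        assert out.std() == pytest.approx(1.0, abs=1e-12)

    def test_bin_means_match_loop_oracle(self, rng):
        v = rng.normal(size=47)
        out = bin_and_znorm(v, 20)  # trailing 7 frames dropped
        means = [sum(v[:20]) / 20, sum(v[20:40]) / 20]
        mu = sum(means) / 2
        sd = (sum((m - mu) ** 2 for m in means) / 2) ** 0.5
        np.testing.assert_allclose(out, [(m - mu) / sd for m in means], atol=1e-12)

    def test_zero_variance_maps_to_zeros(self):
        np.testing.assert_array_equal(bin_and_znorm(np.ones(40), 20), np.zeros(2))

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            bin_and_znorm(np.ones(10), 20)


class TestMovingAverage:
    def test_matches_loop_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 60))
            k = int(rng.integers(1, 30))
            x = rng.normal(size=n)
            np.testing.assert_allclose(
                moving_average(x, k), oracle_moving_average(x, k), atol=1e-10
            )
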