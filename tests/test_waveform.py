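"""Waveform container, periodic resampling and pulsatility features."""
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pulsecomp import (
    FlowWaveform,
    InvalidInputError,
    Territory,
    UndefinedPulsatilityError,
    VesselSample,
    extract_features,
    gosling_pi,
    resample_periodic,
    velocity_index,
    velocity_series_from_flow,
)
from pulsecomp.synthetic import default_shapes

from conftest import make_sine


class TestFlowWaveform:
    def test_rejects_two_concatenated_cycles(self):
        # times reaching/exceeding T means more than one cycle was supplied
        t = np.arange(16) / 8.0  # 0 .. 1.875 with T = 1
        with pytest.raises(InvalidInputError, match="before the cycle duration"):
            FlowWaveform(t, np.ones(16), 1.0)

    @pytest.mark.parametrize(
        "times, flows, T",
        [
            (np.array([0, 0.1, 0.1, 0.3, 0.4, 0.5, 0.6, 0.7]), np.ones(8), 1.0),  # not increasing
            (np.arange(4) / 4, np.ones(4), 1.0),  # too few samples
            (np.arange(8) / 8, np.array([1, 2, 3, np.nan, 5, 6, 7, 8.0]), 1.0),
            (np.arange(8) / 8, np.ones(8), -1.0),
        ],
    )
    def test_invalid_inputs_rejected(self, times, flows, T):
        with pytest.raises(InvalidInputError):
            FlowWaveform(times, flows, T)

    def test_periodic_evaluation_wraps(self):
        w = make_sine(n=32)
        assert w(0.25 + 3.0) == pytest.approx(w(0.25), abs=1e-12)


class TestResamplePeriodic:
    def test_constant_preserved(self):
        w = FlowWaveform(np.arange(8) / 8, np.full(8, 10.0), 1.0)
        out = resample_periodic(w, 64)
        assert out.n_samples == 64
        np.testing.assert_allclose(out.flows, 10.0, atol=1e-12)

    def test_sine_dense_resample_accuracy(self):
        w = make_sine(q0=1.0, q_mean=0.0, n=32)
        out = resample_periodic(w, 256)
        exact = np.sin(2 * np.pi * out.times)
        assert np.max(np.abs(out.flows - exact)) < 1e-3

    def test_mean_preserved_under_resampling(self):
        rng = np.random.default_rng(3)
        w = make_sine(n=32)
        out = resample_periodic(w, 256)
        # trapezoidal mean of a dense evaluation of the underlying spline
        t_dense = np.linspace(0, 1, 20001)
        dense_mean = np.trapezoid(w(t_dense), t_dense)
        assert out.flows.mean() == pytest.approx(dense_mean, rel=1e-3)

    def test_invalid_n_out(self):
        w = make_sine(n=16)
        with pytest.raises(InvalidInputError):
            resample_periodic(w, 3)
        with pytest.raises(InvalidInputError):
            resample_periodic(w, 8)  # below the input sample count


class TestExtractFeatures:
    def test_analytic_sinusoid(self):
        f = extract_features(make_sine(q0=6.0, q_mean=12.0, n=128))
        assert f.q_mean == pytest.approx(12.0, rel=1e-4)
        assert f.q_syst == pytest.approx(18.0, rel=1e-3)
        assert f.q_dias == pytest.approx(6.0, rel=1e-3)
        assert f.delta_q == pytest.approx(12.0, rel=1e-3)
        assert f.pulsatility_index == pytest.approx(1.0, rel=2e-3)

    def test_constant_flow_has_no_pulsatility(self):
        w = FlowWaveform(np.arange(8) / 8, np.full(8, 10.0), 1.0)
        f = extract_features(w)
        assert f.delta_q == pytest.approx(0.0, abs=1e-12)
        assert f.pulsatility_index == pytest.approx(0.0, abs=1e-12)

    def test_nonpositive_mean_flow_signalled(self):
        w = make_sine(q0=6.0, q_mean=-12.0, n=64)
        f = extract_features(w)
        assert f.pulsatility_index is None
        with pytest.raises(UndefinedPulsatilityError):
            gosling_pi(f.delta_q, f.q_mean)

    def test_gamma_pulse_against_dense_grid_oracle(self):
        # physiological pulse shape: brute-force features on a 10^4-point grid
        shape = default_shapes()[Territory.CBF]
        u = np.arange(32) / 32
        w = FlowWaveform(u, 10.5 + 12.6 * shape.evaluate(u), 1.0)
        f = extract_features(w)
        t_dense = np.arange(10_000) / 10_000
        q_dense = 10.5 + 12.6 * shape.evaluate(t_dense)
        assert f.q_mean == pytest.approx(q_dense.mean(), rel=5e-3)
        assert f.q_syst == pytest.approx(q_dense.max(), rel=5e-3)
        assert f.q_dias == pytest.approx(q_dense.min(), rel=5e-3)

    def test_feature_convergence_in_grid_size(self):
        shape = default_shapes()[Territory.AOA]
        u = np.arange(32) / 32
        w = FlowWaveform(u * 0.9, 40 + 360 * shape.evaluate(u), 0.9)
        f256 = extract_features(w, n_grid=256)
        f1024 = extract_features(w, n_grid=1024)
        for attr in ("q_mean", "q_syst", "q_dias", "delta_q"):
            # converged to <0.1% of the pulse amplitude
            assert abs(getattr(f256, attr) - getattr(f1024, attr)) < 1e-3 * f1024.delta_q

    @given(st.floats(min_value=0.01, max_value=100.0))
    def test_pi_invariant_under_flow_scaling(self, k):
        w = make_sine(q0=4.0, q_mean=10.0, n=32)
        scaled = FlowWaveform(w.times, k * w.flows, w.cycle_duration)
        assert extract_features(scaled).pulsatility_index == pytest.approx(
            extract_features(w).pulsatility_index, rel=1e-9
        )

    @given(st.floats(min_value=-5.0, max_value=50.0))
    def test_delta_q_invariant_under_offset(self, c):
        w = make_sine(q0=4.0, q_mean=10.0, n=32)
        shifted = FlowWaveform(w.times, w.flows + c, w.cycle_duration)
        f0, f1 = extract_features(w), extract_features(shifted)
        assert f1.delta_q == pytest.approx(f0.delta_q, rel=1e-9, abs=1e-9)
        assert f1.q_mean == pytest.approx(f0.q_mean + c, rel=1e-9)


class TestVelocityIndex:
    @pytest.mark.parametrize(
        "psv, edv, expected",
        [(50.0, 8.0, 22.0), (30.0, 0.0, 10.0), (17.0, 17.0, 17.0)],
    )
    def test_values(self, psv, edv, expected):
        assert velocity_index(psv, edv) == pytest.approx(expected)

    def test_rejects_psv_below_edv(self):
        with pytest.raises(InvalidInputError):
            velocity_index(10.0, 20.0)

    def test_velocity_fallback_from_flow_and_area(self):
        w = make_sine(q0=0.0, q_mean=14.0, n=16)
        v = velocity_series_from_flow(w, mean_area_cm2=0.7)
        np.testing.assert_allclose(v, 20.0)


class TestVesselSample:
    def test_area_series_length_checked(self):
        w = make_sine(n=32)
        with pytest.raises(InvalidInputError):
            VesselSample(Territory.CBF, w, area_series=np.ones(16))

    def test_nonpositive_area_rejected(self):
        w = make_sine(n=32)
        areas = np.ones(32)
        areas[5] = 0.0
        with pytest.raises(InvalidInputError):
            VesselSample(Territory.CBF, w, area_series=areas)
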