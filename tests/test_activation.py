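"""EMG conditioning, neural-activation recursion and activation curve."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from myoadmit import (
    EnvelopeSignal,
    NeuralActivationParams,
    RawEmg,
    compute_envelope,
    muscle_activation,
    neural_activation,
    solve_activation_curve,
)
from myoadmit.exceptions import NormalizationError, SamplingRateError

FS = 1000.0


class TestEnvelope:
    def test_zero_input_gives_zero_envelope(self):
        raw = RawEmg(np.zeros(5000), FS, mvc_peak=1e-3)
        env = compute_envelope(raw)
        assert np.allclose(env.e, 0.0)

    def test_dc_is_rejected_by_band_pass(self):
        raw = RawEmg(np.ones(5000), FS, mvc_peak=1.0)
        env = compute_envelope(raw)
        assert np.all(env.e[2000:] < 1e-3)

    def test_sine_envelope_matches_rectified_mean(self):
        # Steady envelope of a full-wave-rectified sine is 2/pi of its
        # amplitude.  103 Hz (incommensurate with fs) sweeps the sample
        # phase so the discrete mean converges to the analytic value.
        t = np.arange(0, 6, 1 / FS)
        amp = 2e-3
        raw = RawEmg(amp * np.sin(2 * math.pi * 103.0 * t), FS, mvc_peak=amp)
        env = compute_envelope(raw)
        steady = env.e[3000:]
        assert abs(steady.mean() - 2 / math.pi) < 0.01

    def test_low_sampling_rate_rejected(self):
        with pytest.raises(SamplingRateError):
            compute_envelope(RawEmg(np.zeros(100), fs=900.0, mvc_peak=1.0))

    def test_zero_mvc_peak_rejected(self):
        with pytest.raises(NormalizationError):
            RawEmg(np.zeros(100), FS, mvc_peak=0.0)

    def test_shift_equivariance(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(4000) * 1e-3
        shift = 500
        pad = np.concatenate([np.zeros(2000), x])
        e1 = compute_envelope(RawEmg(pad, FS, mvc_peak=1e-3)).e
        e2 = compute_envelope(
            RawEmg(np.concatenate([np.zeros(2000 + shift), x]), FS,
                   mvc_peak=1e-3)).e
        # past the filter transients the envelope just shifts
        assert np.allclose(e1[2500:5500], e2[2500 + shift:5500 + shift],
                           atol=1e-10)


class TestNeuralActivation:
    def test_zero_in_zero_out(self):
        u = neural_activation(EnvelopeSignal(np.zeros(1000), FS))
        assert np.allclose(u, 0.0)

    def test_step_steady_state_is_recursion_fixed_point(self):
        p = NeuralActivationParams()
        e0 = 0.5
        u = neural_activation(EnvelopeSignal(np.full(5000, e0), FS), p)
        expected = p.alpha * e0 / (1.0 + p.beta1 + p.beta2)
        assert abs(u[-1] - expected) < 1e-9
        assert abs(expected / e0 - 0.99997) < 1e-4

    def test_impulse_delayed_by_electromechanical_delay(self):
        e = np.zeros(1000)
        e[100] = 1.0
        u = neural_activation(EnvelopeSignal(e, FS))
        nz = np.flatnonzero(u)
        assert nz[0] == 100 + 80  # 80 ms at 1 kHz

    def test_linearity(self):
        rng = np.random.default_rng(1)
        e1, e2 = rng.random(500), rng.random(500)
        u12 = neural_activation(EnvelopeSignal(e1 + e2, FS))
        u1 = neural_activation(EnvelopeSignal(e1, FS))
        u2 = neural_activation(EnvelopeSignal(e2, FS))
        assert np.allclose(u12, u1 + u2, atol=1e-12)

    def test_default_recursion_is_stable(self):
        assert NeuralActivationParams().is_stable()


class TestActivationCurve:
    def test_linear_limit_at_A_zero(self):
        c = solve_activation_curve(0.0)
        assert c.u0 == pytest.approx(0.3085)
        assert c.a0 == pytest.approx(0.3085)
        assert c.m == pytest.approx(1.0)
        assert c.n == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("A", [0.0, 0.01, 0.06, 0.12, 0.2, 0.3])
    def test_node_identity_and_slope_continuity(self, A):
        c = solve_activation_curve(A)
        assert abs(c.b * math.log(c.c * c.u0 + 1.0) - c.a0) < 1e-9
        assert abs(c.slope_gap()) < 1e-6
        assert abs(c.m * 1.0 + c.n - 1.0) < 1e-12
        assert 0.0 <= c.u0 < 1.0

    @pytest.mark.parametrize("A", [0.0, 0.06, 0.2, 0.3])
    def test_curve_continuous_and_nondecreasing(self, A):
        c = solve_activation_curve(A)
        u = np.linspace(0.0, 1.0, 1000)
        a = muscle_activation(u, c)
        assert np.all(np.diff(a) >= -1e-12)
        # the only candidate discontinuity is the branch switch at the
        # node: values from both sides must agree
        eps = 1e-9
        gap = abs(muscle_activation(c.u0 + eps, c)
                  - muscle_activation(c.u0 - eps, c))
        assert gap < 1e-6

    def test_negative_A_rejected(self):
        with pytest.raises(ValueError):
            solve_activation_curve(-0.05)

    def test_node_and_endpoints(self):
        c = solve_activation_curve(0.06)
        assert muscle_activation(1.0, c) == pytest.approx(1.0)
        assert muscle_activation(c.u0, c) == pytest.approx(c.a0, abs=1e-9)
        assert muscle_activation(0.0, c) == 0.0

    def test_domain_error_outside_unit_interval(self):
        c = solve_activation_curve(0.06)
        with pytest.raises(ValueError):
            muscle_activation(1.2, c)

    def test_inverse_round_trip(self):
        c = solve_activation_curve(0.06)
        for a in np.linspace(0.01, 0.99, 25):
            assert muscle_activation(c.inverse(a), c) == pytest.approx(
                a, abs=1e-9)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.floats(min_value=0.0, max_value=0.3))
    def test_curve_monotone_for_any_valid_A(self, A):
        c = solve_activation_curve(A)
        u = np.linspace(0.0, 1.0, 256)
        a = muscle_activation(u, c)
        assert np.all(np.diff(a) >= -1e-12)
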