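"""Unit and property tests for the shared signal primitives."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dne.kinematics import (
    Signal1D,
    SummaryStats,
    align_and_cc,
    asymmetry,
    derivative,
    detect_cycles,
    dominant_frequency_fft,
    path_smoothness,
    pearson_cc,
    resample_cycle,
)


class TestAsymmetry:
    @pytest.mark.parametrize(
        "fr,fl,expected",
        [(2.0, 2.0, 0.0), (3.0, 1.0, 0.5), (1.0, 0.0, 1.0), (0.4, 1.0, 3.0 / 7.0)],
    )
    def test_values(self, fr, fl, expected):
        assert asymmetry(fr, fl) == pytest.approx(expected, abs=1e-12)

    def test_undefined_when_both_zero(self):
        assert np.isnan(asymmetry(0.0, 0.0))

    @settings(max_examples=200, derandomize=True)
    @given(
        a=st.floats(0, 1e6, allow_nan=False),
        b=st.floats(1e-6, 1e6, allow_nan=False),
        c=st.floats(1e-6, 1e6, allow_nan=False),
    )
    def test_scale_invariant_and_bounded(self, a, b, c):
        v = asymmetry(a, b)
        assert 0.0 <= v <= 1.0
        assert asymmetry(c * a, c * b) == pytest.approx(v, rel=1e-9, abs=1e-9)
        assert asymmetry(b, a) == v  # symmetric in its arguments


class TestPearson:
    def test_hand_computed_example(self):
        # cov([1,2,3],[1,3,2]) = 0.5 with norms 2, 2 -> CC = 1/2
        assert pearson_cc([1, 2, 3], [1, 3, 2]) == pytest.approx(0.5, abs=1e-12)

    def test_negation_gives_minus_one(self):
        x = np.sin(np.linspace(0, 7, 50))
        assert pearson_cc(x, -x) == pytest.approx(-1.0, abs=1e-12)

    def test_constant_is_undefined(self):
        assert np.isnan(pearson_cc([1.0, 1.0, 1.0], [1, 2, 3]))

    @settings(max_examples=100, derandomize=True)
    @given(
        scale=st.floats(1e-3, 1e3),
        shift=st.floats(-1e3, 1e3),
        seed=st.integers(0, 1000),
    )
    def test_affine_invariance(self, scale, shift, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=30), rng.normal(size=30)
        base = pearson_cc(x, y)
        assert pearson_cc(scale * x + shift, y) == pytest.approx(base, abs=1e-9)
        assert pearson_cc(-x, y) == pytest.approx(-base, abs=1e-9)


class TestDetectCycles:
    def test_two_hz_raised_cosine(self):
        fps, f = 60.0, 2.0
        t = np.arange(int(15 * fps)) / fps
        sig = Signal1D(0.5 * (1 - np.cos(2 * np.pi * f * t)), fps)
        cyc = detect_cycles(sig)
        assert 28 <= cyc.n_cycles <= 30
        assert np.allclose(cyc.per_cycle_period, 0.5, atol=1 / fps + 1e-9)
        assert np.allclose(cyc.per_cycle_amplitude, 1.0, atol=0.02)

    def test_constant_signal_yields_no_cycles(self):
        cyc = detect_cycles(Signal1D(np.ones(600), 60.0))
        assert cyc.n_cycles == 0

    def test_small_ripple_does_not_split_cycles(self):
        fps = 60.0
        t = np.arange(int(15 * fps)) / fps
        clean = 0.5 * (1 - np.cos(2 * np.pi * 2 * t))
        rippled = clean + 0.02 * np.sin(2 * np.pi * 20 * t)
        c0 = detect_cycles(Signal1D(clean, fps), min_prominence_frac=0.1)
        c1 = detect_cycles(Signal1D(rippled, fps), min_prominence_frac=0.1)
        assert c1.n_cycles == c0.n_cycles
        # extrema-based frequency agrees with the FFT oracle within 2%
        f_ext = 1.0 / np.mean(c1.per_cycle_period)
        f_fft = dominant_frequency_fft(Signal1D(rippled, fps))
        assert f_ext == pytest.approx(f_fft, rel=0.02)

    @pytest.mark.parametrize("freq", [1.0, 2.0, 4.0])
    def test_fft_oracle_equivalence_clean_band(self, freq):
        fps = 60.0
        t = np.arange(int(20 * fps)) / fps
        sig = Signal1D(np.sin(2 * np.pi * freq * t), fps)
        cyc = detect_cycles(sig)
        f_ext = 1.0 / np.mean(cyc.per_cycle_period)
        assert f_ext == pytest.approx(dominant_frequency_fft(sig), rel=0.02)


class TestDerivative:
    def test_linear_ramp(self):
        fps = 60.0
        sig = Signal1D(3.0 * np.arange(300) / fps, fps)
        d = derivative(sig, 1)
        assert np.allclose(d.values[1:-1], 3.0, atol=1e-9)

    def test_peak_speed_of_raised_cosine(self):
        fps = 240.0  # fine sampling to approach the analytic max
        t = np.arange(int(10 * fps)) / fps
        sig = Signal1D(0.5 * (1 - np.cos(2 * np.pi * 2 * t)), fps)
        assert np.max(np.abs(derivative(sig, 1).values)) == pytest.approx(2 * np.pi, rel=0.02)

    def test_constant_derivative_is_zero(self):
        sig = Signal1D(np.full(100, 5.0), 60.0)
        assert np.allclose(derivative(sig, 1).values, 0.0)
        assert np.allclose(derivative(sig, 2).values, 0.0)


class TestResampleAlign:
    def test_endpoint_interpolation(self):
        assert np.allclose(resample_cycle([0.0, 1.0], 3), [0.0, 0.5, 1.0])

    def test_identity_on_own_length(self):
        v = np.sin(np.linspace(0, 3, 37))
        assert np.allclose(resample_cycle(v, 37), v)

    def test_resampled_cycles_correlate_perfectly(self):
        t = np.linspace(0, 1, 83)
        a = resample_cycle(np.sin(2 * np.pi * t), 100)
        b = resample_cycle(np.sin(2 * np.pi * np.linspace(0, 1, 59)), 100)
        assert pearson_cc(a, b) == pytest.approx(1.0, abs=1e-6)

    def test_align_identical_series(self):
        x = np.sin(np.linspace(0, 12, 100))
        lag, cc = align_and_cc(x, x)
        assert lag == 0 and cc == pytest.approx(1.0, abs=1e-12)

    def test_align_recovers_known_shift(self):
        # brute-force oracle: the true lag is 10 samples by construction
        i = np.arange(100)
        a = np.sin(2 * np.pi * i / 40)
        b = np.sin(2 * np.pi * (i - 10) / 40)
        lag, cc = align_and_cc(a, b, max_lag_frac=0.25)
        assert abs(lag) == 10
        assert cc > 0.999

    def test_uncorrelated_noise_stays_bounded(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(size=100), rng.normal(size=100)
        lag, cc = align_and_cc(a, b, max_lag_frac=0.25)
        assert abs(lag) <= 25
        assert -1.0 <= cc <= 1.0


class TestPathSmoothness:
    def test_parabola_is_smooth(self):
        # sampled uniformly in x, i.e. at non-constant speed: parameter
        # correction must still recover the generating arc
        x = np.linspace(0, 1, 80)
        pts = np.column_stack([x, 0.3 * x**2 - 0.5 * x])
        assert path_smoothness(pts) == pytest.approx(1.0, abs=1e-4)

    def test_straight_line_is_smooth(self):
        x = np.linspace(0, 2, 50)
        assert path_smoothness(np.column_stack([x, 3 * x])) == pytest.approx(1.0, abs=1e-9)

    def test_zigzag_matches_arc_length_oracle(self):
        # perpendicular zig-zag on a parabola: the expected ratio is computed
        # directly from the generated geometry
        x = np.linspace(0, 1, 81)
        y = 0.5 * x**2
        base = np.column_stack([x, y])
        tang = np.gradient(base, axis=0)
        normal = np.column_stack([-tang[:, 1], tang[:, 0]])
        normal /= np.linalg.norm(normal, axis=1)[:, None]
        zig = base + 0.05 * ((-1.0) ** np.arange(81))[:, None] * normal
        ps = path_smoothness(zig)
        seglen = lambda p: np.sum(np.linalg.norm(np.diff(p, axis=0), axis=1))
        oracle = seglen(zig) / seglen(base)
        assert ps > 1.05
        assert ps == pytest.approx(oracle, rel=0.02)

    def test_degenerate_points_undefined(self):
        assert np.isnan(path_smoothness(np.zeros((10, 2))))

    def test_never_below_one(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            pts = rng.normal(size=(30, 2)).cumsum(axis=0)
            ps = path_smoothness(pts)
            assert ps >= 1.0 - 1e-6


class TestSummaryStats:
    def test_undefined_markers_for_small_n(self):
        s = SummaryStats.from_values([2.0])
        assert s.mean == 2.0 and np.isnan(s.std)
        empty = SummaryStats.from_values([])
        assert np.isnan(empty.mean) and np.isnan(empty.median)
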