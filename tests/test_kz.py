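import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import kzepi as kz
from kzepi import MonthlyTimeSeries
from kzepi.errors import InvalidParameterError

from conftest import sinusoid_series


class TestWindows:
    @pytest.mark.parametrize("m", [1, 3, 13])
    def test_uniform_weights(self, m):
        w = kz.uniform_window(m)
        assert np.allclose(w.weights, 1.0 / m)
        assert w.weights.sum() == pytest.approx(1.0, abs=1e-12)
        assert w.center_offset == m // 2

    @pytest.mark.parametrize("m", [0, 2, 12, -3])
    def test_uniform_rejects_even_or_nonpositive(self, m):
        with pytest.raises(InvalidParameterError):
            kz.uniform_window(m)

    def test_modified_13_weights(self):
        w = kz.modified_13_window()
        assert w.weights[0] == pytest.approx(1 / 24)
        assert w.weights[-1] == pytest.approx(1 / 24)
        assert np.allclose(w.weights[1:-1], 1 / 12)

    def test_modified_13_equals_12x2_convolution(self):
        # oracle: direct convolution of uniform 12-point and 2-point windows
        oracle = np.convolve(np.full(12, 1 / 12), np.full(2, 0.5))
        assert np.allclose(kz.modified_13_window().weights, oracle, atol=1e-15)


class TestConvolveOnce:
    def test_constant_series_is_preserved(self):
        s = MonthlyTimeSeries("1990-01", np.full(40, 7.25))
        for boundary in ("trim", "shrink"):
            out = kz.convolve_once(s, kz.modified_13_window(), boundary)
            assert np.allclose(out.values, 7.25)

    def test_impulse_response_equals_weights(self):
        v = np.zeros(21)
        v[10] = 1.0
        out = kz.convolve_once(
            MonthlyTimeSeries("1990-01", v), kz.uniform_window(3), "trim"
        )
        # output index 9 is input month 10 (anchor advanced by 1)
        assert out.start == MonthlyTimeSeries("1990-02", [0]).start
        assert np.allclose(out.values[8:11], 1 / 3)
        assert np.allclose(np.delete(out.values, [8, 9, 10]), 0.0)

    def test_symmetric_window_passes_linear_ramp(self):
        i = np.arange(60.0)
        ramp = MonthlyTimeSeries("1990-01", 2.0 + 0.5 * i)
        out = kz.convolve_once(ramp, kz.modified_13_window(), "trim")
        assert np.allclose(out.values, 2.0 + 0.5 * np.arange(6, 54), atol=1e-10)

    def test_trim_too_short_raises(self):
        with pytest.raises(InvalidParameterError):
            kz.convolve_once(
                MonthlyTimeSeries("1990-01", np.ones(5)), kz.modified_13_window(), "trim"
            )

    def test_gap_propagates_under_trim_renormalizes_under_shrink(self):
        v = np.ones(30)
        v[15] = np.nan
        s = MonthlyTimeSeries("1990-01", v)
        trimmed = kz.convolve_once(s, kz.uniform_window(3), "trim")
        assert np.isnan(trimmed.values[14])  # windows touching the gap
        shrunk = kz.convolve_once(s, kz.uniform_window(3), "shrink")
        assert not np.isnan(shrunk.values).any()
        assert np.allclose(shrunk.values, 1.0)  # renormalised over the rest


class TestKZFilter:
    def test_double_pass_impulse_weights(self):
        v = np.zeros(21)
        v[10] = 1.0
        out = kz.kz_filter(MonthlyTimeSeries("1990-01", v), kz.uniform_window(3), 2)
        center = out.index_of("1990-11")
        got = out.values[center - 2 : center + 3]
        assert np.allclose(got, np.array([1, 2, 3, 2, 1]) / 9.0, atol=1e-14)

    def test_annual_sinusoid_annihilated(self):
        s = sinusoid_series(12, 600)
        out = kz.kz_filter(s, kz.modified_13_window(), 2)
        assert np.max(np.abs(out.values)) < 1e-10

    @pytest.mark.parametrize("period", [12, 6, 4, 3, 12 / 5, 2])
    def test_all_seasonal_harmonics_killed_long_cycle_retained(self, period):
        harmonic = kz.kz_filter(sinusoid_series(period, 800), kz.modified_13_window(), 2)
        assert np.max(np.abs(harmonic.values)) < 1e-8
        solar = kz.kz_filter(sinusoid_series(132, 800), kz.modified_13_window(), 2)
        assert np.max(np.abs(solar.values)) > 0.95

    @given(
        st.integers(min_value=30, max_value=200),
        st.integers(min_value=1, max_value=3),
        st.sampled_from([3, 5, 13]),
        st.integers(min_value=0, max_value=2**31 - 1),
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_iteration_equals_self_convolved_window(self, n, k, m, seed):
        """KZ(k) == k repeated passes == one pass with the k-fold window."""
        window = kz.uniform_window(m) if m != 13 else kz.modified_13_window()
        if n < k * (m - 1) + 1:
            return
        rng = np.random.default_rng(seed)
        s = MonthlyTimeSeries("1950-01", rng.normal(size=n))
        via_filter = kz.kz_filter(s, window, k)
        via_repeat = s
        for _ in range(k):
            via_repeat = kz.convolve_once(via_repeat, window, "trim")
        via_big = kz.convolve_once(s, window.self_convolved(k), "trim")
        assert via_filter == via_repeat or np.allclose(
            via_filter.values, via_repeat.values, atol=1e-10
        )
        assert via_filter.start == via_big.start
        assert np.allclose(via_filter.values, via_big.values, atol=1e-10)


class TestGain:
    def test_unit_gain_at_zero_frequency(self):
        for window in (kz.uniform_window(5), kz.modified_13_window()):
            assert kz.kz_gain(window, 3, 0.0) == pytest.approx(1.0, abs=1e-14)

    def test_modified_13_zero_at_annual_frequency(self):
        assert kz.kz_gain(kz.modified_13_window(), 2, 1 / 12) < 1e-30

    def test_matches_numeric_dft_of_weights(self):
        w = kz.modified_13_window()
        f = 1 / 132
        j = np.arange(13) - 6
        dft = abs(np.sum(w.weights * np.exp(-2j * np.pi * f * j)))
        assert kz.kz_gain(w, 2, f) == pytest.approx(dft**2, abs=1e-12)

    def test_closed_form_for_modified_13(self):
        w = kz.modified_13_window()
        for f in (0.01, 0.05, 1 / 132, 0.31):
            closed = (
                abs(np.sin(12 * np.pi * f) / (12 * np.sin(np.pi * f)))
                * abs(np.cos(np.pi * f))
            ) ** 2
            assert kz.kz_gain(w, 2, f) == pytest.approx(closed, abs=1e-12)

    @pytest.mark.parametrize("f", [-0.01, 0.51])
    def test_rejects_out_of_band_frequency(self, f):
        with pytest.raises(InvalidParameterError):
            kz.kz_gain(kz.uniform_window(3), 1, f)

    @given(st.floats(min_value=0.005, max_value=0.45), st.integers(1, 3))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_empirical_attenuation_matches_analytic_gain(self, f, k):
        s = sinusoid_series(1 / f, 900)
        out = kz.kz_filter(s, kz.modified_13_window(), k)
        # empirical amplitude via projection onto the quadrature pair
        idx = np.arange(len(out)) + (out.start - s.start).n
        basis = np.column_stack(
            [np.sin(2 * np.pi * f * idx), np.cos(2 * np.pi * f * idx)]
        )
        coef, *_ = np.linalg.lstsq(basis, out.values, rcond=None)
        assert np.hypot(*coef) == pytest.approx(
            kz.kz_gain(kz.modified_13_window(), k, f), abs=1e-6
        )
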