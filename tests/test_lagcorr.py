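import math

import numpy as np
import pytest

import kzepi as kz
from kzepi import MonthlyTimeSeries
from kzepi.errors import EmptyInputError, InsufficientOverlapError, InvalidParameterError
from kzepi.lagcorr import LagCorrelationProfile, LatencyCandidate

from conftest import sinusoid_series


def naive_lagged_pearson(x: MonthlyTimeSeries, y: MonthlyTimeSeries, lag: int):
    """Brute-force oracle: build the pair list month-by-month from the
    calendars, then a two-pass Pearson formula."""
    xs = {str(p): v for p, v in zip(x.periods(), x.values)}
    pairs = []
    for p, yv in zip(y.periods(), y.values):
        xp = str(p - lag)
        if xp in xs and not math.isnan(xs[xp]) and not math.isnan(yv):
            pairs.append((xs[xp], yv))
    if len(pairs) < 3:
        return None
    xa = [a for a, _ in pairs]
    ya = [b for _, b in pairs]
    mx, my = sum(xa) / len(xa), sum(ya) / len(ya)
    sxy = sum((a - mx) * (b - my) for a, b in pairs)
    sxx = sum((a - mx) ** 2 for a in xa)
    syy = sum((b - my) ** 2 for b in ya)
    return sxy / math.sqrt(sxx * syy), len(pairs)


class TestCrossCorrelationAt:
    def test_copy_correlates_perfectly_at_zero_lag(self):
        x = sinusoid_series(132, 300)
        r, n = kz.cross_correlation_at(x, x, 0)
        assert r == pytest.approx(1.0, abs=1e-12)
        assert n == 300

    def test_shifted_copy_recovered_at_shift(self):
        x = sinusoid_series(132, 600, start=(1900, 1))
        y = MonthlyTimeSeries((1902, 1), x.values[:-24])  # same values, 24 later
        r, _ = kz.cross_correlation_at(x, y, 24)
        assert r == pytest.approx(1.0, abs=1e-10)

    def test_negated_copy_gives_minus_one(self):
        x = sinusoid_series(60, 200)
        y = x.with_values(-x.values)
        r, _ = kz.cross_correlation_at(x, y, 0)
        assert r == pytest.approx(-1.0, abs=1e-12)

    def test_insufficient_overlap_raises(self):
        x = MonthlyTimeSeries("1990-01", np.arange(10.0))
        y = MonthlyTimeSeries("1990-09", np.arange(4.0) ** 2)
        with pytest.raises(InsufficientOverlapError):
            kz.cross_correlation_at(x, y, 15)

    def test_matches_bruteforce_oracle_with_offsets_and_gaps(self):
        rng = np.random.default_rng(99)
        for trial in range(30):
            nx, ny = rng.integers(30, 120, 2)
            x = MonthlyTimeSeries((1950, 1), rng.normal(size=nx))
            start_y = (1950 + int(rng.integers(0, 5)), int(rng.integers(1, 13)))
            yv = rng.normal(size=ny)
            yv[rng.integers(0, ny, 3)] = np.nan  # sprinkle gaps
            y = MonthlyTimeSeries(start_y, yv)
            lag = int(rng.integers(0, 40))
            expected = naive_lagged_pearson(x, y, lag)
            if expected is None:
                continue
            r, n = kz.cross_correlation_at(x, y, lag)
            assert n == expected[1]
            assert r == pytest.approx(expected[0], abs=1e-12)


class TestProfile:
    def test_periodic_signal_echoes_at_multiples_of_period(self):
        x = sinusoid_series(132, 900, start=(1900, 1))
        t0 = 24
        y = MonthlyTimeSeries((1900 + 40, 1), x.values[480 - t0 : 840 - t0])
        profile = kz.ccf_profile(x, y, 420)
        cands = kz.find_latency_candidates(profile, 0, 35)
        lags = [c.lag_months for c in cands if c.r > 0.99]
        assert lags == [t0, t0 + 132, t0 + 264]

    def test_white_noise_profile_stays_small(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = MonthlyTimeSeries((1950, 1), rng.normal(size=412))
            y = MonthlyTimeSeries((1958, 5), rng.normal(size=312))
            profile = kz.ccf_profile(x, y, 100)
            assert np.abs(profile.r).max() < 0.3

    def test_symmetry_at_zero_lag(self):
        rng = np.random.default_rng(1)
        x = MonthlyTimeSeries("1950-01", rng.normal(size=100))
        y = MonthlyTimeSeries("1950-01", rng.normal(size=100))
        assert kz.cross_correlation_at(x, y, 0)[0] == pytest.approx(
            kz.cross_correlation_at(y, x, 0)[0], abs=1e-14
        )

    def test_overlap_count_reported_per_lag(self):
        x = MonthlyTimeSeries("1950-01", np.random.default_rng(2).normal(size=50))
        y = MonthlyTimeSeries("1952-01", np.random.default_rng(3).normal(size=50))
        profile = kz.ccf_profile(x, y, 40)
        # once the lag exhausts x's 24-month lead, overlap shrinks 1-for-1
        assert profile.n[0] == 26
        assert profile.n[24] == 50
        assert profile.n[30] == 44


class TestCandidates:
    def test_triangular_profile_yields_apex(self):
        r = np.concatenate([np.linspace(0, 1, 6), np.linspace(1, 0, 6)[1:]])
        profile = LagCorrelationProfile(np.arange(11), r, np.full(11, 100))
        cands = kz.find_latency_candidates(profile, 0, 5)
        assert [c.lag_months for c in cands] == [5]

    def test_plateau_collapses_to_first_lag(self):
        r = np.array([0.1, 0.5, 0.5, 0.5, 0.2, 0.1])
        profile = LagCorrelationProfile(np.arange(6), r, np.full(6, 50))
        cands = kz.find_latency_candidates(profile, 0, 1)
        assert [c.lag_months for c in cands] == [1]

    def test_lag_years_rounded_to_one_decimal(self):
        r = np.array([0.0, 0.9, 0.0])
        profile = LagCorrelationProfile(np.array([505, 506, 507]), r, np.full(3, 288))
        (cand,) = kz.find_latency_candidates(profile, 0, 70)
        assert cand.lag_years == 42.2  # 506/12 = 42.17

    def test_window_bounds_filter_candidates(self):
        r = np.array([0.0, 0.8, 0.0, 0.9, 0.0])
        profile = LagCorrelationProfile(np.array([0, 12, 24, 240, 260]), r, np.full(5, 99))
        cands = kz.find_latency_candidates(profile, 0.5, 10)
        assert [c.lag_months for c in cands] == [12]
        with pytest.raises(InvalidParameterError):
            kz.find_latency_candidates(profile, 50, 40)

    def test_default_scenario_recovers_42_2_years(self, filtered_pair):
        xf, yf = filtered_pair
        profile = kz.ccf_profile(xf, yf, 840)
        cands = kz.find_latency_candidates(profile, 0, 70)
        best = kz.best_latency(cands)
        assert best.lag_years == pytest.approx(42.2, abs=0.5)
        assert best.r == max(c.r for c in cands)


class TestBestLatency:
    def test_singleton_and_argmax(self):
        a = LatencyCandidate(120, 10.0, 0.34, 288)
        b = LatencyCandidate(506, 42.2, 0.68, 288)
        c = LatencyCandidate(628, 52.3, 0.51, 288)
        assert kz.best_latency([a]) is a
        assert kz.best_latency([a, b, c]).lag_months == 506

    def test_tie_reports_earlier_lag_and_metadata(self):
        a = LatencyCandidate(120, 10.0, 0.6, 288)
        b = LatencyCandidate(240, 20.0, 0.6, 288)
        best = kz.best_latency([b, a])
        assert best.lag_months == 120
        assert best.tied_lags == (240,)

    def test_empty_raises(self):
        with pytest.raises(EmptyInputError):
            kz.best_latency([])
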