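"""Windowed lagged cross-correlation: oracle equivalence and properties."""

import numpy as np
import pytest

from dyadsync.core import DataError, WindowedCrossCorrelation
from dyadsync.preprocessing import plan_windows
from dyadsync.synchrony import (
    lag_grid,
    summarize_synchrony,
    windowed_crosscorr,
)

from conftest import make_uniform


def brute_force_wcc(x, y, valid_x, valid_y, bounds, lags_samp, n_min):
    """Independent double-loop reference implementation."""
    out = np.full((len(bounds), len(lags_samp)), np.nan)
    for wi, (s0, s1) in enumerate(bounds):
        for li, k in enumerate(lags_samp):
            xs, ys = [], []
            for t in range(s0, s1):
                u = t + k
                if s0 <= u < s1 and valid_x[t] and valid_y[u]:
                    xs.append(x[t])
                    ys.append(y[u])
            if len(xs) >= max(n_min, 2):
                xs, ys = np.array(xs), np.array(ys)
                if xs.std() > 0 and ys.std() > 0:
                    out[wi, li] = np.corrcoef(xs, ys)[0, 1]
    return out


def test_matches_brute_force_oracle_exactly():
    rng = np.random.default_rng(42)
    for trial in range(8):
        n = int(rng.integers(150, 500))
        x = rng.normal(size=n)
        y = 0.5 * x + rng.normal(size=n)
        vx = rng.random(n) > 0.1
        vy = rng.random(n) > 0.1
        sx = make_uniform(x, 10.0, vx)
        sy = make_uniform(y, 10.0, vy)
        plan = plan_windows(sx, n / 2 / 10.0, min_valid_fraction=0.5)
        wcc = windowed_crosscorr(sx, sy, plan, max_lag_s=1.0, n_min=10)
        ref = brute_force_wcc(x, y, vx, vy, plan.bounds[plan.kept_indices],
                              np.arange(-10, 11), 10)
        np.testing.assert_allclose(wcc.r, ref, atol=1e-9, equal_nan=True)


def test_identical_series_correlate_perfectly_at_zero_lag():
    rng = np.random.default_rng(0)
    x = make_uniform(rng.normal(size=1000), 10.0)
    plan = plan_windows(x, 50.0)
    wcc = windowed_crosscorr(x, x, plan, max_lag_s=1.0)
    zero = np.flatnonzero(wcc.lags_s == 0)[0]
    np.testing.assert_allclose(wcc.r[:, zero], 1.0, atol=1e-12)


def test_pure_shift_recovers_delay_with_unit_correlation():
    rng = np.random.default_rng(1)
    base = np.cumsum(rng.normal(size=1205))
    x = base[:1200]
    y = np.concatenate([base[:5] * 0 + base[0], base[:1195]])  # y delayed 0.5 s
    sx, sy = make_uniform(x, 10.0), make_uniform(y, 10.0)
    plan = plan_windows(sx, 60.0)
    wcc = windowed_crosscorr(sx, sy, plan, max_lag_s=1.0)
    profile = summarize_synchrony(wcc).profile
    peak_lag = wcc.lags_s[np.nanargmax(profile)]
    assert peak_lag == pytest.approx(0.5)
    assert np.nanmax(profile) > 0.999


def test_swapping_series_reflects_lag_axis():
    rng = np.random.default_rng(2)
    x = make_uniform(rng.normal(size=600), 10.0)
    y = make_uniform(rng.normal(size=600), 10.0)
    plan = plan_windows(x, 30.0)
    fwd = windowed_crosscorr(x, y, plan, max_lag_s=1.0, n_min=10)
    rev = windowed_crosscorr(y, x, plan, max_lag_s=1.0, n_min=10)
    np.testing.assert_allclose(fwd.r, rev.r[:, ::-1], atol=1e-9, equal_nan=True)


def test_shift_equivariance_by_one_lag_step():
    rng = np.random.default_rng(3)
    base = np.cumsum(rng.normal(size=1300))
    x = make_uniform(base[:1200], 10.0)
    y0 = make_uniform(base[2:1202], 10.0)
    y1 = make_uniform(base[1:1201], 10.0)  # delayed one extra step
    plan = plan_windows(x, 60.0)
    p0 = summarize_synchrony(windowed_crosscorr(x, y0, plan, 1.0)).profile
    p1 = summarize_synchrony(windowed_crosscorr(x, y1, plan, 1.0)).profile
    assert (np.nanargmax(p1) - np.nanargmax(p0)) == 1


def test_independent_noise_mean_near_zero():
    rng = np.random.default_rng(4)
    x = make_uniform(rng.normal(size=10000), 10.0)
    y = make_uniform(rng.normal(size=10000), 10.0)
    plan = plan_windows(x, 100.0)
    wcc = windowed_crosscorr(x, y, plan, max_lag_s=1.0)
    grand = np.nanmean(wcc.r)
    assert abs(grand) < 3 / np.sqrt(10 * 1000)


def test_correlations_bounded_and_small_overlap_missing():
    rng = np.random.default_rng(5)
    x = make_uniform(rng.normal(size=300), 10.0)
    y = make_uniform(rng.normal(size=300), 10.0)
    plan = plan_windows(x, 30.0)
    wcc = windowed_crosscorr(x, y, plan, max_lag_s=5.0, n_min=280)
    finite = np.isfinite(wcc.r)
    assert np.all(np.abs(wcc.r[finite]) <= 1.0)
    # |lag| > 2 s leaves < 280 overlapping samples in a 30-s window
    assert np.isnan(wcc.r[:, np.abs(wcc.lags_s) > 2.0]).all()


def test_rate_mismatch_rejected():
    x = make_uniform(np.zeros(100), 10.0)
    y = make_uniform(np.zeros(100), 30.0)
    with pytest.raises(DataError):
        windowed_crosscorr(x, y, plan_windows(x, 5.0), 1.0)


class TestSummaries:
    def _wcc(self, matrix, max_lag=0.1):
        matrix = np.asarray(matrix, dtype=float)
        lags = lag_grid(max_lag, 0.1)[: matrix.shape[1]]
        return WindowedCrossCorrelation(
            lags, matrix, np.full(matrix.shape, 100, int),
            np.arange(matrix.shape[0]),
        )

    def test_arithmetic_example(self):
        s = summarize_synchrony(self._wcc([[0.2, -0.4], [0.6, -0.2]]))
        assert s.mean_r == pytest.approx(0.05)
        assert s.abs_mean_r == pytest.approx(0.35)
        assert s.nonneg_mean_r == pytest.approx(0.40)
        assert s.max_r == pytest.approx(0.6)
        assert s.abs_max_r == pytest.approx(0.6)

    def test_constant_matrix(self):
        s = summarize_synchrony(self._wcc([[0.3, 0.3], [0.3, 0.3]]))
        for v in (s.mean_r, s.abs_mean_r, s.nonneg_mean_r, s.max_r, s.abs_max_r):
            assert v == pytest.approx(0.3)

    def test_abs_max_keeps_sign_of_largest_magnitude(self):
        s = summarize_synchrony(self._wcc([[-0.8, 0.1]]))
        assert s.abs_max_r == pytest.approx(-0.8)
        assert s.max_r == pytest.approx(0.1)

    def test_empty_result_is_missing_not_zero(self):
        s = summarize_synchrony(self._wcc(np.empty((0, 2))))
        assert np.isnan(s.mean_r) and np.isnan(s.max_r)

    def test_invariant_orderings(self):
        rng = np.random.default_rng(6)
        s = summarize_synchrony(self._wcc(rng.uniform(-1, 1, (4, 2))))
        assert s.max_r >= s.mean_r
        assert s.abs_mean_r >= abs(s.mean_r)


def test_lag_grid_sizes_match_protocol():
    assert len(lag_grid(5.0, 0.1)) == 101
    assert len(lag_grid(1.0, 0.1)) == 21
    grid = lag_grid(5.0, 0.1)
    np.testing.assert_allclose(grid, -grid[::-1], atol=1e-12)
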