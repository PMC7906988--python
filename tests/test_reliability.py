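"""Variance-mean analysis, total-least-squares power-law fits, rate
summaries."""

import dataclasses

import numpy as np
import pytest

import placecode as pc
from placecode.errors import InsufficientDataError
from placecode.ratemap import LapRateMatrix


def lapmat_from_rates(rate, occupancy=None):
    rate = np.asarray(rate, dtype=float)
    occ = np.ones_like(rate) if occupancy is None else occupancy
    edges = np.arange(rate.shape[1] + 1) * 2.0
    return LapRateMatrix(rate, rate, occ, edges, np.arange(rate.shape[0]))


def grid_search_tls(x, y, n_grid=2001):
    """Brute-force oracle: minimize mean squared orthogonal distance over a
    grid of line angles, refined around the best angle (the intercept is
    optimal through the centroid for any slope)."""
    xc, yc = x - x.mean(), y - y.mean()

    def loss(phi):
        slope = np.tan(phi)
        return ((yc - slope * xc) ** 2 / (1 + slope ** 2)).mean()

    lo, hi = -np.pi / 2 + 1e-6, np.pi / 2 - 1e-6
    for _ in range(3):   # three refinement stages: ~1e-9 rad resolution
        grid = np.linspace(lo, hi, n_grid)
        losses = [loss(phi) for phi in grid]
        k = int(np.argmin(losses))
        step = grid[1] - grid[0]
        lo, hi = grid[k] - 2 * step, grid[k] + 2 * step
    slope = np.tan(grid[k])
    intercept = y.mean() - slope * x.mean()
    return slope, intercept


class TestVarianceMean:
    def test_identical_laps_have_zero_variance(self):
        rate = np.tile(np.linspace(1, 5, 10), (6, 1))
        mean, var = pc.variance_mean_relation(lapmat_from_rates(rate))
        assert np.allclose(var, 0.0)
        assert np.allclose(mean, np.linspace(1, 5, 10))

    def test_amplitude_doubling_scales_mean_2x_variance_4x(self):
        rng = np.random.default_rng(0)
        rate = rng.poisson(3.0, (40, 20)).astype(float)
        m1, v1 = pc.variance_mean_relation(lapmat_from_rates(rate))
        m2, v2 = pc.variance_mean_relation(lapmat_from_rates(2.0 * rate))
        assert np.allclose(m2, 2.0 * m1)
        assert np.allclose(v2, 4.0 * v1)

    def test_sparse_bins_excluded(self):
        rate = np.full((5, 4), np.nan)
        rate[:, 0] = 1.0
        rate[0, 1] = 2.0      # visited on a single lap: variance undefined
        mean, var = pc.variance_mean_relation(lapmat_from_rates(rate))
        assert mean.size == 1

    def test_single_lap_rejected(self):
        with pytest.raises(InsufficientDataError):
            pc.variance_mean_relation(lapmat_from_rates(np.ones((1, 5))))


class TestPowerLawTLS:
    def test_noiseless_recovery_exact(self):
        x = np.linspace(0.5, 8.0, 30)
        y = 2.0 * x ** 1.5
        fit = pc.fit_power_law_tls(x, y)
        assert fit.beta == pytest.approx(1.5, abs=1e-9)
        assert fit.a == pytest.approx(2.0, abs=1e-9)
        assert fit.residual < 1e-12

    def test_matches_grid_search_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            x = rng.uniform(0.2, 5.0, 15)
            y = 1.3 * x ** 1.8 * np.exp(rng.normal(0, 0.3, 15))
            fit = pc.fit_power_law_tls(x, y)
            slope, intercept = grid_search_tls(np.log(x), np.log(y))
            assert fit.beta == pytest.approx(slope, abs=1e-3)
            assert np.log(fit.a) == pytest.approx(intercept, abs=1e-3)

    def test_tls_unbiased_where_ols_attenuates(self):
        # equal-variance log-space noise on both axes: OLS on y|x shrinks
        # the slope toward zero, TLS does not
        rng = np.random.default_rng(2)
        slope_true = 1.5
        tls_slopes, ols_slopes = [], []
        for _ in range(100):
            x_true = rng.uniform(0, 3, 60)
            x = x_true + rng.normal(0, 0.4, 60)
            y = slope_true * x_true + 1.0 + rng.normal(0, 0.4, 60)
            fit = pc.fit_power_law_tls(np.exp(x), np.exp(y))
            tls_slopes.append(fit.beta)
            ols_slopes.append(np.polyfit(x, y, 1)[0])
        assert abs(np.mean(tls_slopes) - slope_true) < 0.1
        assert np.mean(ols_slopes) < slope_true - 0.2

    def test_amplitude_scaling_moves_intercept_not_slope(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0.5, 4.0, 25)
        y = 0.8 * x ** 1.2 * np.exp(rng.normal(0, 0.2, 25))
        base = pc.fit_power_law_tls(x, y)
        # amplitude scaling by c multiplies the mean by c and variance by c^2
        c = 3.0
        scaled = pc.fit_power_law_tls(c * x, c ** 2 * y)
        assert scaled.beta == pytest.approx(base.beta, abs=1e-9)

    def test_too_few_points_rejected(self):
        with pytest.raises(InsufficientDataError):
            pc.fit_power_law_tls([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(InsufficientDataError):
            pc.fit_power_law_tls(np.ones(10), np.ones(10))


class TestRateSummary:
    def make_session(self, activity):
        from placecode.behavior import Trajectory

        t = np.arange(0, 100, 0.01)
        r = 137.5
        ang = 100.0 * t / r
        traj = Trajectory(t=t, x=r * np.cos(ang), y=r * np.sin(ang))
        return pc.session_from_trajectory(traj, activity, 30.0)

    def test_one_event_per_second_train(self):
        n = 2900
        act = np.zeros((n, 1))
        act[::30, 0] = 0.7     # one event every second of frames
        sess = self.make_session(act)
        rates = pc.cell_rates(sess)
        assert rates["event_rate"][0] == pytest.approx(1.0, rel=0.05)

    def test_unit_amplitudes_make_rates_equal(self):
        rng = np.random.default_rng(4)
        act = (rng.random((2900, 3)) < 0.03).astype(float)
        sess = self.make_session(act)
        rates = pc.cell_rates(sess)
        assert np.allclose(rates["event_rate"], rates["activity_rate"])

    def test_lognormal_ci_covers_true_mean(self):
        # the log-scale interval covers the true log-normal mean ~90% of
        # the time
        from placecode.reliability import lognormal_mean_ci

        rng = np.random.default_rng(5)
        mu, sigma, n = -0.5, 0.8, 500
        true_mean = np.exp(mu + sigma ** 2 / 2)
        hits = 0
        reps = 400
        for _ in range(reps):
            lo, hi = lognormal_mean_ci(rng.lognormal(mu, sigma, n), 0.90)
            hits += lo <= true_mean <= hi
        assert 0.86 <= hits / reps <= 0.94

    def test_reliability_table_export(self, short_track_session):
        from placecode.reliability import reliability_table

        sess, gt = short_track_session
        table = reliability_table(sess, (gt["kind"] == "place").to_numpy())
        assert list(table.columns) == ["cell", "group", "event_rate",
                                       "activity_rate", "a", "beta",
                                       "n_points"]
        fitted = table["n_points"] > 0
        assert np.isfinite(table.loc[fitted, "beta"]).all()

    def test_group_summary_structure(self, short_track_session):
        sess, gt = short_track_session
        summary = pc.rate_summary(sess, (gt["kind"] == "place").to_numpy())
        assert set(summary.group_event_rate["group"]) == {"place", "non_place"}
        place_row = summary.group_activity_rate.set_index("group").loc["place"]
        assert place_row["ci_low"] <= place_row["ci_high"]
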