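"""Rate maps: binning, smoothing, normalization, per-lap conservation."""

import dataclasses

import numpy as np
import pytest

import placecode as pc
from placecode.behavior import Trajectory
from placecode.errors import EmptyMapError
from placecode.ratemap import (
    circular_boxcar,
    linear_bin_edges,
    masked_gaussian_smooth,
    square_grid,
)


def uniform_track_session(activity_fn, n_laps=4, frame_rate=30.0,
                          circumference_cm=86.0):
    """Constant-speed track session; activity_fn(n_frames, lin_pos_cm)."""
    params = pc.AnalysisParams(circumference_cm=circumference_cm)
    r = circumference_cm * 10 / (2 * np.pi)
    speed = 100.0
    duration = n_laps * circumference_cm * 10 / speed
    t = np.arange(0, duration, 0.01)
    ang = speed * t / r
    traj = Trajectory(t=t, x=r * np.cos(ang), y=r * np.sin(ang))
    n_frames = int(duration * frame_rate) - 2
    lin = np.mod(speed / 10.0 * (np.arange(n_frames) / frame_rate),
                 circumference_cm)
    activity = activity_fn(n_frames, lin)
    sess = pc.session_from_trajectory(traj, activity, frame_rate, params)
    return sess, params


class TestSmoothers:
    def test_boxcar_delta_response_wraps(self):
        v = np.zeros(10)
        v[0] = 1.0
        out = circular_boxcar(v, 3)
        assert out[0] == pytest.approx(1 / 3)
        assert out[1] == pytest.approx(1 / 3)
        assert out[-1] == pytest.approx(1 / 3)   # wraps to the last bin
        assert np.allclose(out[2:-1], 0.0)

    def test_boxcar_preserves_mass(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(0, 5, 43)
        assert circular_boxcar(v, 3).sum() == pytest.approx(v.sum(), rel=1e-12)

    def test_boxcar_keeps_missing_bins_missing(self):
        v = np.array([1.0, np.nan, 2.0, 3.0])
        out = circular_boxcar(v, 3)
        assert np.isnan(out[1])
        assert np.isfinite(out[[0, 2, 3]]).all()

    def test_gaussian_mass_preserved_on_fully_valid_grid(self):
        rng = np.random.default_rng(1)
        v = rng.uniform(0, 2, (17, 17))
        valid = np.ones_like(v, dtype=bool)
        out = masked_gaussian_smooth(v, valid, 1.5)
        assert out.sum() == pytest.approx(v.sum(), rel=1e-9)

    def test_gaussian_bump_centered_at_event_bin(self):
        v = np.zeros((17, 17))
        v[8, 5] = 1.0
        out = masked_gaussian_smooth(v, np.ones_like(v, bool), 1.5)
        assert np.unravel_index(np.nanargmax(out), out.shape) == (8, 5)


class TestRateMap1D:
    def test_uniform_activity_normalizes_to_one(self):
        sess, params = uniform_track_session(
            lambda n, lin: np.ones((n, 1))
        )
        rm = pc.rate_map_1d(sess, 0, params)
        assert np.allclose(rm.normalized_rate[rm.valid], 1.0)

    def test_event_rate_equals_raw_rate_for_unit_amplitudes(self):
        rng = np.random.default_rng(2)

        def acts(n, lin):
            a = (rng.random((n, 1)) < 0.05).astype(float)
            return a

        sess, params = uniform_track_session(acts)
        rm = pc.rate_map_1d(sess, 0, params)
        ok = rm.valid
        assert np.allclose(rm.event_rate[ok], rm.raw_rate[ok])

    def test_scale_invariance_of_normalized_map(self):
        rng = np.random.default_rng(3)
        base = rng.random(1)

        def acts(n, lin):
            a = np.zeros((n, 2))
            ev = rng.random(n) < 0.1
            a[ev, 0] = rng.lognormal(0, 0.5, ev.sum())
            a[:, 1] = 3.7 * a[:, 0]
            return a

        sess, params = uniform_track_session(acts)
        rm0 = pc.rate_map_1d(sess, 0, params)
        rm1 = pc.rate_map_1d(sess, 1, params)
        ok = rm0.valid & rm1.valid
        assert np.allclose(rm0.normalized_rate[ok], rm1.normalized_rate[ok])

    def test_frame_permutation_invariance(self):
        rng = np.random.default_rng(4)

        def acts(n, lin):
            return (rng.random((n, 1)) < 0.05).astype(float)

        sess, params = uniform_track_session(acts)
        rm = pc.rate_map_1d(sess, 0, params)
        perm = rng.permutation(sess.n_frames)
        permuted = dataclasses.replace(
            sess,
            frame_times=sess.frame_times,
            x=sess.x[perm], y=sess.y[perm],
            speed=sess.speed[perm], activity=sess.activity[perm],
            valid=sess.valid[perm],
            lin_pos_cm=None, cum_dist_cm=None,
        )
        rm2 = pc.rate_map_1d(permuted, 0, params)
        assert np.allclose(rm.occupancy_s, rm2.occupancy_s)
        ok = rm.valid
        assert np.allclose(rm.raw_rate[ok], rm2.raw_rate[ok])

    def test_occupancy_sums_to_moving_time(self):
        sess, params = uniform_track_session(lambda n, lin: np.ones((n, 1)))
        rm = pc.rate_map_1d(sess, 0, params)
        t_moving = sess.moving.sum() / sess.frame_rate
        assert rm.occupancy_s.sum() == pytest.approx(t_moving, abs=1 / 30)

    def test_no_moving_frames_raises(self):
        sess, params = uniform_track_session(lambda n, lin: np.ones((n, 1)))
        still = dataclasses.replace(
            sess, speed=np.zeros(sess.n_frames),
            lin_pos_cm=None, cum_dist_cm=None,
        )
        with pytest.raises(EmptyMapError):
            pc.rate_map_1d(still, 0, params)

    def test_bin_count_follows_circumference(self):
        edges = linear_bin_edges(86.39, 2.0)
        assert len(edges) - 1 == 43
        assert edges[-1] == pytest.approx(86.39)


class TestRateMap2D:
    def make_open_session(self, rng_seed=5, duration=300.0):
        cfg = dataclasses.replace(
            pc.SimConfig(), arena="open_field", duration_s=duration,
            n_place_cells=2, n_untuned_cells=1, rng_seed=rng_seed,
        )
        return pc.simulate_session(cfg)

    def test_out_of_arena_bins_invalid(self):
        sess, _ = self.make_open_session()
        rm = pc.rate_map_2d(sess, 0)
        assert not rm.valid[~rm.in_arena].any()
        assert np.isnan(rm.raw_rate[~rm.in_arena]).all()

    def test_zero_activity_cell_flagged_degenerate(self):
        sess, _ = self.make_open_session()
        silent = dataclasses.replace(
            sess, activity=np.zeros_like(sess.activity)
        )
        rm = pc.rate_map_2d(silent, 0)
        assert not rm.has_activity
        assert np.nansum(rm.normalized_rate) == 0.0

    def test_proportional_cells_same_normalized_map(self):
        sess, _ = self.make_open_session()
        act = sess.activity.copy()
        act[:, 1] = 2.5 * act[:, 0]
        twin = dataclasses.replace(sess, activity=act)
        rm0 = pc.rate_map_2d(twin, 0)
        rm1 = pc.rate_map_2d(twin, 1)
        ok = rm0.valid & rm1.valid
        assert np.allclose(rm0.normalized_rate[ok], rm1.normalized_rate[ok])


class TestPerLapMaps:
    def make_session(self):
        cfg = dataclasses.replace(
            pc.SimConfig(), duration_s=300.0, n_place_cells=2,
            n_untuned_cells=1, rng_seed=6,
        )
        return pc.simulate_session(cfg)

    def test_occupancy_weighted_mean_reconstructs_session_map(self):
        sess, _ = self.make_session()
        laps = sess.laps()
        lapmat = pc.per_lap_maps(sess, 0, laps)
        recon = pc.session_map_from_laps(lapmat)
        mask = np.zeros(sess.n_frames, bool)
        for s, e in laps.complete_laps():
            mask[s:e] = True
        rm = pc.rate_map_1d(sess, 0, frame_mask=mask)
        ok = np.isfinite(recon) & np.isfinite(rm.raw_rate)
        assert np.max(np.abs(recon[ok] - rm.raw_rate[ok])) < 1e-9

    def test_zero_event_lap_rows_are_zero_not_missing(self):
        sess, _ = self.make_session()
        silent = dataclasses.replace(sess, activity=np.zeros_like(sess.activity))
        lapmat = pc.per_lap_maps(silent, 0)
        visited = lapmat.occupancy_s > 0
        assert np.all(lapmat.rate[visited] == 0.0)
        assert np.isnan(lapmat.rate[~visited]).all()

    def test_single_lap_row_equals_session_map(self):
        sess, _ = self.make_session()
        laps = sess.laps()
        s, e = laps.complete_laps()[0]
        mask = np.zeros(sess.n_frames, bool)
        mask[s:e] = True
        lapmat = pc.per_lap_maps(sess, 0, laps)
        rm = pc.rate_map_1d(sess, 0, frame_mask=mask)
        row = lapmat.rate[0]
        ok = np.isfinite(row) & np.isfinite(rm.raw_rate)
        assert np.allclose(row[ok], rm.raw_rate[ok])
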