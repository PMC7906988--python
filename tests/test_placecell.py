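"""Spatial information, shuffle null, field detection and classification."""

import dataclasses

import numpy as np
import pytest

import placecode as pc
from placecode.errors import NoFieldError, UndefinedInformationError
from placecode.placecell import SessionBinning, session_binning
from placecode.ratemap import RateMap1D, circular_boxcar


def map_from_rates(raw, occupancy=None):
    raw = np.asarray(raw, dtype=float)
    n = raw.size
    occ = np.ones(n) if occupancy is None else np.asarray(occupancy, float)
    edges = np.arange(n + 1, dtype=float) * 2.0
    smoothed = circular_boxcar(raw, 3)
    peak = np.nanmax(smoothed)
    normalized = smoothed / peak if peak > 0 else smoothed
    return RateMap1D(edges, occ, raw, raw, smoothed, normalized, occ > 0,
                     peak > 0)


class TestSpatialInformation:
    def test_uniform_rate_carries_no_information(self):
        assert pc.spatial_information(np.full(8, 3.3), np.ones(8)) == 0.0

    def test_activity_in_one_of_four_bins_is_two_bits(self):
        info = pc.spatial_information(np.array([4.0, 0, 0, 0]), np.ones(4))
        assert info == pytest.approx(2.0)

    def test_two_bin_hand_computed_case(self):
        # p = (.5, .5), rates (2, 0): mean 1, I = .5 * 2 * log2(2) = 1
        info = pc.spatial_information(np.array([2.0, 0.0]), np.ones(2))
        assert info == pytest.approx(1.0)

    def test_invariant_to_rate_scaling_and_bin_relabeling(self):
        rng = np.random.default_rng(0)
        rates = rng.uniform(0, 4, 20)
        occ = rng.uniform(0.5, 2, 20)
        base = pc.spatial_information(rates, occ)
        assert pc.spatial_information(7.3 * rates, occ) == pytest.approx(base)
        perm = rng.permutation(20)
        assert pc.spatial_information(rates[perm], occ[perm]) == \
            pytest.approx(base)

    def test_zero_mean_rate_is_undefined(self):
        with pytest.raises(UndefinedInformationError):
            pc.spatial_information(np.zeros(5), np.ones(5))


class TestShuffleNull:
    def test_shuffle_conserves_events_and_amplitude_sum(self, smoke_params):
        rng = np.random.default_rng(1)
        n_frames, n_bins = 3000, 40
        bins = rng.integers(0, n_bins, n_frames)
        amps = np.where(rng.random(n_frames) < 0.03,
                        rng.lognormal(0, 0.5, n_frames), 0.0)
        occ = np.bincount(bins, minlength=n_bins) / 30.0
        # conservation follows from the permutation construction: rates per
        # bin times occupancy recover the full amplitude mass
        b = SessionBinning(np.arange(n_frames), bins, occ, n_bins)

        class FakeSession:
            moving = np.ones(n_frames, bool)
            activity = amps[:, None]
            frame_rate = 30.0
            arena = "circular_track"

        res = pc.shuffle_null(FakeSession(), 0, smoke_params, rng=2, binning=b)
        assert res.null.size == smoke_params.n_shuffles
        assert np.isfinite(res.true_info)
        # amplitude mass (hence event count and mean rate) is conserved
        assert np.allclose(res.null_mean_rate, res.true_mean_rate, rtol=1e-12)

    def test_cell_without_events_raises(self, smoke_params, short_track_session):
        sess, _ = short_track_session
        silent = dataclasses.replace(sess, activity=np.zeros_like(sess.activity),
                                     lin_pos_cm=None, cum_dist_cm=None)
        with pytest.raises(UndefinedInformationError):
            pc.shuffle_null(silent, 0, smoke_params, rng=0)

    def test_strong_place_cell_beats_every_shuffle(self, smoke_params,
                                                   short_track_session):
        sess, gt = short_track_session
        cell = int(gt.index[gt["kind"] == "place"][0])
        res = pc.shuffle_null(sess, cell, smoke_params, rng=0)
        assert res.percentile == 100.0

    def test_rotate_mode_also_conserves_mass(self, short_track_session):
        sess, _ = short_track_session
        params = pc.AnalysisParams(n_shuffles=50, shuffle_mode="rotate")
        res = pc.shuffle_null(sess, 0, params, rng=0)
        assert np.all(res.null >= 0)


class TestFieldDetection1D:
    def test_threshold_count_example(self):
        rm = map_from_rates([0, 0.2, 0.6, 1.0, 0.6, 0.2, 0])
        # smoothing shifts values, so check against the smoothed profile
        fld = pc.detect_field_1d(rm)
        sm = rm.smoothed_rate
        expected = np.nonzero(sm >= 0.5 * np.nanmax(sm))[0]
        assert fld.location_bin == int(np.nanargmax(sm))
        assert np.array_equal(fld.member_bins, expected)
        assert fld.size == pytest.approx(2.0 * expected.size)

    def test_constant_map_is_degenerate_full_track(self):
        rm = map_from_rates(np.full(10, 2.0))
        fld = pc.detect_field_1d(rm)
        assert fld.degenerate
        assert fld.size == pytest.approx(20.0)

    def test_tied_maxima_take_lowest_bin(self):
        raw = np.zeros(12)
        raw[4] = raw[8] = 1.0
        rm = map_from_rates(raw)
        fld = pc.detect_field_1d(rm)
        assert fld.tie
        assert fld.location_bin == int(np.nanargmax(rm.smoothed_rate))

    def test_all_zero_map_has_no_field(self):
        rm = map_from_rates(np.zeros(10))
        with pytest.raises(NoFieldError):
            pc.detect_field_1d(rm)


class TestFieldDetection2D:
    def make_map(self, bump_centers, sess_seed=8):
        cfg = dataclasses.replace(
            pc.SimConfig(), arena="open_field", duration_s=600.0,
            n_place_cells=1, n_untuned_cells=0, background_event_rate=0.0,
            lap_reliability=1.0, rng_seed=sess_seed,
        )
        sess, gt = pc.simulate_session(cfg)
        return sess, gt

    def test_gaussian_bump_centroid_recovered(self):
        sess, gt = self.make_map(None)
        rm = pc.rate_map_2d(sess, 0)
        fld = pc.detect_field_2d(rm)
        cx, cy = fld.centroid_cm
        err = np.hypot(cx - gt["center_x_mm"][0] / 10.0,
                       cy - gt["center_y_mm"][0] / 10.0)
        assert err < 2.0   # within one 2-cm bin

    def test_two_equal_bumps_centroid_at_midpoint(self):
        from placecode.ratemap import RateMap2D, square_grid

        edges, in_arena = square_grid(325.0, 2.0)
        n = len(edges) - 1
        nm = np.zeros((n, n))
        nm[4, 8] = nm[12, 8] = 1.0
        rm = RateMap2D(edges, in_arena, np.ones((n, n)), nm, nm, nm, nm,
                       in_arena, True)
        fld = pc.detect_field_2d(rm)
        centers = (edges[:-1] + edges[1:]) / 2
        assert fld.multimodal
        assert fld.centroid_cm[0] == pytest.approx((centers[4] + centers[12]) / 2)
        assert fld.centroid_cm[1] == pytest.approx(centers[8])


class TestClassification:
    def test_reliable_place_cells_pass_all_criteria(self, track_study):
        gt, stats = track_study["gt"], track_study["stats"]
        place = (gt["kind"] == "place").to_numpy()
        sub = stats[place]
        assert (sub["c1_laps"].astype(bool) & sub["c2_field_occupancy"]
                & sub["c3_information"]).mean() > 0.9

    def test_unreliable_cell_fails_lap_criterion(self):
        cfg = dataclasses.replace(
            pc.SimConfig(), duration_s=600.0, n_place_cells=1,
            n_untuned_cells=0, lap_reliability=0.3, rng_seed=10,
        )
        sess, _ = pc.simulate_session(cfg)
        st = pc.classify_place_cell(sess, 0, pc.AnalysisParams(n_shuffles=100),
                                    rng=0)
        assert st.lap_active_fraction < 0.5
        assert not st.c1_laps
        assert not st.is_place_cell

    def test_homogeneous_cells_rarely_pass_information_criterion(
            self, calibration_percentiles):
        pass_rate = np.mean(calibration_percentiles >= 99.0)
        assert pass_rate <= 0.03

    def test_classification_deterministic_given_seed(self, short_track_session,
                                                     smoke_params):
        sess, _ = short_track_session
        cells = np.arange(5)
        a, _ = pc.classify_population(sess, smoke_params, seed=4, cells=cells)
        b, _ = pc.classify_population(sess, smoke_params, seed=4, cells=cells)
        assert a.equals(b)
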