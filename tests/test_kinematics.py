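"""Centroids, epoch-wise social distance, locomotion and time binning."""

import numpy as np
import pytest

from socialdist.kinematics import (
    CentroidSeries,
    compute_centroids,
    frame_distances,
    locomotion_rate,
    social_distance_epochs,
    time_binned_distance,
)
from socialdist.synthetic_data import SimConfig, simulate_session
from socialdist.trajectory_io import apply_p_cutoff, to_mm

import oracles
from conftest import make_track, random_small_track


def series(xy, fps=30.0):
    xy = np.asarray(xy, float)
    return CentroidSeries(
        xy=xy, n_parts_used=np.full(len(xy), 5), part_subset="all", fps=fps
    )


class TestComputeCentroids:
    def test_symmetric_layout_gives_center(self):
        xy = np.zeros((1, 2, 5, 2))
        xy[0, 0] = [(0, 0), (2, 0), (0, 2), (2, 2), (1, 1)]
        track = apply_p_cutoff(make_track(xy, np.full((1, 2, 5), 0.9), units="mm"), 0.6)
        c1, _ = compute_centroids(track)
        np.testing.assert_allclose(c1.xy[0], [1.0, 1.0])

    def test_rejected_labels_excluded_from_mean(self):
        """With tail labels rejected, the centroid averages the remaining three."""
        xy = np.zeros((1, 2, 5, 2))
        xy[0, 0] = [(0, 0), (3, 0), (0, 3), (100, 100), (200, 200)]
        lk = np.full((1, 2, 5), 0.9)
        lk[0, 0, 3:] = 0.1  # both tail labels sub-cutoff
        track = apply_p_cutoff(make_track(xy, lk, units="mm"), 0.6)
        c1, _ = compute_centroids(track, part_subset="all")
        np.testing.assert_allclose(c1.xy[0], [1.0, 1.0])
        assert c1.n_parts_used[0] == 3

    def test_frame_invalid_below_min_parts(self):
        lk = np.full((2, 2, 5), 0.1)
        lk[1, 0, 0] = 0.9  # one accepted label in frame 1, animal 0
        track = apply_p_cutoff(make_track(np.ones((2, 2, 5, 2)), lk, units="mm"), 0.6)
        c1, c2 = compute_centroids(track, min_parts=2)
        assert not c1.valid.any()
        c1, c2 = compute_centroids(track, min_parts=1)
        assert list(c1.valid) == [False, True]

    @pytest.mark.parametrize("subset", ["all", "no_tail", "ears_only"])
    def test_matches_bruteforce_oracle_on_random_tracks(self, subset):
        rng = np.random.default_rng(101)
        for _ in range(30):
            track = random_small_track(rng)
            c1, c2 = compute_centroids(track, part_subset=subset)
            exp_xy, exp_n = oracles.centroids_bruteforce(track, subset)
            got = np.stack([c1.xy, c2.xy], axis=1)
            np.testing.assert_allclose(got, exp_xy, atol=1e-12, equal_nan=True)
            np.testing.assert_array_equal(
                np.stack([c1.n_parts_used, c2.n_parts_used], axis=1), exp_n
            )

    def test_centroid_inside_hull_of_accepted_labels(self):
        rng = np.random.default_rng(102)
        track = random_small_track(rng, n_frames=60)
        c1, _ = compute_centroids(track)
        for f in range(track.n_frames):
            pts = track.xy[f, 0][track.accepted[f, 0]]
            if len(pts) and c1.valid[f]:
                assert pts[:, 0].min() - 1e-9 <= c1.xy[f, 0] <= pts[:, 0].max() + 1e-9
                assert pts[:, 1].min() - 1e-9 <= c1.xy[f, 1] <= pts[:, 1].max() + 1e-9

    def test_requires_mm_units(self):
        track = apply_p_cutoff(
            make_track(np.zeros((1, 2, 5, 2)), np.full((1, 2, 5), 0.9)), 0.6
        )
        with pytest.raises(ValueError, match="mm"):
            compute_centroids(track)


class TestSocialDistanceEpochs:
    def test_static_3_4_5_triangle(self):
        """Stationary mice at (0,0) and (30,40) mm are 50 mm apart in every epoch."""
        n = 1800
        c1 = series(np.zeros((n, 2)))
        c2 = series(np.tile([30.0, 40.0], (n, 1)))
        e = social_distance_epochs(c1, c2, epoch_length_s=30.0)
        assert e.n_epochs == 2
        np.testing.assert_allclose(e.mean_mm, 50.0)
        np.testing.assert_allclose(e.median_mm, 50.0)
        assert e.grand_mean_mm == pytest.approx(50.0)

    def test_hour_session_has_120_epochs_of_900_frames(self):
        n = 60 * 60 * 30
        rng = np.random.default_rng(7)
        c1 = series(rng.uniform(0, 300, (n, 2)))
        c2 = series(rng.uniform(0, 300, (n, 2)))
        e = social_distance_epochs(c1, c2, epoch_length_s=30.0)
        assert e.n_epochs == 120
        assert e.n_valid_frames.sum() == n
        assert set(e.n_valid_frames) == {900}

    def test_matches_bruteforce_epoch_oracle(self):
        rng = np.random.default_rng(8)
        n = 450
        xy1 = rng.uniform(0, 300, (n, 2))
        xy2 = rng.uniform(0, 300, (n, 2))
        xy1[rng.random(n) < 0.2] = np.nan  # invalid frames
        c1, c2 = series(xy1), series(xy2)
        e = social_distance_epochs(c1, c2, epoch_length_s=3.0)  # 90-frame epochs
        dist = frame_distances(c1, c2)
        exp_mean, exp_median, exp_n = oracles.epoch_stats_bruteforce(dist, 90)
        np.testing.assert_allclose(e.mean_mm, exp_mean, atol=1e-12)
        np.testing.assert_allclose(e.median_mm, exp_median, atol=1e-12)
        np.testing.assert_array_equal(e.n_valid_frames, exp_n)

    def test_empty_epoch_excluded_from_grand_aggregation(self):
        n = 180
        xy1 = np.zeros((n, 2))
        xy2 = np.tile([30.0, 40.0], (n, 1))
        xy1[:90] = np.nan  # first epoch entirely invalid
        e = social_distance_epochs(series(xy1), series(xy2), epoch_length_s=3.0)
        assert np.isnan(e.mean_mm[0])
        assert e.grand_mean_mm == pytest.approx(50.0)

    def test_grand_mean_invariant_under_epoch_reordering(self):
        rng = np.random.default_rng(9)
        c1 = series(rng.uniform(0, 300, (900, 2)))
        c2 = series(rng.uniform(0, 300, (900, 2)))
        e = social_distance_epochs(c1, c2, epoch_length_s=3.0)
        perm = rng.permutation(e.n_epochs)
        assert np.mean(e.mean_mm[perm]) == pytest.approx(e.grand_mean_mm, abs=1e-12)


class TestLocomotionRate:
    def test_constant_velocity(self):
        """1 mm per frame at 30 fps is 30 mm/s."""
        xy = np.column_stack([np.arange(100.0), np.zeros(100)])
        assert locomotion_rate(series(xy)).rate_mm_s == pytest.approx(30.0)

    def test_stationary_is_zero(self):
        assert locomotion_rate(series(np.ones((50, 2)))).rate_mm_s == 0.0

    def test_pairs_spanning_invalid_frames_excluded(self):
        xy = np.column_stack([np.arange(10.0), np.zeros(10)])
        xy[4] = np.nan  # removes pairs (3,4) and (4,5)
        summary = locomotion_rate(series(xy))
        assert summary.n_valid_frame_pairs == 7
        assert summary.rate_mm_s == pytest.approx(30.0)

    def test_fewer_than_two_valid_frames_flagged(self):
        xy = np.full((5, 2), np.nan)
        xy[2] = [1.0, 1.0]
        summary = locomotion_rate(series(xy))
        assert not summary.defined


class TestRigidMotionInvariance:
    def test_distances_and_rates_invariant_under_rigid_transform(self):
        """Rotating + translating both animals changes no distance or rate."""
        track, _ = simulate_session(SimConfig(seed=21, n_frames=600))
        filt = to_mm(apply_p_cutoff(track, 0.6))
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        moved = to_mm(apply_p_cutoff(track, 0.6))
        moved.xy = filt.xy @ R.T + np.array([57.0, -13.0])
        for t in (filt, moved):
            t_c = compute_centroids(t)
            t.result = (
                np.nanmean(frame_distances(*t_c)),
                locomotion_rate(t_c[0]).rate_mm_s,
            )
        np.testing.assert_allclose(filt.result, moved.result, rtol=1e-9)

    def test_scaling_coordinates_scales_distances_and_rates(self):
        track, _ = simulate_session(SimConfig(seed=22, n_frames=300))
        filt = to_mm(apply_p_cutoff(track, 0.6))
        scaled = to_mm(apply_p_cutoff(track, 0.6))
        scaled.xy = filt.xy * 3.0
        c = compute_centroids(filt)
        cs = compute_centroids(scaled)
        assert np.nanmean(frame_distances(*cs)) == pytest.approx(
            3.0 * np.nanmean(frame_distances(*c)), rel=1e-9
        )
        assert locomotion_rate(cs[0]).rate_mm_s == pytest.approx(
            3.0 * locomotion_rate(c[0]).rate_mm_s, rel=1e-9
        )


class TestTimeBinnedDistance:
    def test_60_min_session_in_20_min_bins(self):
        n = 60 * 60 * 30
        rng = np.random.default_rng(23)
        c1 = series(rng.uniform(0, 300, (n, 2)))
        c2 = series(rng.uniform(0, 300, (n, 2)))
        e = social_distance_epochs(c1, c2)
        binned = time_binned_distance(e, bin_minutes=20.0)
        assert len(binned) == 3
        assert list(binned["n_epochs"]) == [40, 40, 40]
        # per-bin aggregation mirrors the grand rule
        np.testing.assert_allclose(
            binned["mean_mm"], e.mean_mm.reshape(3, 40).mean(axis=1), atol=1e-12
        )

    def test_constant_distance_fills_all_bins(self):
        c1 = series(np.zeros((1800, 2)))
        c2 = series(np.tile([30.0, 40.0], (1800, 1)))
        e = social_distance_epochs(c1, c2, epoch_length_s=10.0)
        binned = time_binned_distance(e, bin_minutes=0.5)
        np.testing.assert_allclose(binned["mean_mm"], 50.0)
        np.testing.assert_allclose(binned["median_mm"], 50.0)

    def test_non_divisible_binning_is_an_error(self):
        c1 = series(np.zeros((1800, 2)))
        c2 = series(np.ones((1800, 2)))
        e = social_distance_epochs(c1, c2, epoch_length_s=10.0)  # 6 epochs
        with pytest.raises(ValueError):
            time_binned_distance(e, bin_minutes=0.7)
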