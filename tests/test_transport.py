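import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cortiflow.io import MovieStack
from cortiflow.tracking import Trajectory
from cortiflow.transport import (ChromosomeTrack, TransportRecord,
                                 aggregate_transport, compensate_and_project,
                                 track_chromosome, transport_score)


def dark_spot_movie(path, shape=(60, 80), n=10, bg=50.0, depth=25.0, sigma=3.0):
    """Movie with a dark Gaussian spot following `path` (list of xy)."""
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    frames = []
    for x, y in path[:n]:
        img = bg - depth * np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / (2 * sigma ** 2))
        frames.append(img)
    return MovieStack(np.stack(frames), 0.1, 1.0)


class TestChromosomeTracking:
    def test_translating_spot_tracked_within_one_pixel(self):
        path = [(20.0 + 2 * i, 30.0) for i in range(10)]
        movie = dark_spot_movie(path)
        track = track_chromosome(movie, (20, 30), search_radius_px=5)
        err = np.abs(track.xy - np.asarray(path))
        assert err.max() < 1.0

    def test_static_spot_gives_static_track(self):
        movie = dark_spot_movie([(40.0, 30.0)] * 8, n=8)
        track = track_chromosome(movie, (40, 30), search_radius_px=5)
        assert np.ptp(track.xy, axis=0).max() < 1e-9

    def test_jump_beyond_radius_terminates_with_frame_number(self):
        path = [(20.0, 30.0)] * 3 + [(30.0, 30.0)] * 5
        movie = dark_spot_movie(path, n=8)
        with pytest.raises(ValueError, match="frame 3"):
            track_chromosome(movie, (20, 30), search_radius_px=5)

    def test_track_step_invariant_enforced(self):
        with pytest.raises(ValueError, match="search radius"):
            ChromosomeTrack(np.arange(2), np.array([[0, 0], [9, 0.0]]), 5.0)


class TestProjection:
    def make_traj(self, xy):
        xy = np.asarray(xy, dtype=float)
        return Trajectory(np.arange(len(xy)), xy, np.ones(len(xy)))

    def static_chrom(self, n, pos=(0.0, 0.0)):
        return ChromosomeTrack(np.arange(n), np.tile(pos, (n, 1)), 100.0)

    def test_shared_ap_drift_is_compensated_away(self):
        base = np.column_stack([np.linspace(0, 5, 6), np.zeros(6)])
        drift = np.column_stack([np.linspace(0, 3, 6), np.zeros(6)])
        chrom = ChromosomeTrack(np.arange(6), drift, 100.0)
        z_plain = compensate_and_project(self.make_traj(base),
                                         self.static_chrom(6), (100, 0),
                                         (1, 0), 1.0)
        z_drift = compensate_and_project(self.make_traj(base + drift), chrom,
                                         (100, 0), (1, 0), 1.0)
        np.testing.assert_allclose(z_drift, z_plain, atol=1e-9)

    def test_straight_motion_toward_pole_gives_dz_v_dt(self):
        v_um_s, dt, px = 0.7, 0.83, 0.133
        step_px = v_um_s * dt / px
        xy = np.column_stack([np.arange(8) * step_px, np.zeros(8)])
        z = compensate_and_project(self.make_traj(xy), self.static_chrom(8),
                                   (1000, 0), (1, 0), px)
        np.testing.assert_allclose(np.diff(z), v_um_s * dt, rtol=1e-9)

    def test_motion_perpendicular_to_pole_direction_projects_near_zero(self):
        xy = np.column_stack([np.zeros(8), np.linspace(0, 10, 8)])
        z = compensate_and_project(self.make_traj(xy), self.static_chrom(8),
                                   (0, 1000), (1, 0), 1.0)
        # principal axis is the motion axis; movement is toward the pole
        assert z[-1] > 0
        xy2 = np.column_stack([np.linspace(0, 1e-9, 8), np.linspace(0, 10, 8)])
        z2 = compensate_and_project(self.make_traj(xy2), self.static_chrom(8),
                                    (1000, 5), (1, 0), 1.0)
        # projection onto the principal axis keeps only the y-motion, which
        # is orthogonal to the x-ward pole at large distance: z stays tiny
        # relative to the 10 px of travel
        assert np.abs(z2[-1]) <= 10.0

    def test_short_trajectory_rejected(self):
        with pytest.raises(ValueError, match="2 frames"):
            compensate_and_project(self.make_traj([[0, 0]]),
                                   self.static_chrom(1), (1, 0), (1, 0), 1.0)


class TestScore:
    def test_hand_evaluated_example(self):
        # dz' = [0.5, -0.2, 0.3] with smoothing disabled, I = 2
        z = np.array([0.0, 0.5, 0.3, 0.6])
        rec = transport_score(z, np.full(4, 2.0), smooth_window=1)
        np.testing.assert_allclose(rec.activity, [0.5, 0.0, 0.18])
        assert rec.total == pytest.approx(0.68)

    def test_monotone_decreasing_z_scores_zero(self):
        rec = transport_score(np.linspace(5, 0, 10), np.ones(10), smooth_window=1)
        assert rec.total == 0.0

    def test_activity_linear_in_intensity(self):
        z = np.array([0.0, 0.4, 0.9, 1.0])
        r1 = transport_score(z, np.ones(4), smooth_window=1)
        r2 = transport_score(z, 2 * np.ones(4), smooth_window=1)
        np.testing.assert_allclose(r2.activity, 2 * r1.activity)

    def test_smoothing_is_centered_moving_average_with_shrunk_ends(self):
        z = np.array([0.0, 3.0, 0.0, 3.0, 0.0])
        rec = transport_score(z, np.ones(5), smooth_window=3)
        expect = np.array([1.5, 1.0, 2.0, 1.0, 1.5])
        np.testing.assert_allclose(rec.z_smooth_um, expect)

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_loop_oracle_equivalence(self, seed):
        """Explicit-loop reimplementation agrees to 1e-9 relative."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 30))
        z = rng.normal(size=n).cumsum()
        inten = rng.uniform(1, 10, n)
        w = int(rng.choice([1, 3, 5]))
        rec = transport_score(z, inten, smooth_window=w)
        # oracle: loops only
        zs = []
        half = w // 2
        for i in range(n):
            lo, hi = max(i - half, 0), min(i + half + 1, n)
            acc = 0.0
            for j in range(lo, hi):
                acc += z[j]
            zs.append(acc / (hi - lo))
        acts = []
        for i in range(n - 1):
            dz = zs[i + 1] - zs[i]
            I = (inten[i] + inten[i + 1]) / 2.0
            acts.append(I * dz * dz if dz > 0 else 0.0)
        np.testing.assert_allclose(rec.activity, acts, rtol=1e-9, atol=1e-12)

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1), st.floats(0.5, 3.0))
    def test_scaling_space_by_c_scales_activity_by_c_squared(self, seed, c):
        rng = np.random.default_rng(seed)
        z = rng.normal(size=12).cumsum()
        inten = rng.uniform(1, 5, 12)
        r1 = transport_score(z, inten)
        r2 = transport_score(c * z, inten)
        np.testing.assert_allclose(r2.total, c ** 2 * r1.total, rtol=1e-9)


class TestAggregation:
    def rec(self, activities, frames):
        a = np.asarray(activities, dtype=float)
        return TransportRecord(z_um=np.zeros(len(a) + 1),
                               z_smooth_um=np.zeros(len(a) + 1),
                               dz_um=np.zeros(len(a)), activity=a,
                               frames=np.asarray(frames))

    def test_cumulative_sum_of_per_bin_totals(self):
        r = self.rec([1.0, 0.0, 2.0], [0, 1, 2])
        t, mean, sem = aggregate_transport([[r]], 1.0, 4, grid_dt_s=1.0)
        # cumulative starts at 0 at anaphase onset, then [1, 1, 3]
        np.testing.assert_allclose(t, [0, 1, 2, 3])
        np.testing.assert_allclose(mean, [0, 1, 1, 3])

    def test_mean_and_sem_across_two_embryos(self):
        r1 = self.rec([2.0, 2.0], [0, 1])
        r2 = self.rec([4.0, 4.0], [0, 1])
        t, mean, sem = aggregate_transport([[r1], [r2]], 1.0, 3, grid_dt_s=1.0)
        np.testing.assert_allclose(mean[-1], (4 + 8) / 2)
        np.testing.assert_allclose(sem[-1], 2.0)    # sd([4,8])/sqrt(2)

    def test_embryo_without_records_contributes_zero_series(self):
        r = self.rec([1.0], [0])
        t, mean, _ = aggregate_transport([[r], []], 1.0, 2, grid_dt_s=1.0)
        np.testing.assert_allclose(mean[-1], 0.5)

    def test_empty_input_gives_empty_result(self):
        t, mean, sem = aggregate_transport([], 1.0, 5)
        assert t.size == 0 and mean.size == 0 and sem.size == 0
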