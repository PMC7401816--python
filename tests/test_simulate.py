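import json

import numpy as np
import pytest

from cortiflow import SimConfig, simulate_embryo_movie, simulate_cortex_kymograph
from cortiflow.simulate import (advect_density, flow_velocity, write_fixture,
                                read_fixture, _sha256)


def tiny(**kw):
    base = dict(n_frames=6, flow_onset_s=None, n_particles=0,
                semi_axis_a_um=10.0, semi_axis_b_um=6.0, margin_um=3.0)
    base.update(kw)
    return SimConfig(**base)


class TestDeterminismAndValidation:
    def test_same_config_and_seed_give_bit_identical_movies(self):
        cfg = tiny(n_particles=5)
        m1, _ = simulate_embryo_movie(cfg, seed=3)
        m2, _ = simulate_embryo_movie(cfg, seed=3)
        np.testing.assert_array_equal(m1.data, m2.data)

    def test_different_seed_changes_the_movie(self):
        cfg = tiny()
        m1, _ = simulate_embryo_movie(cfg, seed=3)
        m2, _ = simulate_embryo_movie(cfg, seed=4)
        assert not np.array_equal(m1.data, m2.data)

    @pytest.mark.parametrize("field", ["flow_onset_s", "furrow_onset_s"])
    def test_event_times_beyond_movie_rejected(self, field):
        kwargs = {"flow_onset_s": None, field: 1e4}
        with pytest.raises(ValueError, match=field):
            SimConfig(n_frames=10, **kwargs).validate()

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            tiny(cytoplasm_level=-1.0).validate()


class TestStaticScene:
    def test_noise_free_static_scene_frames_equal_up_to_bleach(self):
        cfg = tiny(poisson_gain=0.0, gaussian_noise_sd=0.0, dtype="float32",
                   background_level=0.0, cortex_turnover_s=None,
                   flow_uni_amp_um_s=0.0, flow_bi_amp_um_s=0.0,
                   pole_a_end_frac=-0.28, pole_p_end_frac=0.28,
                   bleach_tau_s=100.0)
        movie, truth = simulate_embryo_movie(cfg, seed=1)
        f0 = movie.frame(0).astype(float)
        for i in range(1, movie.n_frames):
            factor = np.exp(-i * cfg.frame_interval_s / 100.0)
            np.testing.assert_allclose(movie.frame(i), f0 * factor,
                                       rtol=1e-5, atol=1e-4)

    def test_bleach_constant_recovered_from_whole_frame_mean(self):
        cfg = tiny(n_frames=60, poisson_gain=0.0, gaussian_noise_sd=0.0,
                   dtype="float32", background_level=0.0,
                   cortex_turnover_s=None, pole_a_end_frac=-0.28,
                   pole_p_end_frac=0.28, bleach_tau_s=120.0)
        movie, _ = simulate_embryo_movie(cfg, seed=1)
        means = movie.data.mean(axis=(1, 2))
        t = np.arange(movie.n_frames) * cfg.frame_interval_s
        slope = np.polyfit(t, np.log(means), 1)[0]
        assert abs(-1.0 / slope - 120.0) / 120.0 < 0.05


class TestParticles:
    def test_directed_particle_moves_speed_times_dt_per_frame(self):
        cfg = tiny(n_frames=10, n_particles=4, particles_directed=True,
                   particle_speed_um_s=0.7, frame_interval_s=0.83,
                   pole_a_end_frac=-0.28, pole_p_end_frac=0.28)
        _, truth = simulate_embryo_movie(cfg, seed=5)
        expected = 0.7 * 0.83
        checked = 0
        for tr in truth.particles:
            if len(tr["frames"]) < 3:
                continue
            steps = np.linalg.norm(np.diff(tr["xy"], axis=0), axis=1)
            steps_um = steps * cfg.pixel_size_um
            np.testing.assert_allclose(steps_um, expected, rtol=1e-6)
            checked += 1
        assert checked > 0

    def test_poisson_noise_variance_matches_mean_in_flat_interior(self):
        cfg = SimConfig(n_frames=1, flow_onset_s=None, n_particles=0,
                        gaussian_noise_sd=0.0, poisson_gain=1.0,
                        pole_amplitude=0.0, chromosome_depth_frac=0.0,
                        cytoplasm_level=50.0, dtype="float32")
        movie, truth = simulate_embryo_movie(cfg, seed=9)
        frame = movie.frame(0)
        h, w = frame.shape
        # central flat cytoplasm block, far from cortex and structures
        block = frame[h // 2 - 40:h // 2 + 40, w // 2 - 80:w // 2 + 80]
        assert block.size >= 1e4
        ratio = block.var() / block.mean()
        assert 0.9 < ratio < 1.1

    def test_truth_trajectories_have_consecutive_frames(self):
        cfg = tiny(n_frames=20, n_particles=8, particles_directed=False)
        _, truth = simulate_embryo_movie(cfg, seed=2)
        for tr in truth.particles:
            assert np.all(np.diff(tr["frames"]) == 1)


class TestAdvection:
    def test_uniform_integer_shift_is_exact_circular_shift(self):
        rng = np.random.default_rng(0)
        rho = rng.random(200) + 0.5
        dx, dt = 0.1, 1.0
        v = np.full(200, 3 * dx / dt)        # exactly 3 cells per step
        out = advect_density(rho, v, dt, dx)
        np.testing.assert_allclose(out, np.roll(rho, 3), atol=1e-12)

    def test_mass_conserved_under_arbitrary_periodic_flow(self):
        rng = np.random.default_rng(1)
        rho = rng.random(300) + 0.2
        s = np.arange(300) / 300
        v = 0.3 * np.sin(2 * np.pi * s) + 0.1 * np.cos(6 * np.pi * s)
        dx = 0.13
        out = rho
        for _ in range(50):
            out = advect_density(out, v, 0.7, dx)
        assert abs(out.sum() - rho.sum()) / rho.sum() < 1e-9

    def test_converging_flow_accumulates_density_at_the_sink(self):
        n = 400
        rho = np.ones(n)
        s = np.arange(n) / n
        v = -0.2 * np.sin(2 * np.pi * (s - 0.5))   # sink at s = 0.5
        dx = 0.1
        for _ in range(100):
            rho = advect_density(rho, v, 0.5, dx)
        assert np.argmax(rho) == pytest.approx(n // 2, abs=2)
        assert rho.max() > 1.5


class TestKymographOracle:
    def test_zero_flow_gives_identical_rows(self):
        cfg = tiny(n_frames=8, flow_uni_amp_um_s=0.0, flow_bi_amp_um_s=0.0,
                   cortex_turnover_s=None)
        kymo, flow = simulate_cortex_kymograph(cfg, seed=3)
        for i in range(1, 8):
            np.testing.assert_allclose(kymo.values[:, i], kymo.values[:, 0])
        assert np.all(flow.values == 0)

    def test_uniform_flow_shifts_rows_by_v_dt_over_dx(self):
        # constant v everywhere: each row is the previous circularly
        # shifted by v*dt/dx grid cells (choose an exact integer shift)
        cfg = tiny(n_frames=4, cortex_turnover_s=None)
        kymo, _ = simulate_cortex_kymograph(cfg, seed=4)
        dx = kymo.bin_arc_um
        dt = cfg.frame_interval_s
        v = 2 * dx / dt
        row = kymo.values[:, 0]
        out = advect_density(row, np.full(row.size, v), dt, dx)
        np.testing.assert_allclose(out, np.roll(row, 2), atol=1e-12)

    def test_row_sums_conserved_during_advection(self):
        cfg = SimConfig(n_frames=60, flow_onset_s=20.0, cortex_turnover_s=None)
        kymo, _ = simulate_cortex_kymograph(cfg, seed=5)
        sums = kymo.values.sum(axis=0)
        assert np.max(np.abs(sums / sums[0] - 1.0)) < 0.01

    def test_aliasing_velocity_rejected(self):
        cfg = tiny(flow_uni_amp_um_s=100.0, frame_interval_s=1.0,
                   semi_axis_a_um=5.0, semi_axis_b_um=3.0)
        with pytest.raises(ValueError, match="alias"):
            simulate_cortex_kymograph(cfg, seed=0)


class TestFlowField:
    def test_unidirectional_phase_moves_posterior_material_toward_equator(self):
        cfg = SimConfig(flow_onset_s=100.0)
        v_post = flow_velocity(cfg, np.linspace(0.26, 0.49, 20), 50.0)
        assert np.all(v_post < 0)             # decreasing s on side 1 = P->A
        v_ant = flow_velocity(cfg, np.linspace(0.01, 0.24, 20), 50.0)
        np.testing.assert_allclose(v_ant, 0.0)   # anterior cortex still

    def test_bidirectional_phase_converges_on_the_equator(self):
        cfg = SimConfig(flow_onset_s=100.0)
        v = flow_velocity(cfg, np.array([0.1, 0.4, 0.6, 0.9]), 150.0)
        assert v[0] > 0 and v[1] < 0          # toward s = 0.25
        assert v[2] > 0 and v[3] < 0          # toward s = 0.75


class TestFixtureIO:
    def test_write_then_read_roundtrips_movie_exactly(self, tmp_path):
        cfg = tiny(n_particles=3)
        movie, truth = simulate_embryo_movie(cfg, seed=6)
        write_fixture(movie, truth, tmp_path / "fx")
        back, tables = read_fixture(tmp_path / "fx")
        np.testing.assert_array_equal(back.data, movie.data)
        assert back.pixel_size_um == movie.pixel_size_um
        assert len(tables["particles"]) == sum(
            len(t["frames"]) for t in truth.particles)

    def test_refuses_nonempty_dir_without_overwrite(self, tmp_path):
        cfg = tiny()
        movie, truth = simulate_embryo_movie(cfg, seed=6)
        out = tmp_path / "fx"
        out.mkdir()
        (out / "stale.txt").write_text("x")
        with pytest.raises(FileExistsError):
            write_fixture(movie, truth, out)
        write_fixture(movie, truth, out, overwrite=True)   # explicit opt-in

    def test_empty_particle_truth_gives_header_only_csv(self, tmp_path):
        cfg = tiny(n_particles=0)
        movie, truth = simulate_embryo_movie(cfg, seed=6)
        write_fixture(movie, truth, tmp_path / "fx")
        lines = (tmp_path / "fx" / "particles.csv").read_text().strip().splitlines()
        assert lines == ["track_id,frame,x_px,y_px,intensity"]

    def test_manifest_checksums_match_recomputation(self, tmp_path):
        cfg = tiny(n_particles=2)
        movie, truth = simulate_embryo_movie(cfg, seed=6)
        manifest = write_fixture(movie, truth, tmp_path / "fx")
        for name, digest in manifest["files"].items():
            assert _sha256(tmp_path / "fx" / name) == digest
        on_disk = json.loads((tmp_path / "fx" / "manifest.json").read_text())
        assert on_disk == manifest

    def test_five_plane_stack_has_z_dimension(self):
        cfg = tiny(n_z=5)
        movie, _ = simulate_embryo_movie(cfg, seed=1)
        assert movie.data.ndim == 4 and movie.data.shape[1] == 5
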