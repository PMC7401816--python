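import numpy as np
import pytest

from cortiflow.geometry import parameterize_contour
from cortiflow.io import MovieStack
from cortiflow.kymograph import (CortexKymograph, StraightenedBand,
                                 aggregate_region_series,
                                 bleach_correct_movie, bleach_correct_series,
                                 build_density_kymograph, fold_and_merge,
                                 fold_kymograph, merge_kymographs,
                                 normalize_band, region_density_series,
                                 straighten_edge)
from conftest import circle_polyline


def ring_image(shape=(300, 300), center=(150, 150), radius=100.0,
               bg=5.0, cyto=40.0, ring=150.0, sigma=3.0):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    r = np.hypot(xx - center[0], yy - center[1])
    img = np.where(r <= radius, cyto, bg).astype(float)
    img += ring * np.exp(-(r - radius) ** 2 / (2 * sigma ** 2))
    return img


@pytest.fixture()
def ring_contour():
    return parameterize_contour(circle_polyline(100.0, (150, 150)),
                                (250, 150), pixel_size_um=0.133)


class TestStraighten:
    def test_bright_ring_becomes_horizontal_stripe_at_central_row(self, ring_contour):
        band = straighten_edge(ring_image(), ring_contour, half_width_px=20)
        peak_rows = np.nanargmax(band.data, axis=0)
        assert np.abs(peak_rows - 20).max() <= 1

    def test_half_width_zero_gives_on_contour_interpolation(self, ring_contour):
        img = ring_image()
        band = straighten_edge(img, ring_contour, half_width_px=0)
        assert band.data.shape[0] == 1
        pts = ring_contour.point_at(band.s_grid)
        from scipy.ndimage import map_coordinates
        expect = map_coordinates(img, [pts[:, 1], pts[:, 0]], order=1)
        np.testing.assert_allclose(band.data[0], expect, rtol=1e-6)

    def test_rotated_image_gives_same_band(self):
        img = ring_image()
        rot = np.rot90(img, k=-1)           # (x, y) -> (h-1-y, x)
        h = img.shape[0]
        poly = circle_polyline(100.0, (150, 150))
        poly_rot = np.column_stack([h - 1 - poly[:, 1], poly[:, 0]])
        c1 = parameterize_contour(poly, (250, 150), pixel_size_um=0.133)
        c2 = parameterize_contour(poly_rot, (h - 1 - 150, 250), pixel_size_um=0.133)
        b1 = straighten_edge(img, c1, 10, n_cols=360)
        b2 = straighten_edge(rot, c2, 10, n_cols=360)
        # same circle, same anchor geometry: bands agree up to interpolation
        assert np.nanmax(np.abs(np.sort(b1.data, axis=1) -
                                np.sort(b2.data, axis=1))) < 1.0

    def test_normals_leaving_image_marked_missing_with_warning(self):
        poly = circle_polyline(100.0, (100, 150))   # near the left edge
        c = parameterize_contour(poly, (0, 150))
        with pytest.warns(UserWarning, match="missing"):
            band = straighten_edge(np.ones((300, 300)), c, half_width_px=30)
        assert np.isnan(band.data).any()


class TestNormalize:
    def make_band(self, bg=10.0, cyto=110.0, peak=210.0, rows=41, cols=100):
        data = np.full((rows, cols), cyto)
        data[:10] = bg
        data[rows // 2] = peak
        return StraightenedBand(data, (rows - 1) // 2, np.arange(cols) / cols)

    def test_linear_mapping_of_background_and_cytoplasm(self):
        nb = normalize_band(self.make_band())
        np.testing.assert_allclose(nb.data[:10], 0.0, atol=1e-9)
        np.testing.assert_allclose(nb.data[-10:], 1.0, atol=1e-9)
        np.testing.assert_allclose(nb.data[20], (210 - 10) / (110 - 10))

    def test_flat_band_raises_zero_denominator_error(self):
        band = self.make_band(bg=50.0, cyto=50.0, peak=50.0)
        with pytest.raises(ValueError, match="difference below"):
            normalize_band(band)

    def test_gain_and_offset_invariance(self):
        b1 = self.make_band()
        b2 = StraightenedBand(3.0 * b1.data + 25.0, b1.half_width_px,
                              b1.s_grid)
        n1, n2 = normalize_band(b1), normalize_band(b2)
        np.testing.assert_allclose(n1.data, n2.data, rtol=1e-9, atol=1e-9)


class TestDensityKymograph:
    def gaussian_band(self, peak_row=40, rows=81, cols=60, amp=2.0, sd=2.0):
        r = np.arange(rows)
        profile = amp * np.exp(-(r - peak_row) ** 2 / (2 * sd ** 2))
        data = np.tile(profile[:, None], (1, cols))
        data[-10:] = 1.0
        return StraightenedBand(data, 40, np.arange(cols) / cols,
                                normalized=True)

    def test_selects_five_rows_around_the_peak(self):
        bands = [self.gaussian_band() for _ in range(3)]
        kymo = build_density_kymograph(bands, np.arange(3.0))
        r = np.arange(81)
        prof = 2.0 * np.exp(-(r - 40) ** 2 / (2 * 2.0 ** 2))
        expect = prof[38:43].mean()
        np.testing.assert_allclose(kymo.values, expect, rtol=1e-9)

    def test_all_zero_bands_give_zero_kymograph(self):
        bands = [StraightenedBand(np.zeros((81, 50)), 40,
                                  np.arange(50) / 50, normalized=True)
                 for _ in range(2)]
        kymo = build_density_kymograph(bands, np.arange(2.0))
        assert np.all(kymo.values == 0)

    def test_peak_inside_margins_raises(self):
        band = self.gaussian_band(peak_row=5)
        band.data[-10:] = 0.0
        # peak sits in the outer margin: selection is constrained outside
        # margins, so the margin-adjacent window wins; a band too narrow
        # for any valid window must raise
        narrow = StraightenedBand(np.ones((21, 30)), 10, np.arange(30) / 30)
        with pytest.raises(ValueError, match="too narrow"):
            build_density_kymograph([narrow], np.arange(1.0))


class TestBleach:
    def test_series_tau_recovered_and_flattened(self):
        t = np.arange(100) * 1.0
        y = 50.0 * np.exp(-t / 100.0)
        corrected, tau = bleach_correct_series(t, y)
        assert abs(tau - 100.0) / 100.0 < 0.05
        assert np.ptp(corrected) / corrected[0] < 0.02

    def test_non_decaying_series_returned_unchanged_with_warning(self):
        t = np.arange(30) * 1.0
        y = np.full(30, 5.0) + 0.001 * t
        with pytest.warns(UserWarning, match="not decay"):
            corrected, tau = bleach_correct_series(t, y)
        np.testing.assert_array_equal(corrected, y)
        assert np.isinf(tau)

    def test_correction_is_homogeneous_of_degree_one(self):
        t = np.arange(50) * 1.0
        y = 20.0 * np.exp(-t / 60.0)
        c1, _ = bleach_correct_series(t, y)
        c2, _ = bleach_correct_series(t, 2 * y)
        np.testing.assert_allclose(c2, 2 * c1, rtol=1e-6)

    def test_movie_level_correction_flattens_cytoplasm(self):
        rng = np.random.default_rng(0)
        frames = []
        for i in range(40):
            frames.append(np.full((20, 20), 30.0) * np.exp(-i / 80.0))
        movie = MovieStack(np.stack(frames), 0.1, 1.0)
        mask = np.ones((20, 20), bool)
        corrected, tau = bleach_correct_movie(movie, mask)
        assert abs(tau - 80.0) / 80.0 < 0.05
        means = corrected.data.mean(axis=(1, 2))
        assert np.ptp(means) / means[0] < 0.02


class TestFoldMerge:
    def kymo(self, values, t0=0.0, dt=1.0, folded=False, bin_arc=0.2):
        values = np.asarray(values, dtype=float)
        n, T = values.shape
        pos = (np.linspace(0, 1, n) if folded
               else np.arange(n) / n)
        return CortexKymograph(values, pos, t0 + dt * np.arange(T),
                               folded=folded, normalized=True,
                               bin_arc_um=bin_arc)

    def test_posterior_symmetric_kymograph_folds_to_either_half(self):
        n = 200
        s = np.arange(n) / n
        prof = np.cos(2 * np.pi * s)        # symmetric about s = 0.5
        k = self.kymo(np.tile(prof[:, None], (1, 3)))
        folded = fold_kymograph(k, n_u=100)
        u = np.linspace(0, 1, 100)
        np.testing.assert_allclose(folded.values[:, 0], np.cos(np.pi * u),
                                   atol=1e-3)

    def test_folding_is_idempotent(self):
        k = self.kymo(np.random.default_rng(0).random((120, 4)))
        f1 = fold_kymograph(k)
        f2 = fold_kymograph(f1)
        np.testing.assert_array_equal(f1.values, f2.values)

    def test_blend_weights_linear_across_overlap(self):
        a = self.kymo(np.full((10, 71), 1.0), t0=0.0)      # 0..70
        b = self.kymo(np.full((10, 146), 3.0), t0=35.0)    # 35..180
        merged = merge_kymographs(a, b)
        tv = merged.t_s
        val = merged.values[0]
        assert val[tv == 0.0][0] == 1.0
        assert val[tv == 35.0][0] == 1.0                   # overlap start -> A
        assert val[tv == 70.0][0] == 3.0                   # overlap end -> B
        mid = val[tv == 52.5]
        if mid.size:
            assert mid[0] == pytest.approx(2.0)
        assert val[-1] == 3.0

    def test_disjoint_time_ranges_raise(self):
        a = self.kymo(np.ones((10, 5)), t0=0.0)
        b = self.kymo(np.ones((10, 5)), t0=100.0)
        with pytest.raises(ValueError, match="disjoint"):
            merge_kymographs(a, b)

    def test_fold_and_merge_composes_both(self):
        a = self.kymo(np.ones((100, 40)), t0=0.0)
        b = self.kymo(2 * np.ones((100, 40)), t0=20.0)
        out = fold_and_merge(a, b)
        assert out.folded
        assert out.values[0, 0] == 1.0 and out.values[0, -1] == 2.0


class TestRegionSeries:
    def test_uniform_kymograph_gives_constant_series(self):
        k = CortexKymograph(np.full((512, 6), 3.3), np.linspace(0, 1, 512),
                            np.arange(6.0), folded=True, bin_arc_um=0.2)
        _, series = region_density_series(k, 10.0)
        np.testing.assert_allclose(series, 3.3)

    def test_bin_count_follows_floor_rule(self):
        # 10 um on a 100 um half-perimeter with 512 bins -> 51 bins
        k = CortexKymograph(np.zeros((512, 2)), np.linspace(0, 1, 512),
                            np.arange(2.0), folded=True,
                            bin_arc_um=100.0 / 512)
        k.values[-51:, :] = 1.0
        k.values[:-51, :] = 5.0
        _, series = region_density_series(k, 10.0)
        np.testing.assert_allclose(series, 1.0)

    def test_region_smaller_than_one_bin_raises(self):
        k = CortexKymograph(np.zeros((10, 2)), np.linspace(0, 1, 10),
                            np.arange(2.0), folded=True, bin_arc_um=5.0)
        with pytest.raises(ValueError, match="smaller than one"):
            region_density_series(k, 1.0)

    def test_unfolded_kymograph_rejected(self):
        k = CortexKymograph(np.zeros((10, 2)), np.arange(10) / 10,
                            np.arange(2.0), folded=False, bin_arc_um=1.0)
        with pytest.raises(ValueError, match="folded"):
            region_density_series(k, 1.0)

    def test_mean_and_sem_across_embryos(self):
        mean, sem = aggregate_region_series([np.array([1.0]), np.array([3.0])])
        assert mean[0] == 2.0 and sem[0] == pytest.approx(1.0)
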