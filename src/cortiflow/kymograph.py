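"""Normalized cortical-density kymographs.

Per frame, the band 40 px (5.33 um at 0.133 um/px) inside and outside the
cell edge is straightened: the periphery, traced counterclockwise from the
anterior tip, runs left to right with the posterior tip at the central
column, and rows are inward-normal offsets (row 0 outermost). Each column
is normalized so that the local background (outside the cell) is 0 and the
local cytoplasmic level is 1. The cortex appears as a horizontal bright
stripe; the kymograph averages the five consecutive radial rows with the
strongest cortical signal (0.67 um at the native pixel size), fixed per
embryo. Movies are corrected for mono-exponential photobleaching fitted on
the cytoplasmic mean (optionally with a separate, faster cortical factor),
and recordings of two overlapping time windows are merged by a linear
blend across the overlap. For presentation and pooling, kymographs are
folded at the posterior tip onto the A->P coordinate u in [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize

from .geometry import ParameterizedContour, fold_profile, N_FOLD_BINS
from .io import MovieStack

__all__ = [
    "StraightenedBand",
    "CortexKymograph",
    "straighten_edge",
    "normalize_band",
    "build_density_kymograph",
    "fit_bleach",
    "bleach_correct_series",
    "bleach_correct_movie",
    "fold_kymograph",
    "merge_kymographs",
    "fold_and_merge",
    "region_density_series",
]

DEFAULT_HALF_WIDTH_PX = 40
DEFAULT_MARGIN_ROWS = 10


@dataclass
class StraightenedBand:
    """Straightened edge image: rows = inward-normal offsets (row 0
    outermost, centre row on the contour), columns = peripheral position."""

    data: np.ndarray
    half_width_px: int
    s_grid: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.data.shape[0] != 2 * self.half_width_px + 1:
            raise ValueError("band must have 2*half_width+1 rows")

    @property
    def n_cols(self) -> int:
        return self.data.shape[1]


@dataclass
class CortexKymograph:
    """Cortical density matrix D[position, time].

    ``positions`` is the peripheral coordinate s in [0, 1) (unfolded) or
    the A->P coordinate u in [0, 1] (folded); ``t_s`` is seconds post
    anaphase onset; ``bin_arc_um`` is the physical arc length per position
    bin."""

    values: np.ndarray
    positions: np.ndarray
    t_s: np.ndarray
    folded: bool = False
    normalized: bool = False
    bin_arc_um: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.t_s = np.asarray(self.t_s, dtype=float)
        if self.values.shape != (len(self.positions), len(self.t_s)):
            raise ValueError("kymograph shape must be (n_positions, n_times)")


# ---------------------------------------------------------------------------
# straightening and normalization
# ---------------------------------------------------------------------------

def straighten_edge(frame: np.ndarray, contour: ParameterizedContour,
                    half_width_px: int = DEFAULT_HALF_WIDTH_PX,
                    n_cols: int | None = None) -> StraightenedBand:
    """Resample the frame along inward normals at uniform arc steps.

    Samples falling outside the image are marked NaN (missing) with a
    warning; they are excluded from all downstream means, never zero-filled.
    """
    img = np.asarray(frame, dtype=float)
    h, w = img.shape
    if n_cols is None:
        n_cols = int(round(contour.perimeter_px))
    s_grid = np.arange(n_cols) / n_cols
    pts = contour.point_at(s_grid)
    normals = contour.inward_normal_at(s_grid)
    offsets = np.arange(-half_width_px, half_width_px + 1)

    coords = pts[None, :, :] + offsets[:, None, None] * normals[None, :, :]
    x = coords[..., 0]
    y = coords[..., 1]
    vals = ndimage.map_coordinates(img, [y.ravel(), x.ravel()], order=1,
                                   mode="nearest")
    band = vals.reshape(x.shape)
    outside = (x < 0) | (x > w - 1) | (y < 0) | (y > h - 1)
    if outside.any():
        warnings.warn(f"{int(outside.sum())} band samples fall outside the "
                      "image and are marked missing")
        band[outside] = np.nan
    return StraightenedBand(band, half_width_px, s_grid)


def normalize_band(band: StraightenedBand,
                   margin_rows: int = DEFAULT_MARGIN_ROWS,
                   smooth_cols: int = 25, eps: float = 1e-6) -> StraightenedBand:
    """Per column, map the local background (outer margin rows) to 0 and the
    local cytoplasmic level (inner margin rows) to 1.

    Margin means are smoothed along the periphery (periodic uniform filter
    over ``smooth_cols`` columns) before use. Columns whose cytoplasm minus
    background difference falls below ``eps`` are reported in the error.
    """
    data = band.data
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        bg = np.nanmean(data[:margin_rows], axis=0)
        cyto = np.nanmean(data[-margin_rows:], axis=0)
    if smooth_cols > 1:
        bg = ndimage.uniform_filter1d(bg, smooth_cols, mode="wrap")
        cyto = ndimage.uniform_filter1d(cyto, smooth_cols, mode="wrap")
    denom = cyto - bg
    bad = ~(denom > eps)
    if bad.any():
        cols = np.nonzero(bad)[0]
        raise ValueError(
            f"cytoplasm-background difference below {eps} in "
            f"{cols.size} columns (first: {cols[:10].tolist()})")
    out = (data - bg[None, :]) / denom[None, :]
    return StraightenedBand(out, band.half_width_px, band.s_grid.copy(),
                            normalized=True)


def build_density_kymograph(bands: list[StraightenedBand], t_s: np.ndarray,
                            margin_rows: int = DEFAULT_MARGIN_ROWS,
                            n_rows_avg: int = 5,
                            pixel_size_um: float | None = None,
                            perimeter_um: float | None = None) -> CortexKymograph:
    """Average the ``n_rows_avg`` consecutive radial rows with maximal total
    signal in the cortical peak zone — selected once per embryo, fixed over
    time — into a D[s, t] kymograph.

    Raises when the selected peak rows touch the normalization margins
    (which indicates misconfigured margins).
    """
    if not bands:
        raise ValueError("no bands supplied")
    stack = np.stack([b.data for b in bands], axis=2)   # (rows, cols, T)
    n_rows = stack.shape[0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        row_score = np.nansum(np.nan_to_num(stack, nan=0.0), axis=(1, 2))
    window_sums = np.convolve(row_score, np.ones(n_rows_avg), mode="valid")
    start_lo, start_hi = margin_rows, n_rows - margin_rows - n_rows_avg
    if start_hi < start_lo:
        raise ValueError("band too narrow for peak selection outside margins")
    valid = window_sums[start_lo:start_hi + 1]
    best = start_lo + int(np.argmax(valid))
    rows = slice(best, best + n_rows_avg)
    if best < margin_rows or best + n_rows_avg > n_rows - margin_rows:
        raise ValueError("cortical peak zone overlaps the normalization "
                         "margins; adjust margins or band width")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        values = np.nanmean(stack[rows], axis=0)        # (cols, T)
    bin_arc = None
    if perimeter_um is not None:
        bin_arc = perimeter_um / stack.shape[1]
    elif pixel_size_um is not None:
        bin_arc = pixel_size_um                          # ~1 px per column
    return CortexKymograph(values=values, positions=bands[0].s_grid.copy(),
                           t_s=np.asarray(t_s, dtype=float), folded=False,
                           normalized=all(b.normalized for b in bands),
                           bin_arc_um=bin_arc)


# ---------------------------------------------------------------------------
# bleach correction
# ---------------------------------------------------------------------------

def fit_bleach(t_s: np.ndarray, series: np.ndarray):
    """Fit ``A * exp(-t / tau)``; returns (A, tau_s)."""
    t = np.asarray(t_s, dtype=float)
    y = np.asarray(series, dtype=float)
    if np.any(y <= 0):
        raise ValueError("bleach fit needs positive intensities")
    slope, icept = np.polyfit(t, np.log(y), 1)
    tau0 = -1.0 / slope if slope < 0 else 1e6
    try:
        popt, _ = optimize.curve_fit(
            lambda tt, a, tau: a * np.exp(-tt / tau), t, y,
            p0=[float(np.exp(icept)), float(tau0)], maxfev=10000)
        return float(popt[0]), float(popt[1])
    except Exception:
        return float(np.exp(icept)), float(tau0)


def bleach_correct_series(t_s: np.ndarray, series: np.ndarray):
    """Divide a series by its fitted mono-exponential decay (normalized to
    1 at the first time point). Non-decaying series are returned unchanged
    with a warning. Returns ``(corrected, tau_s)``."""
    y = np.asarray(series, dtype=float)
    if y.size < 20:
        raise ValueError("need at least 20 time points for a bleach fit")
    a, tau = fit_bleach(t_s, y)
    if not (0 < tau < 1e5):
        warnings.warn("series does not decay; bleach correction skipped")
        return y.copy(), np.inf
    factor = np.exp(-(np.asarray(t_s) - t_s[0]) / tau)
    return y / factor, tau


def bleach_correct_movie(movie: MovieStack, cyto_mask: np.ndarray,
                         cortex_mask: np.ndarray | None = None,
                         background_mask: np.ndarray | None = None):
    """Correct a movie for photobleaching using the cytoplasmic mean.

    A mono-exponential is fitted to the mean intensity over ``cyto_mask``
    and the fluorescent part of each frame is divided by the fitted factor
    (1 at frame 0). When ``background_mask`` (outside the cell) is given,
    its per-frame mean — the unbleached camera offset — is subtracted
    before fitting and correcting and added back afterwards; leaving the
    offset in would bias the fitted tau upward. When ``cortex_mask`` is
    given, a separate factor is fitted on the cortical band mean and
    additionally applied there — bleaching is faster at the cortex, where
    exchange with unbleached cytoplasmic molecules is slower.
    Returns ``(corrected_movie, tau_cyto_s)``.
    """
    if movie.n_frames < 20:
        raise ValueError("need at least 20 frames for a bleach fit")
    t = np.arange(movie.n_frames) * movie.frame_interval_s
    frames = np.stack([movie.frame(i) for i in range(movie.n_frames)])
    if background_mask is not None and background_mask.any():
        bg = frames[:, background_mask].mean(axis=1)
    else:
        bg = np.zeros(movie.n_frames)
    series = frames[:, cyto_mask].mean(axis=1) - bg
    _, tau = fit_bleach(t, series)
    if not (0 < tau < 1e5):
        warnings.warn("cytoplasmic mean does not decay; movie unchanged")
        return movie, np.inf
    factor = np.exp(-t / tau)
    corrected = (frames - bg[:, None, None]) / factor[:, None, None] \
        + bg[:, None, None]
    if cortex_mask is not None:
        cser = frames[:, cortex_mask].mean(axis=1) - bg
        _, tau_c = fit_bleach(t, cser)
        if 0 < tau_c < 1e5 and tau_c < tau:
            extra = np.exp(-t * (1.0 / tau_c - 1.0 / tau))
            corrected[:, cortex_mask] = (
                (corrected[:, cortex_mask] - bg[:, None]) / extra[:, None]
                + bg[:, None])
    out = MovieStack(np.clip(corrected, 0, None), movie.pixel_size_um,
                     movie.frame_interval_s, movie.t0_frame, movie.channel)
    return out, tau


# ---------------------------------------------------------------------------
# folding, merging, region series
# ---------------------------------------------------------------------------

def fold_kymograph(kymo: CortexKymograph, n_u: int = N_FOLD_BINS) -> CortexKymograph:
    """Fold at the posterior tip (s = 0.5): average the two half-perimeters
    onto the A->P coordinate u in [0, 1]. Idempotent on folded input."""
    if kymo.folded:
        return kymo
    folded = fold_profile(kymo.values, kymo.positions, n_u=n_u)
    bin_arc = None
    if kymo.bin_arc_um is not None:
        half_perim = kymo.bin_arc_um * kymo.values.shape[0] / 2.0
        bin_arc = half_perim / n_u
    return CortexKymograph(values=folded, positions=np.linspace(0, 1, n_u),
                           t_s=kymo.t_s.copy(), folded=True,
                           normalized=kymo.normalized, bin_arc_um=bin_arc)


def merge_kymographs(kymo_a: CortexKymograph, kymo_b: CortexKymograph) -> CortexKymograph:
    """Merge two kymographs recorded over overlapping time windows.

    Output equals A before the overlap and B after it; across the overlap
    the blending weight of A falls linearly from 1 to 0 (B complementary).
    Both inputs must share the position grid and frame interval.
    """
    if kymo_a.values.shape[0] != kymo_b.values.shape[0]:
        raise ValueError("kymographs must share the position grid")
    ta, tb = kymo_a.t_s, kymo_b.t_s
    t0_ov, t1_ov = max(ta[0], tb[0]), min(ta[-1], tb[-1])
    if t1_ov < t0_ov:
        raise ValueError("time ranges are disjoint; nothing to blend")
    dt = np.median(np.diff(ta))
    t_out = np.arange(min(ta[0], tb[0]), max(ta[-1], tb[-1]) + dt / 2, dt)

    def resample(k):
        out = np.empty((k.values.shape[0], t_out.size))
        for i in range(k.values.shape[0]):
            out[i] = np.interp(t_out, k.t_s, k.values[i],
                               left=np.nan, right=np.nan)
        return out

    va, vb = resample(kymo_a), resample(kymo_b)
    if t1_ov > t0_ov:
        w_a = np.clip((t1_ov - t_out) / (t1_ov - t0_ov), 0.0, 1.0)
    else:
        w_a = (t_out <= t0_ov).astype(float)
    w_a[t_out < tb[0]] = 1.0
    w_a[t_out > ta[-1]] = 0.0
    va = np.nan_to_num(va, nan=0.0)
    vb = np.nan_to_num(vb, nan=0.0)
    merged = w_a[None, :] * va + (1.0 - w_a[None, :]) * vb
    return CortexKymograph(values=merged, positions=kymo_a.positions.copy(),
                           t_s=t_out, folded=kymo_a.folded,
                           normalized=kymo_a.normalized and kymo_b.normalized,
                           bin_arc_um=kymo_a.bin_arc_um)


def fold_and_merge(kymo_a: CortexKymograph, kymo_b: CortexKymograph,
                   n_u: int = N_FOLD_BINS) -> CortexKymograph:
    """Fold both kymographs at the posterior tip, then time-blend them."""
    return merge_kymographs(fold_kymograph(kymo_a, n_u), fold_kymograph(kymo_b, n_u))


def region_density_series(kymo: CortexKymograph, region_um: float = 10.0):
    """Mean density within ``region_um`` of arc length from the posterior
    tip (u = 1), per time point. Requires a folded kymograph with known
    arc calibration; returns ``(t_s, series)``."""
    if not kymo.folded:
        raise ValueError("region series requires a folded kymograph")
    if kymo.bin_arc_um is None:
        raise ValueError("kymograph lacks physical arc calibration")
    n_u = kymo.values.shape[0]
    half_perim = kymo.bin_arc_um * n_u
    n_sel = int(np.floor(region_um / half_perim * n_u))
    if n_sel < 1:
        raise ValueError("region smaller than one kymograph bin")
    series = kymo.values[-n_sel:].mean(axis=0)
    return kymo.t_s.copy(), series


def aggregate_region_series(series_list: list[np.ndarray]):
    """Mean +/- SEM across embryos of per-embryo region series (aligned on
    a common time grid)."""
    stack = np.vstack(series_list)
    n = stack.shape[0]
    mean = stack.mean(axis=0)
    sem = stack.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros_like(mean)
    return mean, sem
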