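"""Cell-boundary extraction, arc-length parameterization and pole geometry.

The cell periphery of each frame is reduced to a closed polyline traced
counterclockwise from the anterior tip. Positions along it are expressed on
the normalized arc coordinate ``s`` in [0, 1) (anterior tip 0, posterior tip
near 0.5) or on the folded coordinate ``u`` in [0, 1] (anterior 0, posterior
1) obtained by averaging the two half-perimeters.

Conventions: 0-based pixel coordinates, x = column, y = row; a polyline is
counterclockwise when its shoelace area in (x, y) is positive, in which case
the cell interior lies to the left of travel and the inward normal of a unit
tangent (tx, ty) is (-ty, tx). Physical length = pixels x ``pixel_size_um``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, interpolate
from scipy.spatial import cKDTree
from skimage import measure, morphology
from skimage.filters import threshold_otsu

__all__ = [
    "ParameterizedContour",
    "PoleTrack",
    "segment_boundary",
    "parameterize_contour",
    "offset_sampling_band",
    "pole_cortex_distance",
    "fold_profile",
    "N_FOLD_BINS",
]

N_FOLD_BINS = 512


def polygon_mask(shape: tuple[int, int], xy: np.ndarray) -> np.ndarray:
    """Boolean mask of the polygon interior, by even-odd scanline fill at
    pixel centres (vectorized over edges per row)."""
    h, w = shape
    x1, y1 = xy[:, 0], xy[:, 1]
    x2, y2 = np.roll(x1, -1), np.roll(y1, -1)
    mask = np.zeros((h, w), dtype=bool)
    row_lo = max(int(np.floor(y1.min())), 0)
    row_hi = min(int(np.ceil(y1.max())), h - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv_dy = 1.0 / (y2 - y1)
    for yc in range(row_lo, row_hi + 1):
        crosses = (y1 <= yc) != (y2 <= yc)
        if not crosses.any():
            continue
        xs = x1[crosses] + (yc - y1[crosses]) * inv_dy[crosses] * (
            x2[crosses] - x1[crosses])
        xs = np.sort(xs)
        for a, b in zip(xs[0::2], xs[1::2]):
            lo = max(int(np.ceil(a)), 0)
            hi = min(int(np.floor(b)), w - 1)
            if hi >= lo:
                mask[yc, lo:hi + 1] = True
    return mask


def _polyline_area(xy: np.ndarray) -> float:
    x, y = xy[:, 0], xy[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _arc_lengths(xy: np.ndarray) -> np.ndarray:
    closed = np.vstack([xy, xy[:1]])
    return np.linalg.norm(np.diff(closed, axis=0), axis=1)


def _is_simple(xy: np.ndarray) -> bool:
    # coarse self-intersection screen: consecutive arc length must dominate
    # point-to-point shortcuts; exact O(n^2) checks are overkill here.
    seg = _arc_lengths(xy)
    return np.all(seg > 0)


@dataclass
class ParameterizedContour:
    """Closed cell boundary with normalized arc-length coordinate.

    ``xy[k]`` sits at arc position ``s[k]``; ``xy[0]`` is the anterior tip
    (s = 0) and vertex order is counterclockwise (positive shoelace area).
    """

    xy: np.ndarray
    s: np.ndarray
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, dtype=float)
        self.s = np.asarray(self.s, dtype=float)
        if self.xy.shape[0] < 3:
            raise ValueError("contour needs at least 3 vertices")
        if np.any(np.diff(self.s) <= 0):
            raise ValueError("arc coordinate must be strictly increasing")

    # -- basic measures ---------------------------------------------------
    @property
    def n(self) -> int:
        return self.xy.shape[0]

    @property
    def perimeter_px(self) -> float:
        return float(_arc_lengths(self.xy).sum())

    @property
    def perimeter_um(self) -> float:
        return self.perimeter_px * self.pixel_size_um

    def enclosed_area_px(self) -> float:
        return abs(_polyline_area(self.xy))

    # -- interpolation ----------------------------------------------------
    def _periodic(self):
        s_ext = np.concatenate([self.s, [1.0]])
        xy_ext = np.vstack([self.xy, self.xy[:1]])
        return s_ext, xy_ext

    @property
    def kdtree(self):
        """Cached KD-tree of the vertices, for nearest-boundary queries."""
        tree = getattr(self, "_kdtree", None)
        if tree is None:
            tree = cKDTree(self.xy)
            object.__setattr__(self, "_kdtree", tree)
        return tree

    def point_at(self, s) -> np.ndarray:
        """Periodic linear interpolation of boundary points at arc values."""
        s = np.mod(np.atleast_1d(np.asarray(s, dtype=float)), 1.0)
        s_ext, xy_ext = self._periodic()
        x = np.interp(s, s_ext, xy_ext[:, 0])
        y = np.interp(s, s_ext, xy_ext[:, 1])
        return np.column_stack([x, y])

    def tangent_at(self, s) -> np.ndarray:
        s = np.atleast_1d(np.asarray(s, dtype=float))
        eps = 0.25 / self.n
        p1 = self.point_at(s + eps)
        p0 = self.point_at(s - eps)
        t = p1 - p0
        norm = np.linalg.norm(t, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        return t / norm

    def inward_normal_at(self, s) -> np.ndarray:
        t = self.tangent_at(s)
        return np.column_stack([-t[:, 1], t[:, 0]])

    # -- landmarks --------------------------------------------------------
    def major_axis(self) -> np.ndarray:
        c = self.xy - self.xy.mean(axis=0)
        cov = c.T @ c / len(c)
        vals, vecs = np.linalg.eigh(cov)
        return vecs[:, int(np.argmax(vals))]

    def posterior_s(self) -> float:
        """Arc position of the vertex farthest along the A-P axis."""
        axis = self.major_axis()
        proj = (self.xy - self.xy[0]) @ axis
        # anterior tip is at an extremum of the projection; posterior is the
        # opposite extremum regardless of the eigenvector's sign
        idx = int(np.argmax(np.abs(proj)))
        return float(self.s[idx])


@dataclass
class PoleTrack:
    """Per-frame (x, y) positions of the anterior and posterior spindle
    poles, in pixels. ``source`` records provenance (ground truth, manual
    annotation, or detection)."""

    anterior_xy: np.ndarray   # (T, 2)
    posterior_xy: np.ndarray  # (T, 2)
    source: str = "ground_truth"

    def __post_init__(self) -> None:
        self.anterior_xy = np.asarray(self.anterior_xy, dtype=float)
        self.posterior_xy = np.asarray(self.posterior_xy, dtype=float)
        if self.anterior_xy.shape != self.posterior_xy.shape:
            raise ValueError("pole tracks must cover the same frames")

    @property
    def n_frames(self) -> int:
        return self.anterior_xy.shape[0]

    def poles_at(self, frame: int) -> np.ndarray:
        return np.vstack([self.anterior_xy[frame], self.posterior_xy[frame]])


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def _refine_to_ridge(img: np.ndarray, xy: np.ndarray, search_px: float,
                     prominence: float = 1.3) -> np.ndarray:
    """Snap each vertex of a closed polyline to the nearby intensity ridge
    along its local normal, where a ridge is prominent.

    A bright cortical band makes the threshold contour sit on the band's
    outer flank; snapping each vertex to the local intensity maximum along
    the normal re-centres the contour on the band. Vertices whose normal
    profile has no prominent maximum (plain step edges, e.g. a uniform
    disk) are left in place, so the refinement is a no-op there.
    """
    n = len(xy)
    tang = np.roll(xy, -1, axis=0) - np.roll(xy, 1, axis=0)
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    normal = np.column_stack([-tang[:, 1], tang[:, 0]])   # inward for ccw
    offsets = np.arange(-search_px, search_px + 1.0)
    coords = xy[None, :, :] + offsets[:, None, None] * normal[None, :, :]
    prof = ndimage.map_coordinates(
        img, [coords[..., 1].ravel(), coords[..., 0].ravel()],
        order=1, mode="nearest").reshape(len(offsets), n)
    imax = np.argmax(prof, axis=0)
    peak = prof[imax, np.arange(n)]
    inner_ref = prof[-3:].mean(axis=0)
    outer_ref = prof[:3].mean(axis=0)
    has_ridge = peak > prominence * np.maximum(inner_ref, outer_ref)
    # subpixel parabolic refinement of the ridge position
    off = offsets[imax].astype(float)
    interior = (imax > 0) & (imax < len(offsets) - 1)
    i0 = np.clip(imax, 1, len(offsets) - 2)
    y0 = prof[i0 - 1, np.arange(n)]
    y1 = prof[i0, np.arange(n)]
    y2 = prof[i0 + 1, np.arange(n)]
    denom = y0 - 2 * y1 + y2
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = np.where(np.abs(denom) > 1e-12, 0.5 * (y0 - y2) / denom, 0.0)
    off = off + np.where(interior, np.clip(delta, -1, 1), 0.0)
    valid = has_ridge & interior
    if not valid.any():
        return xy.copy()
    # the ridge offset varies slowly along the boundary: fill gaps by
    # periodic interpolation and low-pass the offset field, so texture and
    # noise jitter do not corrugate the contour (which would inflate its
    # arc length)
    idx = np.arange(n)
    vi = idx[valid]
    off_filled = np.interp(idx, np.concatenate([vi - n, vi, vi + n]),
                           np.tile(off[valid], 3))
    off_smooth = ndimage.uniform_filter1d(off_filled, max(n // 64, 3),
                                          mode="wrap")
    return xy + off_smooth[:, None] * normal


def segment_boundary(frame: np.ndarray, sigma: float = 1.0,
                     min_area: int = 500, threshold: float | None = None,
                     closing_radius: int = 3, smooth: float | None = None,
                     n_points: int = 1024, ridge_search_px: float = 10.0
                     ) -> np.ndarray:
    """Extract the closed cell boundary from one intensity frame.

    Gaussian blur -> intensity threshold (Otsu between the background and
    cell modes unless given) -> largest connected component -> morphological
    closing and hole filling -> marching-squares contour -> snap to the
    cortical intensity ridge where one is prominent -> periodic smoothing
    spline. Returns an (n, 2) polyline in (x, y) pixels.

    Raises ``ValueError`` ("no embryo found") when no component reaches
    ``min_area``, and an ambiguity error when a second component comes
    within half the size of the largest.
    """
    img = ndimage.gaussian_filter(np.asarray(frame, dtype=float), sigma)
    if threshold is None:
        # the histogram has up to three modes (background, cytoplasm, bright
        # cortical band); the lowest multi-Otsu split separates background
        # from cell without being attracted to the cytoplasm/cortex gap
        try:
            from skimage.filters import threshold_multiotsu
            threshold = float(threshold_multiotsu(img, classes=3)[0])
        except Exception:
            threshold = float(threshold_otsu(img))
    binary = img > threshold

    def _largest(mask_in):
        labels, n_lab = ndimage.label(mask_in)
        return labels, n_lab

    labels, n_lab = _largest(binary)
    if n_lab == 0:
        raise ValueError("no embryo found: nothing above threshold")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n_lab + 1))
    order = np.argsort(sizes)[::-1]
    if sizes[order[0]] < min_area:
        raise ValueError("no embryo found: largest component below min_area")
    if len(order) > 1 and sizes[order[1]] >= 0.5 * sizes[order[0]]:
        raise ValueError(
            "ambiguous segmentation: two comparable components "
            f"({int(sizes[order[0]])} and {int(sizes[order[1]])} px)")
    mask = labels == order[0] + 1
    if closing_radius > 0:
        mask = morphology.closing(mask, morphology.disk(closing_radius))
    mask = ndimage.binary_fill_holes(mask)

    # second pass: re-threshold midway between the interior and exterior
    # medians, so the contour sits at the mid-level crossing of the blurred
    # edge rather than wherever the histogram split happened to land
    inner = ndimage.binary_erosion(mask, iterations=3)
    outer = ~ndimage.binary_dilation(mask, iterations=3)
    if inner.any() and outer.any():
        t_mid = 0.5 * (np.median(img[inner]) + np.median(img[outer]))
        refined = ndimage.binary_fill_holes(img > t_mid) & ndimage.binary_dilation(
            mask, iterations=5)
        labels2, n2 = ndimage.label(refined)
        if n2 >= 1:
            sizes2 = ndimage.sum_labels(np.ones_like(labels2), labels2,
                                        np.arange(1, n2 + 1))
            cand = labels2 == int(np.argmax(sizes2)) + 1
            if cand.sum() >= min_area:
                mask = cand
                if closing_radius > 0:
                    mask = morphology.closing(mask, morphology.disk(closing_radius))
                mask = ndimage.binary_fill_holes(mask)

    contours = measure.find_contours(mask.astype(float), 0.5)
    contour = max(contours, key=len)          # (row, col)
    xy = contour[:, ::-1]
    if np.allclose(xy[0], xy[-1]):
        xy = xy[:-1]

    if smooth is None:
        smooth = len(xy) * 0.5

    def _spline(pts, s_val):
        tck, _ = interpolate.splprep([pts[:, 0], pts[:, 1]], s=s_val, per=1, k=3)
        q = np.linspace(0, 1, n_points, endpoint=False)
        sx, sy = interpolate.splev(q, tck)
        return np.column_stack([sx, sy])

    try:
        xy = _spline(xy, smooth)
        if ridge_search_px > 0:
            xy = _refine_to_ridge(img, xy, ridge_search_px)
            xy = _spline(xy, n_points * 0.25)
    except Exception:                          # degenerate spline: keep raw
        warnings.warn("boundary smoothing failed; returning raw contour")
    return xy


# ---------------------------------------------------------------------------
# parameterization
# ---------------------------------------------------------------------------

def parameterize_contour(polyline: np.ndarray, anterior_hint,
                         pixel_size_um: float = 1.0,
                         n_points: int | None = None) -> ParameterizedContour:
    """Orient a closed polyline counterclockwise, anchor it at the anterior
    tip and attach the normalized arc coordinate.

    The anchor is the boundary point of extremal projection onto the major
    (principal) axis that lies nearest ``anterior_hint``; anterior identity
    is never inferred silently, the hint is required.
    """
    xy = np.asarray(polyline, dtype=float)
    if np.allclose(xy[0], xy[-1]) and len(xy) > 1:
        xy = xy[:-1]
    if xy.shape[0] < 3:
        raise ValueError("degenerate polyline: need at least 3 vertices")
    if not _is_simple(xy):
        raise ValueError("polyline has zero-length segments")

    if _polyline_area(xy) < 0:
        xy = xy[::-1].copy()

    hint = np.asarray(anterior_hint, dtype=float)
    centroid = xy.mean(axis=0)
    c = xy - centroid
    cov = c.T @ c / len(c)
    vals, vecs = np.linalg.eigh(cov)
    axis = vecs[:, int(np.argmax(vals))]
    perp = np.array([-axis[1], axis[0]])

    # anchor = subpixel intersection of the major-axis line with the
    # boundary on the hinted side; the axis is a whole-contour fit, so the
    # anchor is far more stable frame to frame than an extremal vertex
    wc = c @ perp
    uc = c @ axis
    nxt = np.roll(np.arange(len(xy)), -1)
    sign_change = (wc * wc[nxt] < 0) | (wc == 0)
    cand_pts, cand_u, cand_seg, cand_t = [], [], [], []
    for i in np.nonzero(sign_change)[0]:
        j = (i + 1) % len(xy)
        denom = wc[i] - wc[j]
        t = wc[i] / denom if denom != 0 else 0.0
        cand_pts.append(xy[i] + t * (xy[j] - xy[i]))
        cand_u.append(uc[i] + t * (uc[j] - uc[i]))
        cand_seg.append(i)
        cand_t.append(t)
    if len(cand_pts) >= 2:
        cand_u = np.asarray(cand_u)
        tips = [int(np.argmin(cand_u)), int(np.argmax(cand_u))]
        dists = [np.linalg.norm(cand_pts[k] - hint) for k in tips]
        k = tips[int(np.argmin(dists))]
        anchor_pt, seg_i, seg_t = cand_pts[k], cand_seg[k], cand_t[k]
        if seg_t <= 1e-9:
            anchor = seg_i
        elif seg_t >= 1.0 - 1e-9:
            anchor = (seg_i + 1) % len(xy)
        else:                     # insert the anchor as a vertex
            xy = np.insert(xy, seg_i + 1, anchor_pt, axis=0)
            anchor = seg_i + 1
    else:                          # degenerate: fall back to extremal vertex
        proj = c @ axis
        cand = np.array([int(np.argmin(proj)), int(np.argmax(proj))])
        dists = np.linalg.norm(xy[cand] - hint, axis=1)
        anchor = int(cand[int(np.argmin(dists))])

    xy = np.roll(xy, -anchor, axis=0)
    seg = _arc_lengths(xy)
    keep = np.concatenate([[True], seg[:-1] > 1e-12])   # drop duplicate vertices
    xy = xy[keep]
    seg = _arc_lengths(xy)
    total = seg.sum()
    s = np.concatenate([[0.0], np.cumsum(seg[:-1])]) / total

    if n_points is not None and n_points != len(xy):
        s_ext = np.concatenate([s, [1.0]])
        xy_ext = np.vstack([xy, xy[:1]])
        q = np.arange(n_points) / n_points
        xy = np.column_stack([np.interp(q, s_ext, xy_ext[:, 0]),
                              np.interp(q, s_ext, xy_ext[:, 1])])
        s = q
    return ParameterizedContour(xy=xy, s=s, pixel_size_um=pixel_size_um)


# ---------------------------------------------------------------------------
# offset bands and pole distances
# ---------------------------------------------------------------------------

@dataclass
class SampleBand:
    """Transects of sample coordinates at inward offsets from the contour.

    ``coords`` has shape (n_samples, n_across, 2) in (x, y) pixels; the
    transect at peripheral position ``s_grid[i]`` spans inward offsets
    ``offsets_px`` (ascending, px)."""

    coords: np.ndarray
    s_grid: np.ndarray
    offsets_px: np.ndarray


def offset_sampling_band(contour: ParameterizedContour, inset_um: float,
                         width_um: float, n_samples: int,
                         n_across: int | None = None) -> SampleBand:
    """Sampling grid for a band of ``width_um`` centred ``inset_um`` inside
    the boundary (e.g. the 1-um-wide line 1.5 um inside the cell used for
    near-cortex microtubule density)."""
    px = contour.pixel_size_um
    inset_px = inset_um / px
    half_px = 0.5 * width_um / px
    if n_across is None:
        n_across = max(int(round(width_um / px)) + 1, 1)
    if width_um == 0:
        n_across = 1

    s_grid = np.arange(n_samples) / n_samples
    pts = contour.point_at(s_grid)
    normals = contour.inward_normal_at(s_grid)

    # local radius of curvature from the turning rate of the tangent
    tang = contour.tangent_at(s_grid)
    dtds = np.gradient(tang, axis=0) * n_samples    # d tangent / d s
    kappa = np.linalg.norm(dtds, axis=1) / max(contour.perimeter_px, 1e-12)
    with np.errstate(divide="ignore"):
        radius = 1.0 / np.where(kappa > 0, kappa, np.inf)
    max_reach = inset_px + half_px
    bad = radius < max_reach
    if np.any(bad):
        lo, hi = s_grid[bad].min(), s_grid[bad].max()
        raise ValueError(
            f"inset {inset_um} um exceeds the local radius of curvature for "
            f"s in [{lo:.3f}, {hi:.3f}]")

    if n_across == 1:
        offsets = np.array([inset_px])
    else:
        offsets = np.linspace(inset_px - half_px, inset_px + half_px, n_across)
    coords = pts[:, None, :] + offsets[None, :, None] * normals[:, None, :]
    return SampleBand(coords=coords, s_grid=s_grid, offsets_px=offsets)


def fold_profile(values: np.ndarray, s_grid: np.ndarray | None = None,
                 n_u: int = N_FOLD_BINS, signed: bool = False) -> np.ndarray:
    """Fold a profile on the full periphery s in [0, 1) onto the A->P
    coordinate u in [0, 1] by averaging the two half-perimeters.

    With ``signed=True`` the second side is negated before averaging (used
    for velocities, whose along-s sign flips between the two sides).
    Accepts a 1D profile or a (n_s, n_t) kymograph.
    """
    values = np.asarray(values, dtype=float)
    one_d = values.ndim == 1
    if one_d:
        values = values[:, None]
    n_s = values.shape[0]
    if s_grid is None:
        s_grid = np.arange(n_s) / n_s
    u = np.linspace(0.0, 1.0, n_u)
    s_ext = np.concatenate([s_grid, [1.0]])
    v_ext = np.vstack([values, values[:1]])
    out = np.empty((n_u, values.shape[1]))
    for j in range(values.shape[1]):
        side1 = np.interp(u / 2.0, s_ext, v_ext[:, j])
        side2 = np.interp(1.0 - u / 2.0, s_ext, v_ext[:, j])
        out[:, j] = 0.5 * (side1 - side2) if signed else 0.5 * (side1 + side2)
    return out[:, 0] if one_d else out


def pole_cortex_distance(contour: ParameterizedContour, poles: np.ndarray,
                         n_u: int = N_FOLD_BINS):
    """Distance from each peripheral point to the nearest spindle pole.

    ``poles`` is (2, 2): anterior and posterior (x, y) in pixels; both must
    lie inside the contour. Returns ``(u_grid, d_um)`` on the folded A->P
    coordinate with ``n_u`` bins.
    """
    poles = np.asarray(poles, dtype=float)
    from matplotlib.path import Path as MplPath
    path = MplPath(contour.xy)
    if not np.all(path.contains_points(poles)):
        raise ValueError("poles must lie inside the contour")
    n_s = max(2 * n_u, contour.n)
    s_dense = np.arange(n_s) / n_s
    pts = contour.point_at(s_dense)
    d = np.linalg.norm(pts[:, None, :] - poles[None, :, :], axis=2).min(axis=1)
    d_um = d * contour.pixel_size_um
    u = np.linspace(0.0, 1.0, n_u)
    return u, fold_profile(d_um, s_dense, n_u=n_u)


def pole_distance_profiles(contours: dict[int, ParameterizedContour],
                           pole_track: PoleTrack, n_u: int = N_FOLD_BINS):
    """Per-frame d(u) profiles; frames with a missing pole are skipped with
    a warning. Returns ``(u_grid, {frame: d_um})``."""
    u = np.linspace(0.0, 1.0, n_u)
    out: dict[int, np.ndarray] = {}
    for frame, contour in sorted(contours.items()):
        if frame >= pole_track.n_frames:
            warnings.warn(f"no pole positions for frame {frame}; skipped")
            continue
        poles = pole_track.poles_at(frame)
        if np.any(~np.isfinite(poles)):
            warnings.warn(f"missing pole in frame {frame}; skipped")
            continue
        _, out[frame] = pole_cortex_distance(contour, poles, n_u=n_u)
    return u, out
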