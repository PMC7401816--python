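"""Centrosome-directed transport activity of cytoplasmic myosin particles.

The drag force on a particle moving at velocity v in a viscous cytoplasm is
proportional to v, so the power expended is proportional to v^2. With the
particle's fluorescence intensity I as a proxy for its size, the transport
activity of one trajectory step is scored as I * dz'^2, where z is the
centrosome-directed component of the motion (after compensating the whole-
aster drift via the A-P component of a tracked chromosome) and z' its
smoothed version; only steps with dz' > 0 (movement toward the pole) count.
Per embryo the step activities of all away-moving particles are summed per
time point and accumulated from anaphase onset; curves are then averaged
across embryos (mean +/- SEM).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import MovieStack
from .tracking import Trajectory

__all__ = [
    "ChromosomeTrack",
    "TransportRecord",
    "track_chromosome",
    "compensate_and_project",
    "transport_score",
    "aggregate_transport",
]


@dataclass
class ChromosomeTrack:
    """Semi-automated track of a chromosome dark spot: per-frame (x, y)
    obtained by repeatedly locating the nearest intensity minimum within
    ``search_radius_px`` of the previous position."""

    frames: np.ndarray
    xy: np.ndarray
    search_radius_px: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.xy = np.asarray(self.xy, dtype=float).reshape(-1, 2)
        steps = np.linalg.norm(np.diff(self.xy, axis=0), axis=1)
        if steps.size and steps.max() > self.search_radius_px + 1e-9:
            raise ValueError("chromosome step exceeds the search radius")

    def position_at(self, frame: int) -> np.ndarray:
        idx = int(frame) - int(self.frames[0])
        if idx < 0 or idx >= len(self.frames):
            raise KeyError(f"chromosome track does not cover frame {frame}")
        return self.xy[idx]


@dataclass
class TransportRecord:
    """Per-trajectory transport scoring: the centrosome-directed coordinate
    z (um), its smoothed version z', per-step increments dz' and activities
    a = I * dz'^2 (zero where dz' <= 0)."""

    z_um: np.ndarray
    z_smooth_um: np.ndarray
    dz_um: np.ndarray
    activity: np.ndarray
    frames: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.any(self.activity < 0):
            raise ValueError("activity must be nonnegative")

    @property
    def total(self) -> float:
        return float(self.activity.sum())


def track_chromosome(movie: MovieStack, seed_xy, search_radius_px: float,
                     smooth_sigma: float = 2.0, min_dip_frac: float = 0.15,
                     min_dip_abs: float = 0.0, start_frame: int = 0,
                     end_frame: int | None = None) -> ChromosomeTrack:
    """Track a dark chromosome spot frame to frame.

    From the seeded position, each next position is the darkest pixel within
    ``search_radius_px`` of the previous one. The minimum must dip below the
    surrounding cytoplasm (median of a box twice the search radius) by at
    least ``min_dip_frac`` of that level (and by ``min_dip_abs`` absolute
    units, if set); otherwise the spot was lost and the track terminates
    with an error naming the frame. The fractional criterion is scale-free,
    so exposure and bleaching do not affect it.
    """
    end = movie.n_frames if end_frame is None else end_frame
    r = int(np.ceil(search_radius_px))
    rb = 2 * r
    dy, dx = np.mgrid[-r:r + 1, -r:r + 1]
    disc = (dx ** 2 + dy ** 2) <= search_radius_px ** 2

    pos = np.asarray(seed_xy, dtype=float)
    frames, track = [], []
    for f in range(start_frame, end):
        img = movie.frame(f)
        if smooth_sigma > 0:
            img = ndimage.gaussian_filter(np.asarray(img, dtype=float), smooth_sigma)
        h, w = img.shape
        ix, iy = int(round(pos[0])), int(round(pos[1]))
        y0, y1 = max(iy - r, 0), min(iy + r + 1, h)
        x0, x1 = max(ix - r, 0), min(ix + r + 1, w)
        window = img[y0:y1, x0:x1]
        dmask = disc[(y0 - iy + r):(y1 - iy + r), (x0 - ix + r):(x1 - ix + r)]
        vals = np.where(dmask, window, np.inf)
        k = int(np.argmin(vals))
        ky, kx = divmod(k, vals.shape[1])
        box = img[max(iy - rb, 0):min(iy + rb + 1, h),
                  max(ix - rb, 0):min(ix + rb + 1, w)]
        med = float(np.median(box))
        dip = med - float(vals[ky, kx])
        if dip < max(min_dip_frac * max(med, 0.0), min_dip_abs):
            raise ValueError(
                f"chromosome track terminated at frame {f}: no clear dark "
                f"spot within radius {search_radius_px} px")
        pos = np.array([x0 + kx, y0 + ky], dtype=float)
        frames.append(f)
        track.append(pos)
    return ChromosomeTrack(np.array(frames), np.array(track), search_radius_px)


def compensate_and_project(traj: Trajectory, chrom: ChromosomeTrack,
                           pole_xy, ap_axis, pixel_size_um: float) -> np.ndarray:
    """Centrosome-directed coordinate z (um) of a particle trajectory.

    The cumulative A-P component of the chromosome displacement (a proxy for
    the spindle-pole drift, valid because the kinetochore-to-pole distance
    stays constant) is subtracted from the particle positions, which are
    then projected onto the principal axis of the compensated motion, signed
    so that increasing z points toward ``pole_xy``.
    """
    if len(traj) < 2:
        raise ValueError("trajectory must span at least 2 frames")
    ap = np.asarray(ap_axis, dtype=float)
    ap = ap / np.linalg.norm(ap)
    chrom0 = chrom.position_at(int(traj.frames[0]))
    comp = np.empty_like(traj.xy)
    for k, f in enumerate(traj.frames):
        drift = float((chrom.position_at(int(f)) - chrom0) @ ap)
        comp[k] = traj.xy[k] - drift * ap

    centered = comp - comp.mean(axis=0)
    cov = centered.T @ centered / len(comp)
    vals, vecs = np.linalg.eigh(cov)
    axis = vecs[:, int(np.argmax(vals))]
    toward_pole = np.asarray(pole_xy, dtype=float) - comp[0]
    if float(toward_pole @ axis) < 0:
        axis = -axis
    z = (comp - comp[0]) @ axis * pixel_size_um
    return z


def _centered_moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Moving average with the window shrunk near the ends."""
    if window <= 1:
        return np.asarray(x, dtype=float).copy()
    x = np.asarray(x, dtype=float)
    half = window // 2
    out = np.empty_like(x)
    n = len(x)
    for i in range(n):
        lo, hi = max(i - half, 0), min(i + half + 1, n)
        out[i] = x[lo:hi].mean()
    return out


def transport_score(z_um: np.ndarray, intensity: np.ndarray,
                    smooth_window: int = 3,
                    frames: np.ndarray | None = None) -> TransportRecord:
    """Score I * dz'^2 per step for dz' > 0 (else 0).

    ``intensity`` holds the per-frame particle intensities; each step uses
    the mean of its two bracketing values. ``smooth_window`` <= 1 disables
    smoothing.
    """
    z = np.asarray(z_um, dtype=float)
    if z.size < 2:
        raise ValueError("z series must have at least 2 points")
    inten = np.asarray(intensity, dtype=float)
    if inten.size != z.size:
        raise ValueError("intensity and z must have equal length")
    z_s = _centered_moving_average(z, smooth_window)
    dz = np.diff(z_s)
    i_step = 0.5 * (inten[:-1] + inten[1:])
    act = np.where(dz > 0, i_step * dz ** 2, 0.0)
    return TransportRecord(z_um=z, z_smooth_um=z_s, dz_um=dz, activity=act,
                           frames=None if frames is None else np.asarray(frames))


def aggregate_transport(per_embryo_records: list[list[TransportRecord]],
                        frame_interval_s: float | list[float],
                        n_frames: int | list[int], t0_frame: int = 0,
                        grid_dt_s: float = 1.0):
    """Mean cumulative transport activity across embryos.

    Per embryo, the step activities of all records are summed per frame
    interval and accumulated from anaphase onset (t = 0); embryos with no
    qualifying trajectory contribute an all-zero series. Curves sampled at
    different frame intervals are linearly resampled onto a common grid of
    ``grid_dt_s``. Returns ``(t_grid, mean, sem)``; empty input yields
    zero-length arrays.
    """
    n_embryos = len(per_embryo_records)
    if n_embryos == 0:
        return np.array([]), np.array([]), np.array([])
    dts = np.broadcast_to(np.asarray(frame_interval_s, dtype=float), (n_embryos,))
    nfs = np.broadcast_to(np.asarray(n_frames, dtype=int), (n_embryos,))

    curves = []
    t_max = 0.0
    for e, records in enumerate(per_embryo_records):
        nf = int(nfs[e])
        per_bin = np.zeros(max(nf - 1, 1))
        for rec in records:
            if rec.frames is None:
                raise ValueError("records need frame indices for aggregation")
            for k, a in enumerate(rec.activity):
                step_frame = int(rec.frames[k])       # step frame -> frame+1
                if 0 <= step_frame < per_bin.size:
                    per_bin[step_frame] += a
        cum = np.cumsum(per_bin)
        t = (np.arange(1, per_bin.size + 1) - t0_frame) * dts[e]
        keep = t >= 0
        t, cum = t[keep], cum[keep]
        if t.size == 0:
            t, cum = np.array([0.0]), np.array([0.0])
        curves.append((t, cum))
        t_max = max(t_max, t[-1])

    t_grid = np.arange(0.0, t_max + 0.5 * grid_dt_s, grid_dt_s)
    resampled = np.vstack([
        np.interp(t_grid, t, c, left=0.0, right=c[-1] if c.size else 0.0)
        for t, c in curves
    ])
    mean = resampled.mean(axis=0)
    sem = (resampled.std(axis=0, ddof=1) / np.sqrt(n_embryos)
           if n_embryos > 1 else np.zeros_like(mean))
    return t_grid, mean, sem
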