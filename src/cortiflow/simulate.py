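"""Synthetic one-cell embryo movie generator with full ground truth.

Emulates midplane spinning-disk recordings of a ~50 x 30 um ellipsoidal
zygote: a bright cortical band whose tangential density is transported by a
prescribed peripheral flow field, cytoplasmic particles (diffusive, or
pole-directed after anaphase onset), two spindle poles moving along the
anterior-posterior (A-P) axis with chromosome dark spots riding at a fixed
offset, astral rays with exponentially distributed lengths, mono-exponential
photobleaching, Poisson + Gaussian camera noise, and an optional equatorial
furrow ingression.

Every rendered feature is also returned as ground truth (boundary, pole and
chromosome tracks, particle trajectories, the flow field sampled on the
kymograph grid, the bleach constant and the furrow onset), so each analysis
stage can be scored against what was actually simulated.

The peripheral coordinate ``s`` runs over [0, 1): 0 at the anterior tip,
increasing counterclockwise, posterior tip at 0.5. The flow field ``v(s,t)``
is the material velocity along increasing ``s`` in um/s; before the
transition time ``flow_onset_s`` it is a unidirectional posterior-to-
anterior field confined to the posterior half of the periphery, after it
the bidirectional field ``A2*sin(4*pi*s)`` converging on the equator
(s = 0.25 and 0.75). Cortical density obeys the 1D continuity equation
under this field, so converging flow accumulates density at the equator.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from .geometry import polygon_mask
from .io import MovieStack, write_movie, read_movie

__all__ = [
    "SimConfig",
    "GroundTruth",
    "simulate_embryo_movie",
    "simulate_cortex_kymograph",
    "write_fixture",
    "read_fixture",
    "ellipse_boundary",
    "flow_velocity",
    "advect_density",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """All tunable parameters of the synthetic embryo.

    Lengths in micrometres, times in seconds, rates per second. Intensity
    levels are arbitrary camera units. Defaults describe a myosin-II-like
    recording (bright cortical band, cytoplasmic particles, no astral rays);
    use :meth:`tubulin` for a tubulin-like preset (rays on, dim cortex).
    """

    # geometry / calibration
    semi_axis_a_um: float = 25.0
    semi_axis_b_um: float = 15.0
    pixel_size_um: float = 0.133
    frame_interval_s: float = 0.72
    n_frames: int = 200
    t0_frame: int = 0
    margin_um: float = 6.5
    n_z: int = 1               # 1 = already-projected midplane; 5 = z-stack
    z_step_um: float = 0.5

    # intensity levels
    background_level: float = 5.0
    cytoplasm_level: float = 40.0
    cortex_amplitude: float = 120.0
    cortex_sigma_um: float = 0.4       # radial Gaussian sigma of the band
    cortex_texture_contrast: float = 0.5
    cortex_texture_corr_um: float = 0.8
    cortex_turnover_s: float | None = 150.0  # myosin exchange time; None = off

    # peripheral flow field v(s, t)
    flow_uni_amp_um_s: float = 0.05
    flow_bi_amp_um_s: float = 0.1
    flow_onset_s: float | None = 100.0

    # cytoplasmic particles
    n_particles: int = 30
    particles_directed: bool = True     # False = purely diffusive ("dynein off")
    particle_speed_um_s: float = 0.7
    particle_diffusion_um2_s: float = 0.02
    particle_intensity_median: float = 80.0
    particle_intensity_sigma: float = 0.3   # log-normal shape
    particle_sigma_px: float = 1.3
    particle_spawn_inset_um: float = 2.0
    particle_capture_radius_um: float = 1.5
    particle_min_spacing_px: float = 0.0    # >0: despawn to enforce spacing

    # spindle poles (positions as fractions of semi-axis a along A-P axis)
    pole_a_start_frac: float = -0.28
    pole_a_end_frac: float = -0.55
    pole_a_t_range_s: tuple[float, float] = (40.0, 80.0)
    pole_p_start_frac: float = 0.28
    pole_p_end_frac: float = 0.62
    pole_p_t_range_s: tuple[float, float] = (0.0, 40.0)
    pole_amplitude: float = 15.0
    pole_sigma_px: float = 2.0
    chromosome_offset_um: float = 3.0   # toward cell centre from each pole
    chromosome_depth_frac: float = 0.5  # fractional dip below cytoplasm
    chromosome_sigma_um: float = 1.0

    # astral rays
    n_rays_per_pole: int = 0
    ray_mean_length_um: float = 8.0
    ray_amplitude: float = 15.0
    ray_sigma_px: float = 0.7

    # noise and bleaching
    poisson_gain: float = 1.0           # 0 disables Poisson noise
    gaussian_noise_sd: float = 2.0
    bleach_tau_s: float = 400.0         # inf disables bleaching
    bleach_cortex_tau_s: float | None = None  # extra cortical factor, off

    # furrow
    furrow_onset_s: float | None = None
    furrow_rate_frac_s: float = 0.02    # fractional depth per second
    furrow_width_um: float = 3.0
    furrow_max_frac: float = 0.6

    # output
    dtype: str = "uint16"               # or "float32" for noise-free oracles
    n_boundary: int = 2048              # boundary / texture grid resolution

    def validate(self) -> None:
        if self.semi_axis_a_um <= 0 or self.semi_axis_b_um <= 0:
            raise ValueError("semi-axes must be positive")
        if self.pixel_size_um <= 0 or self.frame_interval_s <= 0:
            raise ValueError("pixel size and frame interval must be positive")
        if self.n_frames < 1:
            raise ValueError("need at least one frame")
        if not 0 <= self.t0_frame < self.n_frames:
            raise ValueError("t0_frame must lie within the movie")
        for name in (
            "background_level", "cytoplasm_level", "cortex_amplitude",
            "flow_uni_amp_um_s", "flow_bi_amp_um_s", "particle_speed_um_s",
            "particle_diffusion_um2_s", "poisson_gain", "gaussian_noise_sd",
            "ray_amplitude", "pole_amplitude",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        dur = (self.n_frames - 1 - self.t0_frame) * self.frame_interval_s
        if self.flow_onset_s is not None and self.flow_onset_s > dur:
            raise ValueError(
                f"flow_onset_s={self.flow_onset_s} s lies beyond the movie "
                f"({dur:.1f} s post anaphase onset)"
            )
        if self.furrow_onset_s is not None and self.furrow_onset_s > dur:
            raise ValueError(
                f"furrow_onset_s={self.furrow_onset_s} s lies beyond the "
                f"movie ({dur:.1f} s post anaphase onset)"
            )
        if self.n_z not in (1, 5):
            raise ValueError("n_z must be 1 (midplane) or 5 (z-stack)")

    @classmethod
    def tubulin(cls, **overrides) -> "SimConfig":
        """Preset resembling a tubulin recording: astral rays against a
        noisy unpolymerised-tubulin cytoplasm, dim cortex, no particles."""
        base = dict(
            cortex_amplitude=10.0,
            n_particles=0,
            n_rays_per_pole=60,
            ray_amplitude=15.0,
            frame_interval_s=1.6,
        )
        base.update(overrides)
        return cls(**base)

    # image-frame helpers -------------------------------------------------
    @property
    def px(self) -> float:
        return self.pixel_size_um

    def image_shape(self) -> tuple[int, int]:
        w = int(round(2 * (self.semi_axis_a_um + self.margin_um) / self.px))
        h = int(round(2 * (self.semi_axis_b_um + self.margin_um) / self.px))
        return (h, w)

    def center_px(self) -> tuple[float, float]:
        h, w = self.image_shape()
        return ((w - 1) / 2.0, (h - 1) / 2.0)


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Everything the simulator knows, for recovery oracles.

    ``boundary_xy`` has shape (T, n_b, 2) in pixels; vertex ``k`` sits at
    normalized arc position ``s_grid[k]`` (anterior tip 0, counterclockwise,
    posterior 0.5). ``flow_kymo`` has shape (n_b, T-1): the velocity (um/s,
    positive toward increasing s) acting during the interval frame i ->
    frame i+1. ``particles`` is a list of dicts with keys ``track_id``,
    ``frames`` (consecutive ints), ``xy`` ((n,2) px) and ``intensity``.
    """

    boundary_xy: np.ndarray
    s_grid: np.ndarray
    poles_xy: np.ndarray          # (T, 2, 2): [:, 0]=anterior, [:, 1]=posterior
    chromosomes_xy: np.ndarray    # (T, 2, 2)
    particles: list
    flow_kymo: np.ndarray
    texture_kymo: np.ndarray      # (n_b, T) true cortical density
    bleach_tau_s: float
    furrow_onset_s: float | None
    perimeter_um: float
    equator_s: float = 0.25       # on the s coordinate (u = 0.5 folded)
    anterior_xy: np.ndarray | None = None
    pixel_size_um: float = 0.133
    frame_interval_s: float = 0.72
    t0_frame: int = 0

    def validate(self, image_shape: tuple[int, int]) -> None:
        h, w = image_shape
        for name, arr in (("boundary", self.boundary_xy),
                          ("poles", self.poles_xy)):
            x, y = arr[..., 0], arr[..., 1]
            if (x < -0.5).any() or (x > w - 0.5).any() or \
               (y < -0.5).any() or (y > h - 0.5).any():
                raise ValueError(f"ground-truth {name} leaves the image frame")
        for tr in self.particles:
            if len(tr["frames"]) and np.any(np.diff(tr["frames"]) != 1):
                raise ValueError("trajectory frames must be consecutive")

    def particles_dataframe(self) -> pd.DataFrame:
        rows = []
        for tr in self.particles:
            for f, (x, y), inten in zip(tr["frames"], tr["xy"], tr["intensity"]):
                rows.append((tr["track_id"], int(f), float(x), float(y), float(inten)))
        return pd.DataFrame(rows, columns=["track_id", "frame", "x_px", "y_px", "intensity"])


# ---------------------------------------------------------------------------
# geometry primitives
# ---------------------------------------------------------------------------

def ellipse_boundary(a_px: float, b_px: float, center: tuple[float, float],
                     n: int) -> np.ndarray:
    """Ellipse polyline at ``n`` uniform-arc-length points, starting at the
    anterior tip (-a, 0) and traversed counterclockwise (positive shoelace
    area in (x, y))."""
    m = max(8 * n, 4096)
    phi = np.pi + 2 * np.pi * np.arange(m + 1) / m
    pts = np.column_stack([center[0] + a_px * np.cos(phi),
                           center[1] + b_px * np.sin(phi)])
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    targets = cum[-1] * np.arange(n) / n
    x = np.interp(targets, cum, pts[:, 0])
    y = np.interp(targets, cum, pts[:, 1])
    return np.column_stack([x, y])


def _apply_furrow(boundary: np.ndarray, center: tuple[float, float],
                  depth_frac: float, width_px: float) -> np.ndarray:
    """Pinch boundary points toward the A-P axis around the equator."""
    if depth_frac <= 0:
        return boundary
    cx, cy = center
    g = np.exp(-((boundary[:, 0] - cx) ** 2) / (2 * width_px ** 2))
    out = boundary.copy()
    out[:, 1] = cy + (boundary[:, 1] - cy) * (1.0 - depth_frac * g)
    return out


def flow_velocity(config: SimConfig, s: np.ndarray, t_pao: float) -> np.ndarray:
    """Peripheral flow v(s, t) in um/s along increasing s.

    Unidirectional phase (before ``flow_onset_s``): posterior-to-anterior
    flow confined to the posterior half of the periphery, carrying material
    from the posterior tip toward the equator while the anterior cortex
    stays still — the pattern seen before the flow turns bidirectional.
    Bidirectional phase: ``A2*sin(4*pi*s)``, converging on the equator from
    both sides (s = 0.25 and 0.75).
    """
    s = np.asarray(s, dtype=float)
    if t_pao < 0:
        return np.zeros_like(s)
    if config.flow_onset_s is None or t_pao < config.flow_onset_s:
        posterior = (s >= 0.25) & (s <= 0.75)
        return np.where(posterior,
                        config.flow_uni_amp_um_s * np.sin(4 * np.pi * s), 0.0)
    return config.flow_bi_amp_um_s * np.sin(4 * np.pi * s)


def advect_density(rho: np.ndarray, v_um_s: np.ndarray, dt_s: float,
                   dx_um: float) -> np.ndarray:
    """One conservative semi-Lagrangian step of the 1D continuity equation
    on a periodic grid.

    The cumulative-mass function is advected along backward characteristics
    and re-differenced, so total mass is conserved exactly and converging
    flow accumulates density. A uniform velocity that is an integer number
    of grid cells per step reduces to an exact circular shift.
    """
    rho = np.asarray(rho, dtype=float)
    n = rho.size
    L = n * dx_um
    xe = np.arange(n + 1) * dx_um
    M = np.concatenate([[0.0], np.cumsum(rho)]) * dx_um
    total = M[-1]
    ve = 0.5 * (v_um_s + np.roll(v_um_s, 1))
    ve = np.concatenate([ve, ve[:1]])
    dep = xe - ve * dt_s
    wraps = np.floor(dep / L)
    frac = dep - wraps * L
    Mdep = np.interp(frac, xe, M) + wraps * total
    return np.diff(Mdep) / dx_um


def _smooth_noise(rng: np.random.Generator, n: int, corr_bins: float) -> np.ndarray:
    noise = rng.standard_normal(n)
    if corr_bins > 0:
        noise = ndimage.gaussian_filter1d(noise, corr_bins, mode="wrap")
        sd = noise.std()
        if sd > 0:
            noise /= sd
    return noise


def _smooth_texture(rng: np.random.Generator, n: int, corr_bins: float,
                    contrast: float) -> np.ndarray:
    return np.clip(1.0 + contrast * _smooth_noise(rng, n, corr_bins), 0.05, None)


def _turnover_step(rho: np.ndarray, rng: np.random.Generator, dt_s: float,
                   turnover_s: float, corr_bins: float,
                   contrast: float) -> np.ndarray:
    """Myosin exchange with the cytoplasm: the texture relaxes toward its
    mean while fresh correlated fluctuations bind, keeping the punctate
    contrast statistically stationary. Without this, divergent flow would
    drain the cortex at the poles into a featureless band no real cortex
    shows."""
    sigma_f = contrast * np.sqrt(2.0 / turnover_s)
    fresh = sigma_f * np.sqrt(dt_s) * _smooth_noise(rng, rho.size, corr_bins)
    out = rho + (dt_s / turnover_s) * (1.0 - rho) + fresh
    return np.clip(out, 0.01, None)


def _splat_gaussians(img: np.ndarray, xs, ys, amps, sigma: float,
                     truncate: float = 3.5) -> None:
    """Accumulate isotropic Gaussians into ``img`` in place."""
    h, w = img.shape
    r = int(np.ceil(truncate * sigma))
    for x, y, a in zip(np.atleast_1d(xs), np.atleast_1d(ys), np.atleast_1d(amps)):
        x0, x1 = int(np.floor(x)) - r, int(np.floor(x)) + r + 1
        y0, y1 = int(np.floor(y)) - r, int(np.floor(y)) + r + 1
        x0c, x1c = max(x0, 0), min(x1, w)
        y0c, y1c = max(y0, 0), min(y1, h)
        if x0c >= x1c or y0c >= y1c:
            continue
        gx = np.arange(x0c, x1c) - x
        gy = np.arange(y0c, y1c) - y
        patch = a * np.exp(-(gy[:, None] ** 2 + gx[None, :] ** 2) / (2 * sigma ** 2))
        img[y0c:y1c, x0c:x1c] += patch


def _linear_path(t_pao: float, start: float, end: float,
                 t_range: tuple[float, float]) -> float:
    t0, t1 = t_range
    if t1 <= t0:
        return end if t_pao >= t1 else start
    f = np.clip((t_pao - t0) / (t1 - t0), 0.0, 1.0)
    return start + f * (end - start)


# ---------------------------------------------------------------------------
# particle kinematics
# ---------------------------------------------------------------------------

class _Particle:
    __slots__ = ("pid", "birth", "xy", "amp", "target_pole", "alive",
                 "frames", "track_xy", "track_int")

    def __init__(self, pid, birth, xy, amp, target_pole):
        self.pid = pid
        self.birth = birth
        self.xy = np.asarray(xy, dtype=float)
        self.amp = amp
        self.target_pole = target_pole  # 0 = anterior, 1 = posterior
        self.alive = True
        self.frames: list[int] = []
        self.track_xy: list[np.ndarray] = []
        self.track_int: list[float] = []


def _inside_ellipse(xy, center, a_px, b_px, shrink=1.0):
    dx = (xy[..., 0] - center[0]) / (a_px * shrink)
    dy = (xy[..., 1] - center[1]) / (b_px * shrink)
    return dx ** 2 + dy ** 2 <= 1.0


# ---------------------------------------------------------------------------
# the simulator
# ---------------------------------------------------------------------------

def simulate_embryo_movie(config: SimConfig, seed: int) -> tuple[MovieStack, GroundTruth]:
    """Render a synthetic embryo movie; deterministic for fixed (config, seed)."""
    config.validate()
    rng = np.random.default_rng(seed)

    px = config.px
    dt = config.frame_interval_s
    T = config.n_frames
    h, w = config.image_shape()
    center = config.center_px()
    a_px = config.semi_axis_a_um / px
    b_px = config.semi_axis_b_um / px
    n_b = config.n_boundary

    ref_boundary = ellipse_boundary(a_px, b_px, center, n_b)
    s_grid = np.arange(n_b) / n_b
    seg = np.linalg.norm(np.diff(np.vstack([ref_boundary, ref_boundary[:1]]), axis=0), axis=1)
    perimeter_um = seg.sum() * px
    dx_um = perimeter_um / n_b

    # cortical texture (conserved density along the periphery)
    texture = _smooth_texture(rng, n_b, config.cortex_texture_corr_um / dx_um,
                              config.cortex_texture_contrast)
    sigma_r_px = config.cortex_sigma_um / px
    band_cutoff = 4.0 * sigma_r_px + 1.0

    # particle spawn schedule
    particles: list[_Particle] = []
    if config.n_particles > 0:
        last_birth = max(config.t0_frame, T - 10)
        births = rng.integers(config.t0_frame, max(config.t0_frame + 1, last_birth),
                              size=config.n_particles)
        births = np.sort(births)
        amps = config.particle_intensity_median * np.exp(
            config.particle_intensity_sigma * rng.standard_normal(config.n_particles))
        spawn_s = rng.random(config.n_particles)
        for pid in range(config.n_particles):
            idx = int(spawn_s[pid] * n_b) % n_b
            p_bd = ref_boundary[idx]
            # inward along the local normal (interior is left of ccw travel)
            nxt = ref_boundary[(idx + 1) % n_b]
            prv = ref_boundary[(idx - 1) % n_b]
            tang = nxt - prv
            tang /= np.linalg.norm(tang)
            inward = np.array([-tang[1], tang[0]])
            xy = p_bd + inward * (config.particle_spawn_inset_um / px)
            particles.append(_Particle(pid, int(births[pid]), xy, amps[pid], -1))

    # per-frame state containers
    movie = np.empty((T, h, w), dtype=np.float64)
    boundary_t = np.empty((T, n_b, 2))
    poles_t = np.empty((T, 2, 2))
    chrom_t = np.empty((T, 2, 2))
    flow_kymo = np.zeros((n_b, max(T - 1, 1)))
    texture_kymo = np.zeros((n_b, T))

    static_geometry = config.furrow_onset_s is None
    interior_mask = polygon_mask((h, w), ref_boundary)
    band_info = None  # (pixel indices, distances, boundary index)

    def band_lookup(boundary):
        raster = np.zeros((h, w), dtype=bool)
        bi = np.round(boundary).astype(int)
        bi[:, 0] = np.clip(bi[:, 0], 0, w - 1)
        bi[:, 1] = np.clip(bi[:, 1], 0, h - 1)
        raster[bi[:, 1], bi[:, 0]] = True
        dist = ndimage.distance_transform_edt(~raster)
        yy, xx = np.nonzero(dist <= band_cutoff + 1.5)
        tree = cKDTree(boundary)
        d, idx = tree.query(np.column_stack([xx, yy]), workers=-1)
        return yy, xx, d, idx

    if static_geometry:
        band_info = band_lookup(ref_boundary)

    tau = config.bleach_tau_s
    gauss_sd = config.gaussian_noise_sd
    gain = config.poisson_gain
    chrom_sigma_px = config.chromosome_sigma_um / px
    cap_px = config.particle_capture_radius_um / px

    for i in range(T):
        t_pao = (i - config.t0_frame) * dt

        # -- geometry of this frame
        if static_geometry:
            boundary = ref_boundary
            mask = interior_mask
            yy, xx, dists, bidx = band_info
        else:
            depth = 0.0
            if config.furrow_onset_s is not None and t_pao > config.furrow_onset_s:
                depth = min(config.furrow_rate_frac_s * (t_pao - config.furrow_onset_s),
                            config.furrow_max_frac)
            boundary = _apply_furrow(ref_boundary, center, depth,
                                     config.furrow_width_um / px)
            mask = polygon_mask((h, w), boundary)
            yy, xx, dists, bidx = band_lookup(boundary)
        boundary_t[i] = boundary

        # -- poles and chromosomes
        ax = center[0] + _linear_path(t_pao, config.pole_a_start_frac,
                                      config.pole_a_end_frac,
                                      config.pole_a_t_range_s) * a_px
        pxx = center[0] + _linear_path(t_pao, config.pole_p_start_frac,
                                       config.pole_p_end_frac,
                                       config.pole_p_t_range_s) * a_px
        poles = np.array([[ax, center[1]], [pxx, center[1]]])
        off = config.chromosome_offset_um / px
        chroms = np.array([[ax + off, center[1]], [pxx - off, center[1]]])
        poles_t[i] = poles
        chrom_t[i] = chroms

        # -- scene composition (fluorescent signal, before bleach/noise)
        signal = np.zeros((h, w))
        signal[mask] += config.cytoplasm_level

        cortex_img = np.zeros((h, w))
        if config.cortex_amplitude > 0:
            tex_vals = texture[bidx]
            cortex_img[yy, xx] = (config.cortex_amplitude * tex_vals
                                  * np.exp(-dists ** 2 / (2 * sigma_r_px ** 2)))

        if config.pole_amplitude > 0:
            _splat_gaussians(signal, poles[:, 0], poles[:, 1],
                             [config.pole_amplitude] * 2, config.pole_sigma_px)
        if config.chromosome_depth_frac > 0:
            _splat_gaussians(
                signal, chroms[:, 0], chroms[:, 1],
                [-config.chromosome_depth_frac * config.cytoplasm_level] * 2,
                chrom_sigma_px)

        if config.n_rays_per_pole > 0:
            rays = np.zeros((h, w))
            for pole in poles:
                angles = rng.uniform(0, 2 * np.pi, config.n_rays_per_pole)
                lengths = rng.exponential(config.ray_mean_length_um / px,
                                          config.n_rays_per_pole)
                for ang, length in zip(angles, lengths):
                    npts = max(int(length / 0.5), 2)
                    r = np.linspace(2.0, length, npts)
                    rx = pole[0] + r * np.cos(ang)
                    ry = pole[1] + r * np.sin(ang)
                    ok = (rx >= 0) & (rx < w - 1) & (ry >= 0) & (ry < h - 1)
                    ix, iy = rx[ok].astype(int), ry[ok].astype(int)
                    np.add.at(rays, (iy, ix), config.ray_amplitude * 0.5)
            rays = ndimage.gaussian_filter(rays, config.ray_sigma_px)
            signal += rays

        # -- particles: record truth, render, then advance
        bleach = np.exp(-max(i, 0) * dt / tau) if np.isfinite(tau) else 1.0
        live = [p for p in particles if p.alive and p.birth <= i]
        if config.particle_min_spacing_px > 0 and len(live) > 1:
            pos = np.array([p.xy for p in live])
            tree = cKDTree(pos)
            for j, k in sorted(tree.query_pairs(config.particle_min_spacing_px)):
                if live[k].alive:
                    live[k].alive = False
            live = [p for p in live if p.alive]
        for p in live:
            p.frames.append(i)
            p.track_xy.append(p.xy.copy())
            p.track_int.append(p.amp * bleach)
            _splat_gaussians(signal, p.xy[0], p.xy[1], p.amp,
                             config.particle_sigma_px)
        for p in live:
            if config.particles_directed and t_pao >= 0:
                if p.target_pole < 0:
                    d = np.linalg.norm(poles - p.xy, axis=1)
                    p.target_pole = int(np.argmin(d))
                tgt = poles[p.target_pole]
                delta = tgt - p.xy
                dist = np.linalg.norm(delta)
                step = config.particle_speed_um_s * dt / px
                # absorb before entering the capture radius, so recorded
                # truth positions always stay > capture_radius from the pole
                if dist - step <= cap_px:
                    p.alive = False
                else:
                    p.xy = p.xy + delta / dist * step
            else:
                sd = np.sqrt(2 * config.particle_diffusion_um2_s * dt) / px
                for _ in range(10):
                    cand = p.xy + sd * rng.standard_normal(2)
                    if _inside_ellipse(cand, center, a_px, b_px, 0.97):
                        p.xy = cand
                        break

        # -- bleach, combine, noise
        cortical_extra = 1.0
        if config.bleach_cortex_tau_s is not None and np.isfinite(config.bleach_cortex_tau_s):
            cortical_extra = np.exp(-max(i, 0) * dt / config.bleach_cortex_tau_s)
        frame = (config.background_level
                 + bleach * (signal + cortical_extra * cortex_img))
        frame = np.clip(frame, 0.0, None)
        if gain > 0:
            frame = rng.poisson(frame / gain).astype(np.float64) * gain
        if gauss_sd > 0:
            frame = frame + gauss_sd * rng.standard_normal((h, w))
        movie[i] = np.clip(frame, 0.0, None)

        # -- advance the cortical texture to the next frame
        texture_kymo[:, i] = texture
        if i < T - 1:
            v = flow_velocity(config, s_grid, t_pao)
            flow_kymo[:, i] = v
            texture = advect_density(texture, v, dt, dx_um)
            if config.cortex_turnover_s is not None:
                texture = _turnover_step(
                    texture, rng, dt, config.cortex_turnover_s,
                    config.cortex_texture_corr_um / dx_um,
                    config.cortex_texture_contrast)

    # -- assemble outputs
    if config.n_z == 5:
        weights = np.array([0.7, 0.9, 1.0, 0.9, 0.7])
        movie = movie[:, None, :, :] * weights[None, :, None, None]

    if config.dtype == "uint16":
        data = np.clip(np.round(movie), 0, 65535).astype(np.uint16)
    else:
        data = movie.astype(np.float32)

    stack = MovieStack(data, px, dt, config.t0_frame, channel="synthetic")
    tracks = [
        {
            "track_id": p.pid,
            "frames": np.asarray(p.frames, dtype=int),
            "xy": np.asarray(p.track_xy).reshape(-1, 2),
            "intensity": np.asarray(p.track_int),
        }
        for p in particles if p.frames
    ]
    truth = GroundTruth(
        boundary_xy=boundary_t,
        s_grid=s_grid,
        poles_xy=poles_t,
        chromosomes_xy=chrom_t,
        particles=tracks,
        flow_kymo=flow_kymo,
        texture_kymo=texture_kymo,
        bleach_tau_s=tau,
        furrow_onset_s=config.furrow_onset_s,
        perimeter_um=perimeter_um,
        anterior_xy=ref_boundary[0].copy(),
        pixel_size_um=px,
        frame_interval_s=dt,
        t0_frame=config.t0_frame,
    )
    truth.validate((h, w))
    return stack, truth


# ---------------------------------------------------------------------------
# direct 1D kymograph oracle
# ---------------------------------------------------------------------------

def simulate_cortex_kymograph(config: SimConfig, seed: int):
    """Generate a cortical-density kymograph advected exactly by v(s, t),
    bypassing image rendering; the direct oracle for the 1D PIV stage.

    Returns ``(CortexKymograph, FlowKymograph)`` where the flow kymograph is
    the true field sampled on the same grid (columns = frame pairs).
    """
    from .kymograph import CortexKymograph
    from .piv import FlowKymograph

    config.validate()
    rng = np.random.default_rng(seed)
    px = config.px
    dt = config.frame_interval_s
    T = config.n_frames

    boundary = ellipse_boundary(config.semi_axis_a_um / px,
                                config.semi_axis_b_um / px,
                                (0.0, 0.0), 4096)
    seg = np.linalg.norm(np.diff(np.vstack([boundary, boundary[:1]]), axis=0), axis=1)
    L_um = seg.sum() * px
    n = int(round(L_um / px))
    dx_um = L_um / n
    s = np.arange(n) / n

    vmax = max(config.flow_uni_amp_um_s, config.flow_bi_amp_um_s)
    if vmax * dt >= L_um / 2:
        raise ValueError(
            f"|v|*dt = {vmax * dt:.2f} um exceeds half the periphery "
            f"({L_um / 2:.2f} um): advection would alias")

    rho = _smooth_texture(rng, n, config.cortex_texture_corr_um / dx_um,
                          config.cortex_texture_contrast)
    dens = np.empty((n, T))
    flow = np.zeros((n, max(T - 1, 1)))
    for i in range(T):
        dens[:, i] = rho
        if i < T - 1:
            t_pao = (i - config.t0_frame) * dt
            v = flow_velocity(config, s, t_pao)
            flow[:, i] = v
            rho = advect_density(rho, v, dt, dx_um)
            if config.cortex_turnover_s is not None:
                rho = _turnover_step(rho, rng, dt, config.cortex_turnover_s,
                                     config.cortex_texture_corr_um / dx_um,
                                     config.cortex_texture_contrast)

    t_s = (np.arange(T) - config.t0_frame) * dt
    kymo = CortexKymograph(values=dens, positions=s, t_s=t_s, folded=False,
                           normalized=False, bin_arc_um=dx_um)
    truth = FlowKymograph(values=flow, positions=s, t_s=t_s[:-1], folded=False,
                          pixel_size_um=px, dt_s=dt)
    return kymo, truth


# ---------------------------------------------------------------------------
# fixtures on disk
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    hsh = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            hsh.update(chunk)
    return hsh.hexdigest()


def write_fixture(movie: MovieStack, truth: GroundTruth, out_dir: str | Path,
                  overwrite: bool = False, boundary_stride: int = 8) -> dict:
    """Write a movie + ground truth fixture (TIFF, JSON sidecar, CSV tables)
    and return a manifest with per-file SHA-256 checksums."""
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(f"{out} is not empty; pass overwrite=True")
    out.mkdir(parents=True, exist_ok=True)

    write_movie(movie, out / "movie.tif")

    truth.particles_dataframe().to_csv(out / "particles.csv", index=False)

    T = truth.boundary_xy.shape[0]
    rows = []
    for i in range(T):
        for lbl, (x, y) in zip(("A", "P"), truth.poles_xy[i]):
            rows.append((i, lbl, x, y))
    pd.DataFrame(rows, columns=["frame", "pole", "x_px", "y_px"]).to_csv(
        out / "poles.csv", index=False)
    rows = []
    for i in range(T):
        for lbl, (x, y) in zip(("A", "P"), truth.chromosomes_xy[i]):
            rows.append((i, lbl, x, y))
    pd.DataFrame(rows, columns=["frame", "chromosome", "x_px", "y_px"]).to_csv(
        out / "chromosomes.csv", index=False)

    st = max(int(boundary_stride), 1)
    rows = []
    for i in range(T):
        for k in range(0, truth.boundary_xy.shape[1], st):
            rows.append((i, truth.s_grid[k], truth.boundary_xy[i, k, 0],
                         truth.boundary_xy[i, k, 1]))
    pd.DataFrame(rows, columns=["frame", "s", "x_px", "y_px"]).to_csv(
        out / "boundary.csv", index=False)

    n_b = truth.flow_kymo.shape[0]
    sub = np.arange(0, n_b, st)
    recs = []
    for j, i in np.ndindex(len(sub), truth.flow_kymo.shape[1]):
        recs.append((truth.s_grid[sub[j]],
                     (i - truth.t0_frame) * truth.frame_interval_s,
                     truth.flow_kymo[sub[j], i]))
    pd.DataFrame(recs, columns=["s", "t_s", "v_um_s"]).to_csv(
        out / "flow_truth.csv", index=False)

    (out / "truth.json").write_text(json.dumps({
        "bleach_tau_s": truth.bleach_tau_s,
        "furrow_onset_s": truth.furrow_onset_s,
        "perimeter_um": truth.perimeter_um,
        "equator_s": truth.equator_s,
        "pixel_size_um": truth.pixel_size_um,
        "frame_interval_s": truth.frame_interval_s,
        "t0_frame": truth.t0_frame,
        "boundary_stride": st,
    }, indent=1))

    files = sorted(p.name for p in out.iterdir() if p.is_file()
                   and p.name != "manifest.json")
    manifest = {"files": {f: _sha256(out / f) for f in files}}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def read_fixture(out_dir: str | Path) -> tuple[MovieStack, dict]:
    """Read a fixture directory; returns the movie and a dict of truth tables
    (pandas DataFrames plus the scalar metadata)."""
    out = Path(out_dir)
    movie = read_movie(out / "movie.tif")
    truth = {
        "particles": pd.read_csv(out / "particles.csv"),
        "poles": pd.read_csv(out / "poles.csv"),
        "chromosomes": pd.read_csv(out / "chromosomes.csv"),
        "boundary": pd.read_csv(out / "boundary.csv"),
        "flow": pd.read_csv(out / "flow_truth.csv"),
        "meta": json.loads((out / "truth.json").read_text()),
    }
    return movie, truth
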