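"""End-to-end orchestration: simulate or load a movie, run the analysis
stages in dependency order, and write artifacts with provenance.

Time origin of every output is seconds post anaphase onset (p.a.o.),
anchored by the ``t0_frame`` of the movie sidecar. Furrow onset, scored
visually in live experiments, is detected here geometrically: the first
sustained drop of the equatorial transverse width below a fraction of its
anaphase-onset value, normalized by the global contour scale so that
uniform shrinkage does not register as furrowing.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from . import geometry, kymograph as kg, mtdensity, piv as piv_mod, tracking, transport as tp
from .io import MovieStack, read_movie
from .simulate import SimConfig, GroundTruth, simulate_embryo_movie

__all__ = [
    "AnalysisParams",
    "PipelineConfig",
    "ResultBundle",
    "analyze_movie",
    "detect_furrow_onset",
    "run_pipeline",
    "render_outputs",
]

log = logging.getLogger("cortiflow")

ALL_STAGES = ("kymo", "piv", "track", "transport", "mtdensity", "furrow")


@dataclass
class AnalysisParams:
    """Tunable parameters of every analysis stage (units noted per field)."""

    # segmentation
    seg_sigma: float = 1.0
    seg_min_area: int = 2000
    anterior_hint: tuple[float, float] | None = None   # px; default: image left edge

    # straightening / kymograph
    half_width_px: int = 40
    margin_rows: int = 10
    n_rows_avg: int = 5
    bleach_correction: bool = True

    # PIV
    piv_window_px: int = 256
    piv_factor: int = 5
    piv_max_shift_px: int = 50
    piv_median_validate: tuple[int, int] | None = (15, 5)
    onset_v_min_um_s: float = 0.02
    onset_sustain_frames: int = 3

    # particle tracking
    noise_tolerance: float = 25.0
    detect_sigma: float = 1.0
    max_disp_px: float = 7.0
    min_track_frames: int = 6
    spindle_mask_radius_um: float = 1.2
    cortex_exclusion_um: float = 0.5

    # transport
    chrom_search_radius_px: float = 10.0
    transport_smooth_window: int = 3

    # microtubule density
    mt_inset_um: float = 1.5
    mt_width_um: float = 1.0
    mt_band_samples: int = 512
    mt_pool_frames: int = 10
    mt_use_windows: int = 2       # trailing pooled windows averaged
    mt_window_rel: float = 0.2
    mt_percentile: float = 95.0

    # furrow
    furrow_depth_frac: float = 0.05
    furrow_sustain_frames: int = 3


@dataclass
class PipelineConfig:
    """Run definition: input (movie path or simulation), stage selection,
    analysis parameters, output directory and seed."""

    out_dir: str = "cortiflow_out"
    seed: int = 0
    movie_path: str | None = None
    simulation: SimConfig | None = None
    stages: tuple[str, ...] = ALL_STAGES
    params: AnalysisParams = field(default_factory=AnalysisParams)
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulation", None)
        params = raw.pop("params", None)
        cfg = cls(**{k: v for k, v in raw.items() if k in
                     {f.name for f in dataclasses.fields(cls)}})
        if sim is not None:
            cfg.simulation = SimConfig(**sim)
        if params is not None:
            cfg.params = AnalysisParams(**params)
        cfg.stages = tuple(cfg.stages)
        if cfg.movie_path is None and cfg.simulation is None:
            cfg.simulation = SimConfig()
        return cfg

    def config_hash(self) -> str:
        # out_dir is excluded: the hash identifies the analysis, not where
        # its artifacts happen to be written
        payload = {
            "seed": self.seed,
            "movie_path": self.movie_path,
            "simulation": asdict(self.simulation) if self.simulation else None,
            "stages": list(self.stages),
            "params": asdict(self.params),
        }
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class ResultBundle:
    """All artifacts of one analysis run (single embryo)."""

    contours: dict
    density_kymo: kg.CortexKymograph | None = None          # unfolded
    density_kymo_folded: kg.CortexKymograph | None = None
    flow: piv_mod.FlowKymograph | None = None               # unfolded
    flow_folded: piv_mod.FlowKymograph | None = None
    flow_onset_s: float | None = None
    trajectories: list = field(default_factory=list)        # kept tracks
    all_trajectories: list = field(default_factory=list)
    transport_records: list = field(default_factory=list)
    transport_curve: tuple | None = None                    # (t, cum)
    mt_profile: mtdensity.DensityProfile | None = None
    pole_distance: tuple | None = None                      # (u, {frame: d})
    furrow_onset_s: float | None = None
    bleach_tau_s: float | None = None
    provenance: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _segment_all(movie: MovieStack, params: AnalysisParams):
    h, w = movie.frame(0).shape
    hint = params.anterior_hint or (0.0, h / 2.0)
    contours = {}
    for f in range(movie.n_frames):
        poly = geometry.segment_boundary(movie.frame(f), sigma=params.seg_sigma,
                                         min_area=params.seg_min_area)
        contours[f] = geometry.parameterize_contour(
            poly, hint, pixel_size_um=movie.pixel_size_um)
    return contours


def _interior_masks(contour: geometry.ParameterizedContour, shape,
                    pixel_size_um: float):
    inside = geometry.polygon_mask(shape, contour.xy)
    dist_in = ndimage.distance_transform_edt(inside)
    erode_px = 3.0 / pixel_size_um
    cyto = inside & (dist_in > erode_px)
    cortex = inside & (dist_in <= 1.0 / pixel_size_um)
    return inside, cyto, cortex


def _ap_axis(contour: geometry.ParameterizedContour) -> np.ndarray:
    axis = contour.major_axis()
    posterior = contour.point_at(contour.posterior_s())[0]
    if float((posterior - contour.xy[0]) @ axis) < 0:
        axis = -axis
    return axis


def detect_furrow_onset(contours: dict, frame_interval_s: float,
                        t0_frame: int = 0, equator_u: float = 0.5,
                        depth_frac: float = 0.05,
                        sustain_frames: int = 3) -> float | None:
    """Earliest time (s p.a.o.) at which the equatorial transverse width,
    relative to the global contour scale, drops below (1 - depth_frac) of
    its value at anaphase onset for >= ``sustain_frames`` frames."""
    frames = sorted(contours)
    widths, scales = {}, {}
    for f in frames:
        c = contours[f]
        p1 = c.point_at(equator_u / 2.0)[0]
        p2 = c.point_at(1.0 - equator_u / 2.0)[0]
        widths[f] = float(np.linalg.norm(p1 - p2))
        scales[f] = c.perimeter_px
    ref = t0_frame if t0_frame in widths else frames[0]
    w0, s0 = widths[ref], scales[ref]
    run = 0
    for f in frames:
        if f < ref:
            continue
        ratio = (widths[f] / w0) / (scales[f] / s0)
        run = run + 1 if ratio < 1.0 - depth_frac else 0
        if run >= max(sustain_frames, 1):
            return (f - run + 1 - t0_frame) * frame_interval_s
    return None


# ---------------------------------------------------------------------------
# the analysis driver
# ---------------------------------------------------------------------------

def analyze_movie(movie: MovieStack, params: AnalysisParams | None = None,
                  stages: tuple[str, ...] = ALL_STAGES,
                  poles_xy: np.ndarray | None = None,
                  chrom_seeds: np.ndarray | None = None,
                  contours: dict | None = None) -> ResultBundle:
    """Run the selected analysis stages on one movie.

    ``poles_xy`` ((T, 2, 2), anterior and posterior per frame) comes from
    ground truth or manual annotation — pole positions are never inferred
    silently. ``chrom_seeds`` ((2, 2): first-frame chromosome dark-spot
    positions) seed the semi-automated chromosome tracker for the transport
    stage. Precomputed ``contours`` skip segmentation.
    """
    params = params or AnalysisParams()
    movie = movie.projected()
    dt = movie.frame_interval_s
    px = movie.pixel_size_um
    shape = movie.frame(0).shape

    if contours is None:
        log.info("segmenting %d frames", movie.n_frames)
        contours = _segment_all(movie, params)
    bundle = ResultBundle(contours=contours)

    inside0, cyto0, cortex0 = _interior_masks(contours[0], shape, px)

    corrected = movie
    if params.bleach_correction and movie.n_frames >= 20:
        outside0 = ~ndimage.binary_dilation(inside0, iterations=5)
        corrected, tau = kg.bleach_correct_movie(movie, cyto0, cortex0,
                                                 background_mask=outside0)
        bundle.bleach_tau_s = tau

    perimeter_um = contours[0].perimeter_um

    if "kymo" in stages or "piv" in stages:
        n_cols = int(round(contours[0].perimeter_px))
        bands = []
        for f in range(movie.n_frames):
            band = kg.straighten_edge(corrected.frame(f), contours[f],
                                      params.half_width_px, n_cols=n_cols)
            bands.append(kg.normalize_band(band, params.margin_rows))
        t_s = movie.times_pao()
        bundle.density_kymo = kg.build_density_kymograph(
            bands, t_s, params.margin_rows, params.n_rows_avg,
            perimeter_um=perimeter_um)
        bundle.density_kymo_folded = kg.fold_kymograph(bundle.density_kymo)

    if "piv" in stages:
        bundle.flow = piv_mod.piv_flow_kymograph(
            bundle.density_kymo, params.piv_window_px, params.piv_factor,
            params.piv_max_shift_px, median_size=params.piv_median_validate)
        bundle.flow_folded = piv_mod.fold_flow(bundle.flow)
        bundle.flow_onset_s = piv_mod.bidirectional_onset(
            bundle.flow_folded, params.onset_sustain_frames,
            params.onset_v_min_um_s)

    if "track" in stages or "transport" in stages:
        dets_per_frame = []
        for f in range(movie.n_frames):
            dets = tracking.detect_particles(corrected.frame(f), contours[f],
                                             params.noise_tolerance,
                                             smooth_sigma=params.detect_sigma)
            for d in dets:
                d.frame = f
            dets_per_frame.append(dets)
        trajs = tracking.build_trajectories(dets_per_frame, params.max_disp_px)
        for tr in trajs:
            if len(tr) >= 2:
                tracking.classify_cortex_direction(tr, contours, px)
        bundle.all_trajectories = trajs
        masks = []
        if poles_xy is not None:
            r = params.spindle_mask_radius_um / px
            mask = np.zeros(shape, dtype=bool)
            yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
            for pole in poles_xy[0]:
                mask |= (xx - pole[0]) ** 2 + (yy - pole[1]) ** 2 <= r ** 2
            masks.append(mask)
        bundle.trajectories = tracking.filter_trajectories(
            trajs, params.min_track_frames, masks,
            min_cortex_dist_um=params.cortex_exclusion_um)

    if "transport" in stages and bundle.trajectories:
        if poles_xy is None or chrom_seeds is None:
            warnings.warn("transport stage needs pole positions and "
                          "chromosome seeds; skipped")
        else:
            ap = _ap_axis(contours[0])
            chrom_tracks = [
                tp.track_chromosome(corrected, chrom_seeds[i],
                                    params.chrom_search_radius_px)
                for i in range(2)
            ]
            records = []
            for tr in bundle.trajectories:
                f0 = int(tr.frames[0])
                d = np.linalg.norm(poles_xy[f0] - tr.xy[0], axis=1)
                side = int(np.argmin(d))
                z = tp.compensate_and_project(tr, chrom_tracks[side],
                                              poles_xy[f0, side], ap, px)
                rec = tp.transport_score(z, tr.intensity,
                                         params.transport_smooth_window,
                                         frames=tr.frames[:-1])
                records.append(rec)
            bundle.transport_records = records
            t_grid, mean, _ = tp.aggregate_transport(
                [records], dt, movie.n_frames, movie.t0_frame)
            bundle.transport_curve = (t_grid, mean)

    if "mtdensity" in stages:
        outside = ~ndimage.binary_dilation(inside0, iterations=3)
        profiles = []
        for f in range(movie.n_frames):
            band = geometry.offset_sampling_band(
                contours[f], params.mt_inset_um, params.mt_width_um,
                params.mt_band_samples)
            _, prof = mtdensity.cortical_tubulin_profile(
                corrected.frame(f), band, outside)
            profiles.append(prof)
        pools = []
        for start in range(0, len(profiles), params.mt_pool_frames):
            chunk = profiles[start:start + params.mt_pool_frames]
            if len(chunk) == params.mt_pool_frames:
                pools.append(mtdensity.pool_profiles(chunk))
        if pools:
            # threshold per pooled window, then average the window densities
            use = pools[-max(params.mt_use_windows, 1):]
            per_window = [mtdensity.microtubule_density_profile(
                [p], params.mt_window_rel, params.mt_percentile)
                for p in use]
            mean = np.mean([w.mean for w in per_window], axis=0)
            bundle.mt_profile = mtdensity.DensityProfile(
                u=per_window[0].u, mean=mean,
                sem=np.zeros_like(mean), n_embryos=1)

    if poles_xy is not None:
        track = geometry.PoleTrack(poles_xy[:, 0], poles_xy[:, 1])
        bundle.pole_distance = geometry.pole_distance_profiles(contours, track)

    if "furrow" in stages:
        bundle.furrow_onset_s = detect_furrow_onset(
            contours, dt, movie.t0_frame,
            depth_frac=params.furrow_depth_frac,
            sustain_frames=params.furrow_sustain_frames)

    return bundle


# ---------------------------------------------------------------------------
# artifacts
# ---------------------------------------------------------------------------

def _kymo_to_frame(k) -> pd.DataFrame:
    pos_name = "u" if k.folded else "s"
    pos, t = np.meshgrid(k.positions, k.t_s, indexing="ij")
    return pd.DataFrame({pos_name: pos.ravel(), "t_s": t.ravel(),
                         "value": k.values.ravel()})


def write_bundle(bundle: ResultBundle, out_dir: str | Path,
                 config_hash: str = "", frame_interval_s: float = 1.0,
                 pixel_size_um: float = 1.0, t0_frame: int = 0) -> list[str]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    def save(df: pd.DataFrame, name: str):
        path = out / name
        with open(path, "w") as fh:
            if config_hash:
                fh.write(f"# config_hash={config_hash}\n")
            df.to_csv(fh, index=False)
        written.append(name)

    if bundle.density_kymo_folded is not None:
        save(_kymo_to_frame(bundle.density_kymo_folded), "density_kymograph.csv")
    if bundle.flow_folded is not None:
        save(_kymo_to_frame(bundle.flow_folded), "flow_kymograph.csv")
    if bundle.trajectories is not None:
        rows = []
        for tid, tr in enumerate(bundle.trajectories):
            for k in range(len(tr)):
                f = int(tr.frames[k])
                rows.append((tid, f, (f - t0_frame) * frame_interval_s,
                             tr.xy[k, 0], tr.xy[k, 1], tr.intensity[k],
                             np.nan if tr.cortex_dist_um is None
                             else tr.cortex_dist_um[k],
                             bool(tr.away)))
        save(pd.DataFrame(rows, columns=[
            "track_id", "frame", "t_s", "x_px", "y_px", "intensity",
            "cortex_dist_um", "away"]), "trajectories.csv")
    if bundle.transport_curve is not None:
        t, cum = bundle.transport_curve
        save(pd.DataFrame({"t_s": t, "cumulative_activity": cum}),
             "transport.csv")
    if bundle.mt_profile is not None:
        p = bundle.mt_profile
        save(pd.DataFrame({"u": p.u, "density": p.mean, "sem": p.sem}),
             "mt_density.csv")
    if bundle.furrow_onset_s is not None or bundle.flow_onset_s is not None:
        save(pd.DataFrame([{"embryo_id": 0, "condition": "default",
                            "onset_s": bundle.furrow_onset_s,
                            "flow_onset_s": bundle.flow_onset_s}]),
             "onsets.csv")
    scalars = {
        "flow_onset_s": bundle.flow_onset_s,
        "furrow_onset_s": bundle.furrow_onset_s,
        "bleach_tau_s": bundle.bleach_tau_s,
        "config_hash": config_hash,
    }
    (out / "summary.json").write_text(json.dumps(scalars, indent=1))
    written.append("summary.json")
    return written


def render_outputs(bundle: ResultBundle, out_dir: str | Path,
                   flow_vmax_um_s: float = 0.15) -> list[str]:
    """Figures: time-coded trajectory overlay, grayscale density kymograph,
    green/magenta flow kymograph, cumulative transport and MT density
    curves. Missing artifacts skip their figure with a warning."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    made = []

    def finish(fig, name):
        fig.savefig(out / name, dpi=120)
        plt.close(fig)
        made.append(name)

    if bundle.trajectories:
        fig, ax = plt.subplots(figsize=(6, 4))
        t_all = np.concatenate([tr.frames for tr in bundle.trajectories])
        norm = plt.Normalize(t_all.min(), max(t_all.max(), t_all.min() + 1))
        cmap = plt.get_cmap("viridis")
        for tr in bundle.trajectories:
            for k in range(len(tr) - 1):
                ax.plot(tr.xy[k:k + 2, 0], tr.xy[k:k + 2, 1],
                        color=cmap(norm(tr.frames[k])), lw=1)
        c0 = bundle.contours.get(0)
        if c0 is not None:
            ax.plot(*np.vstack([c0.xy, c0.xy[:1]]).T, "k-", lw=0.5)
        ax.set_aspect("equal")
        ax.invert_yaxis()
        ax.set_title("particle trajectories (time-coded)")
        finish(fig, "trajectories.png")
    else:
        warnings.warn("no trajectories; overlay figure skipped")

    if bundle.density_kymo_folded is not None:
        k = bundle.density_kymo_folded
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.imshow(k.values, aspect="auto", cmap="gray", origin="lower",
                  extent=[k.t_s[0], k.t_s[-1], 0, 1])
        ax.set_xlabel("time (s p.a.o.)")
        ax.set_ylabel("position A->P (u)")
        ax.set_title("cortical myosin density")
        finish(fig, "density_kymograph.png")

    if bundle.flow_folded is not None:
        k = bundle.flow_folded
        rgb = piv_mod.flow_to_rgb(k.values, flow_vmax_um_s)
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.imshow(rgb, aspect="auto", origin="lower",
                  extent=[k.t_s[0], k.t_s[-1], 0, 1])
        ax.set_xlabel("time (s p.a.o.)")
        ax.set_ylabel("position A->P (u)")
        ax.set_title("cortical flow (green: A->P, magenta: P->A)")
        finish(fig, "flow_kymograph.png")

    if bundle.transport_curve is not None:
        t, cum = bundle.transport_curve
        fig, ax = plt.subplots(figsize=(5, 3.5))
        ax.plot(t, cum)
        ax.set_xlabel("time (s p.a.o.)")
        ax.set_ylabel("cumulative transport activity")
        finish(fig, "transport.png")

    if bundle.mt_profile is not None:
        p = bundle.mt_profile
        fig, ax = plt.subplots(figsize=(5, 3.5))
        ax.plot(p.u, p.mean)
        ax.fill_between(p.u, p.mean - p.sem, p.mean + p.sem, alpha=0.3)
        ax.set_xlabel("position A->P (u)")
        ax.set_ylabel("MT density (a.u.)")
        finish(fig, "mt_density.png")
    return made


def run_pipeline(config: PipelineConfig) -> ResultBundle:
    """Execute the configured run; deterministic given (config, seed)."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    log.info("run %s -> %s", chash, out)

    truth: GroundTruth | None = None
    stage = "input"
    try:
        if config.movie_path is not None:
            movie = read_movie(config.movie_path)
            poles = chrom = None
        else:
            stage = "simulate"
            movie, truth = simulate_embryo_movie(config.simulation, config.seed)
            poles = truth.poles_xy
            chrom = truth.chromosomes_xy[0]
        stage = "analysis"
        bundle = analyze_movie(movie, config.params, config.stages,
                               poles_xy=poles, chrom_seeds=chrom)
    except Exception as err:
        (out / "FAILED").write_text(f"stage={stage}: {err}\n")
        raise RuntimeError(f"pipeline failed in stage '{stage}': {err}") from err

    bundle.provenance = {"config_hash": chash, "seed": config.seed,
                         "stages": list(config.stages)}
    write_bundle(bundle, out, chash, movie.frame_interval_s,
                 movie.pixel_size_um, movie.t0_frame)
    render_outputs(bundle, out)
    (out / "run.json").write_text(json.dumps(bundle.provenance, indent=1))
    return bundle
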