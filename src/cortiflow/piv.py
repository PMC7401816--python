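"""1D particle image velocimetry of cortical flow.

The local flow velocity along the periphery is the spatial shift that
maximizes the normalized cross-correlation between corresponding windows of
two consecutive kymograph rows. Rows are first upsampled (linear
interpolation, 5- or 10-fold) so that the velocity quantum becomes
(pixel / factor) / dt; the integer-shift argmax is scanned over
[-max_shift, +max_shift] interpolated pixels at every interpolated position
and the result is set back to the original resolution by block averaging.
Sign convention: positive = flow toward increasing s, i.e. anterior to
posterior on the first half-perimeter; after signed folding, positive = A->P
on the folded coordinate u (rendered green; negative = P->A, magenta).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import fold_profile, N_FOLD_BINS
from .kymograph import CortexKymograph

__all__ = [
    "FlowKymograph",
    "upsample_rows",
    "ncc_shift_map",
    "piv_flow_kymograph",
    "fold_flow",
    "mean_flow",
    "bidirectional_onset",
    "flow_to_rgb",
]

DEFAULT_WINDOW_PX = 256
DEFAULT_FACTOR = 5
DEFAULT_MAX_SHIFT_PX = 50


@dataclass
class FlowKymograph:
    """Signed flow velocity matrix V[position, time] in um/s.

    Column ``i`` holds the velocity measured between frames i and i+1;
    ``t_s`` is the time of the first frame of each pair. ``confidence``
    flags positions where the correlation was informative (False where a
    window was constant and V was set to 0)."""

    values: np.ndarray
    positions: np.ndarray
    t_s: np.ndarray
    folded: bool = False
    pixel_size_um: float | None = None
    dt_s: float | None = None
    window_px: int | None = None
    factor: int | None = None
    max_shift_px: int | None = None
    confidence: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.positions), len(self.t_s)):
            raise ValueError("flow shape must be (n_positions, n_times)")


def upsample_rows(values: np.ndarray, factor: int) -> np.ndarray:
    """Linearly interpolate each row of a (n_pos, n_t) matrix onto a
    periodic grid of factor*n_pos points; original samples are preserved at
    their nodes."""
    if int(factor) != factor or factor < 1:
        raise ValueError("interpolation factor must be an integer >= 1")
    factor = int(factor)
    values = np.asarray(values, dtype=float)
    if factor == 1:
        return values.copy()
    n = values.shape[0]
    x_old = np.arange(n + 1)
    x_new = np.arange(n * factor) / factor
    ext = np.vstack([values, values[:1]])
    out = np.empty((n * factor, values.shape[1]))
    for j in range(values.shape[1]):
        out[:, j] = np.interp(x_new, x_old, ext[:, j])
    return out


def _windowed_sums(ext_cumsum: np.ndarray, starts: np.ndarray, W: int) -> np.ndarray:
    return ext_cumsum[starts + W] - ext_cumsum[starts]


def ncc_shift_map(row1: np.ndarray, row2: np.ndarray, window: int,
                  max_shift: int):
    """Best integer shift of ``row2`` relative to ``row1`` at every position
    of a periodic pair of rows.

    For each centre position p and shift k, the normalized (zero-mean,
    unit-variance) cross-correlation between ``row1[p-W/2 : p+W/2]`` and the
    equally sized window of ``row2`` displaced by k is evaluated; the
    returned shift maximizes it, with ties broken toward the smallest |k|.
    Returns ``(shifts, confident)`` arrays of length n. Positions where
    either window is constant get shift 0 and ``confident=False``.
    """
    r1 = np.asarray(row1, dtype=float)
    r2 = np.asarray(row2, dtype=float)
    n = r1.size
    W = int(window)
    if W > n:
        raise ValueError(f"window ({W}) larger than the domain ({n})")
    if W < 2:
        raise ValueError("window must span at least 2 samples")

    starts = (np.arange(n) - W // 2) % n
    ext1 = np.concatenate([r1, r1[:W]])
    c1 = np.concatenate([[0.0], np.cumsum(ext1)])
    c1sq = np.concatenate([[0.0], np.cumsum(ext1 ** 2)])
    S1 = _windowed_sums(c1, starts, W)
    V1 = _windowed_sums(c1sq, starts, W) - S1 ** 2 / W

    ext2 = np.concatenate([r2, r2[:W]])
    c2 = np.concatenate([[0.0], np.cumsum(ext2)])
    c2sq = np.concatenate([[0.0], np.cumsum(ext2 ** 2)])
    S2_all = _windowed_sums(c2, starts, W)          # per start, unshifted
    V2_all = _windowed_sums(c2sq, starts, W) - S2_all ** 2 / W

    ks = sorted(range(-max_shift, max_shift + 1), key=lambda k: (abs(k), k))
    best_ncc = np.full(n, -np.inf)
    best_k = np.zeros(n, dtype=int)
    eps = 1e-12
    for k in ks:
        prod = r1 * np.roll(r2, -k)
        extp = np.concatenate([prod, prod[:W]])
        cp = np.concatenate([[0.0], np.cumsum(extp)])
        Sxy = _windowed_sums(cp, starts, W)
        # windowed sums of the shifted row2 = unshifted sums at start+k
        idx = (np.arange(n) + k) % n
        S2 = S2_all[idx]
        V2 = V2_all[idx]
        denom = np.sqrt(np.clip(V1, 0, None) * np.clip(V2, 0, None))
        ncc = np.where(denom > eps, (Sxy - S1 * S2 / W) / np.maximum(denom, eps), 0.0)
        better = ncc > best_ncc
        best_ncc[better] = ncc[better]
        best_k[better] = k

    confident = V1 > eps
    shifts = np.where(confident, best_k, 0)
    return shifts, confident


def median_validate(values: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    """Median filter of a (position, time) flow field, periodic along the
    position axis — the standard PIV vector-validation step that replaces
    isolated spurious correlation peaks with the local consensus."""
    from scipy import ndimage
    pad = size[0] // 2
    ext = np.concatenate([values[-pad:], values, values[:pad]], axis=0)
    out = ndimage.median_filter(ext, size=size, mode="nearest")
    return out[pad:pad + values.shape[0]]


def piv_flow_kymograph(kymo: CortexKymograph,
                       window_px: int = DEFAULT_WINDOW_PX,
                       factor: int = DEFAULT_FACTOR,
                       max_shift_px: int = DEFAULT_MAX_SHIFT_PX,
                       pixel_size_um: float | None = None,
                       dt_s: float | None = None,
                       median_size: tuple[int, int] | None = (15, 5)
                       ) -> FlowKymograph:
    """Flow kymograph from a density kymograph by windowed 1D PIV.

    ``window_px`` and ``max_shift_px`` are in interpolated pixels (factor x
    the native column spacing). Velocity = shift x (pixel/factor) / dt.
    The periphery is treated as periodic (the contour is closed), so the
    kymograph must be unfolded. ``median_size`` (position bins, frames)
    applies median vector validation to the result; None disables it.
    """
    if kymo.folded:
        raise ValueError("PIV runs on the unfolded (periodic) kymograph")
    if pixel_size_um is None:
        pixel_size_um = kymo.bin_arc_um
    if pixel_size_um is None:
        raise ValueError("pixel size along the periphery is unknown")
    if dt_s is None:
        dt_s = float(np.median(np.diff(kymo.t_s)))

    up = upsample_rows(kymo.values, factor)
    n_interp, T = up.shape
    n = kymo.values.shape[0]
    if window_px > n_interp:
        raise ValueError(f"window ({window_px}) larger than the interpolated "
                         f"domain ({n_interp})")

    quantum = (pixel_size_um / factor) / dt_s
    V = np.empty((n, T - 1))
    conf = np.empty((n, T - 1), dtype=bool)
    for i in range(T - 1):
        shifts, ok = ncc_shift_map(up[:, i], up[:, i + 1], window_px, max_shift_px)
        v_full = shifts * quantum
        V[:, i] = v_full.reshape(n, factor).mean(axis=1)
        conf[:, i] = ok.reshape(n, factor).all(axis=1)
    if median_size is not None and V.shape[1] >= 2:
        V = median_validate(V, median_size)
    return FlowKymograph(values=V, positions=kymo.positions.copy(),
                         t_s=kymo.t_s[:-1].copy(), folded=False,
                         pixel_size_um=pixel_size_um, dt_s=dt_s,
                         window_px=window_px, factor=factor,
                         max_shift_px=max_shift_px, confidence=conf)


def fold_flow(flow: FlowKymograph, n_u: int = N_FOLD_BINS) -> FlowKymograph:
    """Fold a flow kymograph at the posterior tip with sign handling: on the
    second half-perimeter, increasing s points P->A, so its velocity is
    negated before averaging. Positive folded flow = anterior to posterior."""
    if flow.folded:
        return flow
    folded = fold_profile(flow.values, flow.positions, n_u=n_u, signed=True)
    return FlowKymograph(values=folded, positions=np.linspace(0, 1, n_u),
                         t_s=flow.t_s.copy(), folded=True,
                         pixel_size_um=flow.pixel_size_um, dt_s=flow.dt_s,
                         window_px=flow.window_px, factor=flow.factor,
                         max_shift_px=flow.max_shift_px)


def mean_flow(flows: list[FlowKymograph]) -> FlowKymograph:
    """Average aligned flow kymographs across embryos."""
    stack = np.stack([f.values for f in flows])
    out = flows[0]
    return FlowKymograph(values=stack.mean(axis=0), positions=out.positions.copy(),
                         t_s=out.t_s.copy(), folded=out.folded,
                         pixel_size_um=out.pixel_size_um, dt_s=out.dt_s,
                         window_px=out.window_px, factor=out.factor,
                         max_shift_px=out.max_shift_px)


def bidirectional_onset(flow: FlowKymograph, sustain_frames: int = 3,
                        v_min: float = 0.02) -> float | None:
    """Earliest time at which the flow is bidirectional toward the equator:
    median velocity over the anterior half >= +v_min and over the posterior
    half <= -v_min, sustained for >= ``sustain_frames`` consecutive frames.
    Requires a folded flow kymograph; returns seconds p.a.o. or None."""
    if not flow.folded:
        raise ValueError("onset detection requires a folded flow kymograph")
    u = flow.positions
    ant = u < 0.5
    post = u > 0.5
    med_a = np.median(flow.values[ant], axis=0)
    med_p = np.median(flow.values[post], axis=0)
    ok = (med_a >= v_min) & (med_p <= -v_min)
    run = 0
    for i, flag in enumerate(ok):
        run = run + 1 if flag else 0
        if run >= max(sustain_frames, 1):
            return float(flow.t_s[i - run + 1])
    return None


def flow_to_rgb(values: np.ndarray, vmax: float) -> np.ndarray:
    """Green/magenta rendering: positive -> green, negative -> magenta
    (R + B), linear up to |vmax| then clipped; zero -> black."""
    if vmax <= 0:
        raise ValueError("vmax must be positive")
    v = np.asarray(values, dtype=float) / vmax
    pos = np.clip(v, 0.0, 1.0)
    neg = np.clip(-v, 0.0, 1.0)
    rgb = np.zeros(v.shape + (3,))
    rgb[..., 0] = neg
    rgb[..., 1] = pos
    rgb[..., 2] = neg
    return rgb
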