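"""Movie container and TIFF + JSON-sidecar I/O.

A recording is a multi-page TIFF indexed (frame, y, x) or (frame, z, y, x)
plus a small JSON sidecar carrying the physical calibration: pixel size in
micrometres, frame interval in seconds and the frame index of anaphase
onset, which is the time origin for every downstream quantity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

SIDECAR_SUFFIX = ".json"


@dataclass
class MovieStack:
    """Time-lapse intensity volume with physical calibration.

    Parameters
    ----------
    data:
        Array of shape ``(t, y, x)`` or ``(t, z, y, x)``; nonnegative.
    pixel_size_um:
        Lateral pixel size, micrometres per pixel.
    frame_interval_s:
        Time between consecutive frames, seconds.
    t0_frame:
        Frame index of anaphase onset (time origin, "0 s p.a.o.").
    channel:
        Free-text label of the imaged marker (e.g. ``"myosin"``).
    """

    data: np.ndarray
    pixel_size_um: float
    frame_interval_s: float
    t0_frame: int = 0
    channel: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim not in (3, 4):
            raise ValueError("movie data must be (t, y, x) or (t, z, y, x)")
        if self.data.size and self.data.min() < 0:
            raise ValueError("intensities must be nonnegative")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        if not self.frame_interval_s > 0:
            raise ValueError("frame_interval_s must be positive")
        if not 0 <= self.t0_frame < self.n_frames:
            raise ValueError("t0_frame must lie within the movie")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def has_z(self) -> bool:
        return self.data.ndim == 4

    def frame(self, i: int) -> np.ndarray:
        """2D frame ``i``; z-stacks are average-projected."""
        f = self.data[i]
        return f.mean(axis=0) if f.ndim == 3 else f

    def projected(self) -> "MovieStack":
        """Average z-projection (identity for 2D movies)."""
        if not self.has_z:
            return self
        return MovieStack(
            self.data.mean(axis=1),
            self.pixel_size_um,
            self.frame_interval_s,
            self.t0_frame,
            self.channel,
        )

    def times_pao(self) -> np.ndarray:
        """Per-frame time in seconds post anaphase onset."""
        return (np.arange(self.n_frames) - self.t0_frame) * self.frame_interval_s


def sidecar_path(tiff_path: str | Path) -> Path:
    return Path(tiff_path).with_suffix(SIDECAR_SUFFIX)


def write_movie(movie: MovieStack, tiff_path: str | Path) -> Path:
    """Write a movie as multi-page TIFF with a JSON sidecar next to it."""
    tiff_path = Path(tiff_path)
    tiff_path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(tiff_path, movie.data, photometric="minisblack")
    meta = {
        "pixel_size_um": float(movie.pixel_size_um),
        "frame_interval_s": float(movie.frame_interval_s),
        "t0_frame": int(movie.t0_frame),
        "channel": movie.channel,
        "dtype": str(movie.data.dtype),
        "shape": list(movie.data.shape),
    }
    sc = sidecar_path(tiff_path)
    sc.write_text(json.dumps(meta, indent=1))
    return sc


def read_movie(tiff_path: str | Path) -> MovieStack:
    """Read a TIFF movie and its JSON sidecar."""
    tiff_path = Path(tiff_path)
    sc = sidecar_path(tiff_path)
    if not sc.exists():
        raise FileNotFoundError(f"metadata sidecar not found: {sc}")
    meta = json.loads(sc.read_text())
    data = tifffile.imread(tiff_path)
    return MovieStack(
        data,
        pixel_size_um=float(meta["pixel_size_um"]),
        frame_interval_s=float(meta["frame_interval_s"]),
        t0_frame=int(meta.get("t0_frame", 0)),
        channel=meta.get("channel", ""),
    )
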