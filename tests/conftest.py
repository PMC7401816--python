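import warnings

import numpy as np
import pytest

from cortiflow import SimConfig, simulate_embryo_movie
from cortiflow.geometry import parameterize_contour, segment_boundary


@pytest.fixture(scope="session")
def small_movie():
    """A short myosin-like movie with ground truth, shared across tests."""
    cfg = SimConfig(n_frames=30, flow_onset_s=10.0, n_particles=12)
    movie, truth = simulate_embryo_movie(cfg, seed=42)
    return cfg, movie, truth


@pytest.fixture(scope="session")
def small_contour(small_movie):
    cfg, movie, truth = small_movie
    frame = movie.frame(0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        poly = segment_boundary(frame, min_area=2000)
    return parameterize_contour(poly, (0.0, frame.shape[0] / 2),
                                pixel_size_um=cfg.pixel_size_um)


def circle_polyline(radius, center=(0.0, 0.0), n=720):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([center[0] + radius * np.cos(th),
                            center[1] + radius * np.sin(th)])


def ellipse_polyline(a, b, center=(0.0, 0.0), n=1440):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([center[0] + a * np.cos(th),
                            center[1] + b * np.sin(th)])
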