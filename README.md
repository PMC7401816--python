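# cortiflow

Quantification of cortical myosin II dynamics during cytokinesis in one-cell
embryos, from midplane time-lapse fluorescence movies.

During anaphase in the *C. elegans* zygote, dynein transports myosin II
particles from the polar cortex along astral microtubules toward the spindle
poles. The resulting local relaxation of the polar cortex triggers a
bidirectional cortical flow that converges on the equator and feeds the
assembly of the cytokinetic contractile ring. `cortiflow` implements the
measurements that characterize this process, together with a synthetic
embryo-movie generator that provides exact ground truth for every stage:

- **Particle transport** — detection of cytoplasmic myosin particles inside
  the cell boundary, greedy frame-to-frame linking (links strictly < 7 px,
  i.e. < 1.295 µm/s at 0.133 µm/px and 0.72 s/frame), classification by the
  mean rate of increase of the distance to the nearest cortex point, and a
  ≥ 6-frame filter. Transport activity per step is scored as
  *a* = *I*·(d*z*′)² for d*z*′ > 0, where *z* is the centrosome-directed
  coordinate of the motion after compensating the whole-spindle drift with
  the A-P component of a tracked chromosome dark spot, *z*′ its smoothed
  version, and *I* the particle's fluorescence intensity (a proxy for size,
  so *I*·*v*² is proportional to the power of viscous transport). Per-embryo
  cumulative sums are averaged across embryos (mean ± SEM).
- **Cortical density kymographs** — the cell boundary is segmented and
  parameterized by normalized arc length *s* (anterior tip 0,
  counterclockwise, posterior tip 0.5); a 40-px band around the edge is
  straightened, each column normalized to local background = 0 and
  cytoplasm = 1, and the five consecutive radial rows with the strongest
  cortical signal (0.67 µm) averaged into D(*s*, *t*). Kymographs are folded
  at the posterior tip onto *u* ∈ [0, 1] (anterior → posterior) and
  recordings of overlapping time windows merged by a linear blend.
- **1D PIV cortical flow** — each kymograph row is upsampled 5× (or 10×) by
  linear interpolation and the local velocity is the integer shift in
  [−max, +max] that maximizes the normalized cross-correlation of 256-px
  (6.83 µm) windows between consecutive time points; positive = anterior →
  posterior (green), negative = posterior → anterior (magenta). A
  bidirectional-flow onset detector formalizes the transition time.
- **Astral microtubule density** — line profiles along a 1-µm-wide curve
  1.5 µm inside the boundary, background-subtracted and mean-standardized;
  signal is the excess over the 95th percentile within a sliding window of
  0.2 relative length, pooled over 10 time points and both embryo sides.
- **Pole-to-cortex geometry and furrow onset** — d(*u*) distance maps to the
  nearest spindle pole, and a geometric furrow-onset detector (sustained
  drop of the scale-normalized equatorial width).

## Worked example

Simulate an embryo recorded 0–140 s post anaphase onset (p.a.o.) whose flow
switches from the unidirectional to the bidirectional mode at *t*\* = 100 s,
with pole-directed particles at 0.7 µm/s, and analyze it:

```python
import warnings
import numpy as np
from cortiflow import SimConfig, simulate_embryo_movie
from cortiflow.pipeline import AnalysisParams, analyze_movie
from cortiflow.tracking import trajectory_speed
from cortiflow.piv import fold_flow, bidirectional_onset

cfg = SimConfig(n_frames=195, flow_onset_s=100.0)   # 0-140 s p.a.o.
movie, truth = simulate_embryo_movie(cfg, seed=1)

bundle = analyze_movie(movie, AnalysisParams(),
                       stages=("kymo", "piv", "track"),
                       poles_xy=truth.poles_xy)

speeds = [trajectory_speed(t, cfg.pixel_size_um, cfg.frame_interval_s)
          for t in bundle.trajectories]
print(f"tracks kept: {len(bundle.trajectories)}")
print(f"mean particle speed: {np.mean(speeds):.2f} um/s")

folded = fold_flow(bundle.flow)
onset = bidirectional_onset(folded, sustain_frames=3, v_min=0.02)
print(f"bidirectional flow onset: {onset:.1f} s p.a.o.")

late = bundle.density_kymo_folded.values[:, -10:].mean(axis=1)
u = np.linspace(0, 1, late.size)
print(f"late-time cortical density peak at u = {u[np.argmax(late)]:.2f}")
```

Output:

```
tracks kept: 27
mean particle speed: 0.70 um/s
bidirectional flow onset: 100.8 s p.a.o.
late-time cortical density peak at u = 0.57
```

The recovered mean speed matches the configured dynein-like transport speed
(0.7 µm/s), the flow-mode transition is detected within one frame of the
configured 100 s, and the converging flow has begun piling cortical myosin
up near the equator (*u* = 0.5).

A command-line interface wraps the same pipeline:

```bash
cortiflow simulate --seed 1 --out fixture/          # movie + ground truth
cortiflow analyze  --config cfg.yaml --seed 1 --out results/
```

Real recordings are accepted as multi-page TIFF plus a JSON sidecar with
`pixel_size_um`, `frame_interval_s` and `t0_frame` (anaphase onset).

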