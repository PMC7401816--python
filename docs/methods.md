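# Methods

This note documents the models and procedures implemented in `cortiflow`:
what the synthetic embryo generator simulates (and what it deliberately does
not), how each analysis stage works, the parameters that matter with their
defaults and units, and the numerical choices made where the design was
genuinely open.

## Coordinate conventions

Pixels are 0-based with x = column (rightward) and y = row (downward);
physical length = pixels × `pixel_size_um`. The cell periphery carries the
normalized arc coordinate *s* ∈ [0, 1): 0 at the anterior tip, increasing
counterclockwise (positive shoelace area in (x, y)), posterior tip near 0.5.
A polyline traversed counterclockwise has its interior to the left, so a
unit tangent (tₓ, t_y) has inward normal (−t_y, tₓ). The folded coordinate
*u* ∈ [0, 1] runs anterior → posterior and averages the two half-perimeters
(values at *s* = u/2 and *s* = 1 − u/2) on a 512-bin grid; for velocities
the second side is negated before averaging, because "toward the posterior"
means decreasing *s* there. All times are seconds post anaphase onset
(p.a.o.), anchored by the movie sidecar's `t0_frame`.

## The synthetic embryo generator

The generator renders a midplane view of an ellipsoidal one-cell embryo
(default semi-axes 25 × 15 µm, 0.133 µm/px, 0.72 s/frame) as the sum of:

- **Cortical band.** A Gaussian radial profile (σ 0.4 µm) centred on the
  boundary, whose tangential amplitude is a positive texture ρ(*s*, *t*)
  (mean 1, contrast 0.5, correlation length 0.8 µm — cortical myosin is
  punctate at the sub-micrometre scale). ρ obeys the 1D continuity equation
  under the prescribed peripheral flow v(*s*, *t*), integrated by a
  conservative semi-Lagrangian scheme: the cumulative-mass function is
  advected along backward characteristics and re-differenced, so total mass
  is conserved to machine precision and converging flow accumulates density
  at the equator. A uniform velocity of an integer number of grid cells per
  step reduces to an exact circular shift, which makes the configured flow
  an exact oracle for the PIV stage. An optional turnover term (default
  time constant 150 s, switchable off) relaxes ρ toward its mean while
  injecting fresh correlated fluctuations — emulating myosin exchange with
  the cytoplasm, without which divergent flow would drain the polar cortex
  into a featureless band over long recordings.
- **Flow field.** Piecewise in time. Before the transition time *t*\*
  (default 100 s p.a.o.): a unidirectional, posterior-to-anterior field
  confined to the posterior half of the periphery
  (A₁ sin(4π*s*) for *s* ∈ [0.25, 0.75], zero on the anterior half;
  A₁ = 0.05 µm/s) — material leaves the posterior tip toward the equator
  while the anterior cortex stays still, reproducing the posterior density
  decline and broad equatorial accumulation seen before the flow turns
  bidirectional. After *t*\*: the bidirectional field A₂ sin(4π*s*)
  (A₂ = 0.1 µm/s), converging on the equator from both sides
  (*s* = 0.25 and 0.75, *u* = 0.5).
- **Cytoplasmic particles.** Spawned 2 µm inside the boundary at random
  arc positions with log-normal intensities; after anaphase onset they
  either move straight toward the nearest spindle pole at a constant speed
  (default 0.7 µm/s, "dynein on") or diffuse (D = 0.02 µm²/s,
  Stokes–Einstein scale for a ~0.5 µm particle in viscous cytoplasm,
  "dynein off"). Directed particles are absorbed before entering 1.5 µm of
  the pole, so recorded truth positions never overlap the spindle
  neighbourhood. An optional minimum-spacing rule despawns particles that
  approach each other, for fixtures that require well-separated tracks.
- **Spindle poles and chromosomes.** Poles move along the A-P axis on
  piecewise-linear paths (posterior pole toward the posterior cortex over
  0–40 s, anterior pole toward the anterior tip over 40–80 s; start
  positions ±0.28 of the long semi-axis, i.e. a ~14 µm spindle at anaphase
  onset). Chromosome dark spots ride 3 µm inside each pole (constant
  kinetochore-microtubule length; anaphase A is absent in this system) and
  are rendered as Gaussian intensity dips of half the cytoplasm level.
- **Astral rays.** Per frame and pole, straight rays at uniform angles with
  exponentially distributed lengths (mean 8 µm). The probability that a ray
  reaches the cortex decays as exp(−d/λ) with pole-cortex distance d, which
  is what makes the near-cortex microtubule density a readout of spindle
  geometry.
- **Photobleaching and noise.** Fluorescent signal is multiplied by
  exp(−t/τ) (default τ = 400 s; an optional second, faster cortical factor
  is off by default), then Poisson noise (gain 1) and additive Gaussian
  noise (sd 2) are applied on top of a constant camera background
  (offset 5). Output is uint16 by default; float32 is available for
  noise-free oracles.
- **Furrow (optional).** After the configured onset the boundary is pinched
  toward the A-P axis around the equator with a Gaussian arc profile
  (width 3 µm), at a fractional depth rate of 0.02 s⁻¹, capped at 0.6.

Everything rendered is also returned as ground truth: per-frame boundary,
pole/chromosome tracks, particle trajectories, the flow field on the
kymograph grid, τ and the furrow onset. `simulate_cortex_kymograph`
produces the same advected texture directly as a 1D kymograph, bypassing
rendering — the cleanest oracle for the PIV stage.

**What the generator does not emulate.** No optical PSF or 3D rendering
(the 5-plane z-stack option just scales the midplane scene per plane for
I/O tests); no camera-specific noise calibration; no out-of-focus drift,
embryo rotation, neighbouring embryos, or segmentation-hostile contrast.
Passing tests therefore demonstrate correctness of the measurement chain
under realistic geometry, photon statistics and kinematics — not robustness
to every pathology of real recordings.

## Analysis stages

**Boundary segmentation.** Gaussian blur (σ 1 px) → threshold (lowest
split of a three-class multi-Otsu, separating background from cell without
being attracted to the cytoplasm/cortex gap) → largest connected component
(ambiguity error if a second component reaches half its size) →
morphological closing and hole filling → a second threshold midway between
the interior and exterior medians, so the contour sits at the mid-level
crossing of the blurred edge → marching-squares contour → periodic
smoothing spline. Where a bright cortical ridge is prominent along the
local normal, vertices are snapped to the sub-pixel ridge position; the
per-vertex offsets are low-pass filtered along the boundary first, so noise
does not corrugate the contour (a corrugated contour overestimates arc
length). On plain step edges (no ridge) the refinement is a no-op.

**Parameterization.** The contour is oriented counterclockwise and anchored
at the anterior tip, located as the sub-pixel intersection of the principal
(PCA) axis with the boundary on the side of the user-supplied anterior
hint. The axis is a whole-contour fit, so the anchor is stable to ~0.2 px
frame to frame — essential, because anchor jitter circularly shifts
kymograph columns and would masquerade as flow. Anterior identity always
comes from configuration or ground truth, never from image content alone.

**Straightening and normalization.** The band ±40 px around the boundary is
resampled bilinearly along inward normals at uniform arc steps (columns ≈ 1
native pixel of arc). Samples outside the image are NaN and excluded from
all means. Per column, the outermost 10 rows estimate the local background
and the innermost 10 rows the local cytoplasm (both smoothed along the
periphery over 25 columns, periodic); the column is mapped so background → 0
and cytoplasm → 1. Because this normalization is per frame and per column,
it cancels any global gain, offset, or bleaching factor. The kymograph
averages the 5 consecutive radial rows (0.67 µm) with maximal total
cortical signal, chosen once per embryo outside the margin rows and fixed
over time.

**Bleach correction.** A mono-exponential is fitted (log-linear seed,
least-squares refinement) to the cytoplasmic mean over an interior mask
eroded 3 µm from the boundary; frames are divided by the fitted factor. A
separate, faster cortical factor can be fitted on the cortical band mean
and applied there — bleaching is deeper at the cortex, where exchange with
unbleached cytoplasmic molecules is slower. Non-decaying series are left
unchanged with a warning.

**Folding and window merging.** Kymographs are folded at the posterior tip
(*s* = 0.5) onto the 512-bin *u* grid. Two recordings covering 0–140 s and
70–215 s p.a.o. are merged by linearly sliding the blend weight of the
first from 1 to 0 across the 70–140 s overlap.

**1D PIV.** Rows are upsampled by linear interpolation (factor 5 default,
10 supported; original samples preserved at their nodes). For every
interpolated position and consecutive frame pair, the shift in
[−50, +50] interpolated px that maximizes the zero-mean, unit-variance
cross-correlation of 256-px windows is found by exhaustive integer search
(ties toward the smallest |shift|; constant windows yield 0 with a
low-confidence flag). Velocity = shift × (pixel/factor)/dt — the velocity
quantum is 0.037 µm/s at the defaults — and the field is set back to the
native resolution by block averaging. The periphery is treated as periodic
(the contour is closed). A median vector-validation pass (15 position bins
× 5 frame pairs, the standard PIV outlier-replacement step, configurable
and on by default) replaces isolated spurious correlation peaks with the
local consensus. Per-condition flow maps are means across embryos of the
folded per-embryo fields. The bidirectional-onset detector reports the
earliest time at which the median folded velocity is ≥ +v_min over the
anterior half and ≤ −v_min over the posterior half (v_min 0.02 µm/s) for at
least 3 consecutive frame pairs.

**Particle tracking.** Detections are regional maxima with prominence ≥ the
noise tolerance (h-maxima transform on a lightly smoothed frame, σ 1 px),
restricted to the contour interior, refined by a 3 × 3 intensity centroid;
intensity is the peak above the local 11 × 11 median. Linking is greedy by
ascending distance among candidate pairs strictly closer than 7 px, ties
broken by higher summed intensity then lower index; no gap closing. A
trajectory is "away from the cortex" when the mean per-frame increment of
its distance to the nearest boundary point is strictly positive. Kept
trajectories span ≥ 6 frames, are away-classified, touch no exclusion mask
(default: 1.2 µm discs around the poles, for spindle-trapped signals), and
keep a mean boundary distance ≥ 0.5 µm (cortical texture maxima hugging the
edge are not cytoplasmic particles). Reported speed is total path length
over duration on the raw track.

**Transport scoring.** The chromosome dark spot is tracked from a seeded
position as the darkest pixel within a 10-px radius of its previous
position (frames smoothed with σ 2 px); the track terminates with an error
if the dip below the surrounding cytoplasm median falls under 15% of that
level. Particle positions are compensated by subtracting the cumulative A-P
component of the chromosome displacement, projected onto the principal axis
of the compensated motion (the exact definition of the "main axis of
movement" is an open choice; the largest-variance axis is used), signed toward the
nearest pole at the trajectory's first frame. *z* is smoothed by a centred
moving average (window 3 frames, shrunk at the ends; the smoothing kernel
is not specified upstream and is exposed in configuration). Step activity
uses the mean of the two bracketing intensities. Per embryo, step
activities are summed per frame interval and accumulated from t = 0;
embryos with different frame intervals are resampled onto a 1-s grid by
linear interpolation before averaging.

**Microtubule density.** Line profiles are taken on the offset band (1 µm
wide, 1.5 µm inside the boundary), background-subtracted using the
outside-cell mean and standardized by the mean profile intensity. The two
embryo sides are rescaled to *u* and pooled with 10 consecutive time
points into one sample set. Per position, the threshold is the 95th
percentile (linear interpolation between order statistics) of the pooled
values within a centred sliding window of 0.2 relative length, clipped at
the domain ends — a sliding window rather than tiles avoids block
artifacts; density is the mean excess above threshold, clipped at zero,
then averaged across embryos (mean ± SEM); per embryo the densities of the
last two pooled windows are averaged. Adding a constant to the whole
profile leaves the density unchanged. Note that raising one sample raises
the threshold of every position whose window contains it, so the estimator
is monotone only position-wise, not globally. The density basin between
the two asters is wide and shallow, so its position is summarized as the
centroid of the low-density basin (values below the 25th percentile of
the smoothed interior profile) rather than a bare argmin, which wanders
over the flat basin with sampling noise.

**Furrow onset.** The transverse width at the equator (distance between the
boundary points at *u* = 0.5 on both sides), normalized by the contour
perimeter so that uniform shrinkage does not register, is compared with its
value at anaphase onset; onset is the earliest time the ratio stays below
1 − 0.05 for 3 consecutive frames. The 5% depth threshold is a calibration
against synthetic truth only — there is no published geometric criterion
for "the initial sign of furrowing".

## Problem sizes used in validation

The test suite and the acceptance script run full-scale single embryos
(0.133 µm/px, ~960 arc columns, 0.72 s/frame): 195-frame movies (0–140 s
p.a.o., the first acquisition window) in cohorts of 3 embryos for flow
recovery; a 200-frame spaced-particle fixture for tracking; 150-frame
movies for the directed-vs-diffusive transport contrast; 70-frame tubulin
movies (1.6 s/frame) in cohorts of 3 for microtubule density; a 250-frame
movie for furrow onset. Flow accuracy is assessed on the folded
across-embryo mean, which is how per-condition flow maps are produced.

## Known limitations

- Integer-shift PIV quantizes velocity at (pixel/factor)/dt; sub-quantum
  flows are resolved only in the average over frames or embryos.
- Segmentation assumes a single high-contrast cell on a darker background;
  it is not a general-purpose cell segmenter and will not handle touching
  embryos or low-contrast markers.
- The away/toward classification uses the strict sign of the mean distance
  increment; trajectories with near-zero net radial motion are classified
  by noise. The ≥ 6-frame and cortex-distance filters remove most such
  cases.
- The transport score is a relative activity measure in arbitrary
  intensity units; comparisons are meaningful within a matched imaging
  configuration only.
- The chromosome tracker requires the dark spot to stay within the search
  radius between frames; fast spindle rocking would need a larger radius
  (at the cost of confusing the two chromosome masses when they are close).
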