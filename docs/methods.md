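# Methods

This note documents the models, conventions, numerical choices and
benchmark conditions behind volpiv, at the level of detail a user needs to
interpret its output and its test results.

## Pipeline and conventions

A PIV analysis takes two same-shape scalar arrays (2D images or 3D
volumes) at consecutive time points.  The first frame is tiled into
interrogation windows of size `inter_size` with stride
`inter_size − overlap`; per axis the window count is
`floor((extent − inter) / (inter − overlap)) + 1` and trailing voxels that
do not fit a full window are excluded (no partial windows).  All indices
are 0-based in array storage order; displacement component `u` pairs with
axis 0, `v` with axis 1, `w` with axis 2.  A vector of +k along an axis
means the pattern moved +k voxels along that axis from frame *t* to
*t+1*.  Search windows are enlarged by `search_margin` voxels on all
sides and zero-filled where they extend past the volume border.

## Correlation scores and their support

The full linear cross-correlation matrix (shape `inter + search − 1` per
axis) is computed for every window pair; matrix index `i` along an axis
encodes the displacement `i − center` with `center = inter − 1 + margin`.
FFT lengths are rounded up to products of small primes
(`scipy.fft.next_fast_len`) because FFT run time spikes at prime sizes;
all accumulation is in double precision regardless of input bit depth.

ZNCC and inverse NSQECC need per-translation sums over the window
support.  Both are assembled from one frequency-domain correlation plus
integral-array sliding box sums over the zero-padded search window (the
fast normalized correlation decomposition): for ZNCC the numerator is the
correlation of the mean-subtracted interrogation window with the search
window and the denominator uses the local mean and variance of each
interrogation-sized support; for NSQECC the squared error decomposes into
`Σiv²` (constant), `Σsv²` per translation (integral array) and `−2·(iv ⋆
sv)` (FFT).  Translations whose support has numerically zero variance
(ZNCC) or zero norm (NSQECC) score 0 rather than NaN, keeping the arg-max
well-defined; a constant interrogation window yields an all-zero matrix
flagged degenerate, and an all-zero window under NSQECC is rejected
(undefined normalization) — `run_piv` treats zero-intensity windows as
background before correlation is attempted.

**Peak-search restriction.**  The arg-max is restricted to translations
where the interrogation window overlaps the (margin-enlarged) search
window by at least 50% of its volume — the product of per-axis overlap
fractions must be ≥ 0.5, which also bounds each component by
`margin + inter//2`.  Normalized scores over small, mostly zero-padded
supports are numerically unstable: in 3D, corner translations with ~15%
volume overlap can saturate ZNCC at 1.0 on a handful of accidentally
aligned voxels.  The volume rule removes these while preserving the
classic half-window dynamic range for axis-aligned motion.

**Unnormalized mode is raw.**  The unnormalized score correlates raw
intensities, with no window mean subtraction.  This keeps the score
faithful to its definition and reproduces the characteristic benchmark
behaviors of unnormalized PIV — in particular the degradation at high
seeding density, which is driven by the DC pedestal of raw correlation
over dense, near-uniform windows.  The trade-off is a peak-locking
residual in sub-voxel fits at dense seeding (see the benchmark section);
analyses that need intensity robustness should use ZNCC or NSQECC.

## Peak location, sub-voxel refinement, signal-to-noise

Ties in the arg-max break toward the lexicographically smallest index.
The secondary peak (for the primary peak ratio) is the maximum outside
the 3-per-axis neighborhood of the primary; if no positive secondary
exists the PPR is reported as a capped sentinel (1e6), and an all-equal
matrix scores PPR 1 with a degenerate flag.

Sub-voxel refinement evaluates, per axis, the three samples
`C[x−d], C[x], C[x+d]` around the peak.  The centroid estimator is
`(C[x+d] − C[x−d]) / (C[x+d] + C[x] + C[x−d])`; the 3-point Gaussian
estimator is the vertex of the parabola through the log-samples,
`(ln C[x−d] − ln C[x+d]) / (2 ln C[x+d] − 4 ln C[x] + 2 ln C[x−d])`,
oriented so that a peak truly centered at `x + δ` returns `+δ` — exact
for Gaussian profiles, as one verifies by substituting
`C(t) = exp(−(t−δ)²/2σ²)`.  The Gaussian fit requires three strictly
positive samples and falls back to the centroid formula (flagged) on that
axis otherwise; border peaks and flat denominators yield Δ = 0 with a
flag; refinements are clipped to (−1, 1).  No global offset is added to
make ZNCC samples positive, since offsetting distorts the log-parabola.

## Multi-pass

Round `r` of `f` scales `inter_size`, `search_margin` and `overlap` by
`(1 + f − r)`; the final round runs at the user values.  Because all
three scale by the same factor, `overlap < inter_size` is preserved
automatically (it is still validated each round).  Offsets are
transferred between rounds by nearest-cell lookup: each fine window
center is mapped to the nearest coarse cell, whose displacement is
rounded to integers and used to shift the fine search window.  Offsets
are clamped so the shifted search window keeps at least one voxel inside
the second frame.  Grids of different rounds do not nest exactly in
general; nearest-cell transfer is the simplest rule consistent with the
coarse field's resolution.

## Post-processing

Neighborhoods are square/cubic windows of per-axis radius r, clipped at
field borders; clipped windows use the clipped cell count.  Magnitude
filters (low/high pass, global and local n-sigma rules) OR-combine their
discard masks; replacement is zero, or the componentwise mean/median over
non-masked neighbors (a masked vector with no valid neighbor becomes
zero).  Similarity-selective averaging deems two vectors similar when
their normalized dot product exceeds a threshold (zero vectors are never
similar but count toward the neighbor total); the output direction is the
unit-normalized mean of the similar neighbors including the center
vector, and the output magnitude is `#similar / #neighbors` with the
center excluded from both counts — identical, by construction, to the
collectiveness map at the same radius and threshold.  The divergence map
correlates the per-vector-normalized field with a cube of unit vectors
pointing radially outward from its center (center cell zero); positive
responses mark sources, negative sinks, and the map is antisymmetric
under field negation.  Pseudo-trajectories advect seeded particles by
rounding their position to the nearest grid cell, sampling that cell's
displacement and adding it; particles whose rounded position leaves the
grid are frozen and flagged.  Trajectory positions live in grid-cell
coordinates; conversion to voxel or physical coordinates multiplies by
the grid step and voxel pitch at export time.  Unit conversion scales
component d by `voxel_pitch[d] / frame_interval` and may be applied once.

## Synthetic scenes and the accuracy benchmark

Scenes place `n` particle centers uniformly over the domain extended by
one particle diameter per side (so motion exchanges particles with the
outside).  Rendering sums Gaussian profiles `I₀·exp(−8‖x−c‖²/d²)` — the
e⁻² width convention, intensity `I₀e⁻²` at radius d/2 — truncated at 3
diameters, evaluated analytically at shifted positions for the second
frame so that fractional motion emerges from the continuous profile
rather than from resampling.  Optional additive Gaussian sensor noise is
off by default.  Scenes can emulate a finite sensor by rounding to
integer counts and clipping to `[0, 2^bits − 1]`; the benchmark sweep
configuration does this with 8 bits, since the uniform saturated patches
that limit dense seeding on real cameras cannot occur with unbounded
analytic intensities.  Seeding density is expressed as particles per
interrogation window, `n · window_volume / domain_volume`.

Bias and random errors follow their standard definitions per axis and
are pooled by averaging axes.  Sweeps pool all window vectors of all
seeded repeats for a swept value.

**Benchmark conditions** (chosen once; 2D sweeps on 200×200 px frames,
2 px particles, `I₀` = 100 on an 8-bit sensor, unnormalized correlation,
4 px search margin unless the margin itself is swept):

* *Fractional-shift protocol*: shifts 0.1–0.9 px applied along axis 0,
  32 px windows, seeding 5 particles per 10×10 px.  The moderate seeding
  isolates the sub-voxel estimator from the raw-correlation pedestal: at
  this density the 3-point Gaussian fit reduces the mean bias ~13×
  (from the 0.23 px nearest-integer average), while at 15 particles per
  10×10 px the pedestal residual caps the gain near 8×.
* *Interrogation-size protocol*: 5000 particles, homogeneous translation,
  window sizes 8–48 px; the bias floor at the largest windows is
  ~0.02 px.
* *Density protocol*: 10×10 px windows, 2–50 particles per window,
  integer translation (3, 3) with margin 4; the total (bias + random)
  error is U-shaped with its minimum at 15–20 particles per window.
* *Margin protocol*: translations 0.5–3.5 px at margins 0 and 4; margin 4
  holds the bias at its small-translation level while margin 0 degrades
  monotonically with translation strength.

The pytest suite runs these protocols at 5 seeded repeats per point;
`scripts/acceptance.py` uses 20.  Every sweep is deterministic given its
seed (child seeds are spawned per swept value and repeat).

## What the synthetic benchmark does and does not show

The generator emulates rigid, spatially uniform translations of identical
particles with a clean sensor.  Passing tests therefore demonstrate the
correctness of the correlation, peak-fitting, multi-pass and bookkeeping
machinery and the estimator's intrinsic accuracy — they do not bound
errors on real recordings, where gradients within a window, rotation and
deformation, photon noise, bleaching and out-of-plane motion all degrade
matching.  The density optimum in particular depends on sensor
saturation/quantization details; with a different camera model its
location shifts.  For real LSFM data NSQECC is the recommended score
(diffuse patterns bias ZNCC), with a search margin at least as large as
the expected frame-to-frame motion.

## Known limitations

* No window deformation / iterative image-deformation PIV and no adaptive
  grids — displacements are assumed locally constant per window.
* Normalized scores are only evaluated on supports with ≥ 50% volume
  overlap; motion beyond `margin + inter/2` per axis needs multi-pass.
* Multi-pass offset transfer is nearest-cell, not interpolating; very
  sharp flow gradients can hand a fine window a poor offset.
* The legacy-VTK writer emits ASCII structured points only.
* Single-threaded; large volumes are best subsampled (the `subsample`
  operation and background skipping exist for exactly this purpose).
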