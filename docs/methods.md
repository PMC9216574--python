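# Methods

## The problem

Traction force microscopy (TFM) infers the stresses a cell exerts on a
compliant substrate from the motion of fiducial beads between two images:
one with the cell attached ("deformed") and one after the cell is released
("reference"). On soft gels (Young's modulus of a few kPa) a single mature
adhesion can displace the gel by several microns — tens of pixels — over a
region only a few template-windows wide. Correlation-based trackers fail
exactly there: within one interrogation template the displacement varies by
several pixels, the template decorrelates, and the true shift is either
outside the search range or no longer the global correlation maximum.
Because the inverse elastic problem amplifies displacement errors, the
missing large vectors dominate the error of the reconstructed traction.

This package implements a two-step tracking strategy for that regime:
correlation-based particle tracking (cPTV) for everything the correlation
can decide on its own, followed by neighbor-guided *retracking* (cPTVR)
that rescues the failed locations by constraining the correlation search
with the statistics of the surrounding, confidently tracked vectors, and by
preferring correlation peaks that agree with that neighborhood even when
they are not the global maximum.

## Forward model and synthetic benchmark

The substrate is an isotropic linear-elastic half-space with Young's
modulus `E` (default 8000 Pa) and Poisson's ratio `nu` (default 0.5,
incompressible). Surface displacement follows from the Boussinesq Green's
function for tangential surface loads,

    G(s) = (1+nu) / (pi E r^3) [ (1-nu) r^2 + nu s_x^2      nu s_x s_y
                                 nu s_x s_y       (1-nu) r^2 + nu s_y^2 ],

integrated over the traction field. Tractions are discretized on the pixel
grid; each cell's contribution is integrated *analytically* (the
antiderivatives `y ln(x+r) + x ln(y+r)`, `y ln(x+r)`, `x ln(y+r)`, `-r`
evaluated at the cell corners) within a 10 px neighborhood of the
evaluation point — including the singular self-cell — and by midpoint
quadrature farther away, where the midpoint error is below 1e-4 relative.
Displacements expressed in pixels are independent of the physical pixel
size because `G ~ 1/(E r)`; the nominal 108 nm/px only matters for
physical-unit conversion.

The canonical benchmark (`BenchmarkConfig` defaults):

* field of view 512 x 512 px; 8000 beads uniformly at random;
* one central elliptical Gaussian traction spot, peak 12 kPa, standard
  deviations 15 x 10 px, oriented 35 degrees — an adhesion-scale
  concentrated force producing a peak displacement of ~52 px;
* six small peripheral spots of 250–500 Pa (sub-pixel to ~1.5 px
  displacements), the "small force" territory where plain cPTV excels;
* beads rendered as isotropic Gaussians, sigma = 1.5 px (a
  diffraction-limited 40 nm bead at ~108 nm/px), amplitudes uniform in
  [200, 1000] counts over a background of 100 — a realistic several-fold
  brightness spread. Noise is off by default (an optional
  Poisson + Gaussian read-noise model exists for robustness studies);
* each bead center is advected by the forward solution evaluated at its
  own position — no grid interpolation — and both configurations are
  rendered identically.

What the generator does *not* emulate: out-of-plane bead motion, finite
gel thickness, stage drift, spatially varying illumination, or camera
nonlinearity. Passing the benchmark therefore demonstrates the tracking
algorithm under ideal imaging, not robustness to experimental artifacts.

### Comparison regions

The per-region metrics use masks drawn on the *displacement* map: the
large-force region is where the displacement produced by the central spot
alone exceeds 10% of its own peak (an ellipse of roughly 100 px
equivalent radius — the visible extent of the displacement blob), and
likewise for the small spots, with the large region taking precedence.
Displacement footprints, not traction support, are the natural comparison
regions because the half-space response decays like 1/r and spreads far
beyond the loaded area; a traction-support mask would score only the
steepest core. Traction-support masks (threshold + dilation) remain
available in `metrics.region_masks`.

## Bead detection

Candidates are local maxima of the Laplacian-of-Gaussian-filtered
reference image at the PSF scale; each is refined by a Gauss–Newton fit of
an isotropic Gaussian (fixed sigma) plus local background, vectorized over
all candidates, and kept if its amplitude passes a t-test against the
local fit residual at alpha = 0.05. At 8000 beads per 512 x 512 px the
mean nearest-neighbor spacing is 2.9 px (~2 sigma), so roughly half of
the beads merge into blended maxima; the detector reports roughly half
as many interrogation seeds as there are beads. That is intentional: tracking interrogates image
templates, not isolated emitters, so completeness of detection is not
required (an optional deflation pass that subtracts fitted Gaussians and
re-detects the residual exists, but its extra seeds localize poorly in
this density regime and it is off by default).

## cPTV

Per seed, a template of half-length L = 10 (21 px window) from the
reference image is scored against the deformed image over integer shifts
up to `u_max = 29` px with the zero-normalized cross-correlation,
evaluated in the frequency domain (identical to the direct double sum to
1e-6). The global score maximum is accepted only if the secondary local
maximum is at most `significance = 0.65` times its height; accepted peaks
are refined by a quadratic-surface fit to the 3 x 3 neighborhood (offset
clamped to half a pixel). Outliers are removed with a normalized
vector-median test (neighborhood radius 15 px, residual normalized by the
neighborhood median absolute residual + 0.1 px, threshold 2).

The significance threshold is texture-dependent. For this bead density
and PSF, an *unambiguously correct* match still shows a secondary-peak
ratio of ~0.5 (templates contain ~10 beads of self-similar speckle), so
the threshold must sit above that baseline; 0.65 passes the large majority of correct small-displacement matches
(in calibration, every match it passed was correct) and essentially none
of the ambiguous large-displacement ones, which is exactly the "strict" operating point the
initial pass needs. A generous setting (0.9) admits the large vectors too
— but mostly wrong, which is the documented failure mode of conventional
cPTV on large local deformation.

## cPTVR — retracking

Seed points are all vectors that failed tracking or were filtered out.
The algorithm then iterates a rim-inward cascade:

1. **Neighborhood statistics.** Confident (tracked or retracked) vectors
   are gathered within a search radius grown from 2x the mean bead
   spacing until at least `min_neighbors` (3) are found, capped at 3x the
   initial radius — a deliberately local cap, because statistics borrowed
   from far away systematically underestimate the missing vector and
   invite wrong acceptances. The model vector `u_nei` is the
   component-wise median (neighbor magnitudes around a missed large
   vector are biased low and non-Gaussian, and the median resists that
   bias best); angular statistics are circular (resultant-vector mean and
   std, floored at 5 degrees).
2. **Masked interrogation.** The correlation map — enlarged beyond
   `u_max` when needed, up to 80 px — is restricted to shifts with
   magnitude in [0.5, 3.0] x EF x |u_nei| (a generous upper limit: the
   missing vector is expected to be at least as large as its neighbors)
   and direction within +-2 circular std of the neighbor mean.
3. **Candidate selection.** If the masked global maximum passes the
   significance test it is accepted. Otherwise the local maximum closest
   to the model vector EF x u_nei is accepted when it lies within 2
   magnitude-std and 1 angular-std of the model, scores at least 0.5, and
   has magnitude between `|u_nei| - 1 std` and `max neighbor + 2 std`
   (the two magnitude guards embody "at least as large as the neighbors,
   but not implausibly larger" and suppress accidental texture matches).
4. **Window ladder.** On failure the template shrinks by 2 px and the
   search repeats, down to a 7 px window (about one bead at
   sigma = 1.5 px). The dominance (significance) rule may fire at any
   window; the closest-to-model rule only at windows of 11 px or less,
   where non-global per-bead peaks are crisp — larger windows blur them
   into shifted maxima.
5. **Single-bead re-measurement.** Any acceptance made at a larger window
   is snapped to the nearest strong peak of the single-bead-window map
   (within 3 px): the large-window peak position is biased by the
   displacement gradient across the template, the per-bead peak is not.

Every rescue immediately joins the confident set and guides the
still-missing neighbors, so holes fill inward from their rim. Each sweep
visits the best-constrained seeds first; a sweep that rescues nothing is a
fixed point of the deterministic loop and ends the stage (a stall counter
could never recover after an empty sweep), and failed attempts are not
repeated until the seed's neighborhood has changed.

Two scheduling refinements matter a great deal in practice and are part
of this implementation's design:

* **Dominance first, globally.** All significance-rule rescues are
  exhausted over the whole field before any closest-to-model acceptance
  is allowed. The dominance rule is essentially never wrong, and running
  it to exhaustion densifies the guide field so that the closest-rule
  gambles are anchored by much better statistics.
* **Per-seed enlargement schedule.** The enlargement factor ladder
  EF = 1.0, 1.1, 1.21, ... (10% per step, 15 steps) is swept per seed
  over cached correlation maps (the raw maps do not depend on EF), with
  the window ladder inside each EF level. When a whole escalated pass
  over the remaining seeds rescues nothing, the minimum neighbor count is
  raised (3 -> 5 -> 8) to firm up the radius determination, and the pass
  repeats; any progress restarts the ladder because fresh vectors change
  the neighborhoods. Termination is guaranteed — seeds are finite and
  every pass either rescues one or advances a finite ladder.

After convergence a **repair stage** re-examines the retracked vectors
with the same normalized vector-median test used for filtering: an
accepted vector that disagrees with its now-complete neighborhood was most
likely an accidental texture match ("echo" peak) accepted while the model
still lagged. Such vectors are revoked, their shifts blacklisted for their
seeds, and the cascade reruns (up to 3 rounds) so the matured neighborhood
can guide them to a different peak.

The cPTVR-median variant is the cascade with EF fixed at 1 (plain median
model); the cPTVR-EF variant continues from its fixed point with the
enlargement schedule. Both log per-rescue provenance (window, EF,
neighbor count, rule) so every accepted vector can be audited against the
criterion it passed.

Two further validation ideas were implemented, measured, and *disabled by
default* after they proved counterproductive on this texture: a
reciprocal (forward-backward) match check (rejects 10–20% of genuine
rescues in dense speckle, which starves the cascade more than it protects
it) and repair against a local affine or global elastic smoother of the
field (both get contaminated by the very clusters they should flag). They
remain available as configuration options (`backward_check`,
`repair_mode`).

## Metrics

Over a region of interest with ground truth `V_g` evaluated analytically
at each measured origin:

* deviation ratio ("MSD" by historical name, though the formula is an
  L1 ratio, implemented exactly as defined):
  `MSD = sum |V_g,i - V_m,i| / sum |V_g,i|`;
* accuracy: `Acc = mean( 1 - |V_g,i - V_m,i| / mean|V_g| )`; 1 means
  every vector tracked exactly, and a missed large vector can push
  individual terms negative.

Vectors with failed/filtered status count as zero displacement by default
(a miss is an error); an exclude policy is available.

## Traction reconstruction

`min_t ||G t - u||^2 + lambda ||t||^2` on a regular grid, with the
confident vectors linearly interpolated to the grid (zero outside the
convex hull). Two solvers: a dense reference solver built from the same
analytic per-cell integrals as the forward model (small grids), and a
per-wavevector Tikhonov solve of the periodic Fourier-space Boussinesq
kernel (the classic regularized Fourier-transform traction cytometry
scheme) for production use; the zero wavevector is set to zero (no net
traction). `lambda` is either fixed or chosen at the maximum-curvature
corner of the log-log residual/solution-norm L-curve over 20 log-spaced
values, falling back to the closest point to the normalized curve's
origin when no corner exists. The default comparison grid is 64 x 64 over
the 512 px field (desk-scale stand-in for a per-pixel mesh); the
self-consistency check runs at 128 x 128.

## Numerical and design choices

* Coordinates: x = column, y = row, origin at the top-left pixel center,
  0-based; displacements in px.
* Tie-breaks in peak ranking: higher score, then smaller shift magnitude,
  then lexicographic.
* Border seeds: templates are clamped to the image and out-of-bounds
  shifts are masked (never padded); windows below 7 px report failure.
* Flat (zero-variance) templates report failure, never divide by zero.
* All randomness flows from a single integer seed per benchmark
  realization; the pipeline is deterministic given the seed.
* Problem sizes: the method comparison runs the full 8000-bead, 512 x 512
  benchmark; unit tests use a 2000-bead, 256 px configuration of the same
  generator.

## Known limitations

* The retracking assumes the failed vectors sit next to well-tracked
  ones; an isolated large deformation with no confident rim (or a low
  signal-to-noise image) will not be rescued, and the method is
  recommended only for high-SNR, in-plane bead motion.
* Like the model it implements, retracking tends to overestimate missing
  displacements relative to their neighbors when the enlargement factor
  is escalated far; the magnitude cap and repair stage bound, but do not
  eliminate, this.
* The periodic Fourier inversion slightly misplaces low-frequency content
  for fields that are nonzero at the boundary; the dense solver avoids
  this at small grid sizes.
* At the benchmark bead density, detection seeds are blends of ~2 beads
  on average; per-seed ground truth is then intrinsically ambiguous at
  the ~1 px level, which sets the accuracy ceiling of every variant.
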