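# Methods

## Pipeline overview

A calibrated reflection-mode confocal stack (multi-page grayscale TIFF,
axis order (z, y, x), z = 0 at the substratum, voxel sizes dx, dy, dz in μm)
is thresholded into a foreground mask, from which all descriptors are
computed. The stages, in execution order:

1. **Thresholding.** Foreground is every voxel *strictly above* the
   threshold. The default is Otsu's method computed once over the whole
   stack, not per slice: a global threshold keeps metrics comparable across
   z, whereas per-slice thresholds (available via `per_slice=True`) would
   re-normalize each section and distort the height map. "Strictly above"
   resolves boundary ties so that an all-zero stack yields an exactly empty
   mask. A constant-intensity stack has no separating threshold and is
   rejected rather than silently binarized. RGB pages are rejected unless
   BT.601 luminance conversion is explicitly requested, since reflection-mode
   data are grayscale and silent channel-mixing would corrupt intensities.

2. **Voxel counting metrics.** Biovolume, coverage and A/V are direct
   counts. Surface voxels use strict face adjacency (6-connectivity) — the
   most conservative reading of "attached to a neighboring background
   pixel" — with the stack border counting as background. Surface area
   weights each boundary voxel by one xy-pixel face (dx·dy), matching the
   pixel-counting convention of the confocal-biofilm literature; an
   exposed-face variant (every exposed face with its true area) is available
   via `exposed_faces=True` for users who want a geometric area.

3. **Height map and thickness.** Per column, h = (1 + topmost foreground z
   index)·dz: thickness is the top-surface height, ignoring overhangs and
   internal voids, which matches how a height distribution is read off a
   z-stack. A column-sum variant (`net_volume=True`) measures net biomass
   height instead. Empty columns enter the mean-thickness average as h = 0
   by default because the thickness distribution is defined over every point
   of the imaging plane; `covered_only=True` averages over occupied columns
   only (and is then necessarily ≥ the default).

4. **Roughness fluctuation coefficient.** η = SD(h)/mean(h) with the
   population SD, over the same column set used for the mean. The
   alternative normalization by R_rms that sometimes appears in the
   literature is not used here: η is a thickness-heterogeneity measure and
   SD/M is the form that is dimensionless and scale-free in thickness.

5. **Fractal dimension.** The boundary pixel set of a 2D cross-section
   (foreground 4-adjacent to background, field edge counting as background)
   is box-counted over dyadic sizes ε ∈ {1, 2, 4, …, ≤ min(side)/4}; D is
   the least-squares slope of log N(ε) against log(1/ε). The box grid is
   anchored at (0, 0) with no grid-offset averaging — a documented
   limitation that adds a small anchor-dependent wobble (well inside the
   ±0.1 band the tests enforce). Reported values are clamped to [1, 2]
   (the raw slope is available with `clamp=False`); slices that are empty or
   full have no boundary and are rejected. Per-stack reports use the
   substratum section (z = 0), the section where colony/substratum contact
   geometry lives; NaN is reported when that section is degenerate.

6. **Aggregates.** 3D connected components use 26-connectivity so that
   EPS-bridged colonies touching only diagonally are not fragmented.
   Components touching the field border are kept without edge correction
   (bias documented below). Volumes are voxel counts times voxel volume and
   conserve total biovolume exactly; centroids are mean voxel-center
   positions projected to (x, y).

7. **Hopkins aggregation index.** H = Σu²/Σw² on the 2D centroid pattern:
   u are distances from m uniform random window locations to the nearest
   point, w are nearest-other-point distances from m sampled points
   (without replacement). Squared 2D distances give E[H] ≈ 1 under complete
   spatial randomness, so the working interpretation is H < 2 ⇒ consistent
   with random placement, H > 2 ⇒ patchy. Default m = min(⌈n/10⌉, 50)
   (floor 5, capped at n/2) keeps u and w draws weakly dependent. The
   median over 99 seeded repeats is reported; repeats and seed are explicit
   arguments. The classical [0, 1]-valued statistic Σu²/(Σu²+Σw²) is
   exposed as `variant="classic"`. Centroids, not raw foreground pixels,
   are the point pattern: the statistic is about colony dispersion, and
   pixel-level patterns would be dominated by within-colony mass.

8. **Aggregation coefficient.** AC = (biovolume in aggregates with volume
   strictly greater than the threshold) / (total biovolume), threshold
   30 μm³ by default. This definition is a deliberate reimplementation
   choice — the descriptor is usually cited rather than printed — selected
   because it reproduces every behavior expected of it: AC = 0 for
   well-separated sub-threshold biomass, AC = 1 for a single large cluster,
   monotone non-decreasing under aggregate merging, invariant under
   proportional duplication of the population, and threshold-controlled
   sensitivity.

## Substrate descriptors

R_rms is the RMS deviation of heights about the mean plane; no tilt removal
is applied (substrate tilt correction is out of scope). The roughness factor
R_f triangulates the height field with two triangles per pixel cell and
divides by the projected area; triangulation (rather than gradient
quadrature) is exact for the piecewise-planar synthetic fixtures used to
validate it (flat ⇒ 1, 45° sawtooth ⇒ √2). Line profiles are sampled by
bilinear interpolation at the finer of dx, dy; profiles shorter than 16
samples are rejected as too short to carry roughness statistics.

## Growth fits

The monoexponential saturation SR(V) = SR_eq + A·exp(−V/V_c) and the
logistic coverage curve f(t) = f_max/(1 + exp(−k(t − t0))) are fitted by
bounded nonlinear least squares (V_c > 0; f_max ∈ (0, 1]), from
data-driven initializations (SR_eq from the top-quartile mean — the
saturated tail; V_c from range(V)/3; t0 from the half-maximum crossing) with
three jittered restarts (seed exposed) to avoid local minima. Convergence
failures are reported as such, never replaced by a fallback; near-constant
data flag V_c as unidentifiable; a declining coverage series fits with k < 0
and is flagged. The fit quality R is the Pearson correlation between fitted
and observed values. Spearman ρ uses average ranks for ties and rejects
constant inputs.

## Synthetic-data generator

The generator emulates reflection-mode stacks of surface-attached colony
fields: spherical-cap solids (caps, not spheres, because attached colonies
grow from the substratum; cap-height/radius ratio is a parameter, default 1
= hemisphere) seated on a flat or triangular-grooved substrate, with
lognormal sphere radii, placement either completely spatially random or
parent–offspring clustered, constant solid intensity, an optional
lower-intensity EPS halo shell (amorphous bright material around colonies),
and additive Gaussian noise over a constant background level. Overlapping
colonies union into single solids, which is what drives multi-scale
aggregate behavior. Defaults: 150×150 μm field, 40 slices, dx = dy = 0.5 μm,
dz = 1 μm, 30 colonies, median radius 5 μm (log-SD 0.4) — colony sizes
spanning the yeast-to-algae range (~3–25 μm) observed in marine films —
solid intensity 200, noise SD 20. Groove defaults (period 15 μm, depth
6 μm) mirror sandpaper-roughened plates with 5–8 μm deep valleys and
5–25 μm ridge spacing. Specs exceeding 95% substratum coverage are rejected
as unphysical for colony-resolved analysis. Rendering is a voxel-center
inside test on an integer grid and all randomness flows from one mandatory
seed through `numpy.random.default_rng`, so identical specs give
bit-identical stacks.

Seasonal growth scenarios produce logistic coverage series sampled at days
2, 4, …, 20 with plateaus of 40%/42% (spring/summer) and 5.5% (late autumn),
midpoint 8 d (growth accelerating after a 5–6 day lag) and observation noise
SD 0.02 (0.004 for the low-coverage scenario, keeping draws below 8%
coverage), plus a noiseless, hence monotone, companion aggregation-
coefficient curve rising after the coverage plateau.

What the generator does **not** emulate: confocal point-spread functions and
axial attenuation, diatom frustule geometry, multi-channel stains, the
inorganic reflective fraction of real reflection images, or spatially
correlated noise. Passing tests therefore demonstrate correctness of the
measurement pipeline on geometrically faithful scenes, not robustness to
every optical artifact of real microscopy.

## Numerical choices and degenerate inputs

- Empty masks: biovolume 0; A/V, η, AC and D undefined (raised), reported
  as NaN by the pipeline-level report.
- Otsu thresholding needs a non-trivial foreground fraction; on stacks where
  biomass is ≪ 2% of voxels the between-class criterion can prefer splitting
  the background. Framing the field on the colonies, or a fixed threshold,
  avoids this.
- The Hopkins index needs ≥ 10 points; stacks with fewer aggregates report
  NaN.
- Aggregates at the field border are not edge-corrected, biasing AC upward
  and H downward slightly on dense fields.
- The voxelized cap volume converges to the analytic πh²(3r−h)/3 as voxels
  shrink; at 0.25 μm voxels a 10 μm cap is within 3%.

## Problem sizes

Test and acceptance computations run on desk-scale inputs chosen to make
every statistic well-resolved: 16³–32³ randomized masks for oracle
equivalence (100 seeds), 300×300 μm colony fields for the aggregation
anchors, 500-point patterns with m = 50 and 99 Monte-Carlo repeats for the
Hopkins anchors, and 100 replicates of n = 200 noisy samples for
growth-fit parameter recovery.
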