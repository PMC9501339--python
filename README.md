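# biofilmorph

Quantitative 3D morphology of surface-attached biofilm colonies from
calibrated confocal z-stacks.

Marine and freshwater biofilms — microbial communities glued to submersed
surfaces by an extracellular polymeric (EPS) matrix — are routinely imaged as
reflection-mode confocal stacks. `biofilmorph` turns such a stack (a
multi-page grayscale TIFF with known voxel calibration) into the standard
structural descriptor set used to track biofilm development, substrate
effects and aggregation state, and ships a fully seeded synthetic-stack
generator so every stage of the pipeline can be validated against known
ground truth without microscope data.

## Descriptors

For a binarized stack with voxel sizes *dx, dy, dz* (μm), substratum at
*z* = 0:

- **Biovolume** `V = N_fg · dx·dy·dz` — foreground-voxel count times voxel
  volume (μm³).
- **Coverage fraction** `f` — per-cross-section foreground pixel fraction, or
  (default) the substratum coverage: fraction of (y, x) columns containing
  any biomass.
- **Area/volume ratio** `A/V` — A counts foreground voxels face-adjacent
  (6-connectivity) to background, weighted by one pixel face `dx·dy` (μm⁻¹).
- **Mean thickness** `M` — mean of the per-column top-height map *h(y, x)*
  over the imaging field (μm).
- **Roughness fluctuation coefficient** `η = SD(h)/M` — dimensionless
  heterogeneity of the thickness distribution.
- **Fractal dimension** `D ∈ [1, 2]` — box-counting slope of
  log N(ε) vs log(1/ε) over the 4-connected boundary pixels of a 2D
  cross-section; 1 = smooth boundary, →2 = plane-filling.
- **Hopkins aggregation index** `H = Σu²/Σw²` — empty-space distances u
  (random locations → nearest colony centroid) against nearest-neighbor
  distances w between centroids; H ≈ 1 under complete spatial randomness,
  H > 2 for patchy, clustered colonies. Reported as the median over 99
  seeded Monte-Carlo repeats.
- **Aggregation coefficient** `AC ∈ [0, 1]` — fraction of total biovolume in
  26-connected aggregates larger than 30 μm³: 0 for fully dispersed biomass,
  1 for one large cluster.

Substrate descriptors (`R_rms`, roughness factor `R_f` = effective/projected
area ≥ 1, line profiles) and growth-curve fits (monoexponential roughness
saturation `SR(V) = SR_eq + A·exp(−V/V_c)`, logistic coverage-vs-time,
Spearman ρ) round out the toolkit.

## Worked example

Generate a noisy synthetic colony field (25 spherical-cap colonies, median
radius 8 μm, on a 100×100 μm field; solid intensity 300 over background 100,
noise SD 40 — contrast of 5 noise SDs), segment it by global Otsu
thresholding, and compute the report:

```python
import json
from biofilmorph import SyntheticSpec, generate_stack, binarize
from biofilmorph.morphology3d import analyze_stack

spec = SyntheticSpec(seed=42, width_um=100.0, length_um=100.0, n_slices=24,
                     n_colonies=25, radius_median_um=8.0,
                     background_intensity=100.0, solid_intensity=300.0,
                     noise_sd=40.0)
grid, truth, record = generate_stack(spec)
mask = binarize(grid, method="otsu")
report = analyze_stack(mask, rng_seed=0)
print("true solid volume: %.1f" % record["voxel_volume_um3"])
print(json.dumps(report.to_dict(), indent=2))
```

prints

```
true solid volume: 27832.5
{
  "biovolume_um3": 29383.0,
  "coverage_pct": 50.2725,
  "area_to_volume_per_um": 0.35938297655106693,
  "mean_thickness_um": 4.59395,
  "roughness_coefficient": 1.2980526625584707,
  "fractal_dimension": 1.0369076771859322,
  "hopkins_index": 0.8852791387669183,
  "aggregation_coefficient": 0.9451979035496716
}
```

The segmented biovolume (29 383 μm³) recovers the generator's true solid
volume (27 833 μm³) to ~6% despite the noise; half the substratum is covered;
η ≈ 1.3 reflects the strongly undulating cap-field surface; D ≈ 1.04 says the
colony boundaries in the substratum section are nearly smooth; H < 1 is
consistent with the random (CSR) colony placement the generator used; and
AC ≈ 0.95 because nearly all biomass sits in caps larger than 30 μm³.

The same pipeline is available from the shell:

```bash
biofilmorph simulate --seed 42 --out stack.tif --truth truth.json
biofilmorph analyze stack.tif --dx 0.5 --dy 0.5 --dz 1.0 --threshold otsu --out report.json
biofilmorph fit series.csv --model monoexp
```

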