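"""Per-stack geometric descriptors of biofilm architecture.

Implements the standard confocal-stack morphology set: biovolume V, coverage
fraction f, area-to-volume ratio A/V, per-column height map, mean thickness M,
roughness fluctuation coefficient η = SD(h)/M, and the box-counting fractal
dimension D of a 2D cross-section boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage

from .stack_io import BinaryGrid

__all__ = [
    "HeightMap",
    "MorphologyReport",
    "biovolume",
    "coverage_fraction",
    "area_to_volume",
    "height_map",
    "mean_thickness",
    "roughness_coefficient",
    "fractal_dimension_2d",
    "boundary_pixels_2d",
    "analyze_stack",
]

# 6-connectivity structuring element: face adjacency only.
_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)


@dataclass(frozen=True)
class HeightMap:
    """Per-(y, x) biofilm top height in μm.

    ``h`` is 0 wherever the column contains no foreground; ``covered`` flags
    columns with any foreground.  Carries the lateral calibration so surface
    descriptors (R_rms, R_f) can be computed downstream.
    """

    h: np.ndarray
    covered: np.ndarray
    dx: float
    dy: float

    def __post_init__(self) -> None:
        h = np.asarray(self.h, dtype=np.float64)
        covered = np.asarray(self.covered, dtype=bool)
        if h.ndim != 2 or h.shape != covered.shape:
            raise ValueError("h and covered must be matching 2D arrays")
        if np.any(h < 0):
            raise ValueError("heights must be non-negative")
        object.__setattr__(self, "h", h)
        object.__setattr__(self, "covered", covered)


@dataclass(frozen=True)
class MorphologyReport:
    """One record with the full descriptor set for an analyzed stack."""

    biovolume_um3: float
    coverage_pct: float
    area_to_volume_per_um: float
    mean_thickness_um: float
    roughness_coefficient: float
    fractal_dimension: float
    hopkins_index: float
    aggregation_coefficient: float

    def to_dict(self) -> dict:
        return asdict(self)


def biovolume(mask: BinaryGrid) -> float:
    """Total biomass volume: foreground-voxel count times voxel volume (μm³)."""
    return float(np.count_nonzero(mask.mask)) * mask.voxel_volume


def coverage_fraction(mask: BinaryGrid, z: int | None = None) -> float:
    """Fraction of occupied pixels.

    With ``z`` given, the foreground fraction of that cross-section.  Without,
    the substratum coverage: the fraction of (y, x) columns containing any
    foreground — the quantity tracked in growth series.
    """
    m = mask.mask
    if z is None:
        return float(np.count_nonzero(m.any(axis=0))) / (m.shape[1] * m.shape[2])
    if not 0 <= z < m.shape[0]:
        raise IndexError(f"slice index {z} out of range for {m.shape[0]} slices")
    return float(np.count_nonzero(m[z])) / m[z].size


def surface_voxel_count(mask: BinaryGrid) -> int:
    """Count foreground voxels face-adjacent (6-connectivity) to background.

    The stack border counts as background, so voxels on the field edge are
    surface voxels.
    """
    m = mask.mask
    interior = ndimage.binary_erosion(m, structure=_FACE_STRUCT, border_value=0)
    return int(np.count_nonzero(m & ~interior))


def area_to_volume(mask: BinaryGrid, *, exposed_faces: bool = False) -> float:
    """Surface-area to biovolume ratio in μm⁻¹.

    Default surface area counts boundary voxels weighted by one xy-pixel face
    (dx·dy) each, mirroring the pixel-count convention of confocal biofilm
    analysis.  ``exposed_faces=True`` instead sums every exposed voxel face
    with its true face area.
    """
    m = mask.mask
    n_fg = np.count_nonzero(m)
    if n_fg == 0:
        raise ValueError("area-to-volume ratio undefined for an empty mask")
    v = n_fg * mask.voxel_volume
    if not exposed_faces:
        a = surface_voxel_count(mask) * mask.dx * mask.dy
    else:
        a = 0.0
        face_areas = {0: mask.dx * mask.dy, 1: mask.dx * mask.dz, 2: mask.dy * mask.dz}
        padded = np.pad(m, 1, constant_values=False)
        core = padded[1:-1, 1:-1, 1:-1]
        for axis, fa in face_areas.items():
            for shift in (-1, 1):
                neighbor = np.roll(padded, shift, axis=axis)[1:-1, 1:-1, 1:-1]
                a += fa * np.count_nonzero(core & ~neighbor)
    return float(a / v)


def height_map(mask: BinaryGrid, *, net_volume: bool = False) -> HeightMap:
    """Per-column biofilm height in μm.

    Default is the top-surface height: ``(1 + topmost foreground z index)·dz``,
    ignoring internal voids and overhangs.  ``net_volume=True`` returns instead
    the column-sum ("net volume") height ``n_foreground·dz``.
    """
    m = mask.mask
    covered = m.any(axis=0)
    if net_volume:
        h = m.sum(axis=0, dtype=np.float64) * mask.dz
    else:
        # topmost index = n_z - 1 - argmax over the z-reversed stack
        top = m.shape[0] - 1 - np.argmax(m[::-1], axis=0)
        h = np.where(covered, (top + 1) * mask.dz, 0.0)
    return HeightMap(h=h, covered=covered, dx=mask.dx, dy=mask.dy)


def mean_thickness(hm: HeightMap, covered_only: bool = False) -> float:
    """Mean thickness M: average height over all columns, or covered columns only."""
    if covered_only:
        if not hm.covered.any():
            raise ValueError("no covered columns: mean thickness undefined")
        return float(hm.h[hm.covered].mean())
    return float(hm.h.mean())


def roughness_coefficient(hm: HeightMap, covered_only: bool = False) -> float:
    """Roughness fluctuation coefficient η = SD(h) / mean(h), population SD.

    The same column set (all, or covered only) is used for both moments.
    """
    h = hm.h[hm.covered] if covered_only else hm.h
    if h.size == 0:
        raise ValueError("empty height map: roughness coefficient undefined")
    m = float(np.mean(h))
    if m <= 0:
        raise ValueError("zero mean thickness: roughness coefficient undefined")
    return float(np.std(h) / m)


def boundary_pixels_2d(mask_slice: np.ndarray) -> np.ndarray:
    """Boundary of a 2D cross-section: foreground pixels 4-adjacent to background.

    The field edge counts as background.
    """
    m = np.asarray(mask_slice, dtype=bool)
    interior = ndimage.binary_erosion(
        m, structure=ndimage.generate_binary_structure(2, 1), border_value=0
    )
    return m & ~interior


def _box_counts(points_mask: np.ndarray, sizes: list[int]) -> list[int]:
    """Number of occupied ε-boxes on a grid anchored at (0, 0), per box size."""
    counts = []
    ys, xs = np.nonzero(points_mask)
    for eps in sizes:
        boxes = set(zip((ys // eps).tolist(), (xs // eps).tolist()))
        counts.append(len(boxes))
    return counts


def fractal_dimension_2d(mask_slice: np.ndarray, *, clamp: bool = True) -> float:
    """Box-counting fractal dimension of the foreground/background boundary.

    The boundary pixel set is covered by dyadic boxes of side
    ε ∈ {1, 2, 4, …, ≤ min(side)/4}; D is the least-squares slope of
    log N(ε) versus log(1/ε).  Values near 1 indicate a smooth boundary and
    values toward 2 a convoluted, plane-filling one.  The reported value is
    clamped to [1, 2] by default (``clamp=False`` returns the raw slope).

    Raises
    ------
    ValueError
        If the slice is all-background or all-foreground (no boundary).
    """
    m = np.asarray(mask_slice, dtype=bool)
    if m.ndim != 2:
        raise ValueError("expected a 2D cross-section")
    n_fg = np.count_nonzero(m)
    if n_fg == 0 or n_fg == m.size:
        raise ValueError("slice is empty or full: boundary undefined")
    boundary = boundary_pixels_2d(m)
    max_eps = min(m.shape) // 4
    sizes = []
    eps = 1
    while eps <= max_eps:
        sizes.append(eps)
        eps *= 2
    if len(sizes) < 2:
        raise ValueError("slice too small for box counting (need min side >= 8)")
    counts = _box_counts(boundary, sizes)
    log_inv_eps = -np.log(np.asarray(sizes, dtype=np.float64))
    log_n = np.log(np.asarray(counts, dtype=np.float64))
    slope = np.polyfit(log_inv_eps, log_n, 1)[0]
    if clamp:
        return float(min(2.0, max(1.0, slope)))
    return float(slope)


def analyze_stack(
    mask: BinaryGrid,
    *,
    v_threshold: float = 30.0,
    hopkins_m: int | None = None,
    hopkins_repeats: int = 99,
    rng_seed: int = 0,
) -> MorphologyReport:
    """Compute the full morphology descriptor set for one foreground mask.

    The fractal dimension is evaluated on the substratum cross-section (z=0);
    the Hopkins index on z-projected aggregate centroids.  Either is reported
    as NaN when undefined (empty/full slice; fewer than 10 aggregates).
    """
    from . import aggregation

    hm = height_map(mask)
    v = biovolume(mask)
    try:
        av = area_to_volume(mask)
    except ValueError:
        av = math.nan
    try:
        eta = roughness_coefficient(hm)
    except ValueError:
        eta = math.nan
    try:
        d = fractal_dimension_2d(mask.mask[0])
    except ValueError:
        d = math.nan

    ags = aggregation.label_aggregates(mask)
    try:
        ac = aggregation.aggregation_coefficient(ags, v_threshold=v_threshold)
    except ValueError:
        ac = math.nan
    try:
        pp = aggregation.centroid_pattern(ags)
        h_idx = aggregation.hopkins_index(
            pp, m=hopkins_m, rng_seed=rng_seed, repeats=hopkins_repeats
        )
    except ValueError:
        h_idx = math.nan

    return MorphologyReport(
        biovolume_um3=v,
        coverage_pct=100.0 * coverage_fraction(mask),
        area_to_volume_per_um=av,
        mean_thickness_um=mean_thickness(hm),
        roughness_coefficient=eta,
        fractal_dimension=d,
        hopkins_index=h_idx,
        aggregation_coefficient=ac,
    )
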