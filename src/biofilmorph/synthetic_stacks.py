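"""Synthetic reflection-mode confocal stacks with known ground truth.

Emulates surface-attached marine biofilm colonies: spherical-cap solids on a
substratum plane (flat or grooved), placed completely spatially at random or
as a clustered parent–offspring process, with lognormal colony radii, optional
low-intensity EPS halos and additive Gaussian noise.  Every draw is seeded, so
identical specs yield bit-identical stacks, and the generator returns the
exact ground-truth mask and per-colony geometry alongside the noisy image —
which is what makes the whole analysis pipeline testable without microscope
data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict, field

import numpy as np
import yaml
from scipy import ndimage

from .stack_io import VoxelGrid, BinaryGrid
from .aggregation import PointPattern2D
from .growth_stats import GrowthSeries

__all__ = [
    "SyntheticSpec",
    "generate_stack",
    "generate_point_pattern",
    "generate_growth_series",
    "spherical_cap_volume",
    "GROWTH_SCENARIOS",
]


def spherical_cap_volume(r: float, h: float) -> float:
    """Volume of a cap of height h cut from a sphere of radius r: πh²(3r−h)/3."""
    return math.pi * h * h * (3 * r - h) / 3.0


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic colony field.

    Lengths in μm.  ``placement`` is ``"csr"`` (uniform iid colony centers) or
    ``"clustered"`` (uniform parents, isotropic Gaussian offspring scatter).
    Colony sphere radii are lognormal — ``radius_median_um`` is the median,
    ``radius_log_sigma`` the log-space SD — and each colony is the cap of
    height ``cap_height_ratio · r`` of its sphere, seated on the substratum
    (attached colonies are caps, not floating spheres).  ``substrate`` is
    ``"flat"`` or ``"grooves"`` (triangular corrugation along x).  The seed is
    mandatory: reproducibility is part of the contract.
    """

    seed: int
    width_um: float = 150.0
    length_um: float = 150.0
    n_slices: int = 40
    dx: float = 0.5
    dy: float = 0.5
    dz: float = 1.0
    placement: str = "csr"
    n_parents: int = 20
    offspring_sigma_um: float = 2.0
    n_colonies: int = 30
    radius_median_um: float = 5.0
    radius_log_sigma: float = 0.4
    cap_height_ratio: float = 1.0
    solid_intensity: float = 200.0
    background_intensity: float = 0.0
    halo_rel_intensity: float = 0.0
    halo_thickness_um: float = 1.0
    noise_sd: float = 20.0
    substrate: str = "flat"
    groove_period_um: float = 15.0
    groove_depth_um: float = 6.0

    def __post_init__(self) -> None:
        for name in ("width_um", "length_um", "dx", "dy", "dz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_slices < 1 or self.n_colonies < 0:
            raise ValueError("need at least 1 slice and a non-negative colony count")
        if self.placement not in ("csr", "clustered", "center"):
            raise ValueError(f"unknown placement {self.placement!r}")
        if self.substrate not in ("flat", "grooves"):
            raise ValueError(f"unknown substrate {self.substrate!r}")
        if not 0 < self.cap_height_ratio <= 2:
            raise ValueError("cap_height_ratio must be in (0, 2]")

    @classmethod
    def from_yaml(cls, path) -> "SyntheticSpec":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _substrate_height(spec: SyntheticSpec, x_um: np.ndarray) -> np.ndarray:
    """Substrate height b(x) in μm: 0 for flat, triangular grooves otherwise."""
    if spec.substrate == "flat":
        return np.zeros_like(x_um)
    phase = (x_um / spec.groove_period_um) % 1.0
    tri = 1.0 - 2.0 * np.abs(phase - 0.5)  # 0 at valley center, 1 at ridge
    return spec.groove_depth_um * tri


def generate_point_pattern(
    mode: str,
    n: int,
    window: tuple[float, float],
    seed: int,
    *,
    n_parents: int = 20,
    offspring_sigma_um: float = 2.0,
) -> PointPattern2D:
    """Generate a planar point pattern in [0,W]×[0,L] μm.

    ``csr``: uniform iid points.  ``clustered``: parent–offspring — parents
    uniform, each offspring scattered isotropically (Gaussian σ) around a
    random parent; draws outside the window are rejected and redrawn so
    exactly n points land inside.  ``grid``: a regular √n×√n lattice at cell
    centers (n must be a perfect square).  ``center``: all points at the
    window center (deterministic single-colony fixtures).
    """
    w, l = window
    rng = np.random.default_rng(seed)
    if mode == "center":
        pts = np.tile([w / 2, l / 2], (n, 1))
    elif mode == "csr":
        pts = rng.uniform([0.0, 0.0], [w, l], size=(n, 2))
    elif mode == "clustered":
        parents = rng.uniform([0.0, 0.0], [w, l], size=(n_parents, 2))
        pts = np.empty((n, 2))
        filled = 0
        while filled < n:
            k = n - filled
            parent_idx = rng.integers(0, n_parents, size=k)
            cand = parents[parent_idx] + rng.normal(0.0, offspring_sigma_um, size=(k, 2))
            ok = (cand[:, 0] >= 0) & (cand[:, 0] <= w) & (cand[:, 1] >= 0) & (cand[:, 1] <= l)
            cand = cand[ok]
            pts[filled : filled + len(cand)] = cand
            filled += len(cand)
    elif mode == "grid":
        side = math.isqrt(n)
        if side * side != n:
            raise ValueError(f"grid mode needs a perfect-square n, got {n}")
        xs = (np.arange(side) + 0.5) * (w / side)
        ys = (np.arange(side) + 0.5) * (l / side)
        gx, gy = np.meshgrid(xs, ys)
        pts = np.column_stack([gx.ravel(), gy.ravel()])
    else:
        raise ValueError(f"unknown point-pattern mode {mode!r}")
    return PointPattern2D(points=pts, window=(w, l))


def _render_truth(spec: SyntheticSpec, centers: np.ndarray, radii: np.ndarray) -> np.ndarray:
    """Voxelize the union of substrate-seated spherical caps (voxel-center test)."""
    nz = spec.n_slices
    ny = int(round(spec.length_um / spec.dy))
    nx = int(round(spec.width_um / spec.dx))
    mask = np.zeros((nz, ny, nx), dtype=bool)
    z_um = (np.arange(nz) + 0.5) * spec.dz
    for (cx, cy), r in zip(centers, radii):
        hc = spec.cap_height_ratio * r
        base = float(_substrate_height(spec, np.asarray(cx)))
        zc = base + hc - r  # sphere center depth; cap flat face on the substrate
        ix0 = max(0, int((cx - r) / spec.dx))
        ix1 = min(nx, int(np.ceil((cx + r) / spec.dx)) + 1)
        iy0 = max(0, int((cy - r) / spec.dy))
        iy1 = min(ny, int(np.ceil((cy + r) / spec.dy)) + 1)
        iz1 = min(nz, int(np.ceil((base + hc) / spec.dz)) + 1)
        if ix0 >= ix1 or iy0 >= iy1 or iz1 <= 0:
            continue
        xs = (np.arange(ix0, ix1) + 0.5) * spec.dx - cx
        ys = (np.arange(iy0, iy1) + 0.5) * spec.dy - cy
        zs = z_um[:iz1] - zc
        inside = (
            zs[:, None, None] ** 2 + ys[None, :, None] ** 2 + xs[None, None, :] ** 2
        ) <= r * r
        inside &= z_um[:iz1, None, None] >= base
        mask[:iz1, iy0:iy1, ix0:ix1] |= inside
    return mask


def generate_stack(spec: SyntheticSpec):
    """Render a calibrated synthetic stack.

    Returns ``(stack, truth_mask, truth)``: the noisy intensity stack, the
    exact ground-truth foreground mask, and a truth record with per-colony
    geometry, the analytic solid volume (sum of cap volumes — exact when
    colonies do not overlap), and the voxelized truth volume.

    Raises
    ------
    ValueError
        If colony density would cover more than 95% of the substratum.
    """
    rng = np.random.default_rng(spec.seed)
    placement_seed = int(rng.integers(0, 2**31 - 1))
    pp = generate_point_pattern(
        spec.placement,
        spec.n_colonies,
        (spec.width_um, spec.length_um),
        placement_seed,
        n_parents=spec.n_parents,
        offspring_sigma_um=spec.offspring_sigma_um,
    )
    radii = spec.radius_median_um * np.exp(
        spec.radius_log_sigma * rng.standard_normal(spec.n_colonies)
    )
    mask = _render_truth(spec, pp.points, radii)
    coverage = mask.any(axis=0).mean() if mask.size else 0.0
    if coverage > 0.95:
        raise ValueError(
            f"colony density too high: substratum coverage {coverage:.0%} exceeds 95%"
        )
    bg = spec.background_intensity
    intensity = np.where(mask, spec.solid_intensity, bg)
    if spec.halo_rel_intensity > 0 and mask.any():
        dist = ndimage.distance_transform_edt(
            ~mask, sampling=(spec.dz, spec.dy, spec.dx)
        )
        halo = (~mask) & (dist <= spec.halo_thickness_um)
        intensity[halo] = bg + spec.halo_rel_intensity * (spec.solid_intensity - bg)
    if spec.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, spec.noise_sd, size=intensity.shape)
    intensity = np.clip(intensity, 0.0, None)
    grid = VoxelGrid(data=intensity, dx=spec.dx, dy=spec.dy, dz=spec.dz)
    truth_mask = BinaryGrid(mask=mask, dx=spec.dx, dy=spec.dy, dz=spec.dz)
    cap_heights = spec.cap_height_ratio * radii
    truth = {
        "centers_um": pp.points.tolist(),
        "radii_um": radii.tolist(),
        "cap_heights_um": cap_heights.tolist(),
        "analytic_volume_um3": float(
            sum(spherical_cap_volume(r, h) for r, h in zip(radii, cap_heights))
        ),
        "voxel_volume_um3": float(np.count_nonzero(mask)) * grid.voxel_volume,
        "substratum_coverage": float(coverage),
        "seed": spec.seed,
    }
    return grid, truth_mask, truth


# Seasonal coverage scenarios: plateau f_max, logistic midpoint t0 (d), rate k
# (1/d), observation noise SD, and the companion aggregation-coefficient curve
# (plateau, midpoint, rate).  Plateaus follow the seasonal pattern of temperate
# coastal waters: productive-season films level off near 38-45% coverage while
# late-autumn films stay below ~6%; growth accelerates after a 5-6 day lag.
GROWTH_SCENARIOS = {
    "april": dict(f_max=0.40, t0=8.0, k=0.7, noise_sd=0.02, ac_max=0.50, ac_t0=12.0, ac_k=0.5),
    "august": dict(f_max=0.42, t0=8.0, k=0.7, noise_sd=0.02, ac_max=0.60, ac_t0=12.0, ac_k=0.5),
    "november": dict(f_max=0.055, t0=8.0, k=0.5, noise_sd=0.004, ac_max=0.15, ac_t0=12.0, ac_k=0.5),
}

#: Sampling days of the growth series (every second day out to 20 d).
SAMPLING_DAYS = np.arange(2.0, 21.0, 2.0)


def generate_growth_series(scenario: str, seed: int, *, noise_sd: float | None = None):
    """Generate seeded seasonal growth series with known true parameters.

    Returns ``(series, truth)`` where ``series`` maps ``"coverage"`` to a noisy
    logistic substratum-coverage curve and ``"ac"`` to the companion
    aggregation-coefficient curve (noiseless, hence monotone non-decreasing —
    colonies compact into larger aggregates once coverage plateaus).  ``truth``
    holds the generating parameters.
    """
    if scenario not in GROWTH_SCENARIOS:
        raise ValueError(
            f"unknown scenario {scenario!r}; choose from {sorted(GROWTH_SCENARIOS)}"
        )
    p = GROWTH_SCENARIOS[scenario]
    sd = p["noise_sd"] if noise_sd is None else noise_sd
    rng = np.random.default_rng(seed)
    t = SAMPLING_DAYS.copy()
    f_true = p["f_max"] / (1 + np.exp(-p["k"] * (t - p["t0"])))
    f_obs = np.clip(f_true + rng.normal(0.0, sd, size=t.shape), 0.0, 1.0)
    ac = p["ac_max"] / (1 + np.exp(-p["ac_k"] * (t - p["ac_t0"])))
    series = {
        "coverage": GrowthSeries(t=t, y=f_obs, metric="substratum coverage", units=""),
        "ac": GrowthSeries(t=t, y=ac, metric="aggregation coefficient", units=""),
    }
    truth = dict(p, scenario=scenario, seed=seed, noise_sd=sd)
    return series, truth
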