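"""Aggregate labeling and spatial dispersion statistics.

Two statistics quantify how biofilm biomass clusters: the Hopkins aggregation
index H, a nearest-neighbor empty-space statistic on the 2D point pattern of
colony centroids, and the aggregation coefficient AC, the fraction of total
biovolume held in connected aggregates above a volume threshold (30 μm³ by
default).  AC = 0 for fully dispersed sub-threshold biomass and AC = 1 when a
single large cluster holds everything.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .stack_io import BinaryGrid

__all__ = [
    "AggregateSet",
    "PointPattern2D",
    "label_aggregates",
    "centroid_pattern",
    "hopkins_index",
    "aggregation_coefficient",
]

# 26-connectivity: EPS-bridged colonies touching on a diagonal stay one aggregate.
_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class AggregateSet:
    """Labeled 3D connected components of a foreground mask.

    ``labels`` assigns 1..n to foreground voxels (0 = background).
    ``volumes_um3`` and ``centroids_um`` are per-aggregate, ordered by label;
    centroids are z-projected (x, y) positions at voxel centers.
    """

    labels: np.ndarray
    voxel_counts: np.ndarray
    volumes_um3: np.ndarray
    centroids_um: np.ndarray
    dx: float
    dy: float
    dz: float

    @property
    def n_aggregates(self) -> int:
        return len(self.volumes_um3)

    @property
    def total_volume_um3(self) -> float:
        return float(self.volumes_um3.sum())

    def to_frame(self):
        """Per-aggregate table: label, voxels, volume_um3, centroid_x_um, centroid_y_um."""
        import pandas as pd

        return pd.DataFrame(
            {
                "label": np.arange(1, self.n_aggregates + 1),
                "voxels": self.voxel_counts,
                "volume_um3": self.volumes_um3,
                "centroid_x_um": self.centroids_um[:, 0] if self.n_aggregates else [],
                "centroid_y_um": self.centroids_um[:, 1] if self.n_aggregates else [],
            }
        )


@dataclass(frozen=True)
class PointPattern2D:
    """Planar point pattern in a rectangular observation window [0,W]×[0,L] μm."""

    points: np.ndarray
    window: tuple[float, float]

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=np.float64).reshape(-1, 2)
        w, l = self.window
        if w <= 0 or l <= 0:
            raise ValueError("window dimensions must be positive")
        if pts.size and (
            pts[:, 0].min() < 0 or pts[:, 0].max() > w or pts[:, 1].min() < 0 or pts[:, 1].max() > l
        ):
            raise ValueError("all points must lie inside the window")
        object.__setattr__(self, "points", pts)

    @property
    def n(self) -> int:
        return len(self.points)


def label_aggregates(mask: BinaryGrid) -> AggregateSet:
    """Label 26-connected 3D components and tabulate volumes and centroids."""
    labels, n = ndimage.label(mask.mask, structure=_STRUCT_26)
    if n == 0:
        return AggregateSet(
            labels=labels,
            voxel_counts=np.empty(0, dtype=np.int64),
            volumes_um3=np.empty(0),
            centroids_um=np.empty((0, 2)),
            dx=mask.dx,
            dy=mask.dy,
            dz=mask.dz,
        )
    counts = np.bincount(labels.ravel(), minlength=n + 1)[1:]
    # mean voxel position per label, z-projected; voxel centers at (i + 0.5)·pitch
    coms = ndimage.center_of_mass(mask.mask, labels, index=np.arange(1, n + 1))
    coms = np.asarray(coms)  # (n, 3) in (z, y, x) index space
    centroids = np.column_stack(
        [(coms[:, 2] + 0.5) * mask.dx, (coms[:, 1] + 0.5) * mask.dy]
    )
    return AggregateSet(
        labels=labels,
        voxel_counts=counts.astype(np.int64),
        volumes_um3=counts * mask.voxel_volume,
        centroids_um=centroids,
        dx=mask.dx,
        dy=mask.dy,
        dz=mask.dz,
    )


def centroid_pattern(ags: AggregateSet) -> PointPattern2D:
    """The z-projected aggregate centroids as a point pattern.

    The window is the imaged field; centroids of voxel sets always fall inside.
    """
    nz, ny, nx = ags.labels.shape
    return PointPattern2D(points=ags.centroids_um, window=(nx * ags.dx, ny * ags.dy))


def _hopkins_once(
    pts: np.ndarray,
    tree: cKDTree,
    window: tuple[float, float],
    m: int,
    rng: np.random.Generator,
    variant: str,
) -> float:
    w_dim, l_dim = window
    # empty-space distances: m uniform locations -> nearest pattern point
    locs = rng.uniform([0.0, 0.0], [w_dim, l_dim], size=(m, 2))
    u, _ = tree.query(locs, k=1)
    # inter-point distances: m sampled points -> nearest *other* point
    idx = rng.choice(len(pts), size=m, replace=False)
    d2, _ = tree.query(pts[idx], k=2)
    w = d2[:, 1]
    su2, sw2 = float(np.sum(u**2)), float(np.sum(w**2))
    if variant == "ratio":
        if sw2 == 0:
            return math.inf
        return su2 / sw2
    if variant == "classic":
        return su2 / (su2 + sw2) if (su2 + sw2) > 0 else math.nan
    raise ValueError(f"unknown Hopkins variant {variant!r}")


def hopkins_index(
    pp: PointPattern2D,
    m: int | None = None,
    rng_seed: int = 0,
    *,
    repeats: int = 99,
    variant: str = "ratio",
) -> float:
    """Hopkins aggregation index of a planar point pattern.

    The default ``variant="ratio"`` statistic is H = Σu² / Σw², where the u
    are distances from m uniform random window locations to their nearest
    pattern point and the w are nearest-neighbor distances from m sampled
    pattern points.  Under complete spatial randomness H ≈ 1; clustered
    (patchy) patterns push the empty-space distances u up relative to w, giving
    H > 2 for strong aggregation.  The reported value is the median over
    ``repeats`` Monte-Carlo draws.  ``variant="classic"`` returns the
    [0,1]-valued form Σu² / (Σu² + Σw²), ≈ 0.5 under randomness.

    Parameters
    ----------
    m
        Number of sampling locations/points per repeat; default
        ``min(ceil(n/10), 50)`` with a floor of 5, and at most n/2.
    rng_seed
        Seed for the Monte-Carlo draws (one generator drives all repeats).
    """
    n = pp.n
    if n < 10:
        raise ValueError(f"need at least 10 points for the Hopkins index, got {n}")
    if m is None:
        m = min(max(math.ceil(n / 10), 5), 50)
    if not 1 <= m <= n // 2:
        raise ValueError(f"m must be in [1, n/2] = [1, {n // 2}], got {m}")
    rng = np.random.default_rng(rng_seed)
    pts = pp.points
    tree = cKDTree(pts)
    vals = [_hopkins_once(pts, tree, pp.window, m, rng, variant) for _ in range(repeats)]
    return float(np.median(vals))


def aggregation_coefficient(ags: AggregateSet, v_threshold: float = 30.0) -> float:
    """Fraction of total biovolume in aggregates larger than ``v_threshold`` μm³.

    AC ∈ [0, 1]: 0 for fully dispersed sub-threshold biomass, 1 when every
    voxel belongs to super-threshold clusters.  Insensitive to total biovolume
    in the sense that scaling both populations proportionally preserves it.
    """
    total = ags.total_volume_um3
    if total <= 0:
        raise ValueError("aggregation coefficient undefined for empty foreground")
    above = float(ags.volumes_um3[ags.volumes_um3 > v_threshold].sum())
    return above / total
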