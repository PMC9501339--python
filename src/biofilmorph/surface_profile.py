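"""Surface roughness descriptors for substrata and biofilm top surfaces.

Provides the RMS roughness R_rms (root-mean-square deviation of heights about
the mean plane), the roughness factor R_f (effective/projected area ratio,
≥ 1), and line-profile extraction from a height map — the descriptors used to
compare flat versus grooved substrata.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .morphology3d import HeightMap

__all__ = [
    "RoughnessProfile",
    "rms_roughness",
    "roughness_factor",
    "extract_profile",
    "write_profile_csv",
]

_MIN_PROFILE_SAMPLES = 16


@dataclass(frozen=True)
class RoughnessProfile:
    """1D surface height profile sampled at a uniform lateral pitch (μm)."""

    heights: np.ndarray
    step: float

    def __post_init__(self) -> None:
        h = np.asarray(self.heights, dtype=np.float64).ravel()
        if self.step <= 0:
            raise ValueError("sampling step must be positive")
        if h.size < _MIN_PROFILE_SAMPLES:
            raise ValueError(f"profile needs at least {_MIN_PROFILE_SAMPLES} samples, got {h.size}")
        object.__setattr__(self, "heights", h)

    @property
    def positions(self) -> np.ndarray:
        return np.arange(len(self.heights)) * self.step


def _heights_of(obj) -> np.ndarray:
    if isinstance(obj, RoughnessProfile):
        return obj.heights
    if isinstance(obj, HeightMap):
        return obj.h.ravel()
    return np.asarray(obj, dtype=np.float64).ravel()


def rms_roughness(surface) -> float:
    """R_rms: root-mean-square deviation of heights about their mean (μm).

    Accepts a :class:`HeightMap`, a :class:`RoughnessProfile`, or a raw array.
    No tilt removal is applied — deviations are taken about the mean plane.
    """
    h = _heights_of(surface)
    if h.size == 0:
        raise ValueError("empty height data")
    return float(np.sqrt(np.mean((h - h.mean()) ** 2)))


def roughness_factor(hm: HeightMap) -> float:
    """Roughness factor R_f: effective surface area over projected area (≥ 1).

    The effective area triangulates the height field with two triangles per
    pixel cell, which is exact for piecewise-planar surfaces; the projected
    (nominal) area is the flat cell area.
    """
    h = hm.h
    if h.shape[0] < 2 or h.shape[1] < 2:
        raise ValueError("height map must be at least 2x2 for triangulation")
    dx, dy = hm.dx, hm.dy
    # corner heights of each cell
    h00 = h[:-1, :-1]
    h01 = h[:-1, 1:]
    h10 = h[1:, :-1]
    h11 = h[1:, 1:]
    # triangle (00, 01, 10): area = 0.5·|(dx,0,Δx) × (0,dy,Δy)|
    a1 = 0.5 * np.sqrt((dy * (h00 - h01)) ** 2 + (dx * (h00 - h10)) ** 2 + (dx * dy) ** 2)
    # triangle (11, 01, 10)
    a2 = 0.5 * np.sqrt((dy * (h11 - h10)) ** 2 + (dx * (h11 - h01)) ** 2 + (dx * dy) ** 2)
    effective = float(np.sum(a1 + a2))
    projected = (h.shape[0] - 1) * (h.shape[1] - 1) * dx * dy
    return effective / projected


def extract_profile(
    hm: HeightMap,
    start: tuple[float, float],
    end: tuple[float, float],
) -> RoughnessProfile:
    """Sample heights by bilinear interpolation along a line segment.

    ``start`` and ``end`` are (x, y) positions in μm; sampling pitch is the
    finer of dx, dy.  Endpoints must lie inside the map.
    """
    x0, y0 = start
    x1, y1 = end
    ny, nx = hm.h.shape
    for x, y in ((x0, y0), (x1, y1)):
        if not (0 <= x <= (nx - 1) * hm.dx and 0 <= y <= (ny - 1) * hm.dy):
            raise ValueError(f"endpoint ({x}, {y}) μm outside the height map")
    step = min(hm.dx, hm.dy)
    length = float(np.hypot(x1 - x0, y1 - y0))
    n_samples = int(np.floor(length / step)) + 1
    t = np.linspace(0.0, 1.0, n_samples)
    xs = (x0 + t * (x1 - x0)) / hm.dx
    ys = (y0 + t * (y1 - y0)) / hm.dy
    heights = ndimage.map_coordinates(hm.h, np.vstack([ys, xs]), order=1, mode="nearest")
    return RoughnessProfile(heights=heights, step=step)


def write_profile_csv(profile: RoughnessProfile, path) -> None:
    """Write a profile as a two-column CSV (position_um, height_um)."""
    import pandas as pd

    pd.DataFrame(
        {"position_um": profile.positions, "height_um": profile.heights}
    ).to_csv(path, index=False)
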