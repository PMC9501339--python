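"""Calibrated image-stack I/O and thresholding.

The in-memory containers are :class:`VoxelGrid` (raw reflection-mode
intensities) and :class:`BinaryGrid` (the foreground/biomass mask obtained by
thresholding).  Axis order is fixed as ``(z, y, x)`` with ``z = 0`` at the
substratum plane; TIFF page order maps to increasing ``z``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from skimage.filters import threshold_otsu

__all__ = [
    "VoxelGrid",
    "BinaryGrid",
    "read_stack",
    "write_stack",
    "write_mask",
    "binarize",
    "write_report_json",
    "write_report_csv",
]

#: ITU-R BT.601 luminance weights used when RGB conversion is explicitly requested.
_LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])

_MIN_SLICE_SIDE = 4


def _check_calibration(dx: float, dy: float, dz: float) -> None:
    if not (dx > 0 and dy > 0 and dz > 0):
        raise ValueError(f"voxel calibration must be positive, got dx={dx}, dy={dy}, dz={dz}")


@dataclass(frozen=True)
class VoxelGrid:
    """A calibrated 3D intensity stack indexed ``(z, y, x)``.

    Parameters
    ----------
    data
        Non-negative intensity array of shape ``(n_slices, ny, nx)``.
    dx, dy
        Lateral pixel size in μm.
    dz
        Axial slice spacing in μm.
    """

    data: np.ndarray
    dx: float
    dy: float
    dz: float

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError(f"stack must be 3D (z, y, x), got shape {data.shape}")
        if data.shape[1] < _MIN_SLICE_SIDE or data.shape[2] < _MIN_SLICE_SIDE:
            raise ValueError(f"each slice must be at least 4x4 pixels, got {data.shape[1:]}")
        if np.any(data < 0):
            raise ValueError("intensities must be non-negative")
        _check_calibration(self.dx, self.dy, self.dz)
        object.__setattr__(self, "data", data)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in μm³."""
        return self.dx * self.dy * self.dz


@dataclass(frozen=True)
class BinaryGrid:
    """A calibrated foreground mask; ``z = 0`` is the substratum plane."""

    mask: np.ndarray
    dx: float
    dy: float
    dz: float

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask)
        if mask.ndim != 3:
            raise ValueError(f"mask must be 3D (z, y, x), got shape {mask.shape}")
        if mask.dtype != bool:
            uniq = np.unique(mask)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError("mask must be boolean or {0,1}-valued")
            mask = mask.astype(bool)
        _check_calibration(self.dx, self.dy, self.dz)
        object.__setattr__(self, "mask", mask)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape

    @property
    def voxel_volume(self) -> float:
        return self.dx * self.dy * self.dz


def read_stack(
    path: str | Path,
    dx: float,
    dy: float,
    dz: float,
    *,
    rgb_to_gray: bool = False,
) -> VoxelGrid:
    """Read a single- or multi-page grayscale TIFF as a calibrated stack.

    Page order maps to increasing ``z`` (page 0 = substratum).  RGB input is
    rejected unless ``rgb_to_gray`` is set, in which case BT.601 luminance
    conversion is applied.
    """
    _check_calibration(dx, dy, dz)
    data = tifffile.imread(str(path))
    data = np.asarray(data)
    if data.ndim == 2:
        data = data[np.newaxis, ...]
    if data.ndim == 4 or (data.ndim == 3 and data.shape[-1] in (3, 4) and data.shape[0] > 8):
        # heuristically a color image: last axis is channels
        if not rgb_to_gray:
            raise ValueError(
                "RGB input; pass rgb_to_gray=True to apply luminance conversion"
            )
        rgb = data[..., :3].astype(np.float64)
        data = rgb @ _LUMA_WEIGHTS
        if data.ndim == 2:
            data = data[np.newaxis, ...]
    if data.ndim != 3:
        raise ValueError(f"cannot interpret TIFF of shape {data.shape} as a z-stack")
    return VoxelGrid(data=data, dx=dx, dy=dy, dz=dz)


def write_stack(grid: VoxelGrid, path: str | Path) -> None:
    """Write a stack as a multi-page TIFF, preserving dtype (lossless for integers)."""
    tifffile.imwrite(str(path), np.asarray(grid.data))


def write_mask(mask: BinaryGrid, path: str | Path) -> None:
    """Write a foreground mask as an 8-bit TIFF with values {0, 255}."""
    tifffile.imwrite(str(path), (mask.mask.astype(np.uint8) * 255))


def binarize(
    stack: VoxelGrid,
    method: str = "otsu",
    threshold: float | None = None,
    *,
    per_slice: bool = False,
) -> BinaryGrid:
    """Threshold an intensity stack into a foreground mask.

    Foreground is every voxel with intensity *strictly above* the threshold.
    With ``method="otsu"`` the threshold is computed by Otsu's method, globally
    over the whole stack by default so that metrics stay comparable across z
    (``per_slice=True`` computes one threshold per cross-section instead).
    ``method="fixed"`` uses the given ``threshold``.

    Raises
    ------
    ValueError
        For an unknown method, a missing fixed threshold, or a
        constant-intensity stack under Otsu (no threshold separates it).
    """
    data = np.asarray(stack.data)
    if method == "fixed":
        if threshold is None:
            raise ValueError("method='fixed' requires a threshold")
        mask = data > threshold
    elif method == "otsu":
        if per_slice:
            mask = np.empty(data.shape, dtype=bool)
            for z in range(data.shape[0]):
                sl = data[z]
                if np.all(sl == sl.flat[0]):
                    raise ValueError(f"slice {z} has constant intensity: no threshold separable")
                mask[z] = sl > threshold_otsu(sl)
        else:
            if np.all(data == data.flat[0]):
                raise ValueError("constant-intensity stack: no threshold separable")
            mask = data > threshold_otsu(data)
    else:
        raise ValueError(f"unknown thresholding method {method!r}")
    return BinaryGrid(mask=mask, dx=stack.dx, dy=stack.dy, dz=stack.dz)


def write_report_json(report: dict, path: str | Path) -> None:
    """Write a morphology report dict as JSON."""
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_report_csv(report: dict, path: str | Path) -> None:
    """Write a morphology report as a one-row CSV (columns = metric names)."""
    import pandas as pd

    pd.DataFrame([report]).to_csv(path, index=False)
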