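"""Independent brute-force oracles for cross-checking the package.

Everything here is written as plainly as possible (explicit loops, no shared
code with the implementation) so it can serve as ground truth on small inputs.
"""

from __future__ import annotations

import numpy as np


def naive_biovolume(mask: np.ndarray, dx: float, dy: float, dz: float) -> float:
    n = 0
    for z in range(mask.shape[0]):
        for y in range(mask.shape[1]):
            for x in range(mask.shape[2]):
                if mask[z, y, x]:
                    n += 1
    return n * dx * dy * dz


def naive_slice_coverage(mask: np.ndarray, z: int) -> float:
    n = 0
    for y in range(mask.shape[1]):
        for x in range(mask.shape[2]):
            if mask[z, y, x]:
                n += 1
    return n / (mask.shape[1] * mask.shape[2])


def naive_substratum_coverage(mask: np.ndarray) -> float:
    n = 0
    for y in range(mask.shape[1]):
        for x in range(mask.shape[2]):
            if any(mask[z, y, x] for z in range(mask.shape[0])):
                n += 1
    return n / (mask.shape[1] * mask.shape[2])


def naive_surface_voxels(mask: np.ndarray) -> int:
    """Foreground voxels with a face-adjacent background (or out-of-bounds) voxel."""
    nz, ny, nx = mask.shape
    count = 0
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if not mask[z, y, x]:
                    continue
                for dz_, dy_, dx_ in (
                    (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1),
                ):
                    zz, yy, xx = z + dz_, y + dy_, x + dx_
                    if not (0 <= zz < nz and 0 <= yy < ny and 0 <= xx < nx):
                        count += 1
                        break
                    if not mask[zz, yy, xx]:
                        count += 1
                        break
    return count


def naive_height_map(mask: np.ndarray, dz: float) -> np.ndarray:
    nz, ny, nx = mask.shape
    h = np.zeros((ny, nx))
    for y in range(ny):
        for x in range(nx):
            top = -1
            for z in range(nz):
                if mask[z, y, x]:
                    top = z
            h[y, x] = (top + 1) * dz if top >= 0 else 0.0
    return h


def naive_flood_fill_count(mask: np.ndarray) -> int:
    """Number of 26-connected components by BFS flood fill."""
    nz, ny, nx = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    neighbors = [
        (a, b, c)
        for a in (-1, 0, 1)
        for b in (-1, 0, 1)
        for c in (-1, 0, 1)
        if (a, b, c) != (0, 0, 0)
    ]
    n_components = 0
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if not mask[z, y, x] or seen[z, y, x]:
                    continue
                n_components += 1
                stack = [(z, y, x)]
                seen[z, y, x] = True
                while stack:
                    cz, cy, cx = stack.pop()
                    for a, b, c in neighbors:
                        zz, yy, xx = cz + a, cy + b, cx + c
                        if (
                            0 <= zz < nz and 0 <= yy < ny and 0 <= xx < nx
                            and mask[zz, yy, xx] and not seen[zz, yy, xx]
                        ):
                            seen[zz, yy, xx] = True
                            stack.append((zz, yy, xx))
    return n_components


def naive_box_count_dimension(boundary: np.ndarray) -> float:
    """Box-counting slope over dyadic boxes anchored at (0,0)."""
    sizes = []
    eps = 1
    while eps <= min(boundary.shape) // 4:
        sizes.append(eps)
        eps *= 2
    counts = []
    for eps in sizes:
        occupied = set()
        ys, xs = np.nonzero(boundary)
        for y, x in zip(ys, xs):
            occupied.add((y // eps, x // eps))
        counts.append(len(occupied))
    slope, _ = np.polyfit(-np.log(sizes), np.log(counts), 1)
    return float(slope)


def naive_rms(heights: np.ndarray) -> float:
    h = np.asarray(heights, dtype=float).ravel()
    mean = sum(h) / len(h)
    return float(np.sqrt(sum((v - mean) ** 2 for v in h) / len(h)))


def average_ranks(values: np.ndarray) -> np.ndarray:
    """Ranks 1..n with ties receiving the average of their rank positions."""
    values = np.asarray(values, dtype=float)
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values))
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def naive_spearman(x: np.ndarray, y: np.ndarray) -> float:
    rx = average_ranks(x)
    ry = average_ranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(np.sum(rx * ry) / np.sqrt(np.sum(rx**2) * np.sum(ry**2)))
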