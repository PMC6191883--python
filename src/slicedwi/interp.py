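"""Trilinear sampling with an exact adjoint, and grid/world conventions.

World coordinates are RAS+ millimetres with the origin at the volume centre,
so rotations about the origin are rotations about the volume centre.  Voxel
index ``i`` along an axis with ``n`` voxels of size ``h`` maps to world
coordinate ``(i - (n - 1) / 2) * h``.

The gather (sampling) and scatter operators below use identical trilinear
weights, so ``<gather(vol, X), y> == <vol, scatter(y, X)>`` holds to
round-off — required for conjugate-gradient reconstruction on the normal
equations.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "world_coords",
    "world_to_voxel",
    "slice_world_coords",
    "trilinear_gather",
    "trilinear_scatter",
]


def world_coords(shape, voxel_size) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Meshgrid of world coordinates (mm) for a full volume."""
    axes = [
        (np.arange(n) - (n - 1) / 2.0) * h for n, h in zip(shape, voxel_size)
    ]
    return np.meshgrid(*axes, indexing="ij")


def world_to_voxel(points: np.ndarray, shape, voxel_size) -> np.ndarray:
    """Map world points (3, n) to fractional voxel indices (3, n)."""
    pts = np.asarray(points, dtype=float)
    out = np.empty_like(pts)
    for ax in range(3):
        out[ax] = pts[ax] / voxel_size[ax] + (shape[ax] - 1) / 2.0
    return out


def slice_world_coords(shape, voxel_size, z: int) -> np.ndarray:
    """World coordinates (3, nx*ny) of the pixels of geometric slice z (1-based)."""
    nx, ny = shape[0], shape[1]
    ii, jj = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    x = (ii.ravel() - (nx - 1) / 2.0) * voxel_size[0]
    y = (jj.ravel() - (ny - 1) / 2.0) * voxel_size[1]
    zc = np.full(nx * ny, (z - 1 - (shape[2] - 1) / 2.0) * voxel_size[2])
    return np.stack([x, y, zc])


def _corner_weights(coords: np.ndarray, shape):
    """Shared bookkeeping: integer corners, weights and validity mask."""
    base = np.floor(coords).astype(np.int64)
    frac = coords - base
    corners = []
    for dx in (0, 1):
        wx = frac[0] if dx else 1 - frac[0]
        ix = base[0] + dx
        for dy in (0, 1):
            wy = frac[1] if dy else 1 - frac[1]
            iy = base[1] + dy
            for dz in (0, 1):
                wz = frac[2] if dz else 1 - frac[2]
                iz = base[2] + dz
                w = wx * wy * wz
                valid = (
                    (ix >= 0) & (ix < shape[0])
                    & (iy >= 0) & (iy < shape[1])
                    & (iz >= 0) & (iz < shape[2])
                )
                corners.append((ix, iy, iz, w, valid))
    return corners


def trilinear_gather(volume: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Sample ``volume`` at fractional voxel coordinates (3, n).

    Out-of-volume corners contribute zero (zero-padded boundary).
    """
    out = np.zeros(coords.shape[1], dtype=float)
    for ix, iy, iz, w, valid in _corner_weights(coords, volume.shape):
        if not valid.all():
            ixc = np.clip(ix, 0, volume.shape[0] - 1)
            iyc = np.clip(iy, 0, volume.shape[1] - 1)
            izc = np.clip(iz, 0, volume.shape[2] - 1)
            out += np.where(valid, w * volume[ixc, iyc, izc], 0.0)
        else:
            out += w * volume[ix, iy, iz]
    return out


def trilinear_scatter(values: np.ndarray, coords: np.ndarray, shape) -> np.ndarray:
    """Adjoint of :func:`trilinear_gather`: spread ``values`` onto a grid."""
    out = np.zeros(shape, dtype=float)
    for ix, iy, iz, w, valid in _corner_weights(coords, shape):
        ixc = np.clip(ix, 0, shape[0] - 1)
        iyc = np.clip(iy, 0, shape[1] - 1)
        izc = np.clip(iz, 0, shape[2] - 1)
        np.add.at(out, (ixc, iyc, izc), np.where(valid, w * values, 0.0))
    return out
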