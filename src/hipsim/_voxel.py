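"""Scanline voxelization of closed triangle meshes.

Each (x, y) column of the voxel grid is intersected with every triangle
whose footprint covers it; a crossing at height z toggles the
inside/outside parity of all voxel centers above z.  This is exact for
closed meshes up to grid resolution and needs no spatial index.  The
grid origin is jittered by an irrational sub-voxel offset upstream so
rays through mesh edges/vertices have measure zero.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, fastmath=False)
def _toggle_crossings(tris, ox, oy, oz, dx, dy, dz, nx, ny, nz, toggles):
    for t in range(tris.shape[0]):
        x0 = tris[t, 0, 0]
        y0 = tris[t, 0, 1]
        z0 = tris[t, 0, 2]
        x1 = tris[t, 1, 0]
        y1 = tris[t, 1, 1]
        z1 = tris[t, 1, 2]
        x2 = tris[t, 2, 0]
        y2 = tris[t, 2, 1]
        z2 = tris[t, 2, 2]
        den = (y1 - y2) * (x0 - x2) + (x2 - x1) * (y0 - y2)
        if abs(den) < 1e-12:  # vertical triangle: grazing, no parity change
            continue
        xmin = min(x0, min(x1, x2))
        xmax = max(x0, max(x1, x2))
        ymin = min(y0, min(y1, y2))
        ymax = max(y0, max(y1, y2))
        i0 = int(np.ceil((xmin - ox) / dx - 0.5))
        i1 = int(np.floor((xmax - ox) / dx - 0.5))
        j0 = int(np.ceil((ymin - oy) / dy - 0.5))
        j1 = int(np.floor((ymax - oy) / dy - 0.5))
        if i0 < 0:
            i0 = 0
        if i1 > nx - 1:
            i1 = nx - 1
        if j0 < 0:
            j0 = 0
        if j1 > ny - 1:
            j1 = ny - 1
        for i in range(i0, i1 + 1):
            gx = ox + (i + 0.5) * dx
            for j in range(j0, j1 + 1):
                gy = oy + (j + 0.5) * dy
                la = ((y1 - y2) * (gx - x2) + (x2 - x1) * (gy - y2)) / den
                if la < 0.0:
                    continue
                lb = ((y2 - y0) * (gx - x2) + (x0 - x2) * (gy - y2)) / den
                if lb < 0.0 or la + lb > 1.0:
                    continue
                zc = la * z0 + lb * z1 + (1.0 - la - lb) * z2
                k = int(np.ceil((zc - oz) / dz - 0.5))
                if k < 0:
                    k = 0
                elif k > nz:
                    k = nz
                toggles[i * ny + j, k] += 1


def rasterize_occupancy(tris: np.ndarray, origin, spacing, dims) -> np.ndarray:
    """Boolean occupancy of a closed triangle soup on a regular grid.

    Returns an array of shape ``dims`` (x, y, z order); voxel centers are
    at ``origin + (i + 0.5) * spacing``.
    """
    nx, ny, nz = (int(d) for d in dims)
    toggles = np.zeros((nx * ny, nz + 1), np.int16)
    _toggle_crossings(
        np.ascontiguousarray(tris, dtype=np.float64),
        float(origin[0]), float(origin[1]), float(origin[2]),
        float(spacing[0]), float(spacing[1]), float(spacing[2]),
        nx, ny, nz, toggles,
    )
    occ = (np.cumsum(toggles[:, :nz], axis=1, dtype=np.int32) & 1).astype(bool)
    return occ.reshape(nx, ny, nz)


def block_average(arr: np.ndarray, factor: int) -> np.ndarray:
    """Average ``factor``-sized blocks along every axis (anti-aliasing)."""
    nx, ny, nz = arr.shape
    f = int(factor)
    return (
        arr.reshape(nx // f, f, ny // f, f, nz // f, f)
        .mean(axis=(1, 3, 5))
        .astype(np.float32)
    )
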