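"""Numba kernels for the gamma-index search.

Both kernels minimize the same objective over the same candidate lattice:

    gamma^2(r) = |dr|^2 / dta^2 + (D_e(r + dr) - D_r(r))^2 / dDelta^2

with the evaluated dose trilinearly interpolated at each lattice point and
lattice points outside the voxel-center hull skipped.  The fast kernel visits
offsets in ascending distance and stops as soon as the pure distance term can
no longer beat the current minimum (an exact bound: the dose term is >= 0).
The brute-force kernel visits every offset unconditionally; it exists as the
equivalence oracle for the pruned search.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def _interp(vol, nx, ny, nz, fx, fy, fz):
    if nx == 1:
        x0 = 0
        x1 = 0
        tx = 0.0
    else:
        x0 = int(np.floor(fx))
        if x0 >= nx - 1:
            x0 = nx - 2
        x1 = x0 + 1
        tx = fx - x0
    if ny == 1:
        y0 = 0
        y1 = 0
        ty = 0.0
    else:
        y0 = int(np.floor(fy))
        if y0 >= ny - 1:
            y0 = ny - 2
        y1 = y0 + 1
        ty = fy - y0
    if nz == 1:
        z0 = 0
        z1 = 0
        tz = 0.0
    else:
        z0 = int(np.floor(fz))
        if z0 >= nz - 1:
            z0 = nz - 2
        z1 = z0 + 1
        tz = fz - z0
    c000 = vol[x0, y0, z0]
    c100 = vol[x1, y0, z0]
    c010 = vol[x0, y1, z0]
    c110 = vol[x1, y1, z0]
    c001 = vol[x0, y0, z1]
    c101 = vol[x1, y0, z1]
    c011 = vol[x0, y1, z1]
    c111 = vol[x1, y1, z1]
    c00 = c000 * (1.0 - tx) + c100 * tx
    c10 = c010 * (1.0 - tx) + c110 * tx
    c01 = c001 * (1.0 - tx) + c101 * tx
    c11 = c011 * (1.0 - tx) + c111 * tx
    c0 = c00 * (1.0 - ty) + c10 * ty
    c1 = c01 * (1.0 - ty) + c11 * ty
    return c0 * (1.0 - tz) + c1 * tz


@njit(cache=True)
def gamma_search(ref, ev, idx, off_frac, dist_term, inv_dd):
    """Minimize gamma^2 per scored voxel with exact distance-bound pruning.

    idx: (K, 3) int64 voxel indices of scored reference voxels.
    off_frac: (M, 3) float64 offsets in fractional-index units per axis,
        sorted by ascending distance (offset 0 first).
    dist_term: (M,) float64 |dr|^2 / dta^2 for each offset.
    inv_dd: 1 / (dose tolerance in Gy).
    Returns (K,) float64 gamma values.
    """
    nx, ny, nz = ev.shape
    K = idx.shape[0]
    M = off_frac.shape[0]
    out = np.empty(K, dtype=np.float64)
    for p in range(K):
        ix = idx[p, 0]
        iy = idx[p, 1]
        iz = idx[p, 2]
        dr = ref[ix, iy, iz]
        best = np.inf
        for t in range(M):
            dterm = dist_term[t]
            if dterm >= best:
                break  # offsets are distance-sorted; dose term >= 0
            fx = ix + off_frac[t, 0]
            fy = iy + off_frac[t, 1]
            fz = iz + off_frac[t, 2]
            if fx < 0.0 or fx > nx - 1 or fy < 0.0 or fy > ny - 1 or fz < 0.0 or fz > nz - 1:
                continue
            de = _interp(ev, nx, ny, nz, fx, fy, fz)
            diff = (de - dr) * inv_dd
            g2 = dterm + diff * diff
            if g2 < best:
                best = g2
        out[p] = np.sqrt(best)
    return out


@njit(cache=True, fastmath=True)
def gamma_search_exhaustive(ref, ev, idx, off_frac, dist_term, inv_dd):
    """Exhaustive gamma^2 minimization over the identical lattice (no pruning).

    Written independently of :func:`gamma_search` — the 8-corner trilinear
    interpolation is accumulated as an explicit weight sum — so it can act as
    an equivalence oracle for the pruned search.
    """
    nx, ny, nz = ev.shape
    K = idx.shape[0]
    M = off_frac.shape[0]
    out = np.empty(K, dtype=np.float64)
    for p in range(K):
        ix = idx[p, 0]
        iy = idx[p, 1]
        iz = idx[p, 2]
        dr = ref[ix, iy, iz]
        best = 1e300  # finite sentinel: fastmath assumes no infinities
        for t in range(M):
            fx = ix + off_frac[t, 0]
            fy = iy + off_frac[t, 1]
            fz = iz + off_frac[t, 2]
            if fx < 0.0 or fx > nx - 1 or fy < 0.0 or fy > ny - 1 or fz < 0.0 or fz > nz - 1:
                continue
            if nx == 1:
                x0 = 0
                x1 = 0
                tx = 0.0
            else:
                x0 = min(int(np.floor(fx)), nx - 2)
                x1 = x0 + 1
                tx = fx - x0
            if ny == 1:
                y0 = 0
                y1 = 0
                ty = 0.0
            else:
                y0 = min(int(np.floor(fy)), ny - 2)
                y1 = y0 + 1
                ty = fy - y0
            if nz == 1:
                z0 = 0
                z1 = 0
                tz = 0.0
            else:
                z0 = min(int(np.floor(fz)), nz - 2)
                z1 = z0 + 1
                tz = fz - z0
            # explicit 8-corner weight sum (degenerate axes fold onto x1 == x0
            # with weight tx == 0, so every term stays in bounds)
            de = (
                (1.0 - tx) * (1.0 - ty) * (1.0 - tz) * ev[x0, y0, z0]
                + tx * (1.0 - ty) * (1.0 - tz) * ev[x1, y0, z0]
                + (1.0 - tx) * ty * (1.0 - tz) * ev[x0, y1, z0]
                + tx * ty * (1.0 - tz) * ev[x1, y1, z0]
                + (1.0 - tx) * (1.0 - ty) * tz * ev[x0, y0, z1]
                + tx * (1.0 - ty) * tz * ev[x1, y0, z1]
                + (1.0 - tx) * ty * tz * ev[x0, y1, z1]
                + tx * ty * tz * ev[x1, y1, z1]
            )
            diff = (de - dr) * inv_dd
            g2 = dist_term[t] + diff * diff
            if g2 < best:
                best = g2
        out[p] = np.sqrt(best)
    return out
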