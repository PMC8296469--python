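"""Structure masks: contour rasterization, boolean algebra, volumes, shells.

Rasterization uses voxel-center inclusion under the even-odd rule, with points
exactly on a polygon edge counting as inside.  Multiple polygons that map to
the same grid slice are combined by XOR, so inner contours act as holes (the
usual RT Structure Set convention).  Volumes are reported from the voxelized
mask so that the same voxel set scored by the gamma evaluation defines V_air
and V_bone in the cohort regressions.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage

from .errors import EmptyROIError, GeometryError
from .grid_io import ContourPolygon, GridHeader, VoxelMask

logger = logging.getLogger(__name__)

__all__ = [
    "rasterize_contours",
    "volume_cc",
    "combine_masks",
    "interface_shell",
    "points_in_polygon",
]

_EDGE_EPS = 1e-9


def points_in_polygon(px: np.ndarray, py: np.ndarray, vertices: np.ndarray) -> np.ndarray:
    """Even-odd point-in-polygon test for arrays of points.

    Points within ``1e-9`` mm of an edge are classified inside regardless of
    crossing parity.
    """
    px = np.asarray(px, dtype=np.float64)
    py = np.asarray(py, dtype=np.float64)
    inside = np.zeros(px.shape, dtype=bool)
    on_edge = np.zeros(px.shape, dtype=bool)
    v = np.asarray(vertices, dtype=np.float64)
    n = v.shape[0]
    for i in range(n):
        x1, y1 = v[i]
        x2, y2 = v[(i + 1) % n]
        # edge membership: collinear within eps and inside the segment bbox
        dx, dy = x2 - x1, y2 - y1
        seg_len = np.hypot(dx, dy)
        if seg_len > 0:
            dist = np.abs(dy * (px - x1) - dx * (py - y1)) / seg_len
            t = ((px - x1) * dx + (py - y1) * dy) / (seg_len * seg_len)
            on_edge |= (dist <= _EDGE_EPS) & (t >= -_EDGE_EPS) & (t <= 1 + _EDGE_EPS)
        else:
            on_edge |= (np.abs(px - x1) <= _EDGE_EPS) & (np.abs(py - y1) <= _EDGE_EPS)
        # ray casting toward +x
        crosses = (y1 > py) != (y2 > py)
        if np.any(crosses):
            with np.errstate(divide="ignore", invalid="ignore"):
                x_int = (x2 - x1) * (py - y1) / (y2 - y1) + x1
            inside ^= crosses & (px < x_int)
    return inside | on_edge


def rasterize_contours(polygons: list[ContourPolygon], header: GridHeader) -> VoxelMask:
    """Voxelize a structure onto a grid.

    A voxel is set iff its center lies inside the polygon assigned to the
    nearest contour plane (|z_center - z_plane| <= sz/2).  Polygons whose plane
    falls outside the grid extent are ignored with a warning; a structure with
    zero polygons yields an empty mask plus a warning.
    """
    nx, ny, nz = header.dims
    flags = np.zeros((nx, ny, nz), dtype=bool)
    if not polygons:
        logger.warning("rasterize_contours: structure has no polygons; returning empty mask")
        return VoxelMask(header, flags)
    oz, sz = header.origin[2], header.spacing[2]
    xs = header.axis_centers(0)
    ys = header.axis_centers(1)
    px, py = np.meshgrid(xs, ys, indexing="ij")
    for poly in polygons:
        k = int(round((poly.z - oz) / sz))
        if k < 0 or k >= nz or abs(poly.z - (oz + k * sz)) > sz / 2 + _EDGE_EPS:
            logger.warning("rasterize_contours: polygon at z=%.3f mm outside grid extent; ignored", poly.z)
            continue
        flags[:, :, k] ^= points_in_polygon(px, py, poly.vertices)
    return VoxelMask(header, flags)


def volume_cc(mask: VoxelMask) -> float:
    """Volume of the set voxels in cc (count x voxel volume)."""
    return mask.count * mask.header.voxel_volume_cc


def combine_masks(a: VoxelMask, b: VoxelMask, op: str) -> VoxelMask:
    """Element-wise union / intersect / subtract of two aligned masks."""
    if a.header != b.header:
        raise GeometryError("combine_masks: mask headers differ")
    if op == "union":
        flags = a.flags | b.flags
    elif op == "intersect":
        flags = a.flags & b.flags
    elif op == "subtract":
        flags = a.flags & ~b.flags
    else:
        raise ValueError(f"unknown op {op!r}; expected union/intersect/subtract")
    return VoxelMask(a.header, flags)


def interface_shell(mask: VoxelMask, thickness_mm: float) -> VoxelMask:
    """Outer layer of a mask: voxels removed by k rounds of 6-connected erosion.

    k = round(thickness_mm / min(spacing)).  k == 0 yields an empty shell with
    a warning.  The shell is always a subset of the input mask.
    """
    if thickness_mm <= 0:
        raise ValueError("thickness_mm must be > 0")
    k = int(round(thickness_mm / min(mask.header.spacing)))
    if k == 0:
        logger.warning("interface_shell: thickness %.3g mm rounds to 0 voxels; empty shell", thickness_mm)
        return VoxelMask(mask.header, np.zeros(mask.header.dims, dtype=bool))
    structure = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    eroded = ndimage.binary_erosion(mask.flags, structure=structure, iterations=k)
    return VoxelMask(mask.header, mask.flags & ~eroded)


def require_nonempty(mask: VoxelMask, what: str = "mask") -> None:
    if mask.count == 0:
        raise EmptyROIError(f"{what} contains no voxels")
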