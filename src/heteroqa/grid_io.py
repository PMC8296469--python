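"""Dose-grid containers and I/O.

The in-memory containers are deliberately small: a :class:`GridHeader` pins the
geometry (voxel centers at ``origin + index * spacing``, patient-space mm,
0-based indices), a :class:`DoseGrid` holds absorbed dose in Gy, and a
:class:`VoxelMask` holds a boolean ROI on the same geometry.  Arrays are stored
with shape ``(nx, ny, nz)``; the serialized payload order is x-fastest, which
matches the DICOM RT Dose pixel layout after the axis transpose done on read.

Two on-disk representations are supported:

* **DGRID v1** — a plain-text exchange format used for every pipeline
  artifact.  Line 1 ``DGRID 1``; line 2 ``dims nx ny nz``; line 3
  ``origin ox oy oz``; line 4 ``spacing sx sy sz``; line 5 ``unit Gy`` or
  ``unit mask``; then whitespace-separated payload, x-fastest.  Doses are
  written with 17 significant digits so a write/read round trip is bit-exact.
* **DICOM** — RT Dose (read only) and RT Structure Set (read only).  Only
  axis-aligned identity orientation with uniform frame offsets is accepted;
  anything else raises rather than silently resampling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import (
    GridDomainError,
    GridFormatError,
    GridSizeError,
    UnitError,
    UnsupportedGeometryError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "GridHeader",
    "DoseGrid",
    "VoxelMask",
    "ContourPolygon",
    "ContourSet",
    "read_dgrid",
    "write_dgrid",
    "read_dicom_rtdose",
    "read_dicom_rtstruct",
]


@dataclass(frozen=True)
class GridHeader:
    """Geometry of an axis-aligned uniform voxel grid.

    ``origin`` is the patient-space position (mm) of the *center* of voxel
    (0, 0, 0); ``spacing`` is the center-to-center distance (mm) per axis.
    """

    dims: tuple[int, int, int]
    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.dims) != 3 or len(self.origin) != 3 or len(self.spacing) != 3:
            raise GridFormatError("header fields must be length-3 triples")
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))
        object.__setattr__(self, "spacing", tuple(float(v) for v in self.spacing))
        if any(d < 1 for d in self.dims):
            raise GridDomainError(f"all dims must be >= 1, got {self.dims}")
        if any(not np.isfinite(v) for v in self.origin):
            raise GridDomainError("origin must be finite")
        if any((not np.isfinite(s)) or s <= 0 for s in self.spacing):
            raise GridDomainError(f"all spacing must be > 0, got {self.spacing}")

    @property
    def n_voxels(self) -> int:
        nx, ny, nz = self.dims
        return nx * ny * nz

    @property
    def voxel_volume_cc(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz / 1000.0

    def axis_centers(self, axis: int) -> np.ndarray:
        """Voxel-center coordinates (mm) along one axis."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.dims[axis])


def _as_volume(values: np.ndarray, header: GridHeader, dtype) -> np.ndarray:
    arr = np.asarray(values, dtype=dtype)
    if arr.size != header.n_voxels:
        raise GridSizeError(
            f"value count {arr.size} != nx*ny*nz = {header.n_voxels} for dims {header.dims}"
        )
    if arr.ndim == 1:
        arr = arr.reshape(header.dims, order="F")  # x-fastest flat order
    elif arr.shape != header.dims:
        raise GridSizeError(f"array shape {arr.shape} != dims {header.dims}")
    return arr


@dataclass
class DoseGrid:
    """Absorbed dose (Gy) on a :class:`GridHeader` geometry."""

    header: GridHeader
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = _as_volume(self.values, self.header, np.float64)
        if not np.all(np.isfinite(self.values)):
            raise GridDomainError("dose values must all be finite")
        if np.any(self.values < 0):
            raise GridDomainError("dose values must be >= 0 Gy")

    def flat(self) -> np.ndarray:
        """Values in serialized (x-fastest) order."""
        return self.values.ravel(order="F")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DoseGrid):
            return NotImplemented
        return self.header == other.header and np.array_equal(self.values, other.values)


@dataclass
class VoxelMask:
    """Boolean ROI aligned to a dose grid."""

    header: GridHeader
    flags: np.ndarray

    def __post_init__(self) -> None:
        raw = np.asarray(self.flags)
        if raw.dtype != np.bool_:
            vals = np.asarray(raw, dtype=np.float64)
            if not np.all(np.isin(vals, (0.0, 1.0))):
                raise GridDomainError("mask values must be 0 or 1")
            raw = vals.astype(bool)
        self.flags = _as_volume(raw, self.header, np.bool_)

    def flat(self) -> np.ndarray:
        return self.flags.ravel(order="F")

    @property
    def count(self) -> int:
        return int(self.flags.sum())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, VoxelMask):
            return NotImplemented
        return self.header == other.header and np.array_equal(self.flags, other.flags)


@dataclass(frozen=True)
class ContourPolygon:
    """One closed planar polygon: a z plane (mm) plus ordered (x, y) vertices."""

    z: float
    vertices: np.ndarray  # shape (n, 2), n >= 3

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=np.float64)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise GridDomainError("polygon needs >= 3 (x, y) vertices")
        if not (np.isfinite(v).all() and np.isfinite(self.z)):
            raise GridDomainError("polygon coordinates must be finite")
        object.__setattr__(self, "vertices", v)


@dataclass
class ContourSet:
    """Named structures, each a list of closed planar polygons."""

    structures: dict[str, list[ContourPolygon]] = field(default_factory=dict)

    def add(self, name: str, polygons: Sequence[ContourPolygon]) -> None:
        if name in self.structures:
            raise GridDomainError(f"duplicate structure name {name!r}")
        self.structures[name] = list(polygons)

    def __getitem__(self, name: str) -> list[ContourPolygon]:
        return self.structures[name]

    def names(self) -> list[str]:
        return list(self.structures)


# ---------------------------------------------------------------------------
# DGRID v1
# ---------------------------------------------------------------------------

def _parse_header_line(line: str, key: str, n: int, lineno: int, cast):
    parts = line.split()
    if not parts or parts[0] != key or len(parts) != n + 1:
        raise GridFormatError(f"line {lineno}: expected '{key}' with {n} values, got {line!r}")
    try:
        return tuple(cast(p) for p in parts[1:])
    except ValueError as exc:
        raise GridFormatError(f"line {lineno}: non-numeric value in {line!r}") from exc


def read_dgrid(path) -> DoseGrid | VoxelMask:
    """Read a DGRID v1 file; the unit line selects DoseGrid (Gy) vs VoxelMask."""
    with open(path, "r") as fh:
        magic = fh.readline().strip()
        if magic != "DGRID 1":
            raise GridFormatError(f"line 1: expected 'DGRID 1', got {magic!r}")
        dims = _parse_header_line(fh.readline().rstrip("\n"), "dims", 3, 2, int)
        origin = _parse_header_line(fh.readline().rstrip("\n"), "origin", 3, 3, float)
        spacing = _parse_header_line(fh.readline().rstrip("\n"), "spacing", 3, 4, float)
        unit_line = fh.readline().split()
        if len(unit_line) != 2 or unit_line[0] != "unit" or unit_line[1] not in ("Gy", "mask"):
            raise GridFormatError(f"line 5: expected 'unit Gy' or 'unit mask', got {' '.join(unit_line)!r}")
        unit = unit_line[1]
        payload = fh.read().split()
    header = GridHeader(dims, origin, spacing)
    if len(payload) != header.n_voxels:
        raise GridSizeError(
            f"payload has {len(payload)} values, expected {header.n_voxels} for dims {header.dims}"
        )
    try:
        values = np.array(payload, dtype=np.float64)
    except ValueError as exc:
        raise GridFormatError("non-numeric payload value") from exc
    if unit == "Gy":
        return DoseGrid(header, values)
    return VoxelMask(header, values)


def _write_dgrid_raw(header: GridHeader, unit: str, payload: np.ndarray, fmt: str, path) -> None:
    with open(path, "w") as fh:
        fh.write("DGRID 1\n")
        fh.write("dims %d %d %d\n" % header.dims)
        fh.write("origin %.17g %.17g %.17g\n" % header.origin)
        fh.write("spacing %.17g %.17g %.17g\n" % header.spacing)
        fh.write(f"unit {unit}\n")
        # 8 values per line keeps lines short without affecting the format
        for start in range(0, payload.size, 8):
            fh.write(" ".join(fmt % v for v in payload[start : start + 8]))
            fh.write("\n")


def write_dgrid(grid: DoseGrid | VoxelMask, path) -> None:
    """Write a grid as DGRID v1 text (17 significant digits for doses)."""
    if isinstance(grid, DoseGrid):
        unit, payload, fmt = "Gy", grid.flat(), "%.17g"
    elif isinstance(grid, VoxelMask):
        unit, payload, fmt = "mask", grid.flat().astype(np.int8), "%d"
    else:
        raise TypeError(f"cannot serialize {type(grid).__name__}")
    _write_dgrid_raw(grid.header, unit, payload, fmt, path)


# ---------------------------------------------------------------------------
# DICOM
# ---------------------------------------------------------------------------

def read_dicom_rtdose(path) -> DoseGrid:
    """Read a DICOM RT Dose object into a :class:`DoseGrid`.

    Dose = stored pixel value x DoseGridScaling.  Only identity orientation
    (rows along +y, columns along +x) with uniform grid-frame offsets is
    supported; dose units must be Gy.
    """
    import pydicom

    ds = pydicom.dcmread(path)
    if getattr(ds, "Modality", None) != "RTDOSE":
        raise GridFormatError(f"not an RT Dose object (Modality={getattr(ds, 'Modality', None)!r})")
    units = str(getattr(ds, "DoseUnits", "")).upper()
    if units != "GY":
        raise UnitError(f"dose units must be Gy, got {units!r}")
    orient = [float(v) for v in ds.ImageOrientationPatient]
    if not np.allclose(orient, [1, 0, 0, 0, 1, 0], atol=1e-6):
        raise UnsupportedGeometryError(f"orientation {orient} is not axis-aligned identity")
    offsets = np.asarray([float(v) for v in ds.GridFrameOffsetVector], dtype=np.float64)
    if offsets.size < 1:
        raise UnsupportedGeometryError("empty GridFrameOffsetVector")
    if offsets.size > 1:
        steps = np.diff(offsets)
        if steps[0] <= 0 or not np.allclose(steps, steps[0], atol=1e-6):
            raise UnsupportedGeometryError("non-uniform grid frame offsets")
        sz = float(steps[0])
    else:
        sz = float(getattr(ds, "SliceThickness", 0) or 1.0)
    row_sp, col_sp = (float(v) for v in ds.PixelSpacing)  # (between rows = y, between cols = x)
    ipp = [float(v) for v in ds.ImagePositionPatient]
    pixels = ds.pixel_array  # (frames, rows, cols) == (z, y, x)
    if pixels.ndim == 2:
        pixels = pixels[np.newaxis]
    scaling = float(getattr(ds, "DoseGridScaling", 1.0))
    dose = pixels.astype(np.float64).transpose(2, 1, 0) * scaling  # -> (x, y, z)
    header = GridHeader(
        dims=dose.shape,
        origin=(ipp[0], ipp[1], ipp[2] + float(offsets[0])),
        spacing=(col_sp, row_sp, sz),
    )
    return DoseGrid(header, dose)


def read_dicom_rtstruct(path) -> ContourSet:
    """Read closed planar contours from a DICOM RT Structure Set.

    Contours with fewer than 3 points are dropped with a logged warning.
    """
    import pydicom

    ds = pydicom.dcmread(path)
    if "StructureSetROISequence" not in ds or "ROIContourSequence" not in ds:
        raise GridFormatError("missing StructureSetROISequence/ROIContourSequence")
    names = {int(roi.ROINumber): str(roi.ROIName) for roi in ds.StructureSetROISequence}
    out = ContourSet()
    for rc in ds.ROIContourSequence:
        name = names.get(int(rc.ReferencedROINumber), f"ROI{rc.ReferencedROINumber}")
        polygons: list[ContourPolygon] = []
        for item in getattr(rc, "ContourSequence", []) or []:
            data = np.asarray([float(v) for v in item.ContourData], dtype=np.float64)
            if data.size % 3:
                raise GridFormatError(f"structure {name!r}: contour data not (x,y,z) triplets")
            pts = data.reshape(-1, 3)
            if pts.shape[0] < 3:
                logger.warning("structure %r: dropping degenerate %d-point contour", name, pts.shape[0])
                continue
            polygons.append(ContourPolygon(z=float(pts[0, 2]), vertices=pts[:, :2]))
        out.add(name, polygons)
    return out
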