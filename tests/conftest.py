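"""Shared fixtures and fixture builders.

DICOM fixtures are built programmatically with pydicom at test time (the
package itself never writes DICOM).
"""

from __future__ import annotations

import numpy as np
import pytest

from heteroqa.grid_io import DoseGrid, GridHeader


def make_header(dims=(8, 8, 8), origin=(0.0, 0.0, 0.0), spacing=(2.5, 2.5, 2.5)) -> GridHeader:
    return GridHeader(dims, origin, spacing)


def smooth_dose(header: GridHeader, rng: np.random.Generator, dmax: float = 70.0) -> DoseGrid:
    """Random smooth positive dose field normalized to a given maximum."""
    from scipy import ndimage

    field = ndimage.gaussian_filter(rng.random(header.dims), sigma=1.5)
    field -= field.min()
    if field.max() > 0:
        field /= field.max()
    return DoseGrid(header, field * dmax)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


# ---------------------------------------------------------------------------
# DICOM fixture builders
# ---------------------------------------------------------------------------

def write_rtdose_fixture(
    path,
    dose_xyz: np.ndarray,
    origin=(0.0, 0.0, 0.0),
    spacing=(2.5, 2.5, 2.5),
    scaling: float = 1e-6,
    orientation=(1, 0, 0, 0, 1, 0),
    dose_units: str = "GY",
    frame_offsets=None,
) -> None:
    """Write a minimal conformant RT Dose file from an (x, y, z) dose array."""
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.UID("1.2.840.10008.5.1.4.1.1.481.2")
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTDOSE"
    ds.DoseUnits = dose_units
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "PLAN"
    ds.DoseGridScaling = scaling
    ds.ImageOrientationPatient = list(orientation)
    ds.ImagePositionPatient = list(origin)
    ds.PixelSpacing = [spacing[1], spacing[0]]  # [row (y), col (x)]
    nx, ny, nz = dose_xyz.shape
    if frame_offsets is None:
        frame_offsets = [i * spacing[2] for i in range(nz)]
    ds.GridFrameOffsetVector = list(frame_offsets)
    ds.Rows = ny
    ds.Columns = nx
    ds.NumberOfFrames = nz
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 32
    ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0
    pixels = np.round(dose_xyz / scaling).astype(np.uint32)
    ds.PixelData = pixels.transpose(2, 1, 0).tobytes()  # (z, y, x) frame order
    ds.save_as(str(path), enforce_file_format=True)


def write_rtstruct_fixture(path, structures: dict[str, list[tuple[float, np.ndarray]]]) -> None:
    """Write a minimal RT Structure Set: {name: [(z, (n,2) xy-vertices), ...]}."""
    import pydicom
    from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
    from pydicom.sequence import Sequence
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.UID("1.2.840.10008.5.1.4.1.1.481.3")
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTSTRUCT"
    roi_seq, contour_seq = Sequence(), Sequence()
    for num, (name, polys) in enumerate(structures.items(), start=1):
        roi = Dataset()
        roi.ROINumber = num
        roi.ROIName = name
        roi.ReferencedFrameOfReferenceUID = generate_uid()
        roi_seq.append(roi)
        rc = Dataset()
        rc.ReferencedROINumber = num
        items = Sequence()
        for z, verts in polys:
            item = Dataset()
            item.ContourGeometricType = "CLOSED_PLANAR"
            verts = np.asarray(verts, dtype=float)
            item.NumberOfContourPoints = verts.shape[0]
            data = []
            for x, y in verts:
                data.extend([float(x), float(y), float(z)])
            item.ContourData = data
            items.append(item)
        rc.ContourSequence = items
        contour_seq.append(rc)
    ds.StructureSetROISequence = roi_seq
    ds.ROIContourSequence = contour_seq
    ds.save_as(str(path), enforce_file_format=True)
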