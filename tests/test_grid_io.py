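"""DGRID and DICOM I/O behavior."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from heteroqa.errors import (
    GridDomainError,
    GridFormatError,
    GridSizeError,
    UnitError,
    UnsupportedGeometryError,
)
from heteroqa.grid_io import (
    DoseGrid,
    GridHeader,
    VoxelMask,
    read_dgrid,
    read_dicom_rtdose,
    read_dicom_rtstruct,
    write_dgrid,
)

from .conftest import make_header, write_rtdose_fixture, write_rtstruct_fixture


def _write_text(path, text):
    path.write_text(text)
    return path


class TestDgridFormat:
    def test_small_grid_parses_with_x_fastest_order(self, tmp_path):
        p = _write_text(
            tmp_path / "g.dgrid",
            "DGRID 1\ndims 2 2 1\norigin 0 0 0\nspacing 2.5 2.5 2.5\nunit Gy\n1 2 3 4\n",
        )
        grid = read_dgrid(p)
        assert isinstance(grid, DoseGrid)
        assert grid.header == GridHeader((2, 2, 1), (0, 0, 0), (2.5, 2.5, 2.5))
        assert grid.values[1, 1, 0] == 4.0
        assert grid.values[1, 0, 0] == 2.0  # x varies fastest

    def test_payload_size_mismatch_is_size_error(self, tmp_path):
        p = _write_text(
            tmp_path / "g.dgrid",
            "DGRID 1\ndims 2 2 1\norigin 0 0 0\nspacing 2.5 2.5 2.5\nunit Gy\n1 2 3\n",
        )
        with pytest.raises(GridSizeError):
            read_dgrid(p)

    @pytest.mark.parametrize(
        "line2, err",
        [
            ("dims 2 2", GridFormatError),
            ("dimensions 2 2 1", GridFormatError),
            ("dims a b c", GridFormatError),
        ],
    )
    def test_malformed_header_names_offending_line(self, tmp_path, line2, err):
        p = _write_text(
            tmp_path / "g.dgrid",
            f"DGRID 1\n{line2}\norigin 0 0 0\nspacing 1 1 1\nunit Gy\n1\n",
        )
        with pytest.raises(err, match="line 2"):
            read_dgrid(p)

    def test_bad_magic_and_bad_unit_rejected(self, tmp_path):
        with pytest.raises(GridFormatError, match="line 1"):
            read_dgrid(_write_text(tmp_path / "a", "DGRID 2\n"))
        p = _write_text(
            tmp_path / "b",
            "DGRID 1\ndims 1 1 1\norigin 0 0 0\nspacing 1 1 1\nunit rad\n1\n",
        )
        with pytest.raises(GridFormatError, match="line 5"):
            read_dgrid(p)

    def test_negative_dose_and_nonbinary_mask_are_domain_errors(self, tmp_path):
        p = _write_text(
            tmp_path / "a",
            "DGRID 1\ndims 1 1 1\norigin 0 0 0\nspacing 1 1 1\nunit Gy\n-0.5\n",
        )
        with pytest.raises(GridDomainError):
            read_dgrid(p)
        p = _write_text(
            tmp_path / "b",
            "DGRID 1\ndims 1 1 1\norigin 0 0 0\nspacing 1 1 1\nunit mask\n0.5\n",
        )
        with pytest.raises(GridDomainError):
            read_dgrid(p)

    def test_single_voxel_roundtrip_and_mask_payload(self, tmp_path):
        grid = DoseGrid(make_header((1, 1, 1)), np.array([70.4]))
        path = tmp_path / "one.dgrid"
        write_dgrid(grid, path)
        assert "70.4" in path.read_text()
        assert read_dgrid(path) == grid

        mask = VoxelMask(make_header((2, 1, 1)), np.array([1.0, 0.0]))
        mpath = tmp_path / "m.dgrid"
        write_dgrid(mask, mpath)
        text = mpath.read_text()
        assert "unit mask" in text and set(text.split("\n")[5].split()) <= {"0", "1"}
        assert read_dgrid(mpath) == mask

    def test_invalid_grid_rejected_before_writing(self, tmp_path):
        with pytest.raises(GridDomainError):
            DoseGrid(make_header((1, 1, 1)), np.array([-1.0]))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        dims=st.tuples(*[st.integers(1, 5)] * 3),
        seed=st.integers(0, 2**31 - 1),
    )
    def test_roundtrip_is_bit_exact_for_random_grids(self, tmp_path_factory, dims, seed):
        rng = np.random.default_rng(seed)
        header = GridHeader(dims, tuple(rng.normal(size=3)), tuple(rng.uniform(0.5, 4, 3)))
        grid = DoseGrid(header, rng.uniform(0, 80, size=dims))
        path = tmp_path_factory.mktemp("rt") / "g.dgrid"
        write_dgrid(grid, path)
        back = read_dgrid(path)
        assert back.header == grid.header
        assert np.array_equal(back.values, grid.values)

    def test_reading_does_not_mutate_the_file(self, tmp_path):
        grid = DoseGrid(make_header((2, 2, 2)), np.arange(8, dtype=float))
        path = tmp_path / "g.dgrid"
        write_dgrid(grid, path)
        before = path.read_bytes()
        read_dgrid(path)
        assert path.read_bytes() == before


class TestDicomRtdose:
    def test_scaling_applied_to_stored_pixels(self, tmp_path):
        dose = np.zeros((2, 2, 2))
        dose[0, 0, 0] = 35.0
        path = tmp_path / "rd.dcm"
        write_rtdose_fixture(path, dose, scaling=0.01)
        grid = read_dicom_rtdose(path)
        assert grid.values[0, 0, 0] == pytest.approx(35.0, abs=1e-9)
        assert grid.header.spacing == (2.5, 2.5, 2.5)

    def test_rotated_orientation_rejected(self, tmp_path):
        path = tmp_path / "rot.dcm"
        write_rtdose_fixture(path, np.ones((2, 2, 2)), orientation=(0, 1, 0, -1, 0, 0))
        with pytest.raises(UnsupportedGeometryError):
            read_dicom_rtdose(path)

    def test_non_gray_units_rejected(self, tmp_path):
        path = tmp_path / "cgy.dcm"
        write_rtdose_fixture(path, np.ones((2, 2, 2)), dose_units="CGY")
        with pytest.raises(UnitError):
            read_dicom_rtdose(path)

    def test_non_uniform_frame_offsets_rejected(self, tmp_path):
        path = tmp_path / "nu.dcm"
        write_rtdose_fixture(path, np.ones((2, 2, 3)), frame_offsets=[0.0, 2.5, 6.0])
        with pytest.raises(UnsupportedGeometryError):
            read_dicom_rtdose(path)

    def test_roundtrip_matches_dgrid_reader(self, tmp_path, rng):
        dose = rng.uniform(0, 80, size=(4, 3, 2))
        origin = (-10.0, 5.0, 2.0)
        dcm = tmp_path / "rd.dcm"
        write_rtdose_fixture(dcm, dose, origin=origin)
        via_dicom = read_dicom_rtdose(dcm)
        assert np.abs(via_dicom.values - dose).max() < 1e-6

        grid = DoseGrid(GridHeader((4, 3, 2), origin, (2.5, 2.5, 2.5)), via_dicom.values)
        dg = tmp_path / "rd.dgrid"
        write_dgrid(grid, dg)
        assert read_dgrid(dg) == via_dicom


class TestDicomRtstruct:
    SQUARE = np.array([[0, 0], [10, 0], [10, 10], [0, 10]], dtype=float)

    def test_square_roi_on_two_slices(self, tmp_path):
        path = tmp_path / "rs.dcm"
        write_rtstruct_fixture(path, {"PGTVnx": [(0.0, self.SQUARE), (2.5, self.SQUARE)]})
        cs = read_dicom_rtstruct(path)
        assert cs.names() == ["PGTVnx"]
        assert len(cs["PGTVnx"]) == 2
        assert cs["PGTVnx"][1].z == 2.5

    def test_degenerate_contour_dropped_with_warning(self, tmp_path, caplog):
        path = tmp_path / "rs.dcm"
        write_rtstruct_fixture(
            path,
            {"ROI": [(0.0, self.SQUARE), (2.5, np.array([[0.0, 0.0], [1.0, 1.0]]))]},
        )
        with caplog.at_level("WARNING"):
            cs = read_dicom_rtstruct(path)
        assert len(cs["ROI"]) == 1
        assert any("degenerate" in r.message for r in caplog.records)

    def test_vertex_coordinates_roundtrip(self, tmp_path, rng):
        verts = rng.uniform(-50, 50, size=(7, 2)).round(4)
        path = tmp_path / "rs.dcm"
        write_rtstruct_fixture(path, {"R": [(1.25, verts)]})
        cs = read_dicom_rtstruct(path)
        assert np.abs(cs["R"][0].vertices - verts).max() < 1e-6

    def test_missing_sequences_are_format_error(self, tmp_path):
        import pydicom
        from pydicom.dataset import FileDataset, FileMetaDataset
        from pydicom.uid import ExplicitVRLittleEndian, generate_uid

        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = pydicom.uid.UID("1.2.840.10008.5.1.4.1.1.481.3")
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset("x", {}, file_meta=meta, preamble=b"\0" * 128)
        ds.Modality = "RTSTRUCT"
        path = tmp_path / "empty.dcm"
        ds.save_as(str(path), enforce_file_format=True)
        with pytest.raises(GridFormatError):
            read_dicom_rtstruct(path)
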