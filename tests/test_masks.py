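"""Contour rasterization, mask algebra, volumes, interface shells."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage

from heteroqa.errors import GeometryError
from heteroqa.grid_io import ContourPolygon, GridHeader, VoxelMask
from heteroqa.masks import (
    combine_masks,
    interface_shell,
    points_in_polygon,
    rasterize_contours,
    volume_cc,
)

from .conftest import make_header


def _mask(header, rng, p=0.4):
    return VoxelMask(header, rng.random(header.dims) < p)


class TestRasterize:
    def test_square_covers_exactly_the_interior_centers(self):
        header = GridHeader((8, 8, 1), (1.25, 1.25, 0.0), (2.5, 2.5, 2.5))
        square = ContourPolygon(0.0, np.array([[0, 0], [10, 0], [10, 10], [0, 10]], float))
        mask = rasterize_contours([square], header)
        assert mask.count == 16  # 4x4 centers at 1.25/3.75/6.25/8.75 mm
        assert mask.flags[:4, :4, 0].all()

    def test_tiny_polygon_contains_no_center(self):
        header = GridHeader((4, 4, 1), (1.25, 1.25, 0.0), (2.5, 2.5, 2.5))
        tiny = ContourPolygon(0.0, np.array([[0, 0], [1, 0], [0.5, 0.9]], float))
        assert rasterize_contours([tiny], header).count == 0

    def test_empty_structure_warns_and_gives_empty_mask(self, caplog):
        with caplog.at_level("WARNING"):
            mask = rasterize_contours([], make_header((3, 3, 3)))
        assert mask.count == 0
        assert any("no polygons" in r.message for r in caplog.records)

    def test_polygon_outside_grid_extent_ignored_with_warning(self, caplog):
        header = GridHeader((4, 4, 2), (0, 0, 0), (2.5, 2.5, 2.5))
        square = ContourPolygon(50.0, np.array([[0, 0], [10, 0], [10, 10], [0, 10]], float))
        with caplog.at_level("WARNING"):
            mask = rasterize_contours([square], header)
        assert mask.count == 0
        assert any("outside grid extent" in r.message for r in caplog.records)

    def test_concave_polygon_matches_shapely_oracle(self, rng):
        from shapely.geometry import Point, Polygon

        for trial in range(5):
            # random star-shaped (possibly concave) polygon around the origin
            n = int(rng.integers(5, 11))
            angles = np.sort(rng.uniform(0, 2 * np.pi, n))
            radii = rng.uniform(3, 14, n)
            verts = np.column_stack([radii * np.cos(angles), radii * np.sin(angles)])
            header = GridHeader((16, 16, 1), (-15.1, -15.1, 0.0), (2.0, 2.0, 2.0))
            mask = rasterize_contours([ContourPolygon(0.0, verts)], header)
            poly = Polygon(verts)
            for ix in range(16):
                for iy in range(16):
                    x, y = -15.1 + 2.0 * ix, -15.1 + 2.0 * iy
                    assert mask.flags[ix, iy, 0] == poly.covers(Point(x, y)), (trial, x, y)

    def test_point_on_edge_counts_as_inside(self):
        square = np.array([[0, 0], [10, 0], [10, 10], [0, 10]], float)
        assert points_in_polygon(np.array([5.0]), np.array([0.0]), square)[0]
        assert points_in_polygon(np.array([0.0]), np.array([0.0]), square)[0]
        assert not points_in_polygon(np.array([10.1]), np.array([0.0]), square)[0]

    def test_two_polygons_on_one_slice_xor_to_a_ring(self):
        header = GridHeader((12, 12, 1), (0.5, 0.5, 0.0), (1.0, 1.0, 1.0))
        outer = ContourPolygon(0.0, np.array([[0, 0], [11, 0], [11, 11], [0, 11]], float))
        inner = ContourPolygon(0.0, np.array([[3, 3], [8, 3], [8, 8], [3, 8]], float))
        ring = rasterize_contours([outer, inner], header)
        full = rasterize_contours([outer], header)
        hole = rasterize_contours([inner], header)
        assert ring.count == full.count - hole.count
        assert not (ring.flags & hole.flags).any()


class TestVolumes:
    @pytest.mark.parametrize(
        "dims, spacing, n_set, expected_cc",
        [
            ((4, 4, 4), (2.5, 2.5, 2.5), 64, 1.0),
            ((4, 4, 4), (2.5, 2.5, 2.5), 0, 0.0),
            ((10, 10, 10), (1.0, 1.0, 1.0), 1000, 1.0),
        ],
    )
    def test_volume_is_count_times_voxel_volume(self, dims, spacing, n_set, expected_cc):
        flags = np.zeros(dims, dtype=bool)
        flags.ravel()[:n_set] = True
        mask = VoxelMask(GridHeader(dims, (0, 0, 0), spacing), flags)
        assert volume_cc(mask) == pytest.approx(expected_cc)

    def test_volume_additive_over_disjoint_masks(self, rng):
        header = make_header((6, 6, 6))
        a = _mask(header, rng)
        b = VoxelMask(header, ~a.flags & (rng.random(header.dims) < 0.5))
        union = combine_masks(a, b, "union")
        assert volume_cc(union) == pytest.approx(volume_cc(a) + volume_cc(b))


class TestCombine:
    def test_idempotence_and_self_subtraction(self, rng):
        a = _mask(make_header(), rng)
        assert combine_masks(a, a, "intersect") == a
        assert combine_masks(a, a, "union") == a
        assert combine_masks(a, a, "subtract").count == 0

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_inclusion_exclusion(self, seed):
        rng = np.random.default_rng(seed)
        header = make_header((5, 5, 5))
        a, b = _mask(header, rng), _mask(header, rng)
        union = combine_masks(a, b, "union").count
        inter = combine_masks(a, b, "intersect").count
        assert union + inter == a.count + b.count

    def test_header_mismatch_is_geometry_error(self, rng):
        a = _mask(make_header((4, 4, 4)), rng)
        b = _mask(make_header((4, 4, 4), origin=(1, 0, 0)), rng)
        with pytest.raises(GeometryError):
            combine_masks(a, b, "union")


class TestInterfaceShell:
    def test_cube_shell_is_everything_but_the_center(self):
        header = make_header((5, 5, 5))
        flags = np.zeros((5, 5, 5), dtype=bool)
        flags[1:4, 1:4, 1:4] = True
        shell = interface_shell(VoxelMask(header, flags), thickness_mm=2.5)
        assert shell.count == 26
        assert not shell.flags[2, 2, 2]

    def test_single_voxel_shell_is_itself(self):
        header = make_header((3, 3, 3))
        flags = np.zeros((3, 3, 3), dtype=bool)
        flags[1, 1, 1] = True
        shell = interface_shell(VoxelMask(header, flags), thickness_mm=7.5)
        assert shell == VoxelMask(header, flags)

    def test_sub_voxel_thickness_warns_and_is_empty(self, caplog):
        mask = VoxelMask(make_header((3, 3, 3)), np.ones((3, 3, 3), dtype=bool))
        with caplog.at_level("WARNING"):
            shell = interface_shell(mask, thickness_mm=0.5)
        assert shell.count == 0

    def test_sphere_shell_matches_distance_transform_oracle(self):
        header = GridHeader((20, 20, 20), (0, 0, 0), (1.0, 1.0, 1.0))
        xs = np.arange(20) - 9.5
        r2 = xs[:, None, None] ** 2 + xs[None, :, None] ** 2 + xs[None, None, :] ** 2
        sphere = VoxelMask(header, r2 <= 8.0**2)
        shell = interface_shell(sphere, thickness_mm=2.0)  # k = 2 erosions
        # 6-connected erosion depth equals the taxicab distance to background
        dist = ndimage.distance_transform_cdt(sphere.flags, metric="taxicab")
        assert np.array_equal(shell.flags, sphere.flags & (dist <= 2))

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1), k=st.integers(1, 3))
    def test_shell_is_subset_of_mask(self, seed, k):
        rng = np.random.default_rng(seed)
        mask = _mask(make_header((6, 6, 6)), rng, p=0.6)
        shell = interface_shell(mask, thickness_mm=2.5 * k)
        assert not (shell.flags & ~mask.flags).any()

    def test_refining_the_grid_converges_for_a_convex_structure(self):
        # disc of radius 8 mm rasterized at 2 mm and 1 mm: volumes agree to
        # within one boundary shell of the coarse voxelization
        poly = ContourPolygon(
            0.0,
            np.column_stack(
                [8 * np.cos(np.linspace(0, 2 * np.pi, 64, endpoint=False)),
                 8 * np.sin(np.linspace(0, 2 * np.pi, 64, endpoint=False))]
            ),
        )
        coarse = rasterize_contours(
            [poly], GridHeader((12, 12, 1), (-11, -11, 0), (2.0, 2.0, 2.0))
        )
        fine = rasterize_contours(
            [poly], GridHeader((24, 24, 1), (-11.5, -11.5, 0), (1.0, 1.0, 1.0))
        )
        shell = interface_shell(coarse, thickness_mm=2.0)
        assert abs(volume_cc(fine) / 1.0 - volume_cc(coarse) / 2.0) <= volume_cc(shell) / 2.0
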