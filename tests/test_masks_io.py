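"""Mask file round trips, binarization, polygon rasterization, manifests."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import concord as cc
from conftest import box_mask, make_grid, random_blob_mask


class TestNiftiRoundTrip:
    def test_lossless_occupancy_and_grid(self, tmp_path, rng):
        grid = make_grid((10, 11, 12), spacing=(0.5, 0.5, 2.0), origin=(1.0, -2.0, 3.5))
        mask = random_blob_mask(grid, rng)
        back = cc.read_mask(cc.write_mask(mask, tmp_path / "m.nii.gz"))
        assert np.array_equal(back.occupancy, mask.occupancy)
        assert back.grid.dims == grid.dims
        assert np.allclose(back.grid.spacing, grid.spacing, atol=1e-4)
        assert np.allclose(back.grid.origin, grid.origin, atol=1e-4)

    def test_empty_mask_round_trip(self, tmp_path, grid12):
        mask = cc.StructureMask(grid=grid12, occupancy=np.zeros(grid12.dims, bool))
        back = cc.read_mask(cc.write_mask(mask, tmp_path / "empty.nii"))
        assert back.voxel_count == 0

    def test_voxel_count_and_spacing_preserved(self, tmp_path):
        grid = make_grid((10, 10, 10), spacing=(1.0, 1.0, 2.0))
        mask = box_mask(grid, (0, 0, 0), (10, 10, 10))
        back = cc.read_mask(cc.write_mask(mask, tmp_path / "box.nii.gz"))
        assert back.voxel_count == 1000
        assert back.grid.spacing == (1.0, 1.0, 2.0)

    def test_nonzero_values_binarize(self, tmp_path):
        import nibabel as nib

        data = np.zeros((4, 4, 4), dtype=np.int16)
        data[1, 2, 3] = 7
        nib.save(nib.Nifti1Image(data, np.eye(4)), str(tmp_path / "v.nii"))
        mask = cc.read_mask(tmp_path / "v.nii")
        assert mask.occupancy.dtype == bool
        assert mask.voxel_count == 1 and mask.occupancy[1, 2, 3]


class TestReadErrors:
    def test_missing_spacing_raises(self, tmp_path):
        # nibabel refuses to *write* zero pixdims, so emulate a third-party
        # file with absent spacing by zeroing pixdim in the raw header
        import struct

        import nibabel as nib

        p = tmp_path / "nospacing.nii"
        nib.save(nib.Nifti1Image(np.ones((4, 4, 4), dtype=np.uint8), np.eye(4)), str(p))
        with open(p, "r+b") as fh:
            fh.seek(76)  # pixdim[0..7], float32
            fh.write(struct.pack("<8f", 1, 0, 0, 0, 1, 1, 1, 1))
        with pytest.raises(cc.MissingSpacingError):
            cc.read_mask(p)

    def test_unsupported_format_raises(self, tmp_path):
        p = tmp_path / "mask.txt"
        p.write_text("not a volume")
        with pytest.raises(cc.UnsupportedFormatError):
            cc.read_mask(p)

    def test_grid_mismatch_raises(self, tmp_path, grid12):
        mask = box_mask(grid12, (0, 0, 0), (2, 2, 2))
        path = cc.write_mask(mask, tmp_path / "m.nii")
        other = make_grid((12, 12, 12), spacing=(2.0, 2.0, 2.0))
        with pytest.raises(cc.GridMismatchError):
            cc.read_mask(path, expected_grid=other)

    def test_write_refuses_nrrd(self, tmp_path, grid12):
        mask = box_mask(grid12, (0, 0, 0), (2, 2, 2))
        with pytest.raises(cc.UnsupportedFormatError):
            cc.write_mask(mask, tmp_path / "m.nrrd")


def test_nrrd_read_matches_source(tmp_path):
    import SimpleITK as sitk

    arr = np.zeros((8, 9, 10), dtype=np.uint8)  # (x, y, z)
    arr[1:4, 2:5, 3:7] = 1
    img = sitk.GetImageFromArray(arr.transpose(2, 1, 0))
    img.SetSpacing((1.0, 1.5, 2.0))
    img.SetOrigin((0.0, 1.0, 2.0))
    sitk.WriteImage(img, str(tmp_path / "m.nrrd"))
    mask = cc.read_mask(tmp_path / "m.nrrd")
    assert mask.grid.dims == (8, 9, 10)
    assert mask.grid.spacing == (1.0, 1.5, 2.0)
    assert np.array_equal(mask.occupancy, arr.astype(bool))


class TestRasterization:
    def test_square_occupies_exact_voxel_count(self):
        grid = make_grid((20, 20, 4), spacing=(1.0, 1.0, 2.0))
        square = [(-0.5, -0.5), (9.5, -0.5), (9.5, 9.5), (-0.5, 9.5)]
        mask = cc.rasterize_slice_polygons([(2.0, np.array(square))], grid)
        assert mask.voxel_count == 100
        assert mask.occupancy[:, :, 1].sum() == 100  # slice at z=2 only

    def test_even_odd_rule_cuts_hole(self):
        grid = make_grid((20, 20, 2), spacing=(1.0, 1.0, 2.0))
        outer = np.array([(-0.5, -0.5), (9.5, -0.5), (9.5, 9.5), (-0.5, 9.5)])
        hole = np.array([(1.5, 1.5), (7.5, 1.5), (7.5, 7.5), (1.5, 7.5)])
        mask = cc.rasterize_slice_polygons([(0.0, outer), (0.0, hole)], grid)
        assert mask.voxel_count == 100 - 36

    def test_circle_area_matches_analytic_and_brute_force(self):
        from shapely.geometry import Point, Polygon

        r = 10.0
        grid = make_grid((60, 60, 1), spacing=(0.5, 0.5, 2.0))
        theta = np.linspace(0, 2 * np.pi, 256, endpoint=False)
        verts = np.c_[15 + r * np.cos(theta), 15 + r * np.sin(theta)]
        mask = cc.rasterize_slice_polygons([(0.0, verts)], grid)
        expected = np.pi * r * r / 0.25
        assert abs(mask.voxel_count - expected) / expected < 0.02
        # independent check: shapely point-in-polygon over all voxel centers
        poly = Polygon(verts)
        xs = grid.axis_coords(0)
        ys = grid.axis_coords(1)
        brute = sum(
            poly.contains(Point(x, y)) for x in xs for y in ys
        )
        assert abs(mask.voxel_count - brute) <= 0.005 * expected

    @given(st.integers(0, 7), st.booleans())
    def test_invariant_to_vertex_rotation_and_order(self, roll, reverse):
        grid = make_grid((16, 16, 2), spacing=(1.0, 1.0, 2.0))
        verts = np.array(
            [(1.2, 1.1), (11.4, 2.3), (13.1, 9.8), (6.0, 12.9),
             (2.2, 10.0), (0.8, 5.5), (3.0, 3.2), (1.9, 2.0)]
        )
        base = cc.rasterize_slice_polygons([(0.0, verts)], grid)
        v2 = np.roll(verts, roll, axis=0)
        if reverse:
            v2 = v2[::-1]
        other = cc.rasterize_slice_polygons([(0.0, v2)], grid)
        assert np.array_equal(base.occupancy, other.occupancy)

    def test_abutting_squares_never_double_cover(self):
        grid = make_grid((12, 12, 2), spacing=(1.0, 1.0, 2.0))
        left = np.array([(0.0, 0.0), (5.0, 0.0), (5.0, 5.0), (0.0, 5.0)])
        right = np.array([(5.0, 0.0), (10.0, 0.0), (10.0, 5.0), (5.0, 5.0)])
        ml = cc.rasterize_slice_polygons([(0.0, left)], grid)
        mr = cc.rasterize_slice_polygons([(0.0, right)], grid)
        both = cc.rasterize_slice_polygons([(0.0, left), (0.0, right)], grid)
        assert not (ml.occupancy & mr.occupancy).any()
        assert np.array_equal(both.occupancy, ml.occupancy | mr.occupancy)

    def test_misaligned_plane_raises(self):
        grid = make_grid((8, 8, 4), spacing=(1.0, 1.0, 2.0))
        square = np.array([(0.0, 0.0), (3.0, 0.0), (3.0, 3.0), (0.0, 3.0)])
        # slice centers lie at z = 0, 2, 4, 6 mm; z = 9 is beyond half a
        # slice spacing from every center
        with pytest.raises(cc.PolygonError):
            cc.rasterize_slice_polygons([(9.0, square)], grid)

    def test_self_intersecting_polygon_raises(self):
        grid = make_grid((8, 8, 2), spacing=(1.0, 1.0, 2.0))
        bowtie = np.array([(0.0, 0.0), (4.0, 4.0), (4.0, 0.0), (0.0, 4.0)])
        with pytest.raises(cc.PolygonError):
            cc.rasterize_slice_polygons([(0.0, bowtie)], grid)


class TestManifest:
    def _manifest(self, tmp_path, grid):
        entries = {}
        for p in ("p01", "p02"):
            for r in ("r1", "r2"):
                for s in ("prostate",):
                    rel = f"{p}_{r}_{s}.nii.gz"
                    cc.write_mask(box_mask(grid, (0, 0, 0), (3, 3, 3)), tmp_path / rel)
                    entries[(p, r, s)] = __import__("pathlib").Path(rel)
        return cc.CohortManifest(
            patients=["p01", "p02"], raters=["r1", "r2"],
            structures=["prostate"], entries=entries, root=tmp_path,
        )

    def test_json_round_trip_and_load(self, tmp_path, grid12):
        manifest = self._manifest(tmp_path, grid12)
        cc.save_manifest(manifest, tmp_path / "manifest.json")
        back = cc.load_manifest(tmp_path / "manifest.json")
        assert back.patients == manifest.patients
        mask = back.load("p01", "r2", "prostate")
        assert mask.voxel_count == 27
        assert (mask.patient_id, mask.rater_id) == ("p01", "r2")

    def test_explicit_missing_entry_loads_as_none(self, tmp_path, grid12):
        manifest = self._manifest(tmp_path, grid12)
        manifest.entries[("p02", "r2", "prostate")] = None
        cc.save_manifest(manifest, tmp_path / "manifest.json")
        back = cc.load_manifest(tmp_path / "manifest.json")
        assert back.load("p02", "r2", "prostate") is None

    def test_incomplete_manifest_rejected(self, tmp_path, grid12):
        manifest = self._manifest(tmp_path, grid12)
        del manifest.entries[("p01", "r1", "prostate")]
        cc.save_manifest(manifest, tmp_path / "manifest.json")
        with pytest.raises(cc.ManifestError):
            cc.load_manifest(tmp_path / "manifest.json")

    def test_csv_manifest(self, tmp_path, grid12):
        manifest = self._manifest(tmp_path, grid12)
        lines = ["patient_id,rater_id,structure,path"]
        for (p, r, s), loc in sorted(manifest.entries.items()):
            lines.append(f"{p},{r},{s},{loc}")
        (tmp_path / "manifest.csv").write_text("\n".join(lines) + "\n")
        back = cc.load_manifest(tmp_path / "manifest.csv")
        assert back.load("p02", "r1", "prostate").voxel_count == 27


def test_polygon_csv_round_trip(tmp_path):
    rows = ["structure,slice_z_mm,vertex_index,x_mm,y_mm"]
    square = [(-0.5, -0.5), (4.5, -0.5), (4.5, 4.5), (-0.5, 4.5)]
    for i, (x, y) in enumerate(square):
        rows.append(f"prostate,0.0,{i},{x},{y}")
    (tmp_path / "contours.csv").write_text("\n".join(rows) + "\n")
    polys = cc.read_polygon_csv(tmp_path / "contours.csv")
    grid = make_grid((8, 8, 2), spacing=(1.0, 1.0, 2.0))
    mask = cc.rasterize_slice_polygons(polys["prostate"], grid)
    assert mask.voxel_count == 25
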