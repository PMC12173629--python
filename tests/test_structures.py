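import logging

import numpy as np
import pytest

from rtcompare import (
    EmptyMaskError,
    StructureMask,
    StructureSet,
    VoxelGrid,
    border_difference_table,
    border_extents,
    expand_mask,
    intersection,
    rasterize_polygons,
    read_mask_volume,
    read_rtstruct,
    resample_mask,
    subtract,
    union,
    volume_cc,
    write_mask_volume,
)

from oracles import box_mask, point_in_polygon, random_blob, sphere_mask


# ----------------------------------------------------------------------
# rasterization
# ----------------------------------------------------------------------

def test_rasterize_square_400_voxels():
    grid = VoxelGrid((25, 25, 3), (1.0, 1.0, 1.0), (0.5, 0.5, 0.0))
    square = np.array([[0, 0, 1], [20, 0, 1], [20, 20, 1], [0, 20, 1]], dtype=float)
    mask = rasterize_polygons([square], grid)
    assert mask.n_occupied == 400
    assert mask.occupancy[:, :, 1].sum() == 400


def test_rasterize_empty_contours():
    grid = VoxelGrid((4, 4, 4), (1.0, 1.0, 1.0))
    assert rasterize_polygons([], grid).is_empty


def test_rasterize_circle_vs_analytic_and_oracle():
    grid = VoxelGrid((61, 61, 1), (1.0, 1.0, 1.0), (-30.0, -30.0, 0.0))
    theta = np.linspace(0, 2 * np.pi, 180, endpoint=False)
    circle = np.column_stack([25 * np.cos(theta), 25 * np.sin(theta), np.zeros_like(theta)])
    mask = rasterize_polygons([circle], grid)
    assert mask.n_occupied == pytest.approx(np.pi * 25 ** 2, rel=0.02)
    x, y, _ = grid.coordinate_axes()
    poly = circle[:, :2]
    for i in range(0, grid.dims[0], 3):
        for j in range(0, grid.dims[1], 3):
            assert mask.occupancy[i, j, 0] == point_in_polygon(x[i], y[j], poly)


def test_rasterize_even_odd_hole():
    grid = VoxelGrid((30, 30, 1), (1.0, 1.0, 1.0), (0.5, 0.5, 0.0))
    outer = np.array([[0, 0, 0], [20, 0, 0], [20, 20, 0], [0, 20, 0]], dtype=float)
    inner = np.array([[5, 5, 0], [15, 5, 0], [15, 15, 0], [5, 15, 0]], dtype=float)
    mask = rasterize_polygons([outer, inner], grid)
    assert mask.n_occupied == 400 - 100  # ring: odd crossings only


def test_rasterize_misaligned_plane_rejected():
    grid = VoxelGrid((10, 10, 4), (1.0, 1.0, 5.0))
    below = np.array([[1, 1, -7.0], [5, 1, -7.0], [3, 5, -7.0]], dtype=float)
    with pytest.raises(ValueError, match="does not align"):
        rasterize_polygons([below], grid)
    slanted = np.array([[1, 1, 0.0], [5, 1, 0.0], [3, 5, 2.0]], dtype=float)
    with pytest.raises(ValueError, match="planar"):
        rasterize_polygons([slanted], grid)


# ----------------------------------------------------------------------
# volume and expansion
# ----------------------------------------------------------------------

def test_volume_cc_basics():
    grid = VoxelGrid((10, 10, 10), (2.0, 2.0, 2.0))
    empty = StructureMask("e", grid, np.zeros(grid.dims, dtype=bool))
    assert volume_cc(empty) == 0.0
    occ = np.zeros(grid.dims, dtype=bool)
    occ.ravel()[:1000] = True
    assert volume_cc(StructureMask("m", grid, occ)) == pytest.approx(8.0)


def test_sphere_volume_analytic():
    # sphere centred on a voxel corner: the symmetric placement that keeps
    # the digitization bias of centre-containment rasterization smallest
    grid = VoxelGrid((52, 52, 52), (1.0, 1.0, 1.0), (-25.5, -25.5, -25.5))
    mask = sphere_mask(grid, (0, 0, 0), 20.0)
    assert mask.volume_cc() == pytest.approx(4 / 3 * np.pi * 20 ** 3 / 1000, rel=0.02)


def test_expand_sphere_analytic():
    grid = VoxelGrid((62, 62, 62), (1.0, 1.0, 1.0), (-30.5, -30.5, -30.5))
    mask = sphere_mask(grid, (0, 0, 0), 20.0)
    grown = expand_mask(mask, 5.0)
    assert grown.volume_cc() == pytest.approx(4 / 3 * np.pi * 25 ** 3 / 1000, rel=0.02)


def test_expand_identity_empty_and_monotone():
    grid = VoxelGrid((20, 20, 20), (1.0, 2.0, 1.5))
    rng = np.random.default_rng(5)
    blob = random_blob(grid, rng)
    assert np.array_equal(expand_mask(blob, 0.0).occupancy, blob.occupancy)
    empty = StructureMask("e", grid, np.zeros(grid.dims, dtype=bool))
    assert expand_mask(empty, 10.0).is_empty
    small = expand_mask(blob, 2.0)
    big = expand_mask(blob, 4.0)
    assert np.all(blob.occupancy <= small.occupancy)
    assert np.all(small.occupancy <= big.occupancy)
    with pytest.raises(ValueError):
        expand_mask(blob, -1.0)


def test_expand_respects_anisotropic_spacing():
    grid = VoxelGrid((11, 11, 11), (1.0, 1.0, 4.0), (-5.0, -5.0, -20.0))
    occ = np.zeros(grid.dims, dtype=bool)
    occ[5, 5, 5] = True
    grown = expand_mask(StructureMask("pt", grid, occ), 3.0)
    assert grown.occupancy[8, 5, 5]      # 3 mm away in x: included
    assert not grown.occupancy[5, 5, 6]  # 4 mm away in z: excluded


# ----------------------------------------------------------------------
# set algebra
# ----------------------------------------------------------------------

def test_union_intersection_subtract():
    grid = VoxelGrid((30, 30, 30), (1.0, 1.0, 1.0), (-15.0, -15.0, -15.0))
    a = sphere_mask(grid, (-3, 0, 0), 6.0, "a")
    b = sphere_mask(grid, (3, 0, 0), 6.0, "b")
    u = union([a, b])
    i = intersection([a, b])
    # inclusion-exclusion against direct voxel counting
    assert u.n_occupied == int((a.occupancy | b.occupancy).sum())
    assert u.n_occupied == a.n_occupied + b.n_occupied - i.n_occupied
    assert np.array_equal(union([a, a]).occupancy, a.occupancy)
    d = subtract(a, b)
    assert np.array_equal(d.occupancy, a.occupancy & ~b.occupancy)


def test_union_two_disjoint_voxels():
    grid = VoxelGrid((5, 5, 5), (1.0, 1.0, 1.0))
    occ1 = np.zeros(grid.dims, dtype=bool); occ1[0, 0, 0] = True
    occ2 = np.zeros(grid.dims, dtype=bool); occ2[4, 4, 4] = True
    u = union([StructureMask("a", grid, occ1), StructureMask("b", grid, occ2)])
    assert u.n_occupied == 2


def test_grid_mismatch_rejected():
    a = StructureMask("a", VoxelGrid((3, 3, 3), (1, 1, 1)), np.ones((3, 3, 3), dtype=bool))
    b = StructureMask("b", VoxelGrid((3, 3, 3), (2, 2, 2)), np.ones((3, 3, 3), dtype=bool))
    with pytest.raises(ValueError):
        union([a, b])
    with pytest.raises(ValueError):
        intersection([a, b])


def test_structure_set_invariants():
    grid = VoxelGrid((3, 3, 3), (1, 1, 1))
    s = StructureSet("obs")
    m = StructureMask("a", grid, np.ones((3, 3, 3), dtype=bool))
    s.add(m)
    with pytest.raises(ValueError, match="duplicate"):
        s.add(m.copy())
    other = StructureMask("b", VoxelGrid((3, 3, 3), (2, 2, 2)), np.ones((3, 3, 3), dtype=bool))
    with pytest.raises(ValueError, match="shared grid"):
        s.add(other)
    assert "a" in s and s.labels() == ["a"]


# ----------------------------------------------------------------------
# borders
# ----------------------------------------------------------------------

def test_border_extents_single_voxel():
    grid = VoxelGrid((5, 5, 5), (5.0, 5.0, 25.0), (0.0, 0.0, 0.0))
    occ = np.zeros(grid.dims, dtype=bool)
    occ[2, 0, 2] = True  # world (10, 0, 50)
    ext = border_extents(StructureMask("pt", grid, occ), "left")
    assert ext.cranial_mm == ext.caudal_mm == 50.0
    assert ext.medial_mm == ext.lateral_mm == 10.0


def test_border_extents_box_span_and_laterality():
    grid = VoxelGrid((40, 10, 40), (1.0, 1.0, 1.0))
    box = box_mask(grid, (5, 2, 0), (25, 6, 30))
    left = border_extents(box, "left")
    assert left.cranial_mm - left.caudal_mm == pytest.approx(30.0)
    assert left.lateral_mm == 25.0 and left.medial_mm == 5.0
    right = border_extents(box, "right")
    assert right.lateral_mm == 5.0 and right.medial_mm == 25.0


def test_border_extents_matches_exhaustive_scan():
    grid = VoxelGrid((18, 16, 20), (1.5, 2.0, 2.5), (-9.0, 4.0, 0.0))
    blob = random_blob(grid, np.random.default_rng(11))
    ext = border_extents(blob, "left")
    centers = blob.occupied_centers()
    assert ext.cranial_mm == centers[:, 2].max()
    assert ext.caudal_mm == centers[:, 2].min()
    assert ext.lateral_mm == centers[:, 0].max()
    assert ext.medial_mm == centers[:, 0].min()


def test_border_extents_empty_rejected():
    grid = VoxelGrid((3, 3, 3), (1, 1, 1))
    empty = StructureMask("e", grid, np.zeros(grid.dims, dtype=bool))
    with pytest.raises(EmptyMaskError):
        border_extents(empty)


def _set_with(label, mask):
    s = StructureSet(label)
    s.add(mask)
    return s


def test_border_difference_table_values():
    grid = VoxelGrid((21, 21, 61), (1.0, 1.0, 1.0), (-10.0, -10.0, 0.0))
    a = sphere_mask(grid, (0, 0, 12), 5.0, "CTV")
    b = sphere_mask(grid, (0, 0, 39), 5.0, "CTV")  # 27 mm cranial offset
    diffs = border_difference_table(
        [_set_with("obs1", a), _set_with("obs2", b)], "CTV",
        ("cranial", "caudal", "medial", "lateral"),
    )
    assert diffs["cranial"] == pytest.approx(2.70)
    assert diffs["caudal"] == pytest.approx(2.70)
    assert diffs["medial"] == diffs["lateral"] == 0.0

    # identical observers: all zero
    same = border_difference_table([_set_with("o1", a), _set_with("o2", a.copy())], "CTV")
    assert all(v == 0.0 for v in same.values())


def test_border_difference_lateral_offset_boxes():
    grid = VoxelGrid((50, 10, 10), (1.0, 1.0, 1.0))
    a = box_mask(grid, (5, 2, 2), (15, 7, 7), "CTV")
    b = box_mask(grid, (20, 2, 2), (30, 7, 7), "CTV")
    diffs = border_difference_table(
        [_set_with("o1", a), _set_with("o2", b)], "CTV", ("lateral",)
    )
    assert diffs["lateral"] == pytest.approx(1.50)


def test_border_difference_matches_pairwise_scan():
    grid = VoxelGrid((20, 20, 20), (1.0, 1.5, 2.0), (0.0, 0.0, 0.0))
    rng = np.random.default_rng(3)
    sets = [_set_with(f"o{i}", random_blob(grid, rng, "CTV")) for i in range(5)]
    diffs = border_difference_table([s for s in sets], "CTV")
    for border in ("cranial", "caudal", "medial", "lateral"):
        vals = [border_extents(s["CTV"], "left").as_dict()[border] for s in sets]
        best = max(abs(u - v) for u in vals for v in vals) / 10.0
        assert diffs[border] == pytest.approx(best)


def test_border_difference_skips_missing_observer(caplog):
    grid = VoxelGrid((10, 10, 10), (1, 1, 1))
    a = box_mask(grid, (1, 1, 1), (3, 3, 3), "CTV")
    b = box_mask(grid, (2, 2, 2), (5, 5, 5), "CTV")
    incomplete = StructureSet("o3")
    incomplete.add(box_mask(grid, (0, 0, 0), (1, 1, 1), "other"))
    with caplog.at_level(logging.WARNING):
        diffs = border_difference_table(
            [_set_with("o1", a), _set_with("o2", b), incomplete], "CTV", ("cranial",)
        )
    assert "o3" in caplog.text
    assert diffs["cranial"] == pytest.approx(0.2)
    with pytest.raises(ValueError, match="at least 2"):
        border_difference_table([_set_with("o1", a), incomplete], "CTV")


# ----------------------------------------------------------------------
# I/O
# ----------------------------------------------------------------------

def test_nifti_round_trip(tmp_path):
    grid = VoxelGrid((12, 10, 8), (1.0, 1.0, 3.0), (-6.0, 2.0, 0.0))
    blob = random_blob(grid, np.random.default_rng(2), "CTV-breast")
    path = tmp_path / "ctv.nii.gz"
    write_mask_volume(blob, path)
    back = read_mask_volume(path)
    assert np.array_equal(back.occupancy, blob.occupancy)
    assert back.grid.matches(grid)
    assert back.grid.spacing == (1.0, 1.0, 3.0)
    assert back.label == "ctv"


def test_nifti_nonbinary_needs_threshold(tmp_path):
    import nibabel as nib

    data = np.linspace(0, 2, 27).reshape(3, 3, 3).astype(np.float32)
    nib.save(nib.Nifti1Image(data, np.eye(4)), str(tmp_path / "soft.nii.gz"))
    with pytest.raises(ValueError, match="threshold"):
        read_mask_volume(tmp_path / "soft.nii.gz")
    mask = read_mask_volume(tmp_path / "soft.nii.gz", threshold=1.0)
    assert mask.n_occupied == int((data > 1.0).sum())


def test_nifti_oblique_rejected(tmp_path):
    import nibabel as nib

    affine = np.eye(4)
    affine[0, 1] = 0.3
    nib.save(nib.Nifti1Image(np.zeros((3, 3, 3), dtype=np.uint8), affine),
             str(tmp_path / "obl.nii.gz"))
    with pytest.raises(ValueError, match="oblique"):
        read_mask_volume(tmp_path / "obl.nii.gz")


def test_resample_mask_round_trip_and_outside():
    src = VoxelGrid((10, 10, 10), (2.0, 2.0, 2.0), (0.0, 0.0, 0.0))
    blob = random_blob(src, np.random.default_rng(9))
    assert np.array_equal(resample_mask(blob, src).occupancy, blob.occupancy)
    # shifted target partially outside the source: outside voxels unoccupied
    tgt = VoxelGrid((10, 10, 10), (2.0, 2.0, 2.0), (-4.0, 0.0, 0.0))
    out = resample_mask(blob, tgt)
    assert not out.occupancy[:2].any()
    assert np.array_equal(out.occupancy[2:], blob.occupancy[:8])


def _write_rtstruct(path, contour_points, roi_name="square"):
    import pydicom
    from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
    from pydicom.uid import ImplicitVRLittleEndian, generate_uid

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.UID("1.2.840.10008.5.1.4.1.1.481.3")
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ImplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTSTRUCT"

    roi = Dataset()
    roi.ROINumber = 1
    roi.ROIName = roi_name
    roi.ReferencedFrameOfReferenceUID = generate_uid()
    ds.StructureSetROISequence = [roi]

    contour = Dataset()
    contour.ContourGeometricType = "CLOSED_PLANAR"
    contour.NumberOfContourPoints = len(contour_points)
    contour.ContourData = [f"{v:.4f}" for v in np.asarray(contour_points).ravel()]
    roi_contour = Dataset()
    roi_contour.ReferencedROINumber = 1
    roi_contour.ContourSequence = [contour]
    ds.ROIContourSequence = [roi_contour]
    pydicom.dcmwrite(str(path), ds)


def test_rtstruct_matches_rasterize_polygons(tmp_path):
    grid = VoxelGrid((25, 25, 3), (1.0, 1.0, 1.0), (0.5, 0.5, 0.0))
    square = np.array([[2, 2, 1], [18, 2, 1], [18, 18, 1], [2, 18, 1]], dtype=float)
    path = tmp_path / "rs.dcm"
    _write_rtstruct(path, square)
    via_dicom = read_rtstruct(path, grid)
    direct = rasterize_polygons([square], grid, label="square")
    assert "square" in via_dicom
    assert np.array_equal(via_dicom["square"].occupancy, direct.occupancy)


def test_rtstruct_rejects_non_structure_file(tmp_path):
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ImplicitVRLittleEndian, generate_uid

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ImplicitVRLittleEndian
    ds = FileDataset(str(tmp_path / "ct.dcm"), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.Modality = "CT"
    pydicom.dcmwrite(str(tmp_path / "ct.dcm"), ds)
    with pytest.raises(ValueError, match="RT Structure Set"):
        read_rtstruct(tmp_path / "ct.dcm", VoxelGrid((3, 3, 3), (1, 1, 1)))
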