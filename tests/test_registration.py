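"""Built-in registration backends: centroid Procrustes and SSD demons."""

import numpy as np
import pytest
from scipy import ndimage

from uslr import ImageGrid, VelocityField, resample_image, svf_exp
from uslr.lie_rigid import RigidLog, RigidMatrix, rigid_exp, save_rigid_matrix
from uslr.phantom import PhantomConfig, PhantomStructure, make_phantom_template
from uslr.registration import (
    DegenerateGeometryError,
    RegistrationConfig,
    centroid_rigid_register,
    load_transform,
    ssd_svf_register,
)
from uslr.svf import GridMismatchError, save_velocity_field

from conftest import smooth_field


@pytest.fixture(scope="module")
def phantom_1mm():
    """A 32-cube, 1 mm version of the default head phantom."""
    base = PhantomConfig()
    cfg = PhantomConfig(
        shape=(32, 32, 32),
        spacing=1.0,
        structures=tuple(
            PhantomStructure(s.label, tuple(c / 5 for c in s.center),
                             tuple(r / 5 for r in s.radii), s.intensity, 0.0)
            for s in base.structures
        ),
    )
    return make_phantom_template(cfg)


def test_identical_labelmaps_give_identity(phantom_1mm):
    m = centroid_rigid_register(
        phantom_1mm.segmentation, phantom_1mm.grid,
        phantom_1mm.segmentation, phantom_1mm.grid,
    )
    assert np.abs(m.matrix - np.eye(4)).max() < 1e-9


def test_recover_applied_rigid_exactly_via_world_affine(phantom_1mm):
    """Same voxel data with a world-transformed grid: centroids map exactly,
    so the 10-degree z-rotation plus (3,-2,1) mm shift is recovered to
    better than 0.01 degree and 0.01 mm."""
    true = rigid_exp(RigidLog(np.deg2rad([0.0, 0.0, 10.0]), [3.0, -2.0, 1.0]))
    grid_tgt = ImageGrid(phantom_1mm.grid.shape, true.matrix @ phantom_1mm.grid.affine)
    m = centroid_rigid_register(
        phantom_1mm.segmentation, phantom_1mm.grid,
        phantom_1mm.segmentation, grid_tgt,
    )
    rot_err = np.rad2deg(np.arccos(np.clip((np.trace(m.U.T @ true.U) - 1) / 2, -1, 1)))
    assert rot_err < 0.01
    assert np.abs(m.t - true.t).max() < 0.01


def test_recover_applied_rigid_from_resampled_labels():
    """Resampled (voxelised) labels at 1 mm: recovery within a tenth of a
    millimetre despite nearest-neighbour label quantisation. (The voxel size
    must be fine relative to the translation, or quantisation absorbs it.)"""
    base = PhantomConfig()
    cfg = PhantomConfig(
        shape=(40, 40, 40), spacing=1.0,
        structures=tuple(
            PhantomStructure(s.label, tuple(c / 5 for c in s.center),
                             tuple(r / 5 for r in s.radii), s.intensity, 0.0)
            for s in base.structures
        ),
    )
    tpl = make_phantom_template(cfg)
    true = rigid_exp(RigidLog(np.deg2rad([0.0, 0.0, 10.0]), [3.0, -2.0, 1.0]))
    moved = resample_image(tpl.segmentation.astype(float), tpl.grid,
                           [true], tpl.grid, mode="nearest")
    m = centroid_rigid_register(tpl.segmentation, tpl.grid, moved.astype(int), tpl.grid)
    # resampling through [true] moves the anatomy by true^-1
    expect = true.inverse()
    assert np.abs(m.matrix - expect.matrix).max() < 0.1


def test_mirrored_centroids_still_give_proper_rotation():
    """A reflected constellation must not produce a det = -1 'rotation'."""
    grid = ImageGrid.isotropic((24, 24, 24))
    labels = np.zeros(grid.shape, dtype=int)
    for lab, c in [(1, (4, 4, 4)), (2, (18, 5, 6)), (3, (6, 18, 7)), (4, (7, 6, 18))]:
        labels[c[0] - 2:c[0] + 2, c[1] - 2:c[1] + 2, c[2] - 2:c[2] + 2] = lab
    mirrored = labels[::-1].copy()
    m = centroid_rigid_register(labels, grid, mirrored, grid)
    assert np.isclose(np.linalg.det(m.U), 1.0, atol=1e-9)


def test_too_few_shared_labels_rejected():
    grid = ImageGrid.isotropic((16, 16, 16))
    a = np.zeros(grid.shape, dtype=int)
    a[2:6, 2:6, 2:6] = 1
    a[10:14, 10:14, 10:14] = 2
    with pytest.raises(DegenerateGeometryError):
        centroid_rigid_register(a, grid, a, grid)


@pytest.fixture(scope="module")
def demons_case(phantom_1mm):
    grid = phantom_1mm.grid
    img_ref = ndimage.gaussian_filter(phantom_1mm.intensity, 1.0)
    vstar = smooth_field(grid, 1.5, seed=3)
    img_tgt = resample_image(img_ref, grid, [svf_exp(vstar, time_scale=-1.0)], grid)
    return grid, img_ref, img_tgt, vstar


def test_demons_identity_images_give_null_field(demons_case):
    grid, img_ref, _, _ = demons_case
    v = ssd_svf_register(img_ref, img_ref, grid)
    assert np.sqrt(np.mean(np.sum(v.values**2, axis=-1))) < 1e-3


def test_demons_recovers_known_deformation(demons_case):
    grid, img_ref, img_tgt, vstar = demons_case
    v = ssd_svf_register(img_ref, img_tgt, grid, RegistrationConfig(max_iters=150))
    warped = resample_image(img_tgt, grid, [svf_exp(v)], grid)
    ssd0 = np.sum((img_tgt - img_ref) ** 2)
    ssd1 = np.sum((warped - img_ref) ** 2)
    assert ssd1 <= 0.05 * ssd0  # >= 95 % SSD reduction
    endpoint = svf_exp(v).values - svf_exp(vstar).values
    assert np.sqrt(np.mean(np.sum(endpoint**2, axis=-1))) < 0.5  # voxels at 1 mm


def test_demons_approximate_inverse_consistency(phantom_1mm):
    grid = phantom_1mm.grid
    img_ref = ndimage.gaussian_filter(phantom_1mm.intensity, 1.0)
    vstar = smooth_field(grid, 0.5, seed=9)
    img_tgt = resample_image(img_ref, grid, [svf_exp(vstar, time_scale=-1.0)], grid)
    v_fwd = ssd_svf_register(img_ref, img_tgt, grid)
    v_bwd = ssd_svf_register(img_tgt, img_ref, grid)
    rms = np.sqrt(np.mean(np.sum((v_fwd.values + v_bwd.values) ** 2, axis=-1)))
    assert rms < 0.2


def test_load_transform_roundtrips(tmp_path, small_grid):
    m = rigid_exp(RigidLog([0.01, -0.02, 0.03], [1.0, 2.0, -3.0]))
    save_rigid_matrix(m, tmp_path / "m.txt")
    back = load_transform(tmp_path / "m.txt", kind="rigid")
    assert np.array_equal(back.matrix, m.matrix)

    v = smooth_field(small_grid, 1.0, seed=2)
    save_velocity_field(v, tmp_path / "v.nii.gz")
    back_v = load_transform(tmp_path / "v.nii.gz", kind="svf", expect_grid=small_grid)
    assert isinstance(back_v, VelocityField)
    assert np.allclose(back_v.values, v.values)


def test_load_transform_grid_mismatch(tmp_path, small_grid):
    v = smooth_field(small_grid, 1.0, seed=2)
    save_velocity_field(v, tmp_path / "v.nii.gz")
    with pytest.raises(GridMismatchError):
        load_transform(tmp_path / "v.nii.gz", kind="svf",
                       expect_grid=ImageGrid.isotropic((20, 20, 20)))


def test_backend_interchangeability_contract(small_grid):
    """Inference accepts edges from any source: mocked rigid and SVF payloads
    drive the same solvers."""
    from uslr.graph import TimepointNode, build_full_graph
    from uslr import solve_rigid_graph, solve_svf_graph

    g = build_full_graph([TimepointNode(i, i) for i in range(3)])
    for e in g.edges:
        e.log_params = RigidLog(np.zeros(3), [0.1 * (e.tgt_index - e.ref_index), 0, 0])
    rigid = solve_rigid_graph(g)
    assert len(rigid) == 3

    for e in g.edges:
        e.log_params = VelocityField(
            small_grid,
            np.full(small_grid.shape + (3,), 0.1 * (e.tgt_index - e.ref_index)),
        )
    svf = solve_svf_graph(g)
    assert len(svf) == 3
    assert np.allclose(svf[2].values - svf[0].values, 0.2, atol=1e-6)
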