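"""Core image types, I/O, resampling and moment computations."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from remodel3d.core import (
    BinaryMask,
    DensityImage,
    RegistrationResult,
    RigidTransform,
    center_of_mass,
    principal_axes,
    read_image,
    read_mask,
    read_transform,
    resample_rigid,
    write_image,
    write_transform,
)
from remodel3d.errors import (
    DegenerateInputError,
    DimensionalityError,
    GeometryError,
    TransformError,
)


# ---------------------------------------------------------------- types ----


def test_density_image_rejects_bad_geometry():
    with pytest.raises(DimensionalityError):
        DensityImage(np.zeros((4, 4)))
    with pytest.raises(GeometryError):
        DensityImage(np.zeros((4, 4, 4)), spacing=(0.0, 0.1, 0.1))
    with pytest.raises(ValueError):
        DensityImage(np.full((2, 2, 2), np.nan))


def test_rigid_transform_rejects_improper_rotation():
    with pytest.raises(TransformError):
        RigidTransform(rotation=np.diag([1.0, 1.0, -1.0]))  # reflection
    with pytest.raises(TransformError):
        RigidTransform(rotation=np.eye(3) * 2.0)  # not orthonormal


def test_registration_result_metric_bounds():
    with pytest.raises(ValueError):
        RegistrationResult(RigidTransform.identity(), 1.5, True, 10)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    angles=st.lists(st.floats(-180, 180), min_size=3, max_size=3),
    trans=st.lists(st.floats(-10, 10), min_size=3, max_size=3),
    center=st.lists(st.floats(-5, 5), min_size=3, max_size=3),
)
def test_transform_inverse_composition_is_identity(angles, trans, center):
    tf = RigidTransform.from_euler(angles, trans, center)
    ident = tf.compose(tf.inverse())
    assert np.allclose(ident.rotation, np.eye(3), atol=1e-6)
    pts = np.array([[0.0, 0.0, 0.0], [1.0, -2.0, 3.0], [5.0, 5.0, 5.0]])
    assert np.allclose(ident.apply(pts), pts, atol=1e-6)
    # round-trip of points through forward + inverse
    assert np.allclose(tf.inverse().apply(tf.apply(pts)), pts, atol=1e-6)


def test_transform_matrix_matches_apply():
    tf = RigidTransform.from_euler([10, -5, 30], [1.0, 2.0, -0.5], [0.3, 0.2, 0.1])
    pts = np.array([[0.1, 0.5, -0.2], [2.0, 0.0, 1.0]])
    hom = np.c_[pts, np.ones(len(pts))]
    assert np.allclose((tf.matrix() @ hom.T).T[:, :3], tf.apply(pts), atol=1e-12)


# ------------------------------------------------------------------ I/O ----


@pytest.mark.parametrize("ext", ["mha", "nii", "nii.gz"])
def test_image_round_trip(tmp_path, ext):
    rng = np.random.default_rng(0)
    img = DensityImage(
        rng.normal(0, 300, (10, 10, 10)),  # difference images are negative too
        spacing=(0.0607, 0.0607, 0.0607),
        origin=(1.0, -2.0, 3.0),
    )
    path = tmp_path / f"img.{ext}"
    write_image(img, path)
    back = read_image(path)
    assert np.allclose(back.voxels, img.voxels, atol=1e-6)
    assert np.allclose(back.spacing, img.spacing)
    assert np.allclose(back.origin, img.origin, atol=1e-5)


def test_constant_integer_image_round_trip_exact(tmp_path):
    img = DensityImage(np.full((10, 10, 10), 300.0))
    path = tmp_path / "const.mha"
    write_image(img, path)
    back = read_image(path)
    assert np.array_equal(back.voxels, img.voxels)


def test_mask_round_trip(tmp_path):
    rng = np.random.default_rng(1)
    mask = BinaryMask(rng.random((6, 7, 8)) > 0.5)
    path = tmp_path / "mask.mha"
    write_image(mask, path)
    back = read_mask(path)
    assert np.array_equal(back.voxels, mask.voxels)


def test_read_missing_file_raises():
    with pytest.raises(IOError):
        read_image("/nonexistent/image.mha")


def test_read_2d_image_raises(tmp_path):
    import SimpleITK as sitk

    path = tmp_path / "flat.mha"
    sitk.WriteImage(sitk.GetImageFromArray(np.zeros((5, 5))), str(path))
    with pytest.raises(DimensionalityError):
        read_image(path)


def test_anisotropic_spacing_preserved_with_warning(tmp_path):
    img = DensityImage(np.zeros((4, 4, 4)), spacing=(0.06, 0.06, 0.12))
    path = tmp_path / "aniso.mha"
    write_image(img, path)
    with pytest.warns(UserWarning, match="non-isotropic"):
        back = read_image(path)
    assert np.allclose(back.spacing, (0.06, 0.06, 0.12))


def test_transform_serialization_round_trip(tmp_path):
    tf = RigidTransform.from_euler([2.0, -1.0, 0.5], [0.3, 0.1, -0.2], [1.0, 2.0, 3.0])
    result = RegistrationResult(tf, 0.987, True, 123)
    write_transform(result, tmp_path / "t.txt")
    back = read_transform(tmp_path / "t.txt")
    assert np.allclose(back.transform.matrix(), tf.matrix(), atol=1e-9)
    assert back.final_metric == pytest.approx(0.987)
    assert back.converged and back.iterations == 123
    pts = np.array([[0.5, -0.5, 2.0]])
    assert np.allclose(back.transform.apply(pts), tf.apply(pts), atol=1e-9)


# ----------------------------------------------------------- resampling ----


def _smooth_blob(shape=(40, 40, 40), spacing=0.1):
    idx = np.indices(shape, dtype=float)
    c = (np.asarray(shape) - 1) / 2
    r2 = sum(((idx[d] - c[d]) * spacing) ** 2 for d in range(3))
    vox = 800.0 * np.exp(-r2 / (2 * 0.8**2))
    return DensityImage(vox, (spacing,) * 3)


@pytest.mark.parametrize("interp", ["nearest", "linear", "cubic"])
def test_identity_resample_is_identity(interp):
    img = _smooth_blob()
    out = resample_rigid(img, RigidTransform.identity(), img, interp)
    if interp == "nearest":
        assert np.array_equal(out.voxels, img.voxels)
    else:
        interior = out.voxels[2:-2, 2:-2, 2:-2]
        assert np.allclose(interior, img.voxels[2:-2, 2:-2, 2:-2], atol=1e-6)


def test_integer_voxel_translation_matches_index_shift():
    rng = np.random.default_rng(3)
    img = DensityImage(rng.normal(300, 50, (12, 12, 12)), (0.1, 0.1, 0.1))
    shift = (2, -1, 3)  # voxels
    tf = RigidTransform(translation=np.asarray(shift) * 0.1)
    out = resample_rigid(img, tf, img, "nearest")
    # index-shift oracle: out[i] = img[i - shift] where defined, else fill 0
    expected = np.zeros_like(img.voxels)
    expected[2:, :-1, 3:] = img.voxels[:-2, 1:, :-3]
    assert np.allclose(out.voxels, expected)


def test_half_voxel_shift_preserves_constant():
    img = DensityImage(np.full((16, 16, 16), 500.0), (0.1, 0.1, 0.1))
    tf = RigidTransform(translation=(0.05, 0.05, 0.05))
    out = resample_rigid(img, tf, img, "cubic")
    interior = out.voxels[3:-3, 3:-3, 3:-3]
    assert np.allclose(interior, 500.0, atol=1e-6)


def test_forward_backward_resample_recovers_interior():
    img = _smooth_blob()
    tf = RigidTransform.from_euler([3.0, -2.0, 5.0], [0.21, -0.13, 0.34], [2.0, 2.0, 2.0])
    there = resample_rigid(img, tf, img, "cubic")
    back = resample_rigid(there, tf.inverse(), img, "cubic")
    sel = img.voxels > 50  # the blob proper, away from the border
    mad = np.abs(back.voxels[sel] - img.voxels[sel]).mean()
    assert mad <= 0.01 * np.abs(img.voxels[sel]).mean()


# -------------------------------------------------------------- moments ----


def test_center_of_mass_single_voxel():
    vox = np.zeros((8, 8, 8))
    vox[2, 5, 3] = 400.0
    img = DensityImage(vox, (0.1, 0.2, 0.3), (1.0, 2.0, 3.0))
    com = center_of_mass(img)
    assert np.allclose(com, [1.0 + 0.2, 2.0 + 1.0, 3.0 + 0.9])


def test_center_of_mass_symmetric_cube():
    vox = np.zeros((20, 20, 20))
    vox[5:15, 5:15, 5:15] = 600.0
    img = DensityImage(vox, (0.1, 0.1, 0.1))
    assert np.allclose(center_of_mass(img), [0.95, 0.95, 0.95], atol=1e-9)


def test_center_of_mass_weighted_two_voxels():
    vox = np.zeros((10, 10, 10))
    vox[2, 2, 2] = 200.0
    vox[8, 2, 2] = 600.0
    img = DensityImage(vox, (1.0, 1.0, 1.0))
    # hand summation: x = (2*200 + 8*600) / 800 = 6.5
    assert np.allclose(center_of_mass(img), [6.5, 2.0, 2.0])


def test_center_of_mass_empty_foreground_raises():
    img = DensityImage(np.zeros((5, 5, 5)))
    with pytest.raises(DegenerateInputError):
        center_of_mass(img)


def _ellipsoid(semi_axes_vox, shape=(50, 50, 50), rotation=None):
    idx = np.indices(shape, dtype=float)
    c = (np.asarray(shape) - 1) / 2
    pts = np.stack([idx[d] - c[d] for d in range(3)], axis=-1)
    if rotation is not None:
        pts = pts @ rotation  # inverse-rotate the coordinates
    r2 = sum((pts[..., d] / semi_axes_vox[d]) ** 2 for d in range(3))
    return DensityImage(np.where(r2 <= 1.0, 700.0, 0.0), (0.1, 0.1, 0.1))


def test_principal_axes_axis_aligned_ellipsoid():
    img = _ellipsoid((20, 12, 6))
    axes = principal_axes(img)
    assert np.allclose(np.abs(axes), np.eye(3), atol=1e-3)
    assert axes[0, 0] > 0 and axes[1, 1] > 0 and axes[2, 2] > 0


def test_principal_axes_recover_applied_rotation():
    from scipy.spatial.transform import Rotation

    R = Rotation.from_euler("z", 30, degrees=True).as_matrix()
    img = _ellipsoid((20, 12, 6), rotation=R)
    axes = principal_axes(img)
    expected_first = R @ np.array([1.0, 0.0, 0.0])
    angle = np.degrees(
        np.arccos(np.clip(abs(np.dot(axes[:, 0], expected_first)), -1, 1))
    )
    assert angle < 1.0


def test_principal_axes_sphere_degenerates_to_identity():
    img = _ellipsoid((12, 12, 12))
    with pytest.warns(UserWarning, match="degenerate"):
        axes = principal_axes(img)
    assert np.array_equal(axes, np.eye(3))


def test_moment_equivariance_under_translation_and_rotation():
    from scipy.spatial.transform import Rotation

    img = _ellipsoid((18, 10, 5))
    com0 = center_of_mass(img)
    ax0 = principal_axes(img)

    shift_mm = np.array([0.35, -0.2, 0.5])
    tf = RigidTransform(translation=shift_mm)
    big = DensityImage(np.zeros((60, 60, 60)), img.spacing)
    moved = resample_rigid(img, tf, big, "linear")
    com1 = center_of_mass(moved)
    assert np.linalg.norm(com1 - (com0 + shift_mm)) < 0.5 * 0.1  # 0.5 voxel

    Rz = Rotation.from_euler("z", 20, degrees=True).as_matrix()
    tf_rot = RigidTransform(rotation=Rz, center=com0)
    rot = resample_rigid(img, tf_rot, big, "linear")
    ax1 = principal_axes(rot)
    expected = Rz @ ax0[:, 0]
    angle = np.degrees(np.arccos(np.clip(abs(np.dot(ax1[:, 0], expected)), -1, 1)))
    assert angle < 1.0
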