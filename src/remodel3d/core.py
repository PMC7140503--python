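"""Domain types and geometric primitives shared by the whole pipeline.

Images are calibrated density volumes (mgHA/cm^3) on a regular grid with
physical spacing and origin in millimetres.  The voxel array is indexed
``voxels[i, j, k]`` with the third axis the axial (scan) direction, index
increasing distal to proximal.  All transforms act on physical coordinates,
never on indices, so stacks and scans acquired with different origins
compose correctly.

SimpleITK backs file I/O and resampling; SimpleITK stores arrays in
``(z, y, x)`` order, so conversions transpose.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np
import SimpleITK as sitk
from scipy.spatial.transform import Rotation

from .errors import (
    DegenerateInputError,
    DimensionalityError,
    GeometryError,
    TransformError,
)

logger = logging.getLogger(__name__)

#: Default isotropic voxel size of second-generation HR-pQCT scans (mm).
DEFAULT_SPACING_MM = 0.0607

#: Density threshold (mgHA/cm^3) separating bone from soft tissue / noise,
#: reused for moment-based registration initialization.
BONE_FOREGROUND_THRESHOLD = 125.0

Interpolator = Literal["cubic", "linear", "nearest"]

_SITK_INTERP = {
    "cubic": sitk.sitkBSpline,
    "linear": sitk.sitkLinear,
    "nearest": sitk.sitkNearestNeighbor,
}


def _as_tuple3(value, name: str) -> tuple[float, float, float]:
    arr = np.asarray(value, dtype=float).reshape(-1)
    if arr.size != 3:
        raise GeometryError(f"{name} must have 3 components, got {arr.size}")
    return (float(arr[0]), float(arr[1]), float(arr[2]))


@dataclass
class DensityImage:
    """3D grey-scale density volume in mgHA/cm^3.

    Parameters
    ----------
    voxels
        Array of shape ``(nx, ny, nz)``; the third axis is axial.
    spacing
        Physical voxel size per axis in mm (all > 0).
    origin
        Physical position of voxel ``(0, 0, 0)`` in mm.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (DEFAULT_SPACING_MM,) * 3
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise DimensionalityError(
                f"expected a 3D volume, got {self.voxels.ndim}D"
            )
        if min(self.voxels.shape) < 1:
            raise DimensionalityError("every axis must have >= 1 voxel")
        self.spacing = _as_tuple3(self.spacing, "spacing")
        self.origin = _as_tuple3(self.origin, "origin")
        if any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacing must be positive, got {self.spacing}")
        if np.issubdtype(self.voxels.dtype, np.floating) and not np.all(
            np.isfinite(self.voxels)
        ):
            raise ValueError("voxel values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    def index_to_physical(self, index) -> np.ndarray:
        """Physical coordinates (mm) of a (possibly fractional) voxel index."""
        return np.asarray(self.origin) + np.asarray(self.spacing) * np.asarray(
            index, dtype=float
        )

    def physical_to_index(self, point) -> np.ndarray:
        return (np.asarray(point, dtype=float) - np.asarray(self.origin)) / np.asarray(
            self.spacing
        )

    def same_grid(self, other: "DensityImage | BinaryMask") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=1e-9)
            and np.allclose(self.origin, other.origin, atol=1e-6)
        )

    def to_sitk(self) -> sitk.Image:
        img = sitk.GetImageFromArray(
            np.ascontiguousarray(self.voxels.astype(np.float64).transpose(2, 1, 0))
        )
        img.SetSpacing(self.spacing)
        img.SetOrigin(self.origin)
        return img

    @classmethod
    def from_sitk(cls, img: sitk.Image) -> "DensityImage":
        arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
        return cls(
            voxels=arr.astype(np.float64),
            spacing=tuple(img.GetSpacing()),
            origin=tuple(img.GetOrigin()),
        )

    def copy(self) -> "DensityImage":
        return replace(self, voxels=self.voxels.copy())


@dataclass
class BinaryMask:
    """Boolean voxel grid sharing the geometry conventions of DensityImage."""

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (DEFAULT_SPACING_MM,) * 3
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels).astype(bool)
        if self.voxels.ndim != 3:
            raise DimensionalityError(
                f"expected a 3D mask, got {self.voxels.ndim}D"
            )
        self.spacing = _as_tuple3(self.spacing, "spacing")
        self.origin = _as_tuple3(self.origin, "origin")
        if any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    def count(self) -> int:
        return int(self.voxels.sum())

    same_grid = DensityImage.same_grid
    index_to_physical = DensityImage.index_to_physical
    physical_to_index = DensityImage.physical_to_index

    def to_sitk(self) -> sitk.Image:
        img = sitk.GetImageFromArray(
            np.ascontiguousarray(
                self.voxels.astype(np.uint8).transpose(2, 1, 0)
            )
        )
        img.SetSpacing(self.spacing)
        img.SetOrigin(self.origin)
        return img

    @classmethod
    def from_sitk(cls, img: sitk.Image) -> "BinaryMask":
        arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
        return cls(
            voxels=arr > 0,
            spacing=tuple(img.GetSpacing()),
            origin=tuple(img.GetOrigin()),
        )


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion mapping moving-image physical space to fixed space.

    A point ``x`` (mm) maps to ``R @ (x - c) + c + t`` where ``R`` is a
    proper rotation, ``c`` the rotation center and ``t`` the translation.
    """

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "rotation", np.asarray(self.rotation, dtype=float).reshape(3, 3)
        )
        object.__setattr__(
            self, "translation", np.asarray(self.translation, dtype=float).reshape(3)
        )
        object.__setattr__(
            self, "center", np.asarray(self.center, dtype=float).reshape(3)
        )
        R = self.rotation
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-6):
            raise TransformError("rotation matrix is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-6):
            raise TransformError("rotation matrix must have determinant +1")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def from_euler(
        cls,
        angles_deg,
        translation_mm,
        center_mm=(0.0, 0.0, 0.0),
        order: str = "xyz",
    ) -> "RigidTransform":
        """Build from extrinsic Euler angles in degrees."""
        R = Rotation.from_euler(order, np.asarray(angles_deg, float), degrees=True)
        return cls(
            rotation=R.as_matrix(),
            translation=np.asarray(translation_mm, float),
            center=np.asarray(center_mm, float),
        )

    def apply(self, points) -> np.ndarray:
        """Transform physical points of shape (..., 3)."""
        pts = np.asarray(points, dtype=float)
        return (pts - self.center) @ self.rotation.T + self.center + self.translation

    def inverse(self) -> "RigidTransform":
        Rinv = self.rotation.T
        # y = R (x - c) + c + t  =>  x = R^T (y - c - t) + c
        return RigidTransform(
            rotation=Rinv, translation=-(Rinv @ self.translation), center=self.center
        )

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform applying ``other`` first, then ``self``."""
        # self(other(x)) expressed about self's center
        R = self.rotation @ other.rotation
        c = self.center
        t = (
            self.rotation
            @ (other.apply(c) - c)
            + self.translation
        )
        return RigidTransform(rotation=R, translation=t, center=c)

    def matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix acting on physical column vectors."""
        M = np.eye(4)
        M[:3, :3] = self.rotation
        M[:3, 3] = (
            self.center + self.translation - self.rotation @ self.center
        )
        return M

    def rotation_angle_deg(self) -> float:
        """Magnitude of the rotation in degrees."""
        return float(
            np.degrees(np.linalg.norm(Rotation.from_matrix(self.rotation).as_rotvec()))
        )

    def euler_deg(self, order: str = "xyz") -> np.ndarray:
        return Rotation.from_matrix(self.rotation).as_euler(order, degrees=True)

    def to_sitk(self) -> sitk.AffineTransform:
        tx = sitk.AffineTransform(3)
        tx.SetMatrix(self.rotation.ravel())
        tx.SetCenter(self.center)
        tx.SetTranslation(self.translation)
        return tx


@dataclass
class RegistrationResult:
    """Outcome of one rigid registration."""

    transform: RigidTransform
    final_metric: float
    converged: bool
    iterations: int

    def __post_init__(self) -> None:
        if not -1.0 - 1e-9 <= self.final_metric <= 1.0 + 1e-9:
            raise ValueError(
                f"correlation metric must lie in [-1, 1], got {self.final_metric}"
            )
        self.final_metric = float(np.clip(self.final_metric, -1.0, 1.0))


# --------------------------------------------------------------------------
# File I/O
# --------------------------------------------------------------------------

_FORMAT_EXT = {
    "mha": (".mha", ".mhd"),
    "nifti": (".nii", ".nii.gz"),
}


def _infer_format(path: Path) -> str:
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    if name.endswith((".mha", ".mhd")):
        return "mha"
    raise IOError(f"cannot infer image format from '{path.name}'")


def read_image(path, format: str | None = None) -> DensityImage:
    """Read a 3D scalar image (MetaImage or NIfTI-1) as a DensityImage.

    Integer-stored files are converted to floating density values unchanged.
    A warning is logged when the voxel spacing is anisotropic.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"image file not found: {path}")
    if format is None:
        format = _infer_format(path)
    if format not in _FORMAT_EXT:
        raise IOError(f"unsupported format '{format}'")
    img = sitk.ReadImage(str(path))
    if img.GetDimension() != 3:
        raise DimensionalityError(
            f"{path.name}: expected a 3D image, got {img.GetDimension()}D"
        )
    if img.GetNumberOfComponentsPerPixel() != 1:
        raise DimensionalityError(f"{path.name}: expected a scalar image")
    out = DensityImage.from_sitk(img)
    sp = out.spacing
    if not (np.isclose(sp[0], sp[1]) and np.isclose(sp[0], sp[2])):
        logger.warning("%s: non-isotropic voxel spacing %s mm", path.name, sp)
        warnings.warn(
            f"{path.name}: non-isotropic voxel spacing {sp} mm", stacklevel=2
        )
    return out


def read_mask(path, format: str | None = None) -> BinaryMask:
    """Read a binary mask stored as an 8-bit {0,1} volume."""
    img = read_image(path, format=format)
    return BinaryMask(img.voxels > 0.5, spacing=img.spacing, origin=img.origin)


def write_image(image: DensityImage | BinaryMask, path, format: str | None = None) -> None:
    """Write an image or mask; masks are stored as 8-bit {0,1}."""
    path = Path(path)
    if not path.parent.exists():
        raise IOError(f"parent directory does not exist: {path.parent}")
    if format is None:
        format = _infer_format(path)
    if not path.name.lower().endswith(_FORMAT_EXT[format]):
        raise IOError(f"path '{path.name}' does not match format '{format}'")
    sitk.WriteImage(image.to_sitk(), str(path))


def write_transform(result: RegistrationResult, matrix_path, sidecar_path=None) -> None:
    """Serialize a transform as a 4x4 text matrix plus a JSON sidecar."""
    matrix_path = Path(matrix_path)
    np.savetxt(matrix_path, result.transform.matrix(), fmt="%.12g")
    if sidecar_path is None:
        sidecar_path = matrix_path.with_suffix(".json")
    sidecar = {
        "center_mm": list(result.transform.center),
        "final_metric": result.final_metric,
        "converged": result.converged,
        "iterations": result.iterations,
    }
    Path(sidecar_path).write_text(json.dumps(sidecar, indent=2))


def read_transform(matrix_path, sidecar_path=None) -> RegistrationResult:
    matrix_path = Path(matrix_path)
    M = np.loadtxt(matrix_path)
    if M.shape != (4, 4):
        raise TransformError(f"{matrix_path.name}: expected a 4x4 matrix")
    if sidecar_path is None:
        sidecar_path = matrix_path.with_suffix(".json")
    meta = json.loads(Path(sidecar_path).read_text())
    center = np.asarray(meta.get("center_mm", [0.0, 0.0, 0.0]))
    R = M[:3, :3]
    # offset = c + t - R c  =>  t = offset - c + R c
    t = M[:3, 3] - center + R @ center
    tf = RigidTransform(rotation=R, translation=t, center=center)
    return RegistrationResult(
        transform=tf,
        final_metric=float(meta.get("final_metric", 0.0)),
        converged=bool(meta.get("converged", False)),
        iterations=int(meta.get("iterations", 0)),
    )


# --------------------------------------------------------------------------
# Resampling and moments
# --------------------------------------------------------------------------


def resample_rigid(
    image: DensityImage,
    transform: RigidTransform,
    reference: DensityImage,
    interpolator: Interpolator = "cubic",
    fill_value: float = 0.0,
) -> DensityImage:
    """Resample ``image`` under a rigid motion onto the reference grid.

    The transform maps the moving image's physical space into the fixed
    (reference) space, i.e. the image content moves by ``transform``.
    Voxels whose pre-image lies outside the moving extent receive
    ``fill_value`` (0 mgHA/cm^3 = air by default).
    """
    if interpolator not in _SITK_INTERP:
        raise ValueError(f"unknown interpolator '{interpolator}'")
    out = sitk.Resample(
        image.to_sitk(),
        reference.to_sitk(),
        transform.inverse().to_sitk(),
        _SITK_INTERP[interpolator],
        float(fill_value),
        sitk.sitkFloat64,
    )
    res = DensityImage.from_sitk(out)
    np.nan_to_num(res.voxels, copy=False, nan=fill_value)
    return res


def _foreground(image: DensityImage, threshold: float):
    mask = image.voxels >= threshold
    if not mask.any():
        raise DegenerateInputError(
            f"no voxels at or above {threshold} mgHA/cm^3"
        )
    return mask


def center_of_mass(
    image: DensityImage, threshold: float = BONE_FOREGROUND_THRESHOLD
) -> np.ndarray:
    """Intensity-weighted centroid of foreground voxels in physical mm."""
    mask = _foreground(image, threshold)
    idx = np.argwhere(mask).astype(float)
    w = image.voxels[mask].astype(float)
    centroid_idx = (idx * w[:, None]).sum(axis=0) / w.sum()
    return image.index_to_physical(centroid_idx)


def principal_axes(
    image: DensityImage, threshold: float = BONE_FOREGROUND_THRESHOLD
) -> np.ndarray:
    """Principal axes of the intensity-weighted second-moment tensor.

    Columns are eigenvectors ordered by descending eigenvalue; each
    column's largest-magnitude component is made positive.  Near-degenerate
    tensors (e.g. a sphere) fall back to identity axes with a warning.
    """
    mask = _foreground(image, threshold)
    idx = np.argwhere(mask).astype(float)
    pts = idx * np.asarray(image.spacing) + np.asarray(image.origin)
    w = image.voxels[mask].astype(float)
    w = w / w.sum()
    com = (pts * w[:, None]).sum(axis=0)
    d = pts - com
    cov = (d * w[:, None]).T @ d
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    spread = (evals[0] - evals[-1]) / max(evals[0], 1e-30)
    gaps = np.diff(evals[::-1])[::-1]
    if spread < 1e-6 or np.any(np.abs(gaps) / max(evals[0], 1e-30) < 1e-3):
        warnings.warn(
            "moment tensor is (near-)degenerate; returning identity axes",
            stacklevel=2,
        )
        return np.eye(3)
    for j in range(3):
        k = np.argmax(np.abs(evecs[:, j]))
        if evecs[k, j] < 0:
            evecs[:, j] = -evecs[:, j]
    return evecs
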