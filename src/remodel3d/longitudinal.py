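"""Longitudinal registration: align a follow-up scan to its baseline and
produce the largest-common-volume (LCV) masked pair for remodeling analysis.

Per bone (metacarpal or phalanx), the periosteal mask is dilated and used
to crop the bone with a border of background; the follow-up crop is then
rigidly registered to the baseline crop (mass-center/moment initialization,
simplex search maximizing correlation), resampled with cubic interpolation,
and both images are masked to the LCV — the baseline-grid voxels whose
pre-image lies inside the follow-up extent.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import ndimage
from skimage.morphology import ball

from .core import (
    BONE_FOREGROUND_THRESHOLD,
    BinaryMask,
    DensityImage,
    RegistrationResult,
    RigidTransform,
    resample_rigid,
)
from .errors import DegenerateInputError, GeometryError
from .registration import RegistrationConfig, register_rigid

logger = logging.getLogger(__name__)

#: Default dilation radius (voxels) applied to the periosteal mask.
DEFAULT_DILATION_VOXELS = 5

#: Border of background voxels kept around the dilated mask when cropping.
DEFAULT_BORDER_VOXELS = 5

InterpolationMode = Literal["moving_only", "both"]


@dataclass
class RegisteredPair:
    """A baseline/follow-up pair on one grid, masked to their common volume."""

    baseline: DensityImage
    followup_transformed: DensityImage
    lcv_mask: BinaryMask
    transform: RigidTransform
    interpolation_mode: InterpolationMode

    def __post_init__(self) -> None:
        if not self.baseline.same_grid(self.followup_transformed):
            raise GeometryError("baseline and follow-up must share one grid")
        if not self.baseline.same_grid(self.lcv_mask):
            raise GeometryError("LCV mask must live on the pair's grid")
        if not self.lcv_mask.voxels.any():
            raise DegenerateInputError("largest common volume is empty")


def crop_to_bone(
    image: DensityImage,
    periosteal_mask: BinaryMask,
    dilation_voxels: int = DEFAULT_DILATION_VOXELS,
    border_voxels: int = DEFAULT_BORDER_VOXELS,
) -> tuple[DensityImage, BinaryMask]:
    """Crop one bone out of a scan using its dilated periosteal mask.

    The mask is dilated with a ball structuring element, the image is
    cropped to the dilated mask's bounding box expanded by
    ``border_voxels`` of background on all sides (clamped at the volume
    boundary with a warning), and voxels outside the dilated mask are
    set to 0.  Returns the cropped image and the cropped dilated mask.
    """
    if not periosteal_mask.voxels.any():
        raise DegenerateInputError("periosteal mask is empty")
    if not image.same_grid(periosteal_mask):
        raise GeometryError("periosteal mask grid differs from the image grid")

    if dilation_voxels > 0:
        dilated = ndimage.binary_dilation(
            periosteal_mask.voxels, structure=ball(dilation_voxels)
        )
    else:
        dilated = periosteal_mask.voxels.copy()

    fg = np.argwhere(dilated)
    lo = fg.min(axis=0) - border_voxels
    hi = fg.max(axis=0) + 1 + border_voxels
    clamped_lo = np.maximum(lo, 0)
    clamped_hi = np.minimum(hi, image.shape)
    if (clamped_lo != lo).any() or (clamped_hi != hi).any():
        warnings.warn(
            "crop region clamped at the image boundary; the background "
            "border is incomplete there",
            stacklevel=2,
        )
    sl = tuple(slice(int(a), int(b)) for a, b in zip(clamped_lo, clamped_hi))
    vox = image.voxels[sl].copy()
    dil = dilated[sl]
    vox[~dil] = 0.0
    origin = image.index_to_physical(clamped_lo)
    spacing = image.spacing
    return (
        DensityImage(vox, spacing, tuple(origin)),
        BinaryMask(dil.copy(), spacing, tuple(origin)),
    )


def auto_periosteal_mask(
    image: DensityImage,
    threshold: float = BONE_FOREGROUND_THRESHOLD,
    closing_radius: int = 5,
) -> BinaryMask:
    """Convenience periosteal mask: threshold + morphological closing +
    hole filling.

    Non-canonical: the reference periosteal contour comes from the
    scanner's standard evaluation (or, for phantoms, from ground truth);
    this helper only approximates it for data where none is available.
    """
    fg = image.voxels >= threshold
    if closing_radius > 0:
        fg = ndimage.binary_closing(fg, structure=ball(closing_radius))
    fg = ndimage.binary_fill_holes(fg)
    return BinaryMask(fg, image.spacing, image.origin)


def register_longitudinal(
    baseline_crop: DensityImage,
    followup_crop: DensityImage,
    config: RegistrationConfig | None = None,
) -> RegistrationResult:
    """Rigidly register the follow-up crop (moving) to the baseline crop
    (fixed): mass-center/moment-of-inertia initialization, then simplex
    optimization of the correlation coefficient."""
    return register_rigid(baseline_crop, followup_crop, config)


def _inside_extent_mask(
    reference: DensityImage, moving: DensityImage, transform: RigidTransform
) -> np.ndarray:
    """Reference-grid voxels whose pre-image lies inside the moving extent."""
    inv = transform.inverse()
    nx, ny, nz = reference.shape
    sp = np.asarray(reference.spacing)
    org = np.asarray(reference.origin)
    # Map the reference axes through the inverse transform analytically:
    # x_mov = Rinv (x_ref - c) + c + t_inv is affine, so evaluate on axes
    # and broadcast.
    R, t, c = inv.rotation, inv.translation, inv.center
    base = R @ (org - c) + c + t
    ex = R[:, 0] * sp[0]
    ey = R[:, 1] * sp[1]
    ez = R[:, 2] * sp[2]
    ii = np.arange(nx)[:, None, None, None]
    jj = np.arange(ny)[None, :, None, None]
    kk = np.arange(nz)[None, None, :, None]
    pts = base + ii * ex + jj * ey + kk * ez
    lo = np.asarray(moving.origin) - 1e-6
    hi = np.asarray(moving.origin) + (np.asarray(moving.shape) - 1) * np.asarray(
        moving.spacing
    ) + 1e-6
    return np.all((pts >= lo) & (pts <= hi), axis=-1)


def apply_and_mask(
    baseline: DensityImage,
    followup: DensityImage,
    result: RegistrationResult,
    interpolation_mode: InterpolationMode = "moving_only",
    baseline_region: BinaryMask | None = None,
    force: bool = False,
) -> RegisteredPair:
    """Apply the registration and mask the pair to its common volume.

    ``moving_only``: the follow-up is resampled onto the baseline grid
    with one cubic interpolation; the baseline is untouched.  ``both``:
    the shared grid is the baseline grid shifted by half a voxel, and
    each image is resampled onto it exactly once with cubic
    interpolation, so both carry the same interpolation low-pass.

    The LCV collects the grid voxels whose pre-image under the transform
    lies inside the follow-up extent, intersected with the baseline crop
    region (and with ``baseline_region`` when given).
    """
    if not result.converged and not force:
        logger.warning(
            "registration did not converge (metric %.3f); proceeding",
            result.final_metric,
        )
    transform = result.transform
    if interpolation_mode == "moving_only":
        reference = baseline
        baseline_out = baseline
    elif interpolation_mode == "both":
        shifted_origin = tuple(
            o + 0.5 * s for o, s in zip(baseline.origin, baseline.spacing)
        )
        reference = DensityImage(
            np.zeros(baseline.shape), baseline.spacing, shifted_origin
        )
        baseline_out = resample_rigid(
            baseline, RigidTransform.identity(), reference, "cubic"
        )
    else:
        raise ValueError(f"unknown interpolation mode '{interpolation_mode}'")

    followup_out = resample_rigid(followup, transform, reference, "cubic")

    lcv = _inside_extent_mask(reference, followup, transform)
    if interpolation_mode == "both":
        lcv &= _inside_extent_mask(reference, baseline, RigidTransform.identity())
    if baseline_region is not None:
        if not baseline_region.same_grid(baseline):
            raise GeometryError("baseline_region must live on the baseline grid")
        lcv &= baseline_region.voxels
    if not lcv.any():
        raise DegenerateInputError("largest common volume is empty")

    return RegisteredPair(
        baseline=baseline_out,
        followup_transformed=followup_out,
        lcv_mask=BinaryMask(lcv, reference.spacing, reference.origin),
        transform=transform,
        interpolation_mode=interpolation_mode,
    )
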