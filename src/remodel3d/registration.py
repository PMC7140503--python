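"""Rigid registration engine shared by stack stitching and longitudinal steps.

The method: initialize from the intensity-weighted mass centers (and, when
well-conditioned, the principal axes of the moment-of-inertia tensor) of
fixed and moving images, then refine the six rigid parameters (three Euler
angles, three translations) with a derivative-free Nelder-Mead simplex
search that maximizes the Pearson correlation coefficient of overlapping
voxel intensities sampled on the fixed grid.  Voxels whose pre-image falls
outside the moving extent are excluded from the correlation rather than
filled, since fill values bias the metric.

Angles and translations are scaled so that 1 degree is commensurate with
0.1 mm; the initial simplex steps 1 degree / 0.5 mm and the search stops
when the simplex shrinks below 1e-4 in scaled units or after 500
iterations.  A 2-level multi-resolution pyramid (2x downsampling) precedes
the full-resolution search for robustness and speed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from .core import (
    BONE_FOREGROUND_THRESHOLD,
    DensityImage,
    RegistrationResult,
    RigidTransform,
    center_of_mass,
    principal_axes,
)
from .errors import DegenerateInputError

logger = logging.getLogger(__name__)

#: Scaling making 1 degree commensurate with 0.1 mm in parameter space.
TRANSLATION_SCALE_MM = 0.1

#: Minimum fraction of voxels at/above the bone threshold for registration.
MIN_FOREGROUND_FRACTION = 1e-3


@dataclass
class RegistrationConfig:
    """Tunable knobs of the simplex registration."""

    foreground_threshold: float = BONE_FOREGROUND_THRESHOLD
    max_iterations: int = 500
    xatol: float = 1e-4
    initial_step_deg: float = 1.0
    initial_step_mm: float = 0.5
    pyramid_levels: int = 2
    pyramid_shrink: int = 2
    use_principal_axes: bool = True
    min_overlap_voxels: int = 50
    #: Restrict metric sampling to the fixed foreground bounding box
    #: (expanded by a small margin); background adds cost, not signal.
    metric_roi: bool = True
    metric_roi_margin: int = 3
    #: Gaussian smoothing (in voxels) of both images for metric evaluation
    #: at the finest level.  Uncorrelated acquisition noise otherwise
    #: biases the correlation optimum: interpolating the moving image
    #: averages its noise most at half-voxel offsets, so noisy inputs
    #: reward spurious sub-voxel (especially axial-rotation) offsets.
    metric_smoothing_voxels: float = 0.5


def _check_foreground(image: DensityImage, threshold: float, name: str) -> None:
    frac = float((image.voxels >= threshold).mean())
    if frac < MIN_FOREGROUND_FRACTION:
        raise DegenerateInputError(
            f"{name} image has foreground fraction {frac:.2e} "
            f"(< {MIN_FOREGROUND_FRACTION:.0e}) at {threshold} mgHA/cm^3"
        )


def _foreground_roi(
    img: sitk.Image, threshold: float, margin: int
) -> sitk.Image:
    """Crop to the bounding box of voxels >= threshold, with a margin."""
    arr = sitk.GetArrayFromImage(img)  # (z, y, x)
    fg = np.argwhere(arr >= threshold)
    if fg.size == 0:
        return img
    lo = np.maximum(fg.min(axis=0) - margin, 0)
    hi = np.minimum(fg.max(axis=0) + margin + 1, arr.shape)
    # sitk indexing is (x, y, z)
    index = [int(lo[2]), int(lo[1]), int(lo[0])]
    size = [int(hi[2] - lo[2]), int(hi[1] - lo[1]), int(hi[0] - lo[0])]
    return sitk.RegionOfInterest(img, size, index)


def _shrink(img: sitk.Image, factor: int) -> sitk.Image:
    smoothed = sitk.SmoothingRecursiveGaussian(
        img, sigma=[0.5 * factor * s for s in img.GetSpacing()]
    )
    return sitk.BinShrink(smoothed, [factor] * 3)


def _initial_transform(
    fixed: DensityImage, moving: DensityImage, config: RegistrationConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (R0, t0, center): moment-based starting point."""
    thr = config.foreground_threshold
    com_f = center_of_mass(fixed, thr)
    com_m = center_of_mass(moving, thr)
    R0 = np.eye(3)
    if config.use_principal_axes:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ax_f = principal_axes(fixed, thr)
            ax_m = principal_axes(moving, thr)
        cand = ax_f @ ax_m.T
        # Guard against sign/ordering ambiguities of the eigenvectors: only
        # accept a candidate that is a modest proper rotation.
        if np.isclose(np.linalg.det(cand), 1.0, atol=1e-6):
            angle = np.degrees(
                np.linalg.norm(Rotation.from_matrix(cand).as_rotvec())
            )
            if angle < 10.0:
                R0 = cand
    # Map the moving mass center onto the fixed one under x -> R0(x-c)+c+t0
    center = com_f
    t0 = com_f - (R0 @ (com_m - center) + center)
    return R0, t0, center


def _params_to_transform(
    p: np.ndarray, R0: np.ndarray, t0: np.ndarray, center: np.ndarray
) -> RigidTransform:
    angles = p[:3]
    trans = p[3:] * TRANSLATION_SCALE_MM
    R = Rotation.from_euler("xyz", angles, degrees=True).as_matrix() @ R0
    return RigidTransform(rotation=R, translation=t0 + trans, center=center)


def _correlation(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom <= 0:
        return 0.0
    return float(np.clip((a * b).sum() / denom, -1.0, 1.0))


class _MetricSampler:
    """Evaluate -corr(fixed, moving∘T⁻¹) on (a pyramid level of) the fixed grid."""

    def __init__(
        self,
        fixed: sitk.Image,
        moving: sitk.Image,
        min_overlap_voxels: int,
    ) -> None:
        self.fixed = fixed
        self.moving = moving
        self.fixed_arr = sitk.GetArrayFromImage(fixed)
        self.min_overlap_voxels = min_overlap_voxels

    def __call__(self, transform: RigidTransform) -> float:
        # NaN fill marks voxels mapping (partially) outside the moving extent;
        # linear interpolation propagates the NaN, excluding border voxels.
        res = sitk.Resample(
            self.moving,
            self.fixed,
            transform.inverse().to_sitk(),
            sitk.sitkLinear,
            float("nan"),
            sitk.sitkFloat64,
        )
        arr = sitk.GetArrayFromImage(res)
        valid = np.isfinite(arr)
        if valid.sum() < self.min_overlap_voxels:
            return 1.0  # no usable overlap: worst metric
        return -_correlation(self.fixed_arr[valid], arr[valid])


def register_rigid(
    fixed: DensityImage,
    moving: DensityImage,
    config: RegistrationConfig | None = None,
) -> RegistrationResult:
    """Register ``moving`` to ``fixed``; the result transform maps moving
    physical space into fixed physical space (content moves by it).
    """
    config = config or RegistrationConfig()
    _check_foreground(fixed, config.foreground_threshold, "fixed")
    _check_foreground(moving, config.foreground_threshold, "moving")

    R0, t0, center = _initial_transform(fixed, moving, config)

    fixed_img = fixed.to_sitk()
    moving_img = moving.to_sitk()
    metric_fixed = fixed_img
    if config.metric_roi:
        metric_fixed = _foreground_roi(
            fixed_img, config.foreground_threshold, config.metric_roi_margin
        )

    levels: list[tuple[sitk.Image, sitk.Image, int]] = []
    n_levels = 1
    for lvl in range(config.pyramid_levels - 1, 0, -1):
        factor = config.pyramid_shrink**lvl
        if min(metric_fixed.GetSize()) // factor < 4:
            continue
        levels.append(
            (_shrink(metric_fixed, factor), _shrink(moving_img, factor), 0)
        )
        n_levels += 1
    # Split the iteration budget: the coarse level does the bulk of the
    # search, the fine level refines from a contracted simplex.
    if len(levels) == 0:
        budgets = [config.max_iterations]
    else:
        coarse = int(round(0.6 * config.max_iterations / len(levels)))
        budgets = [coarse] * len(levels) + [
            config.max_iterations - coarse * len(levels)
        ]
    fine_fixed, fine_moving = metric_fixed, moving_img
    if config.metric_smoothing_voxels > 0:
        fine_fixed = sitk.SmoothingRecursiveGaussian(
            metric_fixed,
            sigma=[
                config.metric_smoothing_voxels * s
                for s in metric_fixed.GetSpacing()
            ],
        )
        fine_moving = sitk.SmoothingRecursiveGaussian(
            moving_img,
            sigma=[
                config.metric_smoothing_voxels * s for s in moving_img.GetSpacing()
            ],
        )
    levels = [lv[:2] for lv in levels] + [(fine_fixed, fine_moving)]

    step = np.array(
        [config.initial_step_deg] * 3
        + [config.initial_step_mm / TRANSLATION_SCALE_MM] * 3
    )
    p = np.zeros(6)
    total_iters = 0
    converged = False
    final_metric = 0.0
    for li, (f_img, m_img) in enumerate(levels):
        sampler = _MetricSampler(f_img, m_img, config.min_overlap_voxels)

        def objective(q: np.ndarray) -> float:
            return sampler(_params_to_transform(q, R0, t0, center))

        simplex = np.vstack([p] + [p + step * e for e in np.eye(6)])
        res = minimize(
            objective,
            p,
            method="Nelder-Mead",
            options={
                "maxiter": budgets[li],
                "xatol": config.xatol,
                "fatol": 1e-9,
                "initial_simplex": simplex,
                "adaptive": True,
            },
        )
        p = res.x
        total_iters += int(res.nit)
        converged = bool(res.success)
        final_metric = -float(res.fun)
        # Tighter start simplex on the next (finer) level
        step = np.maximum(step / 4.0, 1e-3)
        logger.debug(
            "level %d/%d: metric=%.6f iters=%d", li + 1, len(levels), final_metric, res.nit
        )

    transform = _params_to_transform(p, R0, t0, center)
    return RegistrationResult(
        transform=transform,
        final_metric=float(np.clip(final_metric, -1.0, 1.0)),
        converged=converged,
        iterations=total_iters,
    )
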