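"""Multi-stack alignment: register overlapping acquisition stacks and
concatenate them into one contiguous scan, removing stack-shift artifact.

The acquisition protocol images three 10.2 mm axial sections ("stacks")
with a 25 % (2.55 mm) overlap between neighbours, for a 25.5 mm total
length.  Patient motion between stacks misaligns them; here the proximal
and distal stacks are rigidly registered to the middle stack over the
nominal overlap slabs, resampled into middle-stack space with cubic
interpolation, and concatenated (the middle stack keeps its overlap
slices; proximal and distal contribute only their non-overlap remainder).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .core import (
    BONE_FOREGROUND_THRESHOLD,
    BinaryMask,
    DensityImage,
    RegistrationResult,
    resample_rigid,
)
from .errors import (
    DegenerateInputError,
    GeometryError,
    ParameterError,
    StitchingError,
)
from .registration import RegistrationConfig, register_rigid

logger = logging.getLogger(__name__)

#: Nominal axial stack length of the scanning protocol (mm).
DEFAULT_STACK_LENGTH_MM = 10.2

#: Nominal overlap between adjacent stacks as a fraction of stack length.
DEFAULT_OVERLAP_FRACTION = 0.25

#: Final correlation below which a stitch is flagged for visual review.
REVIEW_METRIC_THRESHOLD = 0.5


@dataclass
class StackSet:
    """Three overlapping stacks of one scan, ordered along the axial axis.

    The distal stack sits at low z, the proximal at high z (axial index
    increases distal to proximal).  Motion scores are the manufacturer's
    1 (none) to 5 (severe) visual grades, one per stack, in
    (distal, middle, proximal) order.
    """

    distal: DensityImage
    middle: DensityImage
    proximal: DensityImage
    overlap_fraction: float = DEFAULT_OVERLAP_FRACTION
    stack_length_mm: float = DEFAULT_STACK_LENGTH_MM
    motion_scores: tuple[int, int, int] = (1, 1, 1)

    def __post_init__(self) -> None:
        if not 0.0 < self.overlap_fraction <= 0.5:
            raise ParameterError(
                f"overlap_fraction must lie in (0, 0.5], got {self.overlap_fraction}"
            )
        if any(not 1 <= int(s) <= 5 for s in self.motion_scores):
            raise ParameterError(
                f"motion scores must be integers 1-5, got {self.motion_scores}"
            )
        ref = self.middle
        for name, st in (("distal", self.distal), ("proximal", self.proximal)):
            if st.shape[:2] != ref.shape[:2] or not np.allclose(
                st.spacing, ref.spacing
            ):
                raise GeometryError(
                    f"{name} stack in-plane grid/spacing differs from middle"
                )
        for name, st in self.stacks():
            extent = st.shape[2] * st.spacing[2]
            if abs(extent - self.stack_length_mm) > st.spacing[2]:
                raise GeometryError(
                    f"{name} stack axial extent {extent:.3f} mm differs from "
                    f"stack_length {self.stack_length_mm} mm by more than one voxel"
                )

    def stacks(self):
        return (
            ("distal", self.distal),
            ("middle", self.middle),
            ("proximal", self.proximal),
        )


@dataclass
class StitchedScan:
    """A stitched scan with its per-stack transforms and provenance."""

    image: DensityImage
    transforms: dict[str, RegistrationResult]
    seam_indices: tuple[int, int]
    provenance: dict[str, Any] = field(default_factory=dict)


def overlap_slices(stack: DensityImage, overlap_fraction: float) -> int:
    """Thickness of the nominal overlap slab in axial slices."""
    if overlap_fraction <= 0:
        raise ParameterError(
            f"overlap_fraction must be positive, got {overlap_fraction}"
        )
    n = stack.shape[2]
    length_mm = n * stack.spacing[2]
    m = int(round(overlap_fraction * length_mm / stack.spacing[2]))
    if m < 1:
        raise ParameterError("overlap slab has zero thickness")
    if m >= n:
        raise ParameterError("overlap slab covers the entire stack")
    return m


def overlap_region(
    stack_a: DensityImage,
    stack_b: DensityImage,
    overlap_fraction: float = DEFAULT_OVERLAP_FRACTION,
) -> tuple[BinaryMask, BinaryMask]:
    """Masks selecting the nominal overlap slab of two adjacent stacks.

    ``stack_a`` is the more distal stack (lower z): its top slices overlap
    the bottom slices of ``stack_b``.  Slab thickness is
    ``round(overlap_fraction * stack_length / spacing_z)`` slices.
    """
    m = overlap_slices(stack_a, overlap_fraction)
    mask_a = np.zeros(stack_a.shape, dtype=bool)
    mask_a[:, :, -m:] = True
    mask_b = np.zeros(stack_b.shape, dtype=bool)
    mask_b[:, :, :m] = True
    return (
        BinaryMask(mask_a, stack_a.spacing, stack_a.origin),
        BinaryMask(mask_b, stack_b.spacing, stack_b.origin),
    )


def _extract_slab(stack: DensityImage, zslice: slice) -> DensityImage:
    vox = stack.voxels[:, :, zslice]
    start = zslice.indices(stack.shape[2])[0]
    origin = list(stack.origin)
    origin[2] += start * stack.spacing[2]
    return DensityImage(vox.copy(), stack.spacing, tuple(origin))


def register_stack_pair(
    fixed_overlap: DensityImage,
    moving_overlap: DensityImage,
    config: RegistrationConfig | None = None,
) -> RegistrationResult:
    """Register the moving overlap slab to the fixed one.

    Both slabs must contain bone (foreground fraction >= 0.1 % at
    125 mgHA/cm^3).  Initialization uses mass centers and moments of
    inertia; the six rigid parameters are then refined by Nelder-Mead
    simplex search maximizing the correlation coefficient.
    """
    return register_rigid(fixed_overlap, moving_overlap, config)


def seam_discontinuity(
    image: DensityImage,
    seam_index: int,
    threshold: float = BONE_FOREGROUND_THRESHOLD,
) -> float:
    """Mean absolute density jump across the seam plane.

    Averaged over in-plane positions where either side of the seam is
    foreground; background-to-background voxels carry no information
    about the artifact.
    """
    a = image.voxels[:, :, seam_index - 1]
    b = image.voxels[:, :, seam_index]
    sel = (a >= threshold) | (b >= threshold)
    if not sel.any():
        return 0.0
    return float(np.abs(a[sel] - b[sel]).mean())


def _stitched_reference(stacks: StackSet, m: int) -> tuple[DensityImage, int, int]:
    """Empty stitched grid in middle-stack space; returns (grid, n, step)."""
    n = stacks.middle.shape[2]
    step = n - m
    nz = 3 * n - 2 * m
    origin = list(stacks.middle.origin)
    origin[2] -= step * stacks.middle.spacing[2]
    grid = DensityImage(
        np.zeros(stacks.middle.shape[:2] + (nz,)),
        stacks.middle.spacing,
        tuple(origin),
    )
    return grid, n, step


def naive_concatenate(stacks: StackSet) -> DensityImage:
    """Concatenate the stacks at their nominal offsets without registration.

    The middle stack keeps its overlap slices; distal and proximal
    contribute their non-overlap remainders.  This reproduces the
    stack-shift artifact that registration removes.
    """
    m = overlap_slices(stacks.middle, stacks.overlap_fraction)
    grid, n, step = _stitched_reference(stacks, m)
    out = grid.voxels
    out[:, :, :step] = stacks.distal.voxels[:, :, :step]
    out[:, :, step : step + n] = stacks.middle.voxels
    out[:, :, step + n :] = stacks.proximal.voxels[:, :, m:]
    return grid


def align_stacks(
    stacks: StackSet,
    config: RegistrationConfig | None = None,
) -> StitchedScan:
    """Register distal and proximal stacks to the middle stack and stitch.

    Registration runs on the nominal overlap slabs; the resulting
    transform is applied to the whole stack, which is resampled into
    middle-stack space with cubic interpolation.  The middle stack is
    copied verbatim (including both overlap slabs); distal and proximal
    contribute their non-overlap remainder.
    """
    m = overlap_slices(stacks.middle, stacks.overlap_fraction)
    n = stacks.middle.shape[2]

    results: dict[str, RegistrationResult] = {}
    for name, moving_stack, fixed_slab, moving_slab in (
        (
            "distal",
            stacks.distal,
            _extract_slab(stacks.middle, slice(0, m)),
            _extract_slab(stacks.distal, slice(n - m, n)),
        ),
        (
            "proximal",
            stacks.proximal,
            _extract_slab(stacks.middle, slice(n - m, n)),
            _extract_slab(stacks.proximal, slice(0, m)),
        ),
    ):
        try:
            results[name] = register_stack_pair(fixed_slab, moving_slab, config)
        except DegenerateInputError as exc:
            raise StitchingError(
                f"registration of the {name} stack failed: {exc}"
            ) from exc

    grid, n, step = _stitched_reference(stacks, m)
    # Distal piece: slices [0, step) of the stitched grid
    distal_ref = _extract_slab(grid, slice(0, step))
    distal_res = resample_rigid(
        stacks.distal, results["distal"].transform, distal_ref, "cubic"
    )
    # Proximal piece: slices [step + n, 3n - 2m)
    prox_ref = _extract_slab(grid, slice(step + n, grid.shape[2]))
    prox_res = resample_rigid(
        stacks.proximal, results["proximal"].transform, prox_ref, "cubic"
    )
    out = grid.voxels
    out[:, :, :step] = distal_res.voxels
    out[:, :, step : step + n] = stacks.middle.voxels
    out[:, :, step + n :] = prox_res.voxels

    seams = (step, step + n)
    provenance = {
        "overlap_fraction": stacks.overlap_fraction,
        "stack_length_mm": stacks.stack_length_mm,
        "overlap_slices": m,
        "motion_scores": list(stacks.motion_scores),
        "metrics": {k: r.final_metric for k, r in results.items()},
        "converged": {k: r.converged for k, r in results.items()},
        "review_required": any(
            r.final_metric < REVIEW_METRIC_THRESHOLD for r in results.values()
        ),
    }
    if provenance["review_required"]:
        logger.warning(
            "stitch flagged for review: correlation below %.2f (%s)",
            REVIEW_METRIC_THRESHOLD,
            provenance["metrics"],
        )
    return StitchedScan(
        image=grid, transforms=results, seam_indices=seams, provenance=provenance
    )
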