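"""Voxel-wise bone remodeling quantification from a registered scan pair.

The follow-up is subtracted from the baseline to form a resorption
difference image and vice versa for formation; each difference is
segmented at a strictly-greater threshold of 125 mgHA/cm^3 inside the
largest common volume, de-noised with a connected-component filter
removing clusters smaller than 5 voxels (26-connectivity), and the
surviving voxels are expressed as a percentage of the baseline bone
voxels inside the LCV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from skimage.measure import label

from .core import BinaryMask, DensityImage
from .errors import DegenerateInputError, GeometryError, ParameterError
from .longitudinal import RegisteredPair

#: Density-difference threshold (mgHA/cm^3) above which a voxel counts as
#: formed or resorbed bone.
DEFAULT_DIFF_THRESHOLD = 125.0

#: Alternative threshold from earlier first-generation work on the radius
#: and tibia; exposed only as a configurable preset.
LEGACY_DIFF_THRESHOLD = 225.0

#: Minimum connected-cluster size (voxels) surviving the noise filter.
DEFAULT_MIN_CLUSTER_VOXELS = 5

#: Baseline bone segmentation threshold (mgHA/cm^3) used for the overlay
#: and as the fraction denominator.
DEFAULT_BONE_THRESHOLD = 320.0

_CONNECTIVITY_TO_SKIMAGE = {6: 1, 18: 2, 26: 3}

DenominatorMode = Literal["baseline_bone", "lcv_total"]


@dataclass(frozen=True)
class RemodelingParams:
    """Parameters of the remodeling analysis."""

    diff_threshold: float = DEFAULT_DIFF_THRESHOLD
    min_cluster_voxels: int = DEFAULT_MIN_CLUSTER_VOXELS
    connectivity: int = 26
    bone_threshold: float = DEFAULT_BONE_THRESHOLD
    denominator: DenominatorMode = "baseline_bone"

    def __post_init__(self) -> None:
        if self.diff_threshold <= 0:
            raise ParameterError("diff_threshold must be > 0")
        if self.min_cluster_voxels < 1:
            raise ParameterError("min_cluster_voxels must be >= 1")
        if self.connectivity not in _CONNECTIVITY_TO_SKIMAGE:
            raise ParameterError("connectivity must be one of 6, 18, 26")
        if self.denominator not in ("baseline_bone", "lcv_total"):
            raise ParameterError(f"unknown denominator '{self.denominator}'")


@dataclass
class RemodelingResult:
    """Formation/resorption masks, their volume fractions and provenance."""

    formation_mask: BinaryMask
    resorption_mask: BinaryMask
    formation_fraction: float
    resorption_fraction: float
    baseline_bone_mask: BinaryMask
    params: RemodelingParams
    overlay: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]


def difference_images(pair: RegisteredPair) -> tuple[DensityImage, DensityImage]:
    """(resorption_diff, formation_diff), both zeroed outside the LCV.

    resorption_diff = baseline - follow-up (density lost);
    formation_diff = follow-up - baseline (density gained).
    """
    base = pair.baseline
    foll = pair.followup_transformed
    if not base.same_grid(foll):
        raise GeometryError("pair images are not on one grid")
    lcv = pair.lcv_mask.voxels
    resorption = (base.voxels - foll.voxels) * lcv
    formation = -resorption
    return (
        DensityImage(resorption, base.spacing, base.origin),
        DensityImage(formation, base.spacing, base.origin),
    )


def segment_and_filter(
    diff: DensityImage,
    params: RemodelingParams,
    lcv: BinaryMask,
) -> BinaryMask:
    """Threshold a difference image and remove small clusters.

    A voxel is kept when it lies inside the LCV and its difference is
    strictly greater than ``diff_threshold``; connected components (at
    the configured connectivity) smaller than ``min_cluster_voxels``
    are then removed.
    """
    if not diff.same_grid(lcv):
        raise GeometryError("difference image and LCV are not on one grid")
    raw = (diff.voxels > params.diff_threshold) & lcv.voxels
    if raw.any() and params.min_cluster_voxels > 1:
        labels = label(raw, connectivity=_CONNECTIVITY_TO_SKIMAGE[params.connectivity])
        counts = np.bincount(labels.ravel())
        keep = counts >= params.min_cluster_voxels
        keep[0] = False
        raw = keep[labels]
    return BinaryMask(raw, diff.spacing, diff.origin)


def compute_fractions(
    formation_mask: BinaryMask,
    resorption_mask: BinaryMask,
    baseline_bone_mask: BinaryMask,
    lcv: BinaryMask,
    denominator: DenominatorMode = "baseline_bone",
) -> tuple[float, float]:
    """Formation and resorption volume fractions in percent.

    fraction = 100 * |mask| / |baseline bone within the LCV| (or the LCV
    voxel count with ``denominator='lcv_total'``).  Empty masks yield 0.0.
    """
    for m in (formation_mask, resorption_mask, baseline_bone_mask):
        if not m.same_grid(lcv):
            raise GeometryError("all masks must share one grid")
    if denominator == "baseline_bone":
        denom = int((baseline_bone_mask.voxels & lcv.voxels).sum())
    else:
        denom = lcv.count()
    if denom == 0:
        raise DegenerateInputError("fraction denominator is empty")
    formation = 100.0 * int((formation_mask.voxels & lcv.voxels).sum()) / denom
    resorption = 100.0 * int((resorption_mask.voxels & lcv.voxels).sum()) / denom
    return formation, resorption


def make_overlay(
    formation_mask: BinaryMask,
    resorption_mask: BinaryMask,
    baseline_bone_mask: BinaryMask,
) -> np.ndarray:
    """3-label overlay: 1 = baseline bone, 2 = formation, 3 = resorption.

    Remodeling labels take precedence over the bone label; background 0.
    """
    overlay = np.zeros(baseline_bone_mask.shape, dtype=np.uint8)
    overlay[baseline_bone_mask.voxels] = 1
    overlay[formation_mask.voxels] = 2
    overlay[resorption_mask.voxels] = 3
    return overlay


def analyze_remodeling(
    pair: RegisteredPair, params: RemodelingParams | None = None
) -> RemodelingResult:
    """Full remodeling analysis of a registered pair."""
    params = params or RemodelingParams()
    lcv = pair.lcv_mask
    resorption_diff, formation_diff = difference_images(pair)
    formation = segment_and_filter(formation_diff, params, lcv)
    resorption = segment_and_filter(resorption_diff, params, lcv)
    bone = BinaryMask(
        (pair.baseline.voxels >= params.bone_threshold) & lcv.voxels,
        pair.baseline.spacing,
        pair.baseline.origin,
    )
    ff, rf = compute_fractions(
        formation, resorption, bone, lcv, denominator=params.denominator
    )
    overlay = make_overlay(formation, resorption, bone)
    return RemodelingResult(
        formation_mask=formation,
        resorption_mask=resorption,
        formation_fraction=ff,
        resorption_fraction=rf,
        baseline_bone_mask=bone,
        params=params,
        overlay=overlay,
    )


def percent(numerator: int, denominator: int, ndigits: int = 0) -> float:
    """Report a count as a percentage, rounded for display (e.g. 13/57 -> 23)."""
    if denominator <= 0:
        raise DegenerateInputError("denominator must be positive")
    return round(100.0 * numerator / denominator, ndigits)
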