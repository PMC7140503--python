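"""Remodeling quantification: differences, segmentation, fractions, overlay."""

from __future__ import annotations

import numpy as np
import pytest

from remodel3d.core import BinaryMask, DensityImage, RigidTransform
from remodel3d.errors import DegenerateInputError, ParameterError
from remodel3d.longitudinal import RegisteredPair
from remodel3d.remodeling import (
    RemodelingParams,
    analyze_remodeling,
    compute_fractions,
    difference_images,
    make_overlay,
    percent,
    segment_and_filter,
)

from conftest import bfs_label_sizes


def _pair(base_vox, foll_vox, lcv=None, spacing=(0.1, 0.1, 0.1)):
    shape = base_vox.shape
    lcv = np.ones(shape, dtype=bool) if lcv is None else lcv
    return RegisteredPair(
        baseline=DensityImage(base_vox, spacing),
        followup_transformed=DensityImage(foll_vox, spacing),
        lcv_mask=BinaryMask(lcv, spacing),
        transform=RigidTransform.identity(),
        interpolation_mode="moving_only",
    )


def _mask(vox, spacing=(0.1, 0.1, 0.1)):
    return BinaryMask(vox, spacing)


# -------------------------------------------------------- differences ----


def test_identical_images_zero_differences():
    vox = np.random.default_rng(0).normal(400, 50, (8, 8, 8))
    resorption, formation = difference_images(_pair(vox, vox.copy()))
    assert np.allclose(resorption.voxels, 0) and np.allclose(formation.voxels, 0)


def test_difference_sign_convention():
    base = np.full((6, 6, 6), 300.0)
    foll = base.copy()
    foll[2:4, 2:4, 2:4] += 200.0
    resorption, formation = difference_images(_pair(base, foll))
    assert np.all(formation.voxels[2:4, 2:4, 2:4] == 200.0)
    assert np.all(resorption.voxels[2:4, 2:4, 2:4] == -200.0)


def test_differences_are_antisymmetric_and_zero_outside_lcv():
    rng = np.random.default_rng(1)
    base, foll = rng.normal(400, 80, (8, 8, 8)), rng.normal(400, 80, (8, 8, 8))
    lcv = rng.random((8, 8, 8)) > 0.3
    resorption, formation = difference_images(_pair(base, foll, lcv))
    assert np.array_equal(resorption.voxels, -formation.voxels)
    assert np.all(resorption.voxels[~lcv] == 0)


# ------------------------------------------------- segment and filter ----


def test_threshold_is_strictly_greater():
    lcv = _mask(np.ones((5, 5, 5), dtype=bool))
    params = RemodelingParams(min_cluster_voxels=1)
    at = segment_and_filter(DensityImage(np.full((5, 5, 5), 125.0), (0.1,) * 3), params, lcv)
    below = segment_and_filter(DensityImage(np.full((5, 5, 5), 124.0), (0.1,) * 3), params, lcv)
    above = segment_and_filter(DensityImage(np.full((5, 5, 5), 125.1), (0.1,) * 3), params, lcv)
    assert at.count() == 0
    assert below.count() == 0
    assert above.count() == 125


def _hand_grid():
    """One isolated 4-voxel cluster and one 5-voxel cluster (face-connected)."""
    diff = np.zeros((12, 12, 12))
    diff[1, 1, 1:5] = 200.0  # 4 voxels
    diff[8, 8, 4:9] = 200.0  # 5 voxels
    return diff


def test_small_cluster_removed_large_survives():
    diff = DensityImage(_hand_grid(), (0.1,) * 3)
    lcv = _mask(np.ones((12, 12, 12), dtype=bool))
    out = segment_and_filter(diff, RemodelingParams(), lcv)
    # brute-force BFS oracle agrees on which clusters are >= 5 voxels
    sizes = bfs_label_sizes(diff.voxels > 125.0, connectivity=26)
    assert sizes == [4, 5]
    assert out.count() == 5
    assert out.voxels[8, 8, 4:9].all()
    assert not out.voxels[1, 1, :].any()


@pytest.mark.parametrize("connectivity,expected", [(26, 6), (18, 0), (6, 0)])
def test_diagonal_clusters_merge_by_connectivity(connectivity, expected):
    # two 3-voxel rods whose ends touch corner-to-corner: one size-6
    # component at 26-connectivity (survives the 5-voxel filter), two
    # size-3 components at 6/18-connectivity (both removed)
    diff = np.zeros((10, 10, 10))
    diff[2, 2, 2:5] = 200.0
    diff[3, 3, 4] = 0.0  # keep gap explicit
    diff[3, 3, 5:8] = 200.0  # diagonal in (x, y) from the first rod's end
    oracle = bfs_label_sizes(diff > 125.0, connectivity)
    params = RemodelingParams(connectivity=connectivity)
    out = segment_and_filter(
        DensityImage(diff, (0.1,) * 3), params, _mask(np.ones((10, 10, 10), bool))
    )
    assert out.count() == sum(s for s in oracle if s >= 5) == expected


def test_filter_respects_lcv():
    diff = np.full((6, 6, 6), 200.0)
    lcv = np.zeros((6, 6, 6), dtype=bool)
    lcv[:3] = True
    out = segment_and_filter(
        DensityImage(diff, (0.1,) * 3), RemodelingParams(), _mask(lcv)
    )
    assert np.array_equal(out.voxels, lcv)


def test_params_validation():
    with pytest.raises(ParameterError):
        RemodelingParams(diff_threshold=0.0)
    with pytest.raises(ParameterError):
        RemodelingParams(min_cluster_voxels=0)
    with pytest.raises(ParameterError):
        RemodelingParams(connectivity=4)


# ------------------------------------------------------------ fractions ----


def test_empty_masks_give_zero_fractions():
    empty = _mask(np.zeros((10, 10, 10), dtype=bool))
    bone = _mask(np.ones((10, 10, 10), dtype=bool))
    lcv = _mask(np.ones((10, 10, 10), dtype=bool))
    assert compute_fractions(empty, empty, bone, lcv) == (0.0, 0.0)


def test_fraction_arithmetic_21_of_1000():
    bone = np.zeros((10, 10, 10), dtype=bool)
    bone[:10, :10, :10] = True  # 1000 voxels
    formation = np.zeros((10, 10, 10), dtype=bool)
    formation.ravel()[:21] = True
    lcv = np.ones((10, 10, 10), dtype=bool)
    ff, rf = compute_fractions(
        _mask(formation), _mask(np.zeros_like(bone)), _mask(bone), _mask(lcv)
    )
    assert ff == pytest.approx(2.1)
    assert rf == 0.0


def test_empty_denominator_raises():
    empty = _mask(np.zeros((4, 4, 4), dtype=bool))
    lcv = _mask(np.ones((4, 4, 4), dtype=bool))
    with pytest.raises(DegenerateInputError):
        compute_fractions(empty, empty, empty, lcv)


def test_lcv_total_denominator_mode():
    bone = _mask(np.ones((4, 4, 4), dtype=bool))
    formation = np.zeros((4, 4, 4), dtype=bool)
    formation[0, 0, :2] = True
    lcv = _mask(np.ones((4, 4, 4), dtype=bool))
    ff, _ = compute_fractions(
        _mask(formation), _mask(np.zeros_like(formation)), bone, lcv,
        denominator="lcv_total",
    )
    assert ff == pytest.approx(100 * 2 / 64)


# -------------------------------------------------------------- overlay ----


def test_overlay_labels_and_precedence():
    bone = np.zeros((6, 6, 6), dtype=bool)
    bone[1:5, 1:5, 1:5] = True
    formation = np.zeros_like(bone)
    formation[2, 2, 2] = True  # inside bone: remodeling wins
    resorption = np.zeros_like(bone)
    resorption[0, 0, 0] = True
    overlay = make_overlay(_mask(formation), _mask(resorption), _mask(bone))
    assert overlay[2, 2, 2] == 2
    assert overlay[0, 0, 0] == 3
    assert overlay[1, 1, 1] == 1
    assert (overlay > 0).sum() == (bone | formation | resorption).sum()


def test_overlay_empty_masks_is_bone_only():
    bone = np.zeros((4, 4, 4), dtype=bool)
    bone[1:3, 1:3, 1:3] = True
    empty = np.zeros_like(bone)
    overlay = make_overlay(_mask(empty), _mask(empty), _mask(bone))
    assert set(np.unique(overlay)) == {0, 1}


# ------------------------------------------------------------ properties ----


def test_swapping_pair_swaps_formation_and_resorption():
    rng = np.random.default_rng(4)
    base = rng.normal(400, 150, (16, 16, 16))
    foll = base + rng.normal(0, 150, (16, 16, 16))
    fwd = analyze_remodeling(_pair(base, foll))
    bwd = analyze_remodeling(_pair(foll, base))
    assert np.array_equal(fwd.formation_mask.voxels, bwd.resorption_mask.voxels)
    assert np.array_equal(fwd.resorption_mask.voxels, bwd.formation_mask.voxels)


def test_raising_thresholds_never_increases_fractions():
    rng = np.random.default_rng(5)
    base = rng.normal(500, 150, (16, 16, 16))
    foll = base + rng.normal(0, 120, (16, 16, 16))
    fractions = []
    for thr in (75.0, 125.0, 225.0):
        res = analyze_remodeling(_pair(base, foll), RemodelingParams(diff_threshold=thr))
        fractions.append((res.formation_fraction, res.resorption_fraction))
    assert fractions[0] >= fractions[1] >= fractions[2]
    by_cluster = []
    for mc in (1, 5, 9):
        res = analyze_remodeling(
            _pair(base, foll), RemodelingParams(min_cluster_voxels=mc)
        )
        by_cluster.append((res.formation_fraction, res.resorption_fraction))
    assert by_cluster[0] >= by_cluster[1] >= by_cluster[2]


def test_null_stability_under_noise():
    # identical anatomy + Gaussian noise sigma <= 40 stays under 0.2%
    rng = np.random.default_rng(6)
    anatomy = np.clip(rng.normal(500, 200, (32, 32, 32)), 0, None)
    base = anatomy + rng.normal(0, 40, anatomy.shape)
    foll = anatomy + rng.normal(0, 40, anatomy.shape)
    res = analyze_remodeling(_pair(base, foll))
    assert res.formation_fraction <= 0.2
    assert res.resorption_fraction <= 0.2


def test_masks_confined_to_lcv_and_disjoint():
    rng = np.random.default_rng(7)
    base = rng.normal(500, 200, (16, 16, 16))
    foll = base + rng.normal(0, 200, (16, 16, 16))
    lcv = rng.random((16, 16, 16)) > 0.4
    res = analyze_remodeling(_pair(base, foll, lcv))
    assert not (res.formation_mask.voxels & res.resorption_mask.voxels).any()
    assert not (res.formation_mask.voxels & ~lcv).any()
    assert not (res.resorption_mask.voxels & ~lcv).any()


# ------------------------------------------------------ percent utility ----


@pytest.mark.parametrize(
    "num,den,expected",
    [(13, 57, 23), (8, 15, 53), (9, 20, 45), (1, 3, 33), (0, 10, 0)],
)
def test_percent_rounds_to_printed_precision(num, den, expected):
    assert percent(num, den) == expected


def test_percent_rejects_zero_denominator():
    with pytest.raises(DegenerateInputError):
        percent(1, 0)
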