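"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from collections import deque

import numpy as np
import pytest

from remodel3d.core import BinaryMask, DensityImage, RigidTransform, resample_rigid
from remodel3d.phantom import PhantomSpec, make_phantom


def bfs_label_sizes(grid: np.ndarray, connectivity: int) -> list[int]:
    """Brute-force connected-component sizes via breadth-first search.

    Independent of any imaging library; used as the labeling oracle.
    Connectivity 6/18/26 counts face / face+edge / face+edge+corner
    neighbours.
    """
    offsets = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                manhattan = abs(dx) + abs(dy) + abs(dz)
                if connectivity == 6 and manhattan > 1:
                    continue
                if connectivity == 18 and manhattan > 2:
                    continue
                offsets.append((dx, dy, dz))
    seen = np.zeros_like(grid, dtype=bool)
    sizes = []
    for start in np.argwhere(grid):
        start = tuple(start)
        if seen[start]:
            continue
        queue = deque([start])
        seen[start] = True
        size = 0
        while queue:
            p = queue.popleft()
            size += 1
            for off in offsets:
                q = tuple(p[i] + off[i] for i in range(3))
                if any(c < 0 or c >= grid.shape[i] for i, c in enumerate(q)):
                    continue
                if grid[q] and not seen[q]:
                    seen[q] = True
                    queue.append(q)
        sizes.append(size)
    return sorted(sizes)


def transform_error_voxels(
    recovered: RigidTransform,
    applied: RigidTransform,
    point_mm,
    spacing_mm: float,
) -> tuple[float, float]:
    """(translation error in voxels at a point, rotation error in degrees)
    of a recovered transform against the motion it should invert."""
    residual = recovered.compose(applied)
    p = np.asarray(point_mm, dtype=float)
    terr = float(np.linalg.norm(residual.apply(p) - p)) / spacing_mm
    return terr, residual.rotation_angle_deg()


@pytest.fixture(scope="session")
def small_phantom():
    """A small capped-tube phantom with texture, PSF blur, no noise."""
    spec = PhantomSpec(shape=(64, 64, 120), cap_margin_mm=1.5, seed=5)
    return make_phantom(spec)


@pytest.fixture(scope="session")
def longitudinal_phantom():
    """The phantom used for longitudinal registration/remodeling tests:
    bone capped well inside the volume so the common-volume boundary
    stays in background under repositioning."""
    spec = PhantomSpec(shape=(80, 80, 200), cap_margin_mm=3.0, seed=3)
    return make_phantom(spec)


def add_noise(image: DensityImage, sigma: float, seed: int) -> DensityImage:
    rng = np.random.default_rng(seed)
    return DensityImage(
        np.clip(image.voxels + rng.normal(0.0, sigma, image.shape), 0.0, None),
        image.spacing,
        image.origin,
    )


def transformed_mask(
    mask: BinaryMask, transform: RigidTransform, reference: DensityImage
) -> BinaryMask:
    img = DensityImage(mask.voxels.astype(float), mask.spacing, mask.origin)
    res = resample_rigid(img, transform, reference, "nearest")
    return BinaryMask(res.voxels > 0.5, reference.spacing, reference.origin)
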