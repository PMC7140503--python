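"""Synthetic bone phantoms with known ground truth.

Every pipeline stage is validated against simulation: a tube-like long
bone (high-density cortical shell, textured trabecular interior of
periodic rods plus Gaussian anatomical jitter, optional hemispherical
cortical erosions), a three-stack acquisition simulator with per-stack
rigid motion and Gaussian acquisition noise, and a follow-up simulator
that adds known formation/resorption regions and a repositioning
transform.  All randomness is seeded; the same seed yields bit-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import BinaryMask, DensityImage, RigidTransform, resample_rigid
from .errors import GeometryError, ParameterError
from .stacks import (
    DEFAULT_OVERLAP_FRACTION,
    DEFAULT_STACK_LENGTH_MM,
    StackSet,
    overlap_slices,
)

#: Default acquisition noise (mgHA/cm^3); sub-threshold by construction
#: relative to the 125 mgHA/cm^3 remodeling threshold.
DEFAULT_NOISE_SIGMA = 30.0


@dataclass(frozen=True)
class ErosionSpec:
    """A hemispherical cortical break: center on/near the cortex, radius in mm."""

    center_mm: tuple[float, float, float]
    radius_mm: float
    crosses_seam: bool = False


@dataclass
class PhantomSpec:
    """Geometry and composition of a synthetic long-bone phantom.

    Densities in mgHA/cm^3.  The bone is an elliptic tube along z with a
    cortical shell and a trabecular interior of periodic rods; the tube is
    capped (background beyond the caps) so the bone sits wholly inside
    the field of view.
    """

    shape: tuple[int, int, int] = (80, 80, 428)
    spacing_mm: float = 0.0607
    semi_axes_mm: tuple[float, float] = (1.3, 1.0)
    cortical_thickness_mm: float = 0.35
    cortical_density: float = 900.0
    trabecular_density_mean: float = 650.0
    trabecular_density_sigma: float = 50.0
    rod_spacing_mm: float = 0.6
    rod_width_mm: float = 0.18
    marrow_density: float = 100.0
    cap_margin_mm: float = 0.0
    erosions: tuple[ErosionSpec, ...] = ()
    #: Gaussian point-spread blur emulating the scanner's band limit (mm).
    #: Zero gives an ideal piecewise-constant phantom with hard edges.
    psf_sigma_mm: float = 0.08
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cortical_density <= self.trabecular_density_mean:
            raise ParameterError(
                "cortical density must exceed the trabecular mean"
            )
        for name in (
            "cortical_density",
            "trabecular_density_mean",
            "marrow_density",
        ):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")


@dataclass
class PhantomTruth:
    """Ground truth accompanying a synthetic scan (pair)."""

    periosteal_mask: BinaryMask
    stack_motions: dict[str, RigidTransform] = field(default_factory=dict)
    formation_mask: BinaryMask | None = None
    resorption_mask: BinaryMask | None = None
    repositioning: RigidTransform | None = None


def _grids(spec: PhantomSpec):
    nx, ny, nz = spec.shape
    sp = spec.spacing_mm
    x = (np.arange(nx) - (nx - 1) / 2)[:, None, None] * sp
    y = (np.arange(ny) - (ny - 1) / 2)[None, :, None] * sp
    z = (np.arange(nz)[None, None, :]) * sp
    return x, y, z


def make_phantom(spec: PhantomSpec) -> tuple[DensityImage, PhantomTruth]:
    """Build the phantom volume and its ground-truth record."""
    rng = np.random.default_rng(spec.seed)
    nx, ny, nz = spec.shape
    sp = spec.spacing_mm
    x, y, z = _grids(spec)
    a, b = spec.semi_axes_mm
    rho = np.sqrt((x / a) ** 2 + (y / b) ** 2) + 0.0 * z

    zmin = spec.cap_margin_mm
    zmax = (nz - 1) * sp - spec.cap_margin_mm
    in_caps = (z >= zmin) & (z <= zmax) & np.ones_like(rho, bool)

    bone = (rho <= 1.0) & in_caps
    # Cortical shell with smoothly varying thickness around the
    # circumference and along the bone axis, as in real metacarpals; a
    # perfectly uniform shell would leave in-plane rotation almost
    # unconstrained for the registration, unlike real anatomy.
    shell_frac = spec.cortical_thickness_mm / min(a, b)
    theta = np.arctan2(y / b, x / a)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=4)
    thickness_mod = (
        1.0
        + 0.35 * np.sin(theta + phases[0])
        + 0.25 * np.sin(2.0 * theta + phases[1])
        + 0.20 * np.sin(2.0 * np.pi * z / 4.0 + phases[2])
        + 0.15 * np.sin(3.0 * theta + 2.0 * np.pi * z / 7.0 + phases[3])
    )
    thickness_mod = np.clip(thickness_mod, 0.3, 2.0)
    shell = bone & (rho >= 1.0 - shell_frac * thickness_mod)
    interior = bone & ~shell

    # Trabecular network: threshold a smoothed Gaussian random field.  The
    # smoothing length sets the characteristic strut spacing; the result is
    # an aperiodic rod/plate network like real trabecular bone (a strictly
    # periodic lattice would hand the registration spurious self-matches
    # that real anatomy does not have).
    from scipy.ndimage import gaussian_filter

    field_sigma_vox = max(spec.rod_spacing_mm / (2.0 * sp), 0.5)
    fieldv = gaussian_filter(
        rng.standard_normal(spec.shape), sigma=field_sigma_vox
    )
    bv_fraction = min(max(spec.rod_width_mm / spec.rod_spacing_mm * 1.5, 0.1), 0.9)
    cut = np.quantile(fieldv, 1.0 - bv_fraction)
    rods = (fieldv > cut) & interior

    vox = np.zeros(spec.shape, dtype=np.float64)
    vox[interior] = spec.marrow_density
    vox[rods] = spec.trabecular_density_mean
    vox[shell] = spec.cortical_density
    # Anatomical texture: frozen Gaussian jitter inside the bone (part of
    # the anatomy, identical across simulated scans of the same subject)
    if spec.trabecular_density_sigma > 0:
        jitter = rng.normal(0.0, spec.trabecular_density_sigma, spec.shape)
        vox[bone] += jitter[bone]

    periosteal = bone.copy()

    for ero in spec.erosions:
        cx, cy, cz = ero.center_mm
        # centers are expressed relative to the volume origin (voxel 0,0,0)
        dx = x - (cx - (nx - 1) / 2 * sp)
        dy = y - (cy - (ny - 1) / 2 * sp)
        dz = z - cz
        inside = (dx**2 + dy**2 + dz**2) <= ero.radius_mm**2
        if not (inside & bone).any():
            raise ParameterError(
                f"erosion at {ero.center_mm} mm does not intersect the bone"
            )
        vox[inside & bone] = spec.marrow_density * 0.5

    if spec.psf_sigma_mm > 0:
        from scipy.ndimage import gaussian_filter

        vox = gaussian_filter(vox, sigma=spec.psf_sigma_mm / sp)
    if spec.noise_sigma > 0:
        vox += rng.normal(0.0, spec.noise_sigma, spec.shape)
    np.clip(vox, 0.0, None, out=vox)

    image = DensityImage(vox, (sp,) * 3, (0.0, 0.0, 0.0))
    truth = PhantomTruth(
        periosteal_mask=BinaryMask(periosteal, (sp,) * 3, (0.0, 0.0, 0.0))
    )
    return image, truth


def bone_center_mm(image: DensityImage) -> np.ndarray:
    """Geometric center of the volume, a convenient rotation pivot."""
    return image.index_to_physical((np.asarray(image.shape) - 1) / 2.0)


def random_rigid_motion(
    rng: np.random.Generator,
    max_translation_mm: float,
    max_rotation_deg: float,
    center_mm,
) -> RigidTransform:
    """Draw a rigid motion with |t| <= max_translation, angle <= max_rotation."""
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    t = direction * rng.uniform(0.0, max_translation_mm)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.radians(rng.uniform(0.0, max_rotation_deg))
    from scipy.spatial.transform import Rotation

    R = Rotation.from_rotvec(axis * angle).as_matrix()
    return RigidTransform(rotation=R, translation=t, center=np.asarray(center_mm))


def simulate_stack_acquisition(
    phantom: DensityImage,
    stack_length_mm: float = DEFAULT_STACK_LENGTH_MM,
    overlap_fraction: float = DEFAULT_OVERLAP_FRACTION,
    motions: dict[str, RigidTransform] | None = None,
    noise_sigma: float = DEFAULT_NOISE_SIGMA,
    seed: int = 0,
    motion_scores: tuple[int, int, int] = (1, 1, 1),
) -> StackSet:
    """Cut three overlapping stacks from the phantom, each under its own
    rigid motion, with independent Gaussian acquisition noise.

    The motion model is one rigid transform per stack (the reconstruction
    accounts for the average position of each stack; intra-stack blur is
    out of scope).  Motions are expressed relative to the scanner frame;
    only relative inter-stack motion matters for stitching, so the middle
    stack's motion is conventionally the identity.
    """
    dz = phantom.spacing[2]
    n = int(round(stack_length_mm / dz))
    dummy = DensityImage(
        np.zeros((1, 1, n)), phantom.spacing, phantom.origin
    )
    m = overlap_slices(dummy, overlap_fraction)
    step = n - m
    if phantom.shape[2] < 2 * step + n:
        raise GeometryError(
            f"phantom axial extent {phantom.shape[2]} slices is shorter than "
            f"the 3-stack coverage of {2 * step + n} slices"
        )
    motions = motions or {}
    rng = np.random.default_rng(seed)
    cut: dict[str, DensityImage] = {}
    for i, name in enumerate(("distal", "middle", "proximal")):
        motion = motions.get(name, RigidTransform.identity())
        start = i * step
        origin = list(phantom.origin)
        origin[2] += start * dz
        ref = DensityImage(
            np.zeros(phantom.shape[:2] + (n,)), phantom.spacing, tuple(origin)
        )
        if np.allclose(motion.matrix(), np.eye(4)):
            slab = DensityImage(
                phantom.voxels[:, :, start : start + n].copy(),
                phantom.spacing,
                tuple(origin),
            )
        else:
            slab = resample_rigid(phantom, motion, ref, "cubic")
        noise = rng.normal(0.0, noise_sigma, slab.shape) if noise_sigma > 0 else 0.0
        slab = DensityImage(
            np.clip(slab.voxels + noise, 0.0, None), slab.spacing, slab.origin
        )
        cut[name] = slab
    return StackSet(
        distal=cut["distal"],
        middle=cut["middle"],
        proximal=cut["proximal"],
        overlap_fraction=overlap_fraction,
        stack_length_mm=n * dz,
        motion_scores=motion_scores,
    )


@dataclass(frozen=True)
class ChangeRegion:
    """A spherical region of simulated bone change."""

    center_mm: tuple[float, float, float]
    radius_mm: float


def simulate_followup(
    baseline: DensityImage,
    truth: PhantomTruth,
    formation_regions: tuple[ChangeRegion, ...] = (),
    resorption_regions: tuple[ChangeRegion, ...] = (),
    repositioning: RigidTransform | None = None,
    noise_sigma: float = DEFAULT_NOISE_SIGMA,
    seed: int = 0,
    formation_density: float = 650.0,
    resorption_density: float = 50.0,
    min_delta: float = 250.0,
) -> tuple[DensityImage, PhantomTruth]:
    """Simulate a follow-up scan with known remodeling and repositioning.

    Formation regions: low-density voxels (<= formation_density - min_delta)
    inside the sphere and the periosteal envelope are raised to
    ``formation_density``.  Resorption regions: high-density voxels
    (>= resorption_density + min_delta) are lowered to
    ``resorption_density``.  Every changed voxel therefore moves by at
    least ``min_delta`` (default 2 x 125 mgHA/cm^3), and the truth masks
    record exactly the changed voxels, in baseline space.

    The whole volume is then repositioned: the follow-up grid's origin
    follows the translation (the operator re-centers the anatomy), the
    content is resampled once with cubic interpolation, and acquisition
    noise is added.
    """
    vox = baseline.voxels.copy()
    sp = np.asarray(baseline.spacing)
    peri = truth.periosteal_mask.voxels

    idx = np.indices(baseline.shape, dtype=np.float64)
    coords = [idx[d] * sp[d] + baseline.origin[d] for d in range(3)]

    def sphere(region: ChangeRegion) -> np.ndarray:
        d2 = sum(
            (coords[d] - region.center_mm[d]) ** 2 for d in range(3)
        )
        return d2 <= region.radius_mm**2

    formation = np.zeros(baseline.shape, dtype=bool)
    for region in formation_regions:
        eligible = sphere(region) & peri & (vox <= formation_density - min_delta)
        formation |= eligible
    resorption = np.zeros(baseline.shape, dtype=bool)
    for region in resorption_regions:
        eligible = sphere(region) & peri & (vox >= resorption_density + min_delta)
        resorption |= eligible
    if (formation & resorption).any():
        raise ParameterError("formation and resorption regions overlap")

    vox[formation] = formation_density
    vox[resorption] = resorption_density
    changed = DensityImage(vox, baseline.spacing, baseline.origin)

    rng = np.random.default_rng(seed)
    if repositioning is None or np.allclose(repositioning.matrix(), np.eye(4)):
        followup = changed.copy()
        repositioning = RigidTransform.identity()
    else:
        origin = tuple(np.asarray(baseline.origin) + repositioning.translation)
        ref = DensityImage(
            np.zeros(baseline.shape), baseline.spacing, origin
        )
        followup = resample_rigid(changed, repositioning, ref, "cubic")
    if noise_sigma > 0:
        followup = DensityImage(
            np.clip(
                followup.voxels + rng.normal(0.0, noise_sigma, followup.shape),
                0.0,
                None,
            ),
            followup.spacing,
            followup.origin,
        )

    new_truth = replace(
        truth,
        formation_mask=BinaryMask(formation, baseline.spacing, baseline.origin),
        resorption_mask=BinaryMask(resorption, baseline.spacing, baseline.origin),
        repositioning=repositioning,
    )
    return followup, new_truth
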