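"""Synthetic brain-PET phantoms and attenuation-error fields.

Generates everything the analysis needs with no patient data: geometric
template masks, a normal-control database with a linear voxelwise age effect,
AD subjects with regionally confined hypometabolism, and smooth multiplicative
attenuation-error fields whose magnitude concentrates near the skull. Two
error regimes are configurable: a low-variance regime emulating ZTE-based
attenuation correction and a high-variance regime emulating atlas-based
pseudo-CT correction.

Every generator is a pure function of its parameters and a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .volumes import BrainVolume, Cohort, SubjectScan, VolumeMask, validate_mask_nesting

REFERENCE_AGE = 70.0  # years; phantom age effect is anchored here

MIN_MASK_VOXELS = 100


@dataclass
class PhantomParams:
    """Parameters of the uptake phantom.

    base_uptake
        Gray-matter plateau in arbitrary units.
    age_slope_per_year
        Uptake change per year of age (<= 0: metabolism declines with age),
        applied inside the age-sensitive region (brain minus the
        preserved-uptake mask) relative to the reference age of 70 y.
    subject_noise_sd
        Between-subject multiplicative noise SD, as a fraction of base uptake.
        The noise is lognormal with unit mean so uptake stays nonnegative.
    ad_severity
        Fraction of uptake removed multiplicatively inside the AD-pattern
        mask for AD subjects (0.15 = 15% hypometabolism).
    """

    grid_shape: tuple[int, int, int] = (91, 109, 91)
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    base_uptake: float = 100.0
    age_slope_per_year: float = -0.5
    subject_noise_sd: float = 0.10
    ad_severity: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.ad_severity < 1.0:
            raise ValueError(f"ad_severity must be in [0, 1), got {self.ad_severity}")
        if self.subject_noise_sd < 0:
            raise ValueError("subject_noise_sd must be >= 0")
        if self.base_uptake <= 0:
            raise ValueError("base_uptake must be positive")


@dataclass
class ErrorFieldParams:
    """Parameters of a multiplicative attenuation-error field.

    The field is 1 + global_bias*w + field_sd*w*G where G is a smooth
    zero-mean unit-variance random field (Gaussian-smoothed white noise with
    the stated correlation length) and w = 1 + skull_weight * shell, shell
    being the brain voxels within 3 voxels of the brain boundary. This
    concentrates the error near the skull, where attenuation-map errors of
    MR-based methods are largest.
    """

    method_label: str = "ZTE_like"
    global_bias: float = -0.02
    field_sd: float = 0.02
    correlation_length_mm: float = 10.0
    skull_weight: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.field_sd < 0:
            raise ValueError("field_sd must be >= 0")
        if self.skull_weight < 0:
            raise ValueError("skull_weight must be >= 0")


#: Default regimes: both methods slightly underestimate on average; the
#: atlas-like regime has larger between-map variability.
DEFAULT_REGIMES = {
    "ZTE_like": ErrorFieldParams(method_label="ZTE_like", global_bias=-0.02, field_sd=0.02),
    "Atlas_like": ErrorFieldParams(method_label="Atlas_like", global_bias=-0.02, field_sd=0.05),
}


@dataclass
class PseudoCTParams:
    """Constants of the linear ZTE-intensity-to-Hounsfield bone mapping."""

    bone_offset_hu: float = 300.0
    bone_slope_hu: float = 2400.0
    bone_cap_hu: float = 2000.0
    soft_tissue_hu: float = 42.0

    def __post_init__(self) -> None:
        if self.bone_cap_hu < self.bone_offset_hu:
            raise ValueError("bone_cap_hu must be >= bone_offset_hu")
        if self.bone_slope_hu <= 0:
            raise ValueError("bone_slope_hu must be positive")


def zte_bone_to_hu(z, params: PseudoCTParams | None = None, bone_class=True):
    """Map normalized bias-corrected ZTE intensity to Hounsfield units.

    ``z`` in [0, 1] with z = 1 for soft-tissue-like proton density and z = 0
    for dense bone (declared convention). Bone-class voxels get
    min(offset + slope*(1 - z), cap); voxels outside the bone class get the
    fixed soft-tissue value. Scalars and arrays are both accepted;
    ``bone_class`` may be a boolean or a boolean array broadcastable to z.
    """
    params = params or PseudoCTParams()
    z_arr = np.asarray(z, dtype=float)
    if np.any(z_arr < 0) or np.any(z_arr > 1):
        raise ValueError("z must be within [0, 1]")
    bone_hu = np.minimum(params.bone_offset_hu + params.bone_slope_hu * (1.0 - z_arr), params.bone_cap_hu)
    hu = np.where(bone_class, bone_hu, params.soft_tissue_hu)
    return float(hu) if np.isscalar(z) or z_arr.ndim == 0 else hu


# ---------------------------------------------------------------------------
# Template masks
# ---------------------------------------------------------------------------


def make_template_masks(
    grid_shape=(91, 109, 91), voxel_size_mm=(2.0, 2.0, 2.0)
) -> tuple[VolumeMask, VolumeMask, VolumeMask]:
    """Deterministic geometric masks: brain ellipsoid, preserved-uptake and
    AD-pattern sectors.

    The brain is a filled ellipsoid centered in the grid. The AD-pattern mask
    is the posterior-superior sector (geometric proxy for temporoparietal /
    posterior cingulate hypometabolism); the preserved-uptake mask is the
    disjoint anterior-inferior sector.
    """
    grid_shape = tuple(int(n) for n in grid_shape)
    if any(n < 16 for n in grid_shape):
        raise ValueError(f"grid too small for mask construction: {grid_shape}")
    nx, ny, nz = grid_shape
    cx, cy, cz = (nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0
    # semiaxes at 42% of each extent: brain fills most of the box with margin
    ax, ay, az = 0.42 * nx, 0.42 * ny, 0.42 * nz
    ix, iy, iz = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    r2 = ((ix - cx) / ax) ** 2 + ((iy - cy) / ay) ** 2 + ((iz - cz) / az) ** 2
    brain = r2 <= 1.0

    # y axis = anterior(+)/posterior(-), z axis = superior(+)/inferior(-)
    ad = brain & (iy < cy) & (iz > cz)
    preserved = brain & (iy > cy) & (iz < cz)

    for name, m in (("brain", brain), ("ad_pattern", ad), ("preserved_uptake", preserved)):
        if int(m.sum()) < MIN_MASK_VOXELS:
            raise ValueError(f"grid {grid_shape} yields only {int(m.sum())} voxels for {name} mask")

    masks = (
        VolumeMask(brain, "brain"),
        VolumeMask(preserved, "preserved_uptake"),
        VolumeMask(ad, "ad_pattern"),
    )
    validate_mask_nesting(masks[0], masks[1], masks[2])
    return masks


def age_sensitive_region(brain: VolumeMask, preserved: VolumeMask) -> np.ndarray:
    """Region carrying the linear age effect: brain minus preserved-uptake.

    Keeping the preserved mask age-flat makes the intensity-normalization
    reference independent of age, as assumed for preserved-uptake regions.
    """
    return brain.data & ~preserved.data


# ---------------------------------------------------------------------------
# Subjects and cohorts
# ---------------------------------------------------------------------------


def simulate_scan(
    params: PhantomParams,
    masks: tuple[VolumeMask, VolumeMask, VolumeMask],
    age: float,
    diagnosis: str,
    subject_seed: int,
    subject_id: str | None = None,
) -> SubjectScan:
    """One phantom scan: base uptake + age trend, AD hypometabolism if AD,
    lognormal subject noise; zero outside the brain."""
    brain, preserved, ad_pattern = masks
    if brain.grid_shape != tuple(params.grid_shape):
        raise ValueError("masks not on the params grid")
    uptake = np.zeros(brain.grid_shape, dtype=np.float64)
    uptake[brain.data] = params.base_uptake
    region = age_sensitive_region(brain, preserved)
    uptake[region] += params.age_slope_per_year * (age - REFERENCE_AGE)
    if diagnosis == "AD":
        uptake[ad_pattern.data] *= 1.0 - params.ad_severity
    if params.subject_noise_sd > 0:
        rng = np.random.default_rng(subject_seed)
        # lognormal with unit mean and sd ~ subject_noise_sd (fraction)
        s = np.sqrt(np.log1p(params.subject_noise_sd**2))
        noise = rng.lognormal(mean=-0.5 * s * s, sigma=s, size=brain.grid_shape)
        uptake[brain.data] *= noise[brain.data]
    np.maximum(uptake, 0.0, out=uptake)
    vol = BrainVolume(uptake, params.voxel_size_mm)
    sid = subject_id or f"{diagnosis.lower()}-{subject_seed:06d}"
    return SubjectScan(vol, age, diagnosis, sid)


def simulate_cohort(
    params: PhantomParams,
    masks: tuple[VolumeMask, VolumeMask, VolumeMask],
    n_nc: int,
    n_ad: int,
    age_range: tuple[float, float] = (55.0, 90.0),
    seed: int = 0,
    id_prefix: str = "sub",
) -> Cohort:
    """Cohort of n_nc controls + n_ad AD phantoms with uniform ages."""
    if n_nc < 0 or n_ad < 0:
        raise ValueError("group sizes must be >= 0")
    if n_nc + n_ad == 0:
        raise ValueError("empty cohort requested")
    rng = np.random.default_rng(seed)
    subjects = []
    for k, diagnosis in enumerate(["NC"] * n_nc + ["AD"] * n_ad):
        age = float(rng.uniform(*age_range))
        subject_seed = int(rng.integers(0, 2**31 - 1))
        subjects.append(
            simulate_scan(params, masks, age, diagnosis, subject_seed, f"{id_prefix}-{k:04d}-{diagnosis.lower()}")
        )
    return Cohort(subjects)


# ---------------------------------------------------------------------------
# Error fields
# ---------------------------------------------------------------------------


def _skull_shell(brain: np.ndarray, depth_voxels: int = 3) -> np.ndarray:
    """Brain voxels within ``depth_voxels`` of the brain boundary."""
    eroded = ndimage.binary_erosion(brain, iterations=depth_voxels)
    return brain & ~eroded


def _smooth_unit_field(rng: np.random.Generator, shape, sigma_voxels, brain: np.ndarray) -> np.ndarray:
    """Gaussian-smoothed white noise rescaled to zero mean, unit variance over
    the brain."""
    g = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma_voxels, mode="constant")
    vals = g[brain]
    sd = vals.std()
    if sd == 0:
        return np.zeros(shape)
    return (g - vals.mean()) / sd


def simulate_error_field(params: ErrorFieldParams, brain: VolumeMask, voxel_size_mm=(2.0, 2.0, 2.0)):
    """A smooth multiplicative error field, skull-weighted, exactly 1 outside
    the brain.

    Returns an unconditioned :class:`petsim.errors.ErrorMap` (conditioning —
    smoothing and brain masking — mirrors the measured-data pipeline and is a
    separate step).
    """
    from .errors import ErrorMap  # local import to avoid a cycle

    b = brain.data
    shape = b.shape
    w = 1.0 + params.skull_weight * _skull_shell(b).astype(np.float64)
    field = np.ones(shape, dtype=np.float64)
    field[b] += params.global_bias * w[b]
    if params.field_sd > 0:
        rng = np.random.default_rng(params.seed)
        sigma_voxels = [params.correlation_length_mm / v for v in voxel_size_mm]
        g = _smooth_unit_field(rng, shape, sigma_voxels, b)
        field[b] += params.field_sd * w[b] * g[b]
    n_nonpos = int(np.sum(field[b] <= 0))
    if n_nonpos > 0.01 * b.sum():
        raise ValueError(
            f"error-field parameters produce non-positive values on {n_nonpos} brain voxels "
            "(> 1%): misconfiguration"
        )
    np.maximum(field, 0.1, out=field)
    field[~b] = 1.0
    vol = BrainVolume(field, voxel_size_mm)
    return ErrorMap(vol, params.method_label, source_id=f"{params.method_label}-seed{params.seed}")


def simulate_error_maps(params: ErrorFieldParams, brain: VolumeMask, n_maps: int, seed: int, voxel_size_mm=(2.0, 2.0, 2.0)):
    """n_maps independent error fields of one regime, seeds derived from ``seed``."""
    rng = np.random.default_rng(seed)
    maps = []
    for _ in range(n_maps):
        p = replace(params, seed=int(rng.integers(0, 2**31 - 1)))
        maps.append(simulate_error_field(p, brain, voxel_size_mm))
    return maps
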