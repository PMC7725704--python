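"""Multiplicative attenuation-error maps and their injection into a cohort.

An error map is the voxelwise ratio of an MR-based-AC PET volume to its
CT-based-AC counterpart. Before use it is conditioned — smoothed with the
same 12 mm kernel as the scoring pipeline and masked to the brain — and then
multiplied voxelwise into each normalized subject volume, crossing every
subject with every map. No re-smoothing or re-deformation happens after
injection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .scoring import FWHM_TO_SIGMA, NormalDatabase, ScoringConfig, score_subject
from .volumes import BrainVolume, Cohort, ScoreTable, SubjectScan, VolumeMask

log = logging.getLogger(__name__)

EPS_DENOM = 1e-9


@dataclass
class ErrorMap:
    """A multiplicative voxelwise error field tagged with its method label."""

    field: BrainVolume
    method: str
    source_id: str = ""
    conditioned: bool = False

    def __post_init__(self) -> None:
        if np.any(self.field.data <= 0):
            raise ValueError("error field must be strictly positive")


def identity_error_map(grid_shape, voxel_size_mm=(2.0, 2.0, 2.0), source_id="identity") -> ErrorMap:
    """The neutral error map (field identically 1), already conditioned."""
    field = BrainVolume(np.ones(grid_shape), voxel_size_mm)
    return ErrorMap(field, "identity", source_id, conditioned=True)


def compute_error_map(pet_mrac: BrainVolume, pet_ctac: BrainVolume, brain: VolumeMask) -> ErrorMap:
    """Voxelwise ratio MRAC / CTAC inside the brain; 1 outside.

    Brain voxels where the CTAC denominator is ~0 are set to 1 and counted in
    a warning; more than 1% of such voxels is treated as a data error.
    """
    if not (pet_mrac.grid_shape == pet_ctac.grid_shape == brain.grid_shape):
        raise ValueError("grid mismatch between MRAC, CTAC and brain mask")
    b = brain.data
    denom = pet_ctac.data
    bad = b & (denom <= EPS_DENOM)
    n_bad = int(bad.sum())
    if n_bad > 0.01 * b.sum():
        raise ValueError(f"{n_bad} brain voxels with near-zero CTAC denominator (> 1%)")
    if n_bad:
        log.warning("%d brain voxels with near-zero CTAC denominator set to 1", n_bad)
    field = np.ones(pet_mrac.grid_shape, dtype=np.float64)
    ok = b & ~bad
    field[ok] = pet_mrac.data[ok] / denom[ok]
    return ErrorMap(pet_mrac.with_data(field), method="unlabeled", conditioned=False)


def condition_error_map(err: ErrorMap, brain: VolumeMask, fwhm_mm=(12.0, 12.0, 12.0)) -> ErrorMap:
    """Mask-normalized smoothing then brain masking.

    The ratio field (restricted to the brain) and the mask are smoothed
    separately and divided, so brain-edge ratio values are not diluted toward
    the outside-brain fill; outside the brain the field is reset to exactly 1.
    """
    if err.conditioned:
        raise ValueError("error map already conditioned")
    if err.field.grid_shape != brain.grid_shape:
        raise ValueError("grid mismatch between error map and brain mask")
    b = brain.data
    sigma = [f * FWHM_TO_SIGMA / v for f, v in zip(fwhm_mm, err.field.voxel_size_mm)]
    masked = np.where(b, err.field.data, 0.0)
    if all(s == 0 for s in sigma):
        smoothed = masked
        weight = b.astype(np.float64)
    else:
        smoothed = ndimage.gaussian_filter(masked, sigma=sigma, mode="constant")
        weight = ndimage.gaussian_filter(b.astype(np.float64), sigma=sigma, mode="constant")
    field = np.ones(err.field.grid_shape, dtype=np.float64)
    inside = b & (weight > 0)
    field[inside] = smoothed[inside] / weight[inside]
    np.maximum(field, 1e-12, out=field)  # guard strict positivity after smoothing
    return ErrorMap(err.field.with_data(field), err.method, err.source_id, conditioned=True)


def apply_error(subject_vol: BrainVolume, err: ErrorMap) -> BrainVolume:
    """Voxelwise product of a normalized subject volume with a conditioned map."""
    if not err.conditioned:
        raise ValueError("error map must be conditioned before application")
    if subject_vol.grid_shape != err.field.grid_shape:
        raise ValueError("grid mismatch between subject volume and error map")
    if err.method == "identity":
        return subject_vol  # bit-exact no-op
    return subject_vol.with_data(subject_vol.data * err.field.data)


def run_simulation(
    cohort: Cohort,
    error_maps: list[ErrorMap],
    db: NormalDatabase,
    masks,
    config: ScoringConfig | None = None,
    include_original: bool = True,
) -> ScoreTable:
    """Score every (subject x error map) pair, plus one 'original' row per
    subject (identity error). All simulated scoring is pre-normalized: the
    error is imposed voxelwise and no further smoothing is applied."""
    if not error_maps:
        raise ValueError("empty error-map list")
    for m in error_maps:
        if not m.conditioned:
            raise ValueError(f"unconditioned error map {m.source_id!r}")
    config = config or ScoringConfig()
    sim_config = replace(config, pre_normalized=True)
    rows = []
    if include_original:
        for s in cohort:
            res = score_subject(s, db, masks, sim_config)
            rows.append((s.subject_id, "original", "original", res.ad_tsum, res.pet_score))
    for m in error_maps:
        for s in cohort:
            perturbed = SubjectScan(apply_error(s.volume, m), s.age, s.diagnosis, s.subject_id)
            res = score_subject(perturbed, db, masks, sim_config)
            rows.append((s.subject_id, m.source_id, m.method, res.ad_tsum, res.pet_score))
    df = pd.DataFrame(rows, columns=["subject_id", "error_map_id", "method", "ad_tsum", "pet_score"])
    return ScoreTable(df, config.tsum_constant)
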