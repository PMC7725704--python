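"""Automated AD-probability scoring against an age-regressed normal database.

The statistic mirrors the automated discrimination tools used in multi-center
FDG-PET studies: after Gaussian smoothing and intensity normalization to a
preserved-uptake mask, each voxel's uptake is compared with the prediction of
a voxelwise uptake-vs-age regression fitted on healthy controls. The
resulting Student t-values (positive = hypometabolism) are summed over a
predefined AD-related voxel set (the AD t-sum) and mapped to the PET score

    PET score = log2(AD t-sum / K + 1),   K = 11089,

where K is the 95% prediction limit of the AD t-sum, so PET score = 1 marks
that limit.

The t-statistic uses the single-new-observation prediction standard error
s_v * sqrt(1 + 1/n + (age - mean_age)^2 / S_xx), the standard form for
comparing one subject with a regression-modeled reference population. The AD
t-sum includes negative t-values (no thresholding), so the PET score can be
negative for markedly hypermetabolic-looking input.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .volumes import (
    BrainVolume,
    Cohort,
    ScoreTable,
    SubjectScan,
    TSUM_CONSTANT,
    VolumeMask,
    read_volume,
    write_volume,
)

log = logging.getLogger(__name__)

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class ScoringConfig:
    """Knobs of the scoring pipeline.

    fwhm_mm
        Gaussian smoothing kernel, full width at half maximum per axis
        (default 12 mm isotropic).
    tsum_constant
        Normalization constant K of the PET score (95% prediction limit of
        the AD t-sum).
    s_floor
        Lower bound on the per-voxel residual SD; ``None`` derives
        1e-6 x mean normalized uptake over the brain at fit time, which keeps
        noise-free synthetic databases finite.
    pre_normalized
        Skip smoothing when scoring (used for simulated inputs that already
        live on the template grid and carry the target resolution).
    """

    fwhm_mm: tuple[float, float, float] = (12.0, 12.0, 12.0)
    tsum_constant: float = TSUM_CONSTANT
    s_floor: float | None = None
    pre_normalized: bool = False

    def __post_init__(self) -> None:
        if self.tsum_constant <= 0:
            raise ValueError("tsum_constant must be positive")
        if any(f < 0 for f in self.fwhm_mm):
            raise ValueError("fwhm must be >= 0 per axis")


@dataclass
class NormalDatabase:
    """Per-voxel age-regression parameters of the healthy-control reference.

    ``intercept``, ``slope`` and ``resid_sd`` are 3D arrays on the template
    grid (meaningful inside the brain mask); ``resid_sd`` is floored at
    ``s_floor`` everywhere in the brain.
    """

    intercept: np.ndarray
    slope: np.ndarray
    resid_sd: np.ndarray
    n_controls: int
    mean_age: float
    age_ssq: float  # S_xx = sum((age - mean_age)^2)
    brain: VolumeMask
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    smoothed: bool = True
    normalized: bool = True

    def __post_init__(self) -> None:
        if self.n_controls < 3:
            raise ValueError("need at least 3 controls")
        if self.age_ssq <= 0:
            raise ValueError("degenerate age design (all ages identical)")
        inside = self.resid_sd[self.brain.data]
        if np.any(inside <= 0):
            raise ValueError("resid_sd must be positive inside the brain (floor not applied?)")

    def predicted(self, age: float) -> np.ndarray:
        return self.intercept + self.slope * age

    def prediction_se_factor(self, age: float) -> float:
        """sqrt(1 + 1/n + (age - mean_age)^2 / S_xx)."""
        return float(np.sqrt(1.0 + 1.0 / self.n_controls + (age - self.mean_age) ** 2 / self.age_ssq))

    # -- persistence: three NIfTI volumes + a JSON sidecar ------------------

    def save(self, stem: str | Path) -> None:
        stem = Path(stem)
        stem.parent.mkdir(parents=True, exist_ok=True)
        vs = self.voxel_size_mm
        write_volume(BrainVolume(self.intercept, vs), f"{stem}_intercept.nii.gz")
        write_volume(BrainVolume(self.slope, vs), f"{stem}_slope.nii.gz")
        write_volume(BrainVolume(self.resid_sd, vs), f"{stem}_residsd.nii.gz")
        write_volume(BrainVolume(self.brain.data.astype(float), vs), f"{stem}_brainmask.nii.gz")
        sidecar = {
            "n_controls": self.n_controls,
            "mean_age": self.mean_age,
            "age_ssq": self.age_ssq,
            "voxel_size_mm": list(vs),
            "smoothed": self.smoothed,
            "normalized": self.normalized,
        }
        Path(f"{stem}.json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, stem: str | Path) -> "NormalDatabase":
        stem = Path(stem)
        meta = json.loads(Path(f"{stem}.json").read_text())
        return cls(
            intercept=read_volume(f"{stem}_intercept.nii.gz").data,
            slope=read_volume(f"{stem}_slope.nii.gz").data,
            resid_sd=read_volume(f"{stem}_residsd.nii.gz").data,
            n_controls=int(meta["n_controls"]),
            mean_age=float(meta["mean_age"]),
            age_ssq=float(meta["age_ssq"]),
            brain=VolumeMask(read_volume(f"{stem}_brainmask.nii.gz").data, "brain"),
            voxel_size_mm=tuple(meta["voxel_size_mm"]),
            smoothed=bool(meta["smoothed"]),
            normalized=bool(meta["normalized"]),
        )


@dataclass
class ScoreResult:
    """Scoring output for one subject volume."""

    t_map: BrainVolume
    ad_tsum: float
    pet_score: float
    normalization_factor: float


# ---------------------------------------------------------------------------
# Pipeline stages
# ---------------------------------------------------------------------------


def smooth_gaussian(vol: BrainVolume, fwhm_mm) -> BrainVolume:
    """Separable Gaussian smoothing; sigma per axis = FWHM / (2 sqrt(2 ln 2))
    converted to voxel units. FWHM 0 on every axis returns the input
    unchanged. Boundaries are zero-padded; downstream statistics are always
    restricted to the brain mask."""
    fwhm = tuple(float(f) for f in fwhm_mm)
    if any(f < 0 for f in fwhm):
        raise ValueError(f"negative fwhm: {fwhm}")
    if all(f == 0 for f in fwhm):
        return vol
    sigma = [f * FWHM_TO_SIGMA / v for f, v in zip(fwhm, vol.voxel_size_mm)]
    return vol.with_data(ndimage.gaussian_filter(vol.data, sigma=sigma, mode="constant"))


def intensity_normalize(vol: BrainVolume, preserved: VolumeMask) -> tuple[BrainVolume, float]:
    """Divide by the mean over the preserved-uptake mask; returns the factor.

    After this step the mean of the output over the mask is exactly 1, which
    removes any global multiplicative scaling of the input.
    """
    if vol.grid_shape != preserved.grid_shape:
        raise ValueError("grid mismatch between volume and preserved mask")
    factor = float(vol.data[preserved.data].mean())
    if factor <= 0:
        raise ValueError(f"nonpositive mean over preserved mask ({factor}): degenerate input")
    return vol.with_data(vol.data / factor), factor


def fit_age_regression(
    controls: Cohort,
    masks: tuple[VolumeMask, VolumeMask, VolumeMask],
    config: ScoringConfig | None = None,
) -> NormalDatabase:
    """Voxelwise OLS of normalized control uptake on age.

    Controls are smoothed (unless ``pre_normalized``) and intensity-normalized
    first. The residual SD uses the n-2 denominator and is floored at
    ``s_floor``.
    """
    config = config or ScoringConfig()
    brain, preserved, _ = masks
    nc = controls.select("NC")
    if len(nc) < 3:
        raise ValueError(f"need >= 3 NC controls, got {len(nc)}")
    ages = nc.ages
    if np.ptp(ages) == 0:
        raise ValueError("degenerate age design: all control ages identical")

    vols = []
    for s in nc:
        v = s.volume if config.pre_normalized else smooth_gaussian(s.volume, config.fwhm_mm)
        v, _ = intensity_normalize(v, preserved)
        vols.append(v.data)
    stack = np.stack(vols)  # (n, x, y, z)
    n = len(nc)
    mean_age = float(ages.mean())
    dx = ages - mean_age
    sxx = float(np.sum(dx * dx))

    mean_y = stack.mean(axis=0)
    slope = np.tensordot(dx, stack - mean_y, axes=(0, 0)) / sxx
    intercept = mean_y - slope * mean_age
    resid = stack - (intercept[None] + slope[None] * ages[:, None, None, None])
    resid_sd = np.sqrt(np.sum(resid * resid, axis=0) / (n - 2))

    if config.s_floor is not None:
        floor = config.s_floor
    else:
        floor = 1e-6 * float(mean_y[brain.data].mean())
    np.maximum(resid_sd, floor, out=resid_sd)

    return NormalDatabase(
        intercept=intercept,
        slope=slope,
        resid_sd=resid_sd,
        n_controls=n,
        mean_age=mean_age,
        age_ssq=sxx,
        brain=brain,
        voxel_size_mm=nc.subjects[0].volume.voxel_size_mm,
        smoothed=not config.pre_normalized,
        normalized=True,
    )


def compute_tmap(subject: SubjectScan, db: NormalDatabase, brain: VolumeMask) -> BrainVolume:
    """Per-voxel Student t of (predicted - observed) against the prediction SE.

    Positive t = hypometabolism relative to the age-matched reference. Zero
    outside the brain. The subject volume must already be smoothed and
    normalized consistently with the database.
    """
    if subject.volume.grid_shape != db.intercept.shape:
        raise ValueError("grid mismatch between subject and database")
    age = subject.age
    half_range = 3.0 * np.sqrt(db.age_ssq / max(db.n_controls - 1, 1))
    if abs(age - db.mean_age) > half_range:
        log.warning("subject %s age %.1f far outside database age range", subject.subject_id, age)
    c = db.prediction_se_factor(age)
    t = np.zeros(subject.volume.grid_shape, dtype=np.float64)
    b = brain.data
    expected = db.intercept[b] + db.slope[b] * age
    t[b] = (expected - subject.volume.data[b]) / (db.resid_sd[b] * c)
    return subject.volume.with_data(t)


def ad_tsum(t_map: BrainVolume, ad_pattern: VolumeMask) -> float:
    """Sum of t-values over the AD-pattern mask; no thresholding."""
    if t_map.grid_shape != ad_pattern.grid_shape:
        raise ValueError("grid mismatch between t-map and AD-pattern mask")
    return float(t_map.data[ad_pattern.data].sum())


def pet_score(tsum: float, tsum_constant: float = TSUM_CONSTANT) -> float:
    """PET score = log2(AD t-sum / K + 1); score 1 at t-sum = K, 0 at 0."""
    arg = tsum / tsum_constant + 1.0
    if arg <= 0:
        raise ValueError(f"pathological AD t-sum {tsum}: log argument {arg} <= 0")
    return float(np.log2(arg))


def score_subject(
    subject: SubjectScan,
    db: NormalDatabase,
    masks: tuple[VolumeMask, VolumeMask, VolumeMask],
    config: ScoringConfig | None = None,
) -> ScoreResult:
    """Full pipeline: smooth (unless pre_normalized) -> normalize -> t-map ->
    AD t-sum -> PET score."""
    config = config or ScoringConfig()
    brain, preserved, ad_pattern = masks
    vol = subject.volume if config.pre_normalized else smooth_gaussian(subject.volume, config.fwhm_mm)
    vol, factor = intensity_normalize(vol, preserved)
    normalized = SubjectScan(vol, subject.age, subject.diagnosis, subject.subject_id)
    t_map = compute_tmap(normalized, db, brain)
    tsum = ad_tsum(t_map, ad_pattern)
    return ScoreResult(t_map, tsum, pet_score(tsum, config.tsum_constant), factor)


def score_cohort(
    cohort: Cohort,
    db: NormalDatabase,
    masks,
    config: ScoringConfig | None = None,
    error_map_id: str = "original",
    method: str = "original",
) -> ScoreTable:
    """Score every subject of a cohort into a tidy table."""
    import pandas as pd

    config = config or ScoringConfig()
    rows = []
    for s in cohort:
        res = score_subject(s, db, masks, config)
        rows.append(
            {
                "subject_id": s.subject_id,
                "error_map_id": error_map_id,
                "method": method,
                "ad_tsum": res.ad_tsum,
                "pet_score": res.pet_score,
            }
        )
    return ScoreTable(pd.DataFrame(rows), config.tsum_constant)
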