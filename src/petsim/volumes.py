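"""Domain containers for template-space brain volumes, masks, cohorts and
score tables, plus NIfTI-1 / CSV readers and writers.

All downstream stages operate on a single common grid (MNI-like, 2 mm
isotropic by default). Grid mismatches are rejected explicitly rather than
broadcast.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: Default normalization constant of the PET-score statistic (95% prediction
#: limit of the AD t-sum established in multi-center trials).
TSUM_CONSTANT = 11089.0

DIAGNOSES = ("NC", "AD")
MASK_LABELS = ("brain", "preserved_uptake", "ad_pattern")


@dataclass
class BrainVolume:
    """A 3D scalar field on the template grid.

    ``data`` holds tracer uptake in arbitrary units (>= 0) or a dimensionless
    multiplicative ratio for error maps. ``affine`` is carried along for
    lossless NIfTI round-trips.
    """

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    space_tag: str = "template"
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D volume, got {self.data.ndim}D")
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        if len(self.voxel_size_mm) != 3 or any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError(f"voxel size must be 3 positive values, got {self.voxel_size_mm}")
        if not np.all(np.isfinite(self.data)):
            n_bad = int(np.sum(~np.isfinite(self.data)))
            raise ValueError(f"volume contains {n_bad} non-finite voxels")
        if self.affine is None:
            self.affine = np.diag(list(self.voxel_size_mm) + [1.0])

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def with_data(self, data: np.ndarray) -> "BrainVolume":
        """New volume on the same grid with replaced voxel data."""
        return BrainVolume(data, self.voxel_size_mm, self.space_tag, self.affine)

    def same_grid(self, other: "BrainVolume | VolumeMask") -> bool:
        return self.grid_shape == other.grid_shape


@dataclass
class VolumeMask:
    """Boolean mask on the template grid (brain / preserved-uptake / AD-pattern)."""

    data: np.ndarray
    label: str = "brain"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data) > 0.5
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D mask, got {self.data.ndim}D")
        if self.label not in MASK_LABELS:
            raise ValueError(f"unknown mask label {self.label!r}")
        if not self.data.any():
            raise ValueError(f"mask {self.label!r} is empty")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


def validate_mask_nesting(brain: VolumeMask, preserved: VolumeMask, ad_pattern: VolumeMask) -> None:
    """Enforce ad_pattern ⊆ brain, preserved ⊆ brain, ad_pattern ∩ preserved = ∅."""
    if not (brain.grid_shape == preserved.grid_shape == ad_pattern.grid_shape):
        raise ValueError("mask grid mismatch")
    if np.any(ad_pattern.data & ~brain.data):
        raise ValueError("ad_pattern mask extends outside brain mask")
    if np.any(preserved.data & ~brain.data):
        raise ValueError("preserved_uptake mask extends outside brain mask")
    if np.any(ad_pattern.data & preserved.data):
        raise ValueError("ad_pattern and preserved_uptake masks overlap")


@dataclass
class SubjectScan:
    """One subject's template-space PET volume with age and diagnosis."""

    volume: BrainVolume
    age: float
    diagnosis: str
    subject_id: str

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ValueError(f"age must be positive, got {self.age}")
        if self.diagnosis not in DIAGNOSES:
            raise ValueError(f"unknown diagnosis {self.diagnosis!r} (expected one of {DIAGNOSES})")
        if self.volume.space_tag != "template":
            raise ValueError("subject volume must be in template space")


@dataclass
class Cohort:
    """Ordered set of subject scans sharing one grid with unique ids."""

    subjects: list[SubjectScan] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate subject_ids: {dupes}")
        if self.subjects:
            ref = self.subjects[0].volume
            for s in self.subjects[1:]:
                if s.volume.grid_shape != ref.grid_shape:
                    raise ValueError(
                        f"grid mismatch: {s.subject_id} has {s.volume.grid_shape}, "
                        f"expected {ref.grid_shape}"
                    )
                if s.volume.voxel_size_mm != ref.voxel_size_mm:
                    raise ValueError(f"voxel-size mismatch for {s.subject_id}")

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)

    def select(self, diagnosis: str) -> "Cohort":
        return Cohort([s for s in self.subjects if s.diagnosis == diagnosis])

    @property
    def ages(self) -> np.ndarray:
        return np.array([s.age for s in self.subjects], dtype=float)

    @property
    def labels(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": [s.subject_id for s in self.subjects],
                "age": self.ages,
                "diagnosis": [s.diagnosis for s in self.subjects],
            }
        )


SCORE_COLUMNS = ["subject_id", "error_map_id", "method", "ad_tsum", "pet_score"]


@dataclass
class ScoreTable:
    """Per-(subject, error map, method) scoring results.

    Wraps a tidy DataFrame with columns ``subject_id, error_map_id, method,
    ad_tsum, pet_score``; the PET-score formula is re-checked against the
    t-sum column on construction.
    """

    df: pd.DataFrame
    tsum_constant: float = TSUM_CONSTANT

    def __post_init__(self) -> None:
        missing = [c for c in SCORE_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"ScoreTable missing columns: {missing}")
        self.df = self.df[SCORE_COLUMNS].reset_index(drop=True)
        key = self.df[["subject_id", "error_map_id", "method"]]
        if key.duplicated().any():
            raise ValueError("duplicate (subject, error_map, method) rows")
        expected = np.log2(self.df["ad_tsum"].to_numpy() / self.tsum_constant + 1.0)
        if not np.allclose(expected, self.df["pet_score"].to_numpy(), atol=1e-9):
            raise ValueError("pet_score column inconsistent with ad_tsum column")

    def __len__(self) -> int:
        return len(self.df)

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False, float_format="%.12g")

    @classmethod
    def from_csv(cls, path: str | Path, tsum_constant: float = TSUM_CONSTANT) -> "ScoreTable":
        return cls(pd.read_csv(path), tsum_constant)

    @classmethod
    def concat(cls, tables: Iterable["ScoreTable"]) -> "ScoreTable":
        tables = list(tables)
        return cls(pd.concat([t.df for t in tables], ignore_index=True), tables[0].tsum_constant)


# ---------------------------------------------------------------------------
# NIfTI and manifest I/O
# ---------------------------------------------------------------------------


def read_volume(path: str | Path) -> BrainVolume:
    """Load a 3D NIfTI-1 volume; voxel size is taken from the header."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"expected 3D volume in {path}, got {data.ndim}D")
    if not np.all(np.isfinite(data)):
        n_bad = int(np.sum(~np.isfinite(data)))
        raise ValueError(f"{path} contains {n_bad} non-finite (NaN/Inf) voxels")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return BrainVolume(data, zooms, "template", np.asarray(img.affine))


def write_volume(vol: BrainVolume, path: str | Path) -> None:
    """Write a volume as NIfTI-1, overwriting any existing file."""
    path = Path(path)
    if path.exists():
        log.info("overwriting existing volume %s", path)
    img = nib.Nifti1Image(vol.data, vol.affine)
    img.header.set_zooms(vol.voxel_size_mm)
    nib.save(img, str(path))


def read_mask(path: str | Path, label: str) -> VolumeMask:
    """Load a mask stored as 0/1 NIfTI voxels (any value > 0.5 is true)."""
    return VolumeMask(read_volume(path).data, label)


def write_mask(mask: VolumeMask, path: str | Path, voxel_size_mm=(2.0, 2.0, 2.0)) -> None:
    write_volume(BrainVolume(mask.data.astype(np.float64), voxel_size_mm), path)


def read_cohort_manifest(csv_path: str | Path, volume_dir: str | Path) -> Cohort:
    """Build a cohort from a manifest CSV (subject_id, age, diagnosis, filename)."""
    csv_path = Path(csv_path)
    volume_dir = Path(volume_dir)
    table = pd.read_csv(csv_path)
    required = {"subject_id", "age", "diagnosis", "filename"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"manifest {csv_path} missing columns: {sorted(missing)}")
    subjects = []
    for row in table.itertuples(index=False):
        if row.diagnosis not in DIAGNOSES:
            raise ValueError(f"unknown diagnosis {row.diagnosis!r} for subject {row.subject_id}")
        vol = read_volume(volume_dir / row.filename)
        subjects.append(SubjectScan(vol, float(row.age), str(row.diagnosis), str(row.subject_id)))
    return Cohort(subjects)


def write_cohort(cohort: Cohort, out_dir: str | Path, manifest_name: str = "manifest.csv") -> Path:
    """Write every scan as NIfTI plus a manifest CSV; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in cohort:
        fname = f"{s.subject_id}.nii.gz"
        write_volume(s.volume, out_dir / fname)
        rows.append({"subject_id": s.subject_id, "age": s.age, "diagnosis": s.diagnosis, "filename": fname})
    manifest = out_dir / manifest_name
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
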