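"""End-to-end study workflow: phantoms -> normal database -> error injection
-> diagnostic evaluation, driven by a single serializable configuration."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ErrorMap, identity_error_map, run_simulation
from .evaluation import (
    agreement_analysis,
    evaluate_method,
    paired_ttest_abs,
    per_subject_average,
    score_difference_stats,
    score_differences,
)
from .phantom import (
    DEFAULT_REGIMES,
    ErrorFieldParams,
    PhantomParams,
    make_template_masks,
    simulate_cohort,
    simulate_error_maps,
)
from .scoring import ScoringConfig, fit_age_regression
from .volumes import ScoreTable, write_cohort, write_mask

log = logging.getLogger(__name__)

GRID_PRESETS = {"SMALL": (32, 32, 32), "FULL": (91, 109, 91)}


@dataclass
class StudyConfig:
    """Everything one synthetic study run needs; round-trips through YAML."""

    grid_shape: tuple[int, int, int] = (32, 32, 32)
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    phantom: PhantomParams = None  # type: ignore[assignment]
    scoring: ScoringConfig = None  # type: ignore[assignment]
    regimes: dict[str, ErrorFieldParams] = None  # type: ignore[assignment]
    n_db_controls: int = 40
    n_nc: int = 40
    n_ad: int = 40
    n_maps_per_regime: int = 10
    age_range: tuple[float, float] = (55.0, 90.0)
    cutoff: float = 1.0
    bootstrap_reps: int = 2000
    seed: int = 0
    outdir: str = "results/study"

    def __post_init__(self) -> None:
        gs, vs = tuple(self.grid_shape), tuple(self.voxel_size_mm)
        if self.phantom is None:
            self.phantom = PhantomParams(grid_shape=gs, voxel_size_mm=vs)
        else:
            self.phantom = dataclasses.replace(self.phantom, grid_shape=gs, voxel_size_mm=vs)
        if self.scoring is None:
            self.scoring = ScoringConfig(pre_normalized=True)
        if self.regimes is None:
            self.regimes = {k: dataclasses.replace(v) for k, v in DEFAULT_REGIMES.items()}

    # -- YAML round-trip ----------------------------------------------------

    def to_dict(self) -> dict:
        def _plain(obj):
            if isinstance(obj, dict):
                return {k: _plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [_plain(v) for v in obj]
            return obj

        return _plain(dataclasses.asdict(self))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        if "phantom" in d and isinstance(d["phantom"], dict):
            p = dict(d["phantom"])
            p["grid_shape"] = tuple(p.get("grid_shape", d.get("grid_shape", (32, 32, 32))))
            p["voxel_size_mm"] = tuple(p.get("voxel_size_mm", (2.0, 2.0, 2.0)))
            d["phantom"] = PhantomParams(**p)
        if "scoring" in d and isinstance(d["scoring"], dict):
            s = dict(d["scoring"])
            s["fwhm_mm"] = tuple(s.get("fwhm_mm", (12.0, 12.0, 12.0)))
            d["scoring"] = ScoringConfig(**s)
        if "regimes" in d and isinstance(d["regimes"], dict):
            d["regimes"] = {
                k: (ErrorFieldParams(**v) if isinstance(v, dict) else v) for k, v in d["regimes"].items()
            }
        for key in ("grid_shape", "voxel_size_mm", "age_range"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _derive_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


def run_end_to_end(config: StudyConfig, write_volumes: bool = False) -> dict:
    """Run the whole synthetic study and write its outputs.

    Stages: template masks -> control-database cohort -> test cohort ->
    error maps per regime -> database fit -> original + simulated scoring ->
    score-difference / agreement / diagnostic-accuracy evaluation. Every
    output file is declared in ``manifest.json``; reruns with the same seed
    are bit-identical for CSV/JSON outputs.

    Returns a dict with the in-memory results (score table, summaries,
    per-method reports).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    manifest: list[str] = []

    current_stage = ["setup"]

    def _stage(name):
        current_stage[0] = name
        log.info("stage: %s", name)

    try:
        _stage("masks")
        masks = make_template_masks(config.grid_shape, config.voxel_size_mm)

        _stage("database cohort")
        db_cohort = simulate_cohort(
            config.phantom, masks, config.n_db_controls, 0, config.age_range, _derive_seed(rng), id_prefix="db"
        )
        _stage("test cohort")
        cohort = simulate_cohort(
            config.phantom, masks, config.n_nc, config.n_ad, config.age_range, _derive_seed(rng), id_prefix="sub"
        )

        _stage("error maps")
        error_maps: list[ErrorMap] = []
        for name, regime in sorted(config.regimes.items()):
            raw = simulate_error_maps(regime, masks[0], config.n_maps_per_regime, _derive_seed(rng), config.voxel_size_mm)
            # synthetic fields are already smooth; they enter as conditioned maps
            for i, m in enumerate(raw):
                m.conditioned = True
                m.source_id = f"{name}-{i:03d}"
                error_maps.append(m)

        _stage("database fit")
        db = fit_age_regression(db_cohort, masks, config.scoring)

        _stage("scoring")
        table = run_simulation(cohort, error_maps, db, masks, config.scoring)
        score_csv = outdir / "score_table.csv"
        table.to_csv(score_csv)
        manifest.append(score_csv.name)

        _stage("evaluation")
        orig = ScoreTable(table.df[table.df["method"] == "original"], table.tsum_constant)
        diff_stats = score_difference_stats(table, orig)
        diff_csv = outdir / "score_difference_stats.csv"
        diff_stats.to_csv(diff_csv, index=False, float_format="%.12g")
        manifest.append(diff_csv.name)

        labels = cohort.labels
        methods = sorted(config.regimes)
        metrics: dict = {"seed": config.seed, "version": __version__, "methods": {}}

        # paired comparison of absolute errors between the two regimes
        diffs = score_differences(table, orig)
        if len(methods) == 2:
            key = ["subject_id"]
            a = diffs[diffs["method"] == methods[0]].copy()
            b = diffs[diffs["method"] == methods[1]].copy()
            a["map_rank"] = a.groupby("subject_id").cumcount()
            b["map_rank"] = b.groupby("subject_id").cumcount()
            merged = a.merge(b, on=["subject_id", "map_rank"], suffixes=("_a", "_b"))
            t, p = paired_ttest_abs(merged["abs_diff_a"].to_numpy(), merged["abs_diff_b"].to_numpy())
            metrics["paired_ttest_abs"] = {"methods": methods, "t": t, "p": p}

        subj_means = per_subject_average(table)
        orig_means = subj_means[subj_means["method"] == "original"].set_index("subject_id")["mean_score"]
        for method in methods:
            m_rows = table.df[table.df["method"] == method]
            m_means = subj_means[subj_means["method"] == method].set_index("subject_id")["mean_score"]
            x = orig_means.loc[m_means.index].to_numpy()
            agr = agreement_analysis(x, m_means.to_numpy())
            report = evaluate_method(
                table, labels, method, cutoff=config.cutoff, n_boot=config.bootstrap_reps, seed=config.seed
            )
            metrics["methods"][method] = {
                "agreement": dataclasses.asdict(agr),
                "report": dataclasses.asdict(report),
            }
        orig_report = evaluate_method(
            orig, labels, "original", cutoff=config.cutoff, n_boot=config.bootstrap_reps, seed=config.seed
        )
        metrics["methods"]["original"] = {"report": dataclasses.asdict(orig_report)}

        metrics_json = outdir / "metrics.json"
        metrics_json.write_text(json.dumps(metrics, indent=2, sort_keys=True))
        manifest.append(metrics_json.name)

        if write_volumes:
            _stage("volume export")
            vol_dir = outdir / "volumes"
            write_cohort(cohort, vol_dir)
            for label, m in zip(("brain", "preserved", "ad_pattern"), masks):
                write_mask(m, vol_dir / f"mask_{label}.nii.gz", config.voxel_size_mm)
            manifest.append("volumes/")

        cfg_yaml = outdir / "config.yaml"
        config.to_yaml(cfg_yaml)
        manifest.append(cfg_yaml.name)
        (outdir / "manifest.json").write_text(json.dumps({"files": manifest}, indent=2))
    except Exception as exc:  # annotate which stage failed
        raise RuntimeError(f"study failed at stage {current_stage[0]!r}: {exc}") from exc

    return {
        "masks": masks,
        "cohort": cohort,
        "db": db,
        "score_table": table,
        "diff_stats": diff_stats,
        "metrics": metrics,
    }
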