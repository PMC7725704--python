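"""Diagnostic-accuracy evaluation of scored datasets.

Covers the full comparison battery: signed and absolute score-difference
summaries per attenuation-correction method, paired testing of absolute
errors between methods, per-subject averaging across error maps, regression
and Bland-Altman agreement of simulated vs original scores, fixed-cutoff
classification with Wilson confidence intervals, and ROC analysis with
trapezoidal AUC, bootstrap CI and Youden-index cutoff selection.

Rows that share a subject (one per error map) are pooled as independent
observations by default, matching how large simulated samples are usually
reported; a subject-level cluster bootstrap for the AUC CI is available as
the statistically conservative alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve
from statsmodels.stats.proportion import proportion_confint

from .volumes import ScoreTable


@dataclass
class AgreementResult:
    """Regression + Bland-Altman agreement between two score series."""

    slope: float = np.nan
    intercept: float = np.nan
    r_squared: float = np.nan
    bias: float = np.nan
    loa_low: float = np.nan
    loa_high: float = np.nan


@dataclass
class DiagnosticReport:
    """Classification and ROC metrics at one cutoff."""

    cutoff: float
    accuracy: float
    accuracy_ci: tuple[float, float]
    sensitivity: float
    sensitivity_ci: tuple[float, float]
    specificity: float
    specificity_ci: tuple[float, float]
    auc: float | None = None
    auc_ci: tuple[float, float] | None = None
    youden_cutoff: float | None = None
    n_pos: int = 0
    n_neg: int = 0


# ---------------------------------------------------------------------------
# Score differences
# ---------------------------------------------------------------------------


def score_differences(sim: ScoreTable, orig: ScoreTable) -> pd.DataFrame:
    """Row-level signed and absolute PET-score differences (simulated minus
    original), joined on subject_id."""
    o = orig.df[orig.df["method"] == "original"][["subject_id", "pet_score"]].rename(
        columns={"pet_score": "orig_score"}
    )
    s = sim.df[sim.df["method"] != "original"]
    merged = s.merge(o, on="subject_id", how="left", validate="many_to_one")
    if merged["orig_score"].isna().any():
        missing = merged.loc[merged["orig_score"].isna(), "subject_id"].unique()
        raise ValueError(f"no original score for subjects: {list(missing)[:5]}")
    merged = merged.assign(
        signed_diff=merged["pet_score"] - merged["orig_score"],
        abs_diff=(merged["pet_score"] - merged["orig_score"]).abs(),
    )
    return merged


def score_difference_stats(sim: ScoreTable, orig: ScoreTable) -> pd.DataFrame:
    """Per-method summaries (mean, SD, max, min) of signed and absolute
    score differences."""
    diffs = score_differences(sim, orig)
    rows = []
    for method, g in diffs.groupby("method", sort=True):
        for kind, col in (("signed", "signed_diff"), ("absolute", "abs_diff")):
            v = g[col].to_numpy()
            rows.append(
                {
                    "method": method,
                    "kind": kind,
                    "mean": v.mean(),
                    "sd": v.std(ddof=1) if len(v) > 1 else 0.0,
                    "max": v.max(),
                    "min": v.min(),
                    "n": len(v),
                }
            )
    return pd.DataFrame(rows)


def paired_ttest_abs(abs_a: np.ndarray, abs_b: np.ndarray) -> tuple[float, float]:
    """Classical paired t-test (two-sided, n-1 df) between matched absolute
    error vectors."""
    a = np.asarray(abs_a, dtype=float)
    b = np.asarray(abs_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    d = a - b
    if np.ptp(d) == 0 and d.std() == 0:
        if np.all(d == 0):
            return 0.0, 1.0
        raise ValueError("zero-variance nonzero differences: t undefined")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


def per_subject_average(scores: ScoreTable) -> pd.DataFrame:
    """Mean score per (subject, method) across error maps; requires a complete
    subject x map grid within each method."""
    df = scores.df
    out = []
    for method, g in df.groupby("method", sort=True):
        pivot = g.pivot(index="subject_id", columns="error_map_id", values="pet_score")
        if pivot.isna().any().any():
            raise ValueError(f"incomplete subject x error-map grid for method {method!r}")
        means = pivot.mean(axis=1)
        out.append(pd.DataFrame({"subject_id": means.index, "method": method, "mean_score": means.values}))
    return pd.concat(out, ignore_index=True)


# ---------------------------------------------------------------------------
# Agreement
# ---------------------------------------------------------------------------


def regression_agreement(x: np.ndarray, y: np.ndarray) -> AgreementResult:
    """OLS of simulated means (y) on original scores (x) with R^2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("need matched vectors of length >= 3")
    if np.ptp(x) == 0:
        raise ValueError("constant x: regression undefined")
    res = stats.linregress(x, y)
    return AgreementResult(slope=float(res.slope), intercept=float(res.intercept), r_squared=float(res.rvalue**2))


def bland_altman(x: np.ndarray, y: np.ndarray) -> AgreementResult:
    """Bias and 95% limits of agreement of d = y - x (mean +/- 1.96 sample SD)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(x) != len(y):
        raise ValueError("need matched vectors of length >= 2")
    d = y - x
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return AgreementResult(bias=bias, loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd)


def agreement_analysis(x: np.ndarray, y: np.ndarray) -> AgreementResult:
    """Combined regression + Bland-Altman agreement."""
    reg = regression_agreement(x, y)
    ba = bland_altman(x, y)
    return AgreementResult(reg.slope, reg.intercept, reg.r_squared, ba.bias, ba.loa_low, ba.loa_high)


# ---------------------------------------------------------------------------
# Classification and ROC
# ---------------------------------------------------------------------------


def _wilson(k: int, n: int) -> tuple[float, float]:
    lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
    return float(lo), float(hi)


def classify_at_cutoff(scores: np.ndarray, labels: np.ndarray, cutoff: float) -> DiagnosticReport:
    """Classify AD iff score >= cutoff; accuracy/sensitivity/specificity with
    Wilson 95% CIs. ``labels`` is boolean/0-1 with 1 = AD."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    pred = scores >= cutoff
    tp = int((pred & labels).sum())
    tn = int((~pred & ~labels).sum())
    correct = tp + tn
    n = n_pos + n_neg
    return DiagnosticReport(
        cutoff=float(cutoff),
        accuracy=correct / n,
        accuracy_ci=_wilson(correct, n),
        sensitivity=tp / n_pos,
        sensitivity_ci=_wilson(tp, n_pos),
        specificity=tn / n_neg,
        specificity_ci=_wilson(tn, n_neg),
        n_pos=n_pos,
        n_neg=n_neg,
    )


def youden_cutoff(scores: np.ndarray, labels: np.ndarray) -> float:
    """Threshold maximizing sensitivity + specificity - 1 over all observed
    score values; the lowest such threshold on ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    fpr, tpr, thresholds = roc_curve(labels, scores, drop_intermediate=False)
    j = tpr - fpr
    # thresholds are descending; among ties of max J (to float tolerance)
    # pick the lowest finite one
    best = np.flatnonzero(j >= j.max() - 1e-12)
    cut = thresholds[best].min()
    if not np.isfinite(cut):  # sklearn's +inf sentinel (no positives predicted)
        cut = float(scores.max()) + 1.0
    return float(cut)


def bootstrap_auc_ci(
    scores: np.ndarray,
    labels: np.ndarray,
    n_boot: int = 2000,
    seed: int = 0,
    subject_ids: np.ndarray | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap CI for the AUC, stratified by class.

    With ``subject_ids`` the resampling unit is the subject (cluster
    bootstrap), the conservative choice when multiple error-map rows share a
    subject.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    rng = np.random.default_rng(seed)
    aucs = np.empty(n_boot)
    if subject_ids is None:
        pos = np.flatnonzero(labels)
        neg = np.flatnonzero(~labels)
        for i in range(n_boot):
            p = rng.choice(pos, size=len(pos), replace=True)
            q = rng.choice(neg, size=len(neg), replace=True)
            idx = np.concatenate([p, q])
            aucs[i] = roc_auc_score(labels[idx], scores[idx])
    else:
        subject_ids = np.asarray(subject_ids)
        uniq = pd.unique(subject_ids)
        is_pos = {u: labels[subject_ids == u][0] for u in uniq}
        pos_subj = np.array([u for u in uniq if is_pos[u]], dtype=object)
        neg_subj = np.array([u for u in uniq if not is_pos[u]], dtype=object)
        groups = {u: np.flatnonzero(subject_ids == u) for u in uniq}
        for i in range(n_boot):
            chosen = np.concatenate(
                [
                    rng.choice(pos_subj, size=len(pos_subj), replace=True),
                    rng.choice(neg_subj, size=len(neg_subj), replace=True),
                ]
            )
            idx = np.concatenate([groups[u] for u in chosen])
            aucs[i] = roc_auc_score(labels[idx], scores[idx])
    lo, hi = np.percentile(aucs, [2.5, 97.5])
    return float(lo), float(hi)


def roc_analysis(
    scores: np.ndarray,
    labels: np.ndarray,
    n_boot: int = 2000,
    seed: int = 0,
    subject_ids: np.ndarray | None = None,
) -> dict:
    """Empirical ROC: trapezoidal AUC (= pairwise concordance with ties
    counted 1/2), bootstrap 95% CI and Youden cutoff."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    fpr, tpr, _ = roc_curve(labels, scores, drop_intermediate=False)
    auc = float(roc_auc_score(labels, scores))
    ci = bootstrap_auc_ci(scores, labels, n_boot=n_boot, seed=seed, subject_ids=subject_ids)
    return {
        "auc": auc,
        "auc_ci": ci,
        "youden_cutoff": youden_cutoff(scores, labels),
        "roc_points": np.column_stack([fpr, tpr]),
    }


def evaluate_method(
    scores: ScoreTable,
    labels_df: pd.DataFrame,
    method: str,
    cutoff: float = 1.0,
    n_boot: int = 2000,
    seed: int = 0,
) -> DiagnosticReport:
    """Pooled classification + ROC report for one method at a fixed cutoff."""
    g = scores.df[scores.df["method"] == method].merge(
        labels_df[["subject_id", "diagnosis"]], on="subject_id", validate="many_to_one"
    )
    y = (g["diagnosis"] == "AD").to_numpy()
    s = g["pet_score"].to_numpy()
    report = classify_at_cutoff(s, y, cutoff)
    roc = roc_analysis(s, y, n_boot=n_boot, seed=seed)
    report.auc = roc["auc"]
    report.auc_ci = roc["auc_ci"]
    report.youden_cutoff = roc["youden_cutoff"]
    return report
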