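#!/usr/bin/env python
"""Evaluate the scored datasets: score-difference summaries per regime,
paired test of absolute errors, per-subject regression and Bland-Altman
agreement against the original scores, fixed-cutoff (PET score = 1)
classification with Wilson CIs, and ROC/AUC with Youden-index cutoffs.

Writes results/metrics.json, results/score_difference_stats.csv and the
agreement/ROC figures under results/figures/.
"""

import argparse
import dataclasses
import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from petsim.evaluation import (
    agreement_analysis,
    evaluate_method,
    paired_ttest_abs,
    per_subject_average,
    roc_analysis,
    score_difference_stats,
    score_differences,
)
from petsim.volumes import ScoreTable


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--scores", type=Path, default=Path("results/score_table.csv"))
    parser.add_argument("--labels", type=Path, default=Path("scratch/data/study/manifest.csv"))
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    parser.add_argument("--bootstrap-reps", type=int, default=2000)
    args = parser.parse_args()

    table = ScoreTable.from_csv(args.scores)
    labels = pd.read_csv(args.labels)
    orig = ScoreTable(table.df[table.df["method"] == "original"])
    methods = sorted(m for m in table.df["method"].unique() if m != "original")

    figdir = args.outdir / "figures"
    figdir.mkdir(parents=True, exist_ok=True)

    stats = score_difference_stats(table, orig)
    stats.to_csv(args.outdir / "score_difference_stats.csv", index=False, float_format="%.6g")
    print("PET-score differences vs original (per regime):")
    for row in stats.itertuples():
        print(f"  {row.method:11s} {row.kind:8s} mean {row.mean:+.4f}  SD {row.sd:.4f}  "
              f"range [{row.min:+.4f}, {row.max:+.4f}]  (n={row.n})")

    metrics = {"seed": args.seed, "methods": {}}
    if len(methods) == 2:
        diffs = score_differences(table, orig)
        a = diffs[diffs["method"] == methods[0]].copy()
        b = diffs[diffs["method"] == methods[1]].copy()
        a["map_rank"] = a.groupby("subject_id").cumcount()
        b["map_rank"] = b.groupby("subject_id").cumcount()
        merged = a.merge(b, on=["subject_id", "map_rank"], suffixes=("_a", "_b"))
        t, p = paired_ttest_abs(merged["abs_diff_a"].to_numpy(), merged["abs_diff_b"].to_numpy())
        metrics["paired_ttest_abs"] = {"methods": methods, "t": t, "p": p}
        print(f"paired t-test of |error| ({methods[0]} vs {methods[1]}): t = {t:.2f}, p = {p:.2e}")

    means = per_subject_average(table)
    x = means[means["method"] == "original"].set_index("subject_id")["mean_score"]
    for method in methods:
        y = means[means["method"] == method].set_index("subject_id")["mean_score"]
        xv = x.loc[y.index].to_numpy()
        yv = y.to_numpy()
        agr = agreement_analysis(xv, yv)
        rep = evaluate_method(table, labels, method, cutoff=1.0,
                              n_boot=args.bootstrap_reps, seed=args.seed)
        metrics["methods"][method] = {
            "agreement": dataclasses.asdict(agr),
            "report": dataclasses.asdict(rep),
        }
        print(f"{method}: y = {agr.slope:.4f}x + {agr.intercept:.4f}, R^2 = {agr.r_squared:.3f}; "
              f"bias {agr.bias:+.4f}, LOA [{agr.loa_low:.3f}, {agr.loa_high:.3f}]")
        print(f"  cutoff 1.0: accuracy {rep.accuracy:.1%} "
              f"(CI {rep.accuracy_ci[0]:.1%}-{rep.accuracy_ci[1]:.1%}), "
              f"sens {rep.sensitivity:.1%}, spec {rep.specificity:.1%}; "
              f"AUC {rep.auc:.3f} (CI {rep.auc_ci[0]:.3f}-{rep.auc_ci[1]:.3f}); "
              f"Youden cutoff {rep.youden_cutoff:.3f}")

        # agreement figures
        fig, axes = plt.subplots(1, 2, figsize=(9, 4))
        axes[0].scatter(xv, yv, s=12, alpha=0.7)
        lim = [min(xv.min(), yv.min()), max(xv.max(), yv.max())]
        axes[0].plot(lim, lim, "k--", lw=0.8)
        axes[0].plot(lim, [agr.slope * v + agr.intercept for v in lim], "r-", lw=1)
        axes[0].set(xlabel="original PET score", ylabel=f"{method} mean PET score",
                    title=f"y={agr.slope:.3f}x+{agr.intercept:.3f}, R$^2$={agr.r_squared:.3f}")
        d = yv - xv
        axes[1].scatter((xv + yv) / 2, d, s=12, alpha=0.7)
        for yline, style in ((agr.bias, "r-"), (agr.loa_low, "r--"), (agr.loa_high, "r--")):
            axes[1].axhline(yline, ls=style[1:], color="r", lw=0.8)
        axes[1].set(xlabel="mean of scores", ylabel="difference (sim - orig)",
                    title=f"bias {agr.bias:+.3f}, LOA [{agr.loa_low:.3f}, {agr.loa_high:.3f}]")
        fig.tight_layout()
        fig.savefig(figdir / f"agreement_{method}.png", dpi=120)
        plt.close(fig)

    rep = evaluate_method(orig, labels, "original", cutoff=1.0,
                          n_boot=args.bootstrap_reps, seed=args.seed)
    metrics["methods"]["original"] = {"report": dataclasses.asdict(rep)}
    print(f"original: accuracy {rep.accuracy:.1%}, AUC {rep.auc:.3f} "
          f"(CI {rep.auc_ci[0]:.3f}-{rep.auc_ci[1]:.3f})")

    fig, ax = plt.subplots(figsize=(5, 5))
    for method in ["original"] + methods:
        g = table.df[table.df["method"] == method].merge(labels, on="subject_id")
        roc = roc_analysis(g["pet_score"].to_numpy(), (g["diagnosis"] == "AD").to_numpy(),
                           n_boot=2, seed=args.seed)
        pts = roc["roc_points"]
        ax.plot(pts[:, 0], pts[:, 1], label=f"{method} (AUC {roc['auc']:.3f})")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set(xlabel="1 - specificity", ylabel="sensitivity", title="ROC, AD vs NC")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(figdir / "roc.png", dpi=120)
    plt.close(fig)

    (args.outdir / "metrics.json").write_text(json.dumps(metrics, indent=2, sort_keys=True))
    print(f"metrics -> {args.outdir / 'metrics.json'}; figures -> {figdir}/")


if __name__ == "__main__":
    main()
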