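"""Boxplots of study metrics from a finished `run-study` output directory.

Usage: python examples/05_plot_study_metrics.py <study_dir> [out.png]

Reads <study_dir>/metrics_long.tsv (written by `fbdage run-study` or
`fbdage.pipeline.run_study`) and draws per-condition boxplots of fossil-age
relative error, HPD coverage, HPD width and placement accuracy, split by
fossil class.
"""

import sys
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

study_dir = Path(sys.argv[1]) if len(sys.argv) > 1 else Path("study_output")
out = Path(sys.argv[2]) if len(sys.argv) > 2 else study_dir / "metrics.png"
long = pd.read_csv(study_dir / "metrics_long.tsv", sep="\t")

metrics = [
    ("coverage_precise", "95% HPD coverage, precise"),
    ("coverage_imprecise", "95% HPD coverage, imprecise"),
    ("relative_error_precise", "relative error, precise"),
    ("relative_error_imprecise", "relative error, imprecise"),
    ("hpd_width_imprecise", "HPD width (Myr), imprecise"),
    ("placement_imprecise", "correct placement, imprecise"),
]
fig, axes = plt.subplots(2, 3, figsize=(13, 7), sharex=True)
for ax, (metric, title) in zip(axes.ravel(), metrics):
    sub = long[long["metric"] == metric]
    groups = [g["value"].dropna().to_numpy() for _, g in sub.groupby("condition")]
    labels = [c for c, _ in sub.groupby("condition")]
    if groups:
        ax.boxplot(groups, tick_labels=labels)
    ax.set_title(title, fontsize=10)
    ax.tick_params(axis="x", rotation=45, labelsize=8)
fig.tight_layout()
fig.savefig(out, dpi=150)
print(f"wrote {out}")
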