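"""Accuracy metrics for recovered fossil ages, topologies and node times.

Per replicate, the point estimate of a fossil age is the posterior median;
accuracy is the relative error |true - estimate| / true and calibration is
the 95% highest-posterior-density coverage, both averaged separately over
precise-date and imprecise-date fossils.  Topological accuracy is the mean
normalized Robinson-Foulds distance between the true tree and posterior
tree samples (rooted clade comparison; sampled ancestors count as
zero-length tips), and fossil placement accuracy is the fraction of
posterior samples in which the fossil's minimal extant-containing clade
matches the true one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .trees import EXTANT_SAMPLED, FOSSIL, Node, Tree, mrca_age

__all__ = [
    "relative_error",
    "hpd_interval",
    "coverage",
    "normalized_rf",
    "fossil_placement_accuracy",
    "assess_replicate",
    "summarize_replicates",
]


def relative_error(true_value: float, estimate: float) -> float:
    """|true - estimate| / true; requires a positive true value."""
    if true_value <= 0:
        raise ValueError("true_value must be positive")
    return abs(true_value - estimate) / true_value


def hpd_interval(samples: Sequence[float], level: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``ceil(level * n)`` of the samples."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    if n < 20:
        raise ValueError("need at least 20 samples for an HPD interval")
    m = int(np.ceil(level * n))
    widths = x[m - 1:] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])


def coverage(true_value: float, interval: tuple[float, float]) -> int:
    """1 if the true value lies in the closed interval, else 0."""
    lo, hi = interval
    return int(lo <= true_value <= hi)


def normalized_rf(tree_a: Tree, tree_b: Tree) -> float:
    """Normalized rooted Robinson-Foulds distance in [0, 1].

    The symmetric difference of the non-trivial clade sets is divided by
    ``2 (n - 2)``, the maximum for two rooted trees on the same ``n`` tips.
    Sampled-ancestor fossils are already tips in this representation.
    """

    tips_a = {n.label for n in tree_a.leaves()}
    tips_b = {n.label for n in tree_b.leaves()}
    if tips_a != tips_b:
        raise ValueError("trees must share an identical tip set")
    n = len(tips_a)
    if n <= 2:
        return 0.0
    ca, cb = tree_a.clades(), tree_b.clades()
    diff = len(ca ^ cb)
    return diff / (2.0 * (n - 2))


def _extant_clade(tree: Tree, fossil_label: str) -> frozenset:
    """Extant-tip set of the smallest clade containing the fossil and at
    least one extant tip."""
    node = tree.find(fossil_label)
    while node is not None:
        extant = frozenset(
            n.label
            for n in _subtree_leaves(node)
            if n.kind == EXTANT_SAMPLED
        )
        if extant:
            return extant
        node = node.parent
    raise ValueError("tree has no extant tips")


def _subtree_leaves(node: Node):
    stack = [node]
    while stack:
        n = stack.pop()
        if n.is_leaf:
            yield n
        else:
            stack.extend(n.children)


def fossil_placement_accuracy(
    posterior_trees: Iterable[Tree], true_tree: Tree, fossil_label: str
) -> float:
    """Fraction of posterior trees placing the fossil in its true extant clade.

    "Correct" means the extant-tip set of the minimal clade containing the
    fossil together with at least one extant tip equals the corresponding
    set in the true tree.
    """

    truth = _extant_clade(true_tree, fossil_label)
    n = 0
    hits = 0
    for tree in posterior_trees:
        n += 1
        hits += int(_extant_clade(tree, fossil_label) == truth)
    if n == 0:
        raise ValueError("no posterior trees given")
    return hits / n


# ---------------------------------------------------------------------------
# Replicate-level assessment
# ---------------------------------------------------------------------------


def assess_replicate(
    trace_df: pd.DataFrame,
    posterior_trees: Sequence[Tree],
    true_tree: Tree,
    fossil_truth: pd.DataFrame,
    burnin_frac: float = 0.25,
    converged: bool = True,
    level: float = 0.95,
) -> dict:
    """All metrics for one replicate, split by fossil class.

    ``fossil_truth`` columns: fossil_id, true_age, state (1 precise /
    2 imprecise), range_min, range_max.  Fossil age columns of the trace
    are ``age_<fossil_id>``.
    """

    burn = int(len(trace_df) * burnin_frac)
    post = trace_df.iloc[burn:]
    trees = list(posterior_trees[burn:])

    out: dict = {"converged": bool(converged)}
    for cls, name in ((1, "precise"), (2, "imprecise")):
        sub = fossil_truth[fossil_truth["state"] == cls]
        errs, covs, widths, placements = [], [], [], []
        for _, row in sub.iterrows():
            samples = post[f"age_{row['fossil_id']}"].to_numpy()
            med = float(np.median(samples))
            errs.append(relative_error(row["true_age"], med))
            lo, hi = hpd_interval(samples, level)
            covs.append(coverage(row["true_age"], (lo, hi)))
            widths.append(hi - lo)
            if trees:
                placements.append(
                    fossil_placement_accuracy(trees, true_tree, row["fossil_id"])
                )
        out[f"relative_error_{name}"] = float(np.mean(errs)) if errs else np.nan
        out[f"coverage_{name}"] = float(np.mean(covs)) if covs else np.nan
        out[f"hpd_width_{name}"] = float(np.mean(widths)) if widths else np.nan
        out[f"placement_{name}"] = (
            float(np.mean(placements)) if placements else np.nan
        )

    extant_labels = {n.label for n in true_tree.leaves() if n.kind == EXTANT_SAMPLED}
    if trees:
        rf_full = [normalized_rf(true_tree, t) for t in trees]
        out["rf_full"] = float(np.mean(rf_full))
        from .trees import extant_subtree

        true_ext = extant_subtree(true_tree)
        rf_ext = [normalized_rf(true_ext, extant_subtree(t)) for t in trees]
        out["rf_extant"] = float(np.mean(rf_ext))
        # MRCA relative errors: full-tree root age and extant MRCA age
        true_root = true_tree.root.age
        est_root = float(np.median([t.root.age for t in trees]))
        out["mrca_error_full"] = relative_error(true_root, est_root)
        true_mrca = mrca_age(true_tree, extant_labels)
        est_mrca = float(np.median([mrca_age(t, extant_labels) for t in trees]))
        out["mrca_error_extant"] = relative_error(true_mrca, est_mrca)
    return out


def summarize_replicates(reports: Sequence[dict]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Study-level summary over replicates.

    Non-converged replicates are excluded from the metric distributions but
    counted.  Returns ``(long, summary)``: a long-format table
    (condition, replicate, metric, value) ready for boxplots, and a summary
    with means per metric plus the exclusion count.
    """

    if not reports:
        raise ValueError("no replicates to summarize")
    rows = []
    excluded = 0
    for i, rep in enumerate(reports):
        if not rep.get("converged", True):
            excluded += 1
            continue
        for key, value in rep.items():
            if key in ("converged", "condition", "replicate"):
                continue
            rows.append({
                "condition": rep.get("condition", ""),
                "replicate": rep.get("replicate", i),
                "metric": key,
                "value": value,
            })
    if not rows:
        raise RuntimeError("zero converged replicates; nothing to summarize")
    long = pd.DataFrame(rows)
    summary = (
        long.groupby(["condition", "metric"])["value"]
        .agg(["mean", "median", "std", "count"])
        .reset_index()
    )
    summary.attrs["n_excluded"] = excluded
    summary.attrs["n_total"] = len(reports)
    return long, summary
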