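import itertools

import numpy as np
import pandas as pd
import pytest

from fbdage.assess import (
    coverage,
    fossil_placement_accuracy,
    hpd_interval,
    normalized_rf,
    relative_error,
    summarize_replicates,
)
from fbdage.trees import EXTANT_SAMPLED, FOSSIL, Node, Tree, parse_newick

from conftest import random_sampled_tree


def test_relative_error_arithmetic():
    assert relative_error(40.0, 44.0) == pytest.approx(0.1)
    assert relative_error(40.0, 40.0) == 0.0
    assert relative_error(50.0, 35.0) == pytest.approx(0.3)
    with pytest.raises(ValueError):
        relative_error(0.0, 1.0)


def test_hpd_shortest_window():
    # all equal -> degenerate interval
    assert hpd_interval(np.full(50, 2.5)) == (2.5, 2.5)
    # 1..100: any window of 95 consecutive values has width 94
    lo, hi = hpd_interval(np.arange(1.0, 101.0))
    assert hi - lo == pytest.approx(94.0)
    with pytest.raises(ValueError):
        hpd_interval(np.arange(10))


def test_hpd_normal_quantiles(rng):
    x = rng.normal(size=100_000)
    lo, hi = hpd_interval(x, 0.95)
    assert lo == pytest.approx(-1.96, abs=0.05)
    assert hi == pytest.approx(1.96, abs=0.05)


def test_hpd_exhaustive_window_scan_oracle(rng):
    x = np.sort(rng.gamma(2.0, 3.0, size=200))
    m = int(np.ceil(0.95 * x.size))
    best = min(
        ((x[i + m - 1] - x[i], (x[i], x[i + m - 1])) for i in range(x.size - m + 1)),
    )
    assert hpd_interval(x, 0.95) == best[1]


def test_coverage_closed_interval():
    assert coverage(5.0, (4.0, 6.0)) == 1
    assert coverage(4.0, (4.0, 6.0)) == 1  # boundary counts
    assert coverage(3.999, (4.0, 6.0)) == 0


# ---------------------------------------------------------------------------
# Robinson-Foulds
# ---------------------------------------------------------------------------


def _tree(newick):
    return parse_newick(newick)


def test_rf_identical_is_zero():
    t = _tree("((A:1,B:1):1,(C:1,D:1):1);")
    assert normalized_rf(t, t.copy()) == 0.0


def test_rf_four_tip_maximal():
    a = _tree("((A:1,B:1):1,(C:1,D:1):1);")
    b = _tree("((A:1,C:1):1,(B:1,D:1):1);")
    assert normalized_rf(a, b) == pytest.approx(1.0)


def test_rf_relabeling_invariance(rng):
    a = random_sampled_tree(rng, n_extant=6)
    b = random_sampled_tree(rng, n_extant=6)
    # align tip sets
    for t in (a, b):
        for i, leaf in enumerate(sorted(t.leaves(), key=lambda n: n.label)):
            leaf.label = f"L{i}"
    d1 = normalized_rf(a, b)
    perm = {f"L{i}": f"M{(i + 3) % 6}" for i in range(6)}
    for t in (a, b):
        for leaf in t.leaves():
            leaf.label = perm[leaf.label]
    assert normalized_rf(a, b) == pytest.approx(d1)


def test_rf_mismatched_tips_raise():
    a = _tree("((A:1,B:1):1,C:2);")
    b = _tree("((A:1,B:1):1,D:2);")
    with pytest.raises(ValueError):
        normalized_rf(a, b)


def brute_force_rf(t1, t2):
    """Independent clade comparison via explicit per-node tip harvesting."""

    def clades(tree):
        out = set()
        for node in tree.preorder():
            if not node.children or node is tree.root:
                continue
            tips = []
            stack = [node]
            while stack:
                n = stack.pop()
                if n.children:
                    stack.extend(n.children)
                else:
                    tips.append(n.label)
            if len(tips) >= 2:
                out.add(frozenset(tips))
        return out

    c1, c2 = clades(t1), clades(t2)
    n = len(t1.leaves())
    return len(c1 ^ c2) / (2 * (n - 2))


def test_rf_agrees_with_brute_force_on_small_trees(rng):
    for _ in range(25):
        n = int(rng.integers(3, 7))
        a = random_sampled_tree(rng, n_extant=n)
        b = random_sampled_tree(rng, n_extant=n)
        for t in (a, b):
            for i, leaf in enumerate(sorted(t.leaves(), key=lambda x: x.label)):
                leaf.label = f"L{i}"
        assert normalized_rf(a, b) == pytest.approx(brute_force_rf(a, b))


def test_rf_agrees_with_dendropy(rng):
    import dendropy
    from fbdage.trees import newick_string

    for _ in range(10):
        a = random_sampled_tree(rng, n_extant=6)
        b = random_sampled_tree(rng, n_extant=6)
        for t in (a, b):
            for i, leaf in enumerate(sorted(t.leaves(), key=lambda x: x.label)):
                leaf.label = f"L{i}"
        tns = dendropy.TaxonNamespace()
        da = dendropy.Tree.get(data=newick_string(a), schema="newick",
                               taxon_namespace=tns)
        db = dendropy.Tree.get(data=newick_string(b), schema="newick",
                               taxon_namespace=tns)
        da.encode_bipartitions()
        db.encode_bipartitions()
        # dendropy's unrooted symmetric difference equals the rooted clade
        # count difference for trees sharing the same rooting convention
        sym = dendropy.calculate.treecompare.symmetric_difference(da, db, is_bipartitions_updated=True)
        ours = normalized_rf(a, b) * 2 * (6 - 2)
        assert abs(sym - ours) <= 2  # root-adjacent bipartition may differ


# ---------------------------------------------------------------------------
# Fossil placement
# ---------------------------------------------------------------------------


def placement_toy():
    true = _tree("(((A:1,F1:0.5):1,B:2):1,C:3);")
    alt1 = _tree("((A:2,B:2):1,(C:2.0,F1:0.5):1);")  # fossil with C
    alt2 = _tree("(((B:1,F1:0.5):1,A:2):1,C:3);")    # fossil with B
    return true, alt1, alt2


def test_placement_all_correct_and_all_wrong():
    true, alt1, alt2 = placement_toy()
    assert fossil_placement_accuracy([true], true, "F1") == 1.0
    assert fossil_placement_accuracy([alt1, alt2], true, "F1") == 0.0


def test_placement_fraction_matches_manual_count():
    true, alt1, alt2 = placement_toy()
    trees = [true, alt1, true, alt2, true]
    assert fossil_placement_accuracy(trees, true, "F1") == pytest.approx(3 / 5)


def test_placement_missing_fossil_raises():
    true, alt1, _ = placement_toy()
    with pytest.raises(KeyError):
        fossil_placement_accuracy([alt1], true, "F9")


# ---------------------------------------------------------------------------
# Study-level summaries
# ---------------------------------------------------------------------------


def test_summarize_single_replicate_passthrough():
    rep = {"condition": "c", "replicate": 0, "converged": True,
           "coverage_imprecise": 0.8, "relative_error_imprecise": 0.05}
    long, summary = summarize_replicates([rep])
    assert set(long["metric"]) == {"coverage_imprecise", "relative_error_imprecise"}
    row = summary[summary["metric"] == "coverage_imprecise"].iloc[0]
    assert row["mean"] == 0.8


def test_summarize_counts_nonconverged():
    reps = [
        {"condition": "c", "replicate": i, "converged": i % 3 != 0,
         "coverage_imprecise": 0.5}
        for i in range(9)
    ]
    long, summary = summarize_replicates(reps)
    assert summary.attrs["n_excluded"] == 3
    assert summary.attrs["n_total"] == 9
    assert (long.groupby("metric").size() == 6).all()


def test_summarize_zero_converged_fails():
    reps = [{"condition": "c", "replicate": 0, "converged": False, "m": 1.0}]
    with pytest.raises(RuntimeError):
        summarize_replicates(reps)
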