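import itertools

import numpy as np
import pytest
from scipy.linalg import expm

from fbdage.charsim import CharacterMatrix
from fbdage.phylolik import (
    ClockModel,
    HKYModel,
    MkModel,
    batched_transition_matrices,
    discrete_gamma_rates,
    mkv_log_correction,
    morphology_log_likelihood,
    pruning_log_likelihood,
    transition_probabilities,
)
from fbdage.trees import EXTANT_SAMPLED, Node, Tree


def brute_force_log_likelihood(tree, matrix, model, clock):
    """Sum over all interior-state assignments and gamma categories."""
    rates = discrete_gamma_rates(model.gamma_shape, model.n_rate_categories)
    nodes = list(tree.postorder())
    internals = [n for n in nodes if n.children]
    tips = [n for n in nodes if not n.children]
    k = model.stationary().size
    pi = model.stationary()
    total = 0.0
    for site in range(matrix.n_char):
        sitelik = 0.0
        for r in rates:
            P = {}
            for n in nodes:
                if n.parent is not None:
                    d = (n.parent.age - n.age) * clock.rate * r
                    P[id(n)] = expm(model.rate_matrix() * d)
            for assign in itertools.product(range(k), repeat=len(internals)):
                states = {id(n): s for n, s in zip(internals, assign)}
                p = pi[states[id(tree.root)]]
                for n in nodes:
                    if n.parent is None:
                        continue
                    if n.children:
                        p *= P[id(n)][states[id(n.parent)], states[id(n)]]
                    else:
                        obs = matrix.codes[n.label][site]
                        if obs < 0:
                            p *= 1.0
                        else:
                            p *= P[id(n)][states[id(n.parent)], obs]
                sitelik += p
        total += np.log(sitelik / len(rates))
    return total


def chain_tree(ages, labels):
    """Caterpillar tree with given internal ages (old to young)."""
    root = Node(ages[0])
    cur = root
    for i, age in enumerate(ages[1:]):
        nxt = Node(age)
        cur.add_child(nxt)
        cur.add_child(Node(0.0, labels[i], EXTANT_SAMPLED))
        cur = nxt
    cur.add_child(Node(0.0, labels[-2], EXTANT_SAMPLED))
    cur.add_child(Node(0.0, labels[-1], EXTANT_SAMPLED))
    return Tree(root, ages[0] + 1.0)


def balanced_four_tip():
    root = Node(10.0)
    a = root.add_child(Node(4.0))
    b = root.add_child(Node(7.0))
    a.add_child(Node(0.0, "A", EXTANT_SAMPLED))
    a.add_child(Node(0.0, "B", EXTANT_SAMPLED))
    b.add_child(Node(0.0, "C", EXTANT_SAMPLED))
    b.add_child(Node(0.0, "D", EXTANT_SAMPLED))
    return Tree(root, 12.0)


# ---------------------------------------------------------------------------
# Transition probabilities
# ---------------------------------------------------------------------------


def test_duration_zero_is_identity():
    m = HKYModel(kappa=3.0, base_frequencies=(0.4, 0.1, 0.2, 0.3))
    P = transition_probabilities(m, 0.0, ClockModel(0.05))
    assert np.allclose(P, np.eye(4), atol=1e-12)


def test_mk2_closed_form():
    d = 0.9
    P = transition_probabilities(MkModel(2), d, ClockModel(1.0))
    assert P[0, 0] == pytest.approx(0.5 + 0.5 * np.exp(-2 * d), abs=1e-12)
    assert P[0, 1] == pytest.approx(0.5 - 0.5 * np.exp(-2 * d), abs=1e-12)


def test_long_branch_reaches_stationarity():
    m = HKYModel(kappa=5.0, base_frequencies=(0.4, 0.1, 0.2, 0.3))
    P = transition_probabilities(m, 1e6, ClockModel(1.0))
    for row in P:
        assert np.allclose(row, m.base_frequencies, atol=1e-9)


@pytest.mark.parametrize("model", [
    HKYModel(kappa=2.7, base_frequencies=(0.35, 0.15, 0.25, 0.25)),
    MkModel(3),
    MkModel(4),
])
def test_rows_sum_to_one_and_match_expm(model):
    d = np.array([0.0, 0.01, 0.4, 2.5])
    P = batched_transition_matrices(model, d)
    assert np.allclose(P.sum(axis=-1), 1.0, atol=1e-12)
    for i, dd in enumerate(d):
        assert np.allclose(P[i], expm(model.rate_matrix() * dd), atol=1e-10)


# ---------------------------------------------------------------------------
# Pruning likelihood
# ---------------------------------------------------------------------------


def test_two_tip_single_site_matches_direct_computation():
    tree = chain_tree([5.0], ["A", "B"])
    mat = CharacterMatrix.from_strings({"A": "0", "B": "1"}, "standard", [2])
    model = MkModel(2, gamma_shape=1.0, n_rate_categories=1)
    clock = ClockModel(0.1)
    ll = pruning_log_likelihood(tree, mat, model, clock)
    d = 2 * 5.0 * 0.1
    expect = np.log(0.5 * (0.5 - 0.5 * np.exp(-2 * d)))
    assert ll == pytest.approx(expect, abs=1e-12)


@pytest.mark.parametrize("tree_builder,rows,counts", [
    (lambda: chain_tree([8.0, 3.0], ["A", "B", "C"]),
     {"A": "0102", "B": "1100", "C": "010?"}, [2, 3, 2, 3]),
    (balanced_four_tip,
     {"A": "010", "B": "110", "C": "0?1", "D": "101"}, [2, 2, 2]),
])
def test_pruning_equals_brute_force(tree_builder, rows, counts):
    tree = tree_builder()
    mat = CharacterMatrix.from_strings(rows, "standard", counts)
    clock = ClockModel(0.08)
    for k in sorted(set(counts)):
        idx = np.nonzero(np.asarray(counts) == k)[0]
        sub_rows = {t: "".join(rows[t][i] for i in idx) for t in rows}
        sub = CharacterMatrix.from_strings(sub_rows, "standard", [k] * len(idx))
        model = MkModel(k, gamma_shape=0.6, n_rate_categories=3)
        ll = pruning_log_likelihood(tree, sub, model, clock)
        ref = brute_force_log_likelihood(tree, sub, model, clock)
        assert ll == pytest.approx(ref, abs=1e-10)


def test_pruning_hky_equals_brute_force():
    tree = chain_tree([6.0, 2.5], ["A", "B", "C"])
    mat = CharacterMatrix.from_strings({"A": "ACG", "B": "ACT", "C": "?CG"}, "dna")
    model = HKYModel(kappa=4.0, base_frequencies=(0.3, 0.2, 0.3, 0.2),
                     gamma_shape=0.4, n_rate_categories=4)
    clock = ClockModel(0.05)
    ll = pruning_log_likelihood(tree, mat, model, clock)
    ref = brute_force_log_likelihood(tree, mat, model, clock)
    assert ll == pytest.approx(ref, abs=1e-10)


def test_all_missing_column_contributes_nothing():
    tree = balanced_four_tip()
    model = MkModel(2, gamma_shape=1.2, n_rate_categories=2)
    clock = ClockModel(0.05)
    with_col = CharacterMatrix.from_strings(
        {"A": "01?", "B": "11?", "C": "00?", "D": "10?"}, "standard", [2, 2, 2]
    )
    without = CharacterMatrix.from_strings(
        {"A": "01", "B": "11", "C": "00", "D": "10"}, "standard", [2, 2]
    )
    assert pruning_log_likelihood(tree, with_col, model, clock) == pytest.approx(
        pruning_log_likelihood(tree, without, model, clock), abs=1e-12
    )


def test_missing_taxon_contributes_all_ones():
    # dropping a taxon from the matrix equals marking all its states missing
    tree = balanced_four_tip()
    model = MkModel(2, gamma_shape=1.0, n_rate_categories=2)
    clock = ClockModel(0.05)
    full = CharacterMatrix.from_strings(
        {"A": "01", "B": "11", "C": "00", "D": "??"}, "standard", [2, 2]
    )
    partial = CharacterMatrix.from_strings(
        {"A": "01", "B": "11", "C": "00"}, "standard", [2, 2]
    )
    assert pruning_log_likelihood(tree, full, model, clock) == pytest.approx(
        pruning_log_likelihood(tree, partial, model, clock), abs=1e-12
    )


def test_unknown_taxon_raises():
    tree = balanced_four_tip()
    mat = CharacterMatrix.from_strings({"A": "0", "Z": "1"}, "standard", [2])
    with pytest.raises(ValueError):
        pruning_log_likelihood(tree, mat, MkModel(2), ClockModel(0.05))


def test_rerooting_invariance_reversible_model():
    # same unrooted shape and path lengths, different root position
    t1 = chain_tree([5.0], ["A", "B"])  # root midway: 5 + 5
    root = Node(2.0)
    root.add_child(Node(0.0, "A", EXTANT_SAMPLED))
    b = root.add_child(Node(0.0, "B", EXTANT_SAMPLED))
    # stretch B's branch so the path is still 10
    root.children[1] = Node(0.0, "B", EXTANT_SAMPLED)
    root.children[1].parent = root
    root.age = 2.0
    t2 = Tree(root, 3.0)
    # path A-B: t1 = 10, t2 = 4; rescale clock so expected substitutions match
    mat = CharacterMatrix.from_strings({"A": "010", "B": "110"}, "standard", [2] * 3)
    model = MkModel(2, gamma_shape=1.0, n_rate_categories=1)
    ll1 = pruning_log_likelihood(t1, mat, model, ClockModel(0.05))
    ll2 = pruning_log_likelihood(t2, mat, model, ClockModel(0.125))
    assert ll1 == pytest.approx(ll2, abs=1e-10)


def test_one_category_equals_no_rate_variation():
    tree = balanced_four_tip()
    mat = CharacterMatrix.from_strings(
        {"A": "01", "B": "11", "C": "00", "D": "10"}, "standard", [2, 2]
    )
    clock = ClockModel(0.07)
    lls = [
        pruning_log_likelihood(tree, mat, MkModel(2, gamma_shape=s, n_rate_categories=1), clock)
        for s in (0.01, 1.0, 100.0)
    ]
    assert lls[0] == pytest.approx(lls[1], abs=1e-12)
    assert lls[1] == pytest.approx(lls[2], abs=1e-12)


# ---------------------------------------------------------------------------
# Variable-only (Mkv) ascertainment
# ---------------------------------------------------------------------------


def test_mkv_correction_matches_pattern_enumeration():
    tree = chain_tree([8.0, 3.0], ["A", "B", "C"])
    model = MkModel(2, gamma_shape=0.7, n_rate_categories=3)
    clock = ClockModel(0.06)
    # enumerate all 8 patterns on the 3-tip binary tree
    p_inv = 0.0
    for pattern in itertools.product("01", repeat=3):
        if len(set(pattern)) > 1:
            continue
        rows = dict(zip("ABC", ["".join(p) for p in zip(pattern)]))
        mat = CharacterMatrix.from_strings(rows, "standard", [2])
        p_inv += np.exp(brute_force_log_likelihood(tree, mat, model, clock))
    corr = mkv_log_correction(tree, model, clock, n_chars=17)
    assert corr == pytest.approx(17 * np.log1p(-p_inv), abs=1e-10)


def test_mkv_correction_degenerate_tree_raises():
    root = Node(0.0)
    root.add_child(Node(0.0, "A", EXTANT_SAMPLED))
    root.add_child(Node(0.0, "B", EXTANT_SAMPLED))
    tree = Tree(root, 0.0)
    with pytest.raises(FloatingPointError):
        mkv_log_correction(tree, MkModel(2), ClockModel(0.05), 10)


def test_morphology_likelihood_conditioning_toggle():
    tree = balanced_four_tip()
    mat = CharacterMatrix.from_strings(
        {"A": "010", "B": "112", "C": "001", "D": "100"}, "standard", [2, 2, 3]
    )
    clock = ClockModel(0.1)
    raw = morphology_log_likelihood(tree, mat, clock, conditioned=False)
    cond = morphology_log_likelihood(tree, mat, clock, conditioned=True)
    assert cond > raw  # dividing by P(variable) < 1 raises the likelihood
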