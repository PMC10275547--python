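"""Felsenstein pruning likelihoods under strict clocks.

Two substitution models are supported:

* HKY with discrete-gamma rate variation for the molecular partition
  (extant taxa only; taxa absent from the alignment contribute all-ones
  partial likelihoods, so fossil tips are transparent to this partition);
* the symmetric k-state Mk model with discrete-gamma rates for morphology,
  with an optional correction conditioning on characters being variable
  (the "Mkv" ascertainment correction), applied separately per state-count
  class because binary, ternary and quaternary characters have different
  invariant-pattern probabilities.

Branch lengths are durations in Myr; expected substitutions per branch are
``duration * clock_rate * category_rate``.  Partial likelihoods are rescaled
per node and pattern to avoid underflow at alignment sizes of thousands of
sites, and identical columns are collapsed into weighted patterns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numba import njit
from scipy.stats import gamma as _gamma_dist

from .trees import Node, Tree

__all__ = [
    "ClockModel",
    "HKYModel",
    "MkModel",
    "discrete_gamma_rates",
    "transition_probabilities",
    "TreeArrays",
    "pruning_log_likelihood",
    "mkv_log_correction",
    "morphology_log_likelihood",
]


@dataclass
class ClockModel:
    """Strict clock: one rate, in expected substitutions per site per Myr."""

    rate: float

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("clock rate must be positive")


@dataclass
class HKYModel:
    kappa: float = 2.0
    base_frequencies: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    gamma_shape: float = 0.35
    n_rate_categories: int = 5

    def __post_init__(self) -> None:
        f = np.asarray(self.base_frequencies, dtype=float)
        if np.any(f < 0) or abs(f.sum() - 1.0) > 1e-8:
            raise ValueError("base frequencies must be non-negative and sum to 1")
        if self.kappa <= 0 or self.gamma_shape <= 0:
            raise ValueError("kappa and gamma_shape must be positive")

    @property
    def n_states(self) -> int:
        return 4

    def rate_matrix(self) -> np.ndarray:
        """HKY rate matrix normalized to one expected substitution per unit."""
        pi = np.asarray(self.base_frequencies, dtype=float)
        k = self.kappa
        # state order A, C, G, T; transitions: A<->G, C<->T
        Q = np.empty((4, 4))
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                ti = (i, j) in ((0, 2), (2, 0), (1, 3), (3, 1))
                Q[i, j] = (k if ti else 1.0) * pi[j]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mean_rate = -np.sum(pi * np.diag(Q))
        return Q / mean_rate

    def stationary(self) -> np.ndarray:
        return np.asarray(self.base_frequencies, dtype=float)


@dataclass
class MkModel:
    """Symmetric k-state model with unit total rate away from each state."""

    n_states: int = 2
    gamma_shape: float = 0.35
    n_rate_categories: int = 5

    def __post_init__(self) -> None:
        if self.n_states < 2:
            raise ValueError("n_states must be >= 2")
        if self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be positive")

    def rate_matrix(self) -> np.ndarray:
        k = self.n_states
        Q = np.full((k, k), 1.0 / (k - 1))
        np.fill_diagonal(Q, -1.0)
        return Q

    def stationary(self) -> np.ndarray:
        return np.full(self.n_states, 1.0 / self.n_states)


def discrete_gamma_rates(shape: float, n_categories: int) -> np.ndarray:
    """Mean-one discretized gamma rates (category medians, equal weights).

    Medians of the ``n`` equal-probability slices of Gamma(shape, 1/shape)
    are normalized by their mean, so the discretized distribution has mean
    exactly 1 for any shape.
    """

    if n_categories < 1:
        raise ValueError("n_categories must be >= 1")
    return _discrete_gamma_cached(float(shape), int(n_categories)).copy()


from functools import lru_cache as _lru_cache


@_lru_cache(maxsize=4096)
def _discrete_gamma_cached(shape: float, n_categories: int) -> np.ndarray:
    if n_categories == 1:
        return np.ones(1)
    q = (2.0 * np.arange(n_categories) + 1.0) / (2.0 * n_categories)
    med = _gamma_dist.ppf(q, a=shape, scale=1.0 / shape)
    return med / med.mean()


# ---------------------------------------------------------------------------
# Transition probabilities
# ---------------------------------------------------------------------------


def _eigen(model) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Reversible-model eigendecomposition: Q = U diag(lam) U^-1."""
    Q = model.rate_matrix()
    pi = model.stationary()
    sq = np.sqrt(pi)
    S = (Q * sq[:, None]) / sq[None, :]  # D^1/2 Q D^-1/2, symmetric
    lam, V = np.linalg.eigh((S + S.T) / 2.0)
    U = V / sq[:, None]
    Uinv = V.T * sq[None, :]
    return lam, U, Uinv


def batched_transition_matrices(model, eff_lengths: np.ndarray) -> np.ndarray:
    """P matrices for an array of expected-substitution branch lengths.

    ``eff_lengths`` may have any shape; the result appends two state axes.
    The symmetric Mk model uses its two-eigenvalue closed form; general
    reversible models go through a cached eigendecomposition.
    """

    d = np.asarray(eff_lengths, dtype=float)
    if isinstance(model, MkModel):
        k = model.n_states
        e = np.exp(-k * d / (k - 1.0))
        P = np.empty(d.shape + (k, k))
        off = (1.0 - e) / k
        P[...] = off[..., None, None]
        idx = np.arange(k)
        P[..., idx, idx] = off[..., None] + e[..., None]
        return P
    lam, U, Uinv = _eigen_cached(model)
    e = np.exp(d[..., None] * lam)  # (..., k)
    P = (U[None, :, :] * e.reshape(-1, 1, lam.size)) @ Uinv  # (N, k, k)
    P = P.reshape(d.shape + (lam.size, lam.size))
    np.clip(P, 0.0, 1.0, out=P)
    # renormalize rows, removing accumulated rounding
    P /= P.sum(axis=-1, keepdims=True)
    return P


def _eigen_cached(model):
    key = None
    if isinstance(model, HKYModel):
        key = ("hky", model.kappa, model.base_frequencies)
    if key is not None and key == getattr(_eigen_cached, "_key", None):
        return _eigen_cached._value
    value = _eigen(model)
    if key is not None:
        _eigen_cached._key = key
        _eigen_cached._value = value
    return value


def transition_probabilities(
    model, duration: float, clock: ClockModel, category_rate: float = 1.0
) -> np.ndarray:
    """Stochastic matrix for one branch of the given duration (Myr)."""
    if duration < 0:
        raise ValueError("duration must be non-negative")
    d = duration * clock.rate * category_rate
    return batched_transition_matrices(model, np.array(d))


# ---------------------------------------------------------------------------
# Tree serialization for the pruning kernel
# ---------------------------------------------------------------------------


class TreeArrays:
    """Postorder array view of a binary time tree.

    ``durations[i]`` is the time length of the branch above node ``i`` (the
    root's branch runs to the origin).  Leaves carry their taxon labels.
    """

    def __init__(self, tree: Tree):
        nodes = list(tree.postorder())
        index = {id(n): i for i, n in enumerate(nodes)}
        n = len(nodes)
        self.post = np.arange(n, dtype=np.int64)  # postorder == storage order
        self.left = np.full(n, -1, dtype=np.int64)
        self.right = np.full(n, -1, dtype=np.int64)
        self.durations = np.empty(n, dtype=float)
        self.labels: list[Optional[str]] = [None] * n
        self.root_index = index[id(tree.root)]
        for i, node in enumerate(nodes):
            if node.children:
                if len(node.children) != 2:
                    raise ValueError("pruning requires a bifurcating tree")
                self.left[i] = index[id(node.children[0])]
                self.right[i] = index[id(node.children[1])]
            else:
                self.labels[i] = node.label
            self.durations[i] = tree.branch_parent_age(node) - node.age
        self.n_nodes = n

    def tip_codes(self, matrix_codes: dict[str, np.ndarray], n_pat: int) -> np.ndarray:
        """Per-node pattern codes; -1 (missing) for absent taxa and internals."""
        codes = np.full((self.n_nodes, n_pat), -1, dtype=np.int16)
        for i, lab in enumerate(self.labels):
            if lab is not None and lab in matrix_codes:
                codes[i] = matrix_codes[lab]
        return codes


@njit(cache=True)
def _prune_sitelik(left, right, P, tipcodes, root_index, freqs):
    """Per-pattern log-likelihoods (gamma-category averaged)."""
    n_nodes = left.shape[0]
    ncat = P.shape[1]
    k = P.shape[2]
    npat = tipcodes.shape[1]
    partial = np.empty((n_nodes, ncat, npat, k))
    logscale = np.zeros(npat)
    for idx in range(n_nodes):
        l = left[idx]
        r = right[idx]
        if l < 0:
            for p in range(npat):
                s = tipcodes[idx, p]
                for c in range(ncat):
                    for j in range(k):
                        partial[idx, c, p, j] = 1.0 if s < 0 else 0.0
                    if s >= 0:
                        partial[idx, c, p, s] = 1.0
            continue
        for c in range(ncat):
            Pl = P[l, c]
            Pr = P[r, c]
            for p in range(npat):
                for i in range(k):
                    sl = 0.0
                    sr = 0.0
                    for j in range(k):
                        sl += Pl[i, j] * partial[l, c, p, j]
                        sr += Pr[i, j] * partial[r, c, p, j]
                    partial[idx, c, p, i] = sl * sr
        # per-pattern rescaling to avoid underflow
        for p in range(npat):
            m = 0.0
            for c in range(ncat):
                for i in range(k):
                    v = partial[idx, c, p, i]
                    if v > m:
                        m = v
            if m > 0.0 and (m < 1e-80 or m > 1e80):
                for c in range(ncat):
                    for i in range(k):
                        partial[idx, c, p, i] /= m
                logscale[p] += np.log(m)
    out = np.empty(npat)
    for p in range(npat):
        site = 0.0
        for c in range(ncat):
            acc = 0.0
            for i in range(k):
                acc += freqs[i] * partial[root_index, c, p, i]
            site += acc
        site /= ncat
        if site <= 0.0:
            out[p] = -np.inf
        else:
            out[p] = np.log(site) + logscale[p]
    return out


def _prune_kernel(left, right, P, tipcodes, root_index, freqs, weights):
    """Weighted total log-likelihood over patterns."""
    sitelik = _prune_sitelik(left, right, P, tipcodes, root_index, freqs)
    if not np.all(np.isfinite(sitelik)):
        return -np.inf
    return float(np.dot(weights, sitelik))


def compress_patterns(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Collapse identical columns; returns (unique columns, weights)."""
    cols, counts = np.unique(codes, axis=1, return_counts=True)
    return cols, counts.astype(float)


def _matrix_codes(matrix, taxa: list[str], char_idx: np.ndarray):
    """dict taxon -> int16 pattern codes, plus pattern weights."""
    block = np.stack([np.asarray(matrix.codes[t], dtype=np.int16)[char_idx] for t in taxa])
    cols, weights = compress_patterns(block)
    return {t: cols[i] for i, t in enumerate(taxa)}, weights, cols.shape[1]


def pruning_log_likelihood(
    tree: Tree,
    matrix,
    model,
    clock: ClockModel,
    use_stem: bool = False,
    char_idx: Optional[np.ndarray] = None,
    arrays: Optional[TreeArrays] = None,
) -> float:
    """Log-likelihood of a character matrix on a time tree.

    ``matrix`` needs attributes ``taxa`` (list of names), ``codes`` (dict
    name -> integer state codes with -1 for '?') and ``n_char``.  Taxa
    present in the matrix but absent from the tree raise ``ValueError``;
    tree tips absent from the matrix contribute all-ones partials.  The
    branch from the root to the origin carries no data and is ignored.
    """

    ta = arrays if arrays is not None else TreeArrays(tree)
    tree_labels = {lab for lab in ta.labels if lab is not None}
    missing = [t for t in matrix.taxa if t not in tree_labels]
    if missing:
        raise ValueError(f"matrix taxa absent from tree: {missing[:5]}")
    idx = np.arange(matrix.n_char) if char_idx is None else np.asarray(char_idx)
    if idx.size == 0:
        return 0.0
    codes, weights, n_pat = _matrix_codes(matrix, matrix.taxa, idx)
    tipcodes = ta.tip_codes(codes, n_pat)
    rates = discrete_gamma_rates(model.gamma_shape, model.n_rate_categories)
    eff = ta.durations[:, None] * clock.rate * rates[None, :]
    if not use_stem:
        eff[ta.root_index] = 0.0
    P = batched_transition_matrices(model, eff)
    return float(
        _prune_kernel(
            ta.left, ta.right, P, tipcodes, ta.root_index, model.stationary(), weights
        )
    )


def mkv_log_correction(
    tree: Tree,
    model: MkModel,
    clock: ClockModel,
    n_chars: int,
    arrays: Optional[TreeArrays] = None,
) -> float:
    """Variable-characters ascertainment term ``n_chars * log(1 - P_inv)``.

    ``P_inv`` is the probability that a character is invariant across all
    tips, computed by pruning the k constant dummy columns.  The returned
    value is *subtracted* from the unconditioned log-likelihood to condition
    on variability.  Degenerate trees where ``P_inv`` reaches 1 raise
    ``FloatingPointError``.
    """

    ta = arrays if arrays is not None else TreeArrays(tree)
    k = model.n_states
    n_tips = sum(1 for lab in ta.labels if lab is not None)
    # k constant patterns: every tip shows state s in pattern s
    tipcodes = np.full((ta.n_nodes, k), -1, dtype=np.int16)
    const = np.arange(k, dtype=np.int16)
    for i, lab in enumerate(ta.labels):
        if lab is not None:
            tipcodes[i] = const
    rates = discrete_gamma_rates(model.gamma_shape, model.n_rate_categories)
    eff = ta.durations[:, None] * clock.rate * rates[None, :]
    eff[ta.root_index] = 0.0
    P = batched_transition_matrices(model, eff)
    sitelik = _prune_sitelik(
        ta.left, ta.right, P, tipcodes, ta.root_index, model.stationary()
    )
    p_inv = float(np.exp(sitelik).sum())
    if p_inv >= 1.0 - 1e-15:
        raise FloatingPointError("invariant-pattern probability reached 1")
    return n_chars * np.log1p(-p_inv)


def morphology_log_likelihood(
    tree: Tree,
    matrix,
    clock: ClockModel,
    gamma_shape: float = 0.35,
    n_rate_categories: int = 5,
    conditioned: bool = True,
    arrays: Optional[TreeArrays] = None,
) -> float:
    """Mk(+v) log-likelihood over a mixed-state-count morphological matrix.

    Characters are grouped by their state count; each class gets its own Mk
    model and, when ``conditioned`` is true, its own variable-only
    ascertainment correction.
    """

    ta = arrays if arrays is not None else TreeArrays(tree)
    state_counts = np.asarray(matrix.state_counts)
    total = 0.0
    for k in sorted(set(int(s) for s in state_counts)):
        idx = np.nonzero(state_counts == k)[0]
        model = MkModel(n_states=k, gamma_shape=gamma_shape, n_rate_categories=n_rate_categories)
        ll = pruning_log_likelihood(tree, matrix, model, clock, char_idx=idx, arrays=ta)
        if conditioned:
            ll -= mkv_log_correction(tree, model, clock, len(idx), arrays=ta)
        total += ll
    return float(total)
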