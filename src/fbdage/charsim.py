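"""Simulation of molecular alignments and morphological matrices.

Molecular sequences evolve along the extant-restricted tree under HKY with
discrete-gamma rate variation and a strict clock; fossils carry no molecular
data.  Morphological characters evolve along the full sampled tree (extant
and fossil tips) under the symmetric Mk model with a mixed number of states
per character (by default 70% binary, 20% ternary, 10% quaternary) and
discrete-gamma rates.  Characters invariant across all tips are discarded
and re-simulated until the configured number of *variable* characters is
reached, emulating the ascertainment of real morphological matrices.  A
fixed proportion of "soft" characters is re-coded as missing in every fossil
taxon, emulating characters that do not preserve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings
from typing import Iterable, Optional

import numpy as np

from .phylolik import HKYModel, MkModel, batched_transition_matrices, discrete_gamma_rates
from .trees import Tree, extant_subtree

__all__ = [
    "MolecularModelConfig",
    "MorphModelConfig",
    "CharacterMatrix",
    "simulate_molecular",
    "simulate_morphology",
    "mask_soft_characters",
]

DNA_SYMBOLS = "ACGT"
MISSING = -1


@dataclass
class MolecularModelConfig:
    """HKY+gamma strict-clock simulation settings for the extant alignment."""

    n_sites: int = 4500
    gamma_shape: float = 0.35
    n_rate_categories: int = 5
    clock_rate: float = 0.05  # expected substitutions / site / Myr
    kappa: float = 2.0
    base_frequencies: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def model(self) -> HKYModel:
        return HKYModel(
            kappa=self.kappa,
            base_frequencies=self.base_frequencies,
            gamma_shape=self.gamma_shape,
            n_rate_categories=self.n_rate_categories,
        )


@dataclass
class MorphModelConfig:
    """Mk+gamma strict-clock simulation settings for the morphology matrix."""

    n_chars: int = 120
    state_count_mix: dict[int, float] = field(
        default_factory=lambda: {2: 0.70, 3: 0.20, 4: 0.10}
    )
    gamma_shape: float = 0.35
    n_rate_categories: int = 5
    clock_rate: float = 0.1  # expected substitutions / character / Myr
    soft_char_prop: float = 0.05
    variable_only: bool = True

    def __post_init__(self) -> None:
        tot = sum(self.state_count_mix.values())
        if abs(tot - 1.0) > 1e-8:
            raise ValueError("state_count_mix proportions must sum to 1")
        if not 0.0 <= self.soft_char_prop <= 1.0:
            raise ValueError("soft_char_prop must be in [0, 1]")


class CharacterMatrix:
    """Taxon-by-character matrix of integer state codes (-1 = missing '?')."""

    def __init__(
        self,
        taxa: list[str],
        codes: dict[str, np.ndarray],
        state_counts: np.ndarray,
        datatype: str,
    ):
        self.taxa = list(taxa)
        self.codes = {t: np.asarray(codes[t], dtype=np.int16) for t in taxa}
        self.state_counts = np.asarray(state_counts, dtype=np.int64)
        self.datatype = datatype  # "dna" or "standard"
        for t in taxa:
            if self.codes[t].shape[0] != self.n_char:
                raise ValueError("ragged character matrix")
            bad = self.codes[t] >= self.state_counts
            if np.any(bad):
                raise ValueError(f"state code out of range for taxon {t}")

    @property
    def n_char(self) -> int:
        return int(self.state_counts.shape[0])

    def row_string(self, taxon: str) -> str:
        symbols = DNA_SYMBOLS if self.datatype == "dna" else "0123456789"
        return "".join(
            "?" if c < 0 else symbols[c] for c in self.codes[taxon]
        )

    @classmethod
    def from_strings(
        cls, rows: dict[str, str], datatype: str, state_counts=None
    ) -> "CharacterMatrix":
        taxa = list(rows)
        if not taxa:
            raise ValueError("empty matrix")
        n = len(rows[taxa[0]])
        codes = {}
        for t, s in rows.items():
            if datatype == "dna":
                code = [MISSING if ch in "?-NX" else DNA_SYMBOLS.index(ch) for ch in s.upper()]
            else:
                code = [MISSING if ch in "?-" else int(ch) for ch in s]
            codes[t] = np.asarray(code, dtype=np.int16)
        if state_counts is None:
            if datatype == "dna":
                state_counts = np.full(n, 4)
            else:
                stacked = np.stack([codes[t] for t in taxa])
                state_counts = np.maximum(stacked.max(axis=0) + 1, 2)
        return cls(taxa, codes, np.asarray(state_counts), datatype)


def _evolve_sites(
    tree: Tree,
    model,
    clock_rate: float,
    n_sites: int,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Simulate ``n_sites`` i.i.d. characters down a time tree.

    Per-site gamma categories are drawn with equal probability; the root
    state is drawn from the stationary distribution and the stem branch
    carries no substitutions (data are conditioned on the root state being
    at stationarity, which is the same distribution at the origin).
    """

    rates = discrete_gamma_rates(model.gamma_shape, model.n_rate_categories)
    ncat = model.n_rate_categories
    k = model.rate_matrix().shape[0]
    pi = model.stationary()
    cats = rng.integers(ncat, size=n_sites)
    states: dict[int, np.ndarray] = {}
    root_state = rng.choice(k, size=n_sites, p=pi)
    out: dict[str, np.ndarray] = {}

    order = list(tree.preorder())
    states[id(tree.root)] = root_state
    if tree.root.is_leaf:
        out[tree.root.label] = root_state
    for node in order:
        if node is tree.root:
            continue
        dur = node.parent.age - node.age
        parent_state = states[id(node.parent)]
        if dur <= 0.0:
            child_state = parent_state.copy()
        else:
            eff = dur * clock_rate * rates  # (ncat,)
            P = batched_transition_matrices(model, eff)  # (ncat, k, k)
            cum = np.cumsum(P, axis=-1)
            child_state = np.empty(n_sites, dtype=np.int64)
            for c in range(ncat):
                for s in range(k):
                    m = (cats == c) & (parent_state == s)
                    nm = int(m.sum())
                    if nm:
                        u = rng.random(nm)
                        child_state[m] = np.searchsorted(cum[c, s], u, side="right")
        np.clip(child_state, 0, k - 1, out=child_state)
        states[id(node)] = child_state
        if node.is_leaf:
            out[node.label] = child_state
    return out


def simulate_molecular(
    tree: Tree,
    config: MolecularModelConfig,
    seed_or_rng=None,
) -> CharacterMatrix:
    """Simulate the molecular alignment for the sampled extant taxa only."""

    rng = _as_rng(seed_or_rng)
    sub = extant_subtree(tree)
    if sub.n_leaves() < 2:
        raise ValueError("need at least two extant tips for an alignment")
    tips = _evolve_sites(sub, config.model(), config.clock_rate, config.n_sites, rng)
    taxa = sorted(tips)
    return CharacterMatrix(
        taxa, {t: tips[t] for t in taxa}, np.full(config.n_sites, 4), "dna"
    )


def simulate_morphology(
    tree: Tree,
    config: MorphModelConfig,
    seed_or_rng=None,
) -> CharacterMatrix:
    """Simulate the morphological matrix for all sampled taxa.

    Each character draws its state count from the configured mix and then
    evolves under Mk; with ``variable_only`` characters invariant across all
    tips are replaced (re-simulated with the same state count) until the
    matrix holds exactly ``n_chars`` variable characters, so the realized
    state-count mix stays multinomial around the configured proportions.
    """

    rng = _as_rng(seed_or_rng)
    ks = sorted(config.state_count_mix)
    probs = np.array([config.state_count_mix[k] for k in ks])
    draw = rng.choice(len(ks), size=config.n_chars, p=probs)
    taxa = sorted(n.label for n in tree.leaves())
    columns = np.empty((len(taxa), config.n_chars), dtype=np.int16)
    state_counts = np.array([ks[i] for i in draw])

    for ki, k in enumerate(ks):
        idx = np.nonzero(draw == ki)[0]
        if idx.size == 0:
            continue
        model = MkModel(
            n_states=k,
            gamma_shape=config.gamma_shape,
            n_rate_categories=config.n_rate_categories,
        )
        need = idx
        while need.size:
            tips = _evolve_sites(tree, model, config.clock_rate, need.size, rng)
            block = np.stack([tips[t] for t in taxa])
            columns[:, need] = block
            if not config.variable_only:
                break
            invariant = np.all(block == block[0], axis=0)
            need = need[invariant]
    return CharacterMatrix(
        taxa, {t: columns[i] for i, t in enumerate(taxa)}, state_counts, "standard"
    )


def mask_soft_characters(
    matrix: CharacterMatrix,
    fossil_taxa: Iterable[str],
    prop: float = 0.05,
    seed_or_rng=None,
) -> CharacterMatrix:
    """Recode a random ``round(prop * n_char)`` columns as '?' in fossils.

    Extant rows are untouched.  With an empty fossil set the matrix is
    returned unchanged with a warning.
    """

    fossil_taxa = [t for t in fossil_taxa]
    rng = _as_rng(seed_or_rng)
    n_mask = int(round(prop * matrix.n_char))
    if not fossil_taxa:
        warnings.warn("no fossil taxa given; soft-character masking skipped")
        return matrix
    cols = rng.choice(matrix.n_char, size=n_mask, replace=False) if n_mask else []
    codes = {t: matrix.codes[t].copy() for t in matrix.taxa}
    for t in fossil_taxa:
        if t not in codes:
            raise ValueError(f"fossil taxon {t} not in matrix")
        codes[t][cols] = MISSING
    return CharacterMatrix(matrix.taxa, codes, matrix.state_counts, matrix.datatype)


def _as_rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)
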