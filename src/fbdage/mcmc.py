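"""Metropolis-Hastings sampler for Bayesian total-evidence dating.

The state is a sampled time tree (topology, node ages, fossil attachment and
sampled-ancestor configuration), per-fossil ages bounded by their assigned
age ranges, the FBD rates (speciation, extinction, fossil recovery), two
strict-clock rates, the HKY kappa and the two gamma shapes.  The extant
sampling probability rho is fixed to its true value and never proposed.

Priors follow the study design: Exponential(10) on the three FBD rates and
on both clock rates, uniform priors on each fossil age over its assigned
range, and a bounded-uniform prior on the origin age.  Kappa and the gamma
shapes, whose priors the study delegates to standard tutorial choices, get
Exponential(0.5) and Exponential(1) respectively (configurable).

Moves are a random-scan mixture of scale moves on scalar parameters,
uniform node-age slides, reflected fossil-age slides, a reflected origin
slide, narrow exchange on the topology, subtree reattachment for fossil
tips, and a reversible-jump toggle converting a fossil tip into a sampled
ancestor and back.  Every kernel returns the log-Hastings ratio that makes
detailed balance hold.

Chain lengths here count individual proposals.  The study this package
follows ran chains of up to 1.5e8 generations in a compiled sampler; the
desk-scale defaults are far shorter and are meant for the reduced data
sizes used throughout the package.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd

from . import phylolik
from .fbdprior import FBDParameters, fbd_log_density
from .phylolik import (
    ClockModel,
    HKYModel,
    MkModel,
    TreeArrays,
    batched_transition_matrices,
    discrete_gamma_rates,
)
from .trees import EXTANT_SAMPLED, FOSSIL, Node, Tree, newick_string

__all__ = [
    "MCMCConfig",
    "ModelState",
    "PosteriorTrace",
    "Posterior",
    "log_posterior",
    "propose",
    "run_chain",
    "ess",
    "check_convergence",
]

NEG_INF = float("-inf")

SCALAR_PARAMS = (
    "lambda", "mu", "psi", "clock_mol", "clock_morph",
    "kappa", "shape_mol", "shape_morph",
)


@dataclass
class MCMCConfig:
    n_generations: int = 200_000
    sample_every: int = 200
    seed: int = 1
    burnin_frac: float = 0.25
    move_weights: dict = field(default_factory=lambda: {
        "scale_lambda": 1.0, "scale_mu": 1.0, "scale_psi": 1.0,
        "scale_clock_mol": 1.0, "scale_clock_morph": 1.0,
        "scale_kappa": 1.0, "scale_shape_mol": 1.0, "scale_shape_morph": 1.0,
        "origin_slide": 1.0,
        "node_age_slide": 5.0,
        "fossil_age_slide": 5.0,
        "narrow_exchange": 3.0,
        "fossil_reattach": 2.0,
        "sa_toggle": 2.0,
    })
    scale_delta: float = 0.7        # log-multiplier half-width for scale moves
    fossil_age_delta: float = 4.0   # Myr window for fossil-age slides
    origin_delta: float = 10.0      # Myr window for origin slides
    rate_prior_rate: float = 10.0   # Exponential(10) on FBD rates and clocks
    kappa_prior_rate: float = 0.5
    shape_prior_rate: float = 1.0
    origin_max: float = 150.0
    fixed_topology: bool = False
    likelihood_on: bool = True
    tree_prior_on: bool = True  # off only for pure parameter-prior validation
    full_check_every: int = 10_000
    stall_limit: int = 100_000


@dataclass
class ModelState:
    """One point in the posterior: tree plus scalar parameters."""

    tree: Tree
    params: dict
    rho: float

    def copy_tree(self) -> "ModelState":
        return ModelState(self.tree.copy(), dict(self.params), self.rho)

    def copy_params(self) -> "ModelState":
        return ModelState(self.tree, dict(self.params), self.rho)

    def fbd_parameters(self) -> FBDParameters:
        return FBDParameters(
            lam=self.params["lambda"], mu=self.params["mu"],
            psi=self.params["psi"], rho=self.rho,
            origin_age=self.tree.origin_age,
        )


@dataclass
class PosteriorTrace:
    """Sampled scalars (one row per retained generation) plus tree samples."""

    df: pd.DataFrame
    trees: list
    acceptance: dict

    def posterior_series(self) -> np.ndarray:
        return self.df["posterior"].to_numpy()

    def fossil_age_columns(self) -> list:
        return [c for c in self.df.columns if c.startswith("age_")]


# ---------------------------------------------------------------------------
# Posterior evaluation
# ---------------------------------------------------------------------------


class Posterior:
    """Caches pattern-compressed data and evaluates posterior components.

    ``fossil_ranges`` maps fossil taxon labels to (min_age, max_age); every
    fossil tip of a state's tree must have a range.  ``alignment`` or
    ``morphology`` may be None (that partition is then skipped), and
    ``likelihood_on=False`` yields prior-only evaluation for validation
    runs.
    """

    def __init__(
        self,
        alignment=None,
        morphology=None,
        fossil_ranges: Optional[dict] = None,
        config: Optional[MCMCConfig] = None,
        base_frequencies: tuple = (0.25, 0.25, 0.25, 0.25),
    ):
        self.config = config or MCMCConfig()
        self.base_frequencies = tuple(base_frequencies)
        self.fossil_ranges = dict(fossil_ranges or {})
        self.alignment = alignment
        self.morphology = morphology
        self._mol = None
        self._morph_classes = None
        if alignment is not None:
            idx = np.arange(alignment.n_char)
            codes, weights, n_pat = phylolik._matrix_codes(alignment, alignment.taxa, idx)
            self._mol = (codes, weights)
        if morphology is not None:
            sc = np.asarray(morphology.state_counts)
            self._morph_classes = []
            for k in sorted(set(int(s) for s in sc)):
                idx = np.nonzero(sc == k)[0]
                codes, weights, n_pat = phylolik._matrix_codes(
                    morphology, morphology.taxa, idx
                )
                self._morph_classes.append((k, len(idx), codes, weights))

    # -- components --------------------------------------------------------

    def log_prior_params(self, state: ModelState) -> float:
        c = self.config
        lp = 0.0
        for name in ("lambda", "mu", "psi", "clock_mol", "clock_morph"):
            x = state.params[name]
            if x <= 0:
                return NEG_INF
            lp += math.log(c.rate_prior_rate) - c.rate_prior_rate * x
        for name, rate in (("kappa", c.kappa_prior_rate),
                           ("shape_mol", c.shape_prior_rate),
                           ("shape_morph", c.shape_prior_rate)):
            x = state.params[name]
            if x <= 0:
                return NEG_INF
            lp += math.log(rate) - rate * x
        x0 = state.tree.origin_age
        if not 0.0 < x0 <= c.origin_max:
            return NEG_INF
        # uniform fossil-age priors: constant inside ranges, -inf outside
        for tip in state.tree.leaves():
            if tip.kind == FOSSIL:
                rng_ = self.fossil_ranges.get(tip.label)
                if rng_ is None:
                    raise ValueError(f"no age range for fossil {tip.label}")
                lo, hi = rng_
                if not lo - 1e-9 <= tip.age <= hi + 1e-9:
                    return NEG_INF
        return lp

    def log_fbd(self, state: ModelState) -> float:
        if not self.config.tree_prior_on:
            return 0.0
        return fbd_log_density(state.tree, state.fbd_parameters())

    def log_mol(self, state: ModelState) -> float:
        if self._mol is None or not self.config.likelihood_on:
            return 0.0
        from .trees import extant_subtree

        codes, weights = self._mol
        sub = extant_subtree(state.tree)
        ta = TreeArrays(sub)
        model = HKYModel(
            kappa=state.params["kappa"],
            base_frequencies=self.base_frequencies,
            gamma_shape=state.params["shape_mol"],
        )
        return self._partition_loglik(
            ta, codes, weights, model, state.params["clock_mol"]
        )

    def log_morph(self, state: ModelState) -> float:
        if self._morph_classes is None or not self.config.likelihood_on:
            return 0.0
        ta = TreeArrays(state.tree)
        total = 0.0
        clock = state.params["clock_morph"]
        shape = state.params["shape_morph"]
        for k, n_chars, codes, weights in self._morph_classes:
            model = MkModel(n_states=k, gamma_shape=shape)
            rates = discrete_gamma_rates(shape, model.n_rate_categories)
            eff = ta.durations[:, None] * clock * rates[None, :]
            eff[ta.root_index] = 0.0
            P = batched_transition_matrices(model, eff)
            freqs = model.stationary()
            npat = len(weights)
            # data patterns plus the k constant patterns used for the
            # variable-only ascertainment term, in a single kernel pass
            tipcodes = np.full((ta.n_nodes, npat + k), -1, dtype=np.int16)
            tipcodes[:, :npat] = ta.tip_codes(codes, npat)
            row = np.arange(k, dtype=np.int16)
            for i, lab in enumerate(ta.labels):
                if lab is not None:
                    tipcodes[i, npat:] = row
            sl = phylolik._prune_sitelik(
                ta.left, ta.right, P, tipcodes, ta.root_index, freqs
            )
            if not np.all(np.isfinite(sl[:npat])):
                return NEG_INF
            total += float(np.dot(weights, sl[:npat]))
            p_inv = float(np.exp(sl[npat:]).sum())
            if p_inv >= 1.0 - 1e-15:
                return NEG_INF
            total -= n_chars * math.log1p(-p_inv)
        return total

    def _partition_loglik(self, ta, codes, weights, model, clock_rate) -> float:
        rates = discrete_gamma_rates(model.gamma_shape, model.n_rate_categories)
        eff = ta.durations[:, None] * clock_rate * rates[None, :]
        eff[ta.root_index] = 0.0
        P = batched_transition_matrices(model, eff)
        tipcodes = ta.tip_codes(codes, len(weights))
        return float(phylolik._prune_kernel(
            ta.left, ta.right, P, tipcodes, ta.root_index,
            model.stationary(), np.asarray(weights, dtype=float),
        ))

    def components(self, state: ModelState) -> tuple:
        lp = self.log_prior_params(state)
        if lp == NEG_INF:
            return NEG_INF, NEG_INF, NEG_INF, NEG_INF
        fbd = self.log_fbd(state)
        if fbd == NEG_INF:
            return lp, fbd, NEG_INF, NEG_INF
        return lp, fbd, self.log_mol(state), self.log_morph(state)


def log_posterior(state: ModelState, posterior: Posterior) -> float:
    """Full log-posterior; -inf (never an exception) for invalid states."""
    lp, fbd, mol, morph = posterior.components(state)
    total = lp + fbd + mol + morph
    return total if math.isfinite(total) else NEG_INF


# ---------------------------------------------------------------------------
# Move kernels
# ---------------------------------------------------------------------------


def _reflect(x: float, lo: float, hi: float) -> float:
    """Fold a real number into [lo, hi] by reflection at both bounds."""
    width = hi - lo
    if width <= 0:
        return lo
    y = (x - lo) % (2.0 * width)
    return lo + (y if y <= width else 2.0 * width - y)


def _fossil_tips(tree: Tree) -> list:
    return [n for n in tree.leaves() if n.kind == FOSSIL]


def _move_scale(name: str):
    def kernel(state: ModelState, rng, cfg: MCMCConfig):
        new = state.copy_params()
        u = rng.uniform(-cfg.scale_delta, cfg.scale_delta)
        new.params[name] *= math.exp(u)
        flags = {
            "lambda": ("fbd",), "mu": ("fbd",), "psi": ("fbd",),
            "clock_mol": ("mol",), "kappa": ("mol",), "shape_mol": ("mol",),
            "clock_morph": ("morph",), "shape_morph": ("morph",),
        }[name]
        return new, u, flags
    return kernel


def _move_origin(state: ModelState, rng, cfg: MCMCConfig):
    new = state.copy_params()
    new.tree = Tree(state.tree.root, state.tree.origin_age)  # shallow: nodes shared
    lo, hi = state.tree.root.age, cfg.origin_max
    prop = _reflect(state.tree.origin_age + rng.uniform(-cfg.origin_delta, cfg.origin_delta), lo, hi)
    new.tree.origin_age = prop
    return new, 0.0, ("fbd",)


def _bifurcation_nodes(tree: Tree) -> list:
    """Internal nodes whose age is free (not tied to a sampled-ancestor)."""
    out = []
    for n in tree.internal_nodes():
        if any(c.is_leaf and c.sampled_ancestor for c in n.children):
            continue
        out.append(n)
    return out


def _move_node_age(state: ModelState, rng, cfg: MCMCConfig):
    new = state.copy_tree()
    nodes = _bifurcation_nodes(new.tree)
    if not nodes:
        return None
    node = nodes[rng.integers(len(nodes))]
    lower = max(c.age for c in node.children)
    upper = new.tree.branch_parent_age(node)
    if upper <= lower:
        return None
    node.age = lower + (upper - lower) * rng.random()
    mol = _extant_relevant(node)
    return new, 0.0, ("fbd", "morph", "mol") if mol else ("fbd", "morph")


def _extant_relevant(node: Node) -> bool:
    """True when the node is a bifurcation of the extant-restricted tree."""
    def has_extant(n: Node) -> bool:
        stack = [n]
        while stack:
            m = stack.pop()
            if m.is_leaf:
                if m.kind == EXTANT_SAMPLED:
                    return True
            else:
                stack.extend(m.children)
        return False

    return sum(1 for c in node.children if has_extant(c)) >= 2


def _move_fossil_age(state: ModelState, rng, cfg: MCMCConfig, ranges: dict):
    new = state.copy_tree()
    fossils = _fossil_tips(new.tree)
    if not fossils:
        return None
    tip = fossils[rng.integers(len(fossils))]
    lo, hi = ranges[tip.label]
    if tip.sampled_ancestor:
        node = tip.parent
        other = [c for c in node.children if c is not tip][0]
        lower = max(lo, other.age)
        upper = min(hi, new.tree.branch_parent_age(node))
        if upper <= lower:
            return None
        age = _reflect(tip.age + rng.uniform(-cfg.fossil_age_delta, cfg.fossil_age_delta), lower, upper)
        node.age = age
        tip.age = age
    else:
        lower = lo
        upper = min(hi, tip.parent.age if tip.parent else new.tree.origin_age)
        if upper <= lower:
            return None
        tip.age = _reflect(tip.age + rng.uniform(-cfg.fossil_age_delta, cfg.fossil_age_delta), lower, upper)
    return new, 0.0, ("fbd", "morph")


def _nodes_with_grandparent(tree: Tree) -> list:
    return [
        n for n in tree.preorder()
        if n.parent is not None and n.parent.parent is not None
    ]


def _move_narrow_exchange(state: ModelState, rng, cfg: MCMCConfig):
    new = state.copy_tree()
    cands = _nodes_with_grandparent(new.tree)
    if not cands:
        return None
    node = cands[rng.integers(len(cands))]
    parent = node.parent
    grand = parent.parent
    uncle = [c for c in grand.children if c is not parent][0]
    # validity: swapping node and uncle must keep ages ordered and must not
    # detach a sampled-ancestor tip from its attachment node
    if node.sampled_ancestor or uncle.sampled_ancestor:
        return None
    if uncle.age >= parent.age:
        return None
    # swap
    grand.children[grand.children.index(uncle)] = node
    parent.children[parent.children.index(node)] = uncle
    node.parent = grand
    uncle.parent = parent
    mol = _subtree_has_extant(node) or _subtree_has_extant(uncle)
    return new, 0.0, ("fbd", "morph", "mol") if mol else ("fbd", "morph")


def _subtree_has_extant(node: Node) -> bool:
    stack = [node]
    while stack:
        n = stack.pop()
        if n.is_leaf:
            if n.kind == EXTANT_SAMPLED:
                return True
        else:
            stack.extend(n.children)
    return False


def _detach_fossil(tree: Tree, tip: Node) -> tuple:
    """Remove a fossil tip and its attachment node; return (sibling, old_top).

    ``old_top`` is the age of the upper end of the branch the fossil's
    attachment node sat on (in the detached tree the sibling's branch spans
    old_top down to the sibling's age).
    """

    parent = tip.parent
    sibling = [c for c in parent.children if c is not tip][0]
    grand = parent.parent
    if grand is None:
        old_top = tree.origin_age
        sibling.parent = None
        tree.root = sibling
    else:
        old_top = grand.age
        grand.children[grand.children.index(parent)] = sibling
        sibling.parent = grand
    return sibling, old_top


def _attach_fossil(tree: Tree, tip: Node, target: Node, attach_age: float) -> None:
    new_node = Node(attach_age, None, "speciation")
    parent = target.parent
    if parent is None:
        tree.root = new_node
    else:
        parent.children[parent.children.index(target)] = new_node
        new_node.parent = parent
    new_node.add_child(target)
    new_node.add_child(tip)


def _move_fossil_reattach(state: ModelState, rng, cfg: MCMCConfig):
    new = state.copy_tree()
    tips = [n for n in _fossil_tips(new.tree) if not n.sampled_ancestor]
    if not tips:
        return None
    tip = tips[rng.integers(len(tips))]
    if tip.parent is None:
        return None
    sib = [c for c in tip.parent.children if c is not tip][0]
    if sib.sampled_ancestor:
        # the sibling is pinned to the attachment node's age; removing the
        # node would break its zero-length-branch invariant
        return None
    sibling, old_top = _detach_fossil(new.tree, tip)
    len_old = old_top - max(tip.age, sibling.age)
    # candidate branches of the detached tree: any branch whose upper end is
    # older than the fossil age
    cands = []
    for n in new.tree.preorder():
        top = new.tree.branch_parent_age(n)
        if top > tip.age and not (n.is_leaf and n.sampled_ancestor):
            cands.append((n, top))
    if not cands:
        return None
    target, top = cands[rng.integers(len(cands))]
    lower = max(tip.age, target.age)
    len_new = top - lower
    if len_new <= 0:
        return None
    attach_age = lower + len_new * rng.random()
    _attach_fossil(new.tree, tip, target, attach_age)
    log_hastings = math.log(len_new) - math.log(len_old)
    return new, log_hastings, ("fbd", "morph")


def _move_sa_toggle(state: ModelState, rng, cfg: MCMCConfig):
    new = state.copy_tree()
    fossils = _fossil_tips(new.tree)
    if not fossils:
        return None
    tip = fossils[rng.integers(len(fossils))]
    parent = tip.parent
    if parent is None:
        return None
    top = new.tree.branch_parent_age(parent)
    other = [c for c in parent.children if c is not tip][0]
    if tip.sampled_ancestor:
        # expand: sampled ancestor -> fossil tip with free attachment age
        length = top - tip.age
        if length <= 0 or other.sampled_ancestor:
            return None
        parent.age = tip.age + length * rng.random()
        tip.sampled_ancestor = False
        return new, math.log(length), ("fbd", "morph")
    # collapse: fossil tip -> sampled ancestor at the fossil age
    if other.age >= tip.age or tip.age >= top:
        return None
    length = top - tip.age
    parent.age = tip.age
    tip.sampled_ancestor = True
    return new, -math.log(length), ("fbd", "morph")


def propose(state: ModelState, move: str, rng, cfg: MCMCConfig, ranges: dict):
    """Apply one move kernel; returns (new_state, log_hastings, flags) or None.

    ``None`` means the move was inapplicable (no-op; counted as rejected).
    ``flags`` names the posterior components invalidated by the move.
    """

    if move.startswith("scale_"):
        name = {"scale_lambda": "lambda", "scale_mu": "mu", "scale_psi": "psi",
                "scale_clock_mol": "clock_mol", "scale_clock_morph": "clock_morph",
                "scale_kappa": "kappa", "scale_shape_mol": "shape_mol",
                "scale_shape_morph": "shape_morph"}[move]
        return _move_scale(name)(state, rng, cfg)
    if move == "origin_slide":
        return _move_origin(state, rng, cfg)
    if move == "node_age_slide":
        return _move_node_age(state, rng, cfg)
    if move == "fossil_age_slide":
        return _move_fossil_age(state, rng, cfg, ranges)
    if move == "narrow_exchange":
        return _move_narrow_exchange(state, rng, cfg)
    if move == "fossil_reattach":
        return _move_fossil_reattach(state, rng, cfg)
    if move == "sa_toggle":
        return _move_sa_toggle(state, rng, cfg)
    raise ValueError(f"unknown move {move!r}")


# ---------------------------------------------------------------------------
# Chain driver
# ---------------------------------------------------------------------------


def _active_moves(cfg: MCMCConfig, posterior: Posterior) -> tuple:
    weights = dict(cfg.move_weights)
    if cfg.fixed_topology:
        for m in ("narrow_exchange", "fossil_reattach", "sa_toggle"):
            weights.pop(m, None)
    if posterior.alignment is None or not cfg.likelihood_on:
        pass  # kappa/shape still sampled from their priors; harmless
    names = [m for m, w in weights.items() if w > 0]
    w = np.array([weights[m] for m in names], dtype=float)
    return names, w / w.sum()


def run_chain(
    posterior: Posterior,
    init: ModelState,
    cfg: Optional[MCMCConfig] = None,
) -> PosteriorTrace:
    """Run one Metropolis-Hastings chain and return its trace.

    The trace has one row every ``sample_every`` proposals with the log
    posterior decomposition, all scalar parameters, the origin and root
    ages, and one column per fossil age; tree samples (Newick) are stored in
    parallel.  A stall warning is emitted if every proposal in a long
    stretch is rejected.
    """

    cfg = cfg or posterior.config
    rng = np.random.default_rng(cfg.seed)
    names, probs = _active_moves(cfg, posterior)
    ranges = posterior.fossil_ranges

    state = init.copy_tree()
    lp, fbd, mol, morph = posterior.components(state)
    if not all(map(math.isfinite, (lp, fbd, mol, morph))):
        raise ValueError("initial state has zero posterior probability")

    fossil_labels = sorted(t.label for t in _fossil_tips(state.tree))
    rows = []
    trees = []
    accepted = {m: 0 for m in names}
    attempted = {m: 0 for m in names}
    since_accept = 0

    def record(gen):
        row = {
            "state": gen,
            "posterior": lp + fbd + mol + morph,
            "likelihood": mol + morph,
            "prior": lp + fbd,
            "origin_age": state.tree.origin_age,
            "root_age": state.tree.root.age,
        }
        for name in SCALAR_PARAMS:
            row[name] = state.params[name]
        ages = {t.label: t.age for t in _fossil_tips(state.tree)}
        for lab in fossil_labels:
            row[f"age_{lab}"] = ages[lab]
            lo, hi = ranges[lab]
            assert lo - 1e-9 <= ages[lab] <= hi + 1e-9, "fossil age left its range"
        rows.append(row)
        trees.append(newick_string(state.tree))

    record(0)
    for gen in range(1, cfg.n_generations + 1):
        move = names[rng.choice(len(names), p=probs)]
        attempted[move] += 1
        result = propose(state, move, rng, cfg, ranges)
        if result is not None:
            new_state, log_hastings, flags = result
            new_lp = posterior.log_prior_params(new_state)
            if math.isfinite(new_lp):
                new_fbd = posterior.log_fbd(new_state) if "fbd" in flags else fbd
                new_mol = posterior.log_mol(new_state) if "mol" in flags else mol
                new_morph = posterior.log_morph(new_state) if "morph" in flags else morph
                new_post = new_lp + new_fbd + new_mol + new_morph
                cur_post = lp + fbd + mol + morph
                if math.isfinite(new_post) and (
                    math.log(rng.random()) < new_post - cur_post + log_hastings
                ):
                    state, lp, fbd, mol, morph = new_state, new_lp, new_fbd, new_mol, new_morph
                    accepted[move] += 1
                    since_accept = 0
                else:
                    since_accept += 1
            else:
                since_accept += 1
        else:
            since_accept += 1
        if since_accept >= cfg.stall_limit:
            warnings.warn(f"no accepted move in {since_accept} proposals")
            since_accept = 0
        if cfg.full_check_every and gen % cfg.full_check_every == 0:
            clp, cfbd, cmol, cmorph = posterior.components(state)
            drift = abs((lp + fbd + mol + morph) - (clp + cfbd + cmol + cmorph))
            if drift > 1e-6 * max(1.0, abs(clp + cfbd + cmol + cmorph)):
                raise AssertionError(
                    f"cached posterior drifted by {drift} at generation {gen}"
                )
            lp, fbd, mol, morph = clp, cfbd, cmol, cmorph
        if gen % cfg.sample_every == 0:
            record(gen)

    df = pd.DataFrame(rows)
    acc = {
        m: (accepted[m] / attempted[m] if attempted[m] else float("nan"))
        for m in names
    }
    return PosteriorTrace(df=df, trees=trees, acceptance=acc)


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------


def ess(series) -> float:
    """Effective sample size from the autocorrelation time.

    A constant series is reported as ESS 0, which deliberately forces the
    convergence check to fail (a flat trace carries no information about
    mixing).
    """

    x = np.asarray(series, dtype=float)
    if x.size < 10:
        raise ValueError("need at least 10 samples for an ESS estimate")
    if np.ptp(x) == 0.0:
        return 0.0
    import arviz

    value = float(arviz.ess(x))
    if not math.isfinite(value):
        return 0.0
    return value


def check_convergence(
    trace_a: PosteriorTrace,
    trace_b: PosteriorTrace,
    burnin_frac: float = 0.25,
) -> tuple:
    """Study convergence rule: posterior ESS >= 200 in each chain and
    post-burnin posterior medians within 10% (relative) of each other.

    Returns ``(converged, report)``.
    """

    report = {}
    meds = []
    for label, trace in (("a", trace_a), ("b", trace_b)):
        x = trace.posterior_series()
        burn = int(len(x) * burnin_frac)
        if burn >= len(x) - 10:
            raise ValueError("trace shorter than burn-in")
        x = x[burn:]
        report[f"ess_{label}"] = ess(x)
        meds.append(float(np.median(x)))
    report["median_a"], report["median_b"] = meds
    denom = max(abs(meds[0]), abs(meds[1]))
    rel = abs(meds[0] - meds[1]) / denom if denom > 0 else 0.0
    report["median_rel_diff"] = rel
    converged = (
        report["ess_a"] >= 200.0 and report["ess_b"] >= 200.0 and rel <= 0.10
    )
    report["converged"] = converged
    return converged, report


# ---------------------------------------------------------------------------
# Initial states
# ---------------------------------------------------------------------------


def initial_state(
    true_tree: Tree,
    fossil_ranges: dict,
    rho: float,
    rng: Optional[np.random.Generator] = None,
    origin_age: Optional[float] = None,
    randomize_fossil_ages: bool = True,
) -> ModelState:
    """Build a starting state from a reference topology.

    The tree topology is taken from ``true_tree`` (a standard starting-tree
    shortcut); fossil ages are redrawn uniformly from their prior ranges
    (truncated to keep the tree valid) so the chain does not start at the
    true ages; scalar parameters start at their prior means.
    """

    rng = rng or np.random.default_rng()
    tree = true_tree.copy()
    if origin_age is not None:
        tree.origin_age = origin_age
    if randomize_fossil_ages:
        for tip in tree.leaves():
            if tip.kind != FOSSIL:
                continue
            lo, hi = fossil_ranges[tip.label]
            if tip.sampled_ancestor:
                node = tip.parent
                other = [c for c in node.children if c is not tip][0]
                lower = max(lo, other.age)
                upper = min(hi, tree.branch_parent_age(node))
                if upper > lower:
                    age = lower + (upper - lower) * rng.random()
                    node.age = age
                    tip.age = age
            else:
                upper = min(hi, tip.parent.age if tip.parent else tree.origin_age)
                if upper > lo:
                    tip.age = lo + (upper - lo) * rng.random()
    params = {
        "lambda": 0.1, "mu": 0.1, "psi": 0.1,
        "clock_mol": 0.1, "clock_morph": 0.1,
        "kappa": 2.0, "shape_mol": 1.0, "shape_morph": 1.0,
    }
    return ModelState(tree=tree, params=params, rho=rho)
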