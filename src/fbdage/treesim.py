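"""Forward birth-death simulation of complete trees.

The process starts from a single lineage at the origin age and runs toward
the present under constant speciation rate ``lam`` and extinction rate ``mu``.
Lineages reaching the present are independently marked as sampled with
probability ``rho``.  Survival conditioning is done purely by rejection
(:func:`accept_tree`), mirroring the study design this package reimplements:
trees with fewer than ``min_extant_sampled`` or more than
``max_extant_sampled`` sampled extant tips are discarded by the caller.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .trees import (
    EXTANT_SAMPLED,
    EXTANT_UNSAMPLED,
    EXTINCT,
    FOSSIL,
    SPECIATION,
    Node,
    Tree,
)

__all__ = ["BirthDeathConfig", "simulate_complete_tree", "accept_tree", "prune_to_reconstructed"]


@dataclass
class BirthDeathConfig:
    """Parameters of the complete-tree simulation.

    Defaults are the study conditions: origin 120 Myr, speciation 0.05 /Myr,
    extinction 0.02 /Myr, extant sampling probability 0.5, and acceptance of
    trees with 20-30 sampled extant tips.
    """

    origin_age: float = 120.0
    lam: float = 0.05
    mu: float = 0.02
    rho: float = 0.5
    min_extant_sampled: int = 20
    max_extant_sampled: int = 30
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("lam must be positive")
        if self.mu < 0:
            raise ValueError("mu must be non-negative")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must be in [0, 1]")
        if self.origin_age <= 0:
            raise ValueError("origin_age must be positive")
        if self.min_extant_sampled > self.max_extant_sampled:
            raise ValueError("min_extant_sampled must be <= max_extant_sampled")


def simulate_complete_tree(
    config: BirthDeathConfig, rng: Optional[np.random.Generator] = None
) -> Tree:
    """Simulate one complete birth-death tree (no acceptance applied).

    The returned tree contains every lineage, including extinct subtrees and
    unsampled extant tips; it may have zero extant tips if the clade died
    out.  Rejection against the extant-sample window is the caller's job via
    :func:`accept_tree`.
    """

    if rng is None:
        rng = np.random.default_rng(config.seed)
    lam, mu, rho = config.lam, config.mu, config.rho
    total = lam + mu

    tip_counter = 0

    def evolve(start_age: float) -> Node:
        nonlocal tip_counter
        root_holder: Optional[Node] = None

        stack: list[tuple[Optional[Node], float]] = [(None, start_age)]
        while stack:
            parent, age = stack.pop()
            while True:
                wait = rng.exponential(1.0 / total)
                new_age = age - wait
                if new_age <= 0.0:
                    tip_counter += 1
                    sampled = rng.random() < rho
                    kind = EXTANT_SAMPLED if sampled else EXTANT_UNSAMPLED
                    node = Node(0.0, f"T{tip_counter}", kind)
                    break
                if rng.random() < lam / total:
                    node = Node(new_age, None, SPECIATION)
                    stack.append((node, new_age))
                    stack.append((node, new_age))
                    break
                tip_counter += 1
                node = Node(new_age, f"X{tip_counter}", EXTINCT)
                break
            if parent is None:
                root_holder = node
            else:
                parent.add_child(node)
        assert root_holder is not None
        return root_holder

    root = evolve(config.origin_age)
    return Tree(root, config.origin_age)


def accept_tree(tree: Tree, config: BirthDeathConfig) -> bool:
    """True iff the sampled extant tip count is inside the acceptance window."""
    n = sum(1 for tip in tree.leaves() if tip.kind == EXTANT_SAMPLED)
    return config.min_extant_sampled <= n <= config.max_extant_sampled


def simulate_accepted_tree(
    config: BirthDeathConfig,
    rng: np.random.Generator,
    max_attempts: int = 100_000,
) -> tuple[Tree, int]:
    """Simulate until :func:`accept_tree` passes; returns (tree, attempts)."""
    for attempt in range(1, max_attempts + 1):
        tree = simulate_complete_tree(config, rng)
        if accept_tree(tree, config):
            return tree, attempt
    raise RuntimeError(f"no accepted tree in {max_attempts} attempts")


# ---------------------------------------------------------------------------
# Reconstructed (sampled) tree
# ---------------------------------------------------------------------------


def prune_to_reconstructed(tree: Tree, fossils) -> Tree:
    """Minimal time tree connecting sampled extant tips and fossils.

    ``fossils`` is an iterable of occurrence records with attributes
    ``label``, ``branch`` (a node of ``tree``: the younger end of the branch
    the fossil sits on) and ``true_age``.  Fossils on lineages ancestral to
    other samples become sampled-ancestor tips (zero-length branches); all
    other fossils become tips attached at the true divergence age from the
    sampled part of the tree.  All retained node ages are preserved.
    """

    by_branch: dict[int, list] = {}
    for f in fossils:
        top = tree.branch_parent_age(f.branch)
        if not (f.branch.age - 1e-9 <= f.true_age <= top + 1e-9):
            raise ValueError(
                f"fossil {f.label} at age {f.true_age} outside branch "
                f"interval ({f.branch.age}, {top})"
            )
        by_branch.setdefault(id(f.branch), []).append(f)
    for lst in by_branch.values():
        lst.sort(key=lambda f: f.true_age)  # youngest first

    def rec(node: Node) -> Optional[Node]:
        if node.is_leaf:
            current = (
                Node(0.0, node.label, EXTANT_SAMPLED)
                if node.kind == EXTANT_SAMPLED
                else None
            )
        else:
            kept = [r for r in (rec(c) for c in node.children) if r is not None]
            if len(kept) >= 2:
                current = Node(node.age, None, SPECIATION)
                for k in kept:
                    current.add_child(k)
            elif len(kept) == 1:
                current = kept[0]
            else:
                current = None
        # thread fossils on this branch, youngest -> oldest
        for f in by_branch.get(id(node), []):
            if current is None:
                current = Node(f.true_age, f.label, FOSSIL)
            else:
                attach = Node(f.true_age, None, SPECIATION)
                sa_tip = Node(f.true_age, f.label, FOSSIL, sampled_ancestor=True)
                attach.add_child(sa_tip)
                attach.add_child(current)
                current = attach
        return current

    root = rec(tree.root)
    if root is None:
        raise ValueError("no sampled tips or fossils to reconstruct from")
    return Tree(root, tree.origin_age)
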