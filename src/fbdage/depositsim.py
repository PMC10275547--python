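"""Deposit membership, fossil sampling and age-range construction.

A two-state trait identifies lineages belonging to a poorly dated deposit
(state 2) inside a fixed time window (default 30-50 Myr before present,
modelled on the Baltic amber deposit).  Every lineage alive at the older
window edge starts in state 1 and switches 1->2 with rate ``q12`` and back
with rate ``q21``; outside the window the state is 1 by definition.  Fossils
are drawn along *every* branch of the complete tree by an inhomogeneous
Poisson process with rate ``psi_int`` inside the window and ``psi_bg``
outside.  A fossil takes the lineage state at its age: state-1 fossils are
"precise-date" (individually narrow age ranges), state-2 fossils are
"imprecise-date" (all share the deposit's 30-50 range).

Replicates are rejected unless the total fossil count lies in
``n_fossils_range`` and the realized state-2 proportion is within 10%
(relative) of the target proportion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .trees import Node, Tree

__all__ = [
    "DepositConfig",
    "FossilOccurrence",
    "FossilRecord",
    "TraitPaths",
    "simulate_trait",
    "sample_fossils",
    "accept_fossils",
    "build_age_ranges",
    "impose_deposit_interval",
    "TABLE1",
]

#: Calibrated (q12, q21, psi_bg, psi_int) per target imprecise proportion.
TABLE1: dict[float, tuple[float, float, float, float]] = {
    0.1: (0.6, 0.7, 0.03, 0.04),
    0.3: (0.8, 0.5, 0.02, 0.08),
    0.5: (1.0, 0.4, 0.01, 0.15),
}


@dataclass
class DepositConfig:
    """Parameters of the deposit-trait and fossil-sampling process."""

    window: tuple[float, float] = (30.0, 50.0)  # (young, old) in Myr
    q12: float = 0.6
    q21: float = 0.7
    psi_bg: float = 0.03
    psi_int: float = 0.04
    target_prop: float = 0.1
    prop_tolerance: float = 0.10  # relative band around target_prop
    n_fossils_range: tuple[int, int] = (45, 55)
    precise_range_multiplier: float = 0.1
    max_attempts: int = 10_000
    # proportion rejection can be switched off for matched-model validation
    # runs that use a constant rate and no deposit trait
    enforce_proportion: bool = True
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        lo, hi = self.window
        if not lo < hi:
            raise ValueError("window must be (young, old) with young < old")
        for r in (self.q12, self.q21, self.psi_bg, self.psi_int):
            if r < 0:
                raise ValueError("rates must be non-negative")
        if not 0.0 < self.target_prop < 1.0:
            raise ValueError("target_prop must be in (0, 1)")

    @classmethod
    def from_table(cls, target_prop: float, **kwargs) -> "DepositConfig":
        """Config for one calibrated condition (target 0.1, 0.3 or 0.5)."""
        q12, q21, psi_bg, psi_int = TABLE1[target_prop]
        return cls(
            q12=q12, q21=q21, psi_bg=psi_bg, psi_int=psi_int,
            target_prop=target_prop, **kwargs,
        )


@dataclass
class FossilOccurrence:
    label: str
    branch: Node  # younger end of the complete-tree branch carrying it
    true_age: float
    state: int  # 1 = precise-date, 2 = imprecise-date (deposit)
    range_min: Optional[float] = None
    range_max: Optional[float] = None


FossilRecord = list  # list[FossilOccurrence]


class TraitPaths:
    """Piecewise-constant deposit state along each branch inside the window.

    For each branch (keyed by ``id`` of its younger node) we store the state
    at the branch's older end inside the window and the ordered transition
    ages.  Outside the window the state is 1 everywhere.
    """

    def __init__(self, window: tuple[float, float]):
        self.window = window
        # id(node) -> (entry_state, list of transition ages, descending)
        self.paths: dict[int, tuple[int, list[float]]] = {}
        # state at the younger end of each branch, used for inheritance
        self.end_state: dict[int, int] = {}

    def state_at(self, branch: Node, age: float) -> int:
        lo, hi = self.window
        if age > hi or age < lo:
            return 1
        entry_state, transitions = self.paths.get(id(branch), (1, []))
        state = entry_state
        for t_age in transitions:
            if t_age >= age:
                state = 2 if state == 1 else 1
            else:
                break
        return state

    def fraction_in_state2(self, branch: Node, top: float, bottom: float) -> float:
        """Time fraction spent in state 2 on [bottom, top] ∩ window."""
        lo, hi = self.window
        a, b = min(top, hi), max(bottom, lo)
        if b >= a:
            return 0.0
        entry_state, transitions = self.paths.get(id(branch), (1, []))
        # walk from the top of the in-window segment downwards
        state = self.state_at(branch, a)
        t2 = 0.0
        cur = a
        for t_age in transitions:
            if t_age >= a:
                continue
            if t_age <= b:
                break
            if state == 2:
                t2 += cur - t_age
            cur = t_age
            state = 2 if state == 1 else 1
        if state == 2:
            t2 += cur - b
        return t2 / (a - b)


def simulate_trait(
    tree: Tree, config: DepositConfig, rng: Optional[np.random.Generator] = None
) -> TraitPaths:
    """Simulate the two-state deposit trait along the tree inside the window.

    Every lineage alive at the older window edge starts in state 1; daughters
    inherit the parental state at speciation; with ``q12 = 0`` everything
    stays in state 1.
    """

    if rng is None:
        rng = np.random.default_rng(config.seed)
    lo, hi = config.window
    q12, q21 = config.q12, config.q21
    paths = TraitPaths(config.window)

    for node in tree.preorder():
        top = tree.branch_parent_age(node)
        bottom = node.age
        seg_top, seg_bot = min(top, hi), max(bottom, lo)
        if seg_bot >= seg_top:
            # branch does not intersect the window
            if node.parent is not None and bottom >= hi:
                paths.end_state[id(node)] = 1
            else:
                # below the window (or zero overlap): state frozen at 1 or
                # inherited end state for bookkeeping
                paths.end_state[id(node)] = paths.end_state.get(
                    id(node.parent), 1
                ) if node.parent is not None and node.parent.age >= lo else 1
            continue
        # entry state: 1 if the branch top is at/above the window top,
        # else inherited from the parent's end state
        if top >= hi:
            entry = 1
        else:
            entry = paths.end_state.get(id(node.parent), 1)
        transitions: list[float] = []
        state = entry
        age = seg_top
        while True:
            rate = q12 if state == 1 else q21
            if rate <= 0.0:
                break
            age -= rng.exponential(1.0 / rate)
            if age <= seg_bot:
                break
            transitions.append(age)
            state = 2 if state == 1 else 1
        paths.paths[id(node)] = (entry, transitions)
        # state at the younger branch end (inside window) for inheritance;
        # if the branch exits the window at the bottom the state resets to 1
        paths.end_state[id(node)] = state if bottom >= lo else 1
        if bottom < lo:
            # lineage exits the window: descendants below lo are state 1
            pass
    return paths


def sample_fossils(
    tree: Tree,
    traits: TraitPaths,
    config: DepositConfig,
    rng: Optional[np.random.Generator] = None,
) -> FossilRecord:
    """Poisson fossil sampling with piecewise-constant rates on every branch.

    Rate ``psi_int`` applies where the age lies in the closed window, and
    ``psi_bg`` elsewhere.  Each occurrence records the lineage's trait state
    at its age; age ranges are left unset (see :func:`build_age_ranges`).
    """

    if rng is None:
        rng = np.random.default_rng(config.seed)
    lo, hi = config.window
    record: FossilRecord = []
    counter = 0
    for node in tree.preorder():
        top = tree.branch_parent_age(node)
        bottom = node.age
        if top <= bottom:
            continue
        segments = [
            (min(top, hi), max(bottom, lo), config.psi_int),   # inside window
            (top, max(bottom, hi), config.psi_bg),             # above window
            (min(top, lo), bottom, config.psi_bg),             # below window
        ]
        for seg_top, seg_bot, rate in segments:
            dur = seg_top - seg_bot
            if dur <= 0.0 or rate <= 0.0:
                continue
            k = rng.poisson(rate * dur)
            for _ in range(k):
                age = seg_bot + dur * rng.random()
                counter += 1
                record.append(
                    FossilOccurrence(
                        label=f"F{counter}",
                        branch=node,
                        true_age=age,
                        state=traits.state_at(node, age),
                    )
                )
    # deterministic order: oldest first, then label
    record.sort(key=lambda f: (-f.true_age, f.label))
    for i, f in enumerate(record, 1):
        f.label = f"F{i}"
    return record


def accept_fossils(record: FossilRecord, config: DepositConfig) -> bool:
    """Count and proportion rejection rule.

    True iff the total number of fossils lies in ``n_fossils_range`` and the
    state-2 proportion differs from the target by at most
    ``prop_tolerance`` (read as *relative*, i.e. |p - target| <= 0.1*target).
    """

    n = len(record)
    lo, hi = config.n_fossils_range
    if not lo <= n <= hi:
        return False
    if not config.enforce_proportion:
        return True
    prop = sum(1 for f in record if f.state == 2) / n
    return abs(prop - config.target_prop) <= config.prop_tolerance * config.target_prop


def build_age_ranges(
    record: FossilRecord,
    config: DepositConfig,
    rng: Optional[np.random.Generator] = None,
) -> FossilRecord:
    """Assign an age range to every fossil (in place; record returned).

    Imprecise-date (state-2) fossils all get the deposit window.  A
    precise-date fossil of true age ``a`` gets a range of fixed width
    ``m * a`` whose minimum is uniform on ``(a - m*a, a)``, so the range
    always contains the true age.  For multipliers m <= 0.3 the minimum is
    necessarily non-negative; this is asserted rather than clamped.
    """

    if rng is None:
        rng = np.random.default_rng(config.seed)
    lo, hi = config.window
    m = config.precise_range_multiplier
    for f in record:
        if f.state == 2:
            f.range_min, f.range_max = lo, hi
        else:
            width = m * f.true_age
            f.range_min = f.true_age - width * rng.random()
            f.range_max = f.range_min + width
            assert f.range_min >= 0.0, "negative range_min cannot arise for m <= 1"
        assert f.range_min - 1e-12 <= f.true_age <= f.range_max + 1e-12
    return record


def impose_deposit_interval(
    age_table: Sequence[tuple[str, float, float]],
    interval: tuple[float, float],
    fraction: float,
    seed: Optional[int] = None,
) -> list[tuple[str, float, float]]:
    """Mask a random subset of fossils with one large deposit interval.

    Taxa whose observed range [obs_min, obs_max] lies fully inside
    ``interval`` are eligible; a uniformly random ``fraction`` of them
    (rounded to the nearest count) receive the full interval as their age
    range, the rest keep their observed ranges.  This is the operation used
    to impose an artificial poorly dated deposit on an empirical age table.
    """

    lo, hi = interval
    if not lo < hi:
        raise ValueError("interval must satisfy lo < hi")
    eligible = [
        i for i, (_, omin, omax) in enumerate(age_table) if lo <= omin and omax <= hi
    ]
    if not eligible:
        warnings.warn("interval contains no observed age range; nothing masked")
        return [tuple(row) for row in age_table]
    rng = np.random.default_rng(seed)
    n_mask = int(round(fraction * len(eligible)))
    masked = set(rng.choice(eligible, size=n_mask, replace=False).tolist())
    out = []
    for i, (taxon, omin, omax) in enumerate(age_table):
        if i in masked:
            out.append((taxon, lo, hi))
        else:
            out.append((taxon, omin, omax))
    return out
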