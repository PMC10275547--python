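"""Constant-rate fossilized birth-death tree density.

The FBD process runs from a single lineage at the origin age with speciation
rate ``lam``, extinction rate ``mu``, fossil-recovery rate ``psi`` and
extant sampling probability ``rho``.  The density implemented here is the
standard one for sampled trees containing extant tips, fossil tips and
sampled ancestors, conditioned on the origin age (no survival conditioning).

With the helper constants

    c1 = sqrt((lam - mu - psi)^2 + 4 lam psi)
    c2 = -(lam - mu - 2 lam rho - psi) / c1

and the functions

    p0(t) = probability that a lineage at age t leaves no sampled
            descendants at all,
    q(t)  = per-lineage density factor such that branch contributions
            telescope over the tree,

the log-density of a sampled tree T with origin x0, bifurcation ages x_i,
non-ancestral fossil tips at ages y_j, k sampled ancestors and n sampled
extant tips is

    log f[T | x0] = log q(x0) + sum_i [log(2 lam) + log q(x_i)]
                  + sum_j [log psi + log p0(y_j) - log q(y_j)]
                  + k log psi + n log rho.

The factor 2 per bifurcation converts the oriented-tree density to the
density of a labeled tree with unordered children (each bifurcation has two
equally likely orientations); it matters to the sampler because the
sampled-ancestor toggle changes the number of bifurcations.  A constant
factor 1/n! over the extant tip labelings is omitted throughout: it cancels
from every density ratio the sampler forms, but it must be restored when
integrating the density to a class probability.

At psi = 0 this reduces exactly to the constant-rate birth-death density
conditioned on the origin, which :func:`bd_log_density` provides in closed
form as an independent oracle for tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import exp, isfinite, log, sqrt
from typing import Optional

from .trees import EXTANT_SAMPLED, FOSSIL, Node, Tree

__all__ = ["FBDParameters", "fbd_log_density", "bd_log_density"]

NEG_INF = float("-inf")


@dataclass
class FBDParameters:
    lam: float
    mu: float
    psi: float
    rho: float
    origin_age: float

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("lam must be positive")
        if self.mu < 0 or self.psi < 0:
            raise ValueError("mu and psi must be non-negative")
        if not 0.0 < self.rho <= 1.0:
            raise ValueError("rho must be in (0, 1]")
        if self.origin_age <= 0:
            raise ValueError("origin_age must be positive")


def _constants(lam: float, mu: float, psi: float, rho: float) -> tuple[float, float]:
    c1 = sqrt((lam - mu - psi) ** 2 + 4.0 * lam * psi)
    if c1 == 0.0:
        # lam = mu, psi = 0 degenerate point: nudge off the removable
        # singularity; the density is continuous here
        c1 = 1e-12
    c2 = -(lam - mu - 2.0 * lam * rho - psi) / c1
    return c1, c2


def _log_q(t: float, c1: float, c2: float) -> float:
    # q(t) = 4 e^{-c1 t} / (e^{-c1 t}(1-c2) + (1+c2))^2, computed with
    # e^{-c1 t} <= 1 so no overflow for any t >= 0
    w = exp(-c1 * t)
    denom = w * (1.0 - c2) + (1.0 + c2)
    if denom <= 0.0:
        return NEG_INF
    return log(4.0) - c1 * t - 2.0 * log(denom)


def _log_p0(t: float, lam: float, mu: float, psi: float, c1: float, c2: float) -> float:
    w = exp(-c1 * t)
    denom = w * (1.0 - c2) + (1.0 + c2)
    if denom == 0.0:
        return NEG_INF
    ratio = (w * (1.0 - c2) - (1.0 + c2)) / denom
    p0 = (lam + mu + psi + c1 * ratio) / (2.0 * lam)
    if p0 <= 0.0:
        return NEG_INF
    return log(min(p0, 1.0))


def fbd_log_density(tree: Tree, params: FBDParameters) -> float:
    """Log-density of a sampled tree under the constant-rate FBD process.

    Inadmissible trees (ages out of order, fossils older than the origin, or
    any fossil while ``psi`` is zero) return ``-inf`` rather than raising,
    so the sampler can treat them as rejected states.
    """

    lam, mu, psi, rho = params.lam, params.mu, params.psi, params.rho
    x0 = params.origin_age
    if tree.root.age >= x0:
        return NEG_INF
    c1, c2 = _constants(lam, mu, psi, rho)

    logp = _log_q(x0, c1, c2)
    log_lam = log(2.0 * lam)
    log_psi = log(psi) if psi > 0 else NEG_INF
    log_rho = log(rho)
    stack = [(tree.root, x0)]
    while stack:
        node, top = stack.pop()
        age = node.age
        if age > top + 1e-12 or age < 0:
            return NEG_INF
        children = node.children
        if not children:
            if node.kind == FOSSIL:
                if psi <= 0.0 or age >= x0 or age <= 0.0:
                    return NEG_INF
                if node.sampled_ancestor:
                    logp += log_psi
                else:
                    logp += log_psi + _log_p0(age, lam, mu, psi, c1, c2) - _log_q(age, c1, c2)
            elif node.kind == EXTANT_SAMPLED:
                logp += log_rho
            else:
                return NEG_INF  # unsampled tips cannot appear in a sampled tree
        else:
            if len(children) != 2:
                return NEG_INF
            sa = (children[0].sampled_ancestor and not children[0].children) or (
                children[1].sampled_ancestor and not children[1].children
            )
            if not sa:
                # true bifurcation (speciation event with both sides sampled)
                logp += log_lam + _log_q(age, c1, c2)
            stack.append((children[0], age))
            stack.append((children[1], age))
    if not isfinite(logp):
        return NEG_INF
    return logp


def bd_log_density(
    tree: Tree, lam: float, mu: float, rho: float, origin_age: Optional[float] = None
) -> float:
    """Closed-form birth-death density conditioned on the origin (oracle).

    Standard constant-rate reconstructed-tree density with extant sampling
    probability ``rho``, for labeled trees with unordered children (hence
    the factor 2 per bifurcation, matching :func:`fbd_log_density`):

        f = p1(x0) * prod_i 2 * lam * p1(x_i)

    over the bifurcation ages ``x_i``, with

        p1(t) = rho (lam-mu)^2 e^{-(lam-mu) t}
                / (rho lam + (lam(1-rho) - mu) e^{-(lam-mu) t})^2

    and the lam = mu limit p1(t) = rho / (1 + rho lam t)^2.  Used in tests
    as the psi = 0 oracle for :func:`fbd_log_density`.
    """

    x0 = tree.origin_age if origin_age is None else origin_age

    def log_p1(t: float) -> float:
        if abs(lam - mu) < 1e-12:
            return log(rho) - 2.0 * log(1.0 + rho * lam * t)
        r = lam - mu
        w = exp(-r * t)
        denom = rho * lam + (lam * (1.0 - rho) - mu) * w
        return log(rho) + 2.0 * log(abs(r)) - r * t - 2.0 * log(denom)

    logp = log_p1(x0)
    for node in tree.internal_nodes():
        if len(node.children) != 2:
            raise ValueError("birth-death oracle requires a bifurcating tree")
        logp += log(2.0 * lam) + log_p1(node.age)
    return logp
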