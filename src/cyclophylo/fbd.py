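"""Fossilized birth-death (FBD) tree prior and time-tree plumbing.

A :class:`TimeTree` is a rooted binary tree whose nodes carry ages in Myr
before present (extant tips at 0, parents strictly older than children).
Fossils enter as dated sampled tips; a fossil sampled on a lineage that
also has later sampled descendants is a *sampled ancestor*, represented as
a zero-length fossil child (its attachment node has the fossil's age).

The density follows the serially-sampled birth-death process with
speciation rate lambda, extinction rate mu, fossil-recovery rate psi, and
extant sampling probability rho, conditioned on the root age.  With

    c1 = sqrt((lam - mu - psi)^2 + 4 lam psi)
    c2 = -(lam - mu - 2 lam rho - psi) / c1
    q(t)  = 4 e^{-c1 t} / (e^{-c1 t} (1 - c2) + (1 + c2))^2
    p0(t) = [lam + mu + psi
             + c1 (e^{-c1 t}(1 - c2) - (1 + c2))
                  / (e^{-c1 t}(1 - c2) + (1 + c2))] / (2 lam)

the log density of a tree with n rho-sampled extant tips, m fossil tips,
k sampled ancestors, internal speciation times x_i and fossil tip ages y_j
is

    (N-2) log lam + (m+k) log psi + n log rho + 2 log q(x_root)
        + sum_{i != root} log q(x_i) + sum_j [log p0(y_j) - log q(y_j)]

with N = n + m.  At psi = 0, rho = 1 this reduces exactly to the
constant-rate birth-death density (q collapses to the familiar
(lam-mu)^2 e^{-(lam-mu)t} / (lam - mu e^{-(lam-mu)t})^2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .tree import Cladogram, Node, TreeError

__all__ = ["FBDParams", "TimeTree", "fbd_log_density"]

AGE_EPS = 1e-9


@dataclass
class FBDParams:
    lam: float  # speciation rate per lineage per Myr
    mu: float  # extinction rate
    psi: float  # fossil sampling rate
    rho: float  # extant sampling probability

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("speciation rate must be positive")
        if self.mu < 0 or self.psi < 0:
            raise ValueError("extinction and fossil-sampling rates must be >= 0")
        if not 0 < self.rho <= 1:
            raise ValueError("extant sampling probability must be in (0, 1]")


class TimeTree:
    """Rooted, binary, dated tree; wraps a :class:`Cladogram` with ages."""

    def __init__(self, tree: Cladogram):
        if not tree.rooted:
            raise TreeError("a time tree must be rooted")
        self.tree = tree
        self.validate()

    def validate(self) -> None:
        for node in self.tree.postorder():
            if node.age is None:
                raise TreeError(f"node {node.label!r} has no age")
            if node.age < -AGE_EPS:
                raise TreeError("negative node age")
            if not node.is_leaf:
                if len(node.children) != 2:
                    raise TreeError("time tree must be binary")
                for c in node.children:
                    if c.age > node.age + AGE_EPS:
                        raise TreeError("child older than parent")
            else:
                if not node.is_fossil and abs(node.age) > AGE_EPS:
                    raise TreeError(
                        f"extant tip {node.label!r} must be at age 0"
                    )

    # -- derived quantities ---------------------------------------------
    @property
    def root_age(self) -> float:
        return self.tree.root.age

    def extant_tips(self) -> list[Node]:
        return [n for n in self.tree.leaves() if not n.is_fossil]

    def fossil_tips(self) -> list[Node]:
        return [n for n in self.tree.leaves() if n.is_fossil]

    def sampled_ancestors(self) -> list[Node]:
        """Fossil tips attached by a zero-duration branch (their parent sits
        exactly at the fossil's age)."""
        out = []
        for n in self.fossil_tips():
            if n.parent is not None and abs(n.parent.age - n.age) <= AGE_EPS:
                out.append(n)
        return out

    def set_lengths_from_ages(self) -> None:
        """Write branch lengths (time durations) from the node ages."""
        for node in self.tree.postorder():
            if node.parent is not None:
                node.length = node.parent.age - node.age

    def copy(self) -> "TimeTree":
        return TimeTree(self.tree.copy())


def _c1_c2(p: FBDParams) -> tuple[float, float]:
    c1 = math.sqrt((p.lam - p.mu - p.psi) ** 2 + 4 * p.lam * p.psi)
    if c1 == 0:
        raise ValueError("degenerate FBD parameters (c1 = 0)")
    c2 = -(p.lam - p.mu - 2 * p.lam * p.rho - p.psi) / c1
    return c1, c2


def _log_q(t: float, c1: float, c2: float) -> float:
    e = math.exp(-c1 * t)
    denom = e * (1 - c2) + (1 + c2)
    return math.log(4.0) - c1 * t - 2 * math.log(abs(denom))


def _p0(t: float, p: FBDParams, c1: float, c2: float) -> float:
    e = math.exp(-c1 * t)
    frac = (e * (1 - c2) - (1 + c2)) / (e * (1 - c2) + (1 + c2))
    return (p.lam + p.mu + p.psi + c1 * frac) / (2 * p.lam)


def fbd_log_density(t: TimeTree, p: FBDParams) -> float:
    """Log density of a dated sampled tree, conditioned on its root age.

    Returns ``-inf`` for trees violating the age ordering rather than
    raising, so MCMC proposals can be rejected gracefully.
    """
    try:
        t.validate()
    except TreeError:
        return -math.inf
    c1, c2 = _c1_c2(p)
    sampled_anc = set(id(n) for n in t.sampled_ancestors())
    n_extant = len(t.extant_tips())
    fossils = t.fossil_tips()
    m_tip = sum(1 for f in fossils if id(f) not in sampled_anc)
    k_anc = len(fossils) - m_tip
    if (m_tip + k_anc) > 0 and p.psi == 0:
        return -math.inf
    n_total_tips = n_extant + m_tip
    if n_total_tips < 2:
        return -math.inf
    logf = (n_total_tips - 2) * math.log(p.lam)
    logf += n_extant * math.log(p.rho)
    if p.psi > 0:
        logf += (m_tip + k_anc) * math.log(p.psi)
    logf += 2 * _log_q(t.root_age, c1, c2)
    for node in t.tree.postorder():
        if node.is_leaf or node is t.tree.root:
            continue
        if any(id(c) in sampled_anc for c in node.children):
            continue  # sampled-ancestor attachment, not a speciation
        logf += _log_q(node.age, c1, c2)
    for f in fossils:
        if id(f) in sampled_anc:
            continue
        p0 = _p0(f.age, p, c1, c2)
        if p0 <= 0:
            return -math.inf
        logf += math.log(p0) - _log_q(f.age, c1, c2)
    return logf
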