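"""HKY85 substitution model likelihood on time trees.

The HKY rate matrix separates transitions (A<->G, C<->T, weighted kappa)
from transversions and allows arbitrary base frequencies pi.  Q is scaled
so branch lengths are expected substitutions per site; on a time tree the
expected length of a branch is (clock rate) x (time duration).  Likelihoods
use Felsenstein pruning over site patterns (identical alignment columns
collapsed, which is what makes repeated MCMC evaluation affordable);
optional among-site rate variation uses a 4-category discrete gamma.
Tips without sequences (fossils) carry uniform partials, which is exactly
equivalent to pruning them from the likelihood.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .fbd import TimeTree
from .tree import TreeError

__all__ = ["HkyParams", "hky_rate_matrix", "HkyEngine", "hky_loglik"]

BASES = "ACGT"
AMBIGUITY = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "GC", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT", "-": "ACGT", "?": "ACGT", "X": "ACGT",
}


@dataclass
class HkyParams:
    kappa: float = 2.0  # transition/transversion rate ratio
    pi: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    gamma_shape: float | None = None  # None = equal rates across sites

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if len(self.pi) != 4 or any(f <= 0 for f in self.pi):
            raise ValueError("pi must be 4 positive frequencies")
        total = sum(self.pi)
        if abs(total - 1) > 1e-8:
            raise ValueError("pi must sum to 1")
        if self.gamma_shape is not None and self.gamma_shape <= 0:
            raise ValueError("gamma shape must be positive")


def hky_rate_matrix(params: HkyParams) -> np.ndarray:
    """HKY Q matrix scaled to one expected substitution per unit length."""
    pi = np.asarray(params.pi)
    kappa = params.kappa
    Q = np.zeros((4, 4))
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            rate = pi[j]
            if {BASES[i], BASES[j]} in ({"A", "G"}, {"C", "T"}):
                rate *= kappa
            Q[i, j] = rate
    np.fill_diagonal(Q, -Q.sum(axis=1))
    scale = -(pi * np.diag(Q)).sum()
    return Q / scale


class _Eigen:
    """Eigendecomposition of a reversible Q via similarity to a symmetric
    matrix, so P(t) = exp(Qt) is cheap per branch."""

    def __init__(self, Q: np.ndarray, pi: np.ndarray):
        d = np.sqrt(pi)
        S = (Q * d[:, None]) / d[None, :]
        vals, vecs = np.linalg.eigh((S + S.T) / 2)
        self.vals = vals
        self.right = vecs / d[:, None]
        self.left = (vecs * d[:, None]).T

    def transition(self, t: float) -> np.ndarray:
        if t < 0:
            raise TreeError("negative branch duration")
        P = (self.right * np.exp(self.vals * t)) @ self.left
        return np.clip(P, 0.0, None)


class HkyEngine:
    """Pattern-compressed pruning likelihood for one alignment partition."""

    def __init__(self, sequences: dict[str, str]):
        if not sequences:
            raise ValueError("empty alignment")
        lengths = {len(s) for s in sequences.values()}
        if len(lengths) != 1:
            raise ValueError("sequences are not aligned")
        self.names = sorted(sequences)
        cols = list(zip(*(sequences[n].upper() for n in self.names)))
        pattern_weights: dict[tuple[str, ...], int] = {}
        for col in cols:
            pattern_weights[col] = pattern_weights.get(col, 0) + 1
        self.patterns = list(pattern_weights)
        self.weights = np.array([pattern_weights[p] for p in self.patterns], dtype=float)
        self.n_sites = len(cols)
        self._partials: dict[str, np.ndarray] = {}
        for i, name in enumerate(self.names):
            arr = np.zeros((len(self.patterns), 4))
            for pi_, pat in enumerate(self.patterns):
                sym = pat[i]
                if sym not in AMBIGUITY:
                    raise ValueError(f"unknown base symbol {sym!r}")
                for b in AMBIGUITY[sym]:
                    arr[pi_, BASES.index(b)] = 1.0
            self._partials[name] = arr

    def loglik(self, timetree: TimeTree, rate: float, params: HkyParams) -> float:
        """Log likelihood with branch lengths = rate x time duration."""
        if rate <= 0:
            return -math.inf
        pi = np.asarray(params.pi)
        eig = _Eigen(hky_rate_matrix(params), pi)
        if params.gamma_shape is None:
            site_rates = [1.0]
        else:
            from .mk import discrete_gamma_rates

            site_rates = list(discrete_gamma_rates(params.gamma_shape))
        npat = len(self.patterns)
        lik = np.zeros(npat)
        ones = np.ones((npat, 4))
        for r in site_rates:
            cache: dict[int, np.ndarray] = {}
            for node in timetree.tree.postorder():
                if node.is_leaf:
                    cache[id(node)] = self._partials.get(node.label, ones)
                    continue
                acc = None
                for child in node.children:
                    dur = node.age - child.age
                    P = eig.transition(dur * rate * r)
                    term = cache[id(child)] @ P.T
                    acc = term if acc is None else acc * term
                cache[id(node)] = acc
            lik += (cache[id(timetree.tree.root)] * pi).sum(axis=1) / len(site_rates)
        if np.any(lik <= 0):
            return -math.inf
        return float((np.log(lik) * self.weights).sum())


def hky_loglik(
    timetree: TimeTree,
    partitions: list[dict[str, str]],
    rate: float,
    params: list[HkyParams],
) -> float:
    """Strict-clock HKY log likelihood summed over partitions.

    Partitions share the tree and clock rate but have independent HKY
    parameters.  Tips present in the tree but absent from a partition
    (fossils) are marginalised out.
    """
    if len(partitions) != len(params):
        raise ValueError("one HkyParams per partition required")
    total = 0.0
    for seqs, par in zip(partitions, params):
        unknown = set(seqs) - {l.label for l in timetree.tree.leaves()}
        if unknown:
            raise TreeError(f"sequences without tree tips: {sorted(unknown)}")
        total += HkyEngine(seqs).loglik(timetree, rate, par)
    return total
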