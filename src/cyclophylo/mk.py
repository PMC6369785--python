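"""Bayesian inference under the Mk model of discrete character evolution.

The Mk model (Lewis 2001) gives each character k equally exchangeable
states; on a branch of expected length v the transition probability is

    p_ii(v) = 1/k + (k-1)/k * exp(-k v / (k-1))
    p_ij(v) = 1/k - 1/k   * exp(-k v / (k-1))      (i != j)

Likelihoods are computed by Felsenstein pruning, vectorised across all
characters sharing a state count.  Matrices of morphological characters are
collected only when variable, so by default each character's likelihood is
conditioned on being variable (divided by 1 - P(constant pattern)), the
MrBayes ``coding=variable`` correction.  Optional among-character rate
variation uses a 4-category discrete gamma.

Posterior sampling is Metropolis-Hastings over topology (NNI), branch
lengths (multiplier moves, Exp(10) prior), and the gamma shape; runs are
single-chain, with convergence judged by comparing split frequencies
between independent runs.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field

import numpy as np

from .matrix import CharacterMatrix
from .parsimony import majority_consensus
from .tree import Cladogram, Node, TreeError

__all__ = [
    "MkModelParams",
    "McmcSettings",
    "PosteriorTrace",
    "mk_transition_matrix",
    "mk_loglik",
    "run_mcmc",
    "posterior_consensus",
    "split_frequency_difference",
]

BRANCH_PRIOR_RATE = 10.0  # exponential prior on branch lengths


@dataclass
class MkModelParams:
    gamma_shape: float | None = None  # None = equal rates; else 4-cat discrete gamma
    correction: str = "variable"  # "variable" | "none"

    def __post_init__(self) -> None:
        if self.gamma_shape is not None and self.gamma_shape <= 0:
            raise ValueError("gamma shape must be positive")
        if self.correction not in ("variable", "none"):
            raise ValueError(f"unknown correction {self.correction!r}")


@dataclass
class McmcSettings:
    generations: int = 200_000
    n_runs: int = 2
    sample_every: int = 200
    seed: int = 0
    burnin: float = 0.25
    gamma: bool = False

    def __post_init__(self) -> None:
        if self.generations < 0 or self.sample_every < 1 or self.n_runs < 1:
            raise ValueError("invalid MCMC settings")
        if not 0 <= self.burnin <= 1:
            raise ValueError("burn-in fraction must be in [0, 1]")


@dataclass
class PosteriorTrace:
    """Samples from one MCMC run."""

    run_id: int
    generations: list[int] = field(default_factory=list)
    log_posterior: list[float] = field(default_factory=list)
    trees: list[str] = field(default_factory=list)  # newick with lengths
    alpha: list[float | None] = field(default_factory=list)
    burnin: float = 0.25
    acceptance_rate: float = float("nan")

    def post_burnin_trees(self) -> list[Cladogram]:
        start = int(len(self.trees) * self.burnin)
        kept = self.trees[start:]
        if not kept:
            raise ValueError("no post-burn-in samples")
        return [Cladogram.from_newick(nw, rooted=False) for nw in kept]


def discrete_gamma_rates(alpha: float, ncat: int = 4) -> np.ndarray:
    """Equal-probability discrete-gamma category rates (quantile midpoints)."""
    from scipy.stats import gamma as gamma_dist

    quantiles = (2 * np.arange(ncat) + 1) / (2 * ncat)
    rates = gamma_dist.ppf(quantiles, a=alpha, scale=1.0 / alpha)
    return rates / rates.mean()


def mk_transition_matrix(k: int, v: float) -> np.ndarray:
    """Mk transition probability matrix for a branch of length v."""
    if v < 0:
        raise ValueError("negative branch length")
    e = math.exp(-k * v / (k - 1))
    off = 1.0 / k - e / k
    diag = 1.0 / k + (k - 1) / k * e
    P = np.full((k, k), off)
    np.fill_diagonal(P, diag)
    return P


class MkEngine:
    """Caches leaf partials so repeated likelihood evaluation is cheap."""

    def __init__(self, matrix: CharacterMatrix, params: MkModelParams | None = None):
        self.matrix = matrix
        self.params = params or MkModelParams()
        by_k: dict[int, list[int]] = {}
        self.n_used = 0
        for j, ch in enumerate(matrix.characters):
            k = len(matrix.state_space(ch))
            if k < 2:
                if self.params.correction == "variable":
                    # a constant character cannot be conditioned on being
                    # variable; it carries no signal and is skipped
                    continue
                k = 2  # pad the state space so the model is defined
            by_k.setdefault(k, []).append(j)
            self.n_used += 1
        self._leaf_partials: dict[int, dict[str, np.ndarray]] = {}
        self._spaces: dict[int, list[list[str]]] = {}
        for k, cols in sorted(by_k.items()):
            spaces = [sorted(matrix.state_space(matrix.characters[j])) for j in cols]
            partials = {}
            for i, taxon in enumerate(matrix.taxa):
                arr = np.zeros((len(cols), k))
                for cj, j in enumerate(cols):
                    cv = matrix.cells[i][j]
                    if cv.is_states:
                        for s in cv.states:
                            arr[cj, spaces[cj].index(s)] = 1.0
                    else:
                        arr[cj, :] = 1.0
                partials[taxon] = arr
            self._leaf_partials[k] = partials
            self._spaces[k] = spaces

    def loglik(self, tree: Cladogram, alpha: float | None = None) -> float:
        """Log likelihood of the matrix on `tree` (branch lengths required)."""
        if alpha is None:
            alpha = self.params.gamma_shape
        if alpha is not None and alpha <= 0:
            raise ValueError("gamma shape must be positive")
        rates = (
            np.array([1.0]) if alpha is None else discrete_gamma_rates(alpha)
        )
        total = 0.0
        for k, partials in self._leaf_partials.items():
            nchars = next(iter(partials.values())).shape[0]
            per_char = np.zeros(nchars)
            const = np.zeros(k)
            for rate in rates:
                lik, clik = self._prune(tree, k, partials, rate)
                per_char += lik / len(rates)
                const += clik / len(rates)
            if np.any(per_char <= 0):
                return -math.inf
            res = np.log(per_char).sum()
            if self.params.correction == "variable":
                p_const = const.sum()
                if p_const >= 1.0:
                    return -math.inf
                res -= nchars * math.log1p(-p_const)
            total += res
        return total

    def _prune(self, tree: Cladogram, k: int, partials, rate: float):
        cache: dict[int, np.ndarray] = {}
        ccache: dict[int, np.ndarray] = {}
        eye = np.eye(k)
        root = tree.root
        for node in root.postorder():
            if node.is_leaf:
                if node.label not in partials:
                    raise TreeError(f"leaf {node.label!r} has no matrix row")
                cache[id(node)] = partials[node.label]
                ccache[id(node)] = eye.copy()
                continue
            acc = None
            cacc = None
            for child in node.children:
                v = child.length
                if v is None or v < 0:
                    raise TreeError("tree must have nonnegative branch lengths")
                P = mk_transition_matrix(k, v * rate)
                term = cache[id(child)] @ P.T
                cterm = ccache[id(child)] @ P.T
                acc = term if acc is None else acc * term
                cacc = cterm if cacc is None else cacc * cterm
            cache[id(node)] = acc
            ccache[id(node)] = cacc
        lik = cache[id(root)].mean(axis=1)  # uniform root frequencies 1/k
        clik = ccache[id(root)].mean(axis=1)
        return lik, clik


def mk_loglik(
    tree: Cladogram, matrix: CharacterMatrix, params: MkModelParams | None = None
) -> float:
    """Felsenstein-pruning log likelihood under Mk (see :class:`MkEngine`)."""
    return MkEngine(matrix, params).loglik(tree)


# ---------------------------------------------------------------------------
# MCMC
# ---------------------------------------------------------------------------

def _random_start_tree(taxa: list[str], rng: random.Random, v0: float = 0.1) -> Cladogram:
    order = list(taxa)
    rng.shuffle(order)
    root = Node(children=[Node(order[0], v0), Node(length=v0)])
    root.children[1].add_child(Node(order[1], v0))
    root.children[1].add_child(Node(order[2], v0))
    tree = Cladogram(root, rooted=False)
    for label in order[3:]:
        nodes = [n for n in tree.root.postorder() if n.parent is not None]
        at = rng.choice(nodes)
        parent = at.parent
        idx = parent.children.index(at)
        junction = Node(length=v0)
        parent.children[idx] = junction
        junction.parent = parent
        junction.add_child(at)
        junction.add_child(Node(label, v0))
    return tree


def _branch_nodes(tree: Cladogram) -> list[Node]:
    return [n for n in tree.root.postorder() if n.parent is not None]


def _internal_edge_nodes(tree: Cladogram) -> list[Node]:
    return [
        n
        for n in tree.root.postorder()
        if not n.is_leaf and n.parent is not None and n.parent is not tree.root
    ]


def _log_branch_prior(tree: Cladogram) -> float:
    lp = 0.0
    for n in _branch_nodes(tree):
        lp += math.log(BRANCH_PRIOR_RATE) - BRANCH_PRIOR_RATE * n.length
    return lp


def run_mcmc(
    matrix: CharacterMatrix, settings: McmcSettings | None = None
) -> list[PosteriorTrace]:
    """Independent Metropolis-Hastings runs over (topology, branch lengths[, alpha]).

    Returns one :class:`PosteriorTrace` per run; fully deterministic given
    ``settings.seed``.
    """
    settings = settings or McmcSettings()
    if matrix.n_taxa < 4:
        raise ValueError("MCMC requires at least 4 taxa")
    params = MkModelParams(gamma_shape=1.0 if settings.gamma else None)
    engine = MkEngine(matrix, params)
    traces = []
    for run in range(settings.n_runs):
        traces.append(_run_single(engine, matrix, settings, run))
    return traces


def _run_single(
    engine: MkEngine, matrix: CharacterMatrix, settings: McmcSettings, run: int
) -> PosteriorTrace:
    rng = random.Random(settings.seed * 7919 + run)
    tree = _random_start_tree(matrix.taxa, rng)
    alpha = 1.0 if settings.gamma else None
    ll = engine.loglik(tree, alpha)
    lp = _log_branch_prior(tree)
    trace = PosteriorTrace(run_id=run, burnin=settings.burnin)
    accepted = 0
    proposed = 0
    trace.generations.append(0)
    trace.log_posterior.append(ll + lp)
    trace.trees.append(tree.to_newick())
    trace.alpha.append(alpha)
    for gen in range(1, settings.generations + 1):
        proposed += 1
        move = rng.random()
        log_hastings = 0.0
        undo = None
        new_alpha = alpha
        if move < 0.35 and _internal_edge_nodes(tree):
            v = rng.choice(_internal_edge_nodes(tree))
            slot = rng.randrange(2)
            u = v.parent
            s = next(c for c in u.children if c is not v)
            a = v.children[slot]
            ui, vi = u.children.index(s), v.children.index(a)
            u.children[ui], v.children[vi] = a, s
            a.parent, s.parent = u, v

            def undo_nni(u=u, v=v, a=a, s=s, ui=ui, vi=vi):
                u.children[ui], v.children[vi] = s, a
                s.parent, a.parent = u, v

            undo = undo_nni
        elif move < 0.9 or not settings.gamma:
            node = rng.choice(_branch_nodes(tree))
            old_v = node.length
            factor = math.exp(1.0 * (rng.random() - 0.5))
            node.length = old_v * factor
            log_hastings = math.log(factor)

            def undo_branch(node=node, old_v=old_v):
                node.length = old_v

            undo = undo_branch
        else:
            old_alpha = alpha
            factor = math.exp(0.8 * (rng.random() - 0.5))
            new_alpha = alpha * factor
            log_hastings = math.log(factor)

            def undo_alpha():
                pass

            undo = undo_alpha
        new_ll = engine.loglik(tree, new_alpha)
        new_lp = _log_branch_prior(tree)
        if new_alpha is not None:
            # Exp(1) prior on the gamma shape
            new_lp += -new_alpha
            cur_lp = lp + (-alpha)
        else:
            cur_lp = lp
        log_ratio = (new_ll + new_lp) - (ll + cur_lp) + log_hastings
        if new_alpha is not None:
            new_lp -= -new_alpha  # keep lp as branch prior only
        if math.log(rng.random() + 1e-300) < log_ratio:
            ll, lp, alpha = new_ll, new_lp, new_alpha
            accepted += 1
        else:
            undo()
        if gen % settings.sample_every == 0:
            trace.generations.append(gen)
            trace.log_posterior.append(ll + lp)
            trace.trees.append(tree.to_newick())
            trace.alpha.append(alpha)
    trace.acceptance_rate = accepted / proposed if proposed else float("nan")
    return trace


def posterior_consensus(
    traces: list[PosteriorTrace], burnin: float = 0.25
) -> tuple[Cladogram, dict[frozenset[str], float]]:
    """Majority-rule consensus over pooled post-burn-in sampled trees."""
    if not traces:
        raise ValueError("no traces given")
    if not 0 <= burnin < 1:
        raise ValueError("burn-in fraction must be in [0, 1)")
    pooled: list[Cladogram] = []
    for tr in traces:
        start = int(len(tr.trees) * burnin)
        pooled.extend(
            Cladogram.from_newick(nw, rooted=False) for nw in tr.trees[start:]
        )
    if not pooled:
        raise ValueError("no post-burn-in samples")
    return majority_consensus(pooled, threshold=0.5)


def _split_freqs(trace: PosteriorTrace, burnin: float) -> dict[frozenset[str], float]:
    start = int(len(trace.trees) * burnin)
    kept = trace.trees[start:]
    counts: dict[frozenset[str], int] = {}
    for nw in kept:
        for split in Cladogram.from_newick(nw, rooted=False).bipartitions():
            counts[split] = counts.get(split, 0) + 1
    return {s: c / len(kept) for s, c in counts.items()}


def split_frequency_difference(
    a: PosteriorTrace, b: PosteriorTrace, burnin: float = 0.25
) -> float:
    """Mean absolute split-frequency difference between two runs."""
    fa = _split_freqs(a, burnin)
    fb = _split_freqs(b, burnin)
    splits = set(fa) | set(fb)
    if not splits:
        return 0.0
    return sum(abs(fa.get(s, 0.0) - fb.get(s, 0.0)) for s in splits) / len(splits)
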