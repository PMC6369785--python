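"""Tip-dated divergence-time estimation on a fixed topology.

The sampler keeps the topology from the parsimony stage fixed and runs
Metropolis-Hastings over internal node ages, fossil tip ages (uniform
within their stratigraphic calibration ranges), the strict clock rate, and
optionally the HKY kappas and the FBD rates.  The posterior is

    FBD tree prior  x  strict-clock HKY likelihood (per partition)
                    x  parameter priors

with a uniform hyperprior on the root age.  Node-age proposals are uniform
slides inside the window allowed by parent and children, so rejected
states never violate the ordering constraint.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field, replace

import numpy as np

from .fbd import FBDParams, TimeTree, fbd_log_density
from .hky import HkyEngine, HkyParams
from .nexus_io import CalibrationTable
from .tree import Cladogram, Node, TreeError

__all__ = [
    "ClockPriors",
    "ClockSettings",
    "ClockTrace",
    "run_clock_mcmc",
    "summarize_ages",
    "hpd_interval",
]


@dataclass
class ClockPriors:
    root_age_range: tuple[float, float]  # uniform hyperprior, Mya
    rate_ln_mu: float = math.log(0.005)  # lognormal prior on clock rate
    rate_ln_sigma: float = 0.5
    kappa_ln_mu: float = math.log(2.0)
    kappa_ln_sigma: float = 0.5
    estimate_kappa: bool = True
    estimate_fbd: bool = False  # multiplier moves on lam/mu/psi, Exp priors
    fbd_prior_mean: float = 0.05

    def __post_init__(self) -> None:
        lo, hi = self.root_age_range
        if not 0 <= lo < hi:
            raise ValueError("root age range must satisfy 0 <= min < max")


@dataclass
class ClockSettings:
    iterations: int = 2000  # sweeps; each sweep proposes every parameter once
    sample_every: int = 2
    seed: int = 0
    burnin: float = 0.25

    def __post_init__(self) -> None:
        if self.iterations < 0 or self.sample_every < 1:
            raise ValueError("invalid settings")
        if not 0 <= self.burnin <= 1:
            raise ValueError("burn-in fraction must be in [0, 1]")


@dataclass
class ClockTrace:
    node_ages: dict[frozenset[str], list[float]]
    tip_ages: dict[str, list[float]]
    rate: list[float]
    kappa: list[tuple[float, ...]]
    fbd: list[tuple[float, float, float]]
    log_posterior: list[float]
    burnin: float = 0.25
    acceptance_rate: float = float("nan")

    def n_samples(self) -> int:
        return len(self.log_posterior)

    def post_burnin(self, samples: list[float]) -> list[float]:
        start = int(len(samples) * self.burnin)
        kept = samples[start:]
        if not kept:
            raise ValueError("no post-burn-in samples")
        return kept


def _clade_keys(tree: Cladogram) -> dict[int, frozenset[str]]:
    keys: dict[int, frozenset[str]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            keys[id(node)] = frozenset([node.label])
        else:
            keys[id(node)] = frozenset().union(*(keys[id(c)] for c in node.children))
    return keys


def initialize_time_tree(
    topology: Cladogram, calibrations: CalibrationTable, root_target: float
) -> TimeTree:
    """Dated starting state: fossils at calibration midpoints, internal
    nodes spread evenly up to the target root age."""
    tree = topology.copy()
    tree.rooted = True
    for leaf in tree.leaves():
        if leaf.label in calibrations:
            lo, hi = calibrations[leaf.label]
            leaf.age = (lo + hi) / 2
            leaf.is_fossil = True
        else:
            leaf.age = 0.0
            leaf.is_fossil = False
    levels: dict[int, int] = {}
    minfeas: dict[int, float] = {}
    for node in tree.postorder():
        if node.is_leaf:
            levels[id(node)] = 0
            minfeas[id(node)] = node.age
        else:
            levels[id(node)] = 1 + max(levels[id(c)] for c in node.children)
            minfeas[id(node)] = max(minfeas[id(c)] for c in node.children)
    root = tree.root
    span = max(root_target - minfeas[id(root)], 1.0)
    delta = span / max(levels[id(root)], 1)
    for node in tree.postorder():
        if not node.is_leaf:
            node.age = minfeas[id(node)] + levels[id(node)] * delta
    tt = TimeTree(tree)
    tt.set_lengths_from_ages()
    return tt


def run_clock_mcmc(
    topology: Cladogram,
    partitions: list[dict[str, str]],
    calibrations: CalibrationTable,
    fbd_params: FBDParams,
    priors: ClockPriors,
    settings: ClockSettings | None = None,
    hky_params: list[HkyParams] | None = None,
    init_rate: float | None = None,
) -> tuple[ClockTrace, TimeTree]:
    """MH sampler for node ages and clock parameters on a fixed topology.

    Returns the trace and the final tree state (ages from the last
    iteration).  Deterministic given ``settings.seed``.
    """
    settings = settings or ClockSettings()
    rng = random.Random(settings.seed * 65537 + 17)
    hky_params = list(hky_params) if hky_params else [HkyParams() for _ in partitions]
    if len(hky_params) != len(partitions):
        raise ValueError("one HkyParams per partition required")
    tip_labels = {l.label for l in topology.leaves()}
    for f in calibrations.taxa():
        if f not in tip_labels:
            raise TreeError(f"calibrated taxon {f!r} is not a tree tip")
    for seqs in partitions:
        missing = sorted(set(seqs) - tip_labels)
        if missing:
            raise TreeError(f"sequences without tree tips: {missing}")
    lo_root, hi_root = priors.root_age_range
    tt = initialize_time_tree(topology, calibrations, (lo_root + hi_root) / 2)
    if not (lo_root <= tt.root_age <= hi_root):
        raise TreeError("initial root age outside the prior range")
    engines = [HkyEngine(seqs) for seqs in partitions]
    rate = init_rate if init_rate is not None else math.exp(priors.rate_ln_mu)
    fbd = fbd_params

    keys = _clade_keys(tt.tree)
    internal = [n for n in tt.tree.postorder() if not n.is_leaf]
    fossil_tips = [n for n in tt.tree.leaves() if n.is_fossil]

    def log_posterior(rate_, fbd_, hky_):
        lp = fbd_log_density(tt, fbd_)
        if not (lo_root <= tt.root_age <= hi_root):
            return -math.inf
        if lp == -math.inf:
            return lp
        for eng, par in zip(engines, hky_):
            lp += eng.loglik(tt, rate_, par)
        # lognormal prior on the clock rate
        lr = math.log(rate_)
        lp += -lr - (lr - priors.rate_ln_mu) ** 2 / (2 * priors.rate_ln_sigma**2)
        if priors.estimate_kappa:
            for par in hky_:
                lk = math.log(par.kappa)
                lp += -lk - (lk - priors.kappa_ln_mu) ** 2 / (
                    2 * priors.kappa_ln_sigma**2
                )
        if priors.estimate_fbd:
            for val in (fbd_.lam, fbd_.mu, fbd_.psi):
                if val > 0:
                    lp += -val / priors.fbd_prior_mean
        return lp

    current = log_posterior(rate, fbd, hky_params)
    if current == -math.inf:
        raise TreeError("initial state has zero posterior density")

    trace = ClockTrace(
        node_ages={keys[id(n)]: [] for n in internal},
        tip_ages={n.label: [] for n in fossil_tips},
        rate=[],
        kappa=[],
        fbd=[],
        log_posterior=[],
        burnin=settings.burnin,
    )

    def record():
        for n in internal:
            trace.node_ages[keys[id(n)]].append(n.age)
        for n in fossil_tips:
            trace.tip_ages[n.label].append(n.age)
        trace.rate.append(rate)
        trace.kappa.append(tuple(p.kappa for p in hky_params))
        trace.fbd.append((fbd.lam, fbd.mu, fbd.psi))
        trace.log_posterior.append(current)

    record()
    accepted = proposed = 0

    def try_move(apply, revert, log_hastings, rate_=None, fbd_=None, hky_=None):
        nonlocal current, rate, fbd, hky_params, accepted, proposed
        proposed += 1
        apply()
        cand = log_posterior(
            rate if rate_ is None else rate_,
            fbd if fbd_ is None else fbd_,
            hky_params if hky_ is None else hky_,
        )
        if math.log(rng.random() + 1e-300) < cand - current + log_hastings:
            current = cand
            accepted += 1
            if rate_ is not None:
                rate = rate_
            if fbd_ is not None:
                fbd = fbd_
            if hky_ is not None:
                hky_params = hky_
        else:
            revert()

    for it in range(1, settings.iterations + 1):
        for node in internal:
            lo = max(c.age for c in node.children)
            hi = node.parent.age if node.parent is not None else hi_root
            if hi - lo <= 0:
                continue
            old = node.age
            new = rng.uniform(lo, hi)
            try_move(
                lambda n=node, a=new: setattr(n, "age", a),
                lambda n=node, a=old: setattr(n, "age", a),
                0.0,
            )
        for tip in fossil_tips:
            lo, hi = calibrations[tip.label]
            hi = min(hi, tip.parent.age)
            if hi - lo <= 0:
                continue
            old = tip.age
            new = rng.uniform(lo, hi)
            try_move(
                lambda n=tip, a=new: setattr(n, "age", a),
                lambda n=tip, a=old: setattr(n, "age", a),
                0.0,
            )
        factor = math.exp(0.6 * (rng.random() - 0.5))
        try_move(lambda: None, lambda: None, math.log(factor), rate_=rate * factor)
        # joint up/down rescale: all internal ages x c, rate / c -- the move
        # that traverses the rate-age ridge the single-parameter moves cross
        # only by diffusion
        c = math.exp(0.4 * (rng.random() - 0.5))
        old_ages = [(n, n.age) for n in internal]

        def apply_scale(c=c, nodes=internal):
            for n in nodes:
                n.age *= c

        def revert_scale(olds=old_ages):
            for n, a in olds:
                n.age = a

        # Jacobian: c per scaled age, c^-1 for the rate
        try_move(
            apply_scale, revert_scale,
            (len(internal) - 1) * math.log(c),
            rate_=rate / c,
        )
        if priors.estimate_kappa:
            for pi_ in range(len(hky_params)):
                factor = math.exp(0.5 * (rng.random() - 0.5))
                new_par = list(hky_params)
                new_par[pi_] = replace(new_par[pi_], kappa=new_par[pi_].kappa * factor)
                try_move(lambda: None, lambda: None, math.log(factor), hky_=new_par)
        if priors.estimate_fbd:
            for attr in ("lam", "mu", "psi"):
                val = getattr(fbd, attr)
                if val <= 0:
                    continue
                factor = math.exp(0.5 * (rng.random() - 0.5))
                new_fbd = replace(fbd, **{attr: val * factor})
                try_move(lambda: None, lambda: None, math.log(factor), fbd_=new_fbd)
        if it % settings.sample_every == 0:
            record()
    trace.acceptance_rate = accepted / proposed if proposed else float("nan")
    tt.set_lengths_from_ages()
    return trace, tt


# ---------------------------------------------------------------------------
# posterior summaries
# ---------------------------------------------------------------------------

def hpd_interval(samples: list[float], level: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing `level` of the samples."""
    if not samples:
        raise ValueError("empty sample set")
    if not 0 < level <= 1:
        raise ValueError("level must be in (0, 1]")
    xs = sorted(samples)
    n = len(xs)
    w = max(1, math.ceil(level * n))
    best = (xs[0], xs[w - 1])
    for i in range(n - w + 1):
        if xs[i + w - 1] - xs[i] < best[1] - best[0]:
            best = (xs[i], xs[i + w - 1])
    return best


def summarize_ages(
    trace: ClockTrace, level: float = 0.95
) -> dict[frozenset[str], tuple[float, float, float]]:
    """Per internal node: posterior median and HPD interval of its age."""
    out = {}
    for key, samples in trace.node_ages.items():
        kept = trace.post_burnin(samples)
        lo, hi = hpd_interval(kept, level)
        out[key] = (float(np.median(kept)), lo, hi)
    return out
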