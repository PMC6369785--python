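"""Synthetic data with the statistical structure the pipeline assumes.

The generator emulates a study of early-vertebrate relationships built on a
morphological matrix of ~50 taxa x ~170 discrete characters with
hierarchically dependent (contingency-coded) characters, fossil taxa whose
soft-tissue characters are frequently unobservable, and a two-partition
mitochondrial-style alignment (16S-like and COI-like) evolved under a
strict clock on the true time tree.  Trees come from a forward fossilized
birth-death simulation; every stage is deterministic given the seed.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field

import numpy as np

from .contingency import DependencyGraph
from .fbd import FBDParams, TimeTree
from .hky import BASES, HkyParams, hky_rate_matrix
from .matrix import CellValue, CharacterMatrix
from .mk import mk_transition_matrix
from .nexus_io import CalibrationTable
from .tree import Cladogram, Node

__all__ = [
    "SimulationConfig",
    "simulate_fbd_tree",
    "simulate_mk_matrix",
    "simulate_alignment",
    "true_calibrations",
]


@dataclass
class SimulationConfig:
    """Study-scale defaults: ~40 extant + ~12 fossil taxa, 168 characters,
    550 + 650 bp partitions, Paleozoic-depth time scale (Myr)."""

    seed: int = 0
    n_extant: int = 40
    n_fossil: int = 12
    lam: float = 0.02  # speciation, per lineage per Myr
    mu: float = 0.015  # extinction
    psi: float = 0.003  # fossil sampling
    rho: float = 0.5  # extant sampling probability
    origin_time: float = 520.0  # Mya
    n_characters: int = 168
    k_states: int = 2
    char_rate: float = 0.002  # expected changes per character per Myr
    dependency_fraction: float = 0.35  # characters that are dependents
    two_level_fraction: float = 0.3  # of dependents, in 2-level chains
    soft_tissue_fraction: float = 0.4
    taphonomic_missing_prob: float = 0.6
    partition_lengths: tuple[int, int] = (550, 650)
    hky: tuple[HkyParams, ...] = (
        HkyParams(kappa=4.0, pi=(0.35, 0.15, 0.15, 0.35)),
        HkyParams(kappa=6.0, pi=(0.30, 0.20, 0.15, 0.35)),
    )
    clock_rate: float = 0.004  # substitutions per site per Myr
    calibration_halfwidth: float = 5.0  # +/- Myr on fossil tip ages
    exact_taxon_counts: bool = False  # subsample tips down to the targets
    max_lineages: int = 20000
    max_rejections: int = 1000

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        for p in (self.rho, self.dependency_fraction, self.two_level_fraction,
                  self.soft_tissue_fraction, self.taphonomic_missing_prob):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        for r in (self.lam, self.char_rate, self.clock_rate):
            if r <= 0:
                raise ValueError("rates must be positive")


# ---------------------------------------------------------------------------
# forward FBD simulation
# ---------------------------------------------------------------------------

class _Segment:
    __slots__ = ("birth", "end", "children", "fossils", "sampled")

    def __init__(self, birth: float):
        self.birth = birth
        self.end: float | None = None
        self.children: list[_Segment] = []
        self.fossils: list[float] = []
        self.sampled = False


def _forward_once(cfg: SimulationConfig, rng: random.Random):
    T = cfg.origin_time
    root = _Segment(0.0)
    active = [root]
    t = 0.0
    while active and t < T:
        total = len(active) * (cfg.lam + cfg.mu + cfg.psi)
        t += rng.expovariate(total)
        if t >= T:
            break
        if len(active) > cfg.max_lineages:
            return None, 0, 0
        seg = active[rng.randrange(len(active))]
        u = rng.random() * (cfg.lam + cfg.mu + cfg.psi)
        if u < cfg.lam:
            seg.end = t
            kids = [_Segment(t), _Segment(t)]
            seg.children = kids
            active.remove(seg)
            active.extend(kids)
        elif u < cfg.lam + cfg.mu:
            seg.end = t
            active.remove(seg)
        else:
            seg.fossils.append(t)
    n_sampled = 0
    for seg in active:
        seg.end = T
        seg.sampled = rng.random() < cfg.rho
        n_sampled += seg.sampled
    n_fossils = _count_fossils(root)
    return root, n_sampled, n_fossils


def _count_fossils(seg: _Segment) -> int:
    count = len(seg.fossils)
    for c in seg.children:
        count += _count_fossils(c)
    return count


def _reconstruct(seg: _Segment, T: float) -> Node | None:
    """Pruned subtree of sampled tips / fossil samples below this segment."""
    base: Node | None = None
    if seg.children:
        kids = [k for k in (_reconstruct(c, T) for c in seg.children) if k is not None]
        if len(kids) == 2:
            base = Node()
            base.age = T - seg.end
            for k in kids:
                base.add_child(k)
        elif len(kids) == 1:
            base = kids[0]
    elif seg.sampled:
        base = Node()
        base.age = 0.0
        base.is_fossil = False
    for ft in sorted(seg.fossils, reverse=True):  # youngest first
        age = T - ft
        fossil = Node()
        fossil.age = age
        fossil.is_fossil = True
        if base is None:
            base = fossil
        else:
            join = Node()
            join.age = age
            join.add_child(fossil)
            join.add_child(base)
            base = join
    return base


def simulate_fbd_tree(cfg: SimulationConfig, rng: random.Random | None = None) -> TimeTree:
    """Forward birth-death simulation with Poisson fossil sampling,
    rejection-conditioned on >= n_extant sampled extant tips and
    >= n_fossil fossil samples."""
    rng = rng or random.Random(cfg.seed)
    for _ in range(cfg.max_rejections):
        root_seg, n_sampled, n_fossils = _forward_once(cfg, rng)
        if root_seg is None:
            continue
        if n_sampled < max(cfg.n_extant, 2) or n_fossils < cfg.n_fossil:
            continue
        root = _reconstruct(root_seg, cfg.origin_time)
        if root is None or root.is_leaf:
            continue
        _label_tips(root)
        clad = Cladogram(root, rooted=True)
        if cfg.exact_taxon_counts:
            clad = _subsample_tips(clad, cfg, rng)
            if clad is None:
                continue
        _label_tips(clad.root)  # relabel compactly after any subsampling
        tt = TimeTree(clad)
        tt.set_lengths_from_ages()
        return tt
    raise RuntimeError(
        "rejection budget exhausted; adjust rates or required tip counts"
    )


def _subsample_tips(
    clad: Cladogram, cfg: SimulationConfig, rng: random.Random
) -> Cladogram | None:
    """Uniformly drop surplus tips so counts match the configured targets
    exactly (the same thinning that rho- and psi-sampling perform)."""
    extant = [l for l in clad.leaves() if not l.is_fossil]
    fossil = [l for l in clad.leaves() if l.is_fossil]
    drops = []
    if len(extant) > cfg.n_extant:
        drops += rng.sample(extant, len(extant) - cfg.n_extant)
    if len(fossil) > cfg.n_fossil:
        drops += rng.sample(fossil, len(fossil) - cfg.n_fossil)
    for leaf in drops:
        leaf.parent.remove_child(leaf)
    # single postorder pass removes branches left with no surviving tips
    for node in list(clad.root.postorder()):
        if node.label is None and not node.children and node.parent is not None:
            node.parent.remove_child(node)
    clad.suppress_unifurcations()
    if clad.root.is_leaf or len([l for l in clad.leaves() if not l.is_fossil]) < 2:
        return None
    return clad


def _label_tips(root: Node) -> None:
    n_e = n_f = 0
    for node in root.postorder():
        if node.is_leaf:
            if node.is_fossil:
                n_f += 1
                node.label = f"fossil{n_f}"
            else:
                n_e += 1
                node.label = f"taxon{n_e}"


# ---------------------------------------------------------------------------
# morphological characters
# ---------------------------------------------------------------------------

def _build_dependencies(cfg: SimulationConfig, rng: random.Random):
    chars = [f"c{j + 1}" for j in range(cfg.n_characters)]
    n_dep = round(cfg.dependency_fraction * cfg.n_characters)
    n_two = round(cfg.two_level_fraction * n_dep)
    edges = []
    free = list(chars)
    rng.shuffle(free)
    # one-level edges: controller -> dependent
    i = 0
    deps_assigned = 0
    while deps_assigned < n_dep - n_two and i + 1 < len(free):
        ctrl, dep = free[i], free[i + 1]
        edges.append((ctrl, frozenset("1"), dep))
        i += 2
        deps_assigned += 1
    # two-level chains: controller -> mid -> tip  (mid and tip both dependents)
    while deps_assigned < n_dep and i + 2 < len(free):
        ctrl, mid, tip = free[i], free[i + 1], free[i + 2]
        edges.append((ctrl, frozenset("1"), mid))
        edges.append((mid, frozenset("1"), tip))
        i += 3
        deps_assigned += 2
    return chars, DependencyGraph(edges)


def simulate_mk_matrix(
    timetree: TimeTree, cfg: SimulationConfig, rng: random.Random | None = None
) -> tuple[CharacterMatrix, DependencyGraph]:
    """Evolve discrete characters on the time tree under Mk and apply the
    contingency and taphonomic filters.

    Controllers and dependents all evolve under Mk at ``char_rate``;
    wherever a simulated controller state is unlicensed the dependent cell
    is recoded inapplicable (cascading down chains); fossil taxa then lose
    designated soft-tissue characters with the stated probability.
    """
    rng = rng or random.Random(cfg.seed + 1)
    k = cfg.k_states
    symbols = [str(s) for s in range(k)]
    chars, graph = _build_dependencies(cfg, rng)
    tree = timetree.tree
    leaves = tree.leaves()
    states: dict[str, dict[int, int]] = {}
    for ch in chars:
        st: dict[int, int] = {}
        for node in tree.preorder():
            if node.parent is None:
                st[id(node)] = rng.randrange(k)
            else:
                v = (node.parent.age - node.age) * cfg.char_rate
                P = mk_transition_matrix(k, v) if v > 0 else np.eye(k)
                probs = P[st[id(node.parent)]]
                st[id(node)] = rng.choices(range(k), weights=probs)[0]
        states[ch] = st
    taxa = [l.label for l in leaves]
    cells: list[list[CellValue]] = []
    order = graph.topological_order(chars)
    col = {c: j for j, c in enumerate(chars)}
    for leaf in leaves:
        row: list[CellValue] = [
            CellValue.of(symbols[states[ch][id(leaf)]]) for ch in chars
        ]
        for ch in order:
            ctrl = graph.controller_of(ch)
            if ctrl is None:
                continue
            ctrl_char, licensing = ctrl
            ctrl_cell = row[col[ctrl_char]]
            if ctrl_cell.is_inapplicable or (
                ctrl_cell.is_states and not (ctrl_cell.states & licensing)
            ):
                row[col[ch]] = CellValue.inapplicable()
        cells.append(row)
    matrix = CharacterMatrix(taxa=taxa, characters=chars, cells=cells)
    # taphonomic loss of soft-tissue characters in fossils
    n_soft = round(cfg.soft_tissue_fraction * cfg.n_characters)
    soft = set(rng.sample(chars, n_soft))
    for i, leaf in enumerate(leaves):
        if not leaf.is_fossil:
            continue
        for ch in soft:
            if rng.random() < cfg.taphonomic_missing_prob:
                matrix.cells[i][col[ch]] = CellValue.missing()
    return matrix, graph


def simulate_mk_on_cladogram(
    tree: Cladogram,
    n_characters: int,
    k: int = 2,
    rng: random.Random | None = None,
) -> CharacterMatrix:
    """Plain Mk characters on a branch-length tree (no dependencies or
    missingness); branch lengths are expected changes per character."""
    rng = rng or random.Random(0)
    symbols = [str(s) for s in range(k)]
    taxa = [l.label for l in tree.leaves()]
    cells: dict[str, list[CellValue]] = {t: [] for t in taxa}
    for _ in range(n_characters):
        st: dict[int, int] = {}
        for node in tree.preorder():
            if node.parent is None:
                st[id(node)] = rng.randrange(k)
            else:
                P = mk_transition_matrix(k, node.length)
                st[id(node)] = rng.choices(range(k), weights=P[st[id(node.parent)]])[0]
        for leaf in tree.leaves():
            cells[leaf.label].append(CellValue.of(symbols[st[id(leaf)]]))
    return CharacterMatrix(
        taxa=taxa,
        characters=[f"c{j + 1}" for j in range(n_characters)],
        cells=[cells[t] for t in taxa],
    )


# ---------------------------------------------------------------------------
# molecular alignments
# ---------------------------------------------------------------------------

def simulate_alignment(
    timetree: TimeTree, cfg: SimulationConfig, rng: random.Random | None = None
) -> list[dict[str, str]]:
    """Two-partition alignment under strict-clock HKY; extant tips only."""
    rng = rng or random.Random(cfg.seed + 2)
    out: list[dict[str, str]] = []
    for plen, params in zip(cfg.partition_lengths, cfg.hky):
        npr = np.random.default_rng(rng.randrange(2**31))
        Q = hky_rate_matrix(params)
        from .hky import _Eigen

        eig = _Eigen(Q, np.asarray(params.pi))
        tree = timetree.tree
        seqs: dict[str, np.ndarray] = {}
        arrs: dict[int, np.ndarray] = {}
        for node in tree.preorder():
            if node.parent is None:
                arrs[id(node)] = npr.choice(4, size=plen, p=np.asarray(params.pi))
            else:
                dur = (node.parent.age - node.age) * cfg.clock_rate
                P = eig.transition(dur)
                P = P / P.sum(axis=1, keepdims=True)
                parent_states = arrs[id(node.parent)]
                draws = np.empty(plen, dtype=int)
                for b in range(4):
                    idx = parent_states == b
                    if idx.any():
                        draws[idx] = npr.choice(4, size=int(idx.sum()), p=P[b])
                arrs[id(node)] = draws
            if node.is_leaf and not node.is_fossil:
                seqs[node.label] = arrs[id(node)]
        out.append(
            {name: "".join(BASES[b] for b in arr) for name, arr in seqs.items()}
        )
    return out


def true_calibrations(timetree: TimeTree, cfg: SimulationConfig) -> CalibrationTable:
    """Calibration windows of +/- calibration_halfwidth around true fossil ages."""
    ranges = {}
    for tip in timetree.fossil_tips():
        lo = max(0.0, tip.age - cfg.calibration_halfwidth)
        hi = tip.age + cfg.calibration_halfwidth
        ranges[tip.label] = (lo, hi)
    return CalibrationTable(ranges)
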