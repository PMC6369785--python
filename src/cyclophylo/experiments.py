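"""Self-contained validation experiments used by the analysis scripts and
the acceptance checks.

Each experiment simulates data with the synthetic-data module, runs the
corresponding inference machinery, and returns plain-number summaries.

The clock-coverage experiment follows the simulation-based-calibration
design: for each replicate the *true* dated tree is drawn from the
inference model's own prior (by running the clock sampler without data on
a fixed topology), the clock rate and kappas are drawn from their priors,
sequences are then simulated on that truth, and the full inference is run.
Under this design a correct sampler's nominal 95% HPD interval covers the
true root age in 95% of replicates, so observed coverage is a sharp
end-to-end test of the FBD density, the HKY likelihood, and the sampler.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, replace

from .clock import ClockPriors, ClockSettings, run_clock_mcmc, summarize_ages
from .fbd import FBDParams
from .hky import HkyParams
from .mk import (
    McmcSettings,
    posterior_consensus,
    run_mcmc,
    split_frequency_difference,
)
from .nexus_io import CalibrationTable
from .simulate import (
    SimulationConfig,
    simulate_alignment,
    simulate_fbd_tree,
    simulate_mk_on_cladogram,
)
from .tree import Cladogram

__all__ = [
    "MkRecoveryResult",
    "mk_recovery_experiment",
    "ClockCoverageResult",
    "clock_coverage_experiment",
    "SynapomorphyResult",
    "crown_synapomorphy_matrix",
    "crown_synapomorphy_experiment",
]


# ---------------------------------------------------------------------------
# Mk MCMC topology recovery (8 taxa, 500 characters, 2 runs)
# ---------------------------------------------------------------------------

@dataclass
class MkRecoveryResult:
    true_tree: Cladogram
    consensus: Cladogram
    rf_to_truth: int
    split_frequency_diff: float
    acceptance_rates: list[float]
    true_split_frequencies: list[float]


def mk_recovery_experiment(
    seed: int = 0,
    n_characters: int = 500,
    generations: int = 200_000,
    sample_every: int = 200,
    branch_length: float = 0.15,
) -> MkRecoveryResult:
    """Simulate Mk characters on a balanced 8-taxon tree (all branches at
    `branch_length` expected changes) and test whether two independent
    MCMC runs recover the generating topology and agree with each other."""
    true = Cladogram.from_nested(
        ((("A", "B"), ("C", "D")), (("E", "F"), ("G", "H"))), rooted=False
    )
    for n in true.root.postorder():
        if n.parent is not None:
            n.length = branch_length
    matrix = simulate_mk_on_cladogram(
        true, n_characters, k=2, rng=random.Random(seed)
    )
    traces = run_mcmc(
        matrix,
        McmcSettings(
            generations=generations,
            n_runs=2,
            sample_every=sample_every,
            seed=seed + 1,
        ),
    )
    consensus, freqs = posterior_consensus(traces, burnin=0.25)
    return MkRecoveryResult(
        true_tree=true,
        consensus=consensus,
        rf_to_truth=consensus.rf_distance(true),
        split_frequency_diff=split_frequency_difference(
            traces[0], traces[1], burnin=0.25
        ),
        acceptance_rates=[t.acceptance_rate for t in traces],
        true_split_frequencies=[
            freqs.get(s, 0.0) for s in sorted(true.bipartitions(), key=sorted)
        ],
    )


# ---------------------------------------------------------------------------
# FBD clock root-age coverage (simulation-based calibration)
# ---------------------------------------------------------------------------

@dataclass
class ClockCoverageResult:
    n_replicates: int
    n_covered: int
    coverage: float
    records: list[dict]


_COVERAGE_FBD = FBDParams(lam=0.08, mu=0.04, psi=0.025, rho=1.0)
_COVERAGE_PRIORS = dict(
    root_age_range=(5.0, 50.0),
    rate_ln_mu=math.log(0.01),
    rate_ln_sigma=0.3,
    kappa_ln_mu=math.log(5.0),
    kappa_ln_sigma=0.4,
)
_CAL_WIDTH = 4.0  # Myr width of fossil calibration windows


def _coverage_topology(seed: int) -> tuple[Cladogram, CalibrationTable, "TimeTree"]:
    """A 10-tip topology (7 extant + 3 fossils) from the FBD simulator,
    with calibration windows placed uniformly around the fossil ages."""
    rng = random.Random(seed)
    cfg = SimulationConfig(
        seed=seed,
        n_extant=7,
        n_fossil=3,
        lam=_COVERAGE_FBD.lam,
        mu=_COVERAGE_FBD.mu,
        psi=_COVERAGE_FBD.psi,
        rho=1.0,
        origin_time=50.0,
        exact_taxon_counts=True,
    )
    tt = simulate_fbd_tree(cfg, rng)
    ranges = {}
    for tip in tt.fossil_tips():
        offset = rng.random() * _CAL_WIDTH
        lo = max(tip.age - offset, 0.0)
        ranges[tip.label] = (lo, lo + _CAL_WIDTH)
    topo = tt.tree.copy()
    for node in topo.postorder():
        node.age = None
    return Cladogram(topo.root, rooted=True), CalibrationTable(ranges), tt


def clock_coverage_experiment(
    n_replicates: int = 40,
    seed: int = 0,
    prior_sweeps: int = 600,
    inference_sweeps: int = 1500,
    partition_lengths: tuple[int, int] = (600, 500),
    level: float = 0.95,
) -> ClockCoverageResult:
    """Root-age coverage of nominal `level` HPD intervals over replicates.

    Per replicate: the true dated tree comes from a prior-only run of the
    clock sampler (so truth is a draw from the model prior), the clock
    rate and kappas are drawn from their priors, two-partition alignments
    are simulated on the truth, and full inference is run on the same
    topology and calibrations.
    """
    records = []
    covered = 0
    for rep in range(n_replicates):
        rep_seed = seed * 1000 + rep
        rng = random.Random(rep_seed + 7)
        topo, cal, _ = _coverage_topology(rep_seed)
        priors = ClockPriors(**_COVERAGE_PRIORS)
        # draw the truth from the prior: prior-only MCMC on the topology
        prior_trace, truth = run_clock_mcmc(
            topo.copy(), [], cal, _COVERAGE_FBD, priors,
            ClockSettings(iterations=prior_sweeps, sample_every=prior_sweeps,
                          seed=rep_seed + 1, burnin=0.0),
        )
        rate_true = math.exp(rng.gauss(priors.rate_ln_mu, priors.rate_ln_sigma))
        kappas = [
            math.exp(rng.gauss(priors.kappa_ln_mu, priors.kappa_ln_sigma))
            for _ in range(2)
        ]
        pis = [(0.35, 0.15, 0.15, 0.35), (0.30, 0.20, 0.15, 0.35)]
        sim_cfg = SimulationConfig(
            seed=rep_seed + 2,
            partition_lengths=partition_lengths,
            clock_rate=rate_true,
            hky=tuple(HkyParams(kappa=k, pi=p) for k, p in zip(kappas, pis)),
        )
        partitions = simulate_alignment(truth, sim_cfg, random.Random(rep_seed + 3))
        trace, _ = run_clock_mcmc(
            topo.copy(), partitions, cal, _COVERAGE_FBD, priors,
            ClockSettings(iterations=inference_sweeps, sample_every=3,
                          seed=rep_seed + 4, burnin=0.3),
            hky_params=[HkyParams(kappa=5.0, pi=p) for p in pis],
            init_rate=math.exp(priors.rate_ln_mu),
        )
        ages = summarize_ages(trace, level)
        root_key = frozenset(l.label for l in topo.leaves())
        med, lo, hi = ages[root_key]
        true_root = truth.root_age
        inside = lo <= true_root <= hi
        covered += inside
        records.append(
            {
                "replicate": rep,
                "true_root": true_root,
                "median": med,
                "hpd_lo": lo,
                "hpd_hi": hi,
                "covered": bool(inside),
            }
        )
    return ClockCoverageResult(
        n_replicates=n_replicates,
        n_covered=covered,
        coverage=covered / n_replicates,
        records=records,
    )


# ---------------------------------------------------------------------------
# crown-synapomorphy emulation (search -> root -> optimize -> count)
# ---------------------------------------------------------------------------

@dataclass
class SynapomorphyResult:
    n_best_trees: int
    best_score: int
    crown_monophyletic: bool
    n_unambiguous: int
    n_total_changes: int
    unambiguous_characters: list[str]


def crown_synapomorphy_matrix():
    """A fossil-rich emulated matrix whose crown clade carries exactly two
    clean synapomorphies (tooth-plate-like and myomere-like characters).

    Ten taxa: two outgroups, four stem fossils with soft-tissue missingness,
    four crown taxa.  Besides the two crown characters, every other
    character marks a different clade of the pectinate true tree, so no
    additional change can optimise to the crown stem.
    """
    from .matrix import CharacterMatrix, CellValue

    taxa = ["O1", "O2", "S1", "S2", "S3", "S4", "C1", "C2", "C3", "C4"]
    cols: list[str] = []

    def col(pattern: str) -> None:
        cols.append(pattern)

    # two crown synapomorphies (observed in fossils: decay-resistant)
    col("0000001111")  # keratinous-tooth-plate-like
    col("0000001111")  # periocular-myomere-like
    # nested total-group markers along the backbone (S1..C4, S2..C4, ...)
    col("0011111111")
    col("0001111111")
    col("0000111111")
    col("0000011111")
    # crown-internal structure
    col("0000000011")  # C3+C4
    col("0000001100")  # C1+C2
    # outgroup marker
    col("1100000000")
    # soft-tissue characters: missing in the stem fossils
    col("00????1111")
    col("00????0011")
    col("11????0000")
    cells = [
        [
            CellValue.missing() if cols[j][i] == "?" else CellValue.of(cols[j][i])
            for j in range(len(cols))
        ]
        for i in range(len(taxa))
    ]
    return CharacterMatrix(
        taxa=taxa,
        characters=[f"c{j + 1}" for j in range(len(cols))],
        cells=cells,
    )


def crown_synapomorphy_experiment(seed: int = 0) -> SynapomorphyResult:
    """Search the emulated matrix, root on the outgroups, optimise, and
    count unambiguous changes on the crown branch."""
    from .ancestral import reconstruct, synapomorphies
    from .parsimony import SearchSettings, heuristic_search

    matrix = crown_synapomorphy_matrix()
    crown = ["C1", "C2", "C3", "C4"]
    trees, score = heuristic_search(
        matrix, SearchSettings(n_replicates=6, swap="TBR", seed=seed)
    )
    mono = all(t.has_clade(crown) for t in trees)
    rooted = trees[0].root_on_outgroup(["O1", "O2"])
    rec = reconstruct(rooted, matrix)
    syn = synapomorphies(rec, crown)
    unamb = [c for c in syn if c.flag == "unambiguous"]
    return SynapomorphyResult(
        n_best_trees=len(trees),
        best_score=score.total,
        crown_monophyletic=mono,
        n_unambiguous=len(unamb),
        n_total_changes=len(syn),
        unambiguous_characters=sorted(c.character for c in unamb),
    )
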