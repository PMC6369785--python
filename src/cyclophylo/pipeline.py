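"""End-to-end study workflow: recode -> eliminate -> search -> optimize
(-> Bayesian Mk -> tip-dated clock), with a machine-readable manifest.

The pipeline is a pure function of (inputs, config, seeds): every stage is
seeded, outputs are written deterministically, and the manifest records
per-stage output hashes so a rerun can be checked byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .ancestral import reconstruct, synapomorphies
from .contingency import (
    coding_sensitivity,
    elimination_statistic,
    recode_contingent,
    recode_flat,
)
from .fbd import FBDParams
from .matrix import CharacterMatrix
from .mk import McmcSettings, posterior_consensus, run_mcmc, split_frequency_difference
from .nexus_io import (
    read_calibration_table,
    read_dependency_table,
    read_fasta,
    read_newick,
    read_nexus,
    write_newick,
    write_nexus,
)
from .parsimony import SearchSettings, heuristic_search, strict_consensus
from .clock import ClockPriors, ClockSettings, run_clock_mcmc, summarize_ages
from .tree import Cladogram

__all__ = ["RunConfig", "run_study_pipeline"]


@dataclass
class RunConfig:
    """Paths, groups, seeds, and stage toggles for a full run."""

    matrix: str
    dependencies: str
    out_dir: str
    outgroup: list[str] = field(default_factory=list)
    groups: dict[str, list[str]] = field(default_factory=dict)
    focal_clade: list[str] = field(default_factory=list)
    alignments: list[str] = field(default_factory=list)
    calibrations: str | None = None
    seed: int = 0
    search_replicates: int = 10
    search_swap: str = "SPR"
    max_trees: int = 200
    run_bayes: bool = False
    bayes_generations: int = 50_000
    bayes_sample_every: int = 100
    run_clock: bool = False
    clock_iterations: int = 1000
    root_age_range: tuple[float, float] = (1.0, 600.0)
    fbd: tuple[float, float, float, float] = (0.02, 0.015, 0.003, 0.5)
    run_sensitivity: bool = True

    @classmethod
    def from_json(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = json.load(fh)
        if "root_age_range" in data:
            data["root_age_range"] = tuple(data["root_age_range"])
        if "fbd" in data:
            data["fbd"] = tuple(data["fbd"])
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_study_pipeline(cfg: RunConfig) -> dict:
    """Execute the workflow; returns the manifest (also written as JSON)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "stages": {},
        "outputs": {},
    }

    def fail(stage: str, exc: Exception):
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # -- stage: load + recode -------------------------------------------
    try:
        matrix = read_nexus(cfg.matrix)
        graph = read_dependency_table(cfg.dependencies, matrix)
        m_cont = recode_contingent(matrix, graph)
        m_flat = recode_flat(m_cont, graph)
        write_nexus(m_cont, out / "matrix_contingency.nex")
        write_nexus(m_flat, out / "matrix_flat.nex")
        manifest["stages"]["recode"] = {
            "n_taxa": matrix.n_taxa,
            "n_characters": matrix.n_characters,
            "n_dependent": len(graph.dependents()),
        }
    except Exception as exc:
        fail("recode", exc)

    # -- stage: elimination statistic -----------------------------------
    try:
        report = elimination_statistic(m_flat, m_cont, cfg.groups)
        report.to_frame().to_csv(out / "elimination.tsv", sep="\t", index=False)
        manifest["stages"]["elimination"] = {
            g: round(100 * v) for g, v in report.group_means.items()
        }
    except Exception as exc:
        fail("elimination", exc)

    # -- stage: parsimony search + consensus ----------------------------
    try:
        settings = SearchSettings(
            n_replicates=cfg.search_replicates,
            swap=cfg.search_swap,
            max_trees=cfg.max_trees,
            seed=cfg.seed,
        )
        trees, score = heuristic_search(m_cont, settings)
        with open(out / "mp_trees.nwk", "w") as fh:
            for t in trees:
                fh.write(t.to_newick(lengths=False) + "\n")
        cons = strict_consensus(trees)
        write_newick(cons, out / "mp_strict_consensus.nwk", lengths=False)
        manifest["stages"]["parsimony"] = {
            "score": score.total,
            "n_trees": len(trees),
        }
    except Exception as exc:
        fail("parsimony", exc)

    # -- stage: ancestral optimization ----------------------------------
    try:
        rooted = trees[0].root_on_outgroup(cfg.outgroup) if cfg.outgroup else None
        if rooted is not None:
            rec = reconstruct(rooted, m_cont)
            rows = [
                {
                    "branch": "|".join(sorted(c.branch)),
                    "character": c.character,
                    "from": c.from_state,
                    "to": c.to_state,
                    "flag": c.flag,
                }
                for c in rec.changes
            ]
            import pandas as pd

            pd.DataFrame(
                rows, columns=["branch", "character", "from", "to", "flag"]
            ).to_csv(out / "changes.tsv", sep="\t", index=False)
            stage: dict = {"n_changes": len(rec.changes)}
            if cfg.focal_clade and rooted.has_clade(cfg.focal_clade):
                syn = synapomorphies(rec, cfg.focal_clade)
                stage["focal_clade_unambiguous"] = sum(
                    1 for c in syn if c.flag == "unambiguous"
                )
            manifest["stages"]["optimize"] = stage
    except Exception as exc:
        fail("optimize", exc)

    # -- stage: coding sensitivity --------------------------------------
    if cfg.run_sensitivity:
        try:
            sens = coding_sensitivity(
                matrix, graph, settings, clade=cfg.focal_clade,
                clade_name="focal clade",
            )
            manifest["stages"]["sensitivity"] = {
                "monophyletic_contingency": sens.monophyletic_contingency,
                "monophyletic_flat": sens.monophyletic_flat,
                "score_contingency": sens.score_contingency,
                "score_flat": sens.score_flat,
            }
        except Exception as exc:
            fail("sensitivity", exc)

    # -- stage: Bayesian Mk ---------------------------------------------
    if cfg.run_bayes:
        try:
            traces = run_mcmc(
                m_cont,
                McmcSettings(
                    generations=cfg.bayes_generations,
                    sample_every=cfg.bayes_sample_every,
                    seed=cfg.seed,
                ),
            )
            cons_b, freqs = posterior_consensus(traces)
            write_newick(cons_b, out / "bayes_consensus.nwk", lengths=False)
            manifest["stages"]["bayes"] = {
                "asdsf": split_frequency_difference(traces[0], traces[1]),
                "acceptance": [t.acceptance_rate for t in traces],
            }
        except Exception as exc:
            fail("bayes", exc)

    # -- stage: tip-dated clock -----------------------------------------
    if cfg.run_clock:
        try:
            topo = strict_consensus(trees)
            if not topo.is_binary():
                topo = trees[0]
            rooted_topo = (
                topo.root_on_outgroup(cfg.outgroup) if cfg.outgroup else topo
            )
            partitions = [read_fasta(p) for p in cfg.alignments]
            cal = read_calibration_table(cfg.calibrations)
            # drop calibrated taxa absent from the tree, prune others later
            lam, mu, psi, rho = cfg.fbd
            trace, final = run_clock_mcmc(
                rooted_topo,
                partitions,
                cal,
                FBDParams(lam, mu, psi, rho),
                ClockPriors(root_age_range=cfg.root_age_range),
                ClockSettings(iterations=cfg.clock_iterations, seed=cfg.seed),
            )
            ages = summarize_ages(trace)
            import pandas as pd

            pd.DataFrame(
                [
                    {
                        "clade": "|".join(sorted(k)),
                        "median": med,
                        "hpd_lo": lo,
                        "hpd_hi": hi,
                    }
                    for k, (med, lo, hi) in ages.items()
                ]
            ).to_csv(out / "node_ages.tsv", sep="\t", index=False)
            root_key = frozenset(l.label for l in rooted_topo.leaves())
            manifest["stages"]["clock"] = {
                "root_median": ages[root_key][0],
                "root_hpd": list(ages[root_key][1:]),
            }
        except Exception as exc:
            fail("clock", exc)

    for p in sorted(out.iterdir()):
        if p.is_file() and p.name != "manifest.json":
            manifest["outputs"][p.name] = _sha256(p)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
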