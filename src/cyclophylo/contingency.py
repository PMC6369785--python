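"""Contingency (inapplicable-state) character coding.

Morphological characters are often hierarchically dependent: "tooth row
count" can only be observed in taxa whose controller character ("teeth
present") takes a licensing state.  Scoring such dependents as *absent* in
taxa that lack the controlling structure implicitly re-counts the absence
once per dependent character and inflates its weight in tree searches.
Contingency coding instead scores those cells as inapplicable (``-``).

This module recodes matrices between the two schemes and quantifies, per
taxon and per named taxon group, how much otherwise-codable character
information the contingency scheme removes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .matrix import CellValue, CharacterMatrix

__all__ = [
    "DependencyGraph",
    "EliminationReport",
    "recode_contingent",
    "recode_flat",
    "elimination_statistic",
    "CodingSensitivityReport",
    "coding_sensitivity",
]


class DependencyError(ValueError):
    pass


@dataclass
class DependencyGraph:
    """Directed controller -> dependent character relations.

    Each edge is ``(controller_char, licensing_states, dependent_char)``:
    the dependent is observable only in taxa whose controller cell carries
    at least one licensing state.  The graph must be acyclic and each
    dependent may have at most one controller.
    """

    edges: list[tuple[str, frozenset[str], str]]

    def __post_init__(self) -> None:
        self.edges = [
            (c, frozenset(s), d) for c, s, d in self.edges
        ]
        for c, s, d in self.edges:
            if not s:
                raise DependencyError(f"empty licensing state set on edge {c}->{d}")
        controllers: dict[str, str] = {}
        for c, _, d in self.edges:
            if d in controllers and controllers[d] != c:
                raise DependencyError(
                    f"character {d!r} has two controllers: {controllers[d]!r}, {c!r}"
                )
            controllers[d] = c
        self._controller_of = {
            d: (c, s) for c, s, d in self.edges
        }
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        # follow controller chains; a repeat means a cycle
        for start in self._controller_of:
            seen = {start}
            cur = start
            while cur in self._controller_of:
                cur = self._controller_of[cur][0]
                if cur in seen:
                    raise DependencyError(
                        f"dependency cycle involving character {cur!r}"
                    )
                seen.add(cur)

    def controller_of(self, char_id: str) -> tuple[str, frozenset[str]] | None:
        return self._controller_of.get(char_id)

    def dependents(self) -> list[str]:
        return list(self._controller_of)

    def all_characters(self) -> frozenset[str]:
        out: set[str] = set()
        for c, _, d in self.edges:
            out.add(c)
            out.add(d)
        return frozenset(out)

    def topological_order(self, characters: Sequence[str]) -> list[str]:
        """Characters ordered controllers-before-dependents."""
        depth: dict[str, int] = {}

        def chain_depth(ch: str) -> int:
            if ch in depth:
                return depth[ch]
            parent = self._controller_of.get(ch)
            depth[ch] = 0 if parent is None else chain_depth(parent[0]) + 1
            return depth[ch]

        return sorted(characters, key=lambda ch: (chain_depth(ch),
                                                  list(characters).index(ch)))


def _check_graph_against_matrix(m: CharacterMatrix, g: DependencyGraph) -> None:
    unknown = sorted(g.all_characters() - set(m.characters))
    if unknown:
        raise DependencyError(
            f"dependency graph references characters absent from the matrix: {unknown}"
        )


def recode_contingent(m: CharacterMatrix, g: DependencyGraph) -> CharacterMatrix:
    """Apply contingency coding.

    For every taxon and dependent character: if the controller cell is a
    state set disjoint from the licensing set, the dependent becomes
    inapplicable; if the controller is missing or inapplicable, the
    dependent becomes missing (the structure's presence is unobserved, not
    ruled out); otherwise the dependent is left unchanged.  Propagation
    runs controllers-first, so chains cascade.  The operation is
    idempotent.
    """
    _check_graph_against_matrix(m, g)
    out = m.copy()
    order = g.topological_order(m.characters)
    col = {c: j for j, c in enumerate(m.characters)}
    for ch in order:
        dep = g.controller_of(ch)
        if dep is None:
            continue
        ctrl, licensing = dep
        jc, jd = col[ctrl], col[ch]
        for row in out.cells:
            ctrl_cell = row[jc]
            if ctrl_cell.is_states:
                if not (ctrl_cell.states & licensing):
                    row[jd] = CellValue.inapplicable()
            elif ctrl_cell.is_missing:
                row[jd] = CellValue.missing()
            else:  # controller itself inapplicable: structure absent upstream
                row[jd] = CellValue.inapplicable()
    return out


def recode_flat(
    m: CharacterMatrix,
    g: DependencyGraph,
    fill_state: str = "0",
    on_orphan: str = "ignore",
) -> CharacterMatrix:
    """Undo contingency coding by scoring inapplicable dependents as a state.

    Every inapplicable cell of a character that has a controller in `g`
    becomes ``fill_state`` (by convention ``'0'`` = absent).  Inapplicable
    cells in characters without a controller are reported and left
    unchanged (``on_orphan="ignore"``) or raise (``on_orphan="error"``).
    """
    _check_graph_against_matrix(m, g)
    dependents = set(g.dependents())
    out = m.copy()
    col = {c: j for j, c in enumerate(m.characters)}
    orphans: list[tuple[str, str]] = []
    for ch in m.characters:
        j = col[ch]
        for taxon, row in zip(out.taxa, out.cells):
            if not row[j].is_inapplicable:
                continue
            if ch in dependents:
                row[j] = CellValue.of(fill_state)
            else:
                orphans.append((taxon, ch))
    if orphans and on_orphan == "error":
        raise DependencyError(
            f"inapplicable cells in characters with no controller: {orphans[:5]}"
        )
    return out


@dataclass
class EliminationReport:
    """How much flat-codable information contingency coding removed.

    ``per_taxon`` maps taxon -> (n_flat_codable, n_eliminated, fraction);
    ``group_means`` maps group name -> unweighted mean of member fractions.
    """

    per_taxon: dict[str, tuple[int, int, float]]
    group_means: dict[str, float] = field(default_factory=dict)
    group_members: dict[str, list[str]] = field(default_factory=dict)

    def fraction(self, taxon: str) -> float:
        return self.per_taxon[taxon][2]

    def to_frame(self) -> pd.DataFrame:
        group_of: dict[str, str] = {}
        for gname, members in self.group_members.items():
            for t in members:
                group_of[t] = gname
        rows = [
            {
                "taxon": t,
                "n_flat_codable": n_codable,
                "n_eliminated": n_elim,
                "fraction": frac,
                "group": group_of.get(t, ""),
            }
            for t, (n_codable, n_elim, frac) in self.per_taxon.items()
        ]
        return pd.DataFrame(rows)

    def percent(self, group: str) -> int:
        """Group mean as a percentage rounded to the nearest integer."""
        return round(100 * self.group_means[group])


def elimination_statistic(
    m_flat: CharacterMatrix,
    m_cont: CharacterMatrix,
    groups: Mapping[str, Iterable[str]] | None = None,
) -> EliminationReport:
    """Quantify character information eliminated by contingency coding.

    For each taxon, ``n_flat_codable`` counts characters bearing a state
    set under flat coding and ``n_eliminated`` counts those recoded to
    inapplicable under contingency coding; the fraction is their ratio
    (0 for a taxon with nothing codable).  Group values are unweighted
    means over member taxa.
    """
    if m_flat.taxa != m_cont.taxa or m_flat.characters != m_cont.characters:
        raise ValueError("matrices must share taxa and characters in order")
    per_taxon: dict[str, tuple[int, int, float]] = {}
    for i, taxon in enumerate(m_flat.taxa):
        n_codable = 0
        n_elim = 0
        for cv_flat, cv_cont in zip(m_flat.cells[i], m_cont.cells[i]):
            if cv_flat.is_states:
                n_codable += 1
                if cv_cont.is_inapplicable:
                    n_elim += 1
        frac = n_elim / n_codable if n_codable else 0.0
        per_taxon[taxon] = (n_codable, n_elim, frac)
    report = EliminationReport(per_taxon=per_taxon)
    if groups:
        for name, members in groups.items():
            members = list(members)
            unknown = sorted(set(members) - set(m_flat.taxa))
            if unknown:
                raise ValueError(f"group {name!r} references unknown taxa: {unknown}")
            if not members:
                raise ValueError(f"group {name!r} is empty")
            report.group_members[name] = members
            report.group_means[name] = sum(
                per_taxon[t][2] for t in members
            ) / len(members)
    return report


@dataclass
class CodingSensitivityReport:
    """Outcome of searching the same matrix under both coding schemes."""

    clade_name: str
    clade: frozenset[str]
    monophyletic_contingency: bool
    monophyletic_flat: bool
    score_contingency: int
    score_flat: int
    n_trees_contingency: int
    n_trees_flat: int
    shared_splits: frozenset
    contingency_only_splits: frozenset
    flat_only_splits: frozenset
    consensus_contingency: object = None  # Cladogram
    consensus_flat: object = None


def coding_sensitivity(
    m: CharacterMatrix,
    g: DependencyGraph,
    settings=None,
    clade: Iterable[str] = (),
    clade_name: str = "focal clade",
    fill_state: str = "0",
) -> CodingSensitivityReport:
    """Run the parsimony search under contingency and flat codings of the
    same matrix and compare the resulting tree sets.

    The monophyly verdict for the named clade is a bipartition test
    against the strict consensus of each search (the clade is called
    monophyletic iff it is a split of every most-parsimonious tree).
    """
    from .parsimony import SearchSettings, heuristic_search, strict_consensus

    settings = settings or SearchSettings()
    m_cont = recode_contingent(m, g)
    m_flat = recode_flat(m_cont, g, fill_state=fill_state)
    trees_c, score_c = heuristic_search(m_cont, settings)
    trees_f, score_f = heuristic_search(m_flat, settings)
    cons_c = strict_consensus(trees_c)
    cons_f = strict_consensus(trees_f)
    clade = frozenset(clade)
    mono_c = all(t.has_clade(clade) for t in trees_c) if clade else False
    mono_f = all(t.has_clade(clade) for t in trees_f) if clade else False
    splits_c = cons_c.bipartitions()
    splits_f = cons_f.bipartitions()
    return CodingSensitivityReport(
        clade_name=clade_name,
        clade=clade,
        monophyletic_contingency=mono_c,
        monophyletic_flat=mono_f,
        score_contingency=score_c.total,
        score_flat=score_f.total,
        n_trees_contingency=len(trees_c),
        n_trees_flat=len(trees_f),
        shared_splits=frozenset(splits_c & splits_f),
        contingency_only_splits=frozenset(splits_c - splits_f),
        flat_only_splits=frozenset(splits_f - splits_c),
        consensus_contingency=cons_c,
        consensus_flat=cons_f,
    )
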