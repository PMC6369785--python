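"""Readers and writers for all on-disk artifacts.

NEXUS character matrices are parsed through dendropy; the cells are then
mapped onto this package's :class:`~cyclophylo.matrix.CellValue` semantics
(``?`` missing, ``-`` inapplicable, ``{..}``/``(..)`` state sets).  Newick
goes through :class:`~cyclophylo.tree.Cladogram`; FASTA through Biopython;
the dependency and calibration tables are plain TSV read with pandas.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass
from typing import Mapping

import dendropy
import pandas as pd
from Bio import SeqIO

from .contingency import DependencyGraph
from .matrix import CellValue, CharacterMatrix
from .tree import Cladogram, TreeError

__all__ = [
    "NexusError",
    "read_nexus",
    "write_nexus",
    "read_newick",
    "write_newick",
    "read_dependency_table",
    "write_dependency_table",
    "CalibrationTable",
    "read_calibration_table",
    "write_calibration_table",
    "read_fasta",
    "write_fasta",
]


class NexusError(ValueError):
    pass


# ---------------------------------------------------------------------------
# NEXUS character matrices
# ---------------------------------------------------------------------------

def read_nexus(path: str | os.PathLike) -> CharacterMatrix:
    """Read a NEXUS DATA/CHARACTERS block into a :class:`CharacterMatrix`.

    ``?`` becomes a missing cell, ``-`` (the GAP token) an inapplicable
    cell, and ``{..}``/``(..)`` groups become multi-state cells.
    """
    with open(path) as fh:
        text = fh.read()
    return _parse_nexus_text(text, source=str(path))


def _parse_nexus_text(text: str, source: str = "<string>") -> CharacterMatrix:
    _check_declared_dimensions(text, source)
    try:
        dmat = dendropy.StandardCharacterMatrix.get(data=text, schema="nexus")
    except Exception as exc:
        raise NexusError(f"{source}: malformed NEXUS matrix: {exc}") from exc
    taxa = [t.label for t in dmat.taxon_namespace]
    if len(set(taxa)) != len(taxa):
        raise NexusError(f"{source}: duplicate taxon labels")
    ncols = {len(dmat[t]) for t in dmat.taxon_namespace}
    if len(ncols) != 1:
        raise NexusError(f"{source}: rows of unequal length {sorted(ncols)}")
    nchar = ncols.pop()
    characters = [f"c{j + 1}" for j in range(nchar)]
    cells: list[list[CellValue]] = []
    for taxon in dmat.taxon_namespace:
        row: list[CellValue] = []
        for st in dmat[taxon]:
            row.append(_cell_from_dendropy_state(st))
        cells.append(row)
    return CharacterMatrix(taxa=taxa, characters=characters, cells=cells)


def _cell_from_dendropy_state(state) -> CellValue:
    if state.symbol == "?":
        return CellValue.missing()
    if state.symbol == "-":
        return CellValue.inapplicable()
    members = state.member_states
    if members is None:
        return CellValue.of(state.symbol)
    symbols = {m.symbol for m in members}
    if "?" in symbols:
        return CellValue.missing()
    symbols.discard("-")
    if not symbols:
        return CellValue.inapplicable()
    # full-ambiguity multistate equal to the whole alphabet is missing
    return CellValue("states", frozenset(symbols))


def _check_declared_dimensions(text: str, source: str) -> None:
    """Cross-check NTAX/NCHAR declarations against the matrix body.

    dendropy tolerates some dimension disagreements; the contract here is
    strict, so declared and actual dimensions must agree.
    """
    import re

    m = re.search(r"dimensions([^;]*);", text, flags=re.I)
    if m is None:
        raise NexusError(f"{source}: no DIMENSIONS statement found")
    decl = m.group(1)
    ntax = re.search(r"ntax\s*=\s*(\d+)", decl, flags=re.I)
    nchar = re.search(r"nchar\s*=\s*(\d+)", decl, flags=re.I)
    if ntax is None or nchar is None:
        raise NexusError(f"{source}: DIMENSIONS must declare NTAX and NCHAR")
    body = re.search(r"matrix(.*?);", text, flags=re.I | re.S)
    if body is None:
        raise NexusError(f"{source}: no MATRIX statement found")
    rows = [ln.strip() for ln in body.group(1).splitlines() if ln.strip()]
    if len(rows) != int(ntax.group(1)):
        raise NexusError(
            f"{source}: NTAX={ntax.group(1)} but matrix has {len(rows)} rows"
        )
    for ln in rows:
        tokens = _row_cell_count(ln)
        if tokens != int(nchar.group(1)):
            raise NexusError(
                f"{source}: NCHAR={nchar.group(1)} but a row has {tokens} cells"
            )


def _row_cell_count(line: str) -> int:
    # strip the taxon label (first whitespace-delimited token, possibly quoted)
    line = line.strip()
    if line.startswith("'"):
        end = line.index("'", 1)
        rest = line[end + 1 :]
    else:
        parts = line.split(None, 1)
        rest = parts[1] if len(parts) > 1 else ""
    count = 0
    depth = 0
    for ch in rest:
        if ch in "{(":
            depth += 1
            if depth == 1:
                count += 1
        elif ch in "})":
            depth -= 1
        elif not ch.isspace() and depth == 0:
            count += 1
    return count


def write_nexus(matrix: CharacterMatrix, path: str | os.PathLike) -> None:
    """Write a matrix as a NEXUS DATA block (STANDARD datatype)."""
    symbols = sorted(
        {s for row in matrix.cells for cv in row if cv.is_states for s in cv.states}
    ) or ["0"]
    width = max(len(t) for t in matrix.taxa) + 2
    buf = io.StringIO()
    buf.write("#NEXUS\n\nBEGIN DATA;\n")
    buf.write(
        f"    DIMENSIONS NTAX={matrix.n_taxa} NCHAR={matrix.n_characters};\n"
    )
    buf.write(
        '    FORMAT DATATYPE=STANDARD SYMBOLS="'
        + "".join(symbols)
        + '" MISSING=? GAP=-;\n'
    )
    buf.write("    MATRIX\n")
    for label, row in zip(matrix.taxa, matrix.cells):
        name = f"'{label}'" if any(c.isspace() for c in label) else label
        buf.write(f"    {name:<{width}}" + "".join(cv.token() for cv in row) + "\n")
    buf.write("    ;\nEND;\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


# ---------------------------------------------------------------------------
# Newick trees
# ---------------------------------------------------------------------------

def read_newick(path: str | os.PathLike, rooted: bool | None = None) -> Cladogram:
    with open(path) as fh:
        return Cladogram.from_newick(fh.read(), rooted=rooted)


def write_newick(tree: Cladogram, path: str | os.PathLike, lengths: bool = True) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick(lengths=lengths) + "\n")


# ---------------------------------------------------------------------------
# dependency table (controller -> dependent character relations)
# ---------------------------------------------------------------------------

def read_dependency_table(
    path: str | os.PathLike, matrix: CharacterMatrix | None = None
) -> DependencyGraph:
    """Read a TSV with columns controller_char, controlling_state, dependent_char.

    ``controlling_state`` may list several licensing states, e.g. ``12``.
    If `matrix` is given, every referenced character must exist in it.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"controller_char", "controlling_state", "dependent_char"}
    if not required <= set(df.columns):
        raise NexusError(
            f"dependency table must have columns {sorted(required)}; "
            f"found {list(df.columns)}"
        )
    edges = [
        (row.controller_char, frozenset(str(row.controlling_state)), row.dependent_char)
        for row in df.itertuples()
    ]
    graph = DependencyGraph(edges)
    if matrix is not None:
        known = set(matrix.characters)
        unknown = sorted(graph.all_characters() - known)
        if unknown:
            raise NexusError(f"dependency table references unknown characters: {unknown}")
    return graph


def write_dependency_table(graph: DependencyGraph, path: str | os.PathLike) -> None:
    rows = [
        {
            "controller_char": ctrl,
            "controlling_state": "".join(sorted(states)),
            "dependent_char": dep,
        }
        for ctrl, states, dep in graph.edges
    ]
    pd.DataFrame(
        rows, columns=["controller_char", "controlling_state", "dependent_char"]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# fossil tip-age calibrations
# ---------------------------------------------------------------------------

@dataclass
class CalibrationTable:
    """Fossil tip age ranges in Mya (present = 0, older = larger)."""

    ranges: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for taxon, (lo, hi) in self.ranges.items():
            if not (0 <= lo <= hi):
                raise ValueError(
                    f"calibration for {taxon!r} must satisfy 0 <= min <= max; "
                    f"got ({lo}, {hi})"
                )

    def __contains__(self, taxon: str) -> bool:
        return taxon in self.ranges

    def __getitem__(self, taxon: str) -> tuple[float, float]:
        return self.ranges[taxon]

    def taxa(self) -> list[str]:
        return list(self.ranges)


def read_calibration_table(path: str | os.PathLike) -> CalibrationTable:
    df = pd.read_csv(path, sep="\t")
    required = {"taxon", "min_age", "max_age"}
    if not required <= set(df.columns):
        raise NexusError(
            f"calibration table must have columns {sorted(required)}; "
            f"found {list(df.columns)}"
        )
    return CalibrationTable(
        {r.taxon: (float(r.min_age), float(r.max_age)) for r in df.itertuples()}
    )


def write_calibration_table(table: CalibrationTable, path: str | os.PathLike) -> None:
    pd.DataFrame(
        [
            {"taxon": t, "min_age": lo, "max_age": hi}
            for t, (lo, hi) in table.ranges.items()
        ]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTA alignments
# ---------------------------------------------------------------------------

def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not seqs:
        raise NexusError(f"{path}: no sequences found")
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) != 1:
        raise NexusError(f"{path}: sequences are not aligned (lengths {sorted(lengths)})")
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
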