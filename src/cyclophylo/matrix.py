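"""Discrete morphological character matrices.

A :class:`CharacterMatrix` holds, for every (taxon, character) pair, a
:class:`CellValue` that is either an observed state set (a singleton for an
ordinary observation, larger for a polymorphism), *missing* (``?``: the
character could be observed but was not), or *inapplicable* (``-``: the
character cannot logically be observed in that taxon, e.g. bone histology in
a taxon without bone).  The missing/inapplicable distinction is preserved
through every operation in this package; collapsing the two is exactly the
coding decision the contingency-coding machinery is meant to interrogate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

MISSING_SYMBOL = "?"
INAPPLICABLE_SYMBOL = "-"

__all__ = [
    "CellValue",
    "CharacterMatrix",
    "MISSING_SYMBOL",
    "INAPPLICABLE_SYMBOL",
]


@dataclass(frozen=True)
class CellValue:
    """A single matrix cell: a state set, missing, or inapplicable."""

    kind: str  # "states" | "missing" | "inapplicable"
    states: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.kind not in ("states", "missing", "inapplicable"):
            raise ValueError(f"unknown cell kind {self.kind!r}")
        if self.kind == "states" and not self.states:
            raise ValueError("state-set cell must carry at least one state")
        if self.kind != "states" and self.states:
            raise ValueError(f"{self.kind} cell must not carry states")

    @classmethod
    def of(cls, *states: str) -> "CellValue":
        return cls("states", frozenset(states))

    @classmethod
    def missing(cls) -> "CellValue":
        return cls("missing")

    @classmethod
    def inapplicable(cls) -> "CellValue":
        return cls("inapplicable")

    @property
    def is_states(self) -> bool:
        return self.kind == "states"

    @property
    def is_missing(self) -> bool:
        return self.kind == "missing"

    @property
    def is_inapplicable(self) -> bool:
        return self.kind == "inapplicable"

    @property
    def is_polymorphic(self) -> bool:
        return self.kind == "states" and len(self.states) > 1

    def token(self) -> str:
        """Render the cell as a matrix token (``?``, ``-``, ``1``, ``{01}``)."""
        if self.is_missing:
            return MISSING_SYMBOL
        if self.is_inapplicable:
            return INAPPLICABLE_SYMBOL
        syms = sorted(self.states)
        return syms[0] if len(syms) == 1 else "{" + "".join(syms) + "}"


@dataclass
class CharacterMatrix:
    """Taxa x characters table of discrete cells.

    Parameters
    ----------
    taxa
        Ordered unique taxon labels (rows).
    characters
        Ordered character identifiers (columns).
    cells
        ``cells[i][j]`` is the :class:`CellValue` for taxon ``i``,
        character ``j``.
    char_descriptions
        Optional free-text description per character id.
    """

    taxa: list[str]
    characters: list[str]
    cells: list[list[CellValue]]
    char_descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        if len(set(self.taxa)) != len(self.taxa):
            dupes = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise ValueError(f"duplicate taxon labels: {dupes}")
        if len(self.cells) != len(self.taxa):
            raise ValueError(
                f"{len(self.cells)} rows for {len(self.taxa)} taxa"
            )
        ncol = len(self.characters)
        for label, row in zip(self.taxa, self.cells):
            if len(row) != ncol:
                raise ValueError(
                    f"row {label!r} has {len(row)} cells, expected {ncol}"
                )

    # -- indexing --------------------------------------------------------
    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_characters(self) -> int:
        return len(self.characters)

    def taxon_index(self, label: str) -> int:
        try:
            return self.taxa.index(label)
        except ValueError:
            raise KeyError(f"unknown taxon {label!r}") from None

    def char_index(self, char_id: str) -> int:
        try:
            return self.characters.index(char_id)
        except ValueError:
            raise KeyError(f"unknown character {char_id!r}") from None

    def cell(self, taxon: str, char_id: str) -> CellValue:
        return self.cells[self.taxon_index(taxon)][self.char_index(char_id)]

    def column(self, char_id: str) -> list[CellValue]:
        j = self.char_index(char_id)
        return [row[j] for row in self.cells]

    def state_space(self, char_id: str) -> frozenset[str]:
        """Set of state symbols observed for a character across all taxa."""
        out: set[str] = set()
        for cv in self.column(char_id):
            if cv.is_states:
                out |= cv.states
        return frozenset(out)

    # -- derived views ---------------------------------------------------
    def copy(self) -> "CharacterMatrix":
        return CharacterMatrix(
            taxa=list(self.taxa),
            characters=list(self.characters),
            cells=[list(row) for row in self.cells],
            char_descriptions=dict(self.char_descriptions),
        )

    def subset_taxa(self, labels: Sequence[str]) -> "CharacterMatrix":
        idx = [self.taxon_index(t) for t in labels]
        return CharacterMatrix(
            taxa=[self.taxa[i] for i in idx],
            characters=list(self.characters),
            cells=[list(self.cells[i]) for i in idx],
            char_descriptions=dict(self.char_descriptions),
        )

    def reorder(
        self,
        taxa: Sequence[str] | None = None,
        characters: Sequence[str] | None = None,
    ) -> "CharacterMatrix":
        """Return a matrix with rows/columns permuted to the given orders."""
        taxa = list(taxa) if taxa is not None else list(self.taxa)
        characters = (
            list(characters) if characters is not None else list(self.characters)
        )
        if sorted(taxa) != sorted(self.taxa):
            raise ValueError("taxon reordering must be a permutation")
        if sorted(characters) != sorted(self.characters):
            raise ValueError("character reordering must be a permutation")
        ti = [self.taxon_index(t) for t in taxa]
        cj = [self.char_index(c) for c in characters]
        return CharacterMatrix(
            taxa=taxa,
            characters=characters,
            cells=[[self.cells[i][j] for j in cj] for i in ti],
            char_descriptions=dict(self.char_descriptions),
        )

    def equal_cells(self, other: "CharacterMatrix") -> bool:
        """Cell-for-cell equality, including taxon/character order."""
        return (
            self.taxa == other.taxa
            and self.characters == other.characters
            and self.cells == other.cells
        )

    def n_state_cells(self) -> int:
        """Count of cells bearing an observed state set."""
        return sum(cv.is_states for row in self.cells for cv in row)

    def is_parsimony_informative(self, char_id: str) -> bool:
        """True if the character can affect tree choice under parsimony.

        A character is informative when at least two states each occur
        (unambiguously, as singletons) in at least two taxa.
        """
        counts: dict[str, int] = {}
        for cv in self.column(char_id):
            if cv.is_states and len(cv.states) == 1:
                (s,) = cv.states
                counts[s] = counts.get(s, 0) + 1
        return sum(1 for c in counts.values() if c >= 2) >= 2

    def n_informative(self) -> int:
        return sum(
            self.is_parsimony_informative(c) for c in self.characters
        )
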