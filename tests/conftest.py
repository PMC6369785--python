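import random

import pytest

from cyclophylo.matrix import CellValue, CharacterMatrix


def make_matrix(rows: dict[str, str], characters: list[str] | None = None) -> CharacterMatrix:
    """Build a matrix from token strings, e.g. {"A": "01?-{01}"}.

    Tokens: digits = single states, ``?`` missing, ``-`` inapplicable,
    ``{..}`` polymorphic.
    """
    taxa = list(rows)
    cells = []
    n = None
    for taxon in taxa:
        row = []
        s = rows[taxon]
        i = 0
        while i < len(s):
            ch = s[i]
            if ch == "?":
                row.append(CellValue.missing())
            elif ch == "-":
                row.append(CellValue.inapplicable())
            elif ch == "{":
                j = s.index("}", i)
                row.append(CellValue("states", frozenset(s[i + 1 : j])))
                i = j
            else:
                row.append(CellValue.of(ch))
            i += 1
        cells.append(row)
        n = len(row)
    chars = characters or [f"c{j + 1}" for j in range(n)]
    return CharacterMatrix(taxa=taxa, characters=chars, cells=cells)


def random_matrix(
    rng: random.Random,
    n_taxa: int,
    n_chars: int,
    k: int = 2,
    p_missing: float = 0.0,
) -> CharacterMatrix:
    taxa = [chr(65 + i) for i in range(n_taxa)]
    cells = []
    for _ in taxa:
        row = []
        for _ in range(n_chars):
            if rng.random() < p_missing:
                row.append(CellValue.missing())
            else:
                row.append(CellValue.of(str(rng.randrange(k))))
        cells.append(row)
    return CharacterMatrix(
        taxa=taxa, characters=[f"c{j + 1}" for j in range(n_chars)], cells=cells
    )


@pytest.fixture
def rng():
    return random.Random(20260926)
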