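"""How the coding scheme changes the tree: the absence-block demonstration.

Runs the parsimony search on the same matrix under contingency and flat
codings.  The constructed case has a soft-bodied crown pair (H, L) whose
monophyly survives contingency coding but collapses under flat coding,
because six skeletal detail characters scored "absent" unite H with the
soft-bodied outgroups.  Verdicts are bipartition tests over the full tree
sets; the summary lands in results/coding_sensitivity.json.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from cyclophylo.contingency import DependencyGraph, coding_sensitivity
from cyclophylo.matrix import CellValue, CharacterMatrix
from cyclophylo.parsimony import SearchSettings

ROOT = Path(__file__).resolve().parents[1]


def build_matrix() -> CharacterMatrix:
    rows = {
        "O1": "0" + "------" + "00" + "0" + "00",
        "O2": "0" + "------" + "00" + "0" + "00",
        "H": "0" + "------" + "11" + "1" + "00",
        "L": "1" + "111111" + "11" + "1" + "00",
        "G1": "1" + "111111" + "00" + "1" + "11",
        "G2": "1" + "111111" + "00" + "1" + "11",
        "G3": "1" + "111111" + "00" + "1" + "11",
        "G4": "1" + "111111" + "00" + "1" + "11",
    }

    def cell(tok: str) -> CellValue:
        if tok == "-":
            return CellValue.inapplicable()
        return CellValue.of(tok)

    taxa = list(rows)
    return CharacterMatrix(
        taxa,
        [f"c{j + 1}" for j in range(12)],
        [[cell(t) for t in rows[tax]] for tax in taxa],
    )


def main() -> None:
    m = build_matrix()
    g = DependencyGraph([("c1", frozenset("1"), f"c{j}") for j in range(2, 8)])
    rep = coding_sensitivity(
        m, g, SearchSettings(n_replicates=6, swap="SPR", seed=7),
        clade=["H", "L"], clade_name="crown pair",
    )
    summary = {
        "clade": sorted(rep.clade),
        "monophyletic_under_contingency": rep.monophyletic_contingency,
        "monophyletic_under_flat": rep.monophyletic_flat,
        "score_contingency": rep.score_contingency,
        "score_flat": rep.score_flat,
        "n_shared_splits": len(rep.shared_splits),
        "n_conflicting_splits": len(rep.contingency_only_splits)
        + len(rep.flat_only_splits),
    }
    out = ROOT / "results" / "coding_sensitivity.json"
    out.write_text(json.dumps(summary, indent=2) + "\n")
    print(json.dumps(summary, indent=2))
    print(
        "flat recoding adds implicit weight: the crown pair is "
        + ("kept" if rep.monophyletic_flat else "broken")
        + " under flat coding and "
        + ("kept" if rep.monophyletic_contingency else "broken")
        + " under contingency coding"
    )


if __name__ == "__main__":
    main()
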