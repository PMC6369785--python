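# cyclophylo

Inapplicable-aware morphological phylogenetics: contingency character
coding, maximum parsimony with ACCTRAN/DELTRAN synapomorphy optimization,
Bayesian Mk inference, and fossilized birth–death (FBD) tip dating — the
full analytical workflow behind fossil-rich studies of early vertebrate
(cyclostome) relationships, as a tested Python library with an analysis
pipeline.

## The scientific problem

Morphological matrices that mix living and fossil taxa are full of
hierarchically dependent characters: "tooth row count" can only be
observed where a controller character ("teeth present") takes a licensing
state.  Scoring such dependents as *absent* (`0`) in taxa that lack the
controlling structure re-counts that absence once per dependent and
silently up-weights it in tree searches — enough, in practice, to move
clades.  **Contingency coding** scores those cells as *inapplicable*
(`-`, distinct from missing `?`) and removes that implicit weight.

The package implements, end to end:

- **Contingency recoding** between flat and inapplicable-coded schemes,
  with an *elimination statistic*: per taxon, the fraction of
  flat-codable cells that contingency coding removes (group values are
  unweighted means over member taxa).
- **Fitch parsimony** (unordered, equally weighted characters; `?`/`-`
  enter scoring as full ambiguity) with random-addition + NNI/SPR/TBR
  heuristic search, exhaustive enumeration for small problems, and
  strict / majority-rule consensus.
- **Ancestral states**: per-node MPR sets via a unit-cost Sankoff
  inside/outside pass, accelerated (ACCTRAN) and delayed (DELTRAN)
  resolutions, and per-branch change lists flagged
  `unambiguous | acctran-only | deltran-only | ambiguous`.  A change is
  unambiguous iff the MPR sets at both ends of its branch are singletons.
- **Bayesian Mk** inference (Lewis's Mk with the variable-only
  ascertainment correction, optional discrete-gamma rates) by
  Metropolis–Hastings over topology and branch lengths, two independent
  runs compared by split frequencies.
- **FBD tip dating**: strict-clock HKY likelihood over two partitions on
  a fixed topology, serially-sampled birth–death tree prior with fossil
  tips dated inside stratigraphic calibration windows, node ages
  summarised as posterior median + 95% HPD (shortest interval).
- **Synthetic data**: forward FBD tree simulation with fossil sampling,
  Mk character simulation with dependency chains and taphonomic
  missingness, and strict-clock HKY alignments — everything the pipeline
  consumes can be generated with a seed.

## Worked example

```python
import random
from cyclophylo import (SimulationConfig, simulate_fbd_tree,
                        simulate_mk_matrix, recode_flat,
                        elimination_statistic, heuristic_search,
                        SearchSettings, reconstruct, synapomorphies)

cfg = SimulationConfig(seed=2026, exact_taxon_counts=True)  # 52 x 168
rng = random.Random(2026)
tt = simulate_fbd_tree(cfg, rng)
matrix, deps = simulate_mk_matrix(tt, cfg, rng)

flat = recode_flat(matrix, deps)
rep = elimination_statistic(flat, matrix,
                            {"fossil": [t.label for t in tt.fossil_tips()]})
print(rep.percent("fossil"))     # -> 19 (percent of codable info removed)

trees, score = heuristic_search(
    matrix, SearchSettings(n_replicates=2, swap="NNI", seed=11))
print(score.total)               # -> 975 (steps of the best trees found)
```

Running the numbered drivers in `analysis/` reproduces the full study
workflow on the emulated dataset; with the seeds committed there they
print, among other things:

```
wrote 52 taxa x 168 characters (1594 inapplicable, 501 missing cells), ...
contingency coding eliminated, on average, 19% of codable character
  information from fossil taxa and 19% from extant taxa
20 most-parsimonious tree(s) at 975 steps; strict consensus has 43 resolved splits
crown emulation: 2 unambiguous changes on the crown stem (characters c1, c2)
monophyletic_under_contingency: true / monophyletic_under_flat: false
generating topology recovered; split-frequency difference 0.0143
```

The `coding_sensitivity` demonstration is the package's core story in
miniature: a soft-bodied crown pair stays monophyletic under contingency
coding and is broken under flat recoding, because six skeletal "absent"
scores unite one crown taxon with the soft-bodied outgroups.

A console script mirrors the stages:

```bash
cyclophylo simulate --seed 1 --out-dir data/
cyclophylo search --matrix data/matrix.nex --out-trees mp.nwk
cyclophylo optimize --matrix data/matrix.nex --tree mp.nwk \
    --outgroup taxon1 --out changes.tsv
cyclophylo clock --topology data/true_tree.nwk \
    --alignment data/partition1.fasta --alignment data/partition2.fasta \
    --calibrations data/calibrations.tsv --out-ages ages.tsv
```

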