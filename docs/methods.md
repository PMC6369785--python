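# Methods

## Character matrices and the missing / inapplicable distinction

A cell is one of: an observed state set (singleton = ordinary
observation, larger = polymorphism), *missing* (`?`, could have been
observed but was not), or *inapplicable* (`-`, cannot logically be
observed).  The distinction is preserved by every reader, writer and
recoding operation.  Inside tree *scoring* both enter as full ambiguity
over the character's observed state set — the classical treatment; the
package's contribution is at the coding layer, and the scoring interface
(one bitmask per cell) would accept a hierarchy-aware scorer without
change.

## Contingency coding

A dependency graph holds edges (controller character, licensing state
set, dependent character); a dependent has at most one controller and the
graph is acyclic.  `recode_contingent` walks characters
controllers-first: a controller observed in a state disjoint from the
licensing set makes the dependent inapplicable; a *missing* controller
makes the dependent missing (the structure's presence is unobserved, not
ruled out); an inapplicable controller cascades inapplicability down
chains.  The operation is idempotent.  `recode_flat` inverts it by
scoring inapplicable dependents as a designated state (default `'0'`,
absent), the historical convention whose implicit weighting contingency
coding removes.

**Elimination statistic.**  For each taxon, `n_flat_codable` counts cells
bearing a state set under flat coding; `n_eliminated` counts those that
contingency coding turns inapplicable; the taxon's fraction is their
ratio and group values are unweighted means over member taxa, reported
rounded to whole percent.  This cell-based definition is the most direct
reading of "information available to coding"; a character-based variant
would differ only for polymorphic cells.

## Parsimony

Fitch length (unordered states, equal weights) is computed on bitmask
state sets vectorised across characters; trees are kept leaf-rooted and
strictly binary, and the score is invariant to rooting.  The heuristic
search does random-addition-sequence starts followed by
first-improvement branch swapping (NNI, SPR, or TBR; TBR reroots the
pruned subtree on each of its edges before reattachment, so each
bisection's full neighborhood is generated).  After a local optimum is
reached the surrounding equal-length plateau is explored breadth-first so
co-optimal trees are collected (bounded by `max_trees`).  Co-optimal sets
can be disconnected at equal length — replicates are the only way to
reach a separate island, which is why the search-versus-enumeration
checks use 20 replicates on 6–8-taxon problems.  Defaults (100
replicates, TBR, 1000 trees) are desk-scale conventions.  Strict and
majority-rule consensus are built from bipartition counts.

## Ancestral states and synapomorphies

MPR sets come from a unit-cost Sankoff inside/outside pass: a node's MPR
set is the states whose inside + outside cost equals the tree's minimum.
This handles ambiguous (missing/inapplicable/polymorphic) leaves exactly,
where the classical Fitch up-pass needs special cases.  ACCTRAN uses the
downpass-set rule (keep the parent's state when it is in the child's
downpass set), placing changes rootward; DELTRAN walks preorder keeping
the parent's state whenever consistent with minimality under the Sankoff
subtree costs, deferring changes tipward.  Both provably realise the
Fitch length; ties break on the smallest state symbol for
reproducibility.  A branch change is *unambiguous* iff the MPR sets at
both its ends are singletons; changes are never reported on terminal
branches of taxa scored missing or inapplicable for that character.

## Bayesian Mk

Likelihoods use Felsenstein pruning with the closed-form Mk transition
matrix, characters grouped by state count, uniform root frequencies.  The
variable-only ascertainment correction divides each character's
likelihood by (1 − P(constant pattern)), matching how morphological
matrices are collected; constant characters cannot be conditioned on
being variable and are skipped under that correction (they are padded to
k = 2 when the correction is off).  Optional among-character rate
variation uses 4 equal-probability discrete-gamma categories (quantile
midpoints).  The sampler is single-chain Metropolis–Hastings per run —
moves: NNI (35%), branch-length multiplier, gamma-shape multiplier —
with an Exp(10) branch-length prior and uniform topology prior;
convergence is judged by the mean absolute split-frequency difference
between two independent runs.  Desk-scale defaults are 200 000
generations sampled every 200 with 25% burn-in.

## Fossilized birth–death tip dating

The tree prior is the serially-sampled birth–death density in the
standard q/p0 parameterisation (speciation λ, extinction μ, fossil
sampling ψ, extant sampling ρ), conditioned on the root age with a
uniform root-age hyperprior; fossils attached by zero-length branches are
treated as sampled ancestors (factor ψ, no speciation term).  At ψ = 0,
ρ = 1 the density reduces analytically to the constant-rate birth–death
form, and the tests verify this against an independently coded closed
form to 1e−8.

The sequence likelihood is strict-clock HKY(+Γ4 optional) by pruning over
compressed site patterns; two partitions (16S-like and COI-like) share
the tree and clock rate but have independent κ, π, α; tips without
sequences (fossils) carry uniform partials, exactly equivalent to pruning
them.  The sampler updates: each internal node age by a uniform slide
inside its (children, parent) window; each fossil tip age by a uniform
slide inside calibration ∩ (0, parent); the clock rate and κ by
multipliers with lognormal priors; optionally λ, μ, ψ by multipliers; and
a joint up/down move (all internal ages × c, rate ÷ c, Jacobian
c^(n−1)).  The joint move is essential: the posterior is a ridge in
(rate × ages), and without it single-parameter moves cross the ridge only
by diffusion, which manifests as biased, over-narrow age intervals.

Node ages are summarised by the posterior median and the shortest
interval containing the nominal mass (HPD).  Strict set-nesting of HPD
intervals across levels can fail for multimodal samples, so the tests
assert width monotonicity and overlap instead, plus nesting on unimodal
samples.

## Synthetic data

The generator emulates the kind of dataset these methods exist for: a
fossil-rich morphological matrix over living and extinct jawless-fish-like
taxa plus a small mitochondrial alignment for the living taxa.

* **Trees**: forward birth–death simulation from a single lineage at the
  origin with Poisson(ψ) fossilisation, ρ-sampling of extant tips, and
  pruning to the reconstructed tree (fossil samples with sampled
  descendants become sampled ancestors).  Rejection conditions on minimum
  tip counts; `exact_taxon_counts` additionally subsamples tips uniformly
  — the same thinning ρ- and ψ-sampling perform — to hit exact targets.
* **Characters**: all characters evolve under Mk at `char_rate`
  (expected changes per Myr); dependents are recoded inapplicable
  wherever the simulated controller state is unlicensed (one- and
  two-level chains only, mirroring presence→detail structure without
  combinatorial explosion); fossil taxa then lose designated
  "soft-tissue" characters with the taphonomic missingness probability.
* **Alignments**: i.i.d. sites under HKY per partition along the time
  tree scaled by the clock rate; only extant tips emit sequences.

Study-scale defaults (seeded, fixed): 40 extant + 12 fossil taxa, 168
binary characters with 35% dependents, soft-tissue missingness 0.6 over
40% of characters, 550 + 650 bp partitions, λ = 0.02, μ = 0.015,
ψ = 0.003, ρ = 0.5 per Myr from a 520 Mya origin, clock rate 0.004
subs/site/Myr — rates of the order inferred for Paleozoic vertebrate
radiations and mitochondrial markers.  What the generator does *not*
emulate: correlated character evolution beyond the dependency structure,
heterotachy, among-lineage rate variation (the data are strict-clock by
construction), selection on sequences, and non-uniform fossil recovery —
so green tests demonstrate the *machinery* is correct under its stated
model, not that the model fits any particular empirical matrix.

## Validation experiment design

* **Search / optimization**: exhaustive enumeration of all unrooted
  topologies (≤8 taxa) and of all internal-state assignments (≤6 taxa)
  serve as oracles for the heuristic search, Fitch lengths, MPR sets and
  both resolutions.
* **Mk recovery**: 500 binary characters simulated on a balanced 8-taxon
  tree with all branches at 0.15 expected changes — an informative
  standard regime (near-saturated branch lengths make topology recovery
  impossible for any method and would test data hardness rather than
  sampler correctness) — then two independent 200k-generation runs;
  checked: consensus equals the generating topology, split-frequency
  difference < 0.05.
* **Clock calibration**: simulation-based calibration.  Per replicate the
  *true* dated tree is drawn from the inference prior itself (a
  prior-only run of the clock sampler on an FBD-simulated 10-tip
  topology, 7 extant + 3 fossils), the clock rate and κs are drawn from
  their priors, calibration windows (4 Myr wide) are placed uniformly
  around the true fossil ages, alignments (600 + 500 bp) are simulated on
  the truth, and full inference runs 1500 sweeps.  Under this design a
  correct implementation's nominal 95% HPD covers the true root age in
  95% of replicates, so observed coverage is a sharp end-to-end test of
  the FBD density, the HKY likelihood and the sampler together.
  (Forward-simulating from a fixed origin and inferring under the
  root-conditioned prior is *mis-specified* — the simulation and
  inference priors differ — and cannot be used to judge calibration.)

## Problem sizes and numerical choices

The committed experiments use 6–10-taxon oracle problems, the 52 × 168
emulated matrix for I/O and recoding, 8 taxa × 500 characters for Mk
recovery, and 40 replicates × 10 tips for clock calibration; these sizes
make every oracle exact and every stochastic check reproducible in
minutes on one core.  Proposal tunings (multiplier windows 0.4–1.0 in
log space) target acceptance rates near 0.4.  Degenerate inputs are
contracts, not silent fixes: empty post-burn-in samples, non-binary trees
in scoring, unrooted input to ancestral reconstruction, calibration rows
without matching tips, and negative ages all raise typed errors.

## Known limitations

Inapplicable cells are treated as missing *inside* tree scoring
(hierarchy-aware scoring algorithms are out of scope by design); the Mk
sampler is single-chain (no Metropolis coupling) and its topology moves
are NNI-only, adequate at the problem sizes used; the clock is strict
(an uncorrelated relaxed clock is not implemented); the FBD density
conditions on the root age rather than on survival; consensus trees are
not scored; and the parsimony search offers no branch-and-bound
optimality guarantee beyond the enumeration oracles.
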