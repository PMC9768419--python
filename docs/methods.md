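# Methods notes

## The STIMS randomization test

**Model.** Mutation appearance in a gene is treated as a counting process;
the observable is the time-stamped (population, generation, gene) record of
mutations detected in a metagenomic time series. For a focal gene set the
statistic is the cumulative count of its mutations up to each sampled
generation, divided by the set's combined length in nucleotides. The null
hypothesis is that the focal set is exchangeable with any equal-cardinality
set of annotated genes: the null distribution is built by resampling such
sets (default 1000 draws) from the full annotation and recomputing the same
statistic, each draw normalized by its own length. Since observed and null
share one mutation stream, genome-wide rate changes in time (e.g. a
hypermutator sweep) and static rate variation along the chromosome cancel;
what remains is the focal set's deficit (purifying selection) or excess
(positive selection) relative to typical genes.

**Test statistic and p-values.** The statistic is the trajectory value at
the final timepoint. The trajectory is plotted whole, with a per-timepoint
2.5th/97.5th-percentile null envelope, but the inference uses the endpoint:
it is the simplest scalar summary of a cumulative curve, and a cumulative
count at the end of the series dominates any earlier point of the same
curve. One-sided p-values use the pseudocount rank estimator
p = (1 + k)/(n_null + 1) with ties counted in the tail, so p is never 0 and
the floor 1/(n_null + 1) yields the "< 0.001" reporting convention at
n_null = 1000. Both tails are always reported. Each population is tested
separately and no multiple-testing correction is applied; the CLI prints a
note when several populations are tested in one call.

**Design choices made where the design was open.**

* Null sets are drawn from *all* annotated genes, focal members included,
  independently per draw. Exclusion would bias the null by construction;
  inclusion costs O(|focal|/genome) and assumes nothing.
* Default timepoints are the sorted unique generations present in the
  population's records, plus 0 — no binning parameter, no information loss.
* All mutation classes count by default; an include-filter on
  `mutation_class` is available because upstream datasets distinguish
  classes (synonymous, missense, ...), and restricting the stream is a
  scientific decision the caller should make explicitly.

**Numerical notes.** Percentiles use linear interpolation (numpy default).
A mutation record dated after the last timepoint is an error rather than a
silent drop, since the endpoint statistic would otherwise quietly ignore
data. Records in genes absent from the annotation are outside the tested
universe and are ignored by the counting engine.

## Flux balance analysis and knockouts

The model container is a plain stoichiometric structure: metabolites,
reactions with bounds (mmol·gDW⁻¹·h⁻¹ by convention), boolean
gene–protein–reaction (GPR) rules, one biomass objective, and a medium
given as exchange-reaction lower-bound overrides. FBA maximizes biomass
flux subject to S·v = 0 and the bounds, solved with scipy's HiGHS linear
programming backend; the LP matrix is assembled once per model and reused
across knockouts, which keeps the many thousands of single-knockout solves
of a Jenga ensemble cheap. Primal feasibility tolerance is 1e-9, dual 1e-6;
fluxes below 1e-9 are reported as exact zeros; an infeasible model has
fitness 0 by convention; an unbounded objective is an error (it indicates a
missing exchange bound, never biology). The objective value is
deterministic across repeated solves; flux vectors may be degenerate and
are not relied upon.

GPR rules are parsed by a small recursive-descent parser (AND/OR,
parentheses, AND binding tighter) that reports malformed input with a
character position, and supports partial evaluation: knocking out genes
rewrites surviving rules over the remaining genes and zeroes the bounds of
reactions whose rules become false. An empty rule means a spontaneous or
orphan reaction that no knockout can disable. A gene is essential when its
single knockout drops growth below `essentiality_fraction` (default 0.01,
i.e. 1% of that genome's own wild-type optimum — the common convention;
configurable) times the wild-type optimum; genes referenced by no rule are
skipped without a solve.

For real growth-medium work the defaults follow a glucose-limited minimal
medium with the vitamin supplied in excess: glucose exchange lower bound
−10, thiamine −1000, oxygen and inorganic exchanges open. These uptake
rates are conventions, not measurements, and are configurable through a
JSON medium file; they are echoed into result provenance.

## Genome Jenga

One game: starting from a viable model, repeatedly shuffle the remaining
genes (seeded) and test them in order by single-gene knockout of the
*current* genome; the first removal accepted under the nearly-neutral rule
— beneficial, or relative defect strictly below s = 1/N_e — is committed,
the fitness baseline moves to the new genome, and the pass restarts with a
fresh shuffle. A complete pass with no commit proves terminality. Default
N_e = 3.3 × 10⁷ (a large serial-transfer experiment; the interesting
regime is s ≈ 0, where only exactly-neutral redundancy can be shed).

* **Baseline = current genome, not the ancestor.** Sequential comparison
  models loss-of-function mutations fixing one at a time; accepted defects
  therefore compound, giving the auditable bound
  final ≥ ancestor × (1 − s)^k after k removals.
* **Re-testing after every commit.** A gene that was not removable earlier
  may become removable (or vice versa) as the network shrinks — epistasis
  is the point of the game — so no knockout fitness is cached across
  commits, and previously rejected genes stay in the pool.
* Genes in no GPR rule have exactly zero fitness effect and are removed on
  first draw; they are kept in the gene list so genome-size distributions
  are meaningful.
* Replicate r of an ensemble uses seed base + r, making ensembles
  reproducible under any scheduling and resumable from per-replicate
  files. An independent terminality audit (rebuild the terminal model from
  scratch, re-test every retained gene) is part of the test suite rather
  than trusted from the loop.

## Ensemble summaries

Presence/absence matrices (replicates × items) are built for retained
genes, essential genes and active reactions; core = all-true columns,
variable = the rest; size distributions are plain histograms — apparent
bi- or multimodality is reported descriptively, not tested. Row ordering
for block-structure display uses complete-linkage hierarchical clustering
on Jaccard distance, chosen for determinism and simplicity; identical rows
come back in replicate-id order.

## What the synthetic generators emulate — and what they do not

`simulate_mutations` draws per-gene Poisson mutation counts with
length-proportional rates (defaults: 500 genes of 0.5–2 kb, wild-type rate
μ = 1e-10 per nucleotide per generation, a 100-fold hypermutator from
generation 5,000, a 50,000-generation series discretized to 500-generation
sampling boundaries). Purifying selection is modeled as rate *thinning* — a
multiplicative factor < 1 on a named set's observed mutations — which is
precisely the signal the endpoint statistic measures. The generator
deliberately omits: allele-frequency trajectories and their conditioning on
detection thresholds, clonal interference, linkage between mutations,
reversion of the mutator, and gene-to-gene rate heterogeneity beyond
length. Passing calibration and power tests on these data therefore show
that the test holds its size and detects thinning under exchangeable
nulls; they do not certify behavior under chromosomal rate structure that
violates exchangeability of gene sets. The `explicit_sets` field lets a
caller inject externally named genes (e.g. a Jenga core set) into the
simulated universe, which is what closes the simulation → test loop.

`generate_toy_model` builds hand-solvable networks: an optional
non-redundant trunk (whose genes are the guaranteed core of any ensemble),
parallel pathways each alone sufficient, isozyme OR-pairs, and generalist
genes OR-ed into one reaction of every pathway. All stoichiometric yields
are 1, so the ancestral optimum equals the substrate uptake bound and every
expected objective is checkable by hand. These toys reproduce the
qualitative phenomena (divergent minimal genomes, increased fragility,
idiosyncratic essentiality) at a scale where exhaustive enumeration of
terminal sets is possible; they do not emulate genome-scale stoichiometry,
cofactor coupling or maintenance costs.

## Problem sizes and statistical tolerances in the test suite

Calibration uses 200 independent replicates (fresh data and focal set per
replicate) at n_null = 1000; the α = 0.05 rejection rate is checked
against the exact binomial 99% interval and p-values against a
Kolmogorov–Smirnov uniformity check. Power monotonicity across thinning
factors 1.0/0.5/0.2 is evaluated at a mutation supply (~14 expected
mutations per 50-gene null set) where all three median p-values sit above
the rank-test resolution 1/(n_null + 1); at higher supplies the two
stronger factors both collapse onto that floor and cannot be ordered —
the 80%-power check at factor 0.2 runs at the higher supply (~56 expected
mutations per null set). Jenga ensembles in tests use 100 games on the
redundant toy; symmetric-outcome frequencies are checked against central
99% binomial intervals.

## Known limitations

* STIMS power depends on the mutation supply; in low-mutation (non-mutator)
  populations a deficit and relaxed selection are hard to distinguish, and
  the test does not attempt to.
* The Jenga acceptance rule is a threshold on deterministic FBA fitness; it
  ignores drift trajectories, beneficial compensation and gain-of-function.
* FBA fitness equates growth yield with fitness and inherits all standard
  FBA assumptions (steady state, no enzyme costs, fixed biomass
  composition).
* BiGG-JSON is the only model format; SBML is out of scope.
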