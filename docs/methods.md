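# Methods

This note documents the models and procedures implemented in `ace`,
the defaults and why they were chosen, the design decisions taken where
several readings were defensible, and what the synthetic-data
generators do and do not emulate.

## Trees and identifiers

Trees are rooted Newick. Internal node labels are read as ancestor
names unless they parse as a number in [0, 100], in which case they are
treated as bipartition supports (the IQ-TREE/FastTree convention);
unnamed internal nodes receive the deterministic name `N<postorder
index>`. These names are the join keys of every event table, so the
same input file always yields the same keys. Branch lengths are
expected substitutions per site and double as the time axis of the
simulators.

## Genome selection

GQS = completeness(%) − 5 × contamination(%). Quality filters are
lineage-specific and inclusive at the printed thresholds: completeness
≥ 90% and contamination ≤ 2% for non-chlamydial records, completeness
≥ 90% and marker redundancy ≤ 1.02 for chlamydial records (completeness
may be given on either the percent or the fraction scale). One
representative per precomputed dereplication cluster is kept by maximal
GQS; exact ties go to the lexicographically smallest genome id, a
deterministic stand-in for a manual choice. Dereplication itself
(ANI-based) is consumed as an input column, not recomputed.

## Compositional χ²-trimming

Per taxon, observed residue counts (gaps and ambiguity codes excluded)
are compared with expectations from the pooled alignment composition by
χ² with df = 19; a taxon is heterogeneous at P ≤ α (default 0.05). The
per-site heterogeneity score is the same statistic applied to a single
column against the global composition; all-gap columns score 0. While
any taxon is significant, the top ⌈step · L₀⌉ sites are removed (step
default 1% of the *original* length L₀ — the most natural reading of
"increments of 1% of alignment sites"), ties broken leftmost, and
global frequencies are recomputed before re-testing. The trace records
per-iteration removals; exhausting the alignment without convergence is
flagged rather than silently accepted.

Note that removing a zero-score site can still change per-taxon
statistics (the per-taxon and per-site statistics condition on
different margins), so no such invariant is claimed; removing all-gap
columns is a true no-op.

## Clustering evaluation

Confusion counts are pairwise over labeled sequences only: a pair
sharing a reference domain and a cluster is a true positive, and so on.
Balanced accuracy is (sensitivity + specificity)/2; an undefined rate
(zero denominator) contributes 0 and sets a degeneracy flag, as do
vacuous cases with no true-positive or true-negative pairs at all.
Sequences with several domains are reduced to the first listed.
Threshold selection is argmax of balanced accuracy with ties going to
the lower (coarser) threshold.

## Ancestral gene content

**Wagner parsimony** (gene-tree-unaware). Copy states 0..M with
M = max(leaf copies) + 1; under linear branch costs optima never exceed
observed maxima by more than one, so the ceiling is exact in practice.
Branch cost for a change d = child − parent is g·max(0, d) +
max(0, −d) with gain penalty g = 1 by default (symmetric unit costs,
the "default costs" of gene-content parsimony tools). Bottom-up Sankoff
recursion, top-down traceback; all ties resolve toward the smaller
ancestral copy number, which makes reconstructions reproducible and
conservative about ancestral content.

**DTL parsimony** (gene-tree-aware). The undated
duplication–transfer–loss dynamic program over (gene node, species
node) pairs: speciation cost 0, duplication δ = 2, transfer τ_c = 3,
loss λ = 1 by default — conventional parsimony weights, configurable.
Transfers may land on any branch neither ancestral nor descendant to
the donor. Binary species trees are required (standard undated-DTL loss
accounting assumes bifurcations); Wagner parsimony covers
multifurcating trees. Unrooted gene trees are rooted at the
minimum-cost edge, ties by lowest edge index. Event ties resolve
speciation < duplication < transfer, then lower species postorder
index. The traceback also reports, per species node, the number of gene
lineages crossing it — the parsimony analogue of a copy frequency — and
losses at every bypassed branch. Transfers are recorded on the
*acceptor* branch, with the (donor, acceptor) route kept separately for
network analysis.

This reconciler is a deliberate parsimony replacement for probabilistic
reconciliation samplers: aggregating one optimal reconciliation per
gene tree over a family's K-tree sample yields event and copy
*frequencies* (occurrences/K) of the same shape as sampler output, and
externally produced frequency tables can be ingested directly, so all
downstream computations (quantization, presence, proteome sizes,
rates, highways) apply unchanged to either source.

**Singletons** enter as one origination with copy frequency 1 at their
genome's leaf. **Presence** is copy frequency C ≥ τ with τ = 0.3,
boundary inclusive. **Confident event counts** follow the staircase
quantize(f) = 0 if f < τ else ⌊f − τ + ε⌋ + 1 with ε = 1e−9 guarding
the boundary arithmetic (1.3 − 0.3 and friends) against float
rounding. **Proteome size** is the sum of *raw* copy frequencies at a
node — quantization would underestimate transfers and losses — with an
optional per-genome completeness divisor (C/completeness) to compensate
for draft genomes. **Complex presence** is the subunit-majority rule:
present iff ≥ 50% of subunits are present, boundary inclusive.

## Transfer rates and highways

The transfer rate of a branch is the summed raw transfer frequency
divided by the branch length (transfers per substitution per site);
zero-length branches are excluded with a warning. Group comparisons
use the Wilcoxon rank-sum test, exact for combined n ≤ 20 without
ties, normal approximation with tie correction otherwise.

Highways: pairs eligible for testing are unordered, non-nested and
overlapping in depth from the root — nested pairs share families
trivially and lineages from disjoint eras cannot exchange genes, so
either would distort the null (including never-coexisting pairs
measurably deflates the median and makes every other test
anti-conservative). Per pair, n counts families present at both nodes
and x those with a confident transfer between them in either direction;
transfers only count toward x for families in n, which keeps x ≤ n by
construction. The null probability p₀ is the *median transferred
fraction* x/n over eligible pairs — a fraction, not a count, being the
only choice dimensionally compatible with a binomial proportion. Each
pair is tested one-sided, P(X ≥ x) for X ~ Binomial(n, p₀), by exact
tail summation; Benjamini–Hochberg q ≤ α flags highways. Directed
counts are retained for the exported network.

## HGT donor classification

Homolog trees carry per-tip query flags and a three-level taxonomy
(domain, superphylum, phylum) in the tip labels. The workflow:

1. **Coverage filter**: keep sequences covering ≥ 40% of the trimmed
   alignment (inclusive).
2. **Long-branch pruning**: remove tips with terminal length strictly
   above Q3 + 1.5·IQR (quartiles by linear interpolation), one pass.
3. **Query clades**: up to three disjoint clades with ≥ 25% and ≥ 2
   query tips, ranked by query count, then smaller size, then postorder.
4. **Subtree selection**: walk at least three parents up from the
   clade, accept the first node with 150–400 additional tips and
   support ≥ 0.7; oversize candidates are thinned by discarding
   well-supported distant clades (≥ 5 tips, ≥ 6 edges from the common
   ancestor with the query clade); fall back to the whole tree when it
   holds fewer than 150 extra tips.
5. **Outgroup sampling**: 20–50 tips drawn uniformly without
   replacement from the clade sister to the subtree, escalating to the
   next subtending clade while fewer than 20 candidates are available;
   deterministic given the seed.
6. **Donor call**: the clade sister to the (monophyletic) query tips
   needs support ≥ 80; its tips are pooled with the next subtending
   ("nested") clade, and the *most specific* rank at which ≥ level
   (75/90/100%) of the pooled, labeled tips share one label is
   reported. Tips lacking a rank label leave that rank's denominator.
   No non-query homologs at all → de-novo candidate; every other
   failure mode → unresolved.

Tree re-inference between stages is external; the module operates on
the trees it is given.

## Synthetic data: what it emulates, and what it does not

**Species trees** are forward birth–death simulations (defaults birth
1.0, death 0.2) conditioned on the requested number of surviving
leaves; growth stops at the nth lineage and pendant branches extend to
a uniform point before the next scheduled event. Branch lengths are
scaled to a mean root-to-tip depth of 1.0 so that event rates per unit
branch length read as rates per root-to-tip unit.

**Gene families** originate on a branch chosen proportionally to
branch length — including a stem above the root (default length 1.0)
so that a realistic share of families is ancestral to the whole clade —
and evolve by per-lineage Poisson duplication/transfer/loss (defaults
0.03/0.03/0.06 per unit length, a low-rate regime where most families
are vertically inherited, matching the dominance of vertical descent in
real gene-content data). Transfers land uniformly on a branch
overlapping the donor in depth from the root, the undated proxy for
coexistence. The emitted gene trees inherit species-tree path lengths
(no rate variation), the event log records every event with its branch,
and leaf copy numbers replay exactly from the log. Recovery
experiments (10 datasets, 50 genomes, 200 families) score a branch as
recovered when each quantized O/D/T/L sum is within ±1 of the log.
These conditions do not emulate gene-tree estimation error — the
reconciler sees the true gene trees — so passing shows the
reconciliation and aggregation machinery is correct, not that inference
is robust to tree error.

**Biased alignments** have a compositionally *balanced* background:
sites are generated in blocks of 20 columns, each a randomized Latin
square over the amino-acid alphabet, so every taxon row (and, with
≥ 20 taxa, every column) carries each residue equally often and the
composition test has nothing to reject. Planted sites redraw the
biased taxa's residues from a shifted distribution (first five
residues boosted 6-fold). This design was chosen over i.i.d.-site
backgrounds deliberately: with independent sites the per-taxon χ² test
fires at its nominal 5% per taxon — on a 20-taxon alignment *some*
taxon is "significant" in most replicates, and planted sites from a
single biased taxon are not separable by a column-level score. The
balanced background makes the planted deviation the only compositional
signal, which is what a trimming fixture must isolate. The cost is
realism: real alignments have skewed residue usage, conserved columns
and noise; passing these tests demonstrates that the trimming loop
tracks planted heterogeneity and leaves clean data alone, not that the
test is calibrated on real alignments (on real data the χ² composition
test is known to be liberal).

**Highways** use a route-uniform transfer process: every eligible
branch pair fires per family with the same base probability (default
0.04), the planted route with fold × base — a direct realization of
"one pair at a fold-changed rate, all others at base rate", and the
regime in which a common-p₀ binomial null is exact. The preset keeps
all families ancestral with no loss or duplication; under the
per-lineage length-proportional transfer process of the family
simulator, long-branch pairs genuinely exchange more genes and the
median-based binomial null misfires — a limitation inherited by any
analysis of this type, which the fixture intentionally factors out.
Operating characteristics (20 seeds): planted 10× route flagged in
20/20, null runs flag any pair in ≤ 2/20.

**Donor trees** nest a pure query clade inside sister and nested
clades whose pooled tips carry the donor phylum's taxonomy at an exact
purity; contaminant tips draw lineages from a different domain so no
rank reaches consensus above the purity (purity 0.8 therefore resolves
at the 75% level and is unresolved at 90%). All supports are 95;
distractor clades carry mixed labels.

## Numerical choices

χ² p-values from the survival function with df = 19 regardless of the
observed residue support (fixed-class convention). Binomial tails by
exact summation (error ≲ 1e−13 vs. enumeration for n ≤ 12). DP cost
comparisons use an absolute tolerance of 1e−9; both reconcilers were
verified against exhaustive enumeration oracles (100 random instances
each, exact agreement). Degenerate inputs fail loudly: empty clusters
and profiles, all-gap taxa, quantized tables where raw frequencies are
required, unmapped gene-tree leaves, nested or non-coexisting planted
pairs.

## Known limitations

* The DTL reconciler returns one optimal reconciliation per gene tree;
  within-tree optimum multiplicity is collapsed by the deterministic
  tie-break rather than averaged.
* Copy frequencies at duplication-rich nodes count lineage crossings,
  which can differ from an expectation under a probabilistic model.
* The highway test inherits the original method's assumption of a
  common null probability across pairs; on strongly
  length-heterogeneous trees with length-proportional transfer this
  null is miscalibrated (see above).
* Proteome-size completeness correction is a per-leaf divisor, an
  approximation of model-based extinction-probability corrections.
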