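# Methods

`soilbiome` re-implements, as a tested and reusable pipeline, a
meta-analysis workflow for species-level soil bacteriome count surveys:
samples from several groups (countries, in the motivating application)
are compared in terms of alpha diversity, differential taxonomic
richness, group-enriched species, interspecific co-occurrence structure,
and biogeochemical gene-set capacity.  This note records the models, the
parameters that matter, the numerical conventions, and the places where
the design was genuinely open.

## Input model

The pipeline consumes a species × sample matrix of non-negative integer
read counts, a sample table with a group label (plus optional soil class
and pH, which are annotations only — nothing downstream is gated on
them), a five-rank taxonomy (phylum → genus; ranks below phylum may be
missing), and per-species gene repertoires given as sets of gene symbols
(matched case-insensitively).  OTU-level tables are first collapsed to
species by summation (`aggregate_otus`), which preserves per-sample
totals.

## GMPR normalization

Environmental count matrices are zero-inflated, so a DESeq-style
geometric-mean size factor (which conditions on taxa present in *every*
sample) is unusable.  GMPR (geometric mean of pairwise ratios) instead
computes, for each ordered sample pair (i, j), the median count ratio
over the taxa present in both, and takes

        s_i = exp( mean_j log r_ij ),

the geometric mean over all valid partners j — including the trivial
self-ratio r_ii = 1, as in the reference implementation.  Including the
self term is not cosmetic: it is what makes the factors exactly
scale-equivariant (multiplying one sample's counts by c multiplies its
relative factor by exactly c) and makes proportional samples recover
their true scales.  Conventions fixed here: pair medians interpolate
linearly on the *ratio* scale (type-7 quantiles); pairs sharing fewer
than `min_shared` (default 1) taxa are dropped from the mean; the final
vector is rescaled to geometric mean 1 so normalized totals are
comparable across runs; a sample sharing no taxa with any other sample is
a hard error.  The implementation is checked against a literal
double-loop oracle on random matrices.

## Alpha diversity

Chao1 (bias-corrected form, S_obs + F1(F1−1)/(2(F2+1)), via scikit-bio)
and Shannon's index (natural log) are computed on **raw** counts —
richness estimators need integer frequencies, and within-sample
proportions are unaffected by per-sample scaling.  log10(Chao1) and
Shannon are compared between groups by one-way ANOVA with Tukey HSD
post-hoc pairs.  Tukey adjusted p-values come from the exact studentized
range distribution (`scipy.stats.studentized_range`); the common table
interpolation (`psturng`) is clipped at 0.001 and cannot resolve the
stringent 0.001 threshold this analysis uses.  The compact letter
display assigns one letter per maximal clique of the non-significance
graph, which guarantees the defining property: two groups share a letter
iff their adjusted p ≥ α.  Any valid lettering consistent with the
pairwise matrix is acceptable; tests assert the iff-property, not a
particular string.

## Differential taxonomic richness

The richness of a parent taxon (family or genus) in a sample is the
number of distinct child taxa (species or genera) observed (nonzero)
there.  Richness profiles are treated compositionally:

1. a full binary tree over the parent taxa is built by average-linkage
   hierarchical clustering of Euclidean distances between the taxa's
   proportion profiles (richness divided by the per-sample column
   total).  The tree construction is a pluggable choice; average linkage
   on proportion profiles is the convention adopted here.
2. each internal node with left/right leaf sets R, S defines an
   isometric log-ratio balance
   y = sqrt(|R||S|/(|R|+|S|)) · ln( g(x_R)/g(x_S) ),
   where g is the geometric mean of richness values shifted by a
   pseudocount (default 0.5; richness matrices contain zeros, and the
   closure constant cancels inside the ratio).  The balance rows form an
   orthonormal contrast basis (verified numerically).
3. each balance is regressed on the group labels by OLS; the F-test of
   the group effect is exactly the one-way ANOVA F.  Constant balances
   are flagged degenerate and reported with p = 1.
4. a taxon is called **differential** when the balance at its smallest
   enclosing internal node — the node separating it from its sibling
   set — has p below α (default 1e−6).  Attributing a shift to every
   ancestor node would over-flag; the smallest enclosing node is the
   contrast that isolates the taxon.

Two points were genuinely open.  The source analysis phrase "significant
in all groups" is operationalized as a single global F-test across all
group labels, because a balance shift is a property of the full
contrast, not of one group.  And the test is run per-sample (OLS needs
replication) rather than on per-group aggregates.

## Species enrichment

Observed abundance O[s, g] is the GMPR-normalized abundance of species s
summed over the samples of group g.  Expected abundance is the usual
contingency margin product E = rowtot × coltot / grand, and each species
row is tested by a goodness-of-fit chi-squared with df = n_groups − 1,
adjusted across species (Benjamini–Hochberg by default, Bonferroni by
config).  Pearson residuals default to the standardized form
(O − E)/√E; a raw O − E mode is selectable.  A species is **enriched in
a group** iff its adjusted p < α (default 1e−6) *and* its residual in
that group strictly exceeds Q3 + m·IQR (fence multiplier m = 1.0, not
Tukey's 1.5 — the definition used here is literally "third quartile plus
interquartile range") computed over a reference population, by default
the residuals of all significant species within that group.  Quantiles
are linear-interpolation (type-7).

Two caveats are inherent to this published procedure and are stated
rather than patched.  First, the chi-squared test treats group sums of
normalized counts as multinomial draws; its p-values are calibrated only
under near-Poisson per-sample noise.  Under strong overdispersion or
heavy zero-inflation of abundant taxa the statistic inflates roughly by
the Fano factor and the significance stage loses selectivity — the
outlier fence then becomes the only filter and false discoveries rise.
The null-calibration check therefore runs under the test's own sampling
assumptions (high negative-binomial size, no zero inflation).  Second,
because the fence reference is the significant species within a group,
the procedure can flag at most roughly the upper quartile of that
population; enrichment calling presupposes that significant species are
a minority and truly enriched ones a minority of those.

## Association networks

Per sample, the top-k (default 20) most abundant species form a
transaction; within-sample ranking is invariant to per-sample scaling,
so raw counts suffice.  Ties at rank k keep the lexicographically
smaller id; samples with fewer than k species present contribute all of
them.  Pairwise association rules are mined apriori-style per group:
support(a,b) is the fraction of the group's transactions containing both
species, confidence is the larger of the two directional confidences,
and a pair is kept iff support > 0.3 and confidence > 0.7, both strict.
(The pruning step — only items whose singleton support clears the
threshold enter pair counting — is exact here, since a pair's support
bounds its members'.)  The rule graph is undirected.

The graph is reduced to a **minimum spanning forest** with edge weight
1 − support (stronger co-occurrence ⇒ shorter edge; confidence-based
weights available), using Kruskal's algorithm with a fully deterministic
tie order (weight, then lexicographic endpoint pair).  This matters in
practice: transaction data produce many exactly tied supports, and an
implementation-defined tie order makes community recovery
irreproducible.

Communities are found by Girvan–Newman on the forest: repeatedly remove
the edge of highest edge betweenness (ties: lexicographically smallest
pair) and return, among the partition sequence, the earliest partition
maximizing Newman–Girvan modularity Q = Σ_c (e_cc − a_c²) evaluated on
the intact forest.  On a two-node forest this correctly prefers one
community (Q = 0) over two singletons (Q < 0).  Node degree and
betweenness are reported on the forest (the graph the communities live
on); the pre-reduction rule graph is serialized for inspection.  Per
community of ≥ 2 nodes, the **hub** is the node of maximal degree (ties:
higher betweenness, then lexicographic id); **semi-hubs** are non-hub
internal nodes (betweenness > 0, i.e. non-leaves); everything else is a
member.  The semi-hub rule is a documented reconciliation: the verbal
definition ("connected to more than 2 members") conflicts with a
reported semi-hub of degree 2, and "internal non-leaf" covers both.

## Functional profiling

A pathway step is a conjunction of requirement groups; each group is a
set of alternative gene symbols satisfied by at least one member
("any"), or an operon-like set requiring all members ("all").  The
built-in registry transcribes the N/S/C/P transformations of the soil
analysis — nitrogenase nifD/nifK/nifH with vanadium (vnf) alternatives,
assimilatory and dissimilatory nitrate/nitrite reduction (nasAB/narB,
nirA; narGHI; nirBD/nrfAH as position-wise alternative groups),
denitrification (nirS/nirK → norBC → nosZ), sulfate reduction (cys
genes; sat, aprAB, dsrAB), the SOX system (soxAX plus soxB/C/D),
carbohydrate and aromatic-compound utilisation, dct transporters, the
Pho regulon, pstSCAB, phosphatases and the C-P lyase phn operon — and is
editable via JSON round-trip.  Since the source describes no formal
semantics, AND-of-OR with an "all-of" flag is the documented
interpretation; OR between multi-gene operons (nirBD vs nrfAH) is
approximated by position-wise alternative groups.

A community **completes** a step when the pooled union of its members'
gene sets satisfies every group; a **bridging** species is one whose
removal breaks some group's pooled satisfaction (equivalently, the
articulation species of the cover — verified against leave-one-out brute
force).  Heat-map counts report, per (gene, phylum, group), the number
of flagged species carrying the gene; species absent from the gene table
count as lacking all genes.  Functional abundance comparison sums, per
sample, the normalized abundance of the enriched species carrying a
gene, and tests between-group differences by one-way ANOVA at α = 0.001.

## Synthetic data and what the tests show

The generator plants four independently recoverable signal classes in a
4-group design, drawing everything from one seeded stream in documented
order (species effects → size factors → block activations → counts →
dropout):

* counts are negative-binomial with per-species lognormal base
  abundances, per-sample lognormal size factors, and independent
  zero-inflation dropout;
* **enriched species** multiply their group mean by a fold factor;
* **co-occurrence blocks** are species sets that, with per-sample
  activation probability, have their means boosted to an absolute level
  high enough to enter the sample's top-k ranks together (activated
  cells are exempt from dropout — a planted bloom dominates its sample
  by construction);
* a **richness-shift family** is made rare at baseline (mean scaled
  ×0.02 ⇒ frequently absent) and folded up in one group (⇒ nearly always
  detected there), shifting observed child-taxon richness;
* **gene repertoires** are assigned to chosen species from the pathway
  registry's vocabulary.

The `default` fixture (4 × 30 samples, 300 species) uses baseline mean
30, NB size 30, zero inflation 0.1, effect σ 0.8, size-factor σ 0.3,
block boost 600, planted folds 50 (enrichment) and 30 (family), with the
planted species' base effects pinned to 1.0, and places each signal
class in its own group pair (blocks in G1/G2, enrichment folds in G3/G4,
the shifted family in G4).  These are deliberate study conditions, not
neutral draws: near-Poisson noise keeps the chi-squared stage within its
distributional assumptions; the block boost is large enough to force
top-20 membership yet small enough (≈ one third of a sample's reads when
two blocks co-activate) not to distort the margin expectation for
unrelated species; pinning base effects decouples the planted signal
from the lognormal abundance lottery.  Passing recovery tests therefore
show that the pipeline recovers *cleanly planted* structure under the
methods' assumptions.  They do not show robustness to real data's strong
overdispersion, abundance-dependent dropout, compositional coupling
between groups, or phylogenetically correlated gene content — the
generator deliberately models none of these.

Recovery is scored against the recorded truth: enrichment sensitivity
over the fold-planted (species, group) pairs and false-discovery
proportion against the union of all planted pairs (block and
family species genuinely have elevated group abundance, so calling them
is correct, not an error); block recovery as the pairwise Rand index of
community assignments restricted to block species; family recovery as
the flagged-taxon hit rate; the functional effect as the ANOVA detection
rate.  Null calibration uses no-effect simulations: the fraction of
species passing adjusted p < 0.05, uniformity (Kolmogorov–Smirnov) of
balance-test p-values under label permutation, and the functional
ANOVA's false-positive rate at α = 0.001.

With two blocks independently activated at 0.9 in the same group, both
blocks activate together in ≈ 81 % of samples; in an occasional
replicate the two activation patterns (nearly) coincide and the
transactions genuinely contain a single co-occurrence module, which
Girvan–Newman then reports as one community.  The Rand criterion is met
in the mean over seeds; per-replicate dips are expected behavior, not
failures of the community search.

## Numerical conventions and degenerate inputs

Quantiles and medians: linear interpolation (type-7) throughout.  Strict
inequalities at every published threshold ("higher than 0.3/0.7",
p < α, residual > fence).  Constant data: ANOVA on fully constant values
reports F = 0, p = 1; constant balances are degenerate with p = 1; an
all-equal residual population has IQR 0 and flags nothing (strict
exceedance).  All-zero samples are errors for diversity and
normalization; all-zero species rows are retained but excluded from
testing with a log entry.  Determinism: given inputs, config and seed,
every stage is deterministic including row ordering, and `run-all`
produces byte-identical output trees across repeated runs.

## Problem sizes used in the checks

The shipped verification suite runs the full pipeline over 20 fresh
replicates of the default fixture (4 × 30 samples, 300 species), single
null simulations of 200 species for enrichment calibration, and 500
label permutations for the balance and functional null checks; oracle
comparisons use 100 random rule instances (≤ 15 items × 50
transactions), exhaustive spanning forests on ≤ 6 nodes, path counting
on ≤ 12-node trees, and 10 × 8 matrices for GMPR.  These sizes keep the
whole suite under a minute on one CPU while leaving each statistical
criterion with comfortable Monte-Carlo margins.

## Known limitations

* The chi-squared enrichment stage is anti-conservative under real
  microbiome overdispersion (see above); treat its p-values as a ranking
  device coupled to the outlier fence, not as calibrated error rates.
* The balance tree is a clustering of observed profiles, not a
  phylogeny; different tree choices change which contrast a taxon's
  shift loads on.
* Pathway completeness is a set-cover statement about annotated gene
  presence; it says nothing about expression, regulation or flux.
* Rule mining is restricted to pairs (the network is built from pairwise
  edges); higher-order itemsets are out of scope.
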