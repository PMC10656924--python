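# Methods

This note documents the models and procedures implemented in `microsucc`,
the synthetic experiment they are validated against, and the numerical
choices made where the design was genuinely open. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Study design and data model

The unit of analysis is a recolonization experiment: three source
communities (inocula **bL**, **bJ**, **bA**) applied to two substrates —
live, germfree host polyps and inert silicone tubes — and sampled at 2, 7,
14 and 28 days post recolonization (dpr) with replicates, plus one sample
per inoculum. A `CommunityTable` holds an integer samples × ASV count
matrix and per-sample metadata (substrate, inoculum, timepoint,
replicate). Counts must be integers at the I/O layer; relative abundances
are always computed explicitly downstream so the provenance of
normalisation is a single line of code. Inoculum samples describe the
shared source communities; substrate subsetting keeps or drops them
explicitly (`keep_inoculum`), never implicitly.

## Community statistics

Distances are computed on relative abundances without rarefaction (a
`--rarefy`-style preprocessing could be layered on, but the default is a
stated, reproducible transform). Bray–Curtis is
1 − 2Σmin(x,y)/(Σx+Σy); the abundance-weighted Jaccard is derived from it
as 2d/(1+d) (the vegan convention); binary Jaccard operates on
presence/absence; the Jensen–Shannon distance is the square root of the
base-2 divergence. PCoA is classical metric scaling (double-centre
−½JD²J, eigendecompose); negative eigenvalues from non-Euclidean input
are dropped and proportions are reported relative to the positive
eigenvalue total.

PERMANOVA and ANOSIM are one-way by design: the two experimental factors
(dpr, inoculum) are tested in separate one-way runs per substrate. The
permutation scheme shuffles whole-sample labels;
p = (1 + #{F\_perm ≥ F\_obs})/(1 + N) at N = 999 by default, so the
smallest attainable p is 0.001. Passing `n_permutations="exhaustive"`
enumerates every distinct label assignment (multiset permutations) and
returns the exact tail fraction — this mode backs the oracle-equivalence
tests. ANOSIM uses midranks for ties and the divisor n(n−1)/4, which is
the normalisation under which perfectly separated groups give R = 1 and
R ∈ [−1, 1] holds for all group sizes. The Kruskal–Wallis H applies the
standard tie correction and a χ²(k−1) tail. Benjamini–Hochberg is the
step-up procedure with monotonicity enforcement. Chao1 is the
bias-corrected form S_obs + f₁(f₁−1)/(2(f₂+1)), which is finite when no
doubletons exist.

## Succession analysis

The core filter retains an ASV iff there is at least one recolonization
timepoint at which its relative abundance is ≥ `min_abund` (default
5×10⁻⁵, i.e. 0.005 %) in **every** sample of that timepoint, within one
substrate. "Constant detection" is deliberately read as a per-sample
abundance floor, not mere nonzero presence; the floor is the detection
limit of the assay. The filter is monotone in the threshold.

Scaling follows the heatmap layout: column blocks are the inoculum samples
plus one block per treatment (inoculum source), each spanning all
timepoints and replicates; within a block each ASV row is divided by its
block maximum (zero rows stay zero). Scaling per treatment preserves each
ASV's temporal profile — scaling per timepoint instead would erase exactly
the signal the classification needs. Row order is average-linkage
hierarchical clustering on Euclidean distances with optimal leaf ordering,
which makes the display order deterministic and input-order independent.

Colonizer classes are a declared, deterministic rule: per ASV, the mean
scaled abundance is computed per timepoint over all recolonization
samples; the class is *early* iff the argmax lies at 2 or 7 dpr (ties
resolve to the earlier timepoint), else *late*. Historical/manual
curation can be expressed through an explicit class-override table, never
by editing the rule. Because scaling removes magnitude, the class is
invariant to multiplying an ASV's trajectory by any positive constant.

## Sequence matching and clustering

Global identity is defined on a Needleman–Wunsch alignment with match +1,
mismatch −1 and affine gaps (open −2, extend −1: a length-L gap costs
−2−(L−1)), as matches / alignment columns, with gap columns in the
denominator and N never counting as a match (N–N scores as a mismatch).
Alignment uses Biopython's `PairwiseAligner` (C implementation) with a
custom substitution matrix; the first traceback is taken, and the test
suite verifies the score against an exhaustive DP reference and the
(matches, columns) pair against the reference's set of score-optimal
alignments.

Clustering is cd-hit-style greedy incremental assignment: sequences are
visited by decreasing length (ties by id), each joins the first-founded
cluster whose representative it matches at ≥ 0.97 identity, else founds a
new cluster. The declared visit order makes the result independent of
input file order. Genomes are assigned to *every* cluster whose
representative they match at the threshold (the mapping is deliberately
not forced to be unique); unmatched genomes are reported, not dropped.
Word-filter heuristics of the original cd-hit are not reproduced, so
memberships can differ from cd-hit's at boundary identities near the
threshold.

## Pathway projection

Cluster abundances are sums of member-ASV relative abundances (row sums
preserved). A cluster's pathway complement is the **union** over its
assigned genomes — the projection sums the abundance of all organisms
*predicted to possess* a pathway, and union is the faithful reading of
that at cluster resolution; a strict-majority consensus mode is available.
The relative cumulative pathway abundance is A[p,s] = Σ over clusters
carrying p of cluster abundance, so A is linear in the abundance vector
and monotone under adding genomes. Clusters with no matched genome
contribute to no pathway; their summed abundance is reported per sample as
1 − coverage and never silently renormalised, so all pathway abundances
are fractions of the *whole* community.

## Feature selection

Samples at 2 and 7 dpr are labelled early, 14 and 28 dpr late; inoculum
samples are excluded. One Boruta repeat: each iteration appends
value-permuted shadow copies of **all** features, fits a random forest
(500 trees by default), and scores a *hit* for every undecided real
feature whose impurity importance exceeds the maximum shadow importance.
Keeping the full shadow pool at every iteration is load-bearing: the
shadow maximum is then the maximum of m fresh null importances, the same
law the best *chance* association in the real features was drawn from, so
a fixed chance association wins only about half its races and is never
confirmed, while a genuine association wins nearly all of them. Hits
accumulate and one-sided binomial tests at level α/m (Bonferroni over the
feature family, α = 0.01, as in the reference Boruta implementation)
confirm or reject; leftovers at `max_iter` stay tentative.

Selection is repeated (default 10 repeats) with seeds drawn from one
master seed; the **consistent set** is the intersection of confirmed sets.
Reported importances are the forest's impurity importances normalised per
repeat to max 1 and averaged; a leave-one-out permutation importance is
identically zero whenever confirmed features are mutually redundant (any
one can be dropped without accuracy loss), which would make every
downstream threshold degenerate, so the split-based measure is the
informative choice here. Subsystem scores sum the importances of
confirmed pathways per subsystem and retain scores ≥ 0.5 — with the
per-repeat max-1 normalisation that threshold means "half the top
pathway's importance". Fold changes are log2((mean_late + ε)/(mean_early
+ ε)) with ε = 10⁻⁶, so early-enriched pathways are negative. CV accuracy
is pooled stratified k-fold (k = 5) with a fresh forest per fold,
restricted to the consistent set.

## The synthetic experiment

The generator's defaults are the study conditions: 3 inocula × 4
timepoints × 5 replicates × 2 substrates + 3 inoculum samples, 80 taxa,
100 pathways, sequencing depth 20 000. Counts are Dirichlet-multinomial:
per sample the expected composition is perturbed by a Dirichlet draw with
concentration 200 (the replicate-level overdispersion; `None` disables
it; no dispersion estimate is available from real data, so this is a
fixture choice) and then multinomially sampled.

Planted structure:

* **Host reset vs inoculum persistence.** On polyps every taxon follows
  its class trajectory regardless of inoculum — class time weights
  (2, 7, 14, 28 dpr) are (6, 4, 1.5, 1) for early taxa, (1, 1.5, 4, 6)
  for late, flat 0.6 for inoculum-specific ones, giving the early class
  ~6× the per-taxon weight of the late class at 2 dpr and the inverse at
  28 dpr. On tubes the inoculum pool profile persists unchanged over
  time. This is what makes the substrate R² contrast reproducible.
* **Weight-matched early/late pairs.** 40 % of taxa are early, 40 % late,
  20 % inoculum-specific. The late class reuses the early class's
  lognormal(σ = 0.5) weight multiset, rank-paired, and genome presence
  (90 % of taxa) is decided per pair. Neutral pathways are carried by
  both members of a pair or neither (probability `base_p` = 0.3 per
  pair), plus independently by inoculum-specific taxa. Under the
  symmetric class trajectories this makes a neutral pathway's expected
  cumulative abundance *exactly* equal in early and late samples, so
  planted neutrality is the realized truth. A naive independent-Bernoulli
  draw instead leaves every neutral pathway with a real, deterministic
  stage signal from random carrier imbalance (carried-share difference
  s.d. ≈ 0.07 at 40 taxa, far above replicate noise) which any sound
  selector then correctly confirms — the benchmark would be measuring the
  generator's leakage, not the selector's error.
* **Associated pathways.** 10 % early-associated and 10 % late-associated
  pathways are drawn independently Bernoulli with the matching class
  enriched to base_p + e·(1 − base_p), where the effect size e (default
  0.6) is the fraction of the headroom above base_p (e = 1 means certain
  presence in the matching class). Early/late-associated pathways are
  mapped to carbohydrate/chitin-degradation and nitrogen/sulfur-cycle
  subsystems respectively, neutrals to six other subsystems.
* **Sequence families.** One 16S family per taxon: family ancestors are a
  common root mutated at per-site rate 1 − between_identity; members
  mutate their ancestor at 1 − within_identity. Experiment sequences use
  length 400 with within-family rate 0.005 and between-family identity
  0.90, placing ASV–genome identities (~0.99) safely above and
  between-family identities (~0.8) safely below the 0.97 threshold; the
  standalone `generate_sequences` defaults to length 1000 at
  within 0.99 / between 0.90 for clustering benchmarks.

What the generator does **not** emulate: sequencing error and chimeras,
taxon invasions or extinctions mid-course, phylogenetic correlation
between pathway content and sequence similarity, compositional zeros from
undersampling rare taxa, and batch effects. Passing benchmarks therefore
demonstrate correctness and calibration of the algorithms under the
declared model, not performance guarantees on real amplicon data.

## Calibration and recovery benchmarks

`microsucc.benchmarks` (used by `tests/test_acceptance.py` and
`scripts/acceptance.py`) measures: PERMANOVA type-I error at α = 0.05
over 1000 exchangeable simulations (two groups of 10, Euclidean distances
on trivariate normals, 199 permutations); the fraction of 20
label-permuted trials with an empty Boruta consistent set (n = 60
samples, 100 pathways, 3 repeats, 150 trees, 25 iterations — repeat count
and forest size scaled down from the defaults for runtime, which only
makes the emptiness check stricter, since the intersection over more
repeats can never grow); colonizer-class and pathway-association recovery
on the default experiment (selection with 3 repeats, 150 trees, 30
iterations); planted-cluster recovery as the median adjusted Rand index
over three draws of 6 families × 3 members at within 0.99 / between 0.90,
length 1000; and the per-substrate PERMANOVA R² contrast.

## Known limitations

* Exhaustive permutation enumeration is only feasible for n ≲ 8.
* The greedy clustering is quadratic in the number of representatives ×
  sequences; for thousands of long sequences a k-mer prefilter would be
  needed (deliberately out of scope — exact DP is the contract).
* One-way PERMANOVA only; no multi-factor or stratified designs.
* UniFrac-type phylogenetic distances are out of scope (no tree is
  built); the distance set is Bray–Curtis, the two Jaccards and
  Jensen–Shannon.
* Boruta decisions on strongly correlated features are collectively, not
  individually, meaningful: redundant confirmed pathways share importance
  mass.
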