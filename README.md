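# microsucc

Analysis pipeline for **microbiome recolonization succession**: given 16S
amplicon time series from a recolonization experiment — germfree host
animals (sea-anemone polyps) and inert silicone tubes, each inoculated with
one of three source communities (bL/bJ/bA, from larvae, juveniles, adults)
and sampled at 2, 7, 14 and 28 days post recolonization (dpr) — the
package quantifies whether community assembly is host-driven or
inoculum-driven, classifies individual taxa as early or late colonizers,
and projects genome-derived metabolic pathway content onto the community
time series to ask which metabolic capabilities (e.g. chitin degradation
early; nitrite/sulfide oxidation late) track colonization stage.

It is written for microbial ecologists who have an ASV count table with
sample metadata, ASV representative sequences, per-genome 16S sequences and
a genome × pathway presence table (as produced by a metabolic-network tool
such as gapseq), and want the whole chain — ordination statistics,
succession filtering, 97 % OTU clustering, pathway projection, feature
selection — as tested, scriptable functions. A synthetic-data generator
with planted ground truth lets every stage run and be validated without any
external data.

## What it computes

* **Community structure** — Bray–Curtis / Jaccard / binary Jaccard /
  Jensen–Shannon distances; classical PCoA; one-way PERMANOVA with
  pseudo-F = (SS_B/(a−1))/(SS_W/(n−a)) and R² = SS_B/SS_T from the
  Gower-centred squared distance matrix; ANOSIM
  R = (r̄_B − r̄_W)/(n(n−1)/4); pairwise PERMANOVA with
  Benjamini–Hochberg correction; bias-corrected Chao1
  S_obs + f₁(f₁−1)/(2(f₂+1)); tie-corrected Kruskal–Wallis. Permutation
  p-values support exact exhaustive enumeration on small designs.
* **Succession** — core-ASV filter (relative abundance ≥ 0.005 % in
  *every* sample of at least one timepoint), [0, 1] scaling per column
  block (inocula block + one block per treatment), average-linkage row
  ordering with optimal leaf ordering, and early/late colonizer classes
  from the argmax timepoint of per-timepoint mean scaled abundance
  (early ⇔ peak at 2 or 7 dpr).
* **16S ↔ genome matching** — Needleman–Wunsch global identity
  (match +1, mismatch −1, gap open −2, extend −1; identity =
  matches / alignment columns), cd-hit-style greedy clustering at 97 %,
  genome assignment to every matching cluster.
* **Pathway projection** — relative cumulative pathway abundance
  A[p, s] = Σ_{c ∋ p} x_c(s): the summed relative abundance of all
  clusters whose matched genomes encode pathway p, bounded by the
  per-sample *coverage* (community fraction with any matched genome).
* **Feature selection** — repeated Boruta (shadow-feature random forest,
  Bonferroni-adjusted binomial decisions) for pathways separating early
  (2, 7 dpr) from late (14, 28 dpr) samples; the *consistent set* is the
  intersection of confirmed pathways over repeats; stratified k-fold CV
  accuracy; per-subsystem importance scores (impurity importance
  normalised to max 1 per repeat, summed per subsystem, threshold 0.5);
  late-vs-early log2 fold changes.

## Worked example

The numbered drivers under `analysis/` run the full study on the default
synthetic experiment (80 taxa, 100 pathways, 3 inocula × 4 timepoints ×
5 replicates × 2 substrates + 3 inoculum samples):

```sh
python analysis/01_simulate.py
python analysis/02_community_structure.py
...
python analysis/06_feature_selection.py
```

`02_community_structure.py` prints the central substrate contrast:

```
substrate   factor  pseudo_f     r2      p  anosim_r  anosim_p
    polyp      dpr   33.1769 0.6399 0.0010    0.8018    0.0010
    polyp inoculum    0.3660 0.0127 0.9610   -0.0274    0.8900
     tube      dpr    0.2304 0.0122 1.0000   -0.0618    0.9990
     tube inoculum   60.6440 0.6803 0.0010    1.0000    0.0010
```

On the host, time since recolonization explains ~64 % of community
variance and the inoculum essentially none — the host resets whatever
community it receives onto one successional track. On the inert tube the
ranking flips: the inoculum signature persists (R² = 0.68) and time adds
nothing. `03_succession.py` then retains 71/80 ASVs through the core
filter and classifies them into 36 early and 35 late colonizers (100 %
agreement with the planted truth), and `05`/`06` show chitin-degradation
pathway abundance falling from 0.66 to 0.35 of the community between 2 and
28 dpr while nitrogen-cycle pathways rise from 0.34 to 0.61, with the
planted pathway associations recovered at sensitivity 1.00 and zero false
confirmations (CV accuracy 100 %).

The same stages are available as a CLI (`microsucc simulate | validate |
betadiv | succession | cluster | assign | project | select`, or
`microsucc pipeline run --config FILE` for an end-to-end run with a
reproducibility manifest).

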