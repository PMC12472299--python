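# Methods

`litterome` implements the statistical core of a litter-decomposition
microbiome study: substrate-quality metrics, community diversity, null-model
community assembly, co-occurrence networks, and biomarker discovery, plus a
synthetic-data generator that produces communities with known ground truth so
every stage can be validated end to end.

## Synthetic communities

The generator emulates a 6-treatment × 5-replicate microcosm: by default 60
taxa, 30 samples, 5,000 reads per sample — the study-design shape at desk
scale.

* **Phylogeny.** A pure-birth (Yule) tree with unit birth rate, simulated
  until the target tip count.  The process stops exactly at the final
  speciation, which would leave two zero-length terminal branches, so every
  terminal branch is extended by one additional exponential waiting time;
  this keeps the tree ultrametric and all branch lengths positive.
* **Species pool.** Lognormal-ranked relative abundances (σ = 1.5),
  reproducing the strong dominance structure typical of amplicon surveys.
  The rank-sorted abundances are assigned to tree tips in a *random* seeded
  order: laying a sorted abundance curve onto the tip iteration order would
  correlate abundance with the phylogeny and bias even neutral communities
  away from the tip-shuffle null.
* **Local assembly.** Each sample runs 10 Wright–Fisher-style generations of
  multinomial resampling at the sequencing depth; each generation samples
  from a mixture of the current local composition (weight `1 − m`) and the
  regime-specific source pool (weight `m`, the migration rate, default 0.9).
  Migration 1 gives i.i.d. multinomial sampling from the pool; small values
  let drift accumulate.
* **Selection regimes.** Selection tilts the source pool by a Gaussian
  fitness kernel on phylogenetic proximity: `w_i = exp(−s·(d_i/h)²/2)`,
  where `d_i` is the cophenetic distance from taxon *i* to a seeded focal
  optimum taxon and `h` is tree height.  This is the perfectly-conserved-
  trait limit of trait-based habitat filtering.  We initially used a kernel
  on a Brownian trait simulated along the tree, but at 60 taxa a single
  Brownian realization shows enough convergent similarity across distant
  clades that trait-band selection fails to confine communities
  phylogenetically — moderate selection can even *inflate* βNTI, because
  the rare off-band taxa that differ between samples sit far from the other
  sample's band-concentrated support.  The conserved-trait kernel restores
  the theoretically expected negative βNTI response.  Brownian traits are
  still simulated and reported in the ground truth.  Homogeneous selection
  shares one focal taxon across all groups; variable selection draws one
  per group; dispersal limitation partitions taxa into disjoint per-group
  regional pools.
* **Enzymes and spectra.** Enzyme activities (BG, NAG, LAP, AP, C1, Cx,
  laccase, peroxidase; µmol g⁻¹ h⁻¹) are lognormal with log-sd 0.3 around
  literature-scale means, with per-group multiplicative effect factors
  applied so group arithmetic means scale exactly.  FTIR band areas are
  Dirichlet with default concentration (10, 4, 2, 1) — polysaccharide-
  dominated, as in fresh plant litter.

What the generator does *not* emulate: sequencing error, chimeras, PCR bias,
compositional correlations induced by fixed read depth beyond the simplex
constraint, temporal succession, or realistic taxonomies (lineages are
nested synthetic labels).  Passing tests therefore demonstrate statistical
correctness of the estimators on communities with known assembly processes,
not performance on any particular real dataset.

## Substrate metrics

Mass loss is the percentage reduction from initial dry mass (mass gain is
rejected).  Enzyme stoichiometry uses natural logs: the point
`(x, y) = (ln BG / ln AP, ln BG / ln(NAG+LAP))`, vector length `√(x²+y²)`
(C limitation) and vector angle `degrees(atan2(y, x))` (>45° P limitation,
<45° N limitation).  Activities of exactly 1 make a log denominator zero and
raise a degenerate-input error rather than returning infinities — with real
activity units an exact 1.0 is a measure-zero artifact.  FTIR indices:
Index I = (aromatic C=C + aromatic C–H)/aliphatic C–H, Index II =
(aliphatic C–H + aromatic C=C + aromatic C–H)/polysaccharide C–O; both are
scale-invariant ratios of band areas, and band integration itself is
upstream of this package.

## Diversity

Rarefaction subsamples without replacement (multivariate hypergeometric) to
the minimum sample total by default.  Alpha diversity: Chao1 (classic form,
bias-corrected fallback when no doubletons), ACE (rare cutoff 10), Shannon
in nats, Gini–Simpson `1 − Σp²`; all via scikit-bio's estimators.
Bray–Curtis is computed on relative abundances of rarefied counts (the
"rarefied then relative" reading; both normalizations are exposed).  It is a
semimetric — the triangle inequality is not asserted anywhere — so PCoA may
produce negative eigenvalues; these are reported but their axes are dropped
from the coordinates (no Lingoes/Cailliez correction), which keeps
round-trip tests on Euclidean inputs exact.

PERMANOVA uses Anderson's direct partition of squared distances with the
add-one-smoothed permutation p-value `(1 + #{F* ≥ F})/(1 + n_perm)` and a
vectorized evaluation of all permutations (default 999).  PERMDISP computes
per-sample distances to the group centroid in signed PCoA space
(negative-eigenvalue axes subtract from squared distances) and an ANOVA F on
those distances.  Its permutation scheme re-assigns samples to groups and
recomputes centroids and distances for every permutation: the common
shortcut of shuffling distances around fixed centroids measured
anticonservative in our calibration (type-I ≈ 0.08 at α = 0.05 with groups
of six), while the full re-computation calibrates to ≈ 0.03–0.05.

Calibration problem sizes (package choices): 500 null datasets of 18 samples
× 8 taxa with 199 permutations each for the type-I checks; 36 independent
4-sample datasets (≥ 200 pairs) with 299 nulls for the βNTI self-null check;
100 null datasets of 60 features for the biomarker false-positive check.

## Community assembly

βMNTD is the abundance-weighted mean distance from each taxon to its nearest
neighbour in the other sample, averaged over both directions.  βNTI
standardizes it against 999 tip-shuffle nulls (taxa permuted jointly across
the tips; abundances fixed), the canonical null of the Stegen framework.
Two practical consequences at desk scale are worth knowing:

* A pair of samples with *identical* taxon support has βMNTD = 0 under every
  permutation (each taxon's nearest neighbour is itself), so the null has
  zero variance and βNTI is undefined.  Such pairs are reported as NaN /
  `unclassified` and excluded from summaries.  Deeply sequenced small
  communities produce them regularly; real tables with thousands of mostly
  rare taxa almost never do.
* All pairs within one dataset share a single assignment of abundances to
  tips, so their βNTI values share a random dataset-level offset; the
  z-scores are standard-normal only marginally over independent datasets.
  Calibration and regime-recovery checks therefore pool pairs across many
  small independent simulations.

RC_bray follows the occupancy/abundance-weighted Raup–Crick procedure: null
communities preserve each sample's richness and total reads, drawing taxa
with probability proportional to occupancy (Gumbel-max weighted sampling
without replacement), seeding one read per chosen taxon, and distributing
the rest multinomially by regional relative abundance;
`RC = 2·[#(null<obs) + ½·#(null=obs)]/n_null − 1`.  Classification uses
strict thresholds — βNTI < −2 homogeneous selection, > +2 heterogeneous
selection, otherwise RC < −0.95 homogenizing dispersal, RC > +0.95 dispersal
limitation, else drift; boundary values do not exceed.  Summaries default to
within-treatment pairs (all-pairs mode available) and report the stochastic
fraction as dispersal + drift categories.

## Networks

Taxa are filtered to mean relative abundance ≥ 0.01% *and* occupancy ≥ 80%
of samples (both boundaries inclusive).  Spearman correlations (mid-rank
ties, two-sided p) are Benjamini–Hochberg adjusted over all pairs; edges
require |ρ| ≥ 0.8 and q < 0.01.  Constant taxa have undefined correlations;
their pairs are skipped with a warning.  Modules come from seeded Louvain
modularity maximization, relabelled by decreasing size (M1 ≥ M2 ≥ …).
Zi (within-module degree z-score; 0 for zero-variance or singleton modules)
and Pi = 1 − Σ(k_is/k_i)² classify nodes at the classical 2.5/0.62
thresholds; non-peripheral nodes are keystone taxa.

Robustness removes edges or nodes — randomly (averaged over seeded
replicates) or strongest-edge-weight / highest-degree first — and tracks
network efficiency (mean inverse shortest-path length over pairs, unweighted
paths; correlation magnitude is used only for the `edge_strong` removal
order), natural connectivity `ln(Σ e^λ / N)`, and the Molloy–Reed critical
fraction `1 − 1/(⟨k²⟩/⟨k⟩ − 1)` clamped to [0, 1].  Empty-graph measures
are 0 by convention.

Cohesion: pairwise Pearson correlations of relative abundances are corrected
by subtracting a taxon-shuffle null mean (each sample's vector permuted
across taxa, 200 reps); a taxon's positive (negative) connectedness is the
mean of its positive (negative) corrected correlations, and per-sample
cohesion± is the abundance-weighted sum, so cohesion⁺ ≥ 0 ≥ cohesion⁻ by
construction.

## Biomarkers

Taxa roll up into clade features at every parseable rank of the
semicolon-delimited lineage (a clade's abundance is the sum of its members').
A feature is a biomarker when (1) Kruskal–Wallis across groups gives
p < 0.01, (2) the candidate group (highest mean abundance) beats every other
group in one-sided Wilcoxon rank-sum tests at α = 0.05 (the all-against-all
strict reading of the consistency step), and (3) the effect size exceeds
|LDA| > 3.0.  The effect size is deliberately simple: abundances are
rescaled by 10⁶, and over 30 bootstrap subsamples (two-thirds of each class)
the absolute enriched-vs-rest class-mean difference is averaged; the score
is log10 of that mean, floored at 1 — this pins the under-specified scaling
so scores land on the familiar 2–5 range.  The study design has no
subclasses, so the original within-class blocks are omitted.

## Reproducibility and numerics

Every stochastic routine takes an explicit seed and threads a
`numpy.random.Generator`; no global random state is used anywhere, and the
pipeline derives per-stage seeds from one global seed.  Output tables start
with a `#` audit comment (version, stage, seed).  Ties in module detection
are broken by the seeded Louvain order; RC ties are counted half; Bray–Curtis
comparisons in RC use a 1e-12 tolerance.  Known limitations: βNTI pairs with
degenerate nulls are unclassifiable rather than imputed; the cohesion null is
the taxon-shuffle variant only; per-treatment networks with five replicates
cannot pass the FDR gate (the minimum two-sided Spearman p at n = 5 is
≈ 0.017), so network construction defaults to pooled mode.
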