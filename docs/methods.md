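# Methods

This note documents the models implemented in `ecoassembly`, the parameters
that matter, the synthetic-data generator's design, and the numerical
choices — in enough detail that a reader can judge what passing tests do and
do not demonstrate.

## Process partitioning (βNTI + RC_bray)

Pairwise turnover between communities is partitioned into five ecological
processes with a two-stage null-model procedure.

**Stage 1 — phylogenetic turnover.** βMNTD is the abundance-weighted mean
distance from each taxon in one community to its nearest relative in the
other; shared taxa match themselves at distance zero, so βMNTD responds to
the phylogenetic placement of the *differences* between communities. The
null shuffles taxon labels across the metacommunity species pool (all taxa
with nonzero total count in the analyzed table) and recomputes βMNTD per
draw; βNTI is the resulting z-score. Per-group (layer) pools are available
via `assembly_profile(pool="group")`; the pool used is recorded in the
output's metadata. Defaults: 999 draws; |βNTI| > 2 is read as selection
(positive: variable, negative: homogeneous).

**Stage 2 — taxonomic turnover.** For pairs with |βNTI| ≤ 2, RC_bray ranks
the observed Bray–Curtis dissimilarity within a null that assembles both
communities probabilistically while preserving each community's richness
and total individual count: taxa enter with probability proportional to
their metacommunity occupancy (each contributing one individual), and the
remaining individuals are placed with probability proportional to
metacommunity relative abundance. Ties in the ranking get weight ½; the
rank is standardized to [−1, 1]. RC_bray > 0.95 → dispersal limitation,
< −0.95 → homogenizing dispersal, otherwise undominated. The Methods
convention here resolves an internal inconsistency in some published
descriptions: the stochastic categories require |βNTI| **≤** 2, matching
the deterministic definitions.

Degenerate case: when two samples share an identical taxon set, every null
βMNTD draw equals the observation (label shuffles preserve shared-taxon
self-matches); βNTI is then defined as 0 — no deviation from the null — and
classification falls through to RC_bray.

**β-null deviations.** Separately from RC_bray's constrained null, the
abundance-based deviation draws each sample's observed number of
individuals from the metacommunity relative-abundance distribution
(richness free to vary) and reports observed minus null-mean β-diversity
for Bray–Curtis and normalized weighted UniFrac. Deviations are left
unstandardized so that bounded metrics keep deviations in [−1, 1].

## Weighted UniFrac

Implemented through a branch-incidence table: for each branch, the fraction
of each sample's total abundance descending from it; the normalized metric
is Σ l_b |A_b − B_b| / Σ l_b (A_b + B_b) ∈ [0, 1] (the unnormalized raw sum
is available by flag). Normalization is the default so that UniFrac-based
deviations are comparable with Bray–Curtis. Taxa absent from the tree are
dropped with a warning (strict mode raises); the implementation is
cross-checked against scikit-bio's `weighted_unifrac` in the test suite.

## Sloan neutral model

Under drift–migration balance, a taxon with metacommunity mean relative
abundance p has local relative abundance distributed Beta(Nmp, Nm(1−p)) in
communities of N individuals; it is detected when its abundance exceeds
d = 1/N (one read). The predicted occurrence frequency is the upper Beta
tail; m is estimated by bounded least squares on untransformed frequencies
with three bracketed starts (m local minima are shallow but real), and
per-OTU 95% Wilson score intervals are reported around the predictions.
N defaults to the mean per-sample depth (communities should be rarefied to
a common depth first); when N is supplied explicitly, relative abundances
are computed as counts/N so that duplicating identical OTU rows cannot
perturb the fit (weights per OTU, not per read).

## Levins' niche breadth

B_j = 1/Σ_i P_ij² with P_ij the fraction of OTU j's individuals found in
community i (Σ_i P_ij = 1). This convention bounds B in [1, number of
communities]: B = 1 for an OTU confined to one community, B = N for an even
spread over N. The alternative within-community convention is available via
`within_community=True`. B_com for a community is the unweighted mean of B
over the taxa present in it.

## Ensemble co-occurrence networks

Candidate edges are all pairs of OTUs that pass the prevalence filter
(detected in strictly more than ¾ of the group's samples, by default).
Four association measures are computed per pair: Pearson and Spearman on
raw counts; Bray–Curtis and symmetrized Kullback–Leibler on each OTU's
across-sample profile normalized to sum 1 (KL with a 1e-6 pseudocount,
renormalized). Permutation nulls (default B = 1000; one OTU's vector
permuted) give two-sided p-values for the correlations and left-tail
p-values for the dissimilarities (low dissimilarity = association;
mutual-exclusion edges are out of scope). The four p-values are merged with
Brown's method: X = −2Σ ln p is approximated by a scaled χ², with
cov(−2 ln p_i, −2 ln p_j) from the Kost–McDermott cubic
3.263ρ + 0.710ρ² + 0.027ρ³, where ρ is the correlation of the −2 ln p̃
transforms of the shared permutation draws. With ρ = I the method reduces
exactly to Fisher's combination; with identical inputs at ρ = 1 it returns
the common p. BH correction runs across all candidate pairs within the
group; an edge is retained when |pearson| > 0.6 **and** |spearman| > 0.6
and BH-adjusted p < 0.01. The published threshold speaks of a single
"correlation coefficient" for a four-measure ensemble; requiring both
correlation coefficients to pass and letting the dissimilarities enter only
through the merged p is this package's interpretation. Edge sign follows
Pearson (Spearman breaks a zero tie). Nodes are the OTUs participating in
at least one retained edge.

Topology: density 2E/(n(n−1)), average degree 2E/n, mean local clustering
(degree < 2 contributes 0), path length and diameter on the largest
connected component, modularity from deterministic greedy modularity
maximization, and PNC = 100 × negative/total edges.

**O/R ratio.** O% is each phylum pair's share of observed edges. R% is the
exact without-replacement expectation from node frequencies:
100·n_A(n_A−1)/(n(n−1)) within a phylum and 100·2n_An_B/(n(n−1)) between
two; the with-replacement product approximation is emitted alongside since
the two differ only at O(1/n). ΣO = ΣR = 100 exactly; O/R > 1 reads as
deterministic association, < 1 as stochastic.

## Carbon metabolism

AWCD at a single timepoint (96 h default) is the mean blank-corrected OD590
across the 31 substrate wells, with negatives clamped to zero (standard
EcoPlate practice); guild AWCDs average within the six substrate guilds, so
the guild-size-weighted mean of guild AWCDs reproduces the whole-plate
value exactly. SOC mineralization series are fit with
C_t = C0(1 − e^(−kt)) by bounded nonlinear least squares; initialization is
deterministic (C0 ← 1.1·max C_t; k from a log-linear regression of
1 − C_t/C0_init), so fits are bit-reproducible. Non-monotone cumulative
series trigger a warning, not an error.

## Rarefaction, diversity, environment

Rarefaction is an exact multivariate-hypergeometric subsample (without
replacement) to a fixed depth, seeded; the default depth (20,515) matches
the survey design this pipeline targets, and every rarefied column sums to
the depth exactly. Shannon entropy is in nats; Chao1 uses the
bias-corrected form S_obs + F1(F1−1)/(2(F2+1)) by default (defined at
F2 = 0), the classic form by flag. Environmental variation per layer is
summarized two ways, because a single convention is not established: the
trace of the within-layer covariance of globally z-scored variables, and
each sample's squared distance to its layer centroid (box-plottable);
per-variable coefficients of variation are computed on the raw scale.

## The synthetic metacommunity generator

The generator emulates the processed form of a depth-stratified soil
survey: five layers × four treatments × three replicates, a few hundred
OTUs at a fixed read depth, an ultrametric Yule phylogeny, monophyletic
phylum labels, and environmental heterogeneity that declines with depth.
Each layer is assembled under one regime so the five inferred categories
have a known truth:

- **Variable selection** — Gaussian niche filter on a latent axis with the
  axis value spread across samples (±1.5 SD of the trait distribution,
  scaled by the layer's heterogeneity). Taxon optima evolve by Brownian
  motion on the tree, giving the phylogenetic signal βNTI needs. The filter
  has a hard tolerance boundary at 3 filter-widths — the Gaussian tail
  otherwise admits phylogenetically scattered taxa that dilute the
  signature. Default filter width: 0.2 SD of the optima.
- **Homogeneous selection** — a consistent environment selecting one
  habitat-adapted lineage: membership is confined to a seeded clade
  (⅛–¼ of the pool) and lognormal drift (SD 1.0) decides which members
  dominate each sample. A trait filter at a constant axis value was tried
  first and rejected: taxa near any fixed trait value are not reliably
  phylogenetically clustered under Brownian evolution at this pool size, so
  about half of tree realizations produced |βNTI| < 2 — the regime failed
  to embody its own definition. Lineage-level selection makes the clustered
  community the construction, not a hope.
- **Homogenizing dispersal** — every sample drawn multinomially from the
  shared metacommunity pool.
- **Dispersal limitation** — per-sample pools from Dirichlet(α·meta) with
  α = 50 effective colonists plus lognormal drift (SD 2.0): samples are
  dominated by different taxa, pushing observed turnover above the
  richness-constrained null.
- **Neutral (drift)** — each sample's pool is drawn from the stationary
  distribution of drift–migration balance, Beta(Nmp, Nm(1−p)) per taxon
  (renormalized), and the community is the discretized stationary state: a
  taxon whose equilibrium frequency amounts to fewer than one individual is
  absent, and leftover reads go to detected taxa by largest remainder.
  Sampling the equilibrium directly replaces iterating Wright–Fisher
  generations (it is the distribution the iteration converges to, and the
  one the Sloan model assumes); adding a second multinomial read-sampling
  layer on top would double-count drift noise and bias m̂ upward by tens of
  percent. Default m = 0.1.

Expected classifications: the four non-drift regimes map to their namesake
categories. Pure drift surfaces as dispersal limitation or undominated —
its Beta-scale variance exceeds the individual-level noise of the
fixed-richness null — and both are counted as correct recovery.

Defaults are desk-scale: 400 taxa, 2000 reads per sample, lognormal
metacommunity (σ = 1.5). These sizes keep a full five-layer partition at
999 draws per pair in minutes on one core; tests run the recovery check at
299 draws per pair across five seeds, which resolves the ±2 and ±0.95
thresholds comfortably.

**What passing does not show.** The generator draws independent samples
from regime-specific pools; it has no spatial structure, no interaction
between selection and dispersal within a layer, no compositional biases
from amplification or copy number, and its phylum labels are perfectly
monophyletic. Recovery under these conditions validates the inference
machinery, not the interpretability of any particular field dataset.

## Numerical conventions

- All randomness flows from integer seeds through `numpy` `SeedSequence`
  spawn keys; each (stage, pair) gets an independent stream, so per-pair
  results are independent of execution order and of which other pairs are
  computed.
- RC_bray tie counting uses weight ½ at a 1e-12 tolerance (counts are
  integers, so exact ties are meaningful).
- Empty networks report NaN topology markers rather than raising; path
  metrics use the largest connected component; greedy modularity
  maximization is deterministic.
- Real-valued count tables are rejected: the null models operate on
  individuals.
- Missing branch lengths parse as 0 with a warning; negative lengths are
  errors.

## Known limitations

- βNTI loses power when paired communities share nearly all their mass:
  the informative non-shared fraction then carries few effective taxa. The
  generator's drift terms exist partly to keep this fraction realistic.
- The RC_bray null's occupancy weighting uses the analyzed table itself as
  the metacommunity; with few samples the occupancy estimate is coarse.
- Brown's merge relies on the Kost–McDermott polynomial approximation and
  on rank-based pseudo-p transforms of the permutation draws; both are
  accurate at the 1e-2 p-value scale the retention rule uses, not in the
  extreme tails.
- The Sloan fit assumes a common N across samples and independence across
  OTUs; neither holds exactly for compositional count data.
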