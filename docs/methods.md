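# Methods

This note documents the models implemented in `phyllo`, the numerical
choices behind them, what the synthetic-data generators do and do not
emulate, and the known limitations of each inference.

## Data model and normalisation

The unit of analysis is an ASV-by-sample table of non-negative integer
read counts with a per-ASV kingdom label (`bacteria`/`fungi`). All
statistics operate on per-sample relative abundances; no rarefaction is
applied by default because uniform-depth simulation makes it a no-op and
relative abundances are depth-invariant for every statistic used here. A
seeded `FeatureTable.rarefy` is provided for sensitivity checks on real
data with uneven depth.

Two normalisation conventions are fixed package-wide:

* The "relative abundance of a taxon" used for filtering and thresholds is
  the **mean of per-sample fractions**, not the fraction of pooled counts.
  The two differ under uneven depth; mean-of-fractions is chosen because
  filtering operates per dataset partition (per genotype, per kingdom).
* The rare-ASV filter before network inference removes taxa below 0.01 %
  mean relative abundance (fraction 0.0001), the conventional
  zero-inflation guard for Spearman correlation networks.

## Diversity and hypothesis testing

Shannon diversity uses the natural log (the vegan convention). Bray-Curtis
is computed on relative abundances. PCoA eigendecomposes the Gower-centred
−½D² matrix; negative eigenvalues are reported but excluded from the
proportion-explained denominator, and no Cailliez correction is applied
(the axes plotted are unaffected).

PERMANOVA is the one-factor form with free permutation of sample labels
(no strata), pseudo-F computed from total vs within-group sums of squared
distances, `p = (1 + #{F_perm ≥ F_obs}) / (1 + n_perm)`, and
`R² = SS_between/SS_total`. Permutation F-statistics are computed for all
permutations at once via one-hot quadratic forms, which keeps a
999-permutation test on a dozen samples at well under a millisecond and
makes the 500-dataset type-I calibration test cheap. Where a study tests
several factors, each is tested marginally, one at a time.

The differential-abundance ("enrichment") operation classifies taxa
between exactly two groups by |log₂ fold change| > 2 of group-mean
relative abundances and a BH-adjusted two-sided Wilcoxon rank-sum p < 0.01.
This deliberately substitutes a robust nonparametric test for a
negative-binomial GLM on raw counts: the published thresholds are kept,
but exact parity with NB-GLM results is a non-goal. The log₂FC pseudocount
defaults to half the smallest nonzero mean relative abundance in the
table; callers testing exact fold-change semantics on small constructed
tables should pass an explicit pseudocount, since with few, abundant taxa
the default is no longer negligible.

## Co-occurrence networks

Pairwise Spearman ρ (average-tie ranks, two-sided t-approximation p) is
computed on the rare-filtered relative-abundance matrix; constant taxa get
undefined ρ and can never form edges. Edges require |ρ| > 0.6 **and**
BH-adjusted p < 0.01; the BH family is all candidate pairs within one
network build (recorded in the graph metadata; a flag switches to raw p).
Nodes are taxa with at least one retained edge. Edge signs and BB/BF/FF
classes are kept, but clustering, closeness, betweenness, and modularity
are computed on the unweighted, unsigned skeleton. Modularity uses
deterministic greedy (CNM) maximisation rather than Louvain so that
repeated runs give identical partitions; closeness is normalised within
each connected component as (n_component − 1)/Σd; hubs are ranked by
degree, then closeness, then lexicographic ID. Stability is summarised by
the positive/negative edge proportions and modularity (more negative
edges and higher modularity → more stable community).

## Sloan neutral community model

With community size `N` (mean per-sample total count) and migration rate
`m`, the local relative abundance of a taxon with metacommunity abundance
`p` is Beta(Nm·p, Nm·(1−p)); its predicted occurrence frequency at
detection limit `d = 1/N` is `1 − BetaCDF(d; Nm·p, Nm·(1−p))`. `Nm` is
fitted by bounded scalar least squares on log₁₀ Nm against observed
occurrence frequencies, `R² = 1 − SS_res/SS_tot`, and each taxon is
classified above/within/below the Wilson 95 % score interval around its
predicted frequency at n = number of samples. The `d = 1/N` and Wilson
conventions follow the standard implementation lineage of the model; both
are overridable. When every taxon occurs in every sample the occurrence
frequencies have zero variance; the fit is still returned with `R² = NaN`
and a warning rather than an error.

The neutral **generator** inverts this model exactly (per-sample Beta
draws, then multinomial reads), which is what makes simulate→fit parameter
recovery a meaningful end-to-end check: at 60 samples × 5,000 reads × 200
taxa and Nm = 50, the fitted Nm lands within ±20 % with R² > 0.7 in ≥ 90 %
of replicates. The small upward bias in fitted Nm comes from multinomial
read noise adding variance the Beta stage did not produce.

## βNTI, RC_bray, and the five-process partition

Abundance-weighted βMNTD between samples k and l is
`0.5·[Σᵢ f_ik·min_{j∈l} d_ij + Σⱼ f_jl·min_{i∈k} d_ij]` on patristic
distances (verified to 10 decimal places against R picante's `comdistnt`
on a frozen fixture). The βNTI null shuffles taxon labels across all tree
tips; one shuffle sequence is shared across sample pairs so the cost is
O(n_null · pairs) with vectorised per-shuffle βMNTD over all pairs at
once. βNTI is the z-score of the observed βMNTD against 999 null draws;
pairs with zero null SD (e.g. near-identical presence sets) are undefined,
reported as NaN, and excluded from process denominators with a count.
Because the z-score cancels any common scale, βNTI is invariant to uniform
branch-length scaling (asserted to 1e-8 under 10× scaling).

RC_bray builds null communities that preserve each sample's observed
richness and total reads: taxa drawn without replacement with probability
proportional to occupancy, reads then allocated multinomially in
proportion to pooled relative abundance among the drawn taxa. One null
table per iteration serves every pair. RC is the rescaled rank
`((#null < obs) + 0.5·(#null = obs))/n_null → (·−0.5)·2 ∈ [−1, 1]`.

Process assignment per sample pair: βNTI > +2 heterogeneous selection;
< −2 homogeneous selection; otherwise RC > +0.95 dispersal limitation,
RC < −0.95 homogenizing dispersal, else drift. Cut-offs are defaults, not
constants. Following the study design this partition is computed within
genotype and within kingdom; cross-genotype pairs are excluded.

Two calibration caveats discovered and documented here:

* **The βNTI null is approximately normal only when abundance is spread
  over many taxa.** When one taxon carries ~40 % of reads, the null βMNTD
  distribution is heavy-tailed and |βNTI| > 2 occurs for 10–15 % of
  truly-null pairs rather than ~5 %. The calibration check therefore uses
  an even metacommunity (lognormal σ = 0.5, 100 taxa, Nm = 50, 4,000
  reads) where the exceedance rate sits at 5–7 %; on strongly dominated
  real communities βNTI cut-offs should be read as approximate.
* **"Neutral" per Sloan is not "drift" per RC_bray.** Finite-migration
  neutral communities (Nm ~ 50) are more variable than the
  occupancy-proportional RC null, so RC labels many such pairs dispersal
  limitation. The two nulls answer different questions by construction;
  agreement should not be expected.

## Levins' niche breadth

`Bᵢ = 1/Σⱼ Pᵢⱼ²` with `Pᵢⱼ` the share of taxon i's total abundance in
sample j, ranging from 1 (single-sample specialist) to n_samples (even
generalist); the community index is the unweighted mean over taxa with
nonzero totals (all-zero taxa are excluded with a warning).

## Synthetic-data generators

All generators draw from one `numpy` Generator seeded explicitly; same
design + parameters + seed ⇒ byte-identical artifacts. The default design
mirrors the paired field study: 3 sites × 2 genotypes × 5 replicates,
200 taxa per kingdom, uniform 20,000 reads per sample. Bacteria and fungi
are simulated independently (separate lognormal pools, separate unit-depth
pure-birth trees) and stacked; **each kingdom block sums to
`reads_per_sample` per sample**, mirroring separate 16S and ITS sequencing
runs, so the stacked table sums to twice that. Uniform depth is assumed
because the source design does not state a depth distribution.

* **Metacommunity pool**: lognormal ranked-abundance vector, σ (`shape`)
  exposed; σ = 1.5 by default (a few dominant taxa, long rare tail), σ = 0
  degenerates to uniform.
* **Neutral**: Beta(Nm·p, Nm·(1−p)) per sample, then multinomial — the
  exact generative inverse of the Sloan fit.
* **Selection**: a Brownian trait (rate 1 on the unit-depth tree, so
  root-to-tip trait SD = 1) filters the pool by the Gaussian fitness
  kernel `exp(−(trait−env)²/(2·trait_sd²))` before read sampling. Default
  `trait_sd = 0.5` with env blocks at ±2 (trait-SD units) produces strong,
  phylogenetically clustered filtering — between-block βNTI medians near
  +9 — while `trait_sd → ∞` provably reduces to multinomial pool sampling.
  Heterogeneous selection sets env by genotype; homogeneous selection uses
  a common env.
* **Dispersal limitation**: taxa are placed on a latent ring in random
  order (independent of phylogeny and abundance) and each sample colonises
  a contiguous window covering `subsample_fraction` (default 0.2) of the
  ring. Distant samples share no taxa, so pairs exceed the RC null
  (RC → +1) with no phylogenetic signal. An earlier design drew each
  sample's subset i.i.d. uniformly; that generator *is* the RC null
  process and correctly partitions as drift, so it cannot represent
  dispersal limitation — the ring structure is what makes observed
  turnover exceed stochastic expectation.
* **Planted networks**: planted pairs share a latent Gaussian
  log-abundance factor (sign-flipped for negative edges) plus independent
  noise (`noise_sd`, default 0.3 → latent correlation ≈ 0.92); background
  taxa fluctuate independently. Compositional closure (the shared
  denominator) caps noiseless *negative* pairs at Spearman ρ ≈ −0.7 to
  −0.85 rather than −1; positive pairs are unaffected because both members
  share the same denominator distortion.
* **Core/enrichment**: designated core taxa are pinned at a fixed target
  relative abundance in every sample (prevalence 1 by construction);
  enriched taxa get a 2^log2fc multiplier in one genotype; remaining taxa
  carry mild lognormal sample noise (σ = 0.5).

What these generators do **not** emulate: sequencing error and chimeras,
taxonomy misassignment, uneven library sizes, compositional correlation
induced by a shared sequencing run, spatial autocorrelation among
replicates, and phylogenetic signal in abundance itself. Passing tests
therefore demonstrate estimator correctness under the stated generative
models, not robustness to those real-data artifacts.

## Problem sizes used in validation

Validation runs use desk-scale sizes chosen to exercise each property with
comfortable statistical margin: Sloan recovery at 60 × 5,000 × 200 over 50
replicates; βNTI calibration over 100 independent 3-sample datasets (300
pairs, 999 nulls each) — independent datasets rather than one large one
because pairs sharing samples are strongly correlated and a single
dataset's exceedance rate is far too noisy to test; process-partition
consistency on 16-sample, 100-taxon scenarios at 999 nulls; network-metric
oracle equivalence on 20 random graphs of ≤ 30 nodes; planted-edge
recovery over 20 seeds; PERMANOVA type-I over 500 twelve-sample datasets
at 999 permutations.

## Known limitations

* PERMANOVA is one-factor with free permutations; nested/stratified
  designs and sequential (type-I SS) multi-factor decompositions are out
  of scope.
* The enrichment test is rank-based; it will be conservative relative to
  NB-GLM approaches at small n and does not model library-size offsets.
* Signed-modularity and compositionality-aware correlation (SparCC-style)
  are out of scope; Spearman on relative abundances carries the usual
  compositional caveats, visible in the planted-network negative-pair
  ceiling above.
* RC_bray is implemented in its occupancy-proportional colonisation /
  abundance-proportional filling variant (recorded in output metadata);
  other published variants shift RC values for the same data.
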