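# Methods

`gutstruct` reimplements, as a tested pipeline, the downstream analysis of a
large healthy-cohort 16S gut-microbiome study: enterotype detection and
cross-cohort comparison, cooccurrence-network clustering of ASVs, demographic
prevalence screening, and host-factor association — together with a synthetic
cohort generator that emulates the statistical structure those analyses
assume, so every stage can be scored against a planted ground truth.

## Community metrics

**Relative abundance and prevalence.** Abundance of a taxon in a sample is
its read count divided by the sample total; aggregation to genus or phylum
sums counts first, so rows always sum to 1. Prevalence is the fraction of
samples with nonzero reads for the taxon. Alpha diversity is observed ASV
richness (number of nonzero ASVs); no rarefaction is performed, and Shannon
or phylogenetic diversity are out of scope.

**Weighted UniFrac.** The unnormalized form: for communities A and B on a
rooted tree, `d(A,B) = Σ_b ℓ_b |P_A(b) − P_B(b)|`, where `P_X(b)` is the
fraction of X's total mass descending through branch b. It is computed by a
single postorder accumulation of branch masses; the full matrix is then a
weighted L1 distance between branch-mass columns (`scipy.spatial.pdist`
cityblock on length-scaled rows). Distances are computed on full relative
abundances rather than rarefied counts; this choice is deliberate and makes
the distances deterministic functions of the count table. The test suite
checks the implementation against a naive per-branch summation oracle to
1e-12 and property-tests the metric axioms.

**PCoA.** Classical scaling: double-center −D²/2, eigendecompose, order axes
by descending eigenvalue. Axes with non-positive eigenvalues are dropped;
genuinely negative eigenvalues are reported on the result object for
inspection (no Cailliez correction). Proportions explained are relative to
the positive-eigenvalue inertia.

## Enterotypes

Samples are embedded by PCoA of the weighted-UniFrac matrix and clustered
with a K=2 full-covariance Gaussian mixture (scikit-learn, 5 restarts,
seeded). The mixture uses the **leading 3 axes** by default: with full
covariances, feeding many low-inertia axes lets a component stretch along
noise directions and visibly degrades recovery of the planted partition (we
measured ARI dropping from ≈0.95 to 0.61 on one cohort at 10 axes); three
axes carry the compositional signal and are robust across cohort draws. The
axis count is configurable (`n_axes` / `et_axes`). Each cluster is labeled by
the genus with the highest mean relative abundance among its members, with
ties resolved by assigning each cluster the highest-ranked genus not already
used.

External cohorts are labeled by nearest-neighbor transfer: each query sample
takes the enterotype of the reference sample at the smallest cross UniFrac
distance (ties to the smallest reference index). This requires a shared ASV
space; the cross-distance helper concatenates the two count tables and uses
the reference tree.

Three cohort comparisons:

* **Proportion test** — Yates-corrected chi-squared on the 2×2 enterotype
  table (`scipy.stats.chi2_contingency`). The Yates correction reproduces
  the published worked examples to their printed precision.
* **PERMANOVA** — pseudo-F from the distance decomposition
  `SS_total = Σ_{i<j} d²_ij / n`, `SS_within = Σ_g Σ_{i<j∈g} d²_ij / n_g`,
  `F = (SS_between/(g−1))/(SS_within/(n−g))`, with label-permutation p-value
  `(1 + #{F_perm ≥ F_obs})/(1 + n_perm)` — never exactly zero. The pseudo-F
  is cross-checked against scikit-bio's PERMANOVA and the permutation p
  against exhaustive enumeration at n=6.
* **Average-distance test** — for a target enterotype, each foreign sample's
  mean distance to the reference members is compared against each reference
  member's self-excluded mean distance to the others, by a two-sided
  Mann-Whitney U (exact for ≤20 per side, else normal approximation with tie
  correction).

## Cooccurrence network and microbial clusters

Only ASVs with prevalence ≥ 10% are tested. For each pair:

* **Cooccurrence** — two-sided Fisher's exact test on
  `[[n_both, n_a_only], [n_b_only, n_neither]]`. Direction is positive when
  `n_both` exceeds its independence expectation (robust to zero cells,
  unlike the odds ratio). An always-present or always-absent ASV carries no
  cooccurrence information and gets p = 1.
* **Quantitative association** — Spearman correlation of natural-log
  relative abundances on the samples where both ASVs are present
  (the log is cosmetic for a rank statistic; documented for completeness).
  Pairs with overlap < 10 samples are excluded — the overlap floor prevents
  spurious perfect correlations on tiny intersections.

Benjamini-Hochberg runs separately within the two families; an edge requires
**both** criteria — Fisher q < 1e-6 with positive direction AND rho > 0 with
q < 1e-3. The per-criterion hit counts are reported separately, and a union
rule is available via configuration. Negative associations (rho < 0, BH
within the negative family at 1e-3) are reported as a separate edge list and
never enter clusters.

Clusters: (1) find all 3-cliques — computed as connected components of the
subgraph of edges that participate in a triangle, which is equivalent to
merging node-sharing cliques; (2) split each merged group into
phylum-consistent connected components (the deterministic analogue of the
study's manual phylum disjoining); (3) attach any remaining network node
adjacent to a member and carrying the member's lowest-taxon label;
(4) name each cluster after the display taxon of its highest-total-count
member; clusters below 3 members are dropped. ASV display names are
"<lowest assigned taxon> ASV <rank>", ranking by descending total count
within each lowest-taxon group, ties by ASV id.

## Host-factor analyses

**Prevalence screen.** For ASV presence in a demographic group of size n
drawn from N samples with K carriers, upper and lower hypergeometric tails
`P(X ≥ k)` and `P(X ≤ k)` are computed; the reported two-sided p doubles the
smaller tail (capped at 1), since the screen reports both enriched ("+") and
depleted ("−") calls. BH across all ASV × group tests at FDR 0.1. Decade
bins (<40, 40s, 50s, 60s, 70+) are used for age.

**Winsorization.** Host factors are clipped to `[Q1 − 1.5·IQR, Q3 + 1.5·IQR]`
with type-7 (linear-interpolation) quartiles. Note the rule is *not*
idempotent when more than a quarter of the mass sits in a tail (clipping then
moves a quartile); the property test asserts the conditional form.

**Association model.** For each ASV × factor: ordinary least squares of the
(winsorized) factor on log relative abundance, where zeros are replaced by
half the ASV's smallest nonzero relative abundance before the log
(a nonzero-only mode is available). If the ASV's abundance is more strongly
associated with age than with the factor — operationalized as a smaller
univariate p — the model is refit with age as a covariate and the abundance
term is tested by partial F (which equals the squared t of the slope in the
single-predictor case; asserted numerically). BH across all pairs at FDR
0.2. Pairs with fewer than 10 usable samples or zero variance are excluded
and logged.

**Diet PCA.** The 17 food-group intakes are z-scored (constant columns
dropped with a warning) and decomposed by SVD; each axis is oriented so its
largest-magnitude loading is positive. Age correlations (diversity and
per-ASV abundance) are Spearman, sex-stratified where stated, with BH at 0.2
for the abundance screen.

## Synthetic cohort generator

The generator draws, per sample: an enterotype from the (0.60, 0.40)
mixture; genus shares from a Dirichlet (concentration 40) around that
enterotype's genus profile — the profiles carry the study values
(Bacteroides enterotype: Bacteroides 35.3%, Faecalibacterium 14.2%,
Prevotella 2%; Prevotella enterotype: 37.1% / 11.7% / 10.4%), with the
leftover mass spread over nine minor genera; within-genus ASV weights follow
a power law with i.i.d. log-normal noise (sigma 0.8); counts are multinomial
at log-normal library sizes (mean 30,000, sigma 0.3 — comfortably above the
10,000-read inclusion cutoff). The enterotype mixture alone induces the
cohort-level Bacteroides–Prevotella anticorrelation (genus-level Spearman
≈ −0.7 at defaults).

**Planted cooccurrence blocks.** Each block is a set of same-genus ASVs
(default 5 blocks × 6 ASVs, hosted by distinct minor genera) sharing a
log-normal latent factor. Block sigma 1.1 and a base relative abundance of
2.5e-4 per block ASV realize the intended regime — in-block Spearman of
nonzero log abundances ≈ 0.5 and block prevalence ≈ 0.6–0.85 — so the
blocks are detectable but not trivial at the study thresholds. Per-ASV
dispersion values are free parameters of the generator and are recorded in
the ground-truth record.

**Planted host-factor effects.** An effect (asv, factor, β) shifts the
factor by β factor-standard-deviations per standard deviation of the ASV's
*idiosyncratic* log-abundance component (its private log-normal term). Two
points are deliberate. β is in SD units, making it a correlation-like effect
size (r ≈ β/√(1+β²)) independent of the factor's scale. And coupling to the
idiosyncratic component rather than to total log abundance keeps the planted
association attributable to the named ASV: coupling to total abundance makes
the factor a proxy for the genus and enterotype axes the ASV rides on, so
many unplanted-but-genuinely-correlated ASVs are then called, and a
false-discovery accounting against the planted list becomes meaningless.
The observed link to the ASV's measured log abundance is correspondingly
attenuated by its idiosyncratic-variance share (≈0.7 at defaults). Default
effects: β = ±0.5 on BMI for three non-block ASVs from three different
genera. An optional stratum restriction (e.g. female-only) applies the shift
to a metadata subset.

**Host metadata.** Age ~ N(55.6, 15.0) clipped to [20, 90]; 77.5% female;
BMI ~ N(23.5, 3.2); ordinal stool frequency; 17 food-group intakes driven by
two latent diet axes — axis 1 loads on grain/rice/bread (plus weaker staples),
axis 2 contrasts a Westernized pattern (noodles, snacks, meat) with a
traditional one (vegetables, seaweed, soybean) and is coupled to age with
Pearson −0.53, giving a Spearman of ≈ −0.5 between age and the recovered
second principal component. Axis-1 loadings are scaled so the grain axis
carries more shared variance than axis 2, fixing the PC order.

**What the generator does not emulate:** sequencing error, chimeras, or read
processing (counts are drawn directly); taxonomic misassignment; overlapping
or cross-phylum cooccurrence blocks; compositional effects beyond
closure-by-normalization; longitudinal structure. Passing recovery tests
therefore demonstrates the correctness and calibration of the statistical
machinery under the generative assumptions, not performance on real
sequencing data.

## Reproducibility and problem sizes

All randomness flows from explicit seeds; the pipeline derives per-stage
seeds from one config seed via `numpy.random.SeedSequence.spawn`, and
identical config + seed gives byte-identical outputs. The benchmark suite
uses an 800-sample cohort at generator defaults for enterotype and network
recovery, a 200-sample held-out cohort for label transfer, 200 replicate
cohorts (n=300, 60 ASVs) for association power and false-discovery
accounting, and 1000 structure-free replicates (n=20, 99 permutations) plus
200 effect-free cohorts (n=150, 40 ASVs) for null calibration of PERMANOVA
and the association pipeline — sizes chosen to estimate each rate with
Monte-Carlo error well inside the tolerance it is compared at.

## Known limitations

* The quantitative association uses relative abundance on shared-presence
  samples; rank correlations are unaffected by the log base but not by
  library-size composition effects, which are not corrected (SparCC-style
  compositional corrections are out of scope).
* PERMANOVA assumes exchangeability under the null; no strata/blocking.
* The enterotype model fixes K=2 (a BIC scan over K=2..6 is available for
  inspection but never drives labeling).
* Cross-cohort comparisons assume a shared ASV space; re-inference of ASVs
  on merged datasets is out of scope.
* The hypergeometric screen treats demographic groups as fixed partitions;
  no continuous-covariate adjustment.
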