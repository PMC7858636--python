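# Methods

## Problem and model

Given GWAS summary statistics for m traits over the same genomic region of
Q variants — per trait i and SNP j an effect estimate β̂_ij and its
standard error v_ij (log-odds scale for binary traits) — the package asks
whether the traits' association signals are driven by one shared causal
variant (colocalization) rather than distinct variants in linkage
disequilibrium. Three assumptions are inherited from the underlying model:
(i) when studies are not independent, they draw on the same population, so
one LD pattern applies; (ii) at most one causal variant per trait in the
region (a violation mode is simulated and discussed below); (iii) causal
variants are typed or well imputed in every study.

A *causal configuration* S assigns each trait at most one causal SNP.
Configurations group into hypotheses (which traits share a variant, which
have distinct ones, which have none); the posterior of a hypothesis is the
normalized sum of per-configuration Bayes factors times prior odds against
the all-null configuration.

### Evidence

Per trait and SNP the data term is Wakefield's approximate Bayes factor
under a normal effect prior N(0, w²):

    ln ABF = ½ ln(v² / (v² + w²)) + (z²/2) · w² / (v² + w²),

with z = β̂/v. The prior SD defaults to w = 0.15 for continuous traits and
w = 0.2 for binary traits on the log-odds scale. For independent studies a
configuration's Bayes factor is the product of per-trait ABFs at the
assigned SNPs. For overlapping samples, a joint ABF replaces the product:
with Σ_β̂ = Vρ̂V (observed covariance of the estimates, ρ̂ the cross-trait
correlation induced by overlap) and Σ_β = WρW (prior covariance),

    ln JABF = ½ ln(|Σ_β̂| / |Σ_β̂ + Σ_β|) + ½ β̂ᵀ(Σ_β̂ + Σ_β)⁻¹ Σ_β Σ_β̂⁻¹ β̂,

evaluated on the active-trait sub-vector of each configuration (null
traits contribute no data term). ρ̂ is estimated as the empirical
correlation of null-SNP Z-statistics (|z| < 2, at least 50 SNPs), projected
to the nearest PSD correlation matrix; the prior correlation ρ defaults to
ρ̂ and both can be supplied directly. All evidence is accumulated in log
space with log-sum-exp reductions: Z-statistics near 40 give Bayes factors
of order e^800, far outside double range.

The joint ABF is applied per *same-SNP trait group* within a
configuration; groups at distinct SNPs are treated as independent blocks.
The overlap-induced covariance between estimates at SNPs j and k scales
with the LD r_jk, so the trait-level ρ̂ is right within a shared-SNP group
(r = 1) and negligible for unlinked SNPs — applying ρ̂ across distinct
SNPs would let discordant far-apart estimates masquerade as evidence.
Note that adjusting the likelihood alone is conservative: shared noise
explains part of any co-occurring association, so the colocalization
posterior drops, sometimes sharply, relative to the independent-study
analysis of the same data. Restoring calibration would require
trait-correlation-aware configuration priors, which are out of scope here
(traits are a priori exchangeable); treating overlapping studies as
independent is the pragmatic default, with the adjusted analysis as a
lower bound on the evidence.

### Priors

The default *variant-level* scheme uses two interpretable parameters:
p, the probability a variant is causal for one trait (default 1e-4), and
p_c, the conditional colocalization prior — the probability a variant is
causal for an additional trait given it is causal for one (default 0.02).
With γ = 1 − p_c, the prior that one variant is causal for a specific set
of k traits is p_{12…k} = p ∏_{i=2..k}(1 − γ^{i−1}); a configuration's
prior odds multiply one such factor per distinct causal variant, divided by
the per-variant null mass p0. For two traits this is the familiar pairwise
parameterisation p1 = p2 = p, p12 = p·p_c, and p_c relates to a pairwise
prior via p_c = p12/(p12 + p1). Both parameterisations are accepted; note
the two relations differ at relative order p_c (p·p_c = 2.0e-6 versus
p·p_c/(1−p_c) = 2.04e-6 at the defaults), a discrepancy inherent to the
parameterisation, not a bug.

p0 is treated as 1 by default (`p0_policy="unit"`). The exact normalization
p0 = 1 − Σ_k C(m,k) p_{12…k} exists only while that mass is below one; at
the default parameters the binomial growth in trait subsets makes the
nominal per-variant partition improper beyond m = 81, so odds form is the
only coherent choice for very many traits. For m where it exists the
correction is below 0.1% (`p0_policy="normalized"` computes it exactly and
is used in tests).

The alternative *conditionally uniform* scheme gives every configuration
within a hypothesis class equal prior odds 1/|S_H|. Class sizes follow the
convention: a single shared-variant group (any size) has Q configurations;
multi-group shapes are counted at the level of the hypothesis set — the
number of trait partitions of that shape times ordered assignments of
distinct variants (Q(Q−1) for two traits at distinct variants, mQ(Q−1) for
the (m−1,1) shape with m > 2, computed combinatorially for the shapes only
the exhaustive oracle visits). The granularity differs deliberately between
the two cases to match the stated class sizes.

## The fast posterior

Exhaustive enumeration touches (Q+1)^m configurations — hopeless beyond
m ≈ 4. The package instead computes:

* **P_R, regional association probability** — the posterior share of the
  full-colocalization class within the restricted space {all-null;
  one trait null, the rest sharing a SNP; all m sharing a SNP}:
  (m+1)Q + 1 configurations, O(mQ) cost.
* **P_A, alignment probability** — the full-colocalization class against
  the classes where m−1 traits share SNP j and the remaining trait is
  causal at k ≠ j: an additional ≤ mQ(Q−1) configurations, O(mQ²) cost.
  With Q = 1 no competing class exists and P_A = 1. For m = 2 the two
  "one trait elsewhere" branches enumerate the same ordered SNP pairs, so
  the class mass is counted once (Q(Q−1) configurations), while for m > 2
  the m branches are disjoint (mQ(Q−1)).

The estimate is PPFC ≈ P_R·P_A, with error of second order in
δ_R = 1−P_R and δ_A = 1−P_A. The error statement carries a caveat: the
algebraic remainder contains a term proportional to the mass of all
*neglected* classes relative to the alignment class, which vanishes with
the deltas under the generative model (a genuinely shared signal) but need
not on arbitrary data — adversarial fixtures with conflicting moderate
signals can exceed the second-order bound by ~1e-3 even at P_R ≈ 0.85. The
property test therefore draws its fixtures from the generative model; the
validation study measures the realized error directly (median relative
difference from exhaustive enumeration ≲ 1e-4 at m ≤ 4, far below the 0.005
acceptance bar).

A refined regional probability P_R′ adds the two-traits-null classes to the
denominator (O(m²Q) configurations) as a diagnostic. Because its
denominator is a superset, P_R′ ≤ P_R always; the package implements the
construction and the tests record that empirical direction.

Per-SNP fine-mapping shares divide the full-colocalization class mass by
SNP (softmax of the per-SNP log terms); the top share is the PPE, the
proportion of the colocalization posterior explained by the candidate SNP.
The best single configuration is reported as the argmax over all enumerated
classes, ties broken toward the lowest SNP index.

## Clustering

When not all traits colocalize, a branch-and-bound divisive search
partitions them. Starting from all traits: accept the cluster when
P_R ≥ P_R* and P_A ≥ P_A* (defaults 0.5/0.5, so τ = 0.25 with both
marginals bounded); otherwise remove the trait whose exclusion branch
carries maximum posterior evidence — by default the regional branches
(O(kQ)); alignment branches (O(kQ²)) are available — and recurse. A cluster
that shrinks to a single trait marks it unclustered, and the procedure
restarts from scratch on all remaining traits (removed singletons never
re-enter). Exact evidence ties remove the lowest trait index, making the
output deterministic. Clusters are flagged against a reporting threshold
(PPFC > 0.7 by default): reported results are the clusters clearing it.

A pairwise baseline (every pair analysed separately, clusters formed as
clique closures over pairs passing the report threshold, greedy seeding by
descending pair posterior with weakest-link growth — the bookkeeping is
this package's choice) is included purely for benchmarking; it cannot
borrow fine-mapping information across more than two traits.

### Sensitivity analysis

`sensitivity_grid` re-runs the clustering over a grid of conditional
priors (default p_c ∈ {0.05, 0.02, 0.01, 0.005}) and thresholds
(P_R* = P_A* ∈ {0.5, 0.6, 0.7}) and reports, per trait pair, the fraction
of grid cells in which the pair shares a cluster (cells weight equally;
frequency across cells is this package's definition of the shading
statistic). The heatmap orders traits by hierarchical grouping of
co-membership so robust clusters appear as dark blocks.

## Synthetic data

The generator emulates regional association studies of quantitative traits:

* **LD**: AR(1) with r(j,k) = ρ^|j−k|, ρ = 0.95 and Q = 500 by default —
  a desk-scale stand-in for resampled reference-panel regions (which
  average ~880 SNPs); constant-correlation blocks and empirical LD from a
  user-supplied phased 0/1 haplotype panel (with the MAF ≥ 0.05 filter)
  are also available. Nothing requires a download.
* **Effects**: each causal variant explains a stated fraction of trait
  variance (default 1%); allele frequencies are uniform on [0.05, 0.5].
* **Sample sizes**: fixed, per-trait, or drawn from
  {1,000, 5,000, 10,000, 15,000, 20,000} to mirror mixed-cohort analyses.
* **Direct path** (default): Z-statistics drawn from a matrix normal with
  column covariance the LD matrix and non-centrality
  ncp_j = Σ_c r(j,c)·√(n·v_c/(1−v_c)); standard errors back-filled as
  1/√(n·2f(1−f)). Participant overlap induces cross-trait row correlation
  n_ov·r_pheno/√(n_i n_j) at null SNPs.
* **Individual path**: genotype dosages per study, phenotype
  y = Σ β_c g_c + ε with β_c = √(v_c/(2f_c(1−f_c))) and residual variance
  1 − Σ v_c, then per-SNP OLS summaries. The default dosage model is
  Gaussian (mean 2f, variance 2f(1−f), correlation exactly the target LD),
  chosen so the two paths have provably matched asymptotic z-score
  distributions including LD; a thresholded Gaussian-copula variant
  produces discrete 0/1/2 dosages with exact marginals but attenuated LD
  relative to the latent correlation, and is checked on marginals only.
  Overlap is not implemented on this path.
* **Violation designs**: named scenarios plant secondary distinct causal
  variants (≈0.75% or ≈1% variance) in half of each cluster's traits.

What the generator does **not** emulate: real haplotype block structure and
allele-frequency/LD coupling (unless a panel is supplied), binary-trait
liability scales (binary traits enter only as log-odds summaries with
w = 0.2), imputation error, population stratification, and cross-trait
genetic correlation beyond sample overlap. Passing tests therefore certify
the inference machinery under the stated generative model, not performance
on any particular real cohort.

Randomness: one master `SeedSequence` spawns per-replicate streams;
identical scenario and seed reproduce a region bit for bit.

### Classification metrics

Clusterings are scored against the planted partition over unordered trait
pairs: TP = together in both, FP = together only in inference, FN =
together only in truth, TN = together in neither; accuracy, TPR and FPR
follow. Under the reporting filter, traits outside any cluster with
PPFC > 0.7 are excluded before scoring (results below the bar would not be
reported); replicates left with fewer than two traits contribute no
defined metric and are excluded from medians.

## Validation studies and problem sizes

`multicoloc.validation` packages three seeded studies (also driven by
`scripts/acceptance.py`):

* approximation error: m ∈ {2, 3, 4} with Q = 50/40/30, 40 replicates per
  m, one shared causal variant (1% variance, n = 10,000); the median
  |approx − exact|/exact against exhaustive enumeration over (Q+1)^m
  configurations.
* false-detection control: m = 100 traits, 99 sharing one causal variant
  and one null, Q = 500, 100 replicates; the median PPFC.
* thresholded clustering: the three 10-trait designs × p_c ∈
  {0.05, 0.02, 0.01}, 100 replicates, Q = 500, sample sizes drawn from the
  mixed set; median pairwise accuracy/TPR/FPR of reported clusters.

Problem sizes are the package's own desk-scale choices: they keep each
study in the single-digit minutes on one CPU while leaving Monte-Carlo
error well inside the tolerances being checked.

## Numerical choices

* Log-sum-exp everywhere; the alignment class uses an O(Q log Q)
  "exclude-one" log-sum-exp (the argmax entry recomputed exactly on the
  deleted array) so no Q×Q object is materialized on the independent path;
  memory stays O(mQ).
* Correlation matrices are validated (symmetric, unit diagonal, PSD within
  1e-8 on the smallest eigenvalue) and repaired when estimated: negative
  eigenvalues clipped at 1e-10, diagonal renormalized.
* The exhaustive enumerator encodes each configuration's trait partition by
  group-leader digits, applies priors per unique partition, and bin-counts
  posterior mass; the correlated-study variant evaluates a joint ABF per
  configuration and is limited to (Q+1)^m ≤ 2e5.
* Ties: best-configuration and branch-removal ties resolve to the lowest
  index (argmax-first semantics), so reruns are byte-identical.
* Degenerate inputs: Q = 1 regions give P_A = 1 by construction; m = 1
  regions are valid data objects but colocalization operations require
  m ≥ 2; zero or non-finite standard errors are rejected at construction.

## Limitations

Single-causal-variant model per trait: secondary variants explaining
comparable variance erode TPR (the simulated violation designs show the
method degrades conservatively — clusters shrink rather than invent
false pairs). No credible sets beyond the per-SNP share ranking, no
per-annotation priors, no cross-LD-block orchestration (one region per
run), and no imputation of missing summary statistics — SNPs absent in any
trait are dropped by the intersection join, because every configuration
needs every trait observed at its assigned SNP.
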