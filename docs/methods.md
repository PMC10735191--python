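# Methods

## Model and procedure

The analysis treats each genome as a tip of a rooted, branch-length-bearing
phylogeny and each genomic feature as a trait measured at the tips. Under
Brownian motion a continuous trait x is multivariate normal,
x ~ N(μ·1, σ²·C), where C_ij is the branch length shared by the
root-to-tip paths of tips i and j (C_ii is the depth of tip i). All signal
statistics are built on this matrix; μ and σ² are estimated by generalized
least squares: μ̂ = (1ᵀC⁻¹1)⁻¹1ᵀC⁻¹x and σ̂² = rᵀC⁻¹r/n with r = x − μ̂·1.
Linear solves use Cholesky factorizations throughout; explicit inverses
appear only in the test oracles.

### Blomberg's K

K = (MSE₀/MSE) / E[MSE₀/MSE], where MSE₀ = rᵀr/(n−1) is the ordinary
variance of the GLS-centered trait, MSE = rᵀC⁻¹r/(n−1) its
phylogenetically corrected counterpart, and
E[MSE₀/MSE] = (tr C − n/(1ᵀC⁻¹1))/(n−1) the Brownian expectation, so
E[K] ≈ 1 under Brownian motion. K is invariant to affine transforms of x.
The p-value is a one-sided permutation test (high K = strong signal) over
random reassignments of trait values to tips, with a +1 pseudo-count so
p > 0. With n_perm = 199 or 999 the attainable p-values make the nominal
0.05 level exact.

### Pagel's λ

C(λ) scales the off-diagonal entries of C by λ, leaving the diagonal
untouched. λ̂ maximizes the GLS profile likelihood over [0, λ_max] by
bounded scalar search (tolerance 1e-8), where λ_max is the largest value
keeping C(λ) positive definite — for a tree covariance,
max(diag C)/max(offdiag C), at least 1. λ̂ is reported unclipped; values
above 1 are possible and meaningful (stronger-than-Brownian correlation).

The test against λ = 0 is a likelihood-ratio test, but its null
distribution is **not** χ²(1): λ = 0 lies on the boundary of the parameter
space, and empirically (128-tip Yule trees, white-noise traits) only about
a fifth of null LRT statistics are positive, with the positive part
stochastically below χ²(1). A χ²(1) reference rejects at ≈ 0.005 and the
usual ½χ²(0)+½χ²(1) boundary mixture at ≈ 0.01 — both badly conservative.
Because the LRT under λ = 0 is pivotal (invariant to the trait's location
and scale), the package instead calibrates the test by Monte Carlo: n_sim
white-noise datasets with tip variances diag(C) are simulated, observed
and simulated statistics are evaluated on one shared λ grid (41 points on
[0, 1] plus 9 up to λ_max), and p = (1 + #{LRT_sim ≥ LRT_obs})/(n_sim+1).
This is exact up to Monte-Carlo error; measured type-I error at α = 0.05
is 0.05 within binomial error.

### Fritz & Purvis' D

For a binary trait, nodal values are estimated post-order as unweighted
means of the two daughter values (branch lengths play no role in the
observed sum), and d_obs is the sum over internal nodes of the absolute
daughter difference. Polytomies are resolved deterministically (by child
order, zero-length splits) before the sweep. Two nulls position d_obs:

* random: tip states shuffled with prevalence fixed (n_sim draws);
* Brownian: Brownian traits simulated on the tree (one Cholesky of C per
  tree, shared across draws) and thresholded so exactly the observed
  number of tips get state 1.

D = (d_obs − mean d_B)/(mean d_R − mean d_B), so a random trait gives
D ≈ 1 and a Brownian-threshold trait D ≈ 0. p_random is the fraction of
shuffle sums ≤ d_obs (clumping); p_brownian the fraction of Brownian sums
≥ d_obs (overdispersion). Prevalence is matched exactly per simulation
rather than re-drawn, so D calibration is not confounded by prevalence
variance.

### Phylogenetic PCA

The GLS root state a = (1ᵀC⁻¹1)⁻¹1ᵀC⁻¹X centers each trait; the
evolutionary covariance R = (X−1a)ᵀC⁻¹(X−1a)/(n−1) is eigen-decomposed
(eigenvalues descending; rank-deficient R yields trailing zeros); scores
are the centered data projected on the eigenvectors. Component signs are
fixed by making each component's largest-magnitude loading positive.
Per-trait contributions are squared loadings normalized per component.

### Cluster retrieval

Intervening-gene counts use contig gene rank (intervening = rank
difference − 1), not base pairs; the 30 kb consolidation gap is measured
between cluster spans (next span start − previous span end − 1) and is
strict (< 30 000), while every score/identity/coverage threshold is
inclusive ("minimum" read as ≥). Chaining is greedy left-to-right and
consolidation runs to a fixed point; a brute-force fixed-point merge over
adjacent blocks is the test oracle. A lone core homolog is not a cluster:
`min_cluster_genes` defaults to 2 (configurable; the choice is open in the
underlying protocol). Strand is stored but ignored — the rules are
strand-agnostic. A gene matching core queries of several classes
contributes all of them, which is what produces hybrid class labels.

### Reference-match QC

"Aggregate bitscore ≥ 100 × cluster gene quantity" is read with "gene
quantity" = the number of **matched** reference genes n (default); a flag
switches to the reference's full gene count, since the wording is
genuinely ambiguous — under the alternative reading the aggregate rule is
dominated by the 60 % gene-fraction rule for large references. Redundancy
removal keeps, per (candidate, reference) pair and reference gene, the
single best-bitscore hit (ties broken lexicographically by candidate gene
id); one candidate gene hitting several reference genes is kept, since
gene fission in the candidate is legitimate. Boundary equality passes on
both rules.

### Family network

This is a self-contained family-network implementation, not a clone of any
existing tool: domain sequence similarity uses greedy best-pair matching
of domain copies (copy similarity 1 − |identity difference|, unmatched
copies dilute via a max(n_a, n_b) denominator), synteny uses unordered
adjacent domain-type pairs, and presence–absence is a Jaccard index over
domain types. The degradative-cluster weight preset (0.63/0.35/0.02, core
boost 2×) is the analysis configuration; the "default" preset
(0.75/0.20/0.05, boost 4×) is conventional configuration for mixed
classes. Family/clan cutoffs (0.30/0.70) are free parameters chosen for
the synthetic benchmarks; families are connected components at the family
cutoff, clans at the clan cutoff, so the family partition always refines
the clan partition.

### Ecology screen

E:NE = mean count in endophyte genomes / mean count in non-endophyte
genomes (M:S analogously for mycotroph/saprotroph). "Potential" endophytes
count as endophytes by default (policy `exclude` drops them); "unknown"
labels are always excluded. A zero reference mean with a positive focal
mean reports +∞ (which exceeds any ratio cutoff); 0/0 is undefined and
never flags. A trait is flagged per metric when the statistic is ≤ 0.8,
its p-value > 0.05, and the ratio > 2; `flagged_any` is the union of the
K and λ flags. A parallel D-based flag (D > 1, p_brownian ≤ 0.05,
ratio > 2) is reported alongside but kept out of `flagged_any`, matching
how the candidate tables are built from K and λ only. Group-difference
tests are Welch's t or Wilcoxon rank-sum with Holm step-down adjustment.

## Synthetic data: what it emulates, and what it does not

Calibration trees are Yule (pure-birth, rate 1), hence ultrametric —
matching the time-calibrated intuition behind C; after the n-th
speciation the clock runs forward by the Exp(n·birth) waiting time so no
zero-length cherry makes C singular. Traits follow exactly the models the
statistics assume (Brownian, λ-scaled, white noise), binary traits use
exact prevalence counts. The genome benchmark plants each cluster on its
own contig with hits clearing every retrieval threshold by a ±20 % margin
and decoys failing at least one threshold by the same margin; boundary
behaviour (inclusive score thresholds, strict 30 kb) is exercised by
separate deliberate fixtures, not by sampling near the cutoffs.

Passing these benchmarks therefore shows that the implementation does what
the model says — it does **not** show robustness to what real data add:
non-ultrametric or mis-estimated trees, assembly fragmentation (split
contigs truncating clusters), annotation errors, overdispersed count noise
on traits, correlated traits, or ecologies confounded with phylogeny.
Trait counts are modelled as (clipped) Gaussians, not discrete counts.

## Default problem sizes

Calibration checks use 200 replicates on 128-tip trees with 500
simulations per null (the statistics are vectorized across null draws, so
a full calibration run takes on the order of a minute); the screen
benchmark uses 100 replicates of 64 tips with 5 control traits and
n_perm = n_sim = 199; permutation/simulation defaults in the API are
999/1000. Counts were chosen so Monte-Carlo error is comfortably inside
the ±0.10 / ±0.05 calibration bands.

## Numerical choices and degenerate inputs

Cholesky-based solves everywhere; singular C is an error (not silently
regularized), except a 1e-12 diagonal jitter when *simulating* Brownian
traits. Constant traits and single-state binary traits raise
`DegenerateTraitError` and are skipped with a warning by the batch driver.
Gene-rank ties break by (start, end, gene_id); QC dedupe ties by candidate
gene id; family ids are the lexicographically smallest member. All
randomness flows through explicit seeds or `numpy.random.Generator`
objects; fixed seeds give byte-identical outputs, including the pipeline's
TSVs.

## Known limitations

* λ's Monte-Carlo test adds simulation cost per trait; for thousands of
  traits, lower `n_sim` (p-value resolution degrades accordingly).
* D's observed statistic ignores branch lengths by construction; very
  unbalanced trees push both null means together and inflate D's variance.
* The family network's domain "identity" scalar is a one-dimensional proxy
  for sequence similarity; profiles derived from retrieval output carry
  query identities only, not alignments.
* The screen treats traits independently; no multiplicity control is
  applied across the candidate flags themselves (Holm is applied within
  the group-comparison tables).
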