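# Methods

## Model and test

A region of L variants is tested for association with a phenotype through
the score statistic of the generalized linear model `g(E[y]) = b0 + G b`:
`U_l = Σ_n (y_n − ȳ)(g_nl − ḡ_l)`, `V = Cov(G) · Σ_n (y_n − ȳ)²`, and
`T0 = U'V⁻U`, asymptotically χ²(rank V) under the null.  The partitioned
test decorrelates the scores with an upper-triangular factor `A'A = V`
(`S` solves `A'S = U`), sums squared decorrelated scores within each of K
prior-defined groups (`t_k`), maps each group to one degree of freedom
through `H_k = P₁⁻¹(P_{L_k}(t_k))`, and rejects on `T1 = Σ H_k ~ χ²(K)`.

Assumptions: unrelated individuals, variants coded as minor-allele counts,
and a phenotype (or adjusted residual) whose permutations are exchangeable
under the null.  The statistic is not invariant to variant ordering
(the triangular decorrelation fixes a basis), so variants are always
ordered by genomic position with ties broken by variant id before
factorization.  T0 itself is basis-free and unaffected.

## Numerical choices

* **Covariance divisor.**  `Cov(G)` uses the maximum-likelihood divisor
  1/N (matching the score-test derivation); `divisor="n-1"` is available.
* **Singular V.**  Perfect LD or monomorphic-adjacent structure makes V
  singular.  The generalized Cholesky zeroes pivot rows below
  1e−10 × max diag(V) (float-stable rank detection), the decorrelating
  solve falls back to the minimum-norm least-squares solution, and
  `T0 = U'V⁺U` uses the Moore–Penrose pseudoinverse; all three agree via
  `S'S = U'V⁺U`.  Matrices indefinite beyond the tolerance raise an error
  naming the smallest eigenvalue.
* **Collapse saturation.**  For large `t_k`, `P_{L_k}(t_k)` is
  numerically 1 and a naive quantile transform returns infinity.  The
  1-d.f. tail inverts exactly in log space:
  `H = ndtri_exp(log SF_{L_k}(t_k) − log 2)²`, because
  `SF₁(h) = 2Φ(−√h)`.  Where even `log SF` underflows, the leading term of
  the upper incomplete gamma is substituted.  The transform is finite and
  order-preserving at any magnitude.
* **Monomorphic variants** are dropped with a warning (zero score, zero
  covariance row); each variant is recoded so the counted allele has
  sample frequency ≤ 0.5, with exact ties keeping the input coding.

## Permutation inference

The phenotype vector is permuted B times (default 1000; B ≥ 100 enforced);
genotypes and partition stay fixed.  Because Σ(y−ȳ)² is
permutation-invariant, V and its factor are computed once per region.  The
p-value is (r+1)/(B+1) with ties counted as exceedances (conservative).

In the default `empirical-cdf` mode each group's null CDF is a
Gaussian-kernel estimate fitted on its B permutation draws of `t_k` and
applied to observed and permuted replicates alike.  The same draw set
serves both CDF estimation and the T1 null — reusing it makes the
procedure slightly conservative; `split_cdf=True` fits the CDFs on the
first half of the permutations and forms the null from the second half.

**Bandwidth.**  The kernel-CDF bandwidth minimizes the asymptotic MISE,
`h* = (π^{-1/2} / (n R(f')))^{1/3}`, with the curvature functional
estimated by the standard plug-in recursion (normal-reference start at
order 2·stages, pairwise Gaussian functional estimates walking down to
ψ₂; default 2 stages).  Degenerate intermediates fall back to the
normal-reference rule `h = σ(4/n)^{1/3}` with a robust σ
(min of SD and IQR/1.349).  On boundary-supported nulls such as χ²(2) the
functional estimate absorbs part of the boundary spike, which shrinks h —
harmless for CDF estimation (undersmoothing tends toward the empirical
CDF) and beneficial at the boundary; the sup-norm consistency of the
fitted CDF is verified in the tests.  Fitted values are clamped to
[1/(B+1), B/(B+1)] so the downstream χ²(1) quantile never saturates.

## Stratification and covariates

Phenotype, genotype and covariates are projected off the top k principal
components (default 10) of the per-variant standardized genotype matrix
(centered at 2p, scaled by √(2p(1−p))) — a standard PCA equivalent of the
dedicated stratification tools, requiring no external binary.  Covariates
are then regressed out of the adjusted phenotype by OLS and the residuals
are tested against the adjusted genotype.  Dichotomous phenotypes pass
through the same linear operations and their residuals are treated as
quantitative.  Because standardized genotype columns are centered, the PC
loadings are orthogonal to the intercept, so residuals are orthogonal to
both the covariate design and the PCs.

## Theoretical power

Under the alternative T0 is approximately noncentral χ²(L, r); score-test
power is `1 − P_{L,r}(q_{1−α,L})`.  With all causal variants in one group
of size L1 (uncorrelated with the rest), `t_1 ~ χ²(L1, r)` carries the full
noncentrality and the partitioned test's power is
`1 − P(H₁ + χ²_{K−1} < q_{1−α,K})`, evaluated by adaptive quadrature of
the convolution over the χ²(K−1) measure.  The integral is transformed to
the probability scale (u = P_{K−1}(x)), which removes the density
singularity at zero and bounds the integrand; absolute/relative tolerance
1e−8, with an error above 1e−6 raising rather than returning a silently
inaccurate value.  K = 1 degenerates to a point mass at zero and is
special-cased; r = 0 returns exactly α.  With the causal signal split over
several groups no closed form exists; power is estimated by Monte-Carlo
over per-group noncentral χ² draws (default 500,000 paths, seedable).

`estimate_ncp` recovers r from draws of T0 via the moment identity
`E[χ²_L(r)] = L + r`, clipped at zero — an empirical link between effect
size and noncentrality that requires no distributional derivation.

The canonical comparison layouts are exposed as panels: (1) L=10, K=2,
L1 ∈ {2,4,6,8}; (2) L=100, K=10, L1 ∈ {10,20,30,40}; (3) L=50, L1=5,
K ∈ {8,16,24,32}; (4) L=54, K=6, equal group sizes, total r split equally
over m ∈ {2,3,4,5} causal groups.  Note the maximum Panel-1 gain computed
from these formulas is 18.7 percentage points (at L1=2, r≈9.5), verified
independently by quadrature and by direct Monte-Carlo of `H₁ + χ²₁`.

## Case-control simulator

The simulator replaces forward-in-time population simulation with a
parametric stand-in: site allele counts are drawn from a rare-skewed
frequency spectrum (∝ 1/x on {1, …, n_hap−1}; purifying selection only
sharpens the neutral 1/x shape toward rare alleles), and haplotypes carry
alleles independently across sites.  Defaults mirror the study conditions:
4000 haplotypes per pool, a 3 kb region, and a site density of 1/60 per bp
(~50 segregating sites, a plausible nonsynonymous site count for a
selected coding region).  What the pools deliberately lack is linkage
disequilibrium and a selection-driven site-frequency joint distribution;
externally simulated pools can be imported through the rectangular pool
file format when realistic LD matters.  Passing tests therefore certify
the statistical machinery and the direction of power comparisons, not the
exact power levels of any particular demographic model.

Individuals are random haplotype pairs; disease follows
`logit P(D) = logit(0.01) + Σ_l log(OR_l)·e_l` (1% wild-type baseline,
effects additive on the log-odds scale).  Scenarios: **Rare** — a random
half of the rare sites (pool MAF < 1%) causal at OR 3 (an odd count rounds
to nearest, ties down); **LowFrequency** — one random site with MAF in
[1%, 5%] at OR 2.5, falling back to the lowest-MAF site above 5%;
**Common** — one random site with MAF > 5% at OR 1.5; **Interaction** —
half the rare sites at OR 6 per qualifying haplotype, counting a haplotype
only when the rare minor allele is in cis with the minor allele of a
pre-chosen common partner site (the exposure is the count of qualifying
haplotypes, 0/1/2).  Case/control quotas (500+500; 1000+1000 for
Interaction) are filled exactly by batched rejection sampling with an
explicit draw budget.

## Problem sizes used in the shipped checks

The test suite runs desk-scale versions of the studies: 200 null
replicates at N=500, L=20, B=500 for calibration; 200 replicates per
phenotype model over 10 pools at B=500 for the simulation study; 10⁵–10⁶
Monte-Carlo draws for power-engine cross-checks.  Full-scale settings
(100 pools, 1000 replicates, B=1000) are available through `StudyConfig`.

## Known limitations

* The partitioned statistic depends on variant ordering through the
  Cholesky basis; position ordering is a convention, not an optimum.
* Site-independent pools understate LD; power under strong LD should be
  studied with imported pools.
* The kernel-CDF mode assumes the permutation draws of `t_k` form an
  absolutely continuous null; extremely sparse regions (few carriers) can
  make the draws near-discrete, where the clamped empirical CDF dominates
  the kernel refinement.
* Related individuals, dosage genotypes and X-chromosome coding are out
  of scope.
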