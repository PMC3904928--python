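# priorpart

Region-based association tests for sequencing studies lose power when a
region's signal is carried by a few variants drowned in neutral noise: the
classical score statistic spends one degree of freedom on every variant.
`priorpart` implements a partitioned score test that uses prior knowledge —
observed minor allele frequency, functional annotation, or any explicit
grouping — to split a region's variants into K groups, collapse each
group's signal to a single degree of freedom, and test with K d.f. instead
of L.  The package is aimed at statistical geneticists analysing
rare-variant burden in candidate regions or exome data, and at
methodologists who want the test's theoretical power surface and a
case-control simulation bench.

## The statistic

For genotypes `G` (N samples × L variants, minor-allele counts) and
phenotype `Y`, the score test of no association under a GLM is

    T0 = U' V⁻ U,        U_l = Σ_n (y_n − ȳ)(g_nl − ḡ_l),
                         V = Cov(G) · Σ_n (y_n − ȳ)²,

asymptotically χ² with rank(V) d.f. (`V⁻` is the Moore–Penrose
pseudoinverse, so regions in perfect LD are handled).  With a generalized
Cholesky factor `A'A = V`, the decorrelated scores `S` solving `A'S = U`
are asymptotically standard normal under the null.  Given a partition of
the variants into groups `G_1 … G_K`,

    t_k = Σ_{l ∈ G_k} s_l²,      H_k = P₁⁻¹( P_{L_k}( t_k ) ),
    T1  = Σ_k H_k,

where `P_l` is the χ²(l) CDF.  Each `H_k` is χ²(1) under the null, so `T1`
is χ²(K): a group containing only neutral variants costs 1 d.f. instead of
`L_k`.  Because the χ² approximation for `t_k` can be poor at moderate N,
significance is assessed by phenotype permutation, by default replacing
`P_{L_k}` with a Gaussian-kernel CDF estimate of the permutation null
(multi-stage plug-in bandwidth).

Companion modules provide PC-projection/covariate adjustment for
stratified samples, the theoretical power of both tests via noncentral-χ²
convolution, and a case-control simulator over synthetic haplotype pools
with four phenotype scenarios (Rare, LowFrequency, Common, Interaction).

## Worked example

```python
import numpy as np
from priorpart import (
    generate_haplotype_pool, make_model, sample_replicate,
    prepare_genotypes, maf_partition, permutation_test,
)

pool = generate_haplotype_pool(n_hap=4000, region_bp=3000, seed=7)
spec = make_model(pool, "LowFrequency", seed=8)          # one causal SNP, OR 2.5
rep = sample_replicate(pool, spec, n_cases=500, n_controls=500, seed=9)

gm = prepare_genotypes(rep.genotypes)                     # recode, sort, drop monomorphic
partition = maf_partition(gm, threshold=0.01)             # rare (<1%) vs common groups
result = permutation_test(gm, rep.phenotype, partition, B=1000, seed=10)

print(f"region: {gm.n_variants} variants, K={result.df} groups {result.group_names}")
print(f"T0 = {result.T0:.2f}   T1 = {result.T1:.2f}")
print(f"partitioned-test p = {result.p_value:.4f}   score-test p = {result.p_value_score:.4f}")
```

Output:

```
region: 47 variants, K=2 groups ['common', 'rare']
T0 = 62.94   T1 = 8.55
partitioned-test p = 0.0120   score-test p = 0.0430
```

The causal low-frequency allele sits in one group, so collapsing the 47
degrees of freedom to 2 concentrates the signal: the partitioned test's
permutation p-value (0.012) is smaller than the classical score test's
(0.043) on the same replicate.  Both p-values use the estimator
(r+1)/(B+1) over B = 1000 phenotype permutations.

The same analysis is available from the shell:

```sh
priorpart test --vcf region.vcf --pheno pheno.tsv \
    --maf-threshold 0.01 --permutations 1000 --seed 10 --out result.tsv
priorpart power --panel 1 --out panel1.tsv
priorpart study --models Null,Rare,Common --replicates 200 --out study.tsv
```

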