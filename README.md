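# ibdshare

Detection of extended haplotypes shared identical-by-descent (IBD) by
multiple case individuals in SNP-array case/control data, scored by a
likelihood ratio of recent descent against chance sharing and evaluated
against an empirical extreme-value null built from controls.

## The problem and the method

Recent founder mutations sit on long ancestral haplotypes that have been
shortened by only a few generations of recombination.  Among cases of a
disease driven by such a mutation, a small number of individuals —
often with no known relationship — share an unusually long, unusually
rare haplotype around the mutation.  `ibdshare` looks for exactly that
signature in unphased genotypes:

1. **LD partition.**  Each chromosome is divided into LD blocks and
   recombination-hotspot SNPs.  A SNP pair is in *strong* LD when the
   one-sided upper 95% profile-likelihood bound of |D′| exceeds 0.98 and
   *weak* below 0.90; blocks grow 5′→3′ while strong/(strong+weak) > 0.95
   over all within-block pairs and adjacent gaps stay ≤ 50 kb.  A purely
   map-based rule (adjacent SNPs < 0.001 cM apart within 10 kb) is
   available when no controls exist.
2. **Haplotype catalog.**  Within each block, haplotype frequencies
   h_ji are estimated from controls by EM over all haplotype pairs
   consistent with each genotype.  A haplotype never seen in *m*
   controls is assigned h_u = 1 − 0.95^(1/2m).
3. **Catalog phasing.**  Case genotypes are explained block-by-block by
   all compatible catalog haplotype pairs (a unique pair for the vast
   majority of blocks), keeping phase ambiguity explicit.
4. **Pairwise sharing.**  Sample pairs are scanned for extended
   haplotypes: matching runs over blocks and hotspot SNPs, tolerating
   mismatches at ≤ 1% of SNPs and none within 20 SNPs of either end,
   kept when longer than a threshold (1 cM by default).
5. **Groups.**  Pairwise segments are assembled into groups of k ≥ 2
   individuals sharing the same block haplotypes, each with a *core*
   carried by every member; individuals sharing the full core plus at
   least half the threshold are rescued into the group.  Groups larger
   than 2% of the case pool (minimum 20) are set aside.
6. **Score.**  Each group gets the log10 likelihood ratio of IBD versus
   chance:

       P_j    = h_ji^k_j · 2^k_j / C(2k, k)          per block j
       L(H0)  = C(s, k) · ∏_j P_j                     chance sharing
       L(H1)  = 0.5^(n·k),   n = 100 / mean d_g (cM)  recent descent
       score  = log10 L(H1)/L(H0)

7. **Empirical null.**  Drawing s controls at random and recording the
   genome-wide maximum score, at least 1000 times, yields extreme
   values that closely follow a Gumbel distribution; its upper tail
   turns an observed score into a *quasi-P* value.
8. **Control filter.**  Significant haplotypes equally shared by
   controls (full core overlap, > 50% of the extended haplotype, no
   carrier-frequency difference by chi-square) are removed.

A founder-haplotype simulator (Poisson crossovers at 1 per 100 cM per
meiosis, no interference) and a block-structured synthetic-population
generator make the whole procedure testable without any external data.

## Worked example

```python
import numpy as np
from ibdshare import (FounderSimSpec, RunConfig, SharingScan,
                      generate_synthetic_population, make_founder_dataset)

pop = generate_synthetic_population(600, seed=2, n_snps=2000, span_cm=100)
spec = FounderSimSpec(age=10, n_carriers=10, n_cases=200, n_controls=400)
cases, controls, truth = make_founder_dataset(pop, spec,
                                              np.random.default_rng(7))
scan = SharingScan(cases, controls, pop.markers, pop.gmap,
                   RunConfig(min_cm=1.0, iterations=100))
results = scan.fit(seed=1)
print(results.frame().head(3)[["k", "mean_cM", "log10_LR", "quasi_P",
                               "status"]])
```

prints (the top-ranked groups are the inserted founder haplotype and
overlapping variants of it):

```
    k    mean_cM    log10_LR       quasi_P       status
0  20   9.570210  965.763167  3.078903e-10  significant
1  20  11.793113  938.612425  6.750656e-10  significant
2  20   7.773300  912.385204  1.441115e-09  significant
```

Here `k` is the number of case individuals in the group, `mean_cM` the
mean genetic length each member shares, `log10_LR` the descent-vs-chance
score, and `quasi_P` its upper-tail probability under the control-derived
Gumbel null (location ≈ 208, scale ≈ 35 in this run, so scores near 1000
are far beyond anything chance sharing produces).  All ten simulated
carriers are members of significant groups.

The same pipeline is available from the shell:

```bash
ibdshare simulate --n-cases 200 --n-controls 400 --age 10 --carriers 10 \
    --seed 2 --out sim
ibdshare run --cases sim_cases.ped --controls sim_controls.ped \
    --map sim.genmap --iterations 100 --seed 1 --out results/
```

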