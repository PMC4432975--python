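# Methods

This note records the model, its assumptions, the numerical choices, and
the places where the design was genuinely open, in enough detail that a
maintainer can predict the package's behaviour without reading the code.

## Model overview

The package detects extended haplotypes shared identical-by-descent
(IBD) by several case individuals and asks whether such sharing is
surprising relative to equivalent analyses in controls.  Its premise is
the population-genetic asymmetry between *descent* and *chance*:
identity-by-state between unrelated chromosomes in an outbred population
decays within a centimorgan or two, while a haplotype inherited from a
common ancestor *n* generations back survives with expected length
100/n cM per flank.  A long haplotype shared by k individuals therefore
carries evidence for recent common descent, quantified per LD block and
combined across the shared region.

### Likelihood ratio

For a group of k individuals sharing haplotype i (population frequency
h_ji) in block j, with k_j of them covering that block,

    P_j   = h_ji^k_j · 2^k_j / C(2k, k)
    L(H0) = C(s, k) · ∏_j P_j
    L(H1) = 0.5^(n·k),  n = 100 / d̄_g

where s is the case-pool size and d̄_g the members' mean shared genetic
length.  The age n is kept real-valued.  Two properties of these
formulas matter in practice: L(H0) is not a probability (the C(s,k)
prefactor can push it above 1), and the C(2k,k)^-1 factor applies per
block regardless of k_j, so the score grows with both group size and
span.  Neither matters for inference because the score is only ever
compared with an empirical null built by the same formulas on controls.

### Empirical extreme-value null

Each Monte-Carlo iteration draws s samples from the control pool (padded
to 2s with virtual samples generated from the catalog when controls are
scarce), reruns detection + grouping + scoring with the case settings,
and records the genome-wide maximum score among groups within the size
cap.  The recorded maxima are fitted with a maximum-likelihood Gumbel
(moment-based start: β₀ = sd·√6/π, μ₀ = mean − 0.5772·β₀), checked by an
Anderson–Darling test, and an observed score's *quasi-P* is the fitted
upper-tail probability.  Using per-iteration maxima makes the null a
genome-wide multiplicity correction by construction.

An option exists to exclude each iteration's recorded haplotype from
later maxima (`RunConfig.null_exclusion`), motivated by small control
pools being reused across iterations.  It is **off by default**: on the
short simulated genomes used here the pool of distinct top chance
haplotypes is small, exclusion forces the maxima downward iteration by
iteration, and the resulting null is visibly anti-conservative (in a
no-signal calibration experiment the genome-wide best group reached
quasi-P < 0.05 three times as often as nominal) besides skewing the
Gumbel fit.  Without exclusion the maxima are i.i.d. draws of exactly
the statistic evaluated on cases, which is what calibration requires.

## Pipeline steps and their parameters

| parameter | default | meaning |
|---|---|---|
| `min_cm` | 1.0 cM | pairwise sharing selection threshold (0.5 for more sensitivity; 0.25 reserved for post-significance rescue) |
| `cap_fraction` | 0.02 | group-size cap as a fraction of the case pool |
| `cap_min` | 20 | absolute floor of the cap (see below) |
| `iterations` | 1000 | Monte-Carlo null iterations (≥ 1000 recommended; scaled studies use fewer) |
| `alpha` | 0.05 | quasi-P significance level |
| `chi_alpha` | 0.05 | chi-square level of the case/control removal filter |
| `rescue_factor` | 0.5 | rescued members need `rescue_factor·min_cm` of shared length around the full core |
| mismatch budget | 1% of SNPs | tolerated non-complying SNPs per extended haplotype |
| clean ends | 20 SNPs | no mismatch within the first/last 20 SNPs |
| strong / weak LD | bound > 0.98 / < 0.90 | one-sided upper 95% profile bound of D′ |
| block ratio | > 0.95 | strong/(strong+weak) over within-block pairs |
| block gap | 50 kb | maximum adjacent-SNP gap inside a block |

**D′ bound.**  Two-locus haplotype frequencies by EM; allele frequencies
held fixed; the multinomial log-likelihood is profiled over |D′| on a
1000-point grid (both sign branches, elementwise maximum); the bound is
the largest |D′| within χ²₁(0.90)/2 of the maximum.  Pairs with fewer
than 10 complete genotypes are uninformative; uninformative pairs enter
neither side of the 0.95 block ratio.  The "strong" rule is
upper-bound-only, with no additional lower-bound requirement.

**Catalog.**  Plain EM over all within-block haplotype pairs compatible
with each genotype (uniform start, convergence at max |Δf| < 1e-8 or 500
iterations; the log-likelihood is asserted non-decreasing).  Haplotypes
below 1/(4m) are pruned and mass renormalised.  Genotypes whose
ambiguity would exceed 2²⁰ compatible pairs force a mid-block split for
cataloguing (never reached at the simulated block sizes).  Missing
genotypes are marginalised by the EM and act as wildcards in phasing.

**Phasing scenarios.**  (A) unique compatible catalog pair, (B) several
pairs (all kept), (C) one catalog haplotype plus a forced non-catalog
partner carrying frequency h_u = 1 − 0.95^(1/2m), (D) nothing compatible
— treated as genotyping error: the block cannot seed sharing but does
not stop extension through it.  At most one unknown haplotype per pair;
two samples' unknowns match only when their forced allele strings are
identical.  Candidate sets are stored as per-block uint64 bitmasks (one
bit per haplotype id; ids ≥ 63 share the top bit, with a warning).

**Detection.**  Two samples match at a block when their candidate sets
intersect, and at a hotspot SNP when some allele is consistent with both
genotypes (heterozygous or missing genotypes are consistent with
everything).  Maximal matched runs are extracted vectorially; runs are
bridged across mismatching units while the 1% budget and the 20-SNP
clean-end windows hold (greedy left-to-right; a bridged unit therefore
always has ≥ 20 matched SNPs on both flanks).  A segment must contain a
matched block — hotspot-only identity cannot seed sharing.

**Group assembly.**  Groups are seeded per (block, haplotype id): the
group for a seed is the set of samples joined by pairwise segments
sharing that haplotype at that block, each member's interval being the
hull of its supporting segments (contiguous, as all contain the seed).
When chance sharing is sparse this reproduces a transitive merge of
overlapping pair segments on the same allele; in dense regimes it
decomposes common-haplotype "corridors" into per-seed groups rather
than chaining everything into one core-less component.  Over-cap seeds
are refined into multi-block haplotype chains (one branch per haplotype
at the added block, alternating sides, using segments ≥ 4×`min_cm` —
chains supported only by near-threshold segments cannot outscore
directly kept seeds), emitting each branch where it first fits the cap.
From every node with more than six members and long median segments a
dominant-path purification follows the best-supported haplotype outward
and emits the shrinking member sets, so a descent group diluted by
chance sharers is also represented by its consistent core subgroup.
Identical member sets are deduplicated.  The group core is the
contiguous unit run around the seed covered by all members with a
common candidate haplotype.

**Cap.**  `max(ceil(cap_fraction·s), cap_min)` with `cap_min = 20`: the
fraction matches the 2%-of-1000 analysis criterion, and the absolute
floor keeps the criterion meaningful for the small case pools used in
scaled studies (a pure 2% of 200 would be 4 and would discard the very
groups the method exists to find).

**Scoring semantics.**  Per block the shared haplotype is taken from the
AND of the covering members' candidate masks; k_j is the covering count;
when several haplotypes are common to all covering members the
higher-frequency one enters the evaluation; blocks with no common
candidate contribute nothing (conservative: every P_j < 1, so dropping
factors only lowers the score).  Hotspot SNPs never enter the
likelihood.  Non-catalog haplotypes score at h_u.

**Membership completion.**  Two passes run for significant groups,
*after* significance is decided, so that scores and quasi-P values
always reflect the pairwise-detected membership (running them before
scoring inflates k and span in a way no tractable per-iteration null
can mirror, which was measurably anti-conservative).  First, the
pairwise merge rule is applied once more around the group: a non-member
joined to a member by a detected segment that overlaps the group span
and agrees with the group's shared haplotype at every block of the
overlap joins the group — this recovers sharers with short windows whom
the seed-based assembly missed; when more candidates qualify than the
cap allows, the longest consistent overlaps are preferred.  Second, the
rescue scan: a sample joins when some candidate haplotype of it
intersects the group's core haplotype at every core unit and its
consistent stretch around the core reaches `rescue_factor·min_cm`;
re-invoking at 0.25 cM (`ScanResults.loosen_rescue`) implements the
loosened criterion for regions with confirmed sharing.  If a pass would
push the group past the cap, the previous membership is kept.  Power
counting sees the completed membership.

**Case/control filter.**  A significant group is removed when at least
one control carries the complete core and more than half of the extended
haplotype, and the carrier-count chi-square (no continuity correction)
gives p above `chi_alpha`.

## Synthetic data: what it emulates, and what it does not

`generate_synthetic_population` builds one chromosome (default 2000 SNPs
over 100 cM) as alternating LD blocks and hotspot SNPs.  Blocks have
geometric sizes (3–10 SNPs, short sizes favoured) and carry 4–6
haplotypes built under a perfect phylogeny (every within-block SNP pair
is in complete LD, so the LD partition is well-defined) with a mildly
skewed Dirichlet(3) frequency spectrum floored at 0.02.  Individuals
are drawn as two independent chromosomes: block haplotypes sampled
independently per block in proportion to frequency, hotspot alleles from
a first-order Markov transition to the preceding marker (close to
independence).  Genetic distance is negligible inside blocks
(10⁻⁴ cM per link) and exponentially distributed across the gaps
between units; physical spacing is 2 kb within and 8 kb between units.

The governing realism target is the decay of chance identity: with only
~20 markers per cM, per-marker genotype compatibility can never make
1 cM chance matches rare (the strongest per-SNP evidence against
sharing, opposite homozygotes at 50% allele frequency, carries only
−ln(7/8) nats), so the generator carries the decay through block
diversity instead — unrelated chromosome pairs stop matching within a
couple of cM, as they do in real outbred data, while chance matches of
5–10 cM are effectively absent.  That is the regime in which extended
sharing is evidence of descent and in which the method is meant to
operate.  Under a low-diversity or strongly skewed spectrum, 10–20 cM
chance matches become common, conglomerates of cap-sized k tie with
genuine founder groups under the likelihood above, and no detector can
separate them: passing tests in the simulated world say nothing about
panels whose marker density fails to resolve chance identity.

Other things the simulator does not model: genotyping error and
missingness (phasing and detection handle them, but the power studies
run on clean data), between-block LD beyond the hotspot Markov chain,
population structure or admixture, mutation during transmission, and
multi-chromosome genomes (the pipeline supports several chromosomes;
the simulator emits one).

**Founder haplotypes** descend from a uniformly drawn ancestor
chromosome: per generation, crossovers fall as a Poisson process at 1
per 100 cM (no interference) and the mutation-carrying fragment
survives; the surviving interval overwrites one chromosome slot of each
carrier.  Each carrier's lineage applies n independent meioses, matching
the n·k meiosis count in L(H1).  Chromosome-end truncation shortens
intervals placed near the ends; validation of the 100/n length relation
therefore places the mutation centrally, where truncation is negligible
at the tested ages.

## Numerical and performance choices

Pairwise detection, group support, null iteration scoring, membership
counting inside refinement, and the merge-completion qualification all
operate on flat arrays, the hot loops as numba kernels; the per-node
scorer reproduces `score_group` exactly (verified against it in tests).
The null engine phases controls and detects segments once, then per
iteration only re-evaluates group membership for the drawn subset —
identical to re-running detection per draw, since pairwise detection is
per-pair independent.  Nodes are pre-ranked by a proxy of the dominant
score terms and the top 4000 kept (verified to reproduce the drawn
maxima of a twice-larger budget at study scale); a pool seed stays a
direct candidate while a drawn subset could still bring it under the
analysis cap (keep limit scaled by the pool/case-pool ratio — with a
fixed limit, larger control pools silently lose whole classes of seeds
and the null collapses).  Purification paths launch where a refinement
branch first crosses under the keep limit.  On the case side every
group is scored exactly; membership completion runs for the 200
top-ranked significant regions.

Determinism: a single seed feeds a `SeedSequence` whose children drive
virtual-sample padding and the null draws; all orderings are canonical,
so a fit is bit-identical given data, configuration and seed.

## Problem sizes used in the shipped studies

The scaled power study runs 20 replicates of 200 cases + 400 controls
on a 2000-SNP / 100 cM chromosome with 100 null iterations (about half
a minute per replicate); the calibration study runs 100 no-signal
replicates of 50 cases + 200 controls on 500 SNPs / 25 cM with 50
iterations; the power-monotonicity grids use 60 cases + 120 controls on
800 SNPs / 40 cM.  These sizes were chosen as the smallest at which the
studied effects are comfortably larger than Monte-Carlo noise.

## Known limitations

- The likelihood treats blocks as independent under H0; residual
  between-block LD is absorbed empirically by the null rather than
  modelled.
- Groups are anchored on seeds; two disjoint sharing events on the same
  haplotype chain that never overlap are reported as separate groups.
- The quasi-P calibration needs the control pool comfortably larger
  than the case pool (the shipped calibration study uses four times):
  near the 2s minimum, the null conditioned on one realised control set
  misses cohort-level chance clusters and the genome-wide best group is
  flagged at roughly twice the nominal rate on short genomes.  Cases
  and controls must also come from the same population; the
  case/control filter mitigates but does not remove stratification
  artefacts.
- Carriers whose surviving founder segment is so short that it cannot
  contain any detected core (roughly, shorter than the pairwise
  threshold) are genuinely unrecoverable by the rescue rule, which
  bounds attainable carrier-level sensitivity slightly below 1.
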