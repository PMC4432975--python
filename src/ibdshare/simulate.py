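"""Founder-haplotype meiosis simulation and synthetic population generation.

The synthetic population emulates SNP-array data with haplotype-block
structure: a marker panel (default 2000 SNPs over 100 cM) of LD blocks of
3-10 SNPs carrying 2-6 haplotypes drawn under a perfect phylogeny (so all
within-block SNP pairs are in complete LD) with Dirichlet frequency
spectra, separated by recombination-hotspot SNPs in weak LD with their
neighbours.  Individuals are sampled from this truth catalog exactly as
virtual samples are (independent block haplotypes, first-order Markov
hotspot alleles), so the ground-truth partition and catalog are known.

A founder haplotype of age ``n`` generations is made by picking an
ancestor chromosome and a mutation SNP, then shortening the surrounding
haplotype through ``n`` rounds of meiosis with Poisson crossovers (rate 1
per 100 cM, no interference), keeping the mutation-carrying fragment.
The surviving interval is written over one allele slot of each carrier,
mirroring descent of the mutation through n meioses per lineage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .catalog import ChromCatalog, generate_virtual_haplotypes, \
    unknown_haplotype_frequency
from .ld import ChromPartition
from .markers import GeneticMap, MarkerTable


@dataclass
class FounderSimSpec:
    """Conditions of one founder-haplotype power scenario."""

    age: int                     # generations n
    n_carriers: int              # k
    n_cases: int                 # s
    n_controls: int
    mutation: object = "random"  # SNP index, cM position, or "random"
    seed: object = None

    def __post_init__(self) -> None:
        if self.age < 1:
            raise ValueError("founder age must be >= 1 generation")
        if not 2 <= self.n_carriers <= self.n_cases:
            raise ValueError("need 2 <= carriers <= case pool size")


@dataclass
class SimTruth:
    """Ground truth of one carrier's inserted founder interval."""

    carrier: int
    snp0: int
    snp1: int
    alleles: np.ndarray  # founder allele string over [snp0, snp1]
    slot: int = 1        # which chromosome copy was overwritten


def simulate_descendant_interval(mutation_cm: float,
                                 chrom_span_cm: tuple,
                                 n: int,
                                 rng: np.random.Generator) -> tuple:
    """Surviving cM interval around a mutation after n meioses.

    Starting from the full chromosome, each meiosis lays down crossovers
    as a Poisson process at 1 per 100 cM and keeps the fragment containing
    the mutation.  ``n = 0`` returns the full span.
    """
    lo, hi = float(chrom_span_cm[0]), float(chrom_span_cm[1])
    if not lo <= mutation_cm <= hi:
        raise ValueError("mutation outside chromosome span")
    a, b = lo, hi
    for _ in range(int(n)):
        length = b - a
        n_x = rng.poisson(length / 100.0)
        if n_x == 0:
            continue
        points = a + rng.random(n_x) * length
        below = points[points <= mutation_cm]
        above = points[points > mutation_cm]
        if len(below):
            a = float(below.max())
        if len(above):
            b = float(above.min())
    return a, b


def insert_founder(haplotypes: np.ndarray, ancestor: np.ndarray,
                   carriers, intervals, slot: int = 1):
    """Overwrite one allele slot of each carrier with the founder segment.

    ``haplotypes`` is the phased (2*n_samples, n_snps) matrix; carrier i's
    chromosome copy ``slot`` is replaced by ``ancestor`` over its interval
    (inclusive SNP indices).  Returns the modified copy and the SimTruth
    records; genotypes outside the intervals are untouched.
    """
    h = np.array(haplotypes, copy=True)
    n_samples = h.shape[0] // 2
    truths = []
    for carrier, (i0, i1) in zip(carriers, intervals):
        if not 0 <= carrier < n_samples:
            raise IndexError(f"carrier index {carrier} out of range")
        if i1 >= i0:
            h[2 * carrier + slot, i0:i1 + 1] = ancestor[i0:i1 + 1]
        truths.append(SimTruth(carrier=int(carrier), snp0=int(i0),
                               snp1=int(i1),
                               alleles=ancestor[i0:i1 + 1].copy(),
                               slot=slot))
    return h, truths


@dataclass
class SyntheticPopulation:
    """A generated population with its full ground truth."""

    chrom: str
    markers: MarkerTable
    gmap: GeneticMap
    partition: ChromPartition
    catalog: ChromCatalog          # truth catalog used for sampling
    haplotypes: np.ndarray         # (2*n_samples, n_snps)
    snp_cm: np.ndarray

    @property
    def genotypes(self) -> np.ndarray:
        return (self.haplotypes[0::2] + self.haplotypes[1::2]).astype(np.int8)

    @property
    def n_samples(self) -> int:
        return self.haplotypes.shape[0] // 2


def _perfect_phylogeny_block(length: int, n_haps: int,
                             rng: np.random.Generator) -> np.ndarray:
    """Block haplotypes with every SNP mutated once on a haplotype tree,
    guaranteeing |D'| = 1 for all within-block pairs."""
    haps = [np.zeros(length, dtype=np.int8)]
    snps = rng.permutation(length)
    # split the SNPs into n_haps-1 non-empty mutation events
    cuts = np.sort(rng.choice(np.arange(1, length), size=n_haps - 2,
                              replace=False)) if n_haps > 2 else []
    events = np.split(snps, cuts)
    for ev in events:
        parent = haps[rng.integers(len(haps))]
        child = parent.copy()
        child[ev] = 1
        haps.append(child)
    return np.stack(haps)


def generate_synthetic_population(
    n_samples: int,
    seed=None,
    n_snps: int = 2000,
    span_cm: float = 100.0,
    block_snps: tuple = (3, 10),
    block_haps: tuple = (2, 6),
    hotspot_prob: float = 0.5,
    chrom: str = "1",
) -> SyntheticPopulation:
    """Generate a block-structured population with known truth.

    Block haplotype frequencies follow a Dirichlet spectrum floored near
    0.04 so every haplotype is estimable; hotspot SNPs get Markov
    transitions close to independence (weak LD with neighbours).  Genetic
    distance within blocks is negligible (0.0001 cM per link); the
    ``span_cm`` budget is spread over inter-unit gaps with exponential
    weights.  ``n_samples = 0`` yields an empty matrix but a valid panel.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    first, last, is_block = [], [], []
    pos = 0
    while pos < n_snps:
        remaining = n_snps - pos
        if remaining < block_snps[0] + 1:
            # tail too short for a block + separator: emit hotspots
            for _ in range(remaining):
                first.append(pos); last.append(pos); is_block.append(False)
                pos += 1
            break
        # geometric block sizes: at array-scale marker spacing most LD
        # blocks span only a few markers
        size = block_snps[0] + int(rng.geometric(0.45)) - 1
        size = min(size, block_snps[1], remaining)
        first.append(pos); last.append(pos + size - 1); is_block.append(True)
        pos += size
        if pos < n_snps and rng.random() < hotspot_prob:
            first.append(pos); last.append(pos); is_block.append(False)
            pos += 1
    partition = ChromPartition(np.array(first), np.array(last),
                               np.array(is_block))

    cat = ChromCatalog(partition=partition,
                       m_ctrl=max(n_samples, 1),
                       h_u=unknown_haplotype_frequency(max(n_samples, 1)))
    prev_marginal = 0.5
    for u in range(partition.n_units):
        f, l = partition.first[u], partition.last[u]
        if partition.is_block[u]:
            length = l - f + 1
            # near-maximal haplotype diversity per block, mildly skewed:
            # chance identity between unrelated chromosomes then decays
            # within a couple of cM, as in outbred populations — the
            # premise that makes extended sharing evidence of recent
            # descent; the floor keeps every SNP polymorphic in control
            # samples of a few hundred
            hi = min(block_haps[1], length + 1)
            n_h = max(block_haps[0], hi - int(rng.random() < 0.25))
            haps = _perfect_phylogeny_block(length, n_h, rng)
            freqs = rng.dirichlet(np.full(n_h, 3.0))
            freqs = np.maximum(freqs, 0.02)
            freqs = freqs / freqs.sum()
            order = np.argsort(-freqs, kind="stable")
            cat.block_haps[u] = haps[order]
            cat.block_freqs[u] = freqs[order]
            prev_marginal = float(np.sum(
                cat.block_freqs[u] * cat.block_haps[u][:, -1]))
        else:
            base = rng.uniform(0.3, 0.7)
            delta = rng.uniform(-0.1, 0.1)
            q0, q1 = base - delta, base + delta
            trans = np.array([[1 - q0, q0], [1 - q1, q1]])
            if u > 0:
                cat.transitions[u] = trans
            marg = prev_marginal * q1 + (1 - prev_marginal) * q0
            cat.hotspot_freq[u] = float(marg)
            prev_marginal = marg
        if u > 0 and partition.is_block[u]:
            # block sampling is independent of the 5' context
            cat.transitions[u] = np.array([[0.5, 0.5], [0.5, 0.5]])

    # physical and genetic coordinates
    bp = np.zeros(n_snps, dtype=np.int64)
    cm = np.zeros(n_snps, dtype=np.float64)
    unit_of = partition.unit_of_snp() if n_snps else np.array([], dtype=int)
    cur_bp = 1_000_000
    for i in range(n_snps):
        if i > 0:
            same_unit = unit_of[i] == unit_of[i - 1]
            cur_bp += 2_000 if same_unit else 8_000
        bp[i] = cur_bp
    # spread the cM budget over inter-unit gaps
    within = 0.0001
    gap_idx = [i for i in range(1, n_snps) if unit_of[i] != unit_of[i - 1]]
    budget = span_cm - within * (n_snps - 1 - len(gap_idx))
    weights = rng.exponential(1.0, size=len(gap_idx))
    gap_cm = budget * weights / weights.sum() if len(gap_idx) else []
    g = dict(zip(gap_idx, gap_cm))
    for i in range(1, n_snps):
        cm[i] = cm[i - 1] + g.get(i, within)

    alleles = np.array([["A", "B"]] * n_snps, dtype=object)
    markers = MarkerTable(np.full(n_snps, chrom, dtype=object),
                          np.array([f"rs{i+1}" for i in range(n_snps)],
                                   dtype=object),
                          bp, alleles)
    gmap = GeneticMap()
    gmap.add_chromosome(chrom, bp.astype(float), cm)

    if n_samples > 0:
        haplotypes = generate_virtual_haplotypes(cat, n_samples, rng)
    else:
        haplotypes = np.zeros((0, n_snps), dtype=np.int8)
    return SyntheticPopulation(chrom=chrom, markers=markers, gmap=gmap,
                               partition=partition, catalog=cat,
                               haplotypes=haplotypes, snp_cm=cm)


def make_founder_dataset(pop: SyntheticPopulation, spec: FounderSimSpec,
                         rng: np.random.Generator):
    """Insert a founder haplotype into carriers among the cases.

    The first ``spec.n_cases`` samples of ``pop`` are the case pool, the
    rest controls.  The ancestor chromosome comes from a random control
    sample, the mutation SNP is drawn uniformly unless given, and each
    carrier receives an independently shortened interval (n meioses per
    lineage).  Returns (case_genotypes, control_genotypes, truths).
    """
    n_total = pop.n_samples
    if spec.n_cases + spec.n_controls > n_total:
        raise ValueError("population smaller than cases + controls")
    snp_cm = pop.snp_cm
    ancestor_sample = spec.n_cases + int(rng.integers(spec.n_controls))
    ancestor = pop.haplotypes[2 * ancestor_sample].copy()
    if spec.mutation == "random":
        mut_snp = int(rng.integers(len(snp_cm)))
    elif isinstance(spec.mutation, float):
        mut_snp = int(np.argmin(np.abs(snp_cm - spec.mutation)))
    else:
        mut_snp = int(spec.mutation)
    mut_cm = float(snp_cm[mut_snp])
    span = (float(snp_cm[0]), float(snp_cm[-1]))
    carriers = rng.choice(spec.n_cases, size=spec.n_carriers, replace=False)
    intervals = []
    for _ in carriers:
        lo, hi = simulate_descendant_interval(mut_cm, span, spec.age, rng)
        i0 = int(np.searchsorted(snp_cm, lo, side="left"))
        i1 = int(np.searchsorted(snp_cm, hi, side="right")) - 1
        i0, i1 = min(i0, mut_snp), max(i1, mut_snp)
        intervals.append((i0, i1))
    case_haps = pop.haplotypes[:2 * spec.n_cases]
    case_haps, truths = insert_founder(case_haps, ancestor,
                                       carriers, intervals)
    case_g = (case_haps[0::2] + case_haps[1::2]).astype(np.int8)
    ctrl_haps = pop.haplotypes[2 * spec.n_cases:
                               2 * (spec.n_cases + spec.n_controls)]
    ctrl_g = (ctrl_haps[0::2] + ctrl_haps[1::2]).astype(np.int8)
    return case_g, ctrl_g, truths


def founder_power_replicate(seed, *, age: int = 10, n_carriers: int = 10,
                            n_cases: int = 200, n_controls: int = 400,
                            n_snps: int = 2000, span_cm: float = 100.0,
                            min_cm: float = 1.0, iterations: int = 100,
                            alpha: float = 0.05, insert: bool = True,
                            **config_kwargs):
    """One full power-study replicate: population, insertion, scan.

    Generates a fresh synthetic population, optionally inserts a founder
    haplotype of the given age into ``n_carriers`` cases, runs the whole
    case/control pipeline, and returns ``(results, truths,
    phased_cases)`` — the triple consumed by :func:`adjusted_power`.
    With ``insert=False`` cases and controls are exchangeable draws from
    the same population (the calibration condition).
    """
    from .model import RunConfig, SharingScan
    ss = np.random.SeedSequence(seed)
    s_pop, s_ins, s_fit = ss.spawn(3)
    pop = generate_synthetic_population(
        n_cases + n_controls, seed=np.random.default_rng(s_pop),
        n_snps=n_snps, span_cm=span_cm)
    if insert:
        spec = FounderSimSpec(age=age, n_carriers=n_carriers,
                              n_cases=n_cases, n_controls=n_controls)
        case_g, ctrl_g, truths = make_founder_dataset(
            pop, spec, np.random.default_rng(s_ins))
    else:
        g = pop.genotypes
        case_g = g[:n_cases]
        ctrl_g = g[n_cases:n_cases + n_controls]
        truths = []
    cfg = RunConfig(min_cm=min_cm, iterations=iterations, alpha=alpha,
                    **config_kwargs)
    scan = SharingScan(case_g, ctrl_g, pop.markers, pop.gmap, cfg)
    res = scan.fit(seed=int(np.random.default_rng(s_fit)
                            .integers(2 ** 31)))
    phased = res.contexts[pop.chrom].phased_cases
    return res, truths, phased


def carrier_detected(truth: SimTruth, reports, phased_cases,
                     alpha: float = 0.05) -> bool:
    """Is the carrier a member of a significant group that overlaps the
    inserted interval and matches its allele string over >= 1 block?"""
    part = phased_cases.partition
    for rep in reports:
        if rep.status == "not_significant" or rep.quasi_p >= alpha:
            continue
        g = rep.group
        if truth.carrier not in g.member_units:
            continue
        for u, bits in g.block_bits.items():
            f, l = part.first[u], part.last[u]
            if f < truth.snp0 or l > truth.snp1:
                continue
            want = truth.alleles[f - truth.snp0: l - truth.snp0 + 1]
            from .sharing import _iter_bits
            for hap_id in _iter_bits(bits):
                try:
                    hs = phased_cases.hap_string(u, hap_id)
                except (KeyError, IndexError):
                    continue
                if np.array_equal(hs, want):
                    return True
    return False


def adjusted_power(replicates, alpha: float = 0.05) -> float:
    """Fraction of carriers individually recovered across replicates.

    ``replicates`` yields (reports, truths, phased_cases) triples; a
    replicate where 4 of 5 carriers sit in significant matching groups
    contributes 4 found and 1 missed.
    """
    found = total = 0
    for reports, truths, phased_cases in replicates:
        for t in truths:
            total += 1
            if carrier_detected(t, reports, phased_cases, alpha):
                found += 1
    if total == 0:
        raise ValueError("no carriers in any replicate")
    return found / total
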