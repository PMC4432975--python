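"""Founder meiosis simulation, insertion, and adjusted power."""

import numpy as np
import pytest

from conftest import make_phased, uniform_cm

from ibdshare.likelihood import estimate_age
from ibdshare.nullmodel import SignificanceReport
from ibdshare.sharing import SharedGroup
from ibdshare.simulate import (FounderSimSpec, SimTruth, adjusted_power,
                               carrier_detected,
                               generate_synthetic_population,
                               insert_founder,
                               simulate_descendant_interval)


class TestDescendantInterval:
    def test_zero_generations_keeps_full_span(self):
        rng = np.random.default_rng(0)
        assert simulate_descendant_interval(50.0, (0, 100), 0, rng) == \
            (0.0, 100.0)

    def test_mean_length_matches_exponential_flanks(self):
        # central mutation: both flanks ~ Exp(n/100 per cM), so the mean
        # surviving length is ~ 2*(100/n); truncation is negligible
        rng = np.random.default_rng(1)
        for n, reps in ((50, 10_000),):
            lengths = np.array([
                np.diff(simulate_descendant_interval(50.0, (0, 100), n,
                                                     rng))[0]
                for _ in range(reps)])
            expected = 2 * 100.0 / n
            se = lengths.std() / np.sqrt(reps)
            assert abs(lengths.mean() - expected) < 3 * se + 1e-9

    def test_age_recovered_from_lengths(self):
        rng = np.random.default_rng(2)
        for n in (10, 50):
            lengths = np.array([
                np.diff(simulate_descendant_interval(50.0, (0, 100), n,
                                                     rng))[0]
                for _ in range(10_000)])
            # each flank is Exp(100/n); the age estimate uses one flank's
            # expectation E(d_g) = 100/n
            n_hat = estimate_age(lengths.mean() / 2.0)
            assert n_hat == pytest.approx(n, rel=0.2)

    def test_deterministic_given_seed(self):
        a = simulate_descendant_interval(30.0, (0, 100), 20,
                                         np.random.default_rng(7))
        b = simulate_descendant_interval(30.0, (0, 100), 20,
                                         np.random.default_rng(7))
        assert a == b

    def test_mutation_outside_span_rejected(self):
        with pytest.raises(ValueError):
            simulate_descendant_interval(150.0, (0, 100), 5,
                                         np.random.default_rng(0))


class TestInsertFounder:
    def test_carriers_match_founder_over_interval(self):
        rng = np.random.default_rng(3)
        haps = rng.integers(0, 2, size=(10, 50)).astype(np.int8)
        anc = rng.integers(0, 2, size=50).astype(np.int8)
        out, truths = insert_founder(haps, anc, [1, 3], [(5, 20),
                                                         (10, 30)])
        for t in truths:
            carried = out[2 * t.carrier + t.slot, t.snp0:t.snp1 + 1]
            assert np.array_equal(carried, anc[t.snp0:t.snp1 + 1])
            g = out[2 * t.carrier] + out[2 * t.carrier + 1]
            # genotype compatible with founder allele at every SNP
            assert np.all(g[t.snp0:t.snp1 + 1] >= anc[t.snp0:t.snp1 + 1])

    def test_untouched_outside_interval(self):
        rng = np.random.default_rng(4)
        haps = rng.integers(0, 2, size=(6, 40)).astype(np.int8)
        anc = rng.integers(0, 2, size=40).astype(np.int8)
        out, _ = insert_founder(haps, anc, [0], [(10, 20)])
        assert np.array_equal(out[:, :10], haps[:, :10])
        assert np.array_equal(out[:, 21:], haps[:, 21:])
        assert np.array_equal(out[2:], haps[2:])

    def test_overlapping_intervals_consistent(self):
        rng = np.random.default_rng(5)
        haps = rng.integers(0, 2, size=(8, 40)).astype(np.int8)
        anc = rng.integers(0, 2, size=40).astype(np.int8)
        out, truths = insert_founder(haps, anc, [0, 2], [(5, 25),
                                                         (15, 35)])
        lo, hi = 15, 25
        assert np.array_equal(out[1, lo:hi + 1], out[5, lo:hi + 1])

    def test_carrier_out_of_range(self):
        haps = np.zeros((4, 10), dtype=np.int8)
        with pytest.raises(IndexError):
            insert_founder(haps, np.zeros(10, dtype=np.int8), [7],
                           [(0, 5)])


class TestGenerateSyntheticPopulation:
    def test_empty_population_valid_panel(self):
        pop = generate_synthetic_population(0, seed=1, n_snps=300,
                                            span_cm=15)
        assert pop.haplotypes.shape == (0, 300)
        assert pop.partition.n_snps == 300
        assert len(pop.markers) == 300

    def test_same_seed_identical(self):
        a = generate_synthetic_population(30, seed=5, n_snps=200,
                                          span_cm=10)
        b = generate_synthetic_population(30, seed=5, n_snps=200,
                                          span_cm=10)
        assert np.array_equal(a.haplotypes, b.haplotypes)
        assert np.array_equal(a.snp_cm, b.snp_cm)
        assert np.array_equal(a.markers.bp, b.markers.bp)

    def test_haplotype_counts_within_declared_range(self, small_pop):
        part = small_pop.partition
        for u in range(part.n_units):
            if part.is_block[u]:
                assert 2 <= len(small_pop.catalog.block_freqs[u]) <= 6
                size = part.last[u] - part.first[u] + 1
                assert 3 <= size <= 10

    def test_spec_invariants(self, small_pop):
        # strictly increasing bp, non-decreasing cM, genotypes in range
        assert np.all(np.diff(small_pop.markers.bp) > 0)
        assert np.all(np.diff(small_pop.snp_cm) >= 0)
        g = small_pop.genotypes
        assert g.min() >= 0 and g.max() <= 2


def _fake_replicate(found_flags):
    """Reports/truths/phased where carrier i is detected iff flag i."""
    n = len(found_flags)
    masks = np.zeros((n + 2, 10), dtype=np.uint64)
    phased = make_phased(masks)
    n_snps = phased.partition.n_snps
    truths, reports = [], []
    alleles = np.zeros(n_snps, dtype=np.int8)
    for i, flag in enumerate(found_flags):
        truths.append(SimTruth(carrier=i, snp0=0, snp1=n_snps - 1,
                               alleles=alleles.copy()))
        if flag:
            g = SharedGroup(members=[i, n], member_units={i: [(0, 9)],
                                                          n: [(0, 9)]},
                            span=(0, 9), core=(0, 9),
                            block_bits={0: 1}, chrom="1")
            # catalog hap 0 is the all-zeros string in the dummy catalog
            reports.append(SignificanceReport(group=g, log10_ratio=10.0,
                                              quasi_p=1e-6,
                                              status="significant"))
    return reports, truths, phased


class TestAdjustedPower:
    def test_four_of_five_is_point_eight(self):
        reps = [_fake_replicate([1, 1, 1, 1, 0])]
        assert adjusted_power(reps, alpha=0.05) == pytest.approx(0.8)

    def test_all_found(self):
        reps = [_fake_replicate([1, 1, 1])] * 3
        assert adjusted_power(reps, alpha=0.05) == 1.0

    def test_none_significant(self):
        reps = [_fake_replicate([0, 0, 0])]
        assert adjusted_power(reps, alpha=0.05) == 0.0

    def test_carrier_needs_matching_allele_string(self):
        reports, truths, phased = _fake_replicate([1])
        # same group but the truth string differs from the group's hap
        truths[0].alleles[:] = 1
        assert not carrier_detected(truths[0], reports, phased, 0.05)


def test_power_robust_to_case_pool_heterogeneity():
    """Adding unrelated individuals to the case pool barely changes the
    fraction of carriers recovered (fixed carriers and age, scaled)."""
    from ibdshare import adjusted_power, founder_power_replicate

    def power(n_cases, n_controls):
        reps = []
        for seed in (500, 501):
            res, truths, phased = founder_power_replicate(
                seed, age=10, n_carriers=5, n_cases=n_cases,
                n_controls=n_controls, n_snps=600, span_cm=30.0,
                min_cm=1.0, iterations=40)
            phased.block_pairs = {}
            reps.append((res.reports, truths, phased))
            del res
        return adjusted_power(reps, alpha=0.05)

    small = power(50, 100)
    large = power(100, 200)
    assert abs(small - large) <= 0.3  # one-sided sampling tolerance
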