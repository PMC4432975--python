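"""LD classification and chromosome partitioning."""

import numpy as np
import pytest

from ibdshare.ld import (ChromPartition, InsufficientDataError,
                         MonomorphicMarkerError, classify_pair,
                         partition_by_ld, partition_by_map)


def _genotypes_from_haplotypes(h1, h2):
    return np.asarray(h1) + np.asarray(h2)


def _complete_ld_pair(n=100, p=0.4, seed=0):
    """Two-locus genotypes consistent only with haplotypes AB and ab."""
    rng = np.random.default_rng(seed)
    hap = (rng.random((2 * n,)) < p).astype(np.int8)
    ga = hap[0::2] + hap[1::2]
    return ga, ga.copy()


def _equilibrium_pair(n=500, seed=0):
    rng = np.random.default_rng(seed)
    ga = rng.binomial(2, 0.5, size=n).astype(np.int8)
    gb = rng.binomial(2, 0.5, size=n).astype(np.int8)
    return ga, gb


def _oracle_dprime_bound(ga, gb, grid=1000):
    """Independent brute-force profile bound: allele frequencies from
    direct counts, genotype-cell likelihood written out explicitly."""
    keep = (ga >= 0) & (gb >= 0)
    ga, gb = ga[keep], gb[keep]
    n = np.zeros((3, 3))
    for x, y in zip(ga, gb):
        n[x, y] += 1
    pa = ga.mean() / 2.0
    pb = gb.mean() / 2.0
    best = -np.inf
    ll_at = np.full(grid, -np.inf)
    ts = np.linspace(0, 1, grid)
    for sign in (+1, -1):
        if sign > 0:
            dmax = min(pa * (1 - pb), (1 - pa) * pb)
        else:
            dmax = min(pa * pb, (1 - pa) * (1 - pb))
        for i, t in enumerate(ts):
            p11 = pa * pb + sign * t * dmax
            p10, p01 = pa - p11, pb - p11
            p00 = 1 - pa - pb + p11
            ps = np.clip([p00, p01, p10, p11], 0, 1)
            p00, p01, p10, p11 = ps
            cell = np.array([
                [p00 ** 2, 2 * p00 * p01, p01 ** 2],
                [2 * p00 * p10, 2 * p00 * p11 + 2 * p01 * p10,
                 2 * p01 * p11],
                [p10 ** 2, 2 * p10 * p11, p11 ** 2]])
            ll = float((n * np.log(np.maximum(cell, 1e-300))).sum())
            ll_at[i] = max(ll_at[i], ll)
    cutoff = ll_at.max() - 2.7055 / 2
    return ts[np.nonzero(ll_at >= cutoff)[0][-1]]


class TestClassifyPair:
    def test_complete_ld_is_strong_with_bound_one(self):
        ga, gb = _complete_ld_pair()
        c = classify_pair(ga, gb)
        assert c.label == "strong"
        assert c.bound == pytest.approx(1.0, abs=1e-3)

    def test_equilibrium_is_weak(self):
        weak = 0
        for seed in range(10):
            ga, gb = _equilibrium_pair(seed=seed)
            if classify_pair(ga, gb).label == "weak":
                weak += 1
        assert weak >= 8  # overwhelming majority of equilibrium draws

    def test_bound_close_to_independent_oracle(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            # partially linked pair
            h1 = (rng.random(600) < 0.5).astype(np.int8)
            h2 = np.where(rng.random(600) < 0.8, h1,
                          (rng.random(600) < 0.5).astype(np.int8))
            ga = h1[0::2] + h1[1::2]
            gb = h2[0::2] + h2[1::2]
            c = classify_pair(ga, gb)
            oracle = _oracle_dprime_bound(ga, gb)
            assert c.bound == pytest.approx(oracle, abs=0.05)

    def test_monomorphic_marker_raises(self):
        ga = np.zeros(50, dtype=np.int8)
        gb = np.tile([0, 1, 2], 17)[:50].astype(np.int8)
        with pytest.raises(MonomorphicMarkerError):
            classify_pair(ga, gb)

    def test_all_missing_raises(self):
        g = np.full(30, -1, dtype=np.int8)
        with pytest.raises(InsufficientDataError):
            classify_pair(g, g)

    def test_few_samples_uninformative(self):
        ga = np.array([0, 1, 2, 1, 0], dtype=np.int8)
        assert classify_pair(ga, ga).label == "uninformative"


def _perfect_block(n, n_snps, seed=0):
    """Samples from a 2-haplotype block (complete LD throughout)."""
    rng = np.random.default_rng(seed)
    hap = (rng.random(2 * n) < 0.4).astype(np.int8)
    g = hap[0::2] + hap[1::2]
    return np.repeat(g[:, None], n_snps, axis=1)


class TestPartitionByLD:
    def test_three_tight_strong_snps_form_one_block(self):
        g = _perfect_block(200, 3)
        part = partition_by_ld(g, np.array([1000, 3000, 5000]))
        assert part.n_units == 1
        assert bool(part.is_block[0])

    def test_gap_over_50kb_blocks_seeding(self):
        g = _perfect_block(200, 2)
        part = partition_by_ld(g, np.array([1000, 62000]))
        assert part.n_units == 2
        assert not part.is_block.any()

    def test_boundary_where_ratio_drops(self):
        # 3 SNPs in complete LD followed by 3 independent SNPs
        rng = np.random.default_rng(3)
        left = _perfect_block(400, 3, seed=1)
        right = np.stack([rng.binomial(2, 0.5, 400) for _ in range(3)],
                         axis=1).astype(np.int8)
        g = np.concatenate([left, right], axis=1)
        bp = np.arange(6) * 2000 + 1000
        part = partition_by_ld(g, bp)
        assert part.is_block[0] and part.first[0] == 0 and part.last[0] == 2
        # the three equilibrium SNPs stay out of the block
        assert not any(part.is_block[u] and part.first[u] < 3 < part.last[u]
                       for u in range(part.n_units))

    def test_invariant_sample_order_and_allele_swap(self):
        pop = None
        g = _perfect_block(300, 4, seed=5)
        extra = np.random.default_rng(9).binomial(2, 0.5, (300, 2)) \
            .astype(np.int8)
        g = np.concatenate([g, extra], axis=1)
        bp = np.arange(6) * 3000 + 1
        base = partition_by_ld(g, bp)
        perm = np.random.default_rng(1).permutation(300)
        shuffled = partition_by_ld(g[perm], bp)
        swapped = g.copy()
        swapped[:, 2] = 2 - swapped[:, 2]  # allele relabel at marker 2
        relabeled = partition_by_ld(swapped, bp)
        for other in (shuffled, relabeled):
            assert np.array_equal(base.first, other.first)
            assert np.array_equal(base.is_block, other.is_block)

    def test_recovers_simulated_block_boundaries(self, medium_pop):
        g = medium_pop.genotypes
        part = partition_by_ld(g, medium_pop.markers.bp)
        true_u = medium_pop.partition.unit_of_snp()
        est_u = part.unit_of_snp()
        same_t = true_u[1:] == true_u[:-1]
        same_e = est_u[1:] == est_u[:-1]
        assert (same_t == same_e).mean() >= 0.95

    def test_exact_cover(self, small_pop):
        part = partition_by_ld(small_pop.genotypes,
                               small_pop.markers.bp)
        covered = np.concatenate(
            [np.arange(f, l + 1) for f, l in zip(part.first, part.last)])
        assert np.array_equal(np.sort(covered),
                              np.arange(len(small_pop.markers)))


class TestPartitionByMap:
    def test_close_pair_forms_block(self):
        part = partition_by_map(np.array([1000, 6000]),
                                np.array([0.0, 0.0005]))
        assert part.n_units == 1 and part.is_block[0]

    def test_distant_cm_pair_stays_hotspots(self):
        part = partition_by_map(np.array([1000, 6000]),
                                np.array([0.0, 0.002]))
        assert part.n_units == 2 and not part.is_block.any()

    def test_physical_gap_splits_chain(self):
        # 10-SNP chain with a 12 kb physical gap after the 6th SNP
        bp = np.array([1000 + 2000 * i for i in range(6)]
                      + [1000 + 2000 * 5 + 12000 + 2000 * i
                         for i in range(4)])
        cm = np.arange(10) * 0.0001
        part = partition_by_map(bp, cm)
        # independent re-scan of the two chaining rules
        link = (np.diff(cm) < 0.001) & (np.diff(bp) <= 10000)
        assert not link[5]
        assert part.n_units == 2
        assert tuple(part.first) == (0, 6)
        assert tuple(part.last) == (5, 9)

    def test_agreement_with_ld_partition(self, medium_pop):
        g = medium_pop.genotypes
        bp = medium_pop.markers.bp
        by_ld = partition_by_ld(g, bp)
        by_map = partition_by_map(bp, medium_pop.snp_cm)
        same_ld = np.diff(by_ld.unit_of_snp()) == 0
        same_map = np.diff(by_map.unit_of_snp()) == 0
        assert (same_ld == same_map).mean() >= 0.80


def test_partition_rejects_singleton_block():
    with pytest.raises(ValueError):
        ChromPartition(np.array([0]), np.array([0]), np.array([True]))


def test_partition_rejects_gaps():
    with pytest.raises(ValueError):
        ChromPartition(np.array([0, 3]), np.array([1, 4]),
                       np.array([True, True]))
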