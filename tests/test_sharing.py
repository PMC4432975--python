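"""Pairwise segment detection, group assembly, and the rescue scan."""

import numpy as np
import pytest

from conftest import make_phased, uniform_cm
from oracles import oracle_groups, oracle_pair_segments, random_instance

from ibdshare.catalog import build_catalog
from ibdshare.phasing import phase_all
from ibdshare.sharing import (SegmentSet, detect_pairwise,
                              detect_pairwise_arrays, merge_groups,
                              rescue_scan)
from ibdshare.simulate import FounderSimSpec, make_founder_dataset
from ibdshare import generate_synthetic_population


class TestDetectPairwise:
    def test_identical_samples_share_everything(self):
        masks = np.tile(np.uint64(1), (2, 30))
        phased = make_phased(masks)
        cm = uniform_cm(phased, 3.0)
        segs = detect_pairwise(phased, cm, min_cm=1.0)
        assert len(segs) == 1
        s = segs[0]
        assert (s.u0, s.u1) == (0, 29)
        assert s.n_mismatch_snps == 0
        assert s.d_g == pytest.approx(3.0)

    def test_threshold_separates_two_from_three_cm(self):
        # a shared stretch of exactly 2 cM in an otherwise mismatching pair
        masks = np.zeros((2, 40), dtype=np.uint64)
        masks[0, :] = np.uint64(2)
        masks[1, :] = np.uint64(4)     # disjoint candidates: no match
        masks[:, 10:31] = np.uint64(1)  # 21 units = 2 cM shared
        phased = make_phased(masks)
        cm = uniform_cm(phased, 3.9)   # 0.1 cM per unit step
        at1 = detect_pairwise(phased, cm, min_cm=1.0)
        assert [(s.u0, s.u1) for s in at1] == [(10, 30)]
        assert detect_pairwise(phased, cm, min_cm=3.0) == []

    def test_mismatch_near_start_stops_extension(self):
        # mismatch at unit 5: fewer than 20 clean SNPs before it, so it
        # cannot be bridged and the extension stops around it
        masks = np.tile(np.uint64(1), (2, 60))
        masks[1, 5] = np.uint64(2)
        phased = make_phased(masks)
        cm = uniform_cm(phased, 6.0)
        segs = detect_pairwise(phased, cm, min_cm=1.0)
        assert [(s.u0, s.u1) for s in segs] == [(6, 59)]

    def test_interior_mismatch_is_bridged_within_budget(self):
        # 301 single-SNP units: one mismatching unit in the middle is
        # within the 1% budget and >20 SNPs from both ends
        masks = np.tile(np.uint64(1), (2, 301))
        masks[1, 150] = np.uint64(2)
        phased = make_phased(masks)
        cm = uniform_cm(phased, 6.0)
        segs = detect_pairwise(phased, cm, min_cm=1.0)
        assert [(s.u0, s.u1) for s in segs] == [(0, 300)]
        assert segs[0].n_mismatch_snps == 2  # the bad unit's two SNPs
        assert segs[0].bad_units == (150,)

    def test_mismatch_within_clean_window_not_bridged(self):
        masks = np.tile(np.uint64(1), (2, 301))
        masks[1, 296] = np.uint64(2)   # <20 SNPs from the right end
        phased = make_phased(masks)
        cm = uniform_cm(phased, 6.0)
        segs = detect_pairwise(phased, cm, min_cm=1.0)
        # the right flank is too short to bridge or to stand alone
        assert [(s.u0, s.u1) for s in segs] == [(0, 295)]

    def test_hotspot_only_match_cannot_seed(self):
        is_block = np.zeros(30, dtype=bool)
        masks = np.tile(np.uint64(1), (2, 30))
        phased = make_phased(masks, is_block=is_block)
        cm = uniform_cm(phased, 3.0)
        assert detect_pairwise(phased, cm, min_cm=1.0) == []

    def test_matches_oracle_on_random_instances(self):
        rng = np.random.default_rng(1234)
        for _ in range(60):
            phased, snp_cm = random_instance(rng)
            min_cm = float(rng.uniform(0.3, 1.5))
            segs = detect_pairwise(phased, snp_cm, min_cm)
            got = {}
            for s in segs:
                got.setdefault((s.a, s.b), []).append((s.u0, s.u1))
            for k in got:
                got[k].sort()
            n = phased.n_samples
            want = {}
            for a in range(n):
                for b in range(a + 1, n):
                    iv = oracle_pair_segments(phased.masks,
                                              phased.partition, snp_cm,
                                              a, b, min_cm)
                    if iv:
                        want[(a, b)] = iv
            assert got == want


class TestMergeGroups:
    def _three_way(self):
        # samples 0,1,2 share haplotype bit0 over units 5..15; samples 3
        # and 4 share bit1 over the same region (opposite allele); every
        # sample carries a private haplotype elsewhere
        masks = np.zeros((5, 25), dtype=np.uint64)
        for i in range(5):
            masks[i, :] = np.uint64(1 << (i + 2))
        masks[:3, 5:16] = np.uint64(1)
        masks[3:, 5:16] = np.uint64(2)
        phased = make_phased(masks)
        return phased, uniform_cm(phased, 8.0)

    def test_transitive_three_way_merge(self):
        phased, cm = self._three_way()
        segs = detect_pairwise_arrays(phased, cm, min_cm=1.0)
        groups = merge_groups(segs, phased, cap_k=10, snp_cm=cm,
                              min_cm=1.0)
        sets = {tuple(g.members) for g in groups}
        assert (0, 1, 2) in sets
        assert (3, 4) in sets
        g3 = next(g for g in groups if g.members == [0, 1, 2])
        assert g3.core == (5, 15)

    def test_single_segment_pair_group(self):
        masks = np.zeros((2, 20), dtype=np.uint64)
        masks[0, :] = np.uint64(1)
        masks[1, 4:15] = np.uint64(1)
        masks[1, :4] = np.uint64(2)
        masks[1, 15:] = np.uint64(2)
        phased = make_phased(masks)
        cm = uniform_cm(phased, 6.0)
        segs = detect_pairwise_arrays(phased, cm, min_cm=1.0)
        groups = merge_groups(segs, phased, cap_k=10, snp_cm=cm,
                              min_cm=1.0)
        assert len(groups) == 1
        g = groups[0]
        assert g.k == 2
        assert g.core == (4, 14)  # full shared block span

    def test_cap_discards_large_groups(self):
        masks = np.tile(np.uint64(1), (8, 30))
        phased = make_phased(masks)
        cm = uniform_cm(phased, 5.0)
        segs = detect_pairwise_arrays(phased, cm, min_cm=1.0)
        assert merge_groups(segs, phased, cap_k=4, snp_cm=cm,
                            min_cm=1.0) == []
        groups = merge_groups(segs, phased, cap_k=8, snp_cm=cm,
                              min_cm=1.0)
        assert {tuple(g.members) for g in groups} == {tuple(range(8))}

    def test_matches_group_oracle_on_random_instances(self):
        rng = np.random.default_rng(99)
        for _ in range(60):
            phased, snp_cm = random_instance(rng)
            min_cm = float(rng.uniform(0.3, 1.5))
            segs = detect_pairwise_arrays(phased, snp_cm, min_cm)
            groups = merge_groups(segs, phased, cap_k=20, snp_cm=snp_cm,
                                  min_cm=min_cm)
            got = {(frozenset(g.members), g.span) for g in groups}
            want = oracle_groups(phased.masks, phased.partition, snp_cm,
                                 min_cm, cap_k=20)
            assert got == want

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(7)
        phased, snp_cm = random_instance(rng, max_snps=20, max_samples=6)
        segs = detect_pairwise_arrays(phased, snp_cm, 0.5)
        base = {(frozenset(g.members), g.span)
                for g in merge_groups(segs, phased, cap_k=20,
                                      snp_cm=snp_cm, min_cm=0.5)}
        perm = rng.permutation(phased.n_samples)
        inv = np.argsort(perm)
        from ibdshare.phasing import PhasedChrom
        phased2 = PhasedChrom(phased.partition, phased.catalog,
                              phased.masks[perm], phased.scenarios[perm],
                              {}, {})
        segs2 = detect_pairwise_arrays(phased2, snp_cm, 0.5)
        renamed = {(frozenset(int(perm[m]) for m in g.members), g.span)
                   for g in merge_groups(segs2, phased2, cap_k=20,
                                         snp_cm=snp_cm, min_cm=0.5)}
        assert renamed == base


class TestRescueScan:
    def test_rescue_adds_core_carrier(self):
        masks = np.zeros((3, 30), dtype=np.uint64)
        masks[0, :] = np.uint64(1)
        masks[1, 5:25] = np.uint64(1)
        masks[1, :5] = np.uint64(4)
        masks[1, 25:] = np.uint64(4)
        # candidate shares the members' haplotype over units 9..15
        # (0.6 cM at 0.1 cM per unit span from SNP 9 to 15)
        masks[2, :] = np.uint64(4)
        masks[2, 9:16] = np.uint64(1)
        phased = make_phased(masks)
        cm = uniform_cm(phased, 2.9)
        segs = detect_pairwise_arrays(phased, cm, min_cm=1.0,
                                      pairs=np.array([[0, 1]]))
        g = merge_groups(segs, phased, cap_k=10, snp_cm=cm, min_cm=1.0)[0]
        assert g.core == (5, 24)
        # candidate does not carry the full 2 cM core: not rescued
        g2 = rescue_scan(g, phased, cm, min_cm=1.0)
        assert g2.members == [0, 1]
        # with a core restricted to the candidate's stretch it qualifies
        g.core = (9, 15)
        g3 = rescue_scan(g, phased, cm, min_cm=1.0)
        assert g3.members == [0, 1, 2]
        assert g3.rescued == [2]
        # 0.7 cM >= half of 1.0 cM satisfied; at min_cm=2.0 it is not
        g4 = rescue_scan(g, phased, cm, min_cm=2.0)
        assert g4.members == [0, 1]

    def test_rescue_without_candidates_unchanged(self):
        masks = np.zeros((2, 30), dtype=np.uint64)
        masks[:, :] = np.uint64(1)
        phased = make_phased(masks)
        cm = uniform_cm(phased, 2.9)
        segs = detect_pairwise_arrays(phased, cm, min_cm=1.0)
        g = merge_groups(segs, phased, cap_k=10, snp_cm=cm, min_cm=1.0)[0]
        g2 = rescue_scan(g, phased, cm, min_cm=1.0)
        assert g2.members == g.members


class TestOnSimulatedFounder:
    def test_founder_segment_detected_between_carriers(self):
        pop = generate_synthetic_population(80, seed=21, n_snps=600,
                                            span_cm=30.0)
        spec = FounderSimSpec(age=10, n_carriers=4, n_cases=40,
                              n_controls=40, mutation=15.0)
        rng = np.random.default_rng(3)
        case_g, ctrl_g, truths = make_founder_dataset(pop, spec, rng)
        cat = build_catalog(ctrl_g, pop.partition)
        phased = phase_all(case_g, pop.partition, cat)
        carriers = sorted(t.carrier for t in truths)
        pairs = np.array([(a, b) for i, a in enumerate(carriers)
                          for b in carriers[i + 1:]])
        segs = detect_pairwise_arrays(phased, pop.snp_cm, 1.0, pairs=pairs)
        assert len(segs) >= len(pairs) - 1  # nearly every carrier pair
        # the longest carrier segment covers the mutation site
        u_of = pop.partition.unit_of_snp()
        mut_u = u_of[truths[0].snp0 + int(np.argmin(
            np.abs(pop.snp_cm[truths[0].snp0:truths[0].snp1 + 1] - 15.0)))]
        best = np.argmax(segs.d_g)
        assert segs.u0[best] <= mut_u <= segs.u1[best]

    def test_adding_unrelated_sample_keeps_groups(self):
        pop = generate_synthetic_population(60, seed=22, n_snps=400,
                                            span_cm=20.0)
        g = pop.genotypes
        cat = build_catalog(g[30:], pop.partition)
        phased_small = phase_all(g[:20], pop.partition, cat)
        phased_big = phase_all(g[:21], pop.partition, cat)
        cm = pop.snp_cm
        segs_small = detect_pairwise_arrays(phased_small, cm, 1.0)
        segs_big = detect_pairwise_arrays(
            phased_big, cm, 1.0)
        small = {(frozenset(gr.members), gr.span)
                 for gr in merge_groups(segs_small, phased_small,
                                        cap_k=20, snp_cm=cm, min_cm=1.0)}
        big_groups = merge_groups(segs_big, phased_big, cap_k=20,
                                  snp_cm=cm, min_cm=1.0)
        big = {(frozenset(gr.members), gr.span) for gr in big_groups}
        for members, span in small:
            assert any(members <= ms for ms, _ in big), \
                "group lost after adding an unrelated sample"
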