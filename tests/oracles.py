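"""Brute-force reference implementations used to cross-check detection.

These enumerate every candidate interval and every (block, haplotype)
seed directly from the candidate-mask matrix, independent of the
vectorised production code paths.
"""

import numpy as np

MISMATCH_FRACTION = 0.01
CLEAN_END_SNPS = 20


def oracle_pair_segments(masks, partition, snp_cm, a, b, min_cm):
    """All maximal valid shared intervals for one sample pair.

    An interval of units is valid when its end units match, every
    mismatching interior unit keeps at least 20 matched SNPs to both
    segment ends, mismatching SNPs stay within 1% of the segment's SNPs,
    at least one matched LD block is included, and the genetic length
    reaches ``min_cm``.  Maximal = not contained in another valid
    interval.
    """
    n_units = partition.n_units
    match = [(int(masks[a, u]) & int(masks[b, u])) != 0
             for u in range(n_units)]
    valid = []
    for u0 in range(n_units):
        if not match[u0]:
            continue
        for u1 in range(u0, n_units):
            if not match[u1]:
                continue
            snp0 = partition.first[u0]
            snp1 = partition.last[u1]
            total = snp1 - snp0 + 1
            bad_snps = 0
            clean = True
            for u in range(u0, u1 + 1):
                if match[u]:
                    continue
                bad_snps += partition.last[u] - partition.first[u] + 1
                if partition.first[u] - snp0 < CLEAN_END_SNPS or \
                        snp1 - partition.last[u] < CLEAN_END_SNPS:
                    clean = False
            if not clean or bad_snps > MISMATCH_FRACTION * total:
                continue
            if not any(partition.is_block[u] and match[u]
                       for u in range(u0, u1 + 1)):
                continue
            if snp_cm[snp1] - snp_cm[snp0] < min_cm:
                continue
            valid.append((u0, u1))
    maximal = [(u0, u1) for (u0, u1) in valid
               if not any(v0 <= u0 and v1 >= u1 and (v0, v1) != (u0, u1)
                          for (v0, v1) in valid)]
    return sorted(maximal)


def oracle_segments(masks, partition, snp_cm, min_cm):
    """Maximal segments for all sample pairs: {(a, b): [(u0, u1), ...]}."""
    n = masks.shape[0]
    out = {}
    for a in range(n):
        for b in range(a + 1, n):
            segs = oracle_pair_segments(masks, partition, snp_cm, a, b,
                                        min_cm)
            if segs:
                out[(a, b)] = segs
    return out


def oracle_groups(masks, partition, snp_cm, min_cm, cap_k):
    """Seed-key groups from the oracle segments.

    For every (block, haplotype id): members are the samples joined by a
    segment matching that haplotype at that block; member intervals are
    the hulls of their supporting segments; groups over ``cap_k`` are
    discarded; identical member sets with overlapping spans keep the
    widest span.  Returns a set of (members, span) descriptors.
    """
    segs = oracle_segments(masks, partition, snp_cm, min_cm)
    per_key = {}
    for (a, b), intervals in segs.items():
        for (u0, u1) in intervals:
            for u in range(u0, u1 + 1):
                if not partition.is_block[u]:
                    continue
                shared = int(masks[a, u]) & int(masks[b, u])
                if not shared:
                    continue
                bit = 0
                m = shared
                while m:
                    if m & 1:
                        per_key.setdefault((u, bit), []).append(
                            (a, b, u0, u1))
                    m >>= 1
                    bit += 1
    raw = []
    for (u, bit), support in per_key.items():
        hull = {}
        for a, b, u0, u1 in support:
            for s in (a, b):
                lo, hi = hull.get(s, (u0, u1))
                hull[s] = (min(lo, u0), max(hi, u1))
        if not 2 <= len(hull) <= cap_k:
            continue
        members = frozenset(hull)
        span = (min(v[0] for v in hull.values()),
                max(v[1] for v in hull.values()))
        raw.append((members, span))
    # dedup: per member set, overlapping spans keep the widest
    by_members = {}
    for members, span in raw:
        by_members.setdefault(members, []).append(span)
    out = set()
    for members, spans in by_members.items():
        spans.sort()
        kept = []
        for span in spans:
            if kept and span[0] <= kept[-1][1]:
                if span[1] - span[0] > kept[-1][1] - kept[-1][0]:
                    kept[-1] = span
            else:
                kept.append(span)
        for span in kept:
            out.add((members, span))
    return out


def random_instance(rng, max_snps=20, max_samples=6):
    """A random small phased instance (masks + partition + cM grid)."""
    n_samples = int(rng.integers(2, max_samples + 1))
    units = []
    total_snps = 0
    while total_snps < max_snps - 2:
        if rng.random() < 0.6:
            size = int(rng.integers(2, 4))
            units.append((size, True))
        else:
            units.append((1, False))
        total_snps += units[-1][0]
    first, last, is_block = [], [], []
    pos = 0
    for size, blk in units:
        first.append(pos)
        last.append(pos + size - 1)
        is_block.append(blk)
        pos += size
    n_units = len(units)
    masks = np.zeros((n_samples, n_units), dtype=np.uint64)
    for s in range(n_samples):
        for u in range(n_units):
            if is_block[u]:
                n_bits = int(rng.integers(0, 3))
                m = 0
                for _ in range(n_bits):
                    m |= 1 << int(rng.integers(0, 4))
                masks[s, u] = m
            else:
                masks[s, u] = int(rng.integers(1, 4))
    from ibdshare.ld import ChromPartition
    part = ChromPartition(np.array(first), np.array(last),
                          np.array(is_block))
    snp_cm = np.cumsum(rng.uniform(0.05, 0.4, size=pos))
    from ibdshare.catalog import ChromCatalog, unknown_haplotype_frequency
    cat = ChromCatalog(partition=part, m_ctrl=100,
                       h_u=unknown_haplotype_frequency(100))
    f = np.array([0.4, 0.3, 0.2, 0.1])
    for u in range(n_units):
        if is_block[u]:
            cat.block_freqs[u] = f
            cat.block_haps[u] = np.zeros((4, last[u] - first[u] + 1),
                                         dtype=np.int8)
        else:
            cat.hotspot_freq[u] = 0.5
    from ibdshare.phasing import PhasedChrom
    scen = np.zeros(masks.shape, dtype=np.int8)
    scen[:, ~part.is_block] = -1
    phased = PhasedChrom(part, cat, masks, scen, {}, {})
    return phased, snp_cm
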