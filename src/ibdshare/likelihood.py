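"""Likelihood ratio of haplotype sharing by descent vs. by chance.

Under chance sharing, block inheritance is treated as independent across
blocks: the probability that k_j of the k group members share haplotype i
(population frequency h_ji) in block j is

    P_j = h_ji**k_j * 2**k_j / C(2k, k),

and the chance likelihood of the whole extended haplotype among a case
pool of size s is L(H0) = C(s, k) * prod_j P_j.  Under descent from a
common ancestor n generations back, each of the n*k meioses transmits the
haplotype with probability 1/2: L(H1) = 0.5**(n*k), with the age n
estimated from the members' mean shared genetic length via E(d_g) = 100/n
(a 2 cM mean shared haplotype suggests roughly 50 meioses).  The reported
score is log10 L(H1)/L(H0); because of the C(s, k) factor L(H0) can
exceed one, so the score is a relative quantity calibrated empirically
against controls.  Only LD-block haplotypes contribute; hotspot SNPs do
not enter the likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .sharing import SharedGroup


def _log10_comb(n: int, k: int) -> float:
    return (gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)) / np.log(10)


@dataclass
class LikelihoodResult:
    """Score of one shared group."""

    log10_l0: float
    log10_l1: float
    age_generations: float
    k: int
    s: int
    log10_ratio: float
    block_terms: list  # (unit, hap_id, freq, k_j) actually used


def block_sharing_prob(h_ji: float, k_j: int, k: int) -> float:
    """P_j: probability of k_j of k individuals sharing haplotype i by chance."""
    if not 0.0 < h_ji <= 1.0:
        raise ValueError("haplotype frequency must be in (0, 1]")
    if not 2 <= k:
        raise ValueError("group size k must be >= 2")
    if not 1 <= k_j <= k:
        raise ValueError("k_j must satisfy 1 <= k_j <= k")
    return 10.0 ** log10_block_sharing_prob(h_ji, k_j, k)


def log10_block_sharing_prob(h_ji: float, k_j: int, k: int) -> float:
    return (k_j * np.log10(h_ji) + k_j * np.log10(2.0)
            - _log10_comb(2 * k, k))


def likelihood_chance(s: int, k: int, p_list) -> float:
    """L(H0) = C(s, k) * prod_j P_j (may exceed 1)."""
    return 10.0 ** log10_likelihood_chance(
        s, k, [np.log10(p) for p in p_list])


def log10_likelihood_chance(s: int, k: int, log10_p_list) -> float:
    if s < k or k < 2:
        raise ValueError("need s >= k >= 2")
    log10_p_list = list(log10_p_list)
    if not log10_p_list:
        raise ValueError("a group must contain at least one block")
    return float(_log10_comb(s, k) + np.sum(log10_p_list))


def estimate_age(mean_dg: float) -> float:
    """Age in generations from mean shared genetic length: n = 100/d_g."""
    if mean_dg <= 0:
        raise ValueError("mean shared genetic length must be positive")
    return 100.0 / mean_dg


def likelihood_ibd(n: float, k: int) -> float:
    """L(H1) = 0.5**(n*k) over the n*k meioses shaping the shared haplotype."""
    return 10.0 ** log10_likelihood_ibd(n, k)


def log10_likelihood_ibd(n: float, k: int) -> float:
    if n <= 0 or k < 2:
        raise ValueError("need age n > 0 and k >= 2")
    return float(n * k * np.log10(0.5))


def _iter_bits(mask: int):
    m = int(mask)
    while m:
        low = m & -m
        yield low.bit_length() - 1
        m ^= low


def score_group(group: SharedGroup, phased, snp_cm: np.ndarray,
                s: int) -> LikelihoodResult:
    """log10 likelihood ratio of IBD vs. chance sharing for one group.

    Per block ``group.block_bits`` holds the haplotypes common to every
    member covering the block; k_j is the covering count, and when more
    than one haplotype is common, the higher-frequency one enters the
    evaluation (when a member shares both haplotypes of a block the
    commoner one is used).  Unknown (non-catalog) haplotypes carry
    frequency h_u.  Blocks with no common haplotype (tolerated
    mismatches) contribute nothing; hotspot SNPs never do.
    """
    part = phased.partition
    cat = phased.catalog
    k = group.k
    if s < k:
        raise ValueError("case pool smaller than group size")
    if not group.block_bits:
        raise ValueError("group has no scorable block")
    units = np.array(sorted(group.block_bits), dtype=np.int64)
    bits_arr = np.array([group.block_bits[int(u)] for u in units],
                        dtype=np.uint64)
    mu0 = np.array([group.member_units[m][0][0] for m in group.members])
    mu1 = np.array([group.member_units[m][-1][1] for m in group.members])
    cov = ((mu0[:, None] <= units[None, :])
           & (units[None, :] <= mu1[:, None])).sum(axis=0)
    ok = cov >= 1
    if not ok.any():
        raise ValueError("group has no scorable block")
    units, bits_arr, cov = units[ok], bits_arr[ok], cov[ok]
    F = cat.freq_matrix()
    bb = ((bits_arr[:, None] >> np.arange(64, dtype=np.uint64)[None, :])
          & np.uint64(1)).astype(bool)
    fcand = np.where(bb, F[units], -1.0)
    hap_ids = fcand.argmax(axis=1)
    freqs = fcand[np.arange(len(units)), hap_ids]
    k_j = np.minimum(cov, k).astype(np.int64)
    log10_p = (k_j * np.log10(2.0 * freqs) - _log10_comb(2 * k, k))
    terms = [(int(u), int(h), float(f), int(kj))
             for u, h, f, kj in zip(units, hap_ids, freqs, k_j)]
    log10_p = list(log10_p)
    mean_dg = group.mean_length_cm(snp_cm, part)
    n = estimate_age(mean_dg)
    l1 = log10_likelihood_ibd(n, k)
    l0 = log10_likelihood_chance(s, k, log10_p)
    return LikelihoodResult(log10_l0=l0, log10_l1=l1, age_generations=n,
                            k=k, s=s, log10_ratio=l1 - l0,
                            block_terms=terms)
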