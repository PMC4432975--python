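"""Per-block population haplotype catalogs estimated from control genotypes.

Within each LD block, haplotype frequencies are maximum-likelihood
estimates from an EM over all haplotype pairs consistent with each
multilocus genotype (missing sites are marginalised).  Haplotypes rarer
than ``1/(4*m_ctrl)`` are pruned and the mass renormalised.  A haplotype
absent from the catalog is assigned the unknown-haplotype frequency

    h_u = 1 - 0.95**(1/(2*m_ctrl)),

the frequency below which a haplotype has a 95% chance of never being seen
among ``m_ctrl`` diploid controls.  Hotspot SNPs are modelled marginally
plus a first-order Markov transition from the adjacent 5' marker, which is
what the virtual-sample generator uses to preserve local LD.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .ld import ChromPartition, _em_haplotype_freqs, _two_locus_counts

log = logging.getLogger(__name__)

EM_TOL = 1e-8
EM_MAX_ITER = 500
MAX_AMBIGUITY_BITS = 20  # 2**20 cap on compatible pairs per genotype


class EmptyCatalogError(ValueError):
    """A block whose genotypes are entirely missing cannot be catalogued."""


class BlockTooComplexError(ValueError):
    """A genotype implies more compatible haplotype pairs than the cap."""


def unknown_haplotype_frequency(m_ctrl: int) -> float:
    """Assumed frequency of a haplotype never observed in the controls.

    ``1 - 0.95**(1/(2*m_ctrl))``: the largest frequency at which absence
    from ``2*m_ctrl`` control chromosomes still has probability 0.95.
    """
    if m_ctrl <= 0:
        raise ValueError("control sample size must be positive")
    return 1.0 - 0.95 ** (1.0 / (2.0 * m_ctrl))


def _compatible_pairs(g: np.ndarray) -> list[tuple[int, int]]:
    """All unordered haplotype pairs (as bit-ints) compatible with genotype g.

    Sites with g==1 are heterozygous (alleles split between the pair),
    g==-1 missing (both alleles free); compatibility is exact at all other
    sites.
    """
    g = np.asarray(g)
    het = np.nonzero(g == 1)[0]
    mis = np.nonzero(g == -1)[0]
    if len(het) + 2 * len(mis) > MAX_AMBIGUITY_BITS:
        raise BlockTooComplexError(
            f"{len(het)} het + {len(mis)} missing sites exceed ambiguity cap"
        )
    base = 0
    for i in np.nonzero(g == 2)[0]:
        base |= 1 << int(i)
    het_bits = [1 << int(i) for i in het]
    mis_bits = [1 << int(i) for i in mis]
    het_mask = sum(het_bits)
    pairs = set()
    for s in range(1 << len(het_bits)):
        sub = 0
        for t, b in enumerate(het_bits):
            if s >> t & 1:
                sub |= b
        x0 = base | sub
        y0 = base | (het_mask ^ sub)
        for mx in range(1 << len(mis_bits)):
            xm = sum(b for t, b in enumerate(mis_bits) if mx >> t & 1)
            for my in range(1 << len(mis_bits)):
                ym = sum(b for t, b in enumerate(mis_bits) if my >> t & 1)
                x, y = x0 | xm, y0 | ym
                pairs.add((x, y) if x <= y else (y, x))
    return sorted(pairs)


def _int_to_alleles(h: int, length: int) -> np.ndarray:
    return np.array([(h >> i) & 1 for i in range(length)], dtype=np.int8)


def estimate_block_haplotypes(
    block_genotypes: np.ndarray,
    m_ctrl: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """ML haplotype frequencies for one block by EM over compatible pairs.

    Parameters
    ----------
    block_genotypes : (n_samples, n_snps) int codes 0/1/2, -1 missing.
    m_ctrl : pruning scale; haplotypes with frequency < 1/(4*m_ctrl) are
        dropped and the remaining mass renormalised.  Defaults to the
        number of samples.

    Returns ``(haplotypes, frequencies)`` with haplotypes an (H, n_snps)
    0/1 array ordered by decreasing frequency.
    """
    gmat = np.asarray(block_genotypes)
    n_samples, length = gmat.shape
    if m_ctrl is None:
        m_ctrl = n_samples
    informative = (gmat >= 0).any(axis=1)
    if not informative.any():
        raise EmptyCatalogError("all genotypes missing in block")

    # samples with identical genotypes have identical pair lists: run the
    # EM over unique genotype rows weighted by their multiplicity
    uniq, counts = np.unique(gmat[informative], axis=0, return_counts=True)
    xi, yi, sample_of_pair = [], [], []
    for s, row in enumerate(uniq):
        for x, y in _compatible_pairs(row):
            xi.append(x)
            yi.append(y)
            sample_of_pair.append(s)
    xi = np.asarray(xi, dtype=np.int64)
    yi = np.asarray(yi, dtype=np.int64)
    sample_of_pair = np.asarray(sample_of_pair, dtype=np.int64)

    universe, inv = np.unique(np.concatenate([xi, yi]), return_inverse=True)
    xidx = inv[: len(xi)]
    yidx = inv[len(xi):]
    mult = np.where(xi == yi, 1.0, 2.0)
    weights = counts.astype(np.float64)
    n_eff = float(weights.sum())

    f = np.full(len(universe), 1.0 / len(universe))
    last_ll = -np.inf
    for _ in range(EM_MAX_ITER):
        w = mult * f[xidx] * f[yidx]
        per_sample = np.bincount(sample_of_pair, weights=w,
                                 minlength=len(uniq))
        ll = float(np.sum(weights * np.log(np.maximum(per_sample,
                                                      1e-300))))
        if ll < last_ll - 1e-9:
            raise AssertionError("EM log-likelihood decreased")
        last_ll = ll
        post = (w / per_sample[sample_of_pair]) * weights[sample_of_pair]
        counts_h = (np.bincount(xidx, weights=post,
                                minlength=len(universe))
                    + np.bincount(yidx, weights=post,
                                  minlength=len(universe)))
        new_f = counts_h / (2.0 * n_eff)
        if np.max(np.abs(new_f - f)) < EM_TOL:
            f = new_f
            break
        f = new_f

    keep = f >= 1.0 / (4.0 * m_ctrl)
    if not keep.any():
        keep = f == f.max()
    universe, f = universe[keep], f[keep]
    f = f / f.sum()
    order = np.lexsort((universe, -f))
    universe, f = universe[order], f[order]
    haps = np.stack([_int_to_alleles(int(h), length) for h in universe])
    return haps, f


@dataclass
class ChromCatalog:
    """Haplotype catalog for one chromosome, aligned with its partition.

    ``block_haps[u]``/``block_freqs[u]`` are set for block units,
    ``hotspot_freq[u]`` (frequency of allele 1) for hotspot units and
    ``transitions[u]`` is the 2x2 matrix P(allele at the unit's first SNP |
    allele at the preceding marker) for every unit except the first.
    """

    partition: ChromPartition
    block_haps: dict = field(default_factory=dict)
    block_freqs: dict = field(default_factory=dict)
    hotspot_freq: dict = field(default_factory=dict)
    transitions: dict = field(default_factory=dict)
    m_ctrl: int = 0
    h_u: float = 0.0

    def freq_matrix(self, max_bits: int = 64) -> np.ndarray:
        """(n_units, max_bits) frequency lookup; h_u where no catalog
        haplotype (unknown ids score at the unknown-haplotype
        frequency).  Cached."""
        if getattr(self, "_freq_mat", None) is None:
            F = np.full((self.partition.n_units, max_bits), self.h_u)
            for u in range(self.partition.n_units):
                if self.partition.is_block[u]:
                    f = self.block_freqs[u]
                    F[u, :min(len(f), max_bits)] = f[:max_bits]
            self._freq_mat = F
        return self._freq_mat

    def freq_of(self, unit: int, hap_id: int) -> float:
        """Catalog frequency of hap_id in a block; h_u for unknown ids."""
        freqs = self.block_freqs[unit]
        if hap_id < len(freqs):
            return float(freqs[hap_id])
        return self.h_u

    def n_haps(self, unit: int) -> int:
        return len(self.block_freqs[unit])


def _transition_matrix(g_prev: np.ndarray, g_cur: np.ndarray) -> np.ndarray:
    """Smoothed P(cur allele | prev allele) from unphased adjacent markers."""
    n = _two_locus_counts(g_prev, g_cur)
    total = n.sum()
    if total == 0:
        return np.full((2, 2), 0.5)
    try:
        p = _em_haplotype_freqs(n)
    except FloatingPointError:  # pragma: no cover
        return np.full((2, 2), 0.5)
    # expected haplotype counts with add-one smoothing
    c = p * 2 * total + 1.0
    mat = np.array([[c[0], c[1]], [c[2], c[3]]])
    return mat / mat.sum(axis=1, keepdims=True)


def build_catalog(genotypes: np.ndarray, partition: ChromPartition,
                  m_ctrl: int | None = None) -> ChromCatalog:
    """Estimate the full per-unit catalog from control genotypes."""
    n_samples = genotypes.shape[0]
    if m_ctrl is None:
        m_ctrl = n_samples
    cat = ChromCatalog(partition=partition, m_ctrl=m_ctrl,
                       h_u=unknown_haplotype_frequency(m_ctrl))
    for u in range(partition.n_units):
        f, l = partition.first[u], partition.last[u]
        if partition.is_block[u]:
            sub = genotypes[:, f:l + 1]
            try:
                haps, freqs = estimate_block_haplotypes(sub, m_ctrl)
            except BlockTooComplexError:
                haps, freqs = _catalog_split_block(sub, m_ctrl)
            cat.block_haps[u] = haps
            cat.block_freqs[u] = freqs
        else:
            g = genotypes[:, f]
            obs = g[g >= 0]
            cat.hotspot_freq[u] = float(obs.mean() / 2.0) if len(obs) else 0.5
        if u > 0:
            prev_snp = partition.last[u - 1]
            cat.transitions[u] = _transition_matrix(
                genotypes[:, prev_snp], genotypes[:, f])
    return cat


def _catalog_split_block(sub: np.ndarray, m_ctrl: int,
                         max_haps: int = 64) -> tuple[np.ndarray, np.ndarray]:
    """Catalog an over-complex block by splitting it at its midpoint.

    The two halves are catalogued independently and recombined under
    independence; the combined list is pruned to the top frequencies.
    """
    mid = sub.shape[1] // 2
    log.warning("block with >2^%d compatible pairs split at SNP %d for "
                "cataloguing", MAX_AMBIGUITY_BITS, mid)
    hl, fl = estimate_block_haplotypes(sub[:, :mid], m_ctrl)
    hr, fr = estimate_block_haplotypes(sub[:, mid:], m_ctrl)
    haps = np.concatenate(
        [np.repeat(hl, len(hr), axis=0),
         np.tile(hr, (len(hl), 1))], axis=1)
    freqs = np.outer(fl, fr).ravel()
    order = np.argsort(-freqs)[:max_haps]
    haps, freqs = haps[order], freqs[order]
    keep = freqs >= 1.0 / (4.0 * m_ctrl)
    if not keep.any():
        keep = freqs == freqs.max()
    haps, freqs = haps[keep], freqs[keep]
    return haps, freqs / freqs.sum()


def catalog_from_haplotypes(haplotypes: np.ndarray,
                            partition: ChromPartition,
                            m_ctrl: int | None = None) -> ChromCatalog:
    """Build a catalog from externally phased haplotypes (one per row).

    Frequencies are direct counts; transitions are empirical conditional
    frequencies between adjacent markers with add-one smoothing.
    """
    h = np.asarray(haplotypes)
    n_chrom = h.shape[0]
    if m_ctrl is None:
        m_ctrl = n_chrom // 2
    cat = ChromCatalog(partition=partition, m_ctrl=m_ctrl,
                       h_u=unknown_haplotype_frequency(m_ctrl))
    for u in range(partition.n_units):
        f, l = partition.first[u], partition.last[u]
        if partition.is_block[u]:
            sub = h[:, f:l + 1]
            uniq, counts = np.unique(sub, axis=0, return_counts=True)
            freqs = counts / counts.sum()
            order = np.argsort(-freqs, kind="stable")
            cat.block_haps[u] = uniq[order].astype(np.int8)
            cat.block_freqs[u] = freqs[order]
        else:
            cat.hotspot_freq[u] = float(h[:, f].mean())
        if u > 0:
            prev = h[:, partition.last[u - 1]]
            cur = h[:, f]
            mat = np.ones((2, 2))
            np.add.at(mat, (prev.astype(int), cur.astype(int)), 1.0)
            cat.transitions[u] = mat / mat.sum(axis=1, keepdims=True)
    return cat


def generate_virtual_haplotypes(cat: ChromCatalog, n: int,
                                rng: np.random.Generator) -> np.ndarray:
    """Sample ``2*n`` chromosomes from the catalog's block/Markov model.

    Block haplotypes are drawn independently per block proportional to
    their catalog frequencies; hotspot alleles follow the first-order
    Markov transition from the preceding marker on the same chromosome.
    """
    part = cat.partition
    n_chrom = 2 * n
    out = np.zeros((n_chrom, part.n_snps), dtype=np.int8)
    prev_allele = None
    for u in range(part.n_units):
        f, l = part.first[u], part.last[u]
        if part.is_block[u]:
            freqs = cat.block_freqs[u]
            if len(freqs) == 0:
                raise EmptyCatalogError(f"block unit {u} has empty catalog")
            idx = rng.choice(len(freqs), size=n_chrom, p=freqs)
            out[:, f:l + 1] = cat.block_haps[u][idx]
        else:
            if u == 0 or prev_allele is None:
                p1 = np.full(n_chrom, cat.hotspot_freq[u])
            else:
                p1 = cat.transitions[u][prev_allele, 1]
            out[:, f] = (rng.random(n_chrom) < p1).astype(np.int8)
        prev_allele = out[:, l].astype(np.int64)
    return out


def generate_virtual_samples(cat: ChromCatalog, n: int,
                             seed_or_rng) -> np.ndarray:
    """Diploid genotype matrix of ``n`` virtual samples from the catalog."""
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    h = generate_virtual_haplotypes(cat, n, rng)
    return (h[0::2] + h[1::2]).astype(np.int8)
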