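"""Shared fixtures: small synthetic populations and hand-built phasing."""

import numpy as np
import pytest

from ibdshare import generate_synthetic_population
from ibdshare.catalog import ChromCatalog, unknown_haplotype_frequency
from ibdshare.ld import ChromPartition
from ibdshare.phasing import PhasedChrom


@pytest.fixture(scope="session")
def small_pop():
    """400-SNP / 20 cM population of 150 samples with known truth."""
    return generate_synthetic_population(150, seed=11, n_snps=400,
                                         span_cm=20.0)


@pytest.fixture(scope="session")
def medium_pop():
    """1000-SNP / 50 cM population of 500 samples with known truth."""
    return generate_synthetic_population(500, seed=12, n_snps=1000,
                                         span_cm=50.0)


def make_phased(masks, is_block=None, catalog=None):
    """Build a PhasedChrom directly from a candidate-mask matrix.

    Block units hold two SNPs (the minimum), hotspot units one;
    block/hotspot status defaults to all blocks.  Used for surgical
    detection tests where the masks are the ground truth.
    """
    masks = np.asarray(masks, dtype=np.uint64)
    n_units = masks.shape[1]
    if is_block is None:
        is_block = np.ones(n_units, dtype=bool)
    is_block = np.asarray(is_block, dtype=bool)
    sizes = np.where(is_block, 2, 1)
    last = np.cumsum(sizes) - 1
    first = last - sizes + 1
    part = ChromPartition(first, last, is_block)
    if catalog is None:
        catalog = ChromCatalog(partition=part, m_ctrl=100,
                               h_u=unknown_haplotype_frequency(100))
        for u in range(n_units):
            if part.is_block[u]:
                # descending dummy frequencies for up to 8 haplotype ids
                f = np.array([0.4, 0.2, 0.1, 0.08, 0.07, 0.06, 0.05,
                              0.04])
                catalog.block_freqs[u] = f / f.sum()
                size = part.last[u] - part.first[u] + 1
                catalog.block_haps[u] = np.zeros((8, size), dtype=np.int8)
            else:
                catalog.hotspot_freq[u] = 0.5
    scenarios = np.zeros(masks.shape, dtype=np.int8)
    scenarios[:, ~part.is_block] = -1
    return PhasedChrom(part, catalog, masks, scenarios, {}, {})


def uniform_cm(phased, total_cm):
    """Per-SNP cM positions: units evenly spaced over ``total_cm``, zero
    genetic distance inside a unit (so unit spans translate directly to
    genetic lengths)."""
    part = phased.partition
    u_cm = np.linspace(0.0, total_cm, part.n_units)
    return u_cm[part.unit_of_snp()]
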