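"""Block-wise phasing of genotypes against a population haplotype catalog.

Each sample's genotype over an LD block is explained by unordered pairs of
catalog haplotypes whose site-wise allele sums match the genotype at every
non-missing site.  Four scenarios are distinguished: (A) a unique pair,
(B) several pairs (all retained), (C) no catalog pair but one catalog
haplotype plus a forced non-catalog partner (the "unknown" haplotype,
carrying frequency h_u), and (D) nothing compatible — assumed genotyping
error; the block cannot seed sharing but does not stop extension through
it.

For fast downstream pair matching every sample×unit cell also gets a
uint64 candidate bitmask: for blocks one bit per candidate haplotype id
(catalog ids first, then unknown ids per block; ids beyond 63 share bit
63), for hotspot SNPs the set of alleles consistent with the genotype
(heterozygous or missing genotypes are consistent with both).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .catalog import ChromCatalog
from .ld import ChromPartition

log = logging.getLogger(__name__)

SCENARIOS = "ABCD"
MASK_BITS = 64


@dataclass
class PhasedBlockState:
    """Phasing outcome of one sample over one block.

    ``pairs`` holds unordered id pairs; ids >= the catalog size index into
    ``unknown_strings`` (id - n_catalog) and carry frequency h_u.
    """

    scenario: str
    pairs: list
    unknown_strings: list = field(default_factory=list)


def _pair_table(haps: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All unordered catalog id pairs and their site-wise allele sums."""
    h = len(haps)
    ii, jj = np.triu_indices(h)
    sums = haps[ii] + haps[jj]
    return np.stack([ii, jj], axis=1), sums


def _forced_partners(g: np.ndarray, haps: np.ndarray):
    """Scenario-C candidates: (catalog id, forced partner alleles) pairs.

    The partner at missing sites is coded 0 (cannot be inferred); with no
    missing data the string is exact.
    """
    out = []
    obs = g >= 0
    for i, h in enumerate(haps):
        partner = g - h
        if np.all((partner[obs] == 0) | (partner[obs] == 1)):
            p = np.where(obs, partner, 0).astype(np.int8)
            out.append((i, p))
    return out


def phase_block(genotype: np.ndarray, catalog_haps: np.ndarray,
                h_u: float | None = None) -> PhasedBlockState:
    """Phase one genotype over one block against the catalog.

    ``h_u`` is carried by any unknown partner and is only documented here;
    the returned state stores ids and forced allele strings.
    """
    g = np.asarray(genotype)
    haps = np.asarray(catalog_haps)
    if g.shape[0] != haps.shape[1]:
        raise ValueError("genotype length does not match block SNP count")
    ids, sums = _pair_table(haps)
    obs = g >= 0
    ok = np.all(sums[:, obs] == g[obs], axis=1)
    pairs = [tuple(p) for p in ids[ok]]
    if pairs:
        scen = "A" if len(pairs) == 1 else "B"
        return PhasedBlockState(scen, pairs)
    forced = _forced_partners(g, haps)
    if forced:
        n_cat = len(haps)
        strings, pairs = [], []
        for i, p in forced:
            key = p.tobytes()
            existing = [k for k, s in enumerate(strings) if s.tobytes() == key]
            uid = existing[0] if existing else len(strings)
            if not existing:
                strings.append(p)
            pairs.append((i, n_cat + uid))
        return PhasedBlockState("C", pairs, strings)
    return PhasedBlockState("D", [])


@dataclass
class PhasedChrom:
    """Phasing of many samples against one chromosome's catalog.

    ``masks`` is the (n_samples, n_units) uint64 candidate bitmask matrix;
    ``scenarios`` holds 0..3 (= A..D) for block units and -1 for hotspots;
    ``block_pairs[u][s]`` the candidate id-pair list (present for block
    units); ``unknown_strings[u]`` the per-block registry of forced
    non-catalog haplotypes, id = n_catalog + position.
    """

    partition: ChromPartition
    catalog: ChromCatalog
    masks: np.ndarray
    scenarios: np.ndarray
    block_pairs: dict
    unknown_strings: dict

    @property
    def n_samples(self) -> int:
        return self.masks.shape[0]

    def census(self) -> dict:
        """Fractions of scenarios A-D over all sample x block cells."""
        cells = self.scenarios[:, self.partition.is_block]
        total = cells.size
        if total == 0:
            return {s: 0.0 for s in SCENARIOS}
        return {s: float(np.mean(cells == i))
                for i, s in enumerate(SCENARIOS)}

    def hap_string(self, unit: int, hap_id: int) -> np.ndarray:
        """Allele string of a (catalog or unknown) haplotype id in a block."""
        haps = self.catalog.block_haps[unit]
        if hap_id < len(haps):
            return haps[hap_id]
        return self.unknown_strings[unit][hap_id - len(haps)]

    def subset(self, sample_idx: np.ndarray) -> "PhasedChrom":
        sample_idx = np.asarray(sample_idx)
        return PhasedChrom(
            self.partition, self.catalog,
            self.masks[sample_idx], self.scenarios[sample_idx],
            {u: [lst[s] for s in sample_idx]
             for u, lst in self.block_pairs.items()},
            self.unknown_strings,
        )


def _bit(hap_id: int) -> np.uint64:
    return np.uint64(1) << np.uint64(min(hap_id, MASK_BITS - 1))


def hotspot_mask(genotype_column: np.ndarray) -> np.ndarray:
    """Allele-consistency bitmask for a hotspot SNP column."""
    g = np.asarray(genotype_column)
    mask = np.full(g.shape, 3, dtype=np.uint64)
    mask[g == 0] = 1
    mask[g == 2] = 2
    return mask


def phase_all(genotypes: np.ndarray, partition: ChromPartition,
              catalog: ChromCatalog) -> PhasedChrom:
    """Phase every sample over every unit of one chromosome."""
    g = np.asarray(genotypes)
    n_samples = g.shape[0]
    n_units = partition.n_units
    masks = np.zeros((n_samples, n_units), dtype=np.uint64)
    scenarios = np.full((n_samples, n_units), -1, dtype=np.int8)
    block_pairs: dict = {}
    unknown_strings: dict = {}
    overflow_warned = False

    for u in range(n_units):
        f, l = partition.first[u], partition.last[u]
        if not partition.is_block[u]:
            masks[:, u] = hotspot_mask(g[:, f])
            continue
        haps = catalog.block_haps[u]
        n_cat = len(haps)
        ids, sums = _pair_table(haps)
        sub = g[:, f:l + 1]
        obs = sub[:, None, :] < 0
        ok = np.all((sums[None, :, :] == sub[:, None, :]) | obs, axis=2)
        registry: list[np.ndarray] = []
        reg_keys: dict[bytes, int] = {}
        per_sample = []
        for s in range(n_samples):
            plist = [tuple(p) for p in ids[ok[s]]]
            if plist:
                scenarios[s, u] = 0 if len(plist) == 1 else 1
            else:
                forced = _forced_partners(sub[s], haps)
                if forced:
                    scenarios[s, u] = 2
                    for i, pstr in forced:
                        key = pstr.tobytes()
                        if key not in reg_keys:
                            reg_keys[key] = len(registry)
                            registry.append(pstr)
                        plist.append((i, n_cat + reg_keys[key]))
                else:
                    scenarios[s, u] = 3
            per_sample.append(plist)
            m = np.uint64(0)
            for a, b in plist:
                m |= _bit(a) | _bit(b)
            masks[s, u] = m
        if n_cat + len(registry) > MASK_BITS and not overflow_warned:
            overflow_warned = True
            log.warning("unit %d has >%d haplotype ids; rare ids share the "
                        "top mask bit", u, MASK_BITS)
        block_pairs[u] = per_sample
        unknown_strings[u] = registry
    return PhasedChrom(partition, catalog, masks, scenarios,
                       block_pairs, unknown_strings)
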