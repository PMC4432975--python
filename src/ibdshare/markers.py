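"""Marker metadata and genetic-map interpolation.

A :class:`MarkerTable` carries per-SNP metadata (chromosome, id, physical
position, the two allele symbols); a :class:`GeneticMap` maps physical
positions (bp) to cumulative genetic positions (cM) by linear interpolation
between anchors, clamping outside the anchored range.  All genetic distances
used elsewhere in the package derive from the map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger(__name__)


@dataclass
class MarkerTable:
    """Ordered SNP marker metadata for one or more chromosomes.

    Positions must be strictly increasing within each chromosome and every
    marker must have exactly two allele symbols.
    """

    chrom: np.ndarray          # str per SNP
    ids: np.ndarray            # marker names
    bp: np.ndarray             # 1-based physical positions, int64
    alleles: np.ndarray        # (n_snps, 2) allele symbols, str

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.ids = np.asarray(self.ids, dtype=object)
        self.bp = np.asarray(self.bp, dtype=np.int64)
        self.alleles = np.asarray(self.alleles, dtype=object)
        if self.alleles.ndim != 2 or self.alleles.shape[1] != 2:
            raise ValueError("alleles must be an (n_snps, 2) array")
        for c in self.chromosomes():
            pos = self.bp[self.chrom == c]
            if np.any(np.diff(pos) <= 0):
                raise ValueError(
                    f"marker positions not strictly increasing on chromosome {c}"
                )

    def __len__(self) -> int:
        return len(self.bp)

    def chromosomes(self) -> list:
        """Chromosome labels in order of first appearance."""
        seen, out = set(), []
        for c in self.chrom:
            if c not in seen:
                seen.add(c)
                out.append(c)
        return out

    def indices_for(self, chrom) -> np.ndarray:
        return np.nonzero(self.chrom == chrom)[0]

    def subset(self, idx: np.ndarray) -> "MarkerTable":
        return MarkerTable(self.chrom[idx], self.ids[idx], self.bp[idx],
                           self.alleles[idx])


@dataclass
class GeneticMap:
    """Piecewise-linear physical→genetic coordinate map.

    ``anchors`` maps chromosome label to ``(bp, cM)`` arrays with cM
    non-decreasing in bp.  Queries outside the anchored range clamp to the
    terminal cM values (with a warning the first time per chromosome).
    """

    anchors: dict = field(default_factory=dict)
    _warned: set = field(default_factory=set, repr=False)

    def add_chromosome(self, chrom, bp, cm) -> None:
        bp = np.asarray(bp, dtype=np.float64)
        cm = np.asarray(cm, dtype=np.float64)
        if bp.ndim != 1 or bp.shape != cm.shape or len(bp) < 2:
            raise ValueError("need matched 1-d bp/cM arrays with >=2 anchors")
        if np.any(np.diff(bp) <= 0):
            raise ValueError("anchor bp positions must be strictly increasing")
        if np.any(np.diff(cm) < 0):
            raise ValueError("anchor cM positions must be non-decreasing")
        self.anchors[chrom] = (bp, cm)

    def interpolate(self, chrom, bp) -> np.ndarray:
        """cM positions for physical positions ``bp`` on ``chrom`` (clamped)."""
        if chrom not in self.anchors:
            raise KeyError(f"no genetic map for chromosome {chrom}")
        abp, acm = self.anchors[chrom]
        bp = np.asarray(bp, dtype=np.float64)
        if chrom not in self._warned and (
            np.any(bp < abp[0]) or np.any(bp > abp[-1])
        ):
            self._warned.add(chrom)
            log.warning("markers outside genetic-map range on %s clamped", chrom)
        return np.interp(bp, abp, acm)

    def inverse(self, chrom, cm) -> np.ndarray:
        """Physical positions for cM positions (piecewise-linear inverse)."""
        abp, acm = self.anchors[chrom]
        return np.interp(np.asarray(cm, dtype=np.float64), acm, abp)

    def span_cm(self, chrom) -> tuple[float, float]:
        _, acm = self.anchors[chrom]
        return float(acm[0]), float(acm[-1])
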