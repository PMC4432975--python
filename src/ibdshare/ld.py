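"""Chromosome partitioning into LD blocks and recombination hotspots.

Two partition methods are provided.  The primary one classifies adjacent
SNP pairs by the one-sided upper 95% confidence bound of |D'| (strong if
the bound exceeds 0.98, weak if below 0.90, uninformative otherwise) and
grows blocks greedily 5'→3' while the strong/(strong+weak) ratio over all
pairs inside the candidate block stays above 0.95 and no adjacent gap
exceeds 50 kb.  The fallback uses genetic-map distances only: adjacent SNPs
closer than 0.001 cM and within 10 kb are chained into a block.

The |D'| bound is a profile-likelihood bound: two-locus haplotype
frequencies are estimated by EM, allele frequencies are then held fixed and
the multinomial log-likelihood is profiled over |D'| on a 1000-point grid
(both sign branches); the bound is the largest |D'| whose log-likelihood is
within chi2_1(0.90)/2 of the maximum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

STRONG_BOUND = 0.98
WEAK_BOUND = 0.90
BLOCK_RATIO = 0.95
MAX_GAP_BP = 50_000
MAP_MAX_CM = 0.001
MAP_MAX_BP = 10_000
MIN_INFORMATIVE = 10

# chi2_1 quantile at 0.90, halved: drop in log-likelihood defining the
# one-sided upper 95% profile bound
_LL_DROP = 2.705543454095404 / 2.0

_GRID = np.linspace(0.0, 1.0, 1000)


class MonomorphicMarkerError(ValueError):
    """LD is undefined for a marker with a single observed allele."""


class InsufficientDataError(ValueError):
    """No (or too few) samples informative for the SNP pair."""


@dataclass(frozen=True)
class DPrimeClassification:
    """Label and upper 95% profile-likelihood bound of |D'| for a SNP pair."""

    bound: float
    label: str  # "strong" | "weak" | "uninformative"


@dataclass
class ChromPartition:
    """Ordered disjoint cover of one chromosome's SNPs by blocks/hotspots.

    ``first``/``last`` are inclusive SNP indices per unit; ``is_block``
    marks units with >=2 SNPs held together by LD.
    """

    first: np.ndarray
    last: np.ndarray
    is_block: np.ndarray

    def __post_init__(self) -> None:
        self.first = np.asarray(self.first, dtype=np.int64)
        self.last = np.asarray(self.last, dtype=np.int64)
        self.is_block = np.asarray(self.is_block, dtype=bool)
        if np.any(self.last < self.first):
            raise ValueError("unit last < first")
        if np.any(self.is_block & (self.last == self.first)):
            raise ValueError("a Block must contain >=2 SNPs")
        covered = np.concatenate(
            [np.arange(f, l + 1) for f, l in zip(self.first, self.last)]
        ) if len(self.first) else np.array([], dtype=np.int64)
        n = self.last[-1] + 1 if len(self.last) else 0
        if not np.array_equal(np.sort(covered), np.arange(n)):
            raise ValueError("units must cover every SNP exactly once")

    @property
    def n_units(self) -> int:
        return len(self.first)

    @property
    def n_snps(self) -> int:
        return int(self.last[-1]) + 1 if self.n_units else 0

    def unit_sizes(self) -> np.ndarray:
        return self.last - self.first + 1

    def unit_of_snp(self) -> np.ndarray:
        """Array mapping SNP index -> unit index."""
        out = np.empty(self.n_snps, dtype=np.int64)
        for u, (f, l) in enumerate(zip(self.first, self.last)):
            out[f:l + 1] = u
        return out


class LDPartition(dict):
    """Mapping chromosome label -> :class:`ChromPartition`."""


def _two_locus_counts(ga: np.ndarray, gb: np.ndarray) -> np.ndarray:
    ga = np.asarray(ga, dtype=np.int64)
    gb = np.asarray(gb, dtype=np.int64)
    keep = (ga >= 0) & (gb >= 0)
    ga, gb = ga[keep], gb[keep]
    n = np.zeros((3, 3), dtype=np.float64)
    np.add.at(n, (ga, gb), 1.0)
    return n


def _em_haplotype_freqs(n: np.ndarray, tol: float = 1e-10,
                        max_iter: int = 200) -> np.ndarray:
    """EM estimates of the four two-locus haplotype frequencies.

    Returns ``[p00, p01, p10, p11]`` where the first index is the allele at
    the first locus.  Only the double-heterozygote cell is phase-ambiguous.
    """
    c00 = 2 * n[0, 0] + n[0, 1] + n[1, 0]
    c01 = 2 * n[0, 2] + n[0, 1] + n[1, 2]
    c10 = 2 * n[2, 0] + n[1, 0] + n[2, 1]
    c11 = 2 * n[2, 2] + n[2, 1] + n[1, 2]
    ndh = n[1, 1]
    total = c00 + c01 + c10 + c11 + 2 * ndh
    p = np.array([c00 + ndh / 2, c01 + ndh / 2,
                  c10 + ndh / 2, c11 + ndh / 2]) / total
    for _ in range(max_iter):
        cis = p[0] * p[3]
        trans = p[1] * p[2]
        w = cis / (cis + trans) if cis + trans > 0 else 0.5
        new = np.array([c00 + w * ndh, c01 + (1 - w) * ndh,
                        c10 + (1 - w) * ndh, c11 + w * ndh]) / total
        if np.max(np.abs(new - p)) < tol:
            p = new
            break
        p = new
    return p


def _genotype_cell_probs(p00, p01, p10, p11):
    """3x3 genotype-cell probabilities under HWE given haplotype freqs.

    Inputs may be arrays (grid axis); output shape (..., 3, 3).
    """
    probs = np.empty(np.broadcast(p00, p11).shape + (3, 3))
    probs[..., 0, 0] = p00 ** 2
    probs[..., 0, 1] = 2 * p00 * p01
    probs[..., 0, 2] = p01 ** 2
    probs[..., 1, 0] = 2 * p00 * p10
    probs[..., 1, 1] = 2 * p00 * p11 + 2 * p01 * p10
    probs[..., 1, 2] = 2 * p01 * p11
    probs[..., 2, 0] = p10 ** 2
    probs[..., 2, 1] = 2 * p10 * p11
    probs[..., 2, 2] = p11 ** 2
    return probs


def dprime_upper_bound(genotypes_a: np.ndarray,
                       genotypes_b: np.ndarray) -> float:
    """Upper 95% profile-likelihood bound of |D'| for one SNP pair."""
    n = _two_locus_counts(genotypes_a, genotypes_b)
    total = n.sum()
    if total == 0:
        raise InsufficientDataError("no samples with both genotypes observed")
    # marginal allele counts
    ca1 = n[1, :].sum() + 2 * n[2, :].sum()
    cb1 = n[:, 1].sum() + 2 * n[:, 2].sum()
    if ca1 == 0 or ca1 == 2 * total or cb1 == 0 or cb1 == 2 * total:
        raise MonomorphicMarkerError("monomorphic marker: D' undefined")
    p = _em_haplotype_freqs(n)
    pa = p[2] + p[3]
    pb = p[1] + p[3]
    # both sign branches evaluated on one stacked grid
    dmax_pos = min(pa * (1 - pb), (1 - pa) * pb)
    dmax_neg = min(pa * pb, (1 - pa) * (1 - pb))
    d = np.concatenate([_GRID * dmax_pos, -_GRID * dmax_neg])
    p11 = np.clip(pa * pb + d, 0.0, 1.0)
    p10 = np.clip(pa - p11, 0.0, 1.0)
    p01 = np.clip(pb - p11, 0.0, 1.0)
    p00 = np.clip(1.0 - pa - pb + p11, 0.0, 1.0)
    probs = _genotype_cell_probs(p00, p01, p10, p11)
    with np.errstate(divide="ignore"):
        lp = np.log(np.maximum(probs, 1e-300))
    ll2 = np.einsum("gij,ij->g", lp, n)
    ll = np.maximum(ll2[:len(_GRID)], ll2[len(_GRID):])
    cutoff = ll.max() - _LL_DROP
    ok = np.nonzero(ll >= cutoff)[0]
    return float(_GRID[ok[-1]])


def classify_pair(genotypes_a: np.ndarray,
                  genotypes_b: np.ndarray) -> DPrimeClassification:
    """Classify one SNP pair as strong / weak / uninformative LD.

    Raises :class:`MonomorphicMarkerError` for a marker with one allele and
    :class:`InsufficientDataError` if no sample is observed at both markers.
    Pairs with fewer than ``MIN_INFORMATIVE`` complete samples are labelled
    uninformative without computing a bound.
    """
    n = _two_locus_counts(genotypes_a, genotypes_b)
    if n.sum() == 0:
        raise InsufficientDataError("no samples with both genotypes observed")
    if n.sum() < MIN_INFORMATIVE:
        return DPrimeClassification(bound=float("nan"), label="uninformative")
    bound = dprime_upper_bound(genotypes_a, genotypes_b)
    if bound > STRONG_BOUND:
        label = "strong"
    elif bound < WEAK_BOUND:
        label = "weak"
    else:
        label = "uninformative"
    return DPrimeClassification(bound=bound, label=label)


class _PairLabeller:
    """Caches strong/weak/uninformative labels for SNP pairs."""

    def __init__(self, genotypes: np.ndarray):
        self.g = genotypes
        self.cache: dict[tuple[int, int], str] = {}

    def label(self, i: int, j: int) -> str:
        key = (i, j) if i < j else (j, i)
        if key not in self.cache:
            try:
                lab = classify_pair(self.g[:, key[0]], self.g[:, key[1]]).label
            except (MonomorphicMarkerError, InsufficientDataError):
                lab = "uninformative"
            self.cache[key] = lab
        return self.cache[key]


def partition_by_ld(genotypes: np.ndarray, bp: np.ndarray) -> ChromPartition:
    """Partition one chromosome's SNPs into LD blocks and hotspot SNPs.

    ``genotypes`` is (n_samples, n_snps) with codes 0/1/2 and -1 missing;
    ``bp`` the physical positions.  A block is seeded at the first adjacent
    strong-LD pair and extended while the strong/(strong+weak) ratio over
    all pairs within the candidate block stays > 0.95 and no adjacent gap
    exceeds 50 kb.  Uninformative pairs enter neither numerator nor
    denominator.  Unabsorbed SNPs become hotspot units.
    """
    bp = np.asarray(bp, dtype=np.int64)
    n_snps = genotypes.shape[1]
    if n_snps < 2:
        raise ValueError("need >=2 SNPs per chromosome")
    lab = _PairLabeller(genotypes)
    first, last, is_block = [], [], []
    i = 0
    while i < n_snps:
        if i == n_snps - 1:
            first.append(i); last.append(i); is_block.append(False)
            break
        if bp[i + 1] - bp[i] > MAX_GAP_BP or lab.label(i, i + 1) != "strong":
            first.append(i); last.append(i); is_block.append(False)
            i += 1
            continue
        # seed accepted: candidate block [i, j]
        j = i + 1
        strong, weak = 1, 0
        while j + 1 < n_snps and bp[j + 1] - bp[j] <= MAX_GAP_BP:
            s_add = w_add = 0
            for t in range(i, j + 1):
                l = lab.label(t, j + 1)
                if l == "strong":
                    s_add += 1
                elif l == "weak":
                    w_add += 1
            denom = strong + s_add + weak + w_add
            if denom > 0 and (strong + s_add) / denom > BLOCK_RATIO:
                strong += s_add
                weak += w_add
                j += 1
            else:
                break
        first.append(i); last.append(j); is_block.append(True)
        i = j + 1
    return ChromPartition(np.array(first), np.array(last),
                          np.array(is_block))


def partition_by_map(bp: np.ndarray, cm: np.ndarray) -> ChromPartition:
    """Partition using genetic-map distances only.

    Adjacent SNPs are chained iff their genetic distance is < 0.001 cM and
    their physical distance is <= 10 kb; maximal chains of >=2 SNPs become
    blocks, all other SNPs hotspots.
    """
    bp = np.asarray(bp, dtype=np.int64)
    cm = np.asarray(cm, dtype=np.float64)
    n = len(bp)
    if n < 2:
        raise ValueError("need >=2 SNPs per chromosome")
    link = (np.diff(cm) < MAP_MAX_CM) & (np.diff(bp) <= MAP_MAX_BP)
    first, last, is_block = [], [], []
    i = 0
    while i < n:
        j = i
        while j < n - 1 and link[j]:
            j += 1
        if j > i:
            first.append(i); last.append(j); is_block.append(True)
        else:
            first.append(i); last.append(i); is_block.append(False)
        i = j + 1
    return ChromPartition(np.array(first), np.array(last),
                          np.array(is_block))
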