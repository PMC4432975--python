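"""Detection of extended haplotypes shared by pairs and groups of samples.

Pairwise detection works on the unit grid (LD blocks + hotspot SNPs): two
samples match at a unit when their candidate bitmasks intersect (any
candidate haplotype of one equals any of the other; at hotspots, a shared
allele is consistent with both genotypes).  Maximal matched runs become
segments; interior mismatching units are tolerated while the mismatching
SNPs stay within 1% of the segment's SNPs and no mismatch falls within the
first or last 20 SNPs (so a tolerated mismatch needs at least 20 clean
SNPs on each flank).  A segment must contain at least one matched LD block
(hotspot-only matches cannot seed sharing) and reach a minimum genetic
length.

Groups of k >= 2 samples are then seeded per (block, haplotype id) key:
the group for a key consists of every sample joined to another by a
pairwise segment sharing that haplotype at that block; a member's shared
interval is the union of its supporting segments (contiguous, since all
contain the seed block).  Groups with identical member sets and
overlapping spans are deduplicated, and groups larger than the analysis
cap are discarded.  When chance sharing is sparse this reproduces the
transitive merge of overlapping pair segments on the same allele; when it
is dense it decomposes haplotype corridors into per-key groups instead of
chaining them into a single core-less component.  The core of a group is
the contiguous unit run around the seed block over which all members
share a common candidate haplotype.

A rescue scan adds samples that carry the full core haplotype and share
at least half the pairwise length threshold around it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phasing import PhasedChrom

try:
    from numba import njit as _njit
except ImportError:  # pragma: no cover - numba is a standard dependency
    def _njit(*a, **k):
        def deco(f):
            return f
        return deco if not (a and callable(a[0])) else a[0]


@_njit(cache=False)
def _completion_qualify(cand, ou0, ou1, masks, bbarr, span0, ok,
                        matched):
    """Per-segment agreement of a candidate with the group haplotype."""
    for i in range(len(cand)):
        c = cand[i]
        m = 0
        good = True
        for u in range(ou0[i], ou1[i] + 1):
            bits = bbarr[u - span0]
            if bits == np.uint64(0):
                continue
            if masks[c, u] & bits:
                m += 1
            else:
                good = False
                break
        ok[i] = good and m >= 1
        matched[i] = m


@_njit(cache=False)
def _count_distinct(a, b, stamp, version):
    c = 0
    for x in a:
        if stamp[x] != version:
            stamp[x] = version
            c += 1
    for x in b:
        if stamp[x] != version:
            stamp[x] = version
            c += 1
    return c


MISMATCH_FRACTION = 0.01
CLEAN_END_SNPS = 20
MAX_BITS = 64


# ---------------------------------------------------------------------------
# segments

@dataclass
class SharedSegment:
    """A maximal extended haplotype shared by one sample pair."""

    a: int
    b: int
    u0: int
    u1: int
    snp0: int
    snp1: int
    bad_units: tuple
    n_mismatch_snps: int
    d_g: float


@dataclass
class SegmentSet:
    """Column-array store of pairwise segments on one chromosome."""

    a: np.ndarray
    b: np.ndarray
    u0: np.ndarray
    u1: np.ndarray
    snp0: np.ndarray
    snp1: np.ndarray
    n_bad: np.ndarray
    d_g: np.ndarray

    def __len__(self) -> int:
        return len(self.a)

    @staticmethod
    def empty() -> "SegmentSet":
        z = np.array([], dtype=np.int32)
        return SegmentSet(z, z, z.copy(), z.copy(), z.copy(), z.copy(),
                          z.copy(), np.array([], dtype=np.float64))

    @staticmethod
    def concat(parts: list) -> "SegmentSet":
        parts = [p for p in parts if len(p)]
        if not parts:
            return SegmentSet.empty()
        return SegmentSet(*[np.concatenate([getattr(p, f) for p in parts])
                            for f in ("a", "b", "u0", "u1", "snp0", "snp1",
                                      "n_bad", "d_g")])

    def to_objects(self, phased: PhasedChrom) -> list:
        """Materialise :class:`SharedSegment` objects (small inputs)."""
        part = phased.partition
        out = []
        for i in range(len(self)):
            bad = []
            if self.n_bad[i]:
                for u in range(self.u0[i], self.u1[i] + 1):
                    if phased.masks[self.a[i], u] & \
                            phased.masks[self.b[i], u] == 0:
                        bad.append(int(u))
            out.append(SharedSegment(
                int(self.a[i]), int(self.b[i]), int(self.u0[i]),
                int(self.u1[i]), int(self.snp0[i]), int(self.snp1[i]),
                tuple(bad), int(self.n_bad[i]), float(self.d_g[i])))
        return out

    @staticmethod
    def from_objects(segments: list) -> "SegmentSet":
        if not segments:
            return SegmentSet.empty()
        f32 = np.float64
        return SegmentSet(
            np.array([s.a for s in segments], dtype=np.int32),
            np.array([s.b for s in segments], dtype=np.int32),
            np.array([s.u0 for s in segments], dtype=np.int32),
            np.array([s.u1 for s in segments], dtype=np.int32),
            np.array([s.snp0 for s in segments], dtype=np.int32),
            np.array([s.snp1 for s in segments], dtype=np.int32),
            np.array([s.n_mismatch_snps for s in segments], dtype=np.int32),
            np.array([s.d_g for s in segments], dtype=f32))


def all_pairs(n: int) -> np.ndarray:
    """All unordered sample index pairs as an (n*(n-1)/2, 2) array."""
    ii, jj = np.triu_indices(n, k=1)
    return np.stack([ii, jj], axis=1).astype(np.int64)


def _runs_by_row(match: np.ndarray):
    """Maximal True runs per row of a bool matrix as (row, u0, u1)."""
    n_rows, n_units = match.shape
    width = n_units + 2
    padded = np.zeros((n_rows, width), dtype=np.int8)
    padded[:, 1:n_units + 1] = match
    flat = padded.ravel()
    d = np.diff(flat)
    starts = np.nonzero(d == 1)[0] + 1
    ends = np.nonzero(d == -1)[0]
    rows = (starts // width).astype(np.int64)
    return rows, starts % width - 1, ends % width - 1


def _bridge_runs(rows, u0, u1, snp0, snp1, n_bad, fb, lb):
    """One vectorised pass of merging adjacent runs across mismatch gaps.

    ``fb``/``lb`` are the first/last mismatching SNP of each run
    (sentinels when clean).  The merged candidate must keep mismatching
    SNPs within the 1% budget and at least 20 clean SNPs away from both
    segment ends.  Greedy left-to-right within a row; returns updated
    arrays and whether any merge happened.
    """
    n = len(rows)
    if n < 2:
        return (rows, u0, u1, snp0, snp1, n_bad, fb, lb), False
    # cheap prefilter: both flanking runs must offer 20 clean SNPs
    nsnp = snp1 - snp0 + 1
    base = ((rows[:-1] == rows[1:])
            & (nsnp[:-1] - n_bad[:-1] >= CLEAN_END_SNPS)
            & (nsnp[1:] - n_bad[1:] >= CLEAN_END_SNPS))
    cand = np.nonzero(base)[0]
    if len(cand) == 0:
        return (rows, u0, u1, snp0, snp1, n_bad, fb, lb), False
    c1 = cand + 1
    gap_bad_c = snp0[c1] - snp1[cand] - 1
    new_bad_c = n_bad[cand] + n_bad[c1] + gap_bad_c
    span_c = snp1[c1] - snp0[cand] + 1
    first_bad_c = np.minimum(fb[cand], snp1[cand] + 1)
    last_bad_c = np.maximum(lb[c1], snp0[c1] - 1)
    ok_c = ((new_bad_c <= MISMATCH_FRACTION * span_c)
            & (first_bad_c - snp0[cand] >= CLEAN_END_SNPS)
            & (snp1[c1] - last_bad_c >= CLEAN_END_SNPS))
    if not ok_c.any():
        return (rows, u0, u1, snp0, snp1, n_bad, fb, lb), False
    ok = np.zeros(n - 1, dtype=bool)
    ok[cand[ok_c]] = True
    gap_bad = snp0[1:] - snp1[:-1] - 1
    # greedy: a run may merge with at most one neighbour per pass
    idx = np.nonzero(ok)[0]
    chosen = []
    blocked = -1
    for i in idx:
        if i == blocked:
            continue
        chosen.append(int(i))
        blocked = i + 1
    chosen = np.array(chosen, dtype=np.int64)
    keep = np.ones(n, dtype=bool)
    keep[chosen + 1] = False
    gap_first = snp1[chosen] + 1
    gap_last = snp0[chosen + 1] - 1
    u1[chosen] = u1[chosen + 1]
    n_bad[chosen] = n_bad[chosen] + n_bad[chosen + 1] + gap_bad[chosen]
    fb[chosen] = np.minimum(fb[chosen], gap_first)
    lb[chosen] = np.maximum(lb[chosen + 1], gap_last)
    snp1[chosen] = snp1[chosen + 1]
    out = tuple(arr[keep] for arr in (rows, u0, u1, snp0, snp1, n_bad,
                                      fb, lb))
    return out, True


def detect_pairwise_arrays(phased: PhasedChrom, snp_cm: np.ndarray,
                           min_cm: float, pairs: np.ndarray | None = None,
                           chunk_pairs: int = 20000) -> SegmentSet:
    """Maximal pairwise shared segments as a :class:`SegmentSet`."""
    if min_cm <= 0:
        raise ValueError("minimum genetic length must be positive")
    part = phased.partition
    masks = phased.masks
    n_samples = masks.shape[0]
    if pairs is None:
        pairs = all_pairs(n_samples)
    pairs = np.asarray(pairs)
    if len(pairs) == 0:
        return SegmentSet.empty()
    unit_first = part.first
    unit_last = part.last
    is_block = part.is_block
    nblk_cum = np.concatenate([[0], np.cumsum(is_block)])

    parts = []
    for lo in range(0, len(pairs), chunk_pairs):
        sub = pairs[lo:lo + chunk_pairs]
        match = (masks[sub[:, 0]] & masks[sub[:, 1]]) != 0
        rows, u0, u1 = _runs_by_row(match)
        if len(rows) == 0:
            continue
        snp0 = unit_first[u0].astype(np.int64)
        snp1 = unit_last[u1].astype(np.int64)
        n_bad = np.zeros(len(rows), dtype=np.int64)
        # sentinels: a clean run's first bad SNP is +inf-ish, last is -1
        fb = np.full(len(rows), np.iinfo(np.int64).max // 2)
        lb = np.full(len(rows), -1, dtype=np.int64)
        state = (rows, u0.astype(np.int64), u1.astype(np.int64),
                 snp0, snp1, n_bad, fb, lb)
        merged = True
        while merged:
            state, merged = _bridge_runs(*state)
        rows, u0, u1, snp0, snp1, n_bad, fb, lb = state
        d_g = snp_cm[snp1] - snp_cm[snp0]
        has_block = (nblk_cum[u1 + 1] - nblk_cum[u0]) > 0
        keep = (d_g >= min_cm) & has_block
        if not keep.any():
            continue
        parts.append(SegmentSet(
            sub[rows[keep], 0].astype(np.int32),
            sub[rows[keep], 1].astype(np.int32),
            u0[keep].astype(np.int32), u1[keep].astype(np.int32),
            snp0[keep].astype(np.int32), snp1[keep].astype(np.int32),
            n_bad[keep].astype(np.int32), d_g[keep].astype(np.float64)))
    return SegmentSet.concat(parts)


def detect_pairwise(phased: PhasedChrom, snp_cm: np.ndarray,
                    min_cm: float, pairs: np.ndarray | None = None) -> list:
    """Object-level wrapper over :func:`detect_pairwise_arrays`."""
    return detect_pairwise_arrays(phased, snp_cm, min_cm,
                                  pairs).to_objects(phased)


# ---------------------------------------------------------------------------
# groups

@dataclass
class SharedGroup:
    """An extended haplotype shared by k >= 2 samples.

    ``member_units[m]`` is the (contiguous) unit interval over which
    member ``m`` shares the haplotype; ``block_bits[u]`` the bitmask of
    haplotypes common to every member covering block ``u``; ``core`` the
    contiguous unit run around the seed shared by all members.
    """

    members: list
    member_units: dict
    span: tuple
    core: tuple
    block_bits: dict
    seed: tuple = None
    chrom: object = None
    rescued: list = field(default_factory=list)

    @property
    def k(self) -> int:
        return len(self.members)

    def member_length_cm(self, member, snp_cm, partition) -> float:
        total = 0.0
        for a, b in self.member_units[member]:
            total += float(snp_cm[partition.last[b]]
                           - snp_cm[partition.first[a]])
        return total

    def mean_length_cm(self, snp_cm, partition) -> float:
        return float(np.mean([self.member_length_cm(m, snp_cm, partition)
                              for m in self.members]))

    def covering_members(self, u: int) -> list:
        return [m for m in self.members
                if any(a <= u <= b for a, b in self.member_units[m])]

    def span_bp(self, partition, bp) -> tuple:
        return (int(bp[partition.first[self.span[0]]]),
                int(bp[partition.last[self.span[1]]]))

    def core_bp(self, partition, bp) -> tuple:
        return (int(bp[partition.first[self.core[0]]]),
                int(bp[partition.last[self.core[1]]]))


def _iter_bits(mask: int):
    m = int(mask)
    while m:
        low = m & -m
        yield low.bit_length() - 1
        m ^= low


def _key_instances(segs: SegmentSet, phased: PhasedChrom):
    """(segment, block-unit, haplotype-bit) incidence of all segments.

    Returns (seg_idx, key) arrays where key = unit * 64 + bit, covering
    every matched block unit of every segment.
    """
    part = phased.partition
    masks = phased.masks
    n = len(segs)
    if n == 0:
        return (np.array([], dtype=np.int64),) * 2
    lens = (segs.u1 - segs.u0 + 1).astype(np.int64)
    total = int(lens.sum())
    seg_rep = np.repeat(np.arange(n, dtype=np.int64), lens)
    offs = np.cumsum(lens) - lens
    u_flat = (np.arange(total, dtype=np.int64)
              - np.repeat(offs, lens)
              + np.repeat(segs.u0.astype(np.int64), lens))
    m = masks[segs.a[seg_rep], u_flat] & masks[segs.b[seg_rep], u_flat]
    keep = part.is_block[u_flat] & (m != 0)
    seg_rep, u_flat, m = seg_rep[keep], u_flat[keep], m[keep]
    segs_out, keys_out = [], []
    rem = m.copy()
    for bit in range(MAX_BITS):
        if not rem.any():
            break
        hit = (m >> np.uint64(bit)) & np.uint64(1) != 0
        if hit.any():
            segs_out.append(seg_rep[hit])
            keys_out.append(u_flat[hit] * MAX_BITS + bit)
        rem = rem >> np.uint64(1)
    if not segs_out:
        return (np.array([], dtype=np.int64),) * 2
    return np.concatenate(segs_out), np.concatenate(keys_out)


class GroupBuilder:
    """Group construction over a fixed set of pairwise segments.

    Seeds are (block, haplotype-id) keys.  A seed whose sharing set fits
    under ``keep_limit`` members becomes a group node directly.  An
    over-limit seed is refined: the seed is extended into a multi-block
    haplotype chain (alternating right/left, one branch per haplotype id
    at the added block), restricted to segments of at least
    ``refine_min_cm`` genetic length, and a node is emitted where each
    branch first fits under the limit — the extended-haplotype analogue
    of a single-block seed.  Chains supported only by near-threshold
    segments cannot outscore directly-kept seeds, which is why
    refinement may ignore short segments.  From every emitted node with
    more than ``PATH_MIN_MEMBERS`` members a dominant-path purification
    follows the best-supported haplotype at each further block and emits
    the shrinking member sets along the way: a descent group diluted
    with chance sharers is thereby also represented by its consistent
    core subgroup, which scores far higher under the likelihood ratio.
    Nodes with identical member sets are deduplicated.

    Per-node segment support is kept so groups can be rebuilt cheaply
    for arbitrary alive-subsets of the segments (the Monte-Carlo null
    redraws samples every iteration).
    """

    MAX_DEPTH = 64
    PATH_MIN_MEMBERS = 6

    def __init__(self, segs: SegmentSet, phased: PhasedChrom,
                 snp_cm: np.ndarray, chrom=None,
                 keep_limit: int | None = None,
                 refine_until: int | None = None,
                 refine_min_cm: float | None = None):
        self.segs = segs
        self.phased = phased
        self.snp_cm = snp_cm
        self.chrom = chrom
        self.keep_limit = keep_limit
        # refinement continues while a chain could still exceed this
        # size in some sample subset (the null draws subsets; the case
        # side uses refine_until == keep_limit)
        self.refine_until = (refine_until if refine_until is not None
                             else keep_limit)
        self.refine_min_cm = refine_min_cm
        self.keys: list = []  # (key, seg_ids, la, lb, member_ids)
        self._block_units = np.nonzero(phased.partition.is_block)[0]
        self._stamp = np.zeros(phased.n_samples + 1, dtype=np.int64)
        self._version = 0
        if len(segs) == 0:
            return
        seg_idx, key = _key_instances(segs, phased)
        if len(seg_idx) == 0:
            return
        if keep_limit is None:
            self._for_each_key(seg_idx, key, self._emit_direct)
        else:
            support = np.bincount(key)
            cap_support = keep_limit * (keep_limit - 1) // 2
            small = support[key] <= cap_support
            self._for_each_key(seg_idx[small], key[small],
                               self._emit_or_refine)
            if self.refine_min_cm is not None:
                long_seg = segs.d_g >= self.refine_min_cm
                sel = (~small) & long_seg[seg_idx]
                self._for_each_key(seg_idx[sel], key[sel], self._refine)
        self._dedup_nodes()

    # -- construction ------------------------------------------------

    def _for_each_key(self, seg_idx, key, fn):
        if len(seg_idx) == 0:
            return
        order = np.argsort(key, kind="stable")
        seg_idx, key = seg_idx[order], key[order]
        bounds = np.nonzero(np.diff(key))[0] + 1
        for st, en in zip(np.concatenate([[0], bounds]),
                          np.concatenate([bounds, [len(key)]])):
            fn(int(key[st]), seg_idx[st:en])

    def _n_members(self, sids):
        self._version += 1
        return int(_count_distinct(self.segs.a[sids], self.segs.b[sids],
                                   self._stamp, self._version))

    def _emit_direct(self, key, sids):
        self._add_node(key, sids)

    def _path_worthwhile(self, sids) -> bool:
        """Purification only matters for candidate descent groups: a
        chain supported by near-threshold segments cannot outscore the
        directly kept seeds, so paths run only where the median
        supporting segment is long."""
        if self.refine_min_cm is None:
            return True
        return float(np.median(self.segs.d_g[sids])) >= \
            0.5 * self.refine_min_cm

    def _emit_or_refine(self, key, sids):
        nm = self._n_members(sids)
        if nm <= self.keep_limit:
            self._add_node(key, sids)
            if nm > self.PATH_MIN_MEMBERS and self._path_worthwhile(sids):
                self._dominant_path(key, sids)
        if nm > self.refine_until:
            self._refine(key, sids)

    def _add_node(self, key, sids):
        a = self.segs.a[sids]
        b = self.segs.b[sids]
        member_ids, inv = np.unique(np.concatenate([a, b]),
                                    return_inverse=True)
        if len(member_ids) < 2:
            return
        la = inv[:len(sids)]
        lb = inv[len(sids):]
        self.keys.append((key, sids, la, lb, member_ids))

    def _extension_unit(self, sids, c0, c1, go_right):
        """Next block unit beyond the chain covered by some segment."""
        segs = self.segs
        blocks = self._block_units
        for attempt in range(2):
            right = go_right if attempt == 0 else not go_right
            if right:
                cand = blocks[(blocks > c1)
                              & (blocks <= segs.u1[sids].max())]
                if len(cand):
                    return int(cand[0]), right
            else:
                cand = blocks[(blocks < c0)
                              & (blocks >= segs.u0[sids].min())]
                if len(cand):
                    return int(cand[-1]), right
        return None, go_right

    def _branch_masks(self, sids, u_e):
        segs = self.segs
        masks = self.phased.masks
        covers = (segs.u0[sids] <= u_e) & (u_e <= segs.u1[sids])
        m_e = masks[segs.a[sids], u_e] & masks[segs.b[sids], u_e]
        m_e[~covers] = np.uint64(0)
        return m_e

    def _refine(self, key0, sids):
        """Branch an over-limit seed until each chain fits the limit."""
        if self.refine_min_cm is not None:
            sids = sids[self.segs.d_g[sids] >= self.refine_min_cm]
        if len(sids) == 0:
            return
        seed_u = key0 // MAX_BITS
        stack = [(sids, seed_u, seed_u, True, 0, True)]
        while stack:
            sids_c, c0, c1, go_right, depth, parent_over = stack.pop()
            if len(sids_c) == 0:
                continue
            nm = self._n_members(sids_c)
            if nm < 2:
                continue
            if nm <= self.keep_limit:
                self._add_node(key0, sids_c)
                # purification paths launch where a branch first drops
                # under the keep limit; nested in-band nodes are already
                # purification products
                if parent_over and nm > self.PATH_MIN_MEMBERS and \
                        self._path_worthwhile(sids_c):
                    self._dominant_path(key0, sids_c, c0, c1, go_right,
                                        depth)
            if nm <= self.refine_until or depth >= self.MAX_DEPTH:
                continue
            u_e, right = self._extension_unit(sids_c, c0, c1, go_right)
            if u_e is None:
                continue  # chain exhausted while still over the limit
            m_e = self._branch_masks(sids_c, u_e)
            union = 0
            for v in np.unique(m_e):
                union |= int(v)
            nc0, nc1 = min(c0, u_e), max(c1, u_e)
            over = nm > self.keep_limit
            for bit in _iter_bits(union):
                hit = (m_e >> np.uint64(bit)) & np.uint64(1) != 0
                stack.append((sids_c[hit], nc0, nc1, not right,
                              depth + 1, over))

    def _dominant_path(self, key0, sids, c0=None, c1=None,
                       go_right=True, depth=0):
        """Follow the best-supported haplotype chain, emitting the
        shrinking member sets (purification of diluted groups)."""
        seed_u = key0 // MAX_BITS
        if c0 is None:
            c0 = c1 = seed_u
        prev_nm = self._n_members(sids)
        while depth < self.MAX_DEPTH and len(sids) and prev_nm > 2:
            u_e, right = self._extension_unit(sids, c0, c1, go_right)
            if u_e is None:
                return
            m_e = self._branch_masks(sids, u_e)
            # dominance by supporting-segment count (proportional to the
            # member count, far cheaper to evaluate); ties to the
            # commoner haplotype (lower id)
            best_bit, best_count = None, 0
            union = 0
            for v in np.unique(m_e):
                union |= int(v)
            for bit in _iter_bits(union):
                cnt = int(((m_e >> np.uint64(bit))
                           & np.uint64(1)).sum())
                if cnt > best_count:
                    best_bit, best_count = bit, cnt
            if best_bit is None or best_count < 1:
                return
            hit = (m_e >> np.uint64(best_bit)) & np.uint64(1) != 0
            sids = sids[hit]
            c0, c1 = min(c0, u_e), max(c1, u_e)
            go_right = not right
            depth += 1
            nm = self._n_members(sids)
            if nm < 2:
                return
            if nm != prev_nm and nm <= (self.keep_limit or nm):
                self._add_node(key0, sids)
            prev_nm = nm

    def _dedup_nodes(self):
        """Collapse nodes with identical member sets and overlapping
        spans (keeping the best-supported one); same members at disjoint
        spans are distinct groups."""
        by_members: dict = {}
        for node in self.keys:
            by_members.setdefault(node[4].tobytes(), []).append(node)
        kept_all = []
        for nodes in by_members.values():
            spans = []
            for node in nodes:
                sids = node[1]
                spans.append((int(self.segs.u0[sids].min()),
                              int(self.segs.u1[sids].max()), node))
            spans.sort(key=lambda t: (t[0], t[1]))
            kept: list = []
            for u0, u1, node in spans:
                if kept and u0 <= kept[-1][1]:
                    prev = kept[-1]
                    if len(node[1]) > len(prev[2][1]):
                        kept[-1] = (prev[0], max(prev[1], u1), node)
                    else:
                        kept[-1] = (prev[0], max(prev[1], u1), prev[2])
                else:
                    kept.append((u0, u1, node))
            kept_all.extend(n for _, _, n in kept)
        self.keys = sorted(kept_all, key=lambda n: (n[0], len(n[1])))

    def prune_nodes(self, max_nodes: int, s: int, cap_k: int) -> None:
        """Keep the nodes most likely to produce the maximum score.

        The proxy ranks nodes by the dominant terms of the likelihood
        ratio evaluated at full support: span blocks x log10 C(2k,k)
        minus the descent exponent at the mean segment length, with k
        clamped to the analysis cap.  Used by the Monte-Carlo null to
        bound per-iteration work.
        """
        if len(self.keys) <= max_nodes:
            return
        from scipy.special import gammaln
        part = self.phased.partition
        nblk = np.concatenate([[0], np.cumsum(part.is_block)])
        proxies = np.empty(len(self.keys))
        for i, (key, sids, la, lb, member_ids) in enumerate(self.keys):
            k = min(len(member_ids), cap_k)
            u0 = int(self.segs.u0[sids].min())
            u1 = int(self.segs.u1[sids].max())
            m = int(nblk[u1 + 1] - nblk[u0])
            dbar = float(self.segs.d_g[sids].mean())
            log10c2k = (gammaln(2 * k + 1) - 2 * gammaln(k + 1)) \
                / np.log(10)
            log10csk = (gammaln(s + 1) - gammaln(k + 1)
                        - gammaln(s - k + 1)) / np.log(10)
            proxies[i] = (m * log10c2k
                          - (100.0 / max(dbar, 1e-6)) * k
                          * np.log10(2.0) - log10csk)
        order = np.argsort(-proxies, kind="stable")[:max_nodes]
        self.keys = [self.keys[i] for i in sorted(order)]

    # -- evaluation --------------------------------------------------

    def build(self, alive: np.ndarray | None = None,
              cap_k: int | None = None, dedup: bool = True,
              with_core: bool = True) -> list:
        """Construct groups (optionally restricted to alive segments)."""
        segs = self.segs
        groups = []
        for key, sids, la, lb, member_ids in self.keys:
            if alive is not None:
                sel = alive[sids]
                if not sel.any():
                    continue
                sids_s, la_s, lb_s = sids[sel], la[sel], lb[sel]
            else:
                sids_s, la_s, lb_s = sids, la, lb
            nm = len(member_ids)
            present = np.zeros(nm, dtype=bool)
            present[la_s] = True
            present[lb_s] = True
            k = int(present.sum())
            if k < 2 or (cap_k is not None and k > cap_k):
                continue
            mu0 = np.full(nm, np.iinfo(np.int64).max)
            mu1 = np.full(nm, -1, dtype=np.int64)
            su0 = segs.u0[sids_s].astype(np.int64)
            su1 = segs.u1[sids_s].astype(np.int64)
            np.minimum.at(mu0, la_s, su0)
            np.minimum.at(mu0, lb_s, su0)
            np.maximum.at(mu1, la_s, su1)
            np.maximum.at(mu1, lb_s, su1)
            members = member_ids[present]
            mu0, mu1 = mu0[present], mu1[present]
            g = self._make_group(key, members, mu0, mu1, with_core)
            if g is not None:
                groups.append(g)
        if dedup:
            groups = _dedup_groups(groups)
        groups.sort(key=lambda g: (int(g.span[0]), int(g.span[1]),
                                   tuple(g.members)))
        return groups

    def _make_group(self, key, members, mu0, mu1, with_core):
        part = self.phased.partition
        masks = self.phased.masks
        seed_u, seed_bit = key // MAX_BITS, key % MAX_BITS
        span = (int(mu0.min()), int(mu1.max()))
        units = np.arange(span[0], span[1] + 1)
        sub = masks[np.asarray(members)[:, None], units[None, :]]
        covm = (mu0[:, None] <= units[None, :]) & \
               (units[None, :] <= mu1[:, None])
        anded = np.bitwise_and.reduce(
            np.where(covm, sub, ~np.uint64(0)), axis=0)
        cov_count = covm.sum(axis=0)
        anded[cov_count == 0] = 0
        block_bits = {int(u): int(anded[i])
                      for i, u in enumerate(units)
                      if part.is_block[u] and anded[i] != 0}
        core = None
        if with_core:
            # contiguous run around the seed where all members cover and
            # share a common candidate
            all_cov = cov_count == len(members)
            off = seed_u - span[0]
            if not (all_cov[off] and anded[off] != 0):
                return None
            lo = hi = off
            while lo - 1 >= 0 and all_cov[lo - 1] and anded[lo - 1] != 0:
                lo -= 1
            while hi + 1 < len(units) and all_cov[hi + 1] and \
                    anded[hi + 1] != 0:
                hi += 1
            core = (int(units[lo]), int(units[hi]))
        member_units = {int(m): [(int(a), int(b))]
                        for m, a, b in zip(members, mu0, mu1)}
        return SharedGroup(members=[int(m) for m in members],
                           member_units=member_units, span=span,
                           core=core, block_bits=block_bits,
                           seed=(int(seed_u), int(seed_bit)),
                           chrom=self.chrom)


def _dedup_groups(groups: list) -> list:
    """Collapse groups with identical member sets and overlapping spans,
    keeping the widest span (ties: first)."""
    by_members: dict = {}
    for g in groups:
        by_members.setdefault(tuple(g.members), []).append(g)
    out = []
    for glist in by_members.values():
        glist.sort(key=lambda g: (g.span[0], g.span[1]))
        kept: list = []
        for g in glist:
            if kept and g.span[0] <= kept[-1].span[1]:
                if g.span[1] - g.span[0] > \
                        kept[-1].span[1] - kept[-1].span[0]:
                    kept[-1] = g
            else:
                kept.append(g)
        out.extend(kept)
    return out


REFINE_LENGTH_FACTOR = 4.0


def merge_groups(segments, phased: PhasedChrom,
                 cap_k: int | None = None, chrom=None,
                 snp_cm: np.ndarray | None = None,
                 min_cm: float | None = None) -> list:
    """Assemble pairwise segments into shared groups (see module docs).

    ``segments`` may be a list of :class:`SharedSegment` or a
    :class:`SegmentSet`.  Groups above ``cap_k`` members are discarded;
    over-cap seeds are chain-refined using segments of at least
    ``REFINE_LENGTH_FACTOR * min_cm`` when ``min_cm`` is given.
    """
    if isinstance(segments, list):
        segs = SegmentSet.from_objects(segments)
    else:
        segs = segments
    if len(segs) == 0:
        return []
    refine_cm = (REFINE_LENGTH_FACTOR * min_cm
                 if min_cm is not None else None)
    builder = GroupBuilder(segs, phased, snp_cm, chrom,
                           keep_limit=cap_k, refine_until=cap_k,
                           refine_min_cm=refine_cm)
    return builder.build(cap_k=cap_k)


def group_profile(group: SharedGroup, phased: PhasedChrom) -> dict:
    """Per-unit AND of candidate masks over the members covering it."""
    members = np.asarray(group.members)
    mu0 = np.array([group.member_units[m][0][0] for m in group.members])
    mu1 = np.array([group.member_units[m][-1][1] for m in group.members])
    units = np.arange(group.span[0], group.span[1] + 1)
    sub = phased.masks[members[:, None], units[None, :]]
    covm = (mu0[:, None] <= units[None, :]) & \
           (units[None, :] <= mu1[:, None])
    anded = np.bitwise_and.reduce(
        np.where(covm, sub, ~np.uint64(0)), axis=0)
    covc = covm.sum(axis=0)
    return {int(u): int(m) for u, m, c in zip(units, anded, covc) if c}


def merge_completion(group: SharedGroup, segs: SegmentSet,
                     phased: PhasedChrom, snp_cm: np.ndarray,
                     cap_k: int | None = None) -> SharedGroup:
    """Complete a confirmed group's membership by the pairwise merge rule.

    Seed-based assembly approximates the transitive merge of pairwise
    segments; a sample whose segment with a member overlaps the group on
    the same haplotype can still be missing when no admissible seed
    falls inside its (short) shared window.  For a confirmed group this
    pass adds non-members joined to a member by a detected segment that
    overlaps the group span and agrees with the group's shared haplotype
    at every block of their overlap hull (with at least one matched
    block) — the merge criterion, applied once more around the group.
    When more candidates qualify than the analysis cap allows, those
    with the longest consistent overlap are preferred.
    """
    members = set(group.members)
    room = (cap_k - len(members)) if cap_k is not None else None
    if room is not None and room <= 0:
        return group
    part = phased.partition
    masks = phased.masks
    span0, span1 = group.span
    bb = group.block_bits
    member_mask = np.zeros(phased.n_samples, dtype=bool)
    member_mask[list(members)] = True
    a_in = member_mask[segs.a]
    b_in = member_mask[segs.b]
    sel = np.nonzero((a_in ^ b_in)
                     & (segs.u0 <= span1) & (segs.u1 >= span0))[0]
    if len(sel) == 0:
        return group
    cand_sample = np.where(a_in[sel], segs.b[sel],
                           segs.a[sel]).astype(np.int64)
    ou0 = np.maximum(segs.u0[sel], span0).astype(np.int64)
    ou1 = np.minimum(segs.u1[sel], span1).astype(np.int64)
    bbarr = np.zeros(span1 - span0 + 1, dtype=np.uint64)
    for u, bits in bb.items():
        bbarr[u - span0] = bits
    # a segment qualifies when its own overlap agrees throughout; the
    # candidate's interval is the hull of its qualifying overlaps
    ok = np.zeros(len(sel), dtype=np.bool_)
    matched_arr = np.zeros(len(sel), dtype=np.int64)
    _completion_qualify(cand_sample, ou0, ou1, masks, bbarr, span0, ok,
                        matched_arr)
    hull: dict[int, list] = {}
    for c, lo, hi, good, m in zip(cand_sample, ou0, ou1, ok,
                                  matched_arr):
        if not good:
            continue
        c = int(c)
        if c in hull:
            hull[c][0] = min(hull[c][0], int(lo))
            hull[c][1] = max(hull[c][1], int(hi))
            hull[c][2] = max(hull[c][2], int(m))
        else:
            hull[c] = [int(lo), int(hi), int(m)]
    ranked = []
    for c, (lo, hi, matched) in hull.items():
        length = float(snp_cm[part.last[hi]] - snp_cm[part.first[lo]])
        ranked.append((-length, -matched, c, (lo, hi)))
    if not ranked:
        return group
    ranked.sort()
    if room is not None:
        ranked = ranked[:room]
    member_units = {m: list(v) for m, v in group.member_units.items()}
    new_ids = []
    for _, _, c, iv in ranked:
        member_units[c] = [iv]
        new_ids.append(c)
    return SharedGroup(members=sorted(members | set(new_ids)),
                       member_units=member_units,
                       span=group.span, core=group.core,
                       block_bits=group.block_bits, seed=group.seed,
                       chrom=group.chrom,
                       rescued=sorted(set(group.rescued) | set(new_ids)))


def rescue_scan(group: SharedGroup, phased: PhasedChrom,
                snp_cm: np.ndarray, min_cm: float,
                length_factor: float = 0.5,
                candidates=None) -> SharedGroup:
    """Add non-members that carry the full core and enough flanking share.

    A sample joins if some candidate haplotype of it intersects the
    group's core haplotype in every core unit, and the contiguous stretch
    around the core over which it stays consistent with the group profile
    reaches ``min_cm * length_factor`` cM.  ``candidates`` restricts the
    scan to a subset of sample indices.  Re-invoking with a smaller
    threshold (e.g. 0.25 cM) implements the loosened post-significance
    scan for confirmed regions.
    """
    part = phased.partition
    masks = phased.masks
    cu0, cu1 = group.core
    core_bits = {}
    for u in range(cu0, cu1 + 1):
        m = ~np.uint64(0)
        for s in group.members:
            m &= masks[s, u]
        core_bits[u] = m
    profile = group_profile(group, phased)
    members = list(group.members)
    member_units = {m: list(v) for m, v in group.member_units.items()}
    rescued = list(group.rescued)
    scan = (range(phased.n_samples) if candidates is None
            else sorted(candidates))
    for c in scan:
        if c in group.member_units:
            continue
        if any(masks[c, u] & core_bits[u] == 0 for u in range(cu0, cu1 + 1)):
            continue
        left = cu0
        while left - 1 >= group.span[0]:
            p = profile.get(left - 1, 0)
            if p and masks[c, left - 1] & np.uint64(p):
                left -= 1
            else:
                break
        right = cu1
        while right + 1 <= group.span[1]:
            p = profile.get(right + 1, 0)
            if p and masks[c, right + 1] & np.uint64(p):
                right += 1
            else:
                break
        length = float(snp_cm[part.last[right]] - snp_cm[part.first[left]])
        if length >= min_cm * length_factor:
            members.append(c)
            member_units[c] = [(left, right)]
            rescued.append(c)
    members = sorted(members)
    return SharedGroup(members=members, member_units=member_units,
                       span=group.span, core=group.core,
                       block_bits=group.block_bits, seed=group.seed,
                       chrom=group.chrom, rescued=sorted(rescued))
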