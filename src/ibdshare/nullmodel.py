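"""Empirical genome-wide null, quasi-P values, and the case/control filter.

The null is built by Monte Carlo: repeatedly draw s samples from the
control pool (padded with virtual samples if fewer than 2s controls are
available), run the same detection/merging/scoring used on the cases, and
record the largest log10 likelihood ratio among groups of at most k_max
members.  Optionally, haplotypes already recorded in earlier iterations
(keyed by chromosome, core block interval and core haplotype ids) can be
excluded from later maxima; this is off by default because on short
genomes the exclusion visibly drags the maxima downward and the null
loses calibration.  The recorded extreme values follow a Gumbel
distribution;
its maximum-likelihood fit is the genome-wide null, and the quasi-P value
of an observed score is the fitted upper-tail probability.  Because the
null is built from per-iteration maxima rather than from all haplotypes,
these are quasi-P rather than nominal P values: the extreme-value
construction is itself the genome-wide multiplicity correction.

Finally, significant case haplotypes that are equally shared by controls
(complete core overlap, more than half the extended haplotype, and no
case/control carrier-frequency difference by chi-square) are removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .catalog import ChromCatalog, generate_virtual_samples
from .ld import ChromPartition
from .phasing import PhasedChrom, phase_all
from .sharing import (GroupBuilder, SharedGroup, detect_pairwise_arrays,
                      group_profile)

log = logging.getLogger(__name__)

_AD_SIG = np.array([0.25, 0.10, 0.05, 0.025, 0.01])

try:
    from numba import njit as _njit
except ImportError:  # pragma: no cover - numba is a standard dependency
    def _njit(*a, **k):
        def deco(f):
            return f
        return deco if not (a and callable(a[0])) else a[0]


@_njit(cache=False)
def _score_nodes_kernel(alive, nptr, sids, la, lb, mptr, member_ids,
                        seg_u0, seg_u1, masks, is_block, F, ufirst, ulast,
                        snp_cm, k_max, log10c2k, log10csk, max_nm, scores):
    """Drawn-subset scores of all nodes (see NullEngine._score_node)."""
    LOG10_HALF = np.log10(0.5)
    present = np.zeros(max_nm, dtype=np.uint8)
    mu0 = np.empty(max_nm, dtype=np.int64)
    mu1 = np.empty(max_nm, dtype=np.int64)
    n_nodes = len(nptr) - 1
    for i in range(n_nodes):
        scores[i] = -np.inf
        s0, s1 = nptr[i], nptr[i + 1]
        m0, m1 = mptr[i], mptr[i + 1]
        nm = m1 - m0
        for j in range(nm):
            present[j] = 0
            mu0[j] = np.iinfo(np.int64).max
            mu1[j] = -1
        any_alive = False
        for t in range(s0, s1):
            sid = sids[t]
            if not alive[sid]:
                continue
            any_alive = True
            u0s = seg_u0[sid]
            u1s = seg_u1[sid]
            for l in (la[t], lb[t]):
                present[l] = 1
                if u0s < mu0[l]:
                    mu0[l] = u0s
                if u1s > mu1[l]:
                    mu1[l] = u1s
        if not any_alive:
            continue
        k = 0
        for j in range(nm):
            if present[j]:
                k += 1
        if k < 2 or k > k_max:
            continue
        span0 = np.iinfo(np.int64).max
        span1 = -1
        dsum = 0.0
        for j in range(nm):
            if not present[j]:
                continue
            if mu0[j] < span0:
                span0 = mu0[j]
            if mu1[j] > span1:
                span1 = mu1[j]
            dsum += snp_cm[ulast[mu1[j]]] - snp_cm[ufirst[mu0[j]]]
        dbar = dsum / k
        if dbar <= 0.0:
            continue
        total_logp = 0.0
        n_blocks = 0
        for u in range(span0, span1 + 1):
            if not is_block[u]:
                continue
            anded = ~np.uint64(0)
            covc = 0
            for j in range(nm):
                if present[j] and mu0[j] <= u <= mu1[j]:
                    covc += 1
                    anded = anded & masks[member_ids[m0 + j], u]
            if covc == 0 or anded == np.uint64(0):
                continue
            kj = covc if covc < k else k
            best = -1.0
            for b in range(64):
                if (anded >> np.uint64(b)) & np.uint64(1):
                    if F[u, b] > best:
                        best = F[u, b]
            total_logp += kj * np.log10(2.0 * best) - log10c2k[k]
            n_blocks += 1
        if n_blocks == 0:
            continue
        l1 = (100.0 / dbar) * k * LOG10_HALF
        l0 = log10csk[k] + total_logp
        scores[i] = l1 - l0


@dataclass
class NullModel:
    """Per-iteration genome-wide maxima and their Gumbel fit."""

    maxima: np.ndarray          # one value per iteration; -inf sentinels kept
    mu: float
    beta: float
    ad_statistic: float
    ad_p_approx: float          # approximate Anderson-Darling p-value
    n_iterations: int

    @property
    def finite_maxima(self) -> np.ndarray:
        return self.maxima[np.isfinite(self.maxima)]


def fit_gumbel(maxima: np.ndarray) -> NullModel:
    """ML Gumbel fit of the recorded maxima with moment-based start."""
    maxima = np.asarray(maxima, dtype=np.float64)
    finite = maxima[np.isfinite(maxima)]
    n_inf = len(maxima) - len(finite)
    if n_inf:
        log.info("%d null iterations produced no group (excluded from fit)",
                 n_inf)
    if len(finite) < 10:
        raise ValueError("too few finite null maxima to fit a Gumbel")
    beta0 = np.std(finite) * np.sqrt(6.0) / np.pi
    mu0 = np.mean(finite) - 0.5772156649 * beta0
    mu, beta = stats.gumbel_r.fit(finite, loc=mu0, scale=max(beta0, 1e-9))
    try:
        ad = stats.anderson(finite, dist="gumbel_r", method="interpolate")
        stat = float(ad.statistic)
        p = float(ad.pvalue)
    except TypeError:  # older scipy: approximate p from critical values
        ad = stats.anderson(finite, dist="gumbel_r")
        stat = float(ad.statistic)
        cv = np.asarray(ad.critical_values, dtype=float)
        if stat <= cv[0]:
            p = 0.25
        elif stat >= cv[-1]:
            p = 0.005
        else:
            p = float(np.interp(stat, cv, _AD_SIG))
    return NullModel(maxima=maxima, mu=float(mu), beta=float(beta),
                     ad_statistic=stat, ad_p_approx=p,
                     n_iterations=len(maxima))


def quasi_p(log_ratio: float, null: NullModel) -> float:
    """Upper-tail probability of the score under the fitted Gumbel null."""
    if np.isneginf(log_ratio):
        return 1.0
    if np.isposinf(log_ratio):
        return 0.0
    return float(stats.gumbel_r.sf(log_ratio, loc=null.mu, scale=null.beta))


def group_key(group: SharedGroup, phased: PhasedChrom) -> tuple:
    """Exclusion-registry key: chromosome, core interval, core hap masks."""
    cu0, cu1 = group.core
    bits = []
    for u in range(cu0, cu1 + 1):
        m = ~np.uint64(0)
        for s in group.members:
            m &= phased.masks[s, u]
        bits.append(int(m))
    return (group.chrom, cu0, cu1, tuple(bits))


class NullEngine:
    """Reusable machinery for the Monte-Carlo null on one chromosome.

    Controls are phased once, all pairwise segments are detected once
    and the per-seed group support is precomputed once; each iteration
    only restricts the segments to the drawn samples and redoes group
    assembly and scoring — the same output as re-running the detection
    per draw, since pairwise detection is per-pair independent.  Scores
    are pairwise-evidence scores (no rescue), exactly as on the case
    side.
    """

    TOP_CANDIDATES = 40
    MAX_NODES = 4000

    def __init__(self, phased_pool: PhasedChrom, snp_cm: np.ndarray,
                 s: int, k_max: int, min_cm: float, chrom=None,
                 member_margin: float = 1.5):
        self.phased = phased_pool
        self.snp_cm = snp_cm
        self.s = s
        self.k_max = k_max
        self.min_cm = min_cm
        self.chrom = chrom
        self.segments = detect_pairwise_arrays(phased_pool, snp_cm, min_cm)
        from .sharing import REFINE_LENGTH_FACTOR
        # a pool seed stays a direct candidate while a drawn subset of
        # size s could still bring it under the analysis cap: scale the
        # keep limit with the pool/s ratio (margin for draw noise)
        pool_n = phased_pool.n_samples
        keep = int(np.ceil(k_max * pool_n / max(s, 1) * member_margin))
        self.builder = GroupBuilder(self.segments, phased_pool, snp_cm,
                                    chrom,
                                    keep_limit=max(keep, k_max),
                                    refine_until=k_max,
                                    refine_min_cm=REFINE_LENGTH_FACTOR
                                    * min_cm)
        self.builder.prune_nodes(self.MAX_NODES, s, k_max)
        self._F = self._freq_matrix()
        from scipy.special import gammaln
        ln10 = np.log(10.0)
        kk = np.arange(k_max + 1, dtype=np.float64)
        self._log10c2k = (gammaln(2 * kk + 1) - 2 * gammaln(kk + 1)) / ln10
        self._log10csk = (gammaln(s + 1) - gammaln(kk + 1)
                          - gammaln(s - kk + 1)) / ln10
        self._bits64 = np.arange(64, dtype=np.uint64)
        self._is_block = self.phased.partition.is_block
        self._ufirst = self.phased.partition.first
        self._ulast = self.phased.partition.last
        self._flatten_nodes()

    def _flatten_nodes(self) -> None:
        nodes = self.builder.keys
        self._nptr = np.zeros(len(nodes) + 1, dtype=np.int64)
        self._mptr = np.zeros(len(nodes) + 1, dtype=np.int64)
        sids_l, la_l, lb_l, mem_l = [], [], [], []
        for i, (key, sids, la, lb, member_ids) in enumerate(nodes):
            self._nptr[i + 1] = self._nptr[i] + len(sids)
            self._mptr[i + 1] = self._mptr[i] + len(member_ids)
            sids_l.append(sids)
            la_l.append(la)
            lb_l.append(lb)
            mem_l.append(member_ids)
        cat_ = (lambda lst, dt: np.concatenate(lst).astype(dt)
                if lst else np.zeros(0, dtype=dt))
        self._sids = cat_(sids_l, np.int64)
        self._la = cat_(la_l, np.int64)
        self._lb = cat_(lb_l, np.int64)
        self._member_ids = cat_(mem_l, np.int64)
        self._max_nm = int(np.max(np.diff(self._mptr))) if len(nodes) \
            else 1
        self._seg_u0 = self.segments.u0.astype(np.int64)
        self._seg_u1 = self.segments.u1.astype(np.int64)
        self._scores = np.empty(len(nodes))

    def _freq_matrix(self) -> np.ndarray:
        """(n_units, 64) catalog frequencies; h_u where no catalog hap."""
        part = self.phased.partition
        cat = self.phased.catalog
        F = np.full((part.n_units, 64), cat.h_u, dtype=np.float64)
        for u in range(part.n_units):
            if part.is_block[u]:
                f = cat.block_freqs[u]
                F[u, :min(len(f), 64)] = f[:64]
        return F

    def _score_node(self, node, alive):
        """Drawn-subset score of one node; (ratio, members, mu0, mu1).

        Mirrors :func:`score_group` exactly (AND-mask haplotypes,
        covering counts, hull lengths) on arrays, without building the
        group object.
        """
        key, sids, la, lb, member_ids = node
        sel = alive[sids]
        if not sel.any():
            return None
        la_s, lb_s = la[sel], lb[sel]
        nm = len(member_ids)
        present = np.zeros(nm, dtype=bool)
        present[la_s] = True
        present[lb_s] = True
        k = int(present.sum())
        if k < 2 or k > self.k_max:
            return None
        segs = self.segments
        su0 = segs.u0[sids[sel]].astype(np.int64)
        su1 = segs.u1[sids[sel]].astype(np.int64)
        mu0 = np.full(nm, np.iinfo(np.int64).max)
        mu1 = np.full(nm, -1, dtype=np.int64)
        np.minimum.at(mu0, la_s, su0)
        np.minimum.at(mu0, lb_s, su0)
        np.maximum.at(mu1, la_s, su1)
        np.maximum.at(mu1, lb_s, su1)
        members = member_ids[present]
        mu0, mu1 = mu0[present], mu1[present]
        u0, u1 = int(mu0.min()), int(mu1.max())
        units = np.arange(u0, u1 + 1)
        sub = self.phased.masks[members[:, None], units[None, :]]
        covm = (mu0[:, None] <= units[None, :]) & \
               (units[None, :] <= mu1[:, None])
        anded = np.bitwise_and.reduce(
            np.where(covm, sub, ~np.uint64(0)), axis=0)
        covc = covm.sum(axis=0)
        ok = self._is_block[units] & (anded != 0) & (covc > 0)
        if not ok.any():
            return None
        bits = anded[ok]
        k_j = np.minimum(covc[ok], k)
        bb = ((bits[:, None] >> self._bits64[None, :])
              & np.uint64(1)).astype(bool)
        f = np.where(bb, self._F[units[ok]], -1.0).max(axis=1)
        log10p = k_j * np.log10(2.0 * f) - self._log10c2k[k]
        dbar = float(np.mean(self.snp_cm[self._ulast[mu1]]
                             - self.snp_cm[self._ufirst[mu0]]))
        if dbar <= 0:
            return None
        l1 = (100.0 / dbar) * k * np.log10(0.5)
        l0 = self._log10csk[k] + float(log10p.sum())
        return float(l1 - l0), members, mu0, mu1

    def best_group(self, drawn, registry: set):
        """Largest scored group among the drawn samples; (value, key).

        ``drawn`` is an array of drawn pool indices.  Groups whose key is
        already in ``registry`` are skipped; the caller decides whether
        to record the returned key.  Rescue is evaluated for the top
        candidates before the maximum is taken.
        """
        drawn = np.asarray(drawn)
        drawn_mask = np.zeros(self.phased.n_samples, dtype=bool)
        drawn_mask[drawn] = True
        alive = drawn_mask[self.segments.a] & drawn_mask[self.segments.b]
        if len(self.builder.keys) == 0:
            return -np.inf, None
        _score_nodes_kernel(alive, self._nptr, self._sids, self._la,
                            self._lb, self._mptr, self._member_ids,
                            self._seg_u0, self._seg_u1,
                            self.phased.masks, self._is_block, self._F,
                            self._ufirst, self._ulast, self.snp_cm,
                            self.k_max, self._log10c2k, self._log10csk,
                            self._max_nm, self._scores)
        order = np.argsort(-self._scores, kind="stable")
        cand = []
        for i in order[:self.TOP_CANDIDATES]:
            if not np.isfinite(self._scores[i]):
                break
            r = self._score_node(self.builder.keys[i], alive)
            if r is None:
                continue
            ratio, members, mu0, mu1 = r
            cand.append((ratio, self.builder.keys[i], members, mu0, mu1))
        cand.sort(key=lambda t: -t[0])
        for ratio, node, members, mu0, mu1 in cand:
            g = self.builder._make_group(node[0], members, mu0, mu1,
                                         with_core=True)
            if g is None:
                continue
            key = group_key(g, self.phased)
            if key in registry:
                continue
            return float(ratio), key
        return -np.inf, None

    def iterate(self, rng: np.random.Generator, registry: set) -> float:
        pool_n = self.phased.n_samples
        drawn = rng.choice(pool_n, size=self.s, replace=False)
        best, best_key = self.best_group(drawn, registry)
        if best_key is not None:
            registry.add(best_key)
        return best


def simulate_null(controls: np.ndarray, partition: ChromPartition,
                  catalog: ChromCatalog, snp_cm: np.ndarray, s: int,
                  k_max: int, iterations: int = 1000,
                  min_cm: float = 1.0, seed=None, chrom=None,
                  phased_pool: PhasedChrom | None = None,
                  exclude_recorded: bool = False) -> NullModel:
    """Build the empirical genome-wide null from control genotypes.

    If fewer than ``2*s`` controls are available, virtual samples drawn
    from the catalog top the pool up to ``2*s``.  ``phased_pool`` may be
    supplied to reuse an existing phasing of the (already padded) pool.
    ``exclude_recorded`` removes each iteration's recorded maximum
    haplotype from later maxima; at small genome scales this drags the
    null downward and breaks calibration, so it is off by default.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    if phased_pool is None:
        pool = np.asarray(controls)
        if pool.shape[0] < 2 * s:
            extra = generate_virtual_samples(catalog, 2 * s - pool.shape[0],
                                             rng)
            log.info("padding %d controls with %d virtual samples",
                     pool.shape[0], extra.shape[0])
            pool = np.concatenate([pool, extra], axis=0)
        phased_pool = phase_all(pool, partition, catalog)
    engine = NullEngine(phased_pool, snp_cm, s, k_max, min_cm, chrom)
    registry: set = set()
    maxima = np.empty(iterations)
    for it in range(iterations):
        if exclude_recorded:
            maxima[it] = engine.iterate(rng, registry)
        else:
            drawn = rng.choice(phased_pool.n_samples, size=s,
                               replace=False)
            maxima[it], _ = engine.best_group(drawn, registry)
    return fit_gumbel(maxima)


@dataclass
class SignificanceReport:
    """Final per-group verdict after the null and case/control filter."""

    group: SharedGroup
    log10_ratio: float
    quasi_p: float
    n_control_carriers: int = 0
    chisq_p: float = float("nan")
    status: str = "not_significant"
    score: object = None


def control_carriers(group: SharedGroup, phased_controls: PhasedChrom,
                     snp_cm: np.ndarray, phased_cases: PhasedChrom) -> int:
    """Controls carrying the full core plus >50% of the extended haplotype."""
    part = phased_controls.partition
    cu0, cu1 = group.core
    core_bits = {}
    for u in range(cu0, cu1 + 1):
        m = ~np.uint64(0)
        for s in group.members:
            m &= phased_cases.masks[s, u]
        core_bits[u] = m
    profile = group_profile(group, phased_cases)
    span_len = float(snp_cm[part.last[group.span[1]]]
                     - snp_cm[part.first[group.span[0]]])
    count = 0
    for c in range(phased_controls.n_samples):
        if any(phased_controls.masks[c, u] & core_bits[u] == 0
               for u in range(cu0, cu1 + 1)):
            continue
        left = cu0
        while left - 1 >= group.span[0]:
            p = profile.get(left - 1, 0)
            if p and phased_controls.masks[c, left - 1] & np.uint64(p):
                left -= 1
            else:
                break
        right = cu1
        while right + 1 <= group.span[1]:
            p = profile.get(right + 1, 0)
            if p and phased_controls.masks[c, right + 1] & np.uint64(p):
                right += 1
            else:
                break
        length = float(snp_cm[part.last[right]] - snp_cm[part.first[left]])
        if span_len == 0 or length > 0.5 * span_len:
            count += 1
    return count


def case_control_filter(reports: list, phased_cases: PhasedChrom,
                        phased_controls: PhasedChrom, snp_cm: np.ndarray,
                        s_cases: int, chi_alpha: float = 0.05) -> list:
    """Remove significant haplotypes shared equally by cases and controls.

    A significant group is removed iff at least one control carries the
    full core and over half the extended haplotype, and the chi-square
    test of carrier counts (cases vs. controls) gives p > ``chi_alpha``.
    """
    n_controls = phased_controls.n_samples
    out = []
    for rep in reports:
        if rep.status != "significant":
            out.append(rep)
            continue
        c = control_carriers(rep.group, phased_controls, snp_cm,
                             phased_cases)
        rep.n_control_carriers = c
        if c > 0:
            k = rep.group.k
            table = np.array([[k, s_cases - k], [c, n_controls - c]])
            chi_p = float(stats.chi2_contingency(table,
                                                 correction=False)[1])
            rep.chisq_p = chi_p
            if chi_p > chi_alpha:
                rep.status = "removed_shared_with_controls"
        out.append(rep)
    return out


def fdr_estimate(fpr: float, n_null_per_true: float) -> float:
    """FDR when ``n`` null haplotypes are evaluated per true one.

    FDR = n*fpr / (n*fpr + 1).
    """
    if not 0.0 <= fpr <= 1.0:
        raise ValueError("false-positive rate must be in [0, 1]")
    if n_null_per_true < 0:
        raise ValueError("count must be non-negative")
    x = n_null_per_true * fpr
    return x / (x + 1.0)
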