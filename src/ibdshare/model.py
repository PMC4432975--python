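"""End-to-end case/control scan as a model + results pair.

:class:`SharingScan` is built from case and control genotype matrices, a
marker table and a genetic map; ``fit()`` runs the whole procedure —
chromosome partitioning, catalog estimation, phasing, pairwise segment
detection, group merging and rescue, likelihood-ratio scoring, the
Monte-Carlo Gumbel null, quasi-P evaluation and the case/control removal
filter — and returns a :class:`ScanResults` carrying the groups, their
scores and significance, the fitted null and a ``summary()`` table.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from types import SimpleNamespace

import numpy as np
import pandas as pd

from .catalog import ChromCatalog, build_catalog, generate_virtual_samples
from .ld import ChromPartition, partition_by_ld, partition_by_map
from .likelihood import score_group
from .markers import GeneticMap, MarkerTable
from .nullmodel import (NullEngine, NullModel, SignificanceReport,
                        case_control_filter, fit_gumbel, quasi_p)
from .phasing import phase_all
from .sharing import (detect_pairwise_arrays, merge_completion,
                      merge_groups, rescue_scan)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Tunable thresholds of a scan.

    ``min_cm`` is the pairwise selection threshold (1.0 cM default, 0.5
    for higher sensitivity, with 0.25 reserved for the post-significance
    rescue); ``cap_fraction`` limits analysed groups to at most that
    fraction of the case pool (2% default); ``iterations`` is the null
    Monte-Carlo count (>=1000 recommended, smaller values for scaled
    runs).
    """

    min_cm: float = 1.0
    cap_fraction: float = 0.02
    cap_min: int = 20
    iterations: int = 1000
    alpha: float = 0.05
    chi_alpha: float = 0.05
    rescue_factor: float = 0.5
    partition_method: str = "ld"  # "ld" (controls) or "map" (genetic map)
    null_exclusion: bool = False  # exclude previously recorded maxima
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.min_cm <= 0 or self.iterations < 1 or not \
                (0 < self.alpha < 1):
            raise ValueError("invalid configuration")
        if not 0 < self.cap_fraction <= 0.5:
            raise ValueError("cap fraction must be in (0, 0.5]")


class SharingScan:
    """Scan for extended haplotypes shared by multiple case individuals.

    Parameters
    ----------
    case_genotypes, control_genotypes : (n_samples, n_snps) int matrices,
        0/1/2 allele counts with -1 for missing, columns aligned with
        ``markers``.
    markers : marker metadata (chromosome, id, bp, alleles).
    gmap : physical->genetic coordinate map.
    config : thresholds; defaults follow the method's standard settings.
    partition, catalog : optional per-chromosome overrides (e.g. a known
        truth partition), mapping chromosome label to the object.
    """

    def __init__(self, case_genotypes, control_genotypes,
                 markers: MarkerTable, gmap: GeneticMap,
                 config: RunConfig | None = None,
                 partition: dict | None = None,
                 catalog: dict | None = None):
        self.cases = np.asarray(case_genotypes, dtype=np.int8)
        self.controls = np.asarray(control_genotypes, dtype=np.int8)
        if self.cases.shape[0] == 0:
            raise ValueError("case set is empty")
        if self.controls.shape[0] == 0:
            raise ValueError("control set is empty")
        if self.cases.shape[1] != len(markers) or \
                self.controls.shape[1] != len(markers):
            raise ValueError("genotype columns do not match marker table")
        self.markers = markers
        self.gmap = gmap
        self.config = config or RunConfig()
        self._partition_override = partition or {}
        self._catalog_override = catalog or {}

    COMPLETE_TOP_REGIONS = 200

    @property
    def s(self) -> int:
        return self.cases.shape[0]

    @property
    def cap_k(self) -> int:
        # fraction of the case pool, floored at the absolute group-size
        # criterion (20 members) so small pools keep it meaningful
        return max(2, math.ceil(self.config.cap_fraction * self.s),
                   self.config.cap_min)

    def fit(self, seed=None) -> "ScanResults":
        cfg = self.config
        if seed is None:
            seed = cfg.seed
        ss = np.random.SeedSequence(seed if seed is not None else 0)
        rng_pad, rng_null = [np.random.default_rng(c) for c in ss.spawn(2)]
        s = self.s
        n_controls = self.controls.shape[0]
        cap_k = self.cap_k

        contexts: dict = {}
        reports: list[SignificanceReport] = []
        for chrom in self.markers.chromosomes():
            ctx = self._fit_chromosome(chrom, rng_pad)
            contexts[chrom] = ctx
            reports.extend(ctx.reports)

        null = self._fit_null(contexts, rng_null)
        for rep in reports:
            rep.quasi_p = quasi_p(rep.log10_ratio, null)
            rep.status = ("significant" if rep.quasi_p < cfg.alpha
                          else "not_significant")
        n_sig = sum(r.status == "significant" for r in reports)
        log.info("significance: %d of %d groups at alpha=%.3g",
                 n_sig, len(reports), cfg.alpha)

        # membership completion for confirmed regions: first the
        # pairwise-merge rule applied once more around the group, then
        # the core-based rescue at half the threshold (scores and
        # quasi-P keep their pairwise-evidence values); bounded to the
        # top-ranked regions, which are the actionable output
        n_rescued = 0
        sig_sorted = sorted((r for r in reports
                             if r.status == "significant"),
                            key=lambda r: r.quasi_p)
        for rep in sig_sorted[:self.COMPLETE_TOP_REGIONS]:
            ctx = contexts[rep.group.chrom]
            g2 = merge_completion(rep.group, ctx.segments,
                                  ctx.phased_cases, ctx.snp_cm,
                                  cap_k=cap_k)
            g3 = rescue_scan(g2, ctx.phased_cases, ctx.snp_cm,
                             cfg.min_cm, cfg.rescue_factor)
            if g3.k > cap_k:
                g3 = g2
            if g3.k != rep.group.k:
                rep.group = g3
                n_rescued += 1
        if n_sig:
            log.info("membership completion extended %d of %d "
                     "significant groups", n_rescued, n_sig)

        final = []
        for chrom, ctx in contexts.items():
            chrom_reps = [r for r in reports if r.group.chrom == chrom]
            final.extend(case_control_filter(
                chrom_reps, ctx.phased_cases, ctx.phased_controls,
                ctx.snp_cm, s, cfg.chi_alpha))
        n_removed = sum(r.status == "removed_shared_with_controls"
                        for r in final)
        log.info("case/control filter removed %d of %d significant groups",
                 n_removed, n_sig)
        return ScanResults(model=self, config=cfg, contexts=contexts,
                           null=null, reports=final, s=s,
                           n_controls=n_controls, cap_k=cap_k)

    def _fit_chromosome(self, chrom, rng_pad) -> SimpleNamespace:
        cfg = self.config
        s = self.s
        idx = self.markers.indices_for(chrom)
        gcase = self.cases[:, idx]
        gctrl = self.controls[:, idx]
        bp = self.markers.bp[idx]
        snp_cm = self.gmap.interpolate(chrom, bp)

        if chrom in self._partition_override:
            partition = self._partition_override[chrom]
        elif cfg.partition_method == "map":
            partition = partition_by_map(bp, snp_cm)
        else:
            partition = partition_by_ld(gctrl, bp)
        log.info("%s: %d SNPs in %d units (%d blocks)", chrom, len(idx),
                 partition.n_units, int(partition.is_block.sum()))

        if chrom in self._catalog_override:
            catalog = self._catalog_override[chrom]
        else:
            catalog = build_catalog(gctrl, partition,
                                    m_ctrl=gctrl.shape[0])

        pool = gctrl
        if pool.shape[0] < 2 * s:
            extra = generate_virtual_samples(catalog,
                                             2 * s - pool.shape[0], rng_pad)
            log.info("%s: padded %d controls with %d virtual samples",
                     chrom, pool.shape[0], extra.shape[0])
            pool = np.concatenate([pool, extra], axis=0)
        phased_cases = phase_all(gcase, partition, catalog)
        phased_pool = phase_all(pool, partition, catalog)
        phased_controls = phased_pool.subset(np.arange(gctrl.shape[0]))

        segments = detect_pairwise_arrays(phased_cases, snp_cm,
                                          cfg.min_cm)
        groups = merge_groups(segments, phased_cases, cap_k=self.cap_k,
                              chrom=chrom, snp_cm=snp_cm,
                              min_cm=cfg.min_cm)
        log.info("%s: %d pairwise segments -> %d groups (cap k<=%d)",
                 chrom, len(segments), len(groups), self.cap_k)
        scored = []
        for g in groups:
            try:
                res = score_group(g, phased_cases, snp_cm, s)
            except ValueError:
                continue
            scored.append((res, g))
        scored.sort(key=lambda t: -t[0].log10_ratio)
        # scoring uses the pairwise-detected membership; the rescue scan
        # completes membership of significant groups afterwards, keeping
        # the evidence and its null exactly comparable
        reports = []
        for res, g in scored:
            reports.append(SignificanceReport(
                group=g, log10_ratio=res.log10_ratio, quasi_p=np.nan,
                score=res))
        groups = [g for _, g in scored]
        engine = NullEngine(phased_pool, snp_cm, s, self.cap_k,
                            cfg.min_cm, chrom)
        return SimpleNamespace(chrom=chrom, idx=idx, bp=bp, snp_cm=snp_cm,
                               partition=partition, catalog=catalog,
                               phased_cases=phased_cases,
                               phased_pool=phased_pool,
                               phased_controls=phased_controls,
                               segments=segments, groups=groups,
                               reports=reports, engine=engine)

    def _fit_null(self, contexts: dict, rng_null) -> NullModel:
        """Genome-wide maxima: one control draw per iteration, maximum
        over all chromosomes, with the cross-iteration exclusion
        registry."""
        cfg = self.config
        pool_n = next(iter(contexts.values())).phased_pool.n_samples
        registry: set = set()
        maxima = np.empty(cfg.iterations)
        for it in range(cfg.iterations):
            drawn = rng_null.choice(pool_n, size=self.s, replace=False)
            best, best_key = -np.inf, None
            for ctx in contexts.values():
                v, key = ctx.engine.best_group(drawn, registry)
                if v > best:
                    best, best_key = v, key
            if cfg.null_exclusion and best_key is not None:
                registry.add(best_key)
            maxima[it] = best
        return fit_gumbel(maxima)


@dataclass
class ScanResults:
    """Fitted scan: groups, scores, null model and final statuses."""

    model: SharingScan
    config: RunConfig
    contexts: dict
    null: NullModel
    reports: list
    s: int
    n_controls: int
    cap_k: int

    def significant(self) -> list:
        return [r for r in self.reports if r.status == "significant"]

    def scenario_census(self) -> dict:
        """Block-phasing scenario fractions over all case cells."""
        tot = {k: 0.0 for k in "ABCD"}
        cells = 0
        for ctx in self.contexts.values():
            c = ctx.phased_cases.census()
            n = int(ctx.partition.is_block.sum()) * ctx.phased_cases.n_samples
            for k in tot:
                tot[k] += c[k] * n
            cells += n
        return {k: (v / cells if cells else 0.0) for k, v in tot.items()}

    def frame(self) -> pd.DataFrame:
        rows = []
        for rep in self.reports:
            g = rep.group
            ctx = self.contexts[g.chrom]
            start, end = g.span_bp(ctx.partition, ctx.bp)
            cstart, cend = g.core_bp(ctx.partition, ctx.bp)
            rows.append({
                "chrom": g.chrom, "start_bp": start, "end_bp": end,
                "core_start_bp": cstart, "core_end_bp": cend,
                "k": g.k,
                "members": ",".join(str(m) for m in g.members),
                "mean_cM": g.mean_length_cm(ctx.snp_cm, ctx.partition),
                "log10_LR": rep.log10_ratio,
                "quasi_P": rep.quasi_p,
                "chisq_p": rep.chisq_p,
                "status": rep.status,
            })
        df = pd.DataFrame(rows, columns=["chrom", "start_bp", "end_bp",
                                         "core_start_bp", "core_end_bp",
                                         "k", "members", "mean_cM",
                                         "log10_LR", "quasi_P", "chisq_p",
                                         "status"])
        if len(df):
            df = df.sort_values("quasi_P", kind="stable",
                                ignore_index=True)
        return df

    def loosen_rescue(self, min_cm: float = 0.25) -> "ScanResults":
        """Re-run the rescue scan at a looser length threshold for the
        significant groups — the built-in follow-up for regions with
        confirmed sharing.  Membership grows; the pairwise-evidence
        scores and quasi-P values are kept."""
        new_reports = []
        for rep in self.reports:
            if rep.status != "significant":
                new_reports.append(rep)
                continue
            ctx = self.contexts[rep.group.chrom]
            g = rescue_scan(rep.group, ctx.phased_cases, ctx.snp_cm,
                            min_cm, length_factor=1.0)
            if g.k > self.cap_k:
                g = rep.group
            new_reports.append(SignificanceReport(
                group=g, log10_ratio=rep.log10_ratio,
                quasi_p=rep.quasi_p,
                n_control_carriers=rep.n_control_carriers,
                chisq_p=rep.chisq_p, status=rep.status,
                score=rep.score))
        return replace(self, reports=new_reports)

    def summary(self) -> str:
        lines = []
        lines.append("Shared-haplotype scan results")
        lines.append("=" * 64)
        lines.append(f"cases: {self.s}   controls: {self.n_controls}   "
                     f"group cap k<={self.cap_k}")
        lines.append(f"pairwise threshold: {self.config.min_cm} cM   "
                     f"null iterations: {self.null.n_iterations}")
        lines.append(f"Gumbel null: mu={self.null.mu:.3f} "
                     f"beta={self.null.beta:.3f} "
                     f"(AD p~{self.null.ad_p_approx:.3g})")
        census = self.scenario_census()
        lines.append("phasing scenarios: " + "  ".join(
            f"{k}={census[k]:.3f}" for k in "ABCD"))
        df = self.frame()
        n_sig = int((df["status"] == "significant").sum()) if len(df) else 0
        lines.append(f"groups scored: {len(df)}   significant: {n_sig}")
        lines.append("-" * 64)
        if len(df):
            with pd.option_context("display.width", 120,
                                   "display.max_columns", 20):
                lines.append(df.to_string(index=False,
                                          float_format=lambda v: f"{v:.4g}"))
        else:
            lines.append("(no groups)")
        return "\n".join(lines)

    def plot_null(self, ax=None):
        """Histogram of null maxima with the fitted Gumbel density."""
        import matplotlib.pyplot as plt
        from scipy import stats
        if ax is None:
            _, ax = plt.subplots()
        x = self.null.finite_maxima
        ax.hist(x, bins=30, density=True, alpha=0.5, label="null maxima")
        grid = np.linspace(x.min(), x.max(), 200)
        ax.plot(grid, stats.gumbel_r.pdf(grid, self.null.mu,
                                         self.null.beta),
                label="Gumbel fit")
        ax.set_xlabel("log10 likelihood ratio")
        ax.legend()
        return ax


def run_pipeline(cases_ped, controls_ped, genetic_map=None,
                 config: RunConfig | None = None, out_dir=None,
                 seed=None) -> ScanResults:
    """File-level entry point: read ped/map inputs, fit, write artifacts.

    ``genetic_map`` is a HapMap-style per-chromosome table (position,
    rate, cumulative cM with one header line); if omitted, the cM column
    of the PLINK .map file is used.  With a genetic-map file the data
    must be single-chromosome.
    """
    from . import io as _io
    cases_ped = str(cases_ped)
    controls_ped = str(controls_ped)
    case_g, markers, case_ids = _io.read_ped_map(
        cases_ped, cases_ped[:-4] + ".map")
    ctrl_g, cmarkers, _ = _io.read_ped_map(
        controls_ped, controls_ped[:-4] + ".map")
    if len(markers) != len(cmarkers) or \
            not np.array_equal(markers.bp, cmarkers.bp):
        raise ValueError("case and control marker tables differ")
    chroms = markers.chromosomes()
    gmap = GeneticMap()
    if genetic_map is not None:
        if len(chroms) != 1:
            raise ValueError("a genetic-map file requires single-"
                             "chromosome data; use the .map cM column "
                             "for multi-chromosome input")
        _io.read_genetic_map(genetic_map, chrom=chroms[0], gmap=gmap)
    else:
        _, cm = _io.read_map(cases_ped[:-4] + ".map")
        for chrom in chroms:
            idx = markers.indices_for(chrom)
            if np.any(np.diff(cm[idx]) < 0) or np.all(cm[idx] == 0):
                raise ValueError(f"no usable cM column for chromosome "
                                 f"{chrom}; provide a genetic-map file")
            gmap.add_chromosome(chrom, markers.bp[idx].astype(float),
                                cm[idx])
    scan = SharingScan(case_g, ctrl_g, markers, gmap, config)
    results = scan.fit(seed=seed)
    if out_dir is not None:
        _io.write_results(out_dir, results)
    return results
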