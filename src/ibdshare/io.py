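"""Readers and writers for PLINK ped/map text files, genetic maps, and
the tool's TSV artifacts."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .markers import GeneticMap, MarkerTable


class ParseError(ValueError):
    pass


def read_map(map_path) -> tuple[MarkerTable, np.ndarray]:
    """PLINK .map: chrom, id, [cM,] bp.  Returns markers (alleles unset
    until the ped is read) and the cM column (zeros if absent)."""
    chroms, ids, cms, bps = [], [], [], []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 4:
                c, i, cm, bp = parts
            elif len(parts) == 3:
                c, i, bp = parts
                cm = "0"
            else:
                raise ParseError(f"{map_path}:{lineno}: expected 3 or 4 "
                                 f"columns, got {len(parts)}")
            chroms.append(c)
            ids.append(i)
            try:
                cms.append(float(cm))
                bps.append(int(bp))
            except ValueError as e:
                raise ParseError(f"{map_path}:{lineno}: {e}") from None
    alleles = np.array([["0", "0"]] * len(ids), dtype=object)
    mt = MarkerTable(np.array(chroms, dtype=object),
                     np.array(ids, dtype=object),
                     np.array(bps, dtype=np.int64), alleles)
    return mt, np.array(cms)


def read_ped_map(ped_path, map_path):
    """Read genotypes + markers from a PLINK ped/map text pair.

    Alleles are recoded 0/1 per marker by lexicographic order of the
    observed symbols; "0" alleles are missing.  Returns
    ``(genotypes, markers, sample_ids)`` with genotypes coded as counts
    of the lexicographically larger allele (0/1/2, -1 missing).  A
    marker monomorphic in the file necessarily codes as 0 (ped files
    carry no allele metadata, so polarity cannot be recovered).
    """
    markers, _ = read_map(map_path)
    n_snps = len(markers)
    sample_ids = []
    allele_rows = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_snps:
                raise ParseError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * n_snps} "
                    f"fields for {n_snps} markers, got {len(parts)}")
            sample_ids.append(parts[1])
            allele_rows.append(parts[6:])
    if not allele_rows:
        return (np.zeros((0, n_snps), dtype=np.int8), markers, [])
    am = np.array(allele_rows, dtype=object).reshape(len(allele_rows),
                                                     n_snps, 2)
    genotypes = np.empty((len(allele_rows), n_snps), dtype=np.int8)
    allele_pairs = np.empty((n_snps, 2), dtype=object)
    for j in range(n_snps):
        col = am[:, j, :]
        symbols = sorted(set(col.ravel()) - {"0"})
        if len(symbols) > 2:
            raise ParseError(f"{ped_path}: marker {markers.ids[j]} has "
                             f">2 alleles: {symbols}")
        while len(symbols) < 2:
            symbols.append("0")
        allele_pairs[j] = symbols[:2]
        code = {symbols[0]: 0, "0": None}
        if symbols[1] != "0":
            code[symbols[1]] = 1
        a = col[:, 0]
        b = col[:, 1]
        missing = (a == "0") | (b == "0")
        g = np.zeros(len(col), dtype=np.int8)
        g += (a == symbols[1]).astype(np.int8)
        g += (b == symbols[1]).astype(np.int8)
        g[missing] = -1
        genotypes[:, j] = g
    markers.alleles = allele_pairs
    return genotypes, markers, sample_ids


def write_ped_map(prefix, genotypes, markers: MarkerTable,
                  sample_ids=None) -> tuple[str, str]:
    """Write a ped/map pair; returns the two paths."""
    g = np.asarray(genotypes)
    n = g.shape[0]
    if sample_ids is None:
        sample_ids = [f"S{i+1}" for i in range(n)]
    map_path = f"{prefix}.map"
    ped_path = f"{prefix}.ped"
    with open(map_path, "w") as fh:
        for j in range(len(markers)):
            fh.write(f"{markers.chrom[j]}\t{markers.ids[j]}\t0\t"
                     f"{markers.bp[j]}\n")
    with open(ped_path, "w") as fh:
        for i in range(n):
            sid = str(sample_ids[i])
            # PLINK order: FID IID PAT MAT SEX PHENO
            fields = [sid, sid, "0", "0", "0", "-9"]
            for j in range(len(markers)):
                a0, a1 = markers.alleles[j]
                code = g[i, j]
                if code < 0:
                    fields += ["0", "0"]
                elif code == 0:
                    fields += [a0, a0]
                elif code == 1:
                    fields += [a0, a1]
                else:
                    fields += [a1, a1]
            fh.write(" ".join(fields) + "\n")
    return ped_path, map_path


def read_genetic_map(path, chrom=None, gmap: GeneticMap | None = None
                     ) -> GeneticMap:
    """HapMap-style genetic map: whitespace table with one header line,
    columns position(bp), rate, cumulative cM.  Adds one chromosome."""
    bp, cm = [], []
    with open(path) as fh:
        next(fh)  # header
        for lineno, line in enumerate(fh, 2):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 columns")
            bp.append(float(parts[0]))
            cm.append(float(parts[2]))
    if gmap is None:
        gmap = GeneticMap()
    gmap.add_chromosome(chrom if chrom is not None else "1",
                        np.array(bp), np.array(cm))
    return gmap


def write_genetic_map(path, bp, cm) -> None:
    with open(path, "w") as fh:
        fh.write("position\trate\tcM\n")
        bp = np.asarray(bp)
        cm = np.asarray(cm)
        rate = np.zeros(len(bp))
        if len(bp) > 1:
            rate[:-1] = np.diff(cm) / np.maximum(np.diff(bp), 1) * 1e6
        for b, r, c in zip(bp, rate, cm):
            fh.write(f"{int(b)}\t{r:.8g}\t{c:.8g}\n")


def write_partition_tsv(path, partition, markers: MarkerTable,
                        chrom) -> None:
    """BED-like TSV: chrom, start_bp, end_bp, unit_type, n_snps."""
    idx = markers.indices_for(chrom)
    bp = markers.bp[idx]
    with open(path, "w") as fh:
        fh.write("chrom\tstart_bp\tend_bp\tunit_type\tn_snps\n")
        for f, l, blk in zip(partition.first, partition.last,
                             partition.is_block):
            fh.write(f"{chrom}\t{bp[f]}\t{bp[l]}\t"
                     f"{'block' if blk else 'hotspot'}\t{l - f + 1}\n")


def write_catalog_tsv(path, catalog, markers: MarkerTable, chrom) -> None:
    """TSV: chrom, block_start_bp, block_end_bp, haplotype, frequency."""
    idx = markers.indices_for(chrom)
    bp = markers.bp[idx]
    part = catalog.partition
    with open(path, "w") as fh:
        fh.write("chrom\tblock_start_bp\tblock_end_bp\thaplotype\t"
                 "frequency\n")
        for u in range(part.n_units):
            if not part.is_block[u]:
                continue
            f, l = part.first[u], part.last[u]
            for hap, freq in zip(catalog.block_haps[u],
                                 catalog.block_freqs[u]):
                hs = "".join(str(int(a)) for a in hap)
                fh.write(f"{chrom}\t{bp[f]}\t{bp[l]}\t{hs}\t{freq:.6g}\n")


def write_results(outdir, results) -> None:
    """Write partition, catalog, group report and null maxima under
    ``outdir``."""
    import os
    os.makedirs(outdir, exist_ok=True)
    for chrom, ctx in results.contexts.items():
        tag = str(chrom).replace("/", "_")
        write_partition_tsv(os.path.join(outdir, f"partition_{tag}.tsv"),
                            ctx.partition, results.model.markers, chrom)
        write_catalog_tsv(os.path.join(outdir, f"catalog_{tag}.tsv"),
                          ctx.catalog, results.model.markers, chrom)
    results.frame().to_csv(os.path.join(outdir, "report.tsv"), sep="\t",
                           index=False)
    np.savetxt(os.path.join(outdir, "null_maxima.txt"),
               results.null.maxima)
    with open(os.path.join(outdir, "summary.txt"), "w") as fh:
        fh.write(results.summary() + "\n")
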