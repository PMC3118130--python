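"""Readers and writers for the TSV/VCF formats used across the pipeline.

TSV dialects (tab-separated, deterministic row/column order):

* frequency panel — header ``population<TAB>n<TAB><locus...>``, one row per
  population; frequencies are reference-allele (allele A) frequencies.
* genotypes — header ``individual<TAB>population<TAB><locus...>``; cells are
  reference-allele dosages 0/1/2 or ``NA`` for missing.  Empty cells are
  rejected rather than silently coerced.
* rankings — ``rank<TAB>locus<TAB>score<TAB>method``.

VCF input is read through cyvcf2 (biallelic sites only, GT field; dosage =
REF-allele count, half calls and ./. are missing); a sample → population map
must be supplied separately.  VCF output is a minimal text emitter with
synthetic contig/positions, since loci here are opaque identifiers.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import numpy as np

from .core import FrequencyPanel, GenotypeTable
from .informativeness import MarkerRanking, rank_markers

__all__ = [
    "write_frequency_panel", "read_frequency_panel",
    "write_genotypes", "read_genotypes",
    "write_ranking", "read_ranking",
    "write_vcf", "write_assignment_result",
]

log = logging.getLogger(__name__)

_MISSING = "NA"


def write_frequency_panel(panel: FrequencyPanel, path) -> None:
    with open(path, "w") as fh:
        fh.write("population\tn\t" + "\t".join(panel.loci) + "\n")
        for i, pop in enumerate(panel.populations):
            row = "\t".join(format(v, ".10g") for v in panel.freq[i])
            fh.write(f"{pop}\t{panel.n[i]}\t{row}\n")


def read_frequency_panel(path) -> FrequencyPanel:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 3 or header[:2] != ["population", "n"]:
            raise ValueError(
                f"{path}:1: malformed header; expected 'population\\tn\\t"
                "<locus...>'")
        loci = header[2:]
        if len(set(loci)) != len(loci):
            dup = sorted({l for l in loci if loci.count(l) > 1})
            raise ValueError(f"{path}:1: duplicate locus IDs {dup}")
        pops, ns, rows = [], [], []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(header)} fields, got "
                    f"{len(parts)}")
            pops.append(parts[0])
            try:
                ns.append(int(parts[1]))
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-integer sample size "
                    f"{parts[1]!r}") from None
            vals = []
            for col, cell in enumerate(parts[2:], start=3):
                try:
                    v = float(cell)
                except ValueError:
                    raise ValueError(
                        f"{path}:{lineno}: non-numeric frequency {cell!r} "
                        f"in column {col} (locus {loci[col - 3]!r})"
                    ) from None
                if not 0.0 <= v <= 1.0:
                    raise ValueError(
                        f"{path}:{lineno}: frequency {v} outside [0, 1] for "
                        f"population {parts[0]!r}, locus {loci[col - 3]!r}")
                vals.append(v)
            rows.append(vals)
    if not rows:
        raise ValueError(f"{path}: panel has no population rows")
    return FrequencyPanel(pops, loci, np.array(rows), np.array(ns))


def write_genotypes(gt: GenotypeTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("individual\tpopulation\t" + "\t".join(gt.loci) + "\n")
        for i, ind in enumerate(gt.individuals):
            cells = [_MISSING if np.isnan(v) else str(int(v))
                     for v in gt.dosage[i]]
            fh.write(f"{ind}\t{gt.true_pop[i]}\t" + "\t".join(cells) + "\n")


def _read_genotypes_tsv(path) -> GenotypeTable:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 3 or header[:2] != ["individual", "population"]:
            raise ValueError(
                f"{path}:1: malformed header; expected 'individual\\t"
                "population\\t<locus...>'")
        loci = header[2:]
        inds, pops, rows = [], [], []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(header)} fields, got "
                    f"{len(parts)}")
            inds.append(parts[0])
            pops.append(parts[1])
            vals = []
            for col, cell in enumerate(parts[2:], start=3):
                if cell == _MISSING:
                    vals.append(np.nan)
                elif cell in ("0", "1", "2"):
                    vals.append(float(cell))
                else:
                    raise ValueError(
                        f"{path}:{lineno}: invalid dosage {cell!r} in column "
                        f"{col} (expected 0/1/2/{_MISSING})")
            rows.append(vals)
    if not rows:
        raise ValueError(f"{path}: no genotype rows")
    return GenotypeTable(inds, loci, np.array(rows), pops)


def _read_genotypes_vcf(path, sample_map: Mapping[str, str]) -> GenotypeTable:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    unmapped = [s for s in samples if s not in sample_map]
    if unmapped:
        raise ValueError(f"samples missing from population map: {unmapped}")
    loci, columns = [], []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_skipped += 1
            continue
        locus = var.ID if var.ID not in (None, ".") \
            else f"{var.CHROM}:{var.POS}"
        col = np.empty(len(samples))
        for i, g in enumerate(var.genotypes):
            alleles = [a for a in g[:-1] if a >= 0]
            if len(alleles) != 2:
                col[i] = np.nan        # ./., half calls, haploid records
            else:
                col[i] = sum(1 for a in alleles if a == 0)  # REF dosage
        loci.append(locus)
        columns.append(col)
    if n_skipped:
        log.warning("skipped %d multiallelic sites", n_skipped)
    if not loci:
        raise ValueError(f"{path}: no usable biallelic sites")
    dosage = np.column_stack(columns)
    return GenotypeTable(samples, loci, dosage,
                         [sample_map[s] for s in samples])


def read_genotypes(path, format: str = "tsv",
                   sample_map: Mapping[str, str] | None = None
                   ) -> GenotypeTable:
    if format == "tsv":
        return _read_genotypes_tsv(path)
    if format == "vcf":
        if sample_map is None:
            raise ValueError("VCF input requires a sample-to-population map")
        return _read_genotypes_vcf(path, sample_map)
    raise ValueError(f"unknown genotype format {format!r}")


def write_vcf(gt: GenotypeTable, path) -> None:
    """Minimal biallelic VCF export; REF is the reference allele A.

    Loci carry no genomic coordinates, so a synthetic contig and sequential
    positions are emitted; the locus identifier goes in the ID column.
    """
    code = {2.0: "0/0", 1.0: "0/1", 0.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##contig=<ID=chrSim,length=%d>\n" % (gt.n_loci + 1))
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description='
                 '"Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gt.individuals) + "\n")
        for j, locus in enumerate(gt.loci):
            gts = [code.get(gt.dosage[i, j], "./.")
                   for i in range(gt.n_individuals)]
            fh.write(f"chrSim\t{j + 1}\t{locus}\tA\tC\t.\tPASS\t.\tGT\t"
                     + "\t".join(gts) + "\n")


def write_ranking(ranking: MarkerRanking, path) -> None:
    with open(path, "w") as fh:
        fh.write("rank\tlocus\tscore\tmethod\n")
        for r, j in enumerate(ranking.order, start=1):
            fh.write(f"{r}\t{ranking.loci[j]}\t"
                     f"{format(ranking.scores[j], '.10g')}\t"
                     f"{ranking.method}\n")


def read_ranking(path) -> MarkerRanking:
    path = Path(path)
    loci, scores, method = [], [], "custom"
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["rank", "locus", "score", "method"]:
            raise ValueError(f"{path}:1: malformed ranking header")
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 fields")
            loci.append(parts[1])
            scores.append(float(parts[2]))
            method = parts[3]
    return rank_markers(loci, scores, method)


def write_assignment_result(result, path) -> None:
    """Per-individual summary TSV plus the wide log-likelihood table."""
    thresholds = list(result.thresholds)
    with open(path, "w") as fh:
        cols = ["indiv", "true_pop", "best_pop", "llr"]
        cols += [f"correct@{format(t, 'g')}" for t in thresholds]
        cols += [f"loglik_{p}" for p in result.populations]
        fh.write("\t".join(cols) + "\n")
        for i, ind in enumerate(result.individuals):
            row = [ind, result.true_pop[i], result.best_pop[i],
                   format(result.llr[i], ".6g")]
            row += [str(bool(result.correct[t][i])) for t in thresholds]
            row += [format(v, ".6g") for v in result.loglik[i]]
            fh.write("\t".join(row) + "\n")
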