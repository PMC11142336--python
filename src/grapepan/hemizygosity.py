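"""Hemizygous-gene calling from heterozygous insertion/deletion SVs.

A gene carried by only one haplotype of a diploid assembly shows up as a
heterozygous presence/absence variant spanning the whole gene.  The default
rule therefore requires the gene interval to be fully contained in the span
of a single heterozygous deletion (or inside an annotated heterozygous
inserted-sequence interval); an any-overlap variant is available for
sensitivity analyses.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from typing import Optional, Sequence

from .models import Accession, GeneModel, HemizygosityReport, SVCall

log = logging.getLogger(__name__)

MIN_SV_LEN = 50
MAX_SV_LEN = 1_000_000


def filter_svs(
    svs: Sequence[SVCall],
    min_len: int = MIN_SV_LEN,
    max_len: int = MAX_SV_LEN,
    min_support: int = 5,
) -> list[SVCall]:
    """Drop SVs outside [min_len, max_len] or below the read-support floor.

    Both length boundaries are inclusive: 50 bp and 1 Mb calls are kept, calls
    strictly shorter or longer are dropped.  Dropped counts are logged by
    reason.
    """
    kept = []
    dropped = {"too_short": 0, "too_long": 0, "low_support": 0}
    for sv in svs:
        if sv.length < min_len:
            dropped["too_short"] += 1
        elif sv.length > max_len:
            dropped["too_long"] += 1
        elif sv.support < min_support:
            dropped["low_support"] += 1
        else:
            kept.append(sv)
    if any(dropped.values()):
        log.info("filter_svs: kept %d of %d (%s)", len(kept), len(svs), dropped)
    return kept


def _covers(gene: GeneModel, lo: int, hi: int, mode: str) -> bool:
    if mode == "contained":
        return lo <= gene.start and gene.end <= hi
    return gene.start < hi and lo < gene.end  # any overlap


def call_hemizygous_genes(
    genes: Sequence[GeneModel],
    svs: Sequence[SVCall],
    overlap_mode: str = "contained",
) -> HemizygosityReport:
    """Call hemizygous genes for one accession from heterozygous INS/DEL SVs.

    A gene qualifies when its interval is covered by the span of one het DEL,
    or lies within a het insertion's annotated inserted interval; breakpoint-
    only insertions never qualify.  Genes and SVs must come from the same
    accession assembly.
    """
    if overlap_mode not in ("contained", "any"):
        raise ValueError(f"overlap_mode must be contained|any, got {overlap_mode!r}")
    if not genes:
        raise ValueError("no gene models supplied")
    acc = genes[0].accession_id
    for g in genes:
        if g.accession_id != acc:
            raise ValueError(f"mixed accessions in gene list: {acc} vs {g.accession_id}")
    spans_by_chrom: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for sv in svs:
        if sv.accession_id != acc:
            raise ValueError(f"SV from {sv.accession_id} mixed with genes from {acc}")
        if sv.genotype != "het":
            continue
        if sv.svtype == "DEL":
            spans_by_chrom[sv.chrom].append((sv.start, sv.end))
        elif sv.inserted_interval is not None:
            spans_by_chrom[sv.chrom].append(sv.inserted_interval)
    for spans in spans_by_chrom.values():
        spans.sort()

    hemi = set()
    for g in genes:
        for lo, hi in spans_by_chrom.get(g.chrom, ()):
            if lo > (g.end if overlap_mode == "any" else g.start):
                break
            if _covers(g, lo, hi, overlap_mode):
                hemi.add(g.gene_id)
                break
    return HemizygosityReport(acc, len(genes), frozenset(hemi))


def population_hemizygosity(
    reports: Sequence[HemizygosityReport],
    accessions: Sequence[Accession],
) -> dict[str, float]:
    """Unweighted mean of per-accession hemizygous proportions per population.

    Accessions without an SV-backed report are excluded with a logged note
    (e.g. assemblies whose long reads were unavailable); a population left
    empty after exclusions is an error.
    """
    by_id = {r.accession_id: r for r in reports}
    pops: dict[str, list[float]] = defaultdict(list)
    for acc in accessions:
        rep = by_id.get(acc.id)
        if rep is None:
            log.info("population_hemizygosity: no SV data for %s; excluded", acc.id)
            continue
        pops[acc.population].append(rep.proportion)
    out = {}
    for pop in sorted({a.population for a in accessions}):
        if not pops.get(pop):
            raise ValueError(f"population {pop!r} has no accessions with SV data")
        out[pop] = float(sum(pops[pop]) / len(pops[pop]))
    return out
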