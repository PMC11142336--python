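"""Readers and writers for every external format the pipeline touches.

GFF3 and VCF coordinates are converted to the internal 0-based half-open
convention here and nowhere else.  All writers emit UTF-8, tab-separated
text with a header line, so outputs diff cleanly and round-trip exactly.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from pathlib import Path
from typing import Iterable, Optional, Sequence

from cyvcf2 import VCF

from .models import (
    Accession,
    DomainHit,
    FamilyTable,
    FamilyTableError,
    GeneModel,
    GraphGeneLabel,
    SVCall,
)

log = logging.getLogger(__name__)


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# GFF3 genes
# ---------------------------------------------------------------------------

def _attr_field(attrs: str, key: str) -> Optional[str]:
    for part in attrs.strip().split(";"):
        if part.startswith(key + "="):
            return part[len(key) + 1 :]
    return None


def assign_ranks(genes: Sequence[GeneModel]) -> list[GeneModel]:
    """Assign 0-based rank by start (gene_id breaks ties) within (accession, chrom)."""
    by_key: dict[tuple[str, str], list[GeneModel]] = defaultdict(list)
    for g in genes:
        by_key[(g.accession_id, g.chrom)].append(g)
    out: list[GeneModel] = []
    for key in sorted(by_key):
        ordered = sorted(by_key[key], key=lambda g: (g.start, g.gene_id))
        for rank, g in enumerate(ordered):
            out.append(GeneModel(g.gene_id, g.accession_id, g.chrom, g.start, g.end, g.strand, rank))
    return out


def read_gff3(path: str | Path, accession_id: Optional[str] = None) -> list[GeneModel]:
    """Read gene features from a GFF3 file.

    GFF3 1-based inclusive coordinates become 0-based half-open.  Ranks are
    assigned per chromosome by sorted start, ties broken by gene ID so that
    parsing is order-independent.  ``accession_id`` defaults to the file stem.
    """
    path = Path(path)
    acc = accession_id if accession_id is not None else path.stem
    genes: list[GeneModel] = []
    seen_ids: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 tab-separated columns, got {len(cols)}")
            _, _, ftype, start_s, end_s, _, strand, _, attrs = cols
            if ftype != "gene":
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates {start_s!r}/{end_s!r}") from None
            gid = _attr_field(attrs, "ID")
            if gid is None:
                raise ParseError(f"{path}:{lineno}: gene feature lacks an ID attribute")
            if gid in seen_ids:
                raise ParseError(f"{path}:{lineno}: duplicate gene ID {gid!r}")
            seen_ids.add(gid)
            if strand not in ("+", "-", "."):
                raise ParseError(f"{path}:{lineno}: bad strand {strand!r}")
            genes.append(GeneModel(gid, acc, cols[0], start1 - 1, end1, strand))
    return assign_ranks(genes)


def write_gff3(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
            fh.write(
                f"{g.chrom}\tgrapepan\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# VCF structural variants
# ---------------------------------------------------------------------------

def read_vcf_svs(path: str | Path, accession_id: Optional[str] = None) -> list[SVCall]:
    """Read insertion/deletion SVs from a VCF (first sample's GT).

    SVLEN sign is normalised to a positive length; ``0/1``/``1/0`` become het
    and ``1/1`` hom.  Records that are not INS/DEL, lack SVTYPE, or carry an
    uninformative genotype are skipped and counted in the log.
    """
    path = Path(path)
    acc = accession_id if accession_id is not None else path.stem
    calls: list[SVCall] = []
    skipped: Counter[str] = Counter()
    for rec in VCF(str(path)):
        svtype = rec.INFO.get("SVTYPE")
        if svtype is None:
            skipped["missing SVTYPE"] += 1
            continue
        if svtype not in ("INS", "DEL"):
            skipped[f"type {svtype}"] += 1
            continue
        svlen = rec.INFO.get("SVLEN")
        if svlen is None:
            skipped["missing SVLEN"] += 1
            continue
        length = abs(int(svlen))
        gt = rec.genotypes[0][:2] if rec.genotypes else None
        if gt == [0, 1] or gt == [1, 0]:
            genotype = "het"
        elif gt == [1, 1]:
            genotype = "hom"
        else:
            skipped["uninformative GT"] += 1
            continue
        support = int(rec.INFO.get("RE") or 0)
        start = rec.POS - 1  # POS is the first affected base (no padding-base convention)
        if svtype == "DEL":
            end = start + length
            inserted = None
        else:
            end = start + 1
            ispan = rec.INFO.get("ISPAN")
            inserted = None
            if ispan:
                a, b = str(ispan).split("-")
                inserted = (int(a) - 1, int(b))  # 1-based inclusive -> half-open
        calls.append(SVCall(acc, rec.CHROM, start, end, svtype, length, genotype, support, inserted))
    if skipped:
        log.info("%s: skipped %d non-INS/DEL or malformed records (%s)",
                 path.name, sum(skipped.values()), dict(skipped))
    return calls


def write_vcf_svs(svs: Sequence[SVCall], path: str | Path, contigs: Optional[dict[str, int]] = None) -> None:
    """Write SV calls to a minimal, cyvcf2-readable VCF 4.2 file."""
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">',
        '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">',
        '##INFO=<ID=END,Number=1,Type=Integer,Description="End position">',
        '##INFO=<ID=RE,Number=1,Type=Integer,Description="Supporting reads">',
        '##INFO=<ID=ISPAN,Number=1,Type=String,Description="Inserted-sequence span on this assembly (1-based inclusive)">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    if contigs:
        for name, length in contigs.items():
            lines.append(f"##contig=<ID={name},length={length}>")
    sample = svs[0].accession_id if svs else "sample"
    lines.append(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}")
    for i, sv in enumerate(sorted(svs, key=lambda s: (s.chrom, s.start, s.svtype, s.length)), 1):
        svlen = -sv.length if sv.svtype == "DEL" else sv.length
        info = f"SVTYPE={sv.svtype};SVLEN={svlen};END={sv.start + sv.length if sv.svtype == 'DEL' else sv.start + 1};RE={sv.support}"
        if sv.inserted_interval is not None:
            info += f";ISPAN={sv.inserted_interval[0] + 1}-{sv.inserted_interval[1]}"
        gt = "0/1" if sv.genotype == "het" else "1/1"
        lines.append(f"{sv.chrom}\t{sv.start + 1}\tsv{i}\tN\t<{sv.svtype}>\t.\tPASS\t{info}\tGT\t{gt}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Orthogroup table (OrthoFinder Orthogroups.tsv dialect)
# ---------------------------------------------------------------------------

def read_orthogroups(path: str | Path) -> FamilyTable:
    """Read a TSV orthogroup table: header of accession IDs, one family per row,
    comma-separated gene lists per cell.  Empty cells are empty member lists;
    a fully empty family row is an error, as is a gene in two families."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise ParseError(f"{path}:1: orthogroup header needs >=1 accession column")
        accessions = header[1:]
        members: dict[str, dict[str, list[str]]] = {}
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split("\t")
            if len(cells) != len(header):
                raise ParseError(f"{path}:{lineno}: expected {len(header)} columns, got {len(cells)}")
            fam = cells[0]
            if fam in members:
                raise ParseError(f"{path}:{lineno}: duplicate family ID {fam!r}")
            per_acc = {
                acc: [g.strip() for g in cell.split(",") if g.strip()]
                for acc, cell in zip(accessions, cells[1:])
            }
            if not any(per_acc.values()):
                raise ParseError(f"{path}:{lineno}: family {fam!r} has no members")
            members[fam] = per_acc
    try:
        return FamilyTable(members)
    except FamilyTableError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_orthogroups(table: FamilyTable, path: str | Path,
                      accession_ids: Optional[Sequence[str]] = None) -> None:
    accs = list(accession_ids) if accession_ids is not None else table.accession_ids
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("Orthogroup\t" + "\t".join(accs) + "\n")
        for fam in sorted(table.members):
            cells = [",".join(table.members[fam].get(a, [])) for a in accs]
            fh.write(fam + "\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# Simple TSV tables: domain hits, graph labels, population map, GO map
# ---------------------------------------------------------------------------

def read_domain_hits(path: str | Path) -> list[DomainHit]:
    hits = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("protein_id"):
            raise ParseError(f"{path}: missing domain-hit header")
        for lineno, line in enumerate(fh, 2):
            if not line.strip():
                continue
            try:
                pid, source, acc, start, end, score = line.rstrip("\n").split("\t")
                hits.append(DomainHit(pid, source, acc, int(start), int(end), float(score)))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return hits


def write_domain_hits(hits: Sequence[DomainHit], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("protein_id\tsource\taccession\tstart\tend\tscore\n")
        for h in sorted(hits, key=lambda h: (h.protein_id, h.source, h.accession, h.start)):
            fh.write(f"{h.protein_id}\t{h.source}\t{h.accession}\t{h.start}\t{h.end}\t{h.score:g}\n")


def read_graph_labels(path: str | Path) -> list[GraphGeneLabel]:
    labels = []
    seen = set()
    with open(path, encoding="utf-8") as fh:
        fh.readline()  # header
        for lineno, line in enumerate(fh, 2):
            if not line.strip():
                continue
            gid, acc, placement = line.rstrip("\n").split("\t")
            if gid in seen:
                raise ParseError(f"{path}:{lineno}: gene {gid!r} labeled twice")
            seen.add(gid)
            labels.append(GraphGeneLabel(gid, acc, placement))
    return labels


def write_graph_labels(labels: Sequence[GraphGeneLabel], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\taccession_id\tplacement\n")
        for lab in sorted(labels, key=lambda l: l.gene_id):
            fh.write(f"{lab.gene_id}\t{lab.accession_id}\t{lab.placement}\n")


def read_population_map(path: str | Path) -> list[Accession]:
    accs = []
    seen = set()
    with open(path, encoding="utf-8") as fh:
        fh.readline()  # header
        for lineno, line in enumerate(fh, 2):
            if not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) == 2:
                aid, pop, hap = cols[0], cols[1], ""
            elif len(cols) == 3:
                aid, pop, hap = cols
            else:
                raise ParseError(f"{path}:{lineno}: expected 2-3 columns")
            if aid in seen:
                raise ParseError(f"{path}:{lineno}: duplicate accession {aid!r}")
            seen.add(aid)
            accs.append(Accession(aid, pop, hap or None))
    return accs


def write_population_map(accessions: Sequence[Accession], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("accession_id\tpopulation\thaplotype\n")
        for a in accessions:
            fh.write(f"{a.id}\t{a.population}\t{a.haplotype or ''}\n")


def read_go_map(path: str | Path) -> dict[str, list[str]]:
    """Two-column TSV: gene_id, term (one row per gene-term pair)."""
    out: dict[str, list[str]] = defaultdict(list)
    with open(path, encoding="utf-8") as fh:
        fh.readline()  # header
        for line in fh:
            if not line.strip():
                continue
            gene, term = line.rstrip("\n").split("\t")
            out[gene].append(term)
    return dict(out)


def write_go_map(go_map: dict[str, list[str]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\tterm\n")
        for gene in sorted(go_map):
            for term in sorted(go_map[gene]):
                fh.write(f"{gene}\t{term}\n")


# ---------------------------------------------------------------------------
# Paired codon sequences (for Ka/Ks), plain FASTA with /1 /2 suffixes
# ---------------------------------------------------------------------------

def read_codon_pairs(path: str | Path) -> list[tuple[str, str, str, str, str]]:
    """Read pairs as (pair_id, class_label, seq_a, seq_b, description)."""
    seqs: dict[str, str] = {}
    meta: dict[str, str] = {}
    name = None
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                fields = line[1:].split()
                name = fields[0]
                meta[name] = fields[1] if len(fields) > 1 else ""
                seqs[name] = ""
            elif name:
                seqs[name] += line
    pairs = []
    for name in sorted(seqs):
        if name.endswith("/1"):
            base = name[:-2]
            other = base + "/2"
            if other in seqs:
                pairs.append((base, meta[name], seqs[name], seqs[other], meta.get(other, "")))
    return pairs


def write_codon_pairs(pairs: Sequence[tuple[str, str, str, str]], path: str | Path) -> None:
    """Write (pair_id, class_label, seq_a, seq_b) tuples as paired FASTA."""
    with open(path, "w", encoding="utf-8") as fh:
        for pid, label, sa, sb in pairs:
            fh.write(f">{pid}/1 {label}\n{sa}\n>{pid}/2 {label}\n{sb}\n")
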