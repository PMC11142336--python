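"""NLR (nucleotide-binding leucine-rich-repeat receptor) toolkit.

Covers the eight-class domain-architecture typing used for plant pan-NLRome
work, the conserved-motif support filter, physical pairing and clustering of
NLR genes along chromosome gene order, the pan-NLRome frequency spectrum, and
trunk/bubble diversity accounting for graph pan-genomes (ADC).
"""

from __future__ import annotations

from collections import Counter, defaultdict
from typing import Iterable, Optional, Sequence

import networkx as nx
import pandas as pd

from .models import (
    DomainHit,
    FamilyTable,
    GeneModel,
    GraphDiversityStats,
    GraphGeneLabel,
    NLRCluster,
    NLRRecord,
)

NLR_CLASSES = (
    "CC-NBS", "CC-NBS-LRR", "NBS", "NBS-LRR",
    "RPW8-X", "TIR-NBS", "TIR-NBS-LRR", "TIR-X",
)

# Pfam accessions for the three qualifying domains; CC and LRR evidence is
# accepted from any predictor as boolean rows tagged with these labels.
_DOMAIN_LABELS = {
    "PF00931": "NB-ARC",
    "PF01582": "TIR",
    "PF05659": "RPW8",
    "NB-ARC": "NB-ARC",
    "TIR": "TIR",
    "RPW8": "RPW8",
    "CC": "CC",
    "COILS": "CC",
    "LRR": "LRR",
    # common LRR Pfam models
    "PF00560": "LRR", "PF07725": "LRR", "PF13306": "LRR", "PF13855": "LRR",
}


def domains_from_hits(hits: Iterable[DomainHit]) -> frozenset[str]:
    return frozenset(
        _DOMAIN_LABELS[h.accession]
        for h in hits
        if h.source == "domain" and h.accession in _DOMAIN_LABELS
    )


def classify_domains(domains: frozenset[str] | set[str]) -> Optional[str]:
    """Assign the eight-class NLR type from a domain set; ``None`` if the
    protein lacks all of NB-ARC/TIR/RPW8 (not an NLR candidate).

    N-terminal evidence precedence is TIR > RPW8 > CC; first matching row of
    the class table wins.
    """
    d = set(domains)
    if not d & {"NB-ARC", "TIR", "RPW8"}:
        return None
    if "TIR" in d:
        if "NB-ARC" in d and "LRR" in d:
            return "TIR-NBS-LRR"
        if "NB-ARC" in d:
            return "TIR-NBS"
        return "TIR-X"
    if "RPW8" in d:
        return "RPW8-X"
    if "CC" in d:
        if "LRR" in d:
            return "CC-NBS-LRR"
        return "CC-NBS"
    if "LRR" in d:
        return "NBS-LRR"
    return "NBS"


def classify_nlr(
    protein_id: str,
    hits: Sequence[DomainHit],
    gene_id: Optional[str] = None,
) -> NLRRecord:
    """Build an NLRRecord for one protein from its domain hit rows."""
    domains = domains_from_hits(h for h in hits if h.protein_id == protein_id)
    return NLRRecord(
        protein_id=protein_id,
        gene_id=gene_id if gene_id is not None else protein_id,
        domains=domains,
        nlr_class=classify_domains(domains),
    )


def motif_conservation_filter(
    records: Sequence[NLRRecord],
    motif_hits: Sequence[DomainHit],
    min_motifs: int = 5,
) -> list[NLRRecord]:
    """Set each record's conserved-motif support and pass/fail flag.

    Support counts DISTINCT class-specific motif IDs per protein ("at least
    five conserved regions"), not total hit rows; records without an NLR
    class never pass.
    """
    distinct: dict[str, set[str]] = defaultdict(set)
    for h in motif_hits:
        if h.source == "motif":
            distinct[h.protein_id].add(h.accession)
    out = []
    for rec in records:
        n = len(distinct.get(rec.protein_id, ()))
        out.append(
            NLRRecord(
                rec.protein_id, rec.gene_id, rec.domains, rec.nlr_class,
                n_conserved_motifs=n,
                passed_filter=rec.nlr_class is not None and n >= min_motifs,
            )
        )
    return out


def pair_nlr_genes(
    genes_in_order: Sequence[GeneModel],
    nlr_gene_ids: set[str],
    max_intervening: int = 1,
) -> list[tuple[str, str]]:
    """Pairs of NLR genes separated by at most ``max_intervening`` non-NLR
    genes along one chromosome's gene order.

    The default 1 encodes "fewer than two non-NLR genes between them".
    Intervening NLR genes do not block a pair — they form their own pairs.
    """
    ordered = sorted(genes_in_order, key=lambda g: g.rank)
    for i, g in enumerate(ordered):
        if g.rank != i:
            raise ValueError(f"ranks must be contiguous 0..n-1; gene {g.gene_id} has rank {g.rank}")
    is_nlr = [g.gene_id in nlr_gene_ids for g in ordered]
    # prefix sum of non-NLR genes for O(1) gap counts
    prefix = [0]
    for flag in is_nlr:
        prefix.append(prefix[-1] + (0 if flag else 1))
    nlr_pos = [i for i, flag in enumerate(is_nlr) if flag]
    pairs = []
    for a_i, i in enumerate(nlr_pos):
        for j in nlr_pos[a_i + 1 :]:
            between = prefix[j] - prefix[i + 1]
            if between > max_intervening:
                break  # gaps only grow with j
            pairs.append(tuple(sorted((ordered[i].gene_id, ordered[j].gene_id))))
    return sorted(pairs)


def nlr_clusters(
    pairs: Sequence[tuple[str, str]],
    genes: Sequence[GeneModel],
    min_cluster_size: int = 4,
) -> list[NLRCluster]:
    """Connected components of the pairing graph with at least
    ``min_cluster_size`` members ("more than three genes paired to each
    other"; pass 3 for the lenient reading).  Members are reported in
    chromosome order."""
    gene_by_id = {g.gene_id: g for g in genes}
    graph = nx.Graph()
    graph.add_edges_from(pairs)
    clusters = []
    comps = sorted((sorted(c) for c in nx.connected_components(graph)), key=lambda c: c[0])
    i = 0
    for comp in comps:
        if len(comp) < min_cluster_size:
            continue
        i += 1
        members = sorted(comp, key=lambda g: gene_by_id[g].rank if g in gene_by_id else 0)
        first = gene_by_id.get(members[0])
        clusters.append(
            NLRCluster(
                cluster_id=f"NLRC{i:04d}",
                accession_id=first.accession_id if first else "",
                chrom=first.chrom if first else "",
                member_gene_ids=tuple(members),
            )
        )
    return clusters


def pan_nlrome_spectrum(
    nlr_families: FamilyTable,
    accession_ids: Sequence[str],
    family_classes: Optional[dict[str, str]] = None,
) -> pd.DataFrame:
    """Count NLR families present in exactly k genomes, k = 1..N.

    Returns a tidy frame (k, nlr_class, n_families); class "all" aggregates
    over classes.  The spectrum sums to the number of NLR families.
    """
    rows: Counter[tuple[int, str]] = Counter()
    for fam, per_acc in nlr_families.members.items():
        k = sum(1 for a in accession_ids if per_acc.get(a))
        if k == 0:
            continue
        rows[(k, "all")] += 1
        if family_classes and fam in family_classes:
            rows[(k, family_classes[fam])] += 1
    data = [
        {"k": k, "nlr_class": cls, "n_families": n}
        for (k, cls), n in sorted(rows.items())
    ]
    return pd.DataFrame(data, columns=["k", "nlr_class", "n_families"])


def graph_diversity(
    nlr_gene_ids: set[str],
    labels: Sequence[GraphGeneLabel],
    n_accessions: int,
    population: str = "",
) -> GraphDiversityStats:
    """Trunk/bubble accounting over the NLR genes of one graph pan-genome.

    ADC (average diversity contribution) = bubble-resident NLR genes divided
    by the number of accessions.  Every NLR gene must carry a label.
    """
    if n_accessions < 1:
        raise ValueError("n_accessions must be >= 1")
    by_gene = {l.gene_id: l.placement for l in labels}
    missing = sorted(g for g in nlr_gene_ids if g not in by_gene)
    if missing:
        raise ValueError(f"unlabeled NLR genes, e.g. {missing[:5]}")
    n_bubble = sum(1 for g in nlr_gene_ids if by_gene[g] == "bubble")
    n_total = len(nlr_gene_ids)
    return GraphDiversityStats(
        population=population,
        n_accessions=n_accessions,
        n_nlr_total=n_total,
        n_trunk=n_total - n_bubble,
        n_bubble=n_bubble,
    )


def nlr_chromosome_map(
    records: Sequence[NLRRecord],
    genes: Sequence[GeneModel],
    chrom_lengths: Optional[dict[str, int]] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Positions of classified NLR genes along chromosomes.

    Returns (positions, counts): positions has one row per NLR gene with its
    chromosome, class and interval midpoint (ideogram-ready); counts is the
    per-chromosome, per-class tally.
    """
    gene_by_id = {g.gene_id: g for g in genes}
    rows = []
    for rec in records:
        if rec.nlr_class is None:
            continue
        g = gene_by_id.get(rec.gene_id)
        if g is None:
            raise KeyError(f"NLR gene {rec.gene_id!r} has no gene model")
        if chrom_lengths is not None and g.chrom not in chrom_lengths:
            raise KeyError(f"gene {rec.gene_id!r} on unknown chromosome {g.chrom!r}")
        rows.append(
            {"accession_id": g.accession_id, "chrom": g.chrom,
             "nlr_class": rec.nlr_class, "gene_id": g.gene_id, "midpoint": g.midpoint}
        )
    positions = pd.DataFrame(rows, columns=["accession_id", "chrom", "nlr_class", "gene_id", "midpoint"])
    if len(positions):
        counts = (
            positions.groupby(["chrom", "nlr_class"]).size().reset_index(name="n_genes")
        )
    else:
        counts = pd.DataFrame(columns=["chrom", "nlr_class", "n_genes"])
    return positions, counts
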