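"""Synthetic multi-population cohort generator with planted, retrievable truth.

Emulates the 17-accession study design (1 outgroup, 5 wild progenitors,
9 cultivars, 2 wild relatives) on a 19-chromosome karyotype: gene families
with planted core/shell/cloud structure, families with planted member-count
bias toward or against the cultivar population, heterozygous deletions that
make a planted fraction of genes hemizygous, NLR proteins with planted domain
architectures, motif support and physical clusters, trunk/bubble graph
labels, a GO map with one planted enriched term, and codon pairs whose
nonsynonymous load differs by frequency class.

Everything is drawn from one seeded generator, so a fixed seed yields a
byte-identical bundle on disk; changing the seed moves coordinates and
identities but never the planted category counts.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import io as cio
from .gainloss import CODON_TABLE
from .hemizygosity import call_hemizygous_genes, filter_svs
from .models import (
    Accession,
    DomainHit,
    FamilyTable,
    GeneModel,
    GraphGeneLabel,
    SVCall,
)
from .nlr import NLR_CLASSES

_BASES = "TCAG"

# domain-hit rows emitted per planted class
_CLASS_DOMAINS = {
    "TIR-NBS-LRR": ("PF01582", "PF00931", "LRR"),
    "TIR-NBS": ("PF01582", "PF00931"),
    "TIR-X": ("PF01582",),
    "RPW8-X": ("PF05659",),
    "CC-NBS-LRR": ("CC", "PF00931", "LRR"),
    "CC-NBS": ("CC", "PF00931"),
    "NBS-LRR": ("PF00931", "LRR"),
    "NBS": ("PF00931",),
}

ENRICHED_TERM = "GO:0009999"


@dataclass
class CohortConfig:
    """Study-design knobs; defaults reproduce the cohort structure the
    analyses assume (sizes, 50 bp-1 Mb SV window, ~15% hemizygosity,
    core/shell/cloud split near the observed 17.5%/74.7%/7.8%)."""

    n_outgroup: int = 1
    n_wild: int = 5
    n_cultivar: int = 9
    n_relative: int = 2
    n_families: int = 1000
    frac_core: float = 0.175
    frac_shell: float = 0.745
    frac_cloud: float = 0.08
    n_gained: int = 20
    n_lost: int = 20
    gained_effect: int = 4
    hemizygous_frac: float = 0.15
    n_nlr: int = 64
    nlr_decoy_frac: float = 0.25
    sv_len_range: tuple[int, int] = (50, 1_000_000)
    n_chromosomes: int = 19
    lam: float = 1.2  # zero-truncated Poisson rate for member counts
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_outgroup", "n_wild", "n_cultivar", "n_relative",
                     "n_families", "n_gained", "n_lost", "n_nlr"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        fr = self.frac_core + self.frac_shell + self.frac_cloud
        if not np.isclose(fr, 1.0):
            raise ValueError(f"frac_core + frac_shell + frac_cloud must sum to 1, got {fr}")
        if not 0 <= self.hemizygous_frac <= 1:
            raise ValueError("hemizygous_frac must be in [0,1]")
        if self.n_gained > self.n_core:
            raise ValueError("n_gained cannot exceed the core family count")
        if self.n_lost > self.n_shell:
            raise ValueError("n_lost cannot exceed the shell family count")

    @property
    def n_accessions(self) -> int:
        return self.n_outgroup + self.n_wild + self.n_cultivar + self.n_relative

    @property
    def n_core(self) -> int:
        return round(self.frac_core * self.n_families)

    @property
    def n_cloud(self) -> int:
        return round(self.frac_cloud * self.n_families)

    @property
    def n_shell(self) -> int:
        return self.n_families - self.n_core - self.n_cloud


@dataclass
class PlantedTruth:
    """Ground-truth labels retrievable for recovery scoring."""

    family_class: dict[str, str] = field(default_factory=dict)
    biased_families: dict[str, str] = field(default_factory=dict)
    hemizygous_genes: dict[str, set[str]] = field(default_factory=dict)
    nlr_class: dict[str, str] = field(default_factory=dict)
    nlr_decoys: set[str] = field(default_factory=set)
    nlr_clusters: list[frozenset[str]] = field(default_factory=list)
    enriched_term: str = ENRICHED_TERM


@dataclass
class CohortBundle:
    config: CohortConfig
    accessions: list[Accession]
    genes: list[GeneModel]
    families: FamilyTable
    svs: dict[str, list[SVCall]]  # accession -> calls
    domain_hits: list[DomainHit]
    graph_labels: list[GraphGeneLabel]
    go_map: dict[str, list[str]]
    codon_pairs: list[tuple[str, str, str, str]]  # (pair_id, class, seq_a, seq_b)
    chrom_lengths: dict[str, dict[str, int]]  # accession -> chrom -> length
    truth: PlantedTruth


def truth_report(bundle: CohortBundle) -> PlantedTruth:
    """The planted labels of a bundle generated by this module."""
    return bundle.truth


def _ztpois(rng: np.random.Generator, lam: float, size: int) -> np.ndarray:
    out = rng.poisson(lam, size)
    while (zero := out == 0).any():
        out[zero] = rng.poisson(lam, int(zero.sum()))
    return out


def _random_codon(rng: np.random.Generator) -> str:
    while True:
        c = "".join(_BASES[i] for i in rng.integers(0, 4, 3))
        if CODON_TABLE[c] != "*":
            return c


def _mutate(rng: np.random.Generator, codons: list[str], synonymous: bool) -> None:
    """Apply one synonymous (3rd-position, same amino acid) or nonsynonymous
    (different amino acid, never a stop) point substitution in place."""
    order = rng.permutation(len(codons))
    for idx in order:
        c = codons[idx]
        positions = [2] if synonymous else [0, 1, 2]
        for pos in rng.permutation(positions):
            for b in rng.permutation(list(_BASES)):
                if b == c[pos]:
                    continue
                m = c[:pos] + b + c[pos + 1 :]
                if CODON_TABLE[m] == "*":
                    continue
                if (CODON_TABLE[m] == CODON_TABLE[c]) == synonymous:
                    codons[idx] = m
                    return
    # no eligible site (vanishingly unlikely for realistic lengths)


def generate_cohort(config: CohortConfig) -> CohortBundle:
    """Generate a full cohort; deterministic for a fixed config (incl. seed)."""
    rng = np.random.default_rng(config.seed)
    truth = PlantedTruth()

    # --- accessions -------------------------------------------------------
    accessions = (
        [Accession(f"out{i+1}", "outgroup") for i in range(config.n_outgroup)]
        + [Accession(f"wld{i+1}", "wild") for i in range(config.n_wild)]
        + [Accession(f"cvr{i+1}", "cultivar") for i in range(config.n_cultivar)]
        + [Accession(f"rel{i+1}", "relative") for i in range(config.n_relative)]
    )
    acc_ids = [a.id for a in accessions]
    wild_idx = [i for i, a in enumerate(accessions) if a.population == "wild"]
    cultivar_idx = [i for i, a in enumerate(accessions) if a.population == "cultivar"]
    n_acc = len(accessions)

    # --- family presence/count design ------------------------------------
    fam_ids = [f"FAM{i+1:06d}" for i in range(config.n_families)]
    counts = np.zeros((config.n_families, n_acc), dtype=int)
    n_core, n_cloud = config.n_core, config.n_cloud
    core_ids = fam_ids[:n_core]
    shell_ids = fam_ids[n_core : n_core + config.n_shell]
    cloud_ids = fam_ids[n_core + config.n_shell :]
    for f in core_ids:
        truth.family_class[f] = "core"
    for f in shell_ids:
        truth.family_class[f] = "shell"
    for f in cloud_ids:
        truth.family_class[f] = "cloud"

    gained = core_ids[: config.n_gained]
    lost = shell_ids[: config.n_lost]
    for f in gained:
        truth.biased_families[f] = "more_in_cultivar"
    for f in lost:
        truth.biased_families[f] = "lost_in_cultivar"

    for row, fam in enumerate(fam_ids):
        if fam in truth.biased_families:
            if truth.biased_families[fam] == "more_in_cultivar":
                counts[row, :] = 1
                counts[row, cultivar_idx] = 1 + config.gained_effect
            else:  # lost_in_cultivar: members in every wild accession, none elsewhere
                counts[row, wild_idx] = _ztpois(rng, config.lam, len(wild_idx))
        elif truth.family_class[fam] == "core":
            counts[row, :] = _ztpois(rng, config.lam, n_acc)
        elif truth.family_class[fam] == "shell":
            k = int(rng.integers(2, n_acc - 1))  # 2..N-2 accessions
            cols = rng.choice(n_acc, size=k, replace=False)
            counts[row, cols] = _ztpois(rng, config.lam, k)
        else:  # cloud: exactly one accession, rotating deterministically
            col = (row - n_core - config.n_shell) % n_acc
            counts[row, col] = _ztpois(rng, config.lam, 1)[0]

    # --- gene models: membership lists, then chromosome placement --------
    members: dict[str, dict[str, list[str]]] = {f: {} for f in fam_ids}
    genes_per_acc: dict[str, list[tuple[str, str]]] = {a: [] for a in acc_ids}  # (gene_id, family)
    serial = {a: 0 for a in acc_ids}
    for row, fam in enumerate(fam_ids):
        for col, acc in enumerate(acc_ids):
            c = int(counts[row, col])
            if c == 0:
                continue
            ids = []
            for _ in range(c):
                serial[acc] += 1
                ids.append(f"{acc}_g{serial[acc]:05d}")
            members[fam][acc] = ids
            genes_per_acc[acc].extend((g, fam) for g in ids)
    families = FamilyTable(members)

    chroms = [f"chr{i+1:02d}" for i in range(config.n_chromosomes)]
    all_genes: list[GeneModel] = []
    genes_by_acc_chrom: dict[tuple[str, str], list[GeneModel]] = {}
    chrom_lengths: dict[str, dict[str, int]] = {}
    for acc in acc_ids:
        pool = [g for g, _ in genes_per_acc[acc]]
        rng.shuffle(pool)
        chrom_of = rng.integers(0, config.n_chromosomes, len(pool))
        cursor = {c: 10_000 for c in chroms}
        placed: dict[str, list[GeneModel]] = {c: [] for c in chroms}
        for gid, ci in zip(pool, chrom_of):
            chrom = chroms[int(ci)]
            start = cursor[chrom] + int(rng.integers(2_000, 8_001))
            length = int(rng.integers(1_000, 4_001))
            strand = "+" if rng.random() < 0.5 else "-"
            gm = GeneModel(gid, acc, chrom, start, start + length, strand)
            placed[chrom].append(gm)
            cursor[chrom] = start + length
        chrom_lengths[acc] = {c: cursor[c] + 10_000 for c in chroms}
        for chrom in chroms:
            ordered = [
                GeneModel(g.gene_id, g.accession_id, g.chrom, g.start, g.end, g.strand, rank)
                for rank, g in enumerate(placed[chrom])
            ]
            genes_by_acc_chrom[(acc, chrom)] = ordered
            all_genes.extend(ordered)

    # --- NLR planting -----------------------------------------------------
    class_cycle = itertools.cycle(NLR_CLASSES)
    domain_hits: list[DomainHit] = []
    used_nlr_idx: dict[tuple[str, str], set[int]] = {}

    def _free_run(key: tuple[str, str], size: int, tries: int = 200) -> Optional[int]:
        genes_here = genes_by_acc_chrom[key]
        used = used_nlr_idx.setdefault(key, set())
        if len(genes_here) < size + 8:
            return None
        for _ in range(tries):
            s = int(rng.integers(0, len(genes_here) - size + 1))
            if all(u < s - 4 or u > s + size + 3 for u in used):
                used.update(range(s, s + size))
                return s
        return None

    def _plant_protein(gene: GeneModel, cls: str, n_motifs: int) -> None:
        pid = gene.gene_id
        pos = 1
        for dom in _CLASS_DOMAINS[cls]:
            domain_hits.append(DomainHit(pid, "domain", dom, pos, pos + 120, 50.0))
            pos += 140
        for m in range(n_motifs):
            domain_hits.append(DomainHit(pid, "motif", f"{cls}:m{m+1}", 10 + 15 * m, 20 + 15 * m, 30.0))

    # interleave accessions so planted NLRs spread across the whole cohort
    nlr_keys = [(a, c) for c in chroms for a in acc_ids]
    cluster_size = 4
    n_clusters = config.n_nlr // 20 if config.n_nlr >= cluster_size else 0
    n_placed = 0
    key_cycle = itertools.cycle(nlr_keys)
    for _ in range(n_clusters):
        for _ in range(len(nlr_keys)):
            key = next(key_cycle)
            s = _free_run(key, cluster_size)
            if s is not None:
                run = genes_by_acc_chrom[key][s : s + cluster_size]
                truth.nlr_clusters.append(frozenset(g.gene_id for g in run))
                for g in run:
                    cls = next(class_cycle)
                    truth.nlr_class[g.gene_id] = cls
                    _plant_protein(g, cls, 5)
                n_placed += cluster_size
                break
    while n_placed < config.n_nlr:
        for _ in range(len(nlr_keys)):
            key = next(key_cycle)
            s = _free_run(key, 1)
            if s is not None:
                g = genes_by_acc_chrom[key][s]
                cls = next(class_cycle)
                truth.nlr_class[g.gene_id] = cls
                _plant_protein(g, cls, 5)
                n_placed += 1
                break
        else:
            raise RuntimeError("could not place all planted NLR genes; enlarge the cohort")
    n_decoys = round(config.nlr_decoy_frac * config.n_nlr)
    placed_decoys = 0
    while placed_decoys < n_decoys:
        for _ in range(len(nlr_keys)):
            key = next(key_cycle)
            s = _free_run(key, 1)
            if s is not None:
                g = genes_by_acc_chrom[key][s]
                cls = next(class_cycle)
                truth.nlr_decoys.add(g.gene_id)
                _plant_protein(g, cls, 3)  # below the >=5 conserved-motif bar
                placed_decoys += 1
                break
        else:
            raise RuntimeError("could not place all NLR decoys; enlarge the cohort")

    # --- hemizygosity planting + decoy SVs --------------------------------
    svs: dict[str, list[SVCall]] = {a: [] for a in acc_ids}
    min_len, max_len = config.sv_len_range
    for acc in acc_ids:
        acc_genes = [g for key, gs in genes_by_acc_chrom.items() if key[0] == acc for g in gs]
        n_hemi = round(config.hemizygous_frac * len(acc_genes))
        order = rng.permutation(len(acc_genes))
        hemi_genes = [acc_genes[i] for i in order[:n_hemi]]
        other_genes = [acc_genes[i] for i in order[n_hemi:]]
        truth.hemizygous_genes[acc] = {g.gene_id for g in hemi_genes}

        def _neighbour_gaps(g: GeneModel) -> tuple[int, int]:
            row = genes_by_acc_chrom[(acc, g.chrom)]
            prev_end = row[g.rank - 1].end if g.rank > 0 else 0
            next_start = row[g.rank + 1].start if g.rank + 1 < len(row) else g.end + 10_000
            return g.start - prev_end, next_start - g.end

        for g in hemi_genes:
            gap_l, gap_r = _neighbour_gaps(g)
            pad_l = int(rng.integers(10, max(11, min(gap_l - 10, 800))))
            pad_r = int(rng.integers(10, max(11, min(gap_r - 10, 800))))
            start, end = g.start - pad_l, g.end + pad_r
            length = end - start
            if not (min_len <= length <= max_len):  # genes are kbp-scale, so this holds
                raise RuntimeError("planted deletion fell outside the configured length window")
            svs[acc].append(SVCall(acc, g.chrom, start, end, "DEL", length, "het", support=10))

        # decoys: none of these may hemizygose a gene
        decoy_pool = [g for g in other_genes if g.rank > 0]
        rng.shuffle(decoy_pool)
        for g, kind in zip(decoy_pool, itertools.cycle(["short", "partial", "hom", "lowsup", "ins"])):
            if len(svs[acc]) >= len(hemi_genes) + max(5, n_hemi // 3):
                break
            gap_l, gap_r = _neighbour_gaps(g)
            if kind == "short":  # 30 bp: always dropped by the length filter
                svs[acc].append(SVCall(acc, g.chrom, g.start - 200, g.start - 170, "DEL", 30, "het", 10))
            elif kind == "partial":  # overlaps but does not contain
                start = g.start + (g.end - g.start) // 3
                end = g.end + min(200, max(11, gap_r - 10))
                svs[acc].append(SVCall(acc, g.chrom, start, end, "DEL", end - start, "het", 10))
            elif kind == "hom":  # contains, but homozygous
                svs[acc].append(SVCall(acc, g.chrom, g.start - 10, g.end + 10, "DEL", g.end - g.start + 20, "hom", 10))
            elif kind == "lowsup":  # contains, het, but read support below the floor
                svs[acc].append(SVCall(acc, g.chrom, g.start - 10, g.end + 10, "DEL", g.end - g.start + 20, "het", 1))
            else:  # breakpoint-only insertion inside the gene
                pos = g.start + (g.end - g.start) // 2
                svs[acc].append(SVCall(acc, g.chrom, pos, pos + 1, "INS", int(rng.integers(min_len, 5_000)), "het", 10))

    # --- graph labels ------------------------------------------------------
    fam_of_gene = families.family_of_gene()
    graph_labels = []
    for g in all_genes:
        cls = truth.family_class[fam_of_gene[g.gene_id]]
        if cls == "core":
            placement = "trunk"
        elif cls == "cloud":
            placement = "bubble"
        else:
            placement = "bubble" if rng.random() < 0.5 else "trunk"
        graph_labels.append(GraphGeneLabel(g.gene_id, g.accession_id, placement))

    # --- GO map ------------------------------------------------------------
    terms = [f"GO:{i:07d}" for i in range(1, 16)]
    go_map: dict[str, list[str]] = {}
    gained_set = set(gained)
    for g in all_genes:
        k = int(rng.integers(1, 4))
        assigned = sorted(rng.choice(terms, size=k, replace=False))
        if fam_of_gene[g.gene_id] in gained_set:
            assigned.append(ENRICHED_TERM)
        go_map[g.gene_id] = assigned

    # --- codon pairs by frequency class ------------------------------------
    codon_pairs = []
    mutation_plan = {"core": (6, 1), "shell": (4, 3), "cloud": (1, 8)}  # (syn, nonsyn)
    for label in ("core", "shell", "cloud"):
        n_syn, n_non = mutation_plan[label]
        for i in range(25):
            codons = [_random_codon(rng) for _ in range(60)]
            partner = list(codons)
            for _ in range(n_syn):
                _mutate(rng, partner, synonymous=True)
            for _ in range(n_non):
                _mutate(rng, partner, synonymous=False)
            codon_pairs.append((f"{label}_pair{i+1:03d}", label, "".join(codons), "".join(partner)))

    bundle = CohortBundle(
        config=config,
        accessions=accessions,
        genes=all_genes,
        families=families,
        svs=svs,
        domain_hits=domain_hits,
        graph_labels=graph_labels,
        go_map=go_map,
        codon_pairs=codon_pairs,
        chrom_lengths=chrom_lengths,
        truth=truth,
    )
    _check_planted_hemizygosity(bundle)
    return bundle


def _check_planted_hemizygosity(bundle: CohortBundle) -> None:
    """Generation-time consistency check: the hemizygosity rule recovers the
    planted set exactly on every accession."""
    genes_by_acc: dict[str, list[GeneModel]] = {}
    for g in bundle.genes:
        genes_by_acc.setdefault(g.accession_id, []).append(g)
    for acc, genes in genes_by_acc.items():
        report = call_hemizygous_genes(genes, filter_svs(bundle.svs[acc]))
        if set(report.hemizygous_gene_ids) != bundle.truth.hemizygous_genes[acc]:
            raise AssertionError(f"planted hemizygosity not recovered on {acc}")


def write_bundle(bundle: CohortBundle, outdir: str | Path) -> Path:
    """Write the bundle in exactly the formats :mod:`grapepan.io` reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cio.write_population_map(bundle.accessions, outdir / "populations.tsv")
    genes_by_acc: dict[str, list[GeneModel]] = {a.id: [] for a in bundle.accessions}
    for g in bundle.genes:
        genes_by_acc[g.accession_id].append(g)
    for acc in bundle.accessions:
        cio.write_gff3(genes_by_acc[acc.id], outdir / f"{acc.id}.gff3")
        cio.write_vcf_svs(bundle.svs[acc.id], outdir / f"{acc.id}.vcf",
                          contigs=bundle.chrom_lengths[acc.id])
    cio.write_orthogroups(bundle.families, outdir / "orthogroups.tsv",
                          [a.id for a in bundle.accessions])
    cio.write_domain_hits(bundle.domain_hits, outdir / "domain_hits.tsv")
    cio.write_graph_labels(bundle.graph_labels, outdir / "graph_labels.tsv")
    cio.write_go_map(bundle.go_map, outdir / "go_map.tsv")
    cio.write_codon_pairs(bundle.codon_pairs, outdir / "codon_pairs.fasta")
    return outdir


def read_bundle(indir: str | Path) -> dict:
    """Load a written bundle back through the ordinary readers (no truth)."""
    indir = Path(indir)
    accessions = cio.read_population_map(indir / "populations.tsv")
    genes: list[GeneModel] = []
    svs: dict[str, list[SVCall]] = {}
    for acc in accessions:
        genes.extend(cio.read_gff3(indir / f"{acc.id}.gff3", acc.id))
        svs[acc.id] = cio.read_vcf_svs(indir / f"{acc.id}.vcf", acc.id)
    return {
        "accessions": accessions,
        "genes": genes,
        "svs": svs,
        "families": cio.read_orthogroups(indir / "orthogroups.tsv"),
        "domain_hits": cio.read_domain_hits(indir / "domain_hits.tsv"),
        "graph_labels": cio.read_graph_labels(indir / "graph_labels.tsv"),
        "go_map": cio.read_go_map(indir / "go_map.tsv"),
        "codon_pairs": cio.read_codon_pairs(indir / "codon_pairs.fasta"),
    }
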