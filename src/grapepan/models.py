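"""Core domain types shared by every analysis stage.

All genomic intervals are 0-based, half-open; conversion from the 1-based
inclusive conventions of GFF3 and VCF happens exclusively in :mod:`grapepan.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

POPULATIONS = ("outgroup", "wild", "cultivar", "relative")

SVTYPES = ("INS", "DEL")


@dataclass(frozen=True)
class Accession:
    """One assembly in the cohort.

    Haplotype-resolved assemblies are modelled as two separate accessions
    sharing a ``parent_id`` (e.g. ``Chard_hap1`` / ``Chard_hap2`` with parent
    ``Chard``), which lets haplotype comparisons reuse the ordinary
    presence/absence machinery.
    """

    id: str
    population: str
    haplotype: Optional[str] = None

    def __post_init__(self) -> None:
        if self.population not in POPULATIONS:
            raise ValueError(
                f"unknown population {self.population!r} for accession {self.id!r}; "
                f"expected one of {POPULATIONS}"
            )

    @property
    def parent_id(self) -> str:
        """Diploid parent identifier; strips a trailing ``_hapN`` suffix if present."""
        if self.haplotype and self.id.endswith(f"_{self.haplotype}"):
            return self.id[: -(len(self.haplotype) + 1)]
        return self.id


@dataclass(frozen=True)
class GeneModel:
    """A gene interval on one accession's chromosome.

    ``rank`` is the 0-based position of the gene in the start-sorted gene
    order of its (accession, chromosome); it drives NLR pairing.
    """

    gene_id: str
    accession_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."
    rank: int = -1

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"gene {self.gene_id}: start must be < end ({self.start} >= {self.end})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2


@dataclass(frozen=True)
class SVCall:
    """A structural-variant call (insertion or deletion) on one accession.

    Deletions span ``[start, end)`` with ``end - start == length``.  Insertions
    are stored as a 1-bp breakpoint interval (``end == start + 1``); when the
    caller annotated the inserted sequence's location on the assembly itself,
    ``inserted_interval`` holds that (start, end) span and heterozygous genes
    inside it can be called hemizygous.
    """

    accession_id: str
    chrom: str
    start: int
    end: int
    svtype: str
    length: int
    genotype: str  # "het" | "hom"
    support: int = 0
    inserted_interval: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if self.svtype not in SVTYPES:
            raise ValueError(f"unsupported SV type {self.svtype!r}")
        if self.length <= 0:
            raise ValueError(f"SV length must be positive, got {self.length}")
        if self.genotype not in ("het", "hom"):
            raise ValueError(f"genotype must be 'het' or 'hom', got {self.genotype!r}")
        if self.svtype == "DEL" and self.end - self.start != self.length:
            raise ValueError(
                f"DEL at {self.chrom}:{self.start} spans {self.end - self.start} bp "
                f"but declares length {self.length}"
            )
        if self.svtype == "INS" and self.end != self.start + 1:
            raise ValueError("INS must be stored as a 1-bp breakpoint interval")


class FamilyTableError(ValueError):
    pass


class FamilyTable:
    """Gene families: ``family_id -> {accession_id -> [gene_id, ...]}``.

    Families partition the annotated gene space: a gene may belong to at most
    one family (validated on construction).
    """

    def __init__(self, members: dict[str, dict[str, list[str]]]):
        self.members = members
        self._validate_disjoint()

    def _validate_disjoint(self) -> None:
        seen: dict[str, str] = {}
        for fam, per_acc in self.members.items():
            for genes in per_acc.values():
                for g in genes:
                    if g in seen and seen[g] != fam:
                        raise FamilyTableError(
                            f"gene {g!r} listed in families {seen[g]!r} and {fam!r}"
                        )
                    seen[g] = fam

    @property
    def family_ids(self) -> list[str]:
        return list(self.members)

    @property
    def accession_ids(self) -> list[str]:
        out: list[str] = []
        for per_acc in self.members.values():
            for a in per_acc:
                if a not in out:
                    out.append(a)
        return out

    def count(self, family_id: str, accession_id: str) -> int:
        return len(self.members[family_id].get(accession_id, ()))

    def family_of_gene(self) -> dict[str, str]:
        out = {}
        for fam, per_acc in self.members.items():
            for genes in per_acc.values():
                for g in genes:
                    out[g] = fam
        return out

    def __len__(self) -> int:
        return len(self.members)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, FamilyTable) and self.members == other.members


@dataclass(frozen=True)
class DomainHit:
    """One protein-domain or motif hit (coordinates in amino acids)."""

    protein_id: str
    source: str  # "domain" | "motif"
    accession: str  # e.g. PF00931, CC, LRR, or a motif ID
    start: int
    end: int
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.source not in ("domain", "motif"):
            raise ValueError(f"hit source must be 'domain' or 'motif', got {self.source!r}")
        if not self.start < self.end:
            raise ValueError(f"hit on {self.protein_id}: start must be < end")


@dataclass(frozen=True)
class GraphGeneLabel:
    """Placement of a gene in a graph-based pan-genome: shared trunk or bubble."""

    gene_id: str
    accession_id: str
    placement: str  # "trunk" | "bubble"

    def __post_init__(self) -> None:
        if self.placement not in ("trunk", "bubble"):
            raise ValueError(f"placement must be trunk|bubble, got {self.placement!r}")


@dataclass
class ComparisonResult:
    """Outcome of a per-family member-count comparison between two populations.

    ``U`` and ``p_value`` are ``None`` for rows resolved without a test
    (all-zero on one or both sides).
    """

    family_id: str
    counts_a: tuple[int, ...]
    counts_b: tuple[int, ...]
    U: Optional[float]
    p_value: Optional[float]
    direction: str  # more_in_a | more_in_b | none
    status: str  # significant_more_a | significant_more_b | lost_in_a | lost_in_b | ns
    p_bh: Optional[float] = None


@dataclass(frozen=True)
class KaKsResult:
    """NG86 substitution-rate estimates for one coding-sequence pair.

    ``ratio`` is ``None`` whenever Ks is 0 or either rate's Jukes–Cantor
    correction was undefined (p >= 3/4) — never silently 0 or inf.
    """

    pair: tuple[str, str]
    ka: Optional[float]
    ks: Optional[float]
    ratio: Optional[float]
    sites_syn: float = 0.0
    sites_nonsyn: float = 0.0
    diffs_syn: float = 0.0
    diffs_nonsyn: float = 0.0


@dataclass
class HemizygosityReport:
    """Per-accession hemizygous-gene call summary."""

    accession_id: str
    n_genes: int
    hemizygous_gene_ids: frozenset[str]
    @property
    def proportion(self) -> float:
        return len(self.hemizygous_gene_ids) / self.n_genes if self.n_genes else 0.0


@dataclass
class NLRRecord:
    """A protein's NLR evidence: domain architecture, class, motif support."""

    protein_id: str
    gene_id: str
    domains: frozenset[str]
    nlr_class: Optional[str]
    n_conserved_motifs: int = 0
    passed_filter: bool = False


@dataclass
class NLRCluster:
    cluster_id: str
    accession_id: str
    chrom: str
    member_gene_ids: tuple[str, ...]


@dataclass
class GraphDiversityStats:
    """Trunk/bubble accounting for the NLR genes of one graph pan-genome.

    ``adc`` — average diversity contribution: bubble-resident NLR genes
    divided by the number of accessions in the graph.
    """

    population: str
    n_accessions: int
    n_nlr_total: int
    n_trunk: int
    n_bubble: int

    @property
    def bubble_fraction(self) -> float:
        return self.n_bubble / self.n_nlr_total if self.n_nlr_total else 0.0

    @property
    def adc(self) -> float:
        return self.n_bubble / self.n_accessions
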