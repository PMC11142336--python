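"""End-to-end orchestration from a single YAML config.

Stages run in a fixed order (io -> matrix -> classification -> saturation ->
gain/loss -> hemizygosity -> NLR -> graph stats -> enrichment), each writing
into its own subdirectory of the output directory, and a manifest records
every parameter, the seed, input checksums and per-stage record counts so a
run can be reproduced byte-for-byte from the manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Optional

import yaml

from . import io as cio
from .gainloss import hypergeometric_enrichment, kaks_by_frequency, ng86_kaks, population_gain_loss
from .hemizygosity import call_hemizygous_genes, filter_svs, population_hemizygosity
from .models import GeneModel
from .nlr import (
    classify_nlr,
    graph_diversity,
    motif_conservation_filter,
    nlr_clusters,
    pair_nlr_genes,
)
from .pav import build_pav_matrix, classify_frequency, saturation_curves
from .simulate import CohortConfig, generate_cohort, write_bundle

log = logging.getLogger(__name__)

REPORT_FILES = (
    "matrix/matrix.tsv",
    "matrix/classes.tsv",
    "saturation/saturation.tsv",
    "gainloss/gainloss.tsv",
    "hemizygosity/hemizygosity.tsv",
    "nlr/nlr_records.tsv",
    "nlr/graph_stats.json",
    "enrichment/enrichment.tsv",
)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """One run: either a synthetic cohort spec or paths to real inputs."""

    outdir: str
    synthetic: Optional[dict[str, Any]] = None
    inputs: Optional[dict[str, str]] = None  # bundle directory with the standard file names
    alpha: float = 0.05
    core_min_present: Optional[int] = None  # default: N - 1 (i.e. "more than N-2")
    saturation_permutations: int = 1000
    seed: int = 0
    sv_min_len: int = 50
    sv_max_len: int = 1_000_000
    sv_min_support: int = 5
    overlap_mode: str = "contained"
    min_motifs: int = 5
    max_intervening: int = 1
    min_cluster_size: int = 4

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.inputs is None):
            raise ValueError("exactly one of 'synthetic' and 'inputs' must be given")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _json_dump(obj: Any, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest (also written to disk)."""
    outdir = Path(config.outdir)
    manifest: dict[str, Any] = {"config": asdict(config), "stages": {}}
    stage = "startup"
    try:
        # ---- io ----------------------------------------------------------
        stage = "io"
        if config.synthetic is not None:
            cc = CohortConfig(**{**config.synthetic, "seed": config.synthetic.get("seed", config.seed)})
            bundle = generate_cohort(cc)
            bundle_dir = outdir / "cohort"
            write_bundle(bundle, bundle_dir)
        else:
            bundle_dir = Path(config.inputs["bundle_dir"])
            if not bundle_dir.is_dir():
                raise FileNotFoundError(f"input bundle directory {bundle_dir} does not exist")
        from .simulate import read_bundle  # read everything back through the parsers

        data = read_bundle(bundle_dir)
        accessions = data["accessions"]
        genes: list[GeneModel] = data["genes"]
        families = data["families"]
        outdir.mkdir(parents=True, exist_ok=True)
        manifest["inputs"] = {
            p.name: _sha256(p) for p in sorted(bundle_dir.iterdir()) if p.is_file()
        }
        manifest["stages"]["io"] = {
            "n_accessions": len(accessions),
            "n_genes": len(genes),
            "n_families": len(families),
            "n_svs": sum(len(v) for v in data["svs"].values()),
        }
        pops: dict[str, list[str]] = {}
        for a in accessions:
            pops.setdefault(a.population, []).append(a.id)

        # ---- matrix + classification -------------------------------------
        stage = "matrix"
        (outdir / "matrix").mkdir(exist_ok=True)
        matrix = build_pav_matrix(families, [a.id for a in accessions])
        matrix.to_tsv(outdir / "matrix/matrix.tsv")
        core_min = config.core_min_present or len(accessions) - 1
        classes, class_counts = classify_frequency(matrix, core_min)
        with open(outdir / "matrix/classes.tsv", "w", encoding="utf-8") as fh:
            fh.write("family_id\tn_present\tlabel\n")
            for c in classes:
                fh.write(f"{c.family_id}\t{c.n_present}\t{c.label}\n")
        manifest["stages"]["matrix"] = {"n_families": len(matrix.family_ids), **class_counts}

        # ---- saturation ---------------------------------------------------
        stage = "saturation"
        (outdir / "saturation").mkdir(exist_ok=True)
        sat = saturation_curves(matrix, config.saturation_permutations, seed=config.seed)
        sat.to_csv(outdir / "saturation/saturation.tsv", sep="\t", index=False, float_format="%.4f")
        manifest["stages"]["saturation"] = {"n_permutations": config.saturation_permutations}

        # ---- gain/loss ----------------------------------------------------
        stage = "gainloss"
        (outdir / "gainloss").mkdir(exist_ok=True)
        if not pops.get("cultivar") or not pops.get("wild"):
            raise ValueError("gain/loss needs both a cultivar and a wild population")
        gl, gl_summary = population_gain_loss(
            matrix, pops["cultivar"], pops["wild"], alpha=config.alpha
        )
        gl.to_csv(outdir / "gainloss/gainloss.tsv", sep="\t", index=False, float_format="%.6g")
        manifest["stages"]["gainloss"] = {
            k: v for k, v in gl_summary.items() if not isinstance(v, list)
        }

        # ---- hemizygosity -------------------------------------------------
        stage = "hemizygosity"
        (outdir / "hemizygosity").mkdir(exist_ok=True)
        genes_by_acc: dict[str, list[GeneModel]] = {}
        for g in genes:
            genes_by_acc.setdefault(g.accession_id, []).append(g)
        reports = []
        for a in accessions:
            kept = filter_svs(
                data["svs"].get(a.id, []),
                config.sv_min_len, config.sv_max_len, config.sv_min_support,
            )
            reports.append(call_hemizygous_genes(genes_by_acc[a.id], kept, config.overlap_mode))
        pop_means = population_hemizygosity(reports, accessions)
        with open(outdir / "hemizygosity/hemizygosity.tsv", "w", encoding="utf-8") as fh:
            fh.write("accession_id\tn_genes\tn_hemizygous\tproportion\n")
            for r in reports:
                fh.write(f"{r.accession_id}\t{r.n_genes}\t{len(r.hemizygous_gene_ids)}\t{r.proportion:.4f}\n")
        manifest["stages"]["hemizygosity"] = {k: round(v, 4) for k, v in pop_means.items()}

        # ---- NLR ----------------------------------------------------------
        stage = "nlr"
        (outdir / "nlr").mkdir(exist_ok=True)
        hits = data["domain_hits"]
        by_protein: dict[str, list] = {}
        for h in hits:
            by_protein.setdefault(h.protein_id, []).append(h)
        records = [classify_nlr(pid, phits) for pid, phits in sorted(by_protein.items())]
        records = motif_conservation_filter(records, hits, config.min_motifs)
        passed = [r for r in records if r.passed_filter]
        with open(outdir / "nlr/nlr_records.tsv", "w", encoding="utf-8") as fh:
            fh.write("protein_id\tgene_id\tnlr_class\tn_conserved_motifs\tpassed_filter\n")
            for r in records:
                fh.write(f"{r.protein_id}\t{r.gene_id}\t{r.nlr_class or ''}\t{r.n_conserved_motifs}\t{int(r.passed_filter)}\n")
        nlr_ids = {r.gene_id for r in passed}
        gene_index = {g.gene_id: g for g in genes}
        all_pairs = []
        all_clusters = []
        keys = sorted({(g.accession_id, g.chrom) for g in genes if g.gene_id in nlr_ids})
        for acc_id, chrom in keys:
            row = [g for g in genes_by_acc[acc_id] if g.chrom == chrom]
            pairs = pair_nlr_genes(row, nlr_ids, config.max_intervening)
            all_pairs.extend(pairs)
            all_clusters.extend(nlr_clusters(pairs, row, config.min_cluster_size))
        with open(outdir / "nlr/clusters.bed", "w", encoding="utf-8") as fh:
            for cl in all_clusters:
                lo = min(gene_index[g].start for g in cl.member_gene_ids)
                hi = max(gene_index[g].end for g in cl.member_gene_ids)
                fh.write(f"{cl.chrom}\t{lo}\t{hi}\t{cl.accession_id}:{cl.cluster_id}\t{len(cl.member_gene_ids)}\n")
        manifest["stages"]["nlr"] = {
            "n_candidates": len(records),
            "n_passed": len(passed),
            "n_pairs": len(all_pairs),
            "n_clusters": len(all_clusters),
        }

        # ---- graph stats ---------------------------------------------------
        stage = "graph"
        stats_out = {}
        labels = data["graph_labels"]
        for pop in sorted(pops):
            pop_nlr = {g for g in nlr_ids if gene_index[g].accession_id in set(pops[pop])}
            if not pop_nlr:
                continue
            st = graph_diversity(pop_nlr, labels, len(pops[pop]), population=pop)
            stats_out[pop] = {
                "n_accessions": st.n_accessions,
                "n_nlr_total": st.n_nlr_total,
                "n_trunk": st.n_trunk,
                "n_bubble": st.n_bubble,
                "bubble_fraction": round(st.bubble_fraction, 4),
                "adc": round(st.adc, 1),
            }
        _json_dump(stats_out, outdir / "nlr/graph_stats.json")
        manifest["stages"]["graph"] = {pop: s["adc"] for pop, s in stats_out.items()}

        # ---- enrichment ----------------------------------------------------
        stage = "enrichment"
        (outdir / "enrichment").mkdir(exist_ok=True)
        go_map = data["go_map"]
        universe = set(go_map)
        gained = set(gl_summary["gained_a"])
        fam_members = families.members
        study = {
            g
            for fam in gained
            for acc_genes in fam_members.get(fam, {}).values()
            for g in acc_genes
        } & universe
        if study:
            enr = hypergeometric_enrichment(study, universe, go_map, alpha=config.alpha)
        else:
            import pandas as pd

            enr = pd.DataFrame(columns=["term", "k", "K", "n", "N", "p_value", "p_bh", "enriched"])
        enr.to_csv(outdir / "enrichment/enrichment.tsv", sep="\t", index=False, float_format="%.6g")
        manifest["stages"]["enrichment"] = {
            "n_study_genes": len(study),
            "n_terms": int(len(enr)),
            "n_enriched": int(enr["enriched"].sum()) if len(enr) else 0,
        }

        # ---- Ka/Ks ---------------------------------------------------------
        stage = "kaks"
        pairs = data["codon_pairs"]
        labeled = [
            (ng86_kaks(sa, sb, (f"{pid}/1", f"{pid}/2")), label)
            for pid, label, sa, sb, _ in pairs
        ]
        kaks_summary = kaks_by_frequency(labeled, alpha=config.alpha)
        _json_dump(kaks_summary, outdir / "gainloss/kaks.json")
        manifest["stages"]["kaks"] = {"n_pairs": len(labeled)}

    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - reported with the failing stage
        raise PipelineError(stage, str(exc)) from exc

    _json_dump(manifest, outdir / "manifest.json")
    for rel in REPORT_FILES:
        if not (outdir / rel).exists():
            raise PipelineError("report", f"missing expected report file {rel}")
    return manifest
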