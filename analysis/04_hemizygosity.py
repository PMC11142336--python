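#!/usr/bin/env python
"""Hemizygous-gene calling from heterozygous SVs, per accession and population.

Applies the 50 bp-1 Mb length filter and read-support floor to each
accession's SV calls, calls genes fully contained in heterozygous deletions,
scores the calls against the planted truth, and reports per-population mean
hemizygosity.  Outputs in results/hemizygosity/.
"""

from pathlib import Path

from grapepan.hemizygosity import call_hemizygous_genes, filter_svs, population_hemizygosity
from grapepan.simulate import CohortConfig, generate_cohort

COHORT = CohortConfig(n_families=1000, seed=1)
ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    bundle = generate_cohort(COHORT)
    out = ROOT / "hemizygosity"
    out.mkdir(parents=True, exist_ok=True)
    genes_by_acc: dict[str, list] = {}
    for g in bundle.genes:
        genes_by_acc.setdefault(g.accession_id, []).append(g)

    reports = []
    tp = fp = fn = 0
    with open(out / "per_accession.tsv", "w", encoding="utf-8") as fh:
        fh.write("accession_id\tn_genes\tn_hemizygous\tproportion\n")
        for acc in [a.id for a in bundle.accessions]:
            kept = filter_svs(bundle.svs[acc])
            report = call_hemizygous_genes(genes_by_acc[acc], kept)
            reports.append(report)
            called = set(report.hemizygous_gene_ids)
            truth = bundle.truth.hemizygous_genes[acc]
            tp += len(called & truth)
            fp += len(called - truth)
            fn += len(truth - called)
            fh.write(f"{acc}\t{report.n_genes}\t{len(called)}\t{report.proportion:.4f}\n")

    means = population_hemizygosity(reports, bundle.accessions)
    with open(out / "population_means.tsv", "w", encoding="utf-8") as fh:
        fh.write("population\tmean_proportion\n")
        for pop, v in sorted(means.items()):
            fh.write(f"{pop}\t{v:.4f}\n")

    print(f"hemizygous calls: {tp + fp} (precision {tp / (tp + fp):.3f}, "
          f"recall {tp / (tp + fn):.3f} against planted truth)")
    for pop, v in sorted(means.items()):
        print(f"  {pop:9s}: mean proportion {100 * v:.2f}%")
    print(f"tables in {out}")


if __name__ == "__main__":
    main()
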