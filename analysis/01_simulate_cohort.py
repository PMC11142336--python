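#!/usr/bin/env python
"""Generate the study cohort used by every downstream analysis script.

Emits a 17-accession synthetic cohort (1 outgroup, 5 wild, 9 cultivars,
2 relatives; 1,000 gene families with planted core/shell/cloud structure,
20 cultivar-gained and 20 cultivar-lost families, 15% planted hemizygous
genes, 64 planted NLRs) under results/cohort/ in the standard formats
(GFF3, VCF, TSV, FASTA), and prints what was planted.
"""

from pathlib import Path

from grapepan.simulate import CohortConfig, generate_cohort, write_bundle

COHORT = CohortConfig(n_families=1000, seed=1)
OUT = Path(__file__).resolve().parent.parent / "results" / "cohort"


def main() -> None:
    bundle = generate_cohort(COHORT)
    write_bundle(bundle, OUT)
    truth = bundle.truth
    n_hemi = sum(map(len, truth.hemizygous_genes.values()))
    print(f"cohort written to {OUT}")
    print(f"  accessions : {len(bundle.accessions)} "
          f"(outgroup 1, wild 5, cultivar 9, relative 2)")
    print(f"  genes      : {len(bundle.genes)}")
    print(f"  families   : {len(bundle.families)} "
          f"(core {COHORT.n_core}, shell {COHORT.n_shell}, cloud {COHORT.n_cloud})")
    print(f"  planted bias: {COHORT.n_gained} more_in_cultivar, {COHORT.n_lost} lost_in_cultivar")
    print(f"  hemizygous : {n_hemi} genes "
          f"({100 * n_hemi / len(bundle.genes):.1f}% of genes)")
    print(f"  NLRs       : {len(truth.nlr_class)} true, {len(truth.nlr_decoys)} decoys, "
          f"{len(truth.nlr_clusters)} physical clusters")


if __name__ == "__main__":
    main()
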