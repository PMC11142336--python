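"""NLR classification truth table, pairing/cluster geometry, spectra, ADC."""

import itertools

import numpy as np
import pytest

from grapepan.models import DomainHit, FamilyTable, GeneModel, GraphGeneLabel, NLRRecord
from grapepan.nlr import (
    NLR_CLASSES,
    classify_domains,
    classify_nlr,
    graph_diversity,
    motif_conservation_filter,
    nlr_chromosome_map,
    nlr_clusters,
    pair_nlr_genes,
    pan_nlrome_spectrum,
)

ALL_DOMAINS = ("NB-ARC", "TIR", "RPW8", "CC", "LRR")


def oracle_classify(domains):
    """Independent literal enumeration of the eight-class assignment rules."""
    has = {d: d in domains for d in ALL_DOMAINS}
    if not (has["NB-ARC"] or has["TIR"] or has["RPW8"]):
        return None
    if has["TIR"] and has["NB-ARC"] and has["LRR"]:
        return "TIR-NBS-LRR"
    if has["TIR"] and has["NB-ARC"]:
        return "TIR-NBS"
    if has["TIR"]:
        return "TIR-X"
    if has["RPW8"]:
        return "RPW8-X"
    if has["CC"] and has["NB-ARC"] and has["LRR"]:
        return "CC-NBS-LRR"
    if has["CC"] and has["NB-ARC"]:
        return "CC-NBS"
    if has["NB-ARC"] and has["LRR"]:
        return "NBS-LRR"
    return "NBS"


def brute_force_pairs(order, nlr_set, max_intervening=1):
    pairs = set()
    for i, gi in enumerate(order):
        for j, gj in enumerate(order):
            if j <= i or gi not in nlr_set or gj not in nlr_set:
                continue
            between = sum(1 for k in range(i + 1, j) if order[k] not in nlr_set)
            if between <= max_intervening:
                pairs.add(tuple(sorted((gi, gj))))
    return sorted(pairs)


def chrom_genes(order):
    return [GeneModel(g, "a", "chr1", 1000 * i, 1000 * i + 500, "+", i)
            for i, g in enumerate(order)]


class TestClassification:
    def test_truth_table_over_all_32_subsets(self):
        for r in range(len(ALL_DOMAINS) + 1):
            for subset in itertools.combinations(ALL_DOMAINS, r):
                assert classify_domains(frozenset(subset)) == oracle_classify(set(subset)), subset

    def test_canonical_architectures(self):
        assert classify_domains({"TIR", "NB-ARC", "LRR"}) == "TIR-NBS-LRR"
        assert classify_domains({"LRR"}) is None
        assert classify_domains({"CC", "NB-ARC"}) == "CC-NBS"
        assert classify_domains({"RPW8", "NB-ARC"}) == "RPW8-X"

    def test_all_eight_classes_reachable(self):
        reachable = {
            classify_domains(frozenset(s))
            for r in range(6)
            for s in itertools.combinations(ALL_DOMAINS, r)
        }
        assert set(NLR_CLASSES) <= reachable

    def test_classify_nlr_reads_pfam_accessions(self):
        hits = [DomainHit("p1", "domain", "PF01582", 1, 100),
                DomainHit("p1", "domain", "PF00931", 150, 400),
                DomainHit("p1", "domain", "LRR", 500, 700),
                DomainHit("p2", "domain", "PF05659", 1, 90)]
        rec = classify_nlr("p1", hits)
        assert rec.nlr_class == "TIR-NBS-LRR"
        assert rec.domains == frozenset({"TIR", "NB-ARC", "LRR"})


class TestMotifFilter:
    def rec(self, pid="p1", cls="NBS"):
        return NLRRecord(pid, pid, frozenset({"NB-ARC"}), cls)

    def motif(self, pid, mid):
        return DomainHit(pid, "motif", mid, 1, 10)

    def test_five_distinct_motifs_pass(self):
        hits = [self.motif("p1", f"m{i}") for i in range(5)]
        (rec,) = motif_conservation_filter([self.rec()], hits)
        assert rec.passed_filter and rec.n_conserved_motifs == 5

    def test_repeated_hits_of_one_motif_count_once(self):
        hits = [self.motif("p1", "m1") for _ in range(5)]
        (rec,) = motif_conservation_filter([self.rec()], hits)
        assert rec.n_conserved_motifs == 1 and not rec.passed_filter

    def test_non_candidates_never_pass(self):
        rec = NLRRecord("p1", "p1", frozenset({"LRR"}), None)
        hits = [self.motif("p1", f"m{i}") for i in range(9)]
        (out,) = motif_conservation_filter([rec], hits)
        assert not out.passed_filter

    def test_planted_decoys_dropped_and_true_nlrs_kept(self, default_cohort):
        truth = default_cohort.truth
        by_protein = {}
        for h in default_cohort.domain_hits:
            by_protein.setdefault(h.protein_id, []).append(h)
        records = [classify_nlr(pid, hits) for pid, hits in by_protein.items()]
        records = motif_conservation_filter(records, default_cohort.domain_hits)
        passed = {r.protein_id for r in records if r.passed_filter}
        assert passed == set(truth.nlr_class)
        assert not passed & truth.nlr_decoys


class TestPairing:
    def test_one_intervening_non_nlr_still_pairs(self):
        genes = chrom_genes(["N1", "x", "N2"])
        assert pair_nlr_genes(genes, {"N1", "N2"}) == [("N1", "N2")]

    def test_two_intervening_non_nlr_blocks(self):
        genes = chrom_genes(["N1", "x", "y", "N2"])
        assert pair_nlr_genes(genes, {"N1", "N2"}) == []

    def test_intervening_nlr_does_not_block(self):
        genes = chrom_genes(["N1", "N2", "N3"])
        assert pair_nlr_genes(genes, {"N1", "N2", "N3"}) == \
            [("N1", "N2"), ("N1", "N3"), ("N2", "N3")]

    def test_matches_brute_force_on_random_chromosomes(self):
        rng = np.random.default_rng(23)
        for _ in range(40):
            n = 30
            order = [f"g{i}" for i in range(n)]
            nlr = {g for g in order if rng.random() < 0.3}
            assert pair_nlr_genes(chrom_genes(order), nlr) == brute_force_pairs(order, nlr)

    def test_noncontiguous_ranks_rejected(self):
        genes = chrom_genes(["a", "b"])
        broken = [genes[0], GeneModel("b", "a", "chr1", 5000, 5500, "+", 7)]
        with pytest.raises(ValueError, match="contiguous"):
            pair_nlr_genes(broken, {"a", "b"})


class TestClusters:
    def test_chain_of_four_is_one_cluster(self):
        order = ["N1", "x", "N2", "y", "N3", "z", "N4"]
        genes = chrom_genes(order)
        pairs = pair_nlr_genes(genes, {"N1", "N2", "N3", "N4"})
        clusters = nlr_clusters(pairs, genes)
        assert len(clusters) == 1
        assert clusters[0].member_gene_ids == ("N1", "N2", "N3", "N4")

    def test_two_distant_pairs_make_no_cluster_at_default_size(self):
        order = ["N1", "N2"] + [f"x{i}" for i in range(5)] + ["N3", "N4"]
        genes = chrom_genes(order)
        pairs = pair_nlr_genes(genes, {"N1", "N2", "N3", "N4"})
        assert nlr_clusters(pairs, genes) == []
        assert len(nlr_clusters(pairs, genes, min_cluster_size=2)) == 2

    def test_nesting_clustered_within_paired_within_all(self, default_cohort):
        truth = default_cohort.truth
        nlr_ids = set(truth.nlr_class)
        genes_by_key = {}
        for g in default_cohort.genes:
            genes_by_key.setdefault((g.accession_id, g.chrom), []).append(g)
        paired, clustered = set(), set()
        for key, genes in genes_by_key.items():
            pairs = pair_nlr_genes(genes, nlr_ids)
            for a, b in pairs:
                paired.update((a, b))
            for cl in nlr_clusters(pairs, genes):
                clustered.update(cl.member_gene_ids)
        assert clustered <= paired <= nlr_ids

    def test_planted_clusters_recovered_exactly(self, default_cohort):
        truth = default_cohort.truth
        nlr_ids = set(truth.nlr_class)
        genes_by_key = {}
        for g in default_cohort.genes:
            genes_by_key.setdefault((g.accession_id, g.chrom), []).append(g)
        found = []
        for key, genes in genes_by_key.items():
            pairs = pair_nlr_genes(genes, nlr_ids)
            found.extend(frozenset(c.member_gene_ids) for c in nlr_clusters(pairs, genes))
        assert sorted(found, key=sorted) == sorted(truth.nlr_clusters, key=sorted)


class TestSpectrumAndGraph:
    def test_spectrum_concentrations(self):
        fams_all = FamilyTable({"F1": {"A": ["a1"], "B": ["b1"]},
                                "F2": {"A": ["a2"], "B": ["b2"]}})
        df = pan_nlrome_spectrum(fams_all, ["A", "B"])
        assert df[df.nlr_class == "all"].set_index("k").n_families.to_dict() == {2: 2}
        fams_single = FamilyTable({"F1": {"A": ["a1"]}, "F2": {"B": ["b2"]}})
        df = pan_nlrome_spectrum(fams_single, ["A", "B"])
        assert df[df.nlr_class == "all"].set_index("k").n_families.to_dict() == {1: 2}

    def test_spectrum_sums_to_family_count(self):
        rng = np.random.default_rng(29)
        members = {}
        for i in range(40):
            accs = rng.choice(["A", "B", "C", "D"], size=rng.integers(1, 5), replace=False)
            members[f"F{i}"] = {a: [f"F{i}_{a}"] for a in accs}
        table = FamilyTable(members)
        df = pan_nlrome_spectrum(table, ["A", "B", "C", "D"])
        assert df[df.nlr_class == "all"].n_families.sum() == 40

    def test_adc_from_bubble_count(self):
        labels = [GraphGeneLabel(f"n{i}", "a", "bubble") for i in range(1458)]
        stats = graph_diversity({f"n{i}" for i in range(1458)}, labels, n_accessions=9)
        assert stats.adc == pytest.approx(162.0)
        assert stats.bubble_fraction == 1.0

    def test_zero_bubbles(self):
        labels = [GraphGeneLabel("n0", "a", "trunk")]
        stats = graph_diversity({"n0"}, labels, n_accessions=3)
        assert stats.adc == 0.0 and stats.bubble_fraction == 0.0

    def test_trunk_plus_bubble_conservation_on_random_labelings(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            n = int(rng.integers(1, 50))
            labels = [GraphGeneLabel(f"n{i}", "a", "bubble" if rng.random() < 0.5 else "trunk")
                      for i in range(n)]
            stats = graph_diversity({f"n{i}" for i in range(n)}, labels, n_accessions=2)
            assert stats.n_trunk + stats.n_bubble == stats.n_nlr_total == n

    def test_unlabeled_nlr_gene_is_error(self):
        with pytest.raises(ValueError, match="unlabeled"):
            graph_diversity({"n0"}, [], n_accessions=1)


class TestChromosomeMap:
    def test_empty_input(self):
        positions, counts = nlr_chromosome_map([], [])
        assert positions.empty and counts.empty

    def test_counts_match_brute_force_group_by(self):
        rng = np.random.default_rng(37)
        genes, records = [], []
        for i in range(25):
            chrom = f"chr{int(rng.integers(18, 20))}"
            g = GeneModel(f"g{i}", "a", chrom, 1000 * i, 1000 * i + 500, "+", 0)
            genes.append(g)
            records.append(NLRRecord(f"g{i}", f"g{i}", frozenset({"NB-ARC"}),
                                     str(rng.choice(["NBS", "TIR-NBS"]))))
        positions, counts = nlr_chromosome_map(records, genes)
        assert len(positions) == 25
        brute = {}
        for g, r in zip(genes, records):
            brute[(g.chrom, r.nlr_class)] = brute.get((g.chrom, r.nlr_class), 0) + 1
        got = {(row.chrom, row.nlr_class): row.n_genes for row in counts.itertuples()}
        assert got == brute

    def test_unknown_chromosome_is_error(self):
        g = GeneModel("g1", "a", "chrX", 0, 100, "+", 0)
        rec = NLRRecord("g1", "g1", frozenset({"NB-ARC"}), "NBS")
        with pytest.raises(KeyError, match="unknown chromosome"):
            nlr_chromosome_map([rec], [g], chrom_lengths={"chr1": 10_000})
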