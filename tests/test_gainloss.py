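"""Mann-Whitney exactness, family comparisons, enrichment, NG86 Ka/Ks."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from grapepan.gainloss import (
    CODON_TABLE,
    compare_family,
    hypergeometric_enrichment,
    kaks_by_frequency,
    mann_whitney_u,
    ng86_kaks,
    population_gain_loss,
)
from grapepan.pav import PAVMatrix


def brute_force_exact(xs, ys):
    """Independent oracle: U from pairwise comparisons, p from enumerating
    every assignment of the pooled values to the two group sizes."""
    pooled = list(xs) + list(ys)
    n1, n2 = len(xs), len(ys)

    def ustat(a, b):
        return sum((x > y) + 0.5 * (x == y) for x in a for y in b)

    u_obs = ustat(xs, ys)
    mu = n1 * n2 / 2
    total = extreme = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        sel = set(idx)
        a = [pooled[i] for i in idx]
        b = [pooled[j] for j in range(len(pooled)) if j not in sel]
        total += 1
        if abs(ustat(a, b) - mu) >= abs(u_obs - mu) - 1e-9:
            extreme += 1
    return u_obs, extreme / total


def matrix_from_counts(**rows):
    accs = [f"a{i}" for i in range(len(next(iter(rows.values()))))]
    return PAVMatrix(pd.DataFrame.from_dict(rows, orient="index", columns=accs))


class TestMannWhitney:
    def test_fully_separated_groups(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6], mode="exact")
        assert u == 0.0
        assert p == pytest.approx(0.1)  # 2 of the 20 assignments are as extreme

    def test_identical_multisets_give_p_one(self):
        u, p = mann_whitney_u([1, 2, 2], [2, 1, 2], mode="exact")
        assert p == 1.0

    def test_empty_sample_is_error(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1])

    def test_exact_matches_brute_force_with_and_without_ties(self):
        rng = np.random.default_rng(42)
        for _ in range(60):
            n1 = int(rng.integers(1, 6))
            n2 = int(rng.integers(1, 11 - n1))
            tied = rng.random() < 0.5
            hi = 3 if tied else 1000
            xs = rng.integers(0, hi, n1).tolist()
            ys = rng.integers(0, hi, n2).tolist()
            u, p = mann_whitney_u(xs, ys, mode="exact")
            u_o, p_o = brute_force_exact(xs, ys)
            assert u == pytest.approx(u_o)
            assert p == pytest.approx(p_o)

    def test_symmetry_in_arguments(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            xs = rng.integers(0, 4, 4).tolist()
            ys = rng.integers(0, 4, 5).tolist()
            _, pa = mann_whitney_u(xs, ys, mode="exact")
            _, pb = mann_whitney_u(ys, xs, mode="exact")
            assert pa == pytest.approx(pb)

    def test_normal_mode_delegates_to_tie_corrected_asymptotics(self):
        xs, ys = [1, 2, 2, 3, 5, 5], [2, 4, 4, 5, 6, 7]
        u, p = mann_whitney_u(xs, ys, mode="normal")
        ref = stats.mannwhitneyu(xs, ys, alternative="two-sided",
                                 method="asymptotic", use_continuity=True)
        assert (u, p) == (ref.statistic, ref.pvalue)

    def test_singleton_group_exact_tail(self):
        # 1-vs-16 contrast: the single value ranks at an end, tail = 1/17 per side
        xs = [99]
        ys = list(range(16))
        _, p = mann_whitney_u(xs, ys, mode="auto")  # auto -> exact at C(17,1)=17
        assert p == pytest.approx(2 / 17)


class TestCompareFamily:
    def test_lost_in_a_needs_no_test(self):
        m = matrix_from_counts(F=(0, 0, 0, 0, 0, 1, 2, 1, 1, 2))
        res = compare_family(m, "F", [f"a{i}" for i in range(5)], [f"a{i}" for i in range(5, 10)])
        assert res.status == "lost_in_a" and res.p_value is None

    def test_zero_everywhere_is_ns(self):
        m = matrix_from_counts(F=(0, 0, 0, 0), G=(1, 1, 1, 1))
        res = compare_family(m, "F", ["a0", "a1"], ["a2", "a3"])
        assert res.status == "ns" and res.direction == "none"

    def test_separated_counts_are_significant(self):
        m = matrix_from_counts(F=(5, 6, 5, 7, 6, 5, 6, 5, 6, 1, 1, 2, 1, 1))
        pop_a = [f"a{i}" for i in range(9)]
        pop_b = [f"a{i}" for i in range(9, 14)]
        res = compare_family(m, "F", pop_a, pop_b)
        assert res.status == "significant_more_a"
        _, p_oracle = brute_force_exact([5, 6, 5, 7, 6, 5, 6, 5, 6], [1, 1, 2, 1, 1])
        assert res.p_value == pytest.approx(p_oracle)
        assert res.p_value < 0.05

    def test_equal_counts_are_ns(self):
        m = matrix_from_counts(F=(2, 2, 2, 2, 2, 2))
        res = compare_family(m, "F", ["a0", "a1", "a2"], ["a3", "a4", "a5"])
        assert res.status == "ns" and res.direction == "none"

    def test_overlapping_populations_rejected(self):
        m = matrix_from_counts(F=(1, 1, 1))
        with pytest.raises(ValueError, match="disjoint"):
            compare_family(m, "F", ["a0", "a1"], ["a1", "a2"])


class TestPopulationGainLoss:
    def test_swapping_populations_swaps_gained_and_lost(self):
        rng = np.random.default_rng(3)
        m = PAVMatrix(pd.DataFrame(rng.integers(0, 4, (50, 8)),
                                   index=[f"F{i}" for i in range(50)],
                                   columns=[f"a{i}" for i in range(8)]))
        m.counts.iloc[0] = [1, 1, 1, 1, 0, 0, 0, 0]
        pop_a, pop_b = [f"a{i}" for i in range(4)], [f"a{i}" for i in range(4, 8)]
        _, s_ab = population_gain_loss(m, pop_a, pop_b)
        _, s_ba = population_gain_loss(m, pop_b, pop_a)
        assert s_ab["gained_a"] == s_ba["lost_a"]
        assert s_ab["lost_a"] == s_ba["gained_a"]

    def test_alpha_zero_keeps_only_lost_families(self):
        m = matrix_from_counts(F=(9, 9, 9, 1, 1, 1), G=(1, 1, 1, 0, 0, 0))
        pop_a, pop_b = ["a0", "a1", "a2"], ["a3", "a4", "a5"]
        _, summary = population_gain_loss(m, pop_a, pop_b, alpha=0.0)
        assert summary["gained_a"] == ["G"]  # lost_in_b only; no test can pass
        assert summary["lost_a"] == []

    def test_planted_loss_recovery(self, default_cohort):
        from grapepan.pav import build_pav_matrix

        truth = default_cohort.truth
        m = build_pav_matrix(default_cohort.families, [a.id for a in default_cohort.accessions])
        cultivars = [a.id for a in default_cohort.accessions if a.population == "cultivar"]
        wilds = [a.id for a in default_cohort.accessions if a.population == "wild"]
        _, summary = population_gain_loss(m, cultivars, wilds)
        planted_lost = {f for f, b in truth.biased_families.items() if b == "lost_in_cultivar"}
        assert planted_lost <= set(summary["lost_a"])


class TestEnrichment:
    def test_closed_form_extreme_case(self):
        universe = {f"g{i}" for i in range(20)}
        study = {f"g{i}" for i in range(5)}
        term_map = {g: ["T"] for g in study}
        df = hypergeometric_enrichment(study, universe, term_map)
        assert df.loc[0, "p_value"] == pytest.approx(1 / math.comb(20, 5))

    def test_matches_fisher_exact_on_random_tables(self):
        rng = np.random.default_rng(11)
        universe = {f"g{i}" for i in range(60)}
        for _ in range(100):
            ulist = sorted(universe)
            K = int(rng.integers(1, 30))
            n = int(rng.integers(1, 30))
            term_genes = set(rng.choice(ulist, K, replace=False))
            study = set(rng.choice(ulist, n, replace=False))
            term_map = {g: ["T"] for g in term_genes}
            df = hypergeometric_enrichment(study, universe, term_map)
            k = len(term_genes & study)
            table = [[k, K - k], [n - k, 60 - K - (n - k)]]
            _, p_fisher = stats.fisher_exact(table, alternative="greater")
            assert df.loc[0, "p_value"] == pytest.approx(p_fisher)

    def test_study_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            hypergeometric_enrichment({"x"}, {"y"}, {})

    def test_type_one_error_under_random_assignment(self):
        rng = np.random.default_rng(13)
        universe = {f"g{i}" for i in range(200)}
        ulist = sorted(universe)
        study = set(rng.choice(ulist, 50, replace=False))
        n_sig = n_terms = 0
        for _ in range(40):
            term_map = {}
            for t in range(25):
                for g in rng.choice(ulist, 20, replace=False):
                    term_map.setdefault(g, []).append(f"T{t}")
            df = hypergeometric_enrichment(study, universe, term_map)
            n_terms += len(df)
            n_sig += int((df["p_value"] < 0.05).sum())
        assert n_sig / n_terms == pytest.approx(0.05, abs=0.02)


class TestNG86:
    def test_identical_sequences(self):
        r = ng86_kaks("ATGAAA", "ATGAAA")
        assert (r.ka, r.ks, r.ratio) == (0.0, 0.0, None)

    def test_hand_example_lys_to_arg(self):
        # AAA->AGA: one nonsynonymous difference; synonymous sites averaged
        # over both codons: S = (1/3 + 2/3)/2 = 0.5, N = 2.5, pN = 0.4
        r = ng86_kaks("AAA", "AGA")
        assert r.diffs_nonsyn == 1 and r.diffs_syn == 0
        assert r.sites_syn == pytest.approx(0.5)
        assert r.ka == pytest.approx(-0.75 * math.log(1 - 4 * 0.4 / 3))
        assert r.ka == pytest.approx(0.57161, abs=1e-5)
        assert r.ks == 0.0 and r.ratio is None

    def test_site_conservation_on_random_pairs(self):
        rng = np.random.default_rng(17)
        bases = "TCAG"
        for _ in range(25):
            codons = []
            while len(codons) < 50:
                c = "".join(bases[i] for i in rng.integers(0, 4, 3))
                if CODON_TABLE[c] != "*":
                    codons.append(c)
            seq = "".join(codons)
            r = ng86_kaks(seq, seq)
            assert r.sites_syn + r.sites_nonsyn == pytest.approx(len(seq))

    def test_symmetry(self):
        a, b = "ATGAAATTTGGG", "ATGAGATTCGGA"
        ra, rb = ng86_kaks(a, b), ng86_kaks(b, a)
        assert ra.ka == pytest.approx(rb.ka)
        assert ra.ks == pytest.approx(rb.ks)

    def test_matches_biopython_reference_on_mutated_pairs(self):
        Bio = pytest.importorskip("Bio.codonalign.codonseq")
        rng = np.random.default_rng(19)
        bases = "TCAG"

        def rand_cds(n):
            out = []
            while len(out) < n:
                c = "".join(bases[i] for i in rng.integers(0, 4, 3))
                if CODON_TABLE[c] != "*":
                    out.append(c)
            return "".join(out)

        def mutate(s, k):
            s = list(s)
            done = 0
            while done < k:
                i = int(rng.integers(0, len(s)))
                b = bases[int(rng.integers(0, 4))]
                new = s.copy()
                new[i] = b
                cod = "".join(new[(i // 3) * 3 : (i // 3) * 3 + 3])
                if CODON_TABLE[cod] != "*":
                    s = new
                    done += 1
            return "".join(s)

        for _ in range(15):
            a = rand_cds(40)
            b = mutate(a, int(rng.integers(1, 12)))
            mine = ng86_kaks(a, b)
            dn, ds = Bio.cal_dn_ds(Bio.CodonSeq(a), Bio.CodonSeq(b), method="NG86")
            if not math.isnan(dn):
                assert mine.ka == pytest.approx(dn, abs=1e-9)
            if not math.isnan(ds):
                assert mine.ks == pytest.approx(ds, abs=1e-9)

    def test_length_mismatch_and_stop_codon_errors(self):
        with pytest.raises(ValueError, match="mismatch"):
            ng86_kaks("AAA", "AAAGGG")
        with pytest.raises(ValueError, match="stop"):
            ng86_kaks("TAA", "AAA")


class TestKaksByFrequency:
    def test_identical_pairs_give_empty_summary(self):
        pairs = [(ng86_kaks("AAA", "AAA"), "core"), (ng86_kaks("GGG", "GGG"), "cloud")]
        summary = kaks_by_frequency(pairs)
        assert summary["classes"] == {} and "cloud_vs_core" not in summary

    def test_cloud_shift_detected(self, default_cohort):
        labeled = [
            (ng86_kaks(sa, sb), label)
            for _, label, sa, sb in default_cohort.codon_pairs
        ]
        summary = kaks_by_frequency(labeled)
        assert summary["cloud_vs_core"]["cloud_higher"]
        assert summary["cloud_vs_core"]["significant"]

    def test_single_class_gives_distribution_only(self):
        pairs = [(ng86_kaks("AAA", "AGA"), "shell")]
        summary = kaks_by_frequency(pairs)
        assert "cloud_vs_core" not in summary and summary["classes"] == {}
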