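"""Per-family gain/loss tests between populations, set enrichment, and NG86 Ka/Ks.

The member-count comparison uses the Mann-Whitney U test.  Because family
member counts are small integers with heavy ties, the exact mode enumerates
all C(n1+n2, n1) assignments of the observed values to the two groups
(a permutation-exact test, valid under ties); the normal mode uses the
tie-corrected normal approximation with continuity correction.

Loss is resolved before testing: a family with zero members throughout one
population and at least one member in the other is "lost" in the empty
population — no rank test is needed or meaningful there.
"""

from __future__ import annotations

import itertools
import logging
import math
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .models import ComparisonResult, KaKsResult
from .pav import PAVMatrix, family_proportion

log = logging.getLogger(__name__)

# exact enumeration cap for auto mode: C(16, 8); covers every cohort-size
# comparison in the study design including the 1-vs-16 outgroup contrast
_AUTO_EXACT_MAX = 12870


@lru_cache(maxsize=64)
def _combinations(n: int, k: int) -> np.ndarray:
    return np.array(list(itertools.combinations(range(n), k)), dtype=np.intp)


def _u_from_ranks(rank_sum: np.ndarray | float, n1: int) -> np.ndarray | float:
    return rank_sum - n1 * (n1 + 1) / 2


def mann_whitney_u(
    xs: Sequence[float],
    ys: Sequence[float],
    mode: str = "auto",
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Mann-Whitney U for ``xs`` (with midranks) and its p-value.

    ``mode='exact'`` enumerates every assignment of the pooled observations to
    the two group sizes and reports the tail probability of deviations at
    least as extreme as observed (two-sided: |U - n1*n2/2|).  ``'normal'``
    delegates to scipy's tie-corrected normal approximation with continuity
    correction.  ``'auto'`` picks exact while the enumeration stays small
    (C(n1+n2, n1) <= 12870, i.e. all study-design group sizes) and normal
    otherwise.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.size == 0 or ys.size == 0:
        raise ValueError("both samples must be non-empty")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"bad alternative {alternative!r}")
    n1, n2 = xs.size, ys.size

    if mode == "auto":
        mode = "exact" if math.comb(n1 + n2, n1) <= _AUTO_EXACT_MAX else "normal"
    if mode == "normal":
        res = stats.mannwhitneyu(xs, ys, alternative=alternative,
                                 method="asymptotic", use_continuity=True)
        return float(res.statistic), float(res.pvalue)
    if mode != "exact":
        raise ValueError(f"unknown mode {mode!r}")

    pooled = np.concatenate([xs, ys])
    ranks = stats.rankdata(pooled)
    u_obs = float(_u_from_ranks(ranks[:n1].sum(), n1))
    combs = _combinations(n1 + n2, n1)
    u_all = _u_from_ranks(ranks[combs].sum(axis=1), n1)
    mu = n1 * n2 / 2
    eps = 1e-9
    if alternative == "two-sided":
        p = float(np.mean(np.abs(u_all - mu) >= abs(u_obs - mu) - eps))
    elif alternative == "greater":
        p = float(np.mean(u_all >= u_obs - eps))
    else:
        p = float(np.mean(u_all <= u_obs + eps))
    return u_obs, p


def compare_family(
    matrix: PAVMatrix,
    family_id: str,
    pop_a: Sequence[str],
    pop_b: Sequence[str],
    alpha: float = 0.05,
    mode: str = "auto",
    alternative: str = "two-sided",
) -> ComparisonResult:
    """Compare one family's member counts between two disjoint accession sets.

    Lost statuses are assigned before any test; otherwise the direction is the
    side with the larger mean midrank and significance requires p < alpha.
    """
    if set(pop_a) & set(pop_b):
        raise ValueError("pop_a and pop_b must be disjoint")
    if family_id not in matrix.counts.index:
        raise KeyError(f"unknown family {family_id!r}")
    xs = tuple(int(v) for v in matrix.counts.loc[family_id, list(pop_a)])
    ys = tuple(int(v) for v in matrix.counts.loc[family_id, list(pop_b)])

    a_zero, b_zero = all(v == 0 for v in xs), all(v == 0 for v in ys)
    if a_zero and b_zero:
        return ComparisonResult(family_id, xs, ys, None, None, "none", "ns")
    if a_zero:
        return ComparisonResult(family_id, xs, ys, None, None, "more_in_b", "lost_in_a")
    if b_zero:
        return ComparisonResult(family_id, xs, ys, None, None, "more_in_a", "lost_in_b")

    u, p = mann_whitney_u(xs, ys, mode=mode, alternative=alternative)
    ranks = stats.rankdata(np.concatenate([xs, ys]))
    mean_a, mean_b = ranks[: len(xs)].mean(), ranks[len(xs):].mean()
    if math.isclose(mean_a, mean_b):
        return ComparisonResult(family_id, xs, ys, u, p, "none", "ns")
    direction = "more_in_a" if mean_a > mean_b else "more_in_b"
    if p < alpha:
        status = "significant_more_a" if direction == "more_in_a" else "significant_more_b"
    else:
        status = "ns"
    return ComparisonResult(family_id, xs, ys, u, p, direction, status)


def _benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    n = len(pvals)
    order = np.argsort(pvals, kind="stable")
    adj = np.empty(n)
    adj[order] = np.minimum.accumulate((pvals[order] * n / np.arange(1, n + 1))[::-1])[::-1]
    return np.minimum(adj, 1.0)


def population_gain_loss(
    matrix: PAVMatrix,
    pop_a: Sequence[str],
    pop_b: Sequence[str],
    alpha: float = 0.05,
    total_families: Optional[int] = None,
    mode: str = "auto",
) -> tuple[pd.DataFrame, dict]:
    """Test every family and summarise gains and losses for each population.

    Gained for population A = significantly more members in A, plus families
    lost (all members missing) in B; lost for A is the mirror image.  The
    summary proportions are computed against ``total_families`` (defaults to
    the number of families tested), mirroring percentages quoted against a
    master family count.  A Benjamini-Hochberg column is always attached for
    reuse, but the gained/lost calls use the raw p < alpha rule.
    """
    results = [
        compare_family(matrix, fam, pop_a, pop_b, alpha=alpha, mode=mode)
        for fam in matrix.family_ids
    ]
    pvals = np.array([r.p_value if r.p_value is not None else np.nan for r in results])
    tested = ~np.isnan(pvals)
    if tested.any():
        adj = np.full(len(results), np.nan)
        adj[tested] = _benjamini_hochberg(pvals[tested])
        for r, q in zip(results, adj):
            r.p_bh = None if np.isnan(q) else float(q)

    df = pd.DataFrame(
        {
            "family_id": [r.family_id for r in results],
            "U": [r.U for r in results],
            "p_value": [r.p_value for r in results],
            "p_bh": [r.p_bh for r in results],
            "direction": [r.direction for r in results],
            "status": [r.status for r in results],
        }
    )
    total = total_families if total_families is not None else len(results)
    gained_a = sorted(r.family_id for r in results if r.status in ("significant_more_a", "lost_in_b"))
    lost_a = sorted(r.family_id for r in results if r.status in ("significant_more_b", "lost_in_a"))
    summary = {
        "n_families_tested": len(results),
        "total_families": total,
        "gained_a": gained_a,
        "lost_a": lost_a,
        "n_gained_a": len(gained_a),
        "n_lost_a": len(lost_a),
        "pct_gained_a": family_proportion(len(gained_a), total),
        "pct_lost_a": family_proportion(len(lost_a), total),
    }
    return df, summary


# ---------------------------------------------------------------------------
# Hypergeometric over-representation (GO-style enrichment)
# ---------------------------------------------------------------------------

def hypergeometric_enrichment(
    study_genes: set[str],
    universe_genes: set[str],
    term_map: dict[str, list[str]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-sided over-representation test per term.

    With N universe genes, K of them carrying the term, and a study set of n
    genes of which k carry it, p is the upper hypergeometric tail P(X >= k).
    Terms with raw p < alpha are flagged enriched; a BH-adjusted column is
    reported alongside but does not drive the flag.
    """
    if not study_genes <= universe_genes:
        extra = sorted(study_genes - universe_genes)[:5]
        raise ValueError(f"study set is not a subset of the universe (e.g. {extra})")
    N, n = len(universe_genes), len(study_genes)
    term_to_universe: dict[str, set[str]] = {}
    for gene, terms in term_map.items():
        if gene in universe_genes:
            for t in terms:
                term_to_universe.setdefault(t, set()).add(gene)
    rows = []
    for term in sorted(term_to_universe):
        genes_k = term_to_universe[term]
        K = len(genes_k)
        k = len(genes_k & study_genes)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((term, k, K, n, N, p))
    df = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "p_value"])
    if len(df):
        df["p_bh"] = _benjamini_hochberg(df["p_value"].values)
        df["enriched"] = df["p_value"] < alpha
    return df


# ---------------------------------------------------------------------------
# NG86 Ka/Ks
# ---------------------------------------------------------------------------

_BASES = "TCAG"
_AA = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
CODON_TABLE = {
    a + b + c: _AA[i]
    for i, (a, b, c) in enumerate(itertools.product(_BASES, repeat=3))
}


def _codon_syn_sites(codon: str) -> float:
    """Fraction-of-synonymous-changes site count for one codon.

    Each position contributes (synonymous single-base changes)/3; changes that
    create a stop codon count as nonsynonymous.
    """
    aa = CODON_TABLE[codon]
    s = 0.0
    for pos in range(3):
        for alt in _BASES:
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1 :]
            if CODON_TABLE[mutant] == aa:
                s += 1 / 3
    return s


@lru_cache(maxsize=4096)
def _codon_pair_diffs(ca: str, cb: str) -> tuple[float, float]:
    """Synonymous and nonsynonymous difference counts between two codons,
    averaged over all shortest mutational pathways with equal weights;
    pathways passing through stop codons are excluded (unless all do)."""
    diff_pos = [i for i in range(3) if ca[i] != cb[i]]
    if not diff_pos:
        return 0.0, 0.0
    pathways = []
    for order in itertools.permutations(diff_pos):
        sd = nd = 0.0
        cur = ca
        blocked = False
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
            if CODON_TABLE[nxt] == "*" and nxt != cb:
                blocked = True
                break
            if CODON_TABLE[nxt] == CODON_TABLE[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if not blocked:
            pathways.append((sd, nd))
    if not pathways:  # every pathway runs through a stop; fall back to all
        for order in itertools.permutations(diff_pos):
            sd = nd = 0.0
            cur = ca
            for pos in order:
                nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
                sd += CODON_TABLE[nxt] == CODON_TABLE[cur]
                nd += CODON_TABLE[nxt] != CODON_TABLE[cur]
                cur = nxt
            pathways.append((sd, nd))
    sd = sum(p[0] for p in pathways) / len(pathways)
    nd = sum(p[1] for p in pathways) / len(pathways)
    return sd, nd


def _jukes_cantor(p: float) -> Optional[float]:
    if p >= 0.75:
        return None
    return -0.75 * math.log(1 - 4 * p / 3)


def ng86_kaks(cds_a: str, cds_b: str, pair: tuple[str, str] = ("a", "b")) -> KaKsResult:
    """Nei-Gojobori (1986) Ka and Ks for an aligned codon-sequence pair.

    Site counts are averaged over the two sequences; per-codon differences are
    averaged over shortest mutational pathways; proportions are corrected with
    the Jukes-Cantor formula d = -(3/4) ln(1 - 4p/3).  An undefined ratio
    (Ks = 0 or an undefined correction) is reported as ``None``.
    """
    for seq in (cds_a, cds_b):
        if len(seq) % 3:
            raise ValueError("sequence length must be a multiple of 3")
    if len(cds_a) != len(cds_b):
        raise ValueError(f"length mismatch: {len(cds_a)} vs {len(cds_b)}")
    cds_a, cds_b = cds_a.upper(), cds_b.upper()
    codons_a = [cds_a[i : i + 3] for i in range(0, len(cds_a), 3)]
    codons_b = [cds_b[i : i + 3] for i in range(0, len(cds_b), 3)]
    for c in itertools.chain(codons_a, codons_b):
        if c not in CODON_TABLE:
            raise ValueError(f"invalid codon {c!r}")
        if CODON_TABLE[c] == "*":
            raise ValueError(f"internal stop codon {c!r}")

    s_a = sum(_codon_syn_sites(c) for c in codons_a)
    s_b = sum(_codon_syn_sites(c) for c in codons_b)
    S = (s_a + s_b) / 2
    N = len(cds_a) - S
    sd = nd = 0.0
    for ca, cb in zip(codons_a, codons_b):
        d_s, d_n = _codon_pair_diffs(ca, cb)
        sd += d_s
        nd += d_n

    ps = sd / S if S > 0 else 0.0
    pn = nd / N if N > 0 else 0.0
    ks = _jukes_cantor(ps)
    ka = _jukes_cantor(pn)
    ratio = None
    if ka is not None and ks is not None and ks > 0:
        ratio = ka / ks
    return KaKsResult(pair, ka, ks, ratio, S, N, sd, nd)


def kaks_by_frequency(
    labeled_results: Sequence[tuple[KaKsResult, str]],
    alpha: float = 0.05,
) -> dict:
    """Summarise Ka/Ks distributions per family-frequency class and compare
    cloud against core with the Mann-Whitney test (higher cloud Ka/Ks is the
    signature of relaxed constraint on rare families)."""
    by_class: dict[str, list[float]] = {}
    for res, label in labeled_results:
        if res.ratio is not None:
            by_class.setdefault(label, []).append(res.ratio)
    summary: dict = {"classes": {}}
    for label in sorted(by_class):
        vals = np.array(by_class[label])
        summary["classes"][label] = {
            "n": int(vals.size),
            "q1": float(np.percentile(vals, 25)),
            "median": float(np.median(vals)),
            "q3": float(np.percentile(vals, 75)),
            "mean": float(vals.mean()),
        }
    missing = [lab for lab, vals in by_class.items() if not vals]
    if missing:
        log.warning("classes with no defined Ka/Ks ratios omitted: %s", missing)
    if "cloud" in by_class and "core" in by_class and by_class["cloud"] and by_class["core"]:
        u, p = mann_whitney_u(by_class["cloud"], by_class["core"], mode="auto")
        summary["cloud_vs_core"] = {
            "U": u,
            "p_value": p,
            "cloud_higher": bool(np.median(by_class["cloud"]) > np.median(by_class["core"])),
            "significant": p < alpha,
        }
    return summary
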