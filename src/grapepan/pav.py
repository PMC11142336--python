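"""The families x accessions count matrix and all pan-genome summaries.

Presence means count >= 1; member multiplicity only matters for gene totals
and for the gain/loss tests.  Frequency classes follow the usual pan-genome
nomenclature: core families occur in (nearly) all accessions, cloud families
in exactly one, shell families in between.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from itertools import permutations as iter_permutations
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .models import Accession, FamilyTable


@dataclass
class PAVMatrix:
    """Families x accessions member-count matrix (wrapper over a DataFrame)."""

    counts: pd.DataFrame  # index: family_ids, columns: accession_ids, int

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("PAV counts must be non-negative")

    @property
    def family_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def accession_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_accessions(self) -> int:
        return self.counts.shape[1]

    @property
    def presence(self) -> pd.DataFrame:
        return self.counts >= 1

    def restrict(self, accession_ids: Sequence[str]) -> "PAVMatrix":
        """View over a subset of accessions; families absent everywhere in the
        subset are dropped (their all-zero rows removed)."""
        missing = [a for a in accession_ids if a not in self.counts.columns]
        if missing:
            raise KeyError(f"unknown accessions {missing}")
        sub = self.counts[list(accession_ids)]
        return PAVMatrix(sub[sub.sum(axis=1) > 0].copy())

    def to_tsv(self, path: str | Path) -> None:
        out = self.counts.copy()
        out.index.name = "family_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PAVMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.astype(int))


@dataclass(frozen=True)
class FrequencyClass:
    family_id: str
    n_present: int
    label: str  # core | shell | cloud


def build_pav_matrix(families: FamilyTable, accessions: Sequence[str | Accession]) -> PAVMatrix:
    """Count members of each family in each requested accession.

    The accession set must be a subset of the table's columns; restricting to
    a subset drops families with no member in any requested accession.
    """
    acc_ids = [a.id if isinstance(a, Accession) else a for a in accessions]
    known = set(families.accession_ids)
    unknown = [a for a in acc_ids if a not in known]
    if unknown:
        raise KeyError(f"accessions {unknown} not present in the family table")
    data = {
        a: [families.count(f, a) for f in families.family_ids] for a in acc_ids
    }
    df = pd.DataFrame(data, index=families.family_ids, dtype=int)
    df = df[df.sum(axis=1) > 0]
    return PAVMatrix(df)


def classify_frequency(
    matrix: PAVMatrix,
    core_min_present: int = 16,
    cloud_max_present: int = 1,
) -> tuple[list[FrequencyClass], dict[str, int]]:
    """Label each family core/shell/cloud from its presence count.

    Defaults reproduce the 17-accession design: core = present in more than
    15 accessions (>=16), cloud = exactly one, shell = everything between.
    """
    if core_min_present > matrix.n_accessions:
        raise ValueError(
            f"core_min_present={core_min_present} exceeds accession count {matrix.n_accessions}"
        )
    n_present = matrix.presence.sum(axis=1)
    out = []
    counts = {"core": 0, "shell": 0, "cloud": 0}
    for fam, k in n_present.items():
        # cloud (presence in a single accession) takes precedence in the
        # degenerate overlap, e.g. a single-accession matrix
        if k <= cloud_max_present:
            label = "cloud"
        elif k >= core_min_present:
            label = "core"
        else:
            label = "shell"
        counts[label] += 1
        out.append(FrequencyClass(fam, int(k), label))
    return out, counts


def saturation_curves(
    matrix: PAVMatrix,
    n_permutations: int = 1000,
    seed: Optional[int] = None,
    exhaustive: bool = False,
    return_per_permutation: bool = False,
):
    """Pan- and core-genome sizes as genomes are added in random order.

    For each sampled accession ordering, pan(k) counts families present in at
    least one of the first k accessions and core(k) families present in all of
    them.  Returns a DataFrame with per-k means and standard deviations; with
    ``return_per_permutation`` the raw (n_orderings x N) pan and core arrays
    are returned as well.  ``exhaustive`` enumerates every ordering instead of
    sampling (feasible for small N).
    """
    pres = matrix.presence.values  # families x accessions
    n_fam, n_acc = pres.shape
    if exhaustive:
        orderings = np.array(list(iter_permutations(range(n_acc))), dtype=np.intp)
    else:
        if n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        rng = np.random.default_rng(seed)
        orderings = np.array([rng.permutation(n_acc) for _ in range(n_permutations)], dtype=np.intp)

    pan = np.empty((len(orderings), n_acc), dtype=np.int64)
    core = np.empty_like(pan)
    ks = np.arange(1, n_acc + 1)
    for r, order in enumerate(orderings):
        cum = np.cumsum(pres[:, order], axis=1)
        pan[r] = (cum > 0).sum(axis=0)
        core[r] = (cum == ks).sum(axis=0)

    df = pd.DataFrame(
        {
            "k": np.arange(1, n_acc + 1),
            "pan_mean": pan.mean(axis=0),
            "pan_sd": pan.std(axis=0, ddof=1) if len(orderings) > 1 else np.zeros(n_acc),
            "core_mean": core.mean(axis=0),
            "core_sd": core.std(axis=0, ddof=1) if len(orderings) > 1 else np.zeros(n_acc),
        }
    )
    if return_per_permutation:
        return df, pan, core
    return df


def shared_and_private(matrix: PAVMatrix):
    """Families present in every accession, and families private to one.

    Returns ``(shared_families, private_families_per_accession, gene_totals)``
    where gene_totals holds the summed member counts inside the shared set and
    inside each private set.
    """
    pres = matrix.presence
    shared = set(matrix.counts.index[pres.all(axis=1)])
    private: dict[str, set[str]] = {a: set() for a in matrix.accession_ids}
    n_present = pres.sum(axis=1)
    for fam in matrix.counts.index[n_present == 1]:
        acc = pres.columns[pres.loc[fam].values.argmax()]
        private[acc].add(fam)
    gene_totals = {
        "shared": int(matrix.counts.loc[sorted(shared)].values.sum()) if shared else 0,
        "private": {
            a: int(matrix.counts.loc[sorted(fams), a].sum()) if fams else 0
            for a, fams in private.items()
        },
    }
    return shared, private, gene_totals


def family_proportion(count: int, total: int, decimals: int = 2) -> float:
    """Percentage 100*count/total, rounded half-up to ``decimals`` places.

    Half-up rounding reproduces the conventional printed percentages from
    printed counts (banker's rounding would not).
    """
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= count <= total:
        raise ValueError(f"count {count} outside [0, {total}]")
    q = Decimal(1).scaleb(-decimals)
    return float((Decimal(count) * 100 / Decimal(total)).quantize(q, rounding=ROUND_HALF_UP))


def haplotype_difference(
    matrix: PAVMatrix,
    hap_a: Accession,
    hap_b: Accession,
) -> tuple[int, float]:
    """Families present in exactly one haplotype of a diploid assembly.

    Returns (number of differing families, percentage of families present in
    at least one of the two haplotypes).  Both columns must belong to the same
    diploid parent.
    """
    if hap_a.parent_id != hap_b.parent_id:
        raise ValueError(
            f"haplotypes {hap_a.id} and {hap_b.id} belong to different parents "
            f"({hap_a.parent_id} vs {hap_b.parent_id})"
        )
    sub = matrix.counts[[hap_a.id, hap_b.id]]
    pres = sub >= 1
    in_any = pres.any(axis=1)
    different = int((pres.sum(axis=1) == 1).sum())
    denom = int(in_any.sum())
    if denom == 0:
        return 0, 0.0
    return different, family_proportion(different, denom)
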