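"""Markov clustering (MCL) of a gene-similarity graph into families.

Dense-matrix implementation intended for desk-scale graphs (<= ~10^4 nodes):
self-loops are added, the column-stochastic transition matrix is iterated
through expansion (squaring) and inflation (element-wise power followed by
re-normalisation) until it stops changing, and clusters are read from the
attractor rows of the limit matrix.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .models import FamilyTable

log = logging.getLogger(__name__)

PRUNE_THRESHOLD = 1e-8


@dataclass
class SimilarityGraph:
    """Undirected weighted gene-similarity graph."""

    nodes: list[str]
    edges: list[tuple[str, str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for a, b, w in self.edges:
            if not np.isfinite(w) or w < 0:
                raise ValueError(f"edge ({a},{b}) has invalid weight {w}")


def read_abc(path) -> SimilarityGraph:
    """Read the de-facto MCL edge-list dialect: gene1 TAB gene2 TAB weight."""
    nodes: list[str] = []
    seen = set()
    edges = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            a, b, w = line.split("\t")
            for n in (a, b):
                if n not in seen:
                    seen.add(n)
                    nodes.append(n)
            edges.append((a, b, float(w)))
    return SimilarityGraph(nodes, edges)


def _normalize_columns(m: np.ndarray) -> np.ndarray:
    colsum = m.sum(axis=0)
    colsum[colsum == 0] = 1.0
    return m / colsum


def mcl_cluster(
    graph: SimilarityGraph,
    inflation: float = 1.5,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> list[set[str]]:
    """Partition graph nodes into clusters with standard MCL.

    Self-loop weight per node is its maximum incident edge weight (at least 1).
    Every node lands in exactly one cluster; a node attracted by several
    attractors goes to the one holding more of its mass, ties broken by
    lexicographically smallest attractor gene ID.  Clusters are returned
    sorted by their smallest member.
    """
    if inflation <= 1:
        raise ValueError(f"inflation must be > 1, got {inflation}")
    if not graph.nodes:
        raise ValueError("graph is empty")

    nodes = list(graph.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    m = np.zeros((n, n))
    for a, b, w in graph.edges:
        i, j = idx[a], idx[b]
        m[i, j] = max(m[i, j], w)
        m[j, i] = max(m[j, i], w)
    loop = np.maximum(m.max(axis=0), 1.0)
    np.fill_diagonal(m, loop)

    m = _normalize_columns(m)
    converged = False
    for _ in range(max_iter):
        expanded = m @ m
        inflated = _normalize_columns(np.power(expanded, inflation))
        inflated[inflated < PRUNE_THRESHOLD] = 0.0
        inflated = _normalize_columns(inflated)
        if np.max(np.abs(inflated - m)) < tol:
            m = inflated
            converged = True
            break
        m = inflated
    if not converged:
        warnings.warn(
            f"MCL did not converge within {max_iter} iterations; "
            "reading clusters from the final matrix",
            RuntimeWarning,
            stacklevel=2,
        )

    # Attractors carry mass on their own diagonal in the limit matrix.
    attractors = [i for i in range(n) if m[i, i] > PRUNE_THRESHOLD]
    if not attractors:  # pathological non-convergence; fall back to all rows
        attractors = list(range(n))

    # Merge attractors that lie in each other's support into attractor systems.
    parent = list(range(len(attractors)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    apos = {a: k for k, a in enumerate(attractors)}
    for k, a in enumerate(attractors):
        for b in attractors:
            if m[a, b] > PRUNE_THRESHOLD or m[b, a] > PRUNE_THRESHOLD:
                ra, rb = find(k), find(apos[b])
                if ra != rb:
                    parent[rb] = ra

    systems: dict[int, list[int]] = {}
    for k, a in enumerate(attractors):
        systems.setdefault(find(k), []).append(a)

    # Assign every node to the attractor system holding most of its column mass.
    assignment: dict[int, int] = {}
    for j in range(n):
        best_root, best_mass, best_name = None, -1.0, None
        for root, members in systems.items():
            mass = float(m[members, j].sum())
            name = min(nodes[a] for a in members)
            if mass > best_mass + 1e-15 or (
                abs(mass - best_mass) <= 1e-15 and best_name is not None and name < best_name
            ):
                best_root, best_mass, best_name = root, mass, name
        if best_mass <= 0:
            # isolated node that lost all mass: its own singleton
            assignment[j] = -(j + 1)
        else:
            assignment[j] = best_root

    clusters: dict[int, set[str]] = {}
    for j, root in assignment.items():
        clusters.setdefault(root, set()).add(nodes[j])
    return sorted(clusters.values(), key=lambda c: min(c))


def clusters_to_family_table(
    clusters: Iterable[set[str]],
    gene_to_accession: dict[str, str],
    prefix: str = "OG",
) -> FamilyTable:
    """Turn clusters into a FamilyTable; IDs are assigned in the deterministic
    order of each cluster's smallest member gene ID (OG000001, OG000002, ...)."""
    ordered = sorted((sorted(c) for c in clusters), key=lambda c: c[0])
    members: dict[str, dict[str, list[str]]] = {}
    for i, genes in enumerate(ordered, 1):
        fam = f"{prefix}{i:06d}"
        per_acc: dict[str, list[str]] = {}
        for g in genes:
            if g not in gene_to_accession:
                raise KeyError(f"gene {g!r} has no accession assignment")
            per_acc.setdefault(gene_to_accession[g], []).append(g)
        members[fam] = per_acc
    return FamilyTable(members)
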