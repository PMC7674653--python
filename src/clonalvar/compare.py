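"""Gene-by-strain mutation matrix, recurrence counts, and bi-clustering.

The presence matrix marks whether a strain carries at least one passing
variant in a locus (coding, pseudogene, or rRNA/tRNA loci; intergenic
variants are excluded).  Rows and columns are clustered by complete linkage
over the asymmetric binary distance (the complement of the Jaccard index),
with a deterministic lexicographic tie-break.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import AnnotatedVariant


@dataclass
class BinaryMutationMatrix:
    """0/1 presence of >=1 passing variant per (gene, strain)."""

    gene_labels: list
    strain_labels: list
    cells: np.ndarray  # shape (n_genes, n_strains)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.cells, index=self.gene_labels, columns=self.strain_labels)


@dataclass
class LinkageResult:
    """Agglomerative merge history plus a deterministic leaf ordering."""

    merges: list = field(default_factory=list)  # (members_a, members_b, height)
    leaf_order: list = field(default_factory=list)

    @property
    def heights(self) -> list:
        return [h for _, _, h in self.merges]


def build_binary_matrix(variants_by_strain: dict) -> BinaryMutationMatrix:
    """Build the gene x strain matrix from per-strain variant lists.

    Values may be :class:`AnnotatedVariant` lists or plain iterables of locus
    tags; variants without a locus (intergenic) are skipped.  All-zero rows
    and columns cannot arise by construction (a gene row exists only because
    some strain hit it) but are dropped defensively before clustering.
    """
    loci_by_strain: dict[str, set] = {}
    for strain, variants in variants_by_strain.items():
        loci = set()
        for v in variants:
            tag = v.locus_tag if isinstance(v, AnnotatedVariant) else str(v)
            if tag:
                loci.add(tag)
        loci_by_strain[strain] = loci
    strains = list(variants_by_strain.keys())
    genes = sorted(set().union(*loci_by_strain.values()) if loci_by_strain else set())
    cells = np.zeros((len(genes), len(strains)), dtype=int)
    for j, s in enumerate(strains):
        for i, g in enumerate(genes):
            if g in loci_by_strain[s]:
                cells[i, j] = 1
    keep_rows = cells.sum(axis=1) > 0
    keep_cols = cells.sum(axis=0) > 0
    return BinaryMutationMatrix(
        gene_labels=[g for g, k in zip(genes, keep_rows) if k],
        strain_labels=[s for s, k in zip(strains, keep_cols) if k],
        cells=cells[np.ix_(keep_rows, keep_cols)],
    )


def recurrence_counts(matrix: BinaryMutationMatrix) -> pd.Series:
    """Per-gene number of strains carrying a mutation in that gene."""
    return pd.Series(matrix.cells.sum(axis=1), index=matrix.gene_labels, name="n_strains")


def genes_at_least(matrix: BinaryMutationMatrix, k: int) -> int:
    """Number of genes mutated in at least ``k`` strains."""
    return int((matrix.cells.sum(axis=1) >= k).sum())


def binary_distance(x, y, variant: str = "asymmetric") -> float:
    """Binary distance between two 0/1 vectors.

    ``asymmetric`` (default): (b + c) / (a + b + c) over the pair counts
    a = both 1, b = x-only, c = y-only — one minus the Jaccard index, joint
    absences carrying no signal.  ``matching`` is the simple-matching
    alternative (b + c) / n.  If a + b + c = 0 the asymmetric distance is
    defined as 0 with a warning.
    """
    x = np.asarray(x, dtype=bool)
    y = np.asarray(y, dtype=bool)
    if x.shape != y.shape:
        raise ValueError("vectors have different lengths")
    a = int(np.sum(x & y))
    b = int(np.sum(x & ~y))
    c = int(np.sum(~x & y))
    if variant == "matching":
        return (b + c) / len(x)
    if variant != "asymmetric":
        raise ValueError(f"unknown binary distance variant {variant!r}")
    if a + b + c == 0:
        warnings.warn("binary distance between two all-zero vectors; defined as 0")
        return 0.0
    return (b + c) / (a + b + c)


def distance_matrix(matrix: BinaryMutationMatrix, axis: str = "genes", variant: str = "asymmetric"):
    """Pairwise binary distance over rows (genes) or columns (strains)."""
    if axis == "genes":
        vectors, labels = matrix.cells, matrix.gene_labels
    elif axis == "strains":
        vectors, labels = matrix.cells.T, matrix.strain_labels
    else:
        raise ValueError("axis must be 'genes' or 'strains'")
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = binary_distance(vectors[i], vectors[j], variant=variant)
    return D, labels


def complete_linkage(D: np.ndarray, labels: list) -> LinkageResult:
    """Agglomerative complete-linkage clustering with a deterministic
    tie-break.

    At each step the pair of clusters with the smallest inter-cluster maximum
    distance merges; ties are broken by the lexicographically smallest pair
    of cluster representative labels (the minimum member label of each).
    Merge heights are non-decreasing.
    """
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    n = D.shape[0]
    if len(labels) != n:
        raise ValueError("label count does not match matrix size")
    clusters: dict[int, list] = {i: [labels[i]] for i in range(n)}
    dist: dict[frozenset, float] = {
        frozenset((i, j)): float(D[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    order: dict[int, list] = {i: [labels[i]] for i in range(n)}
    result = LinkageResult()
    next_id = n
    while len(clusters) > 1:
        def sort_key(pair: frozenset):
            i, j = sorted(pair)
            rep = sorted((str(min(clusters[i])), str(min(clusters[j]))))
            return (dist[pair], rep[0], rep[1])

        best = min(dist, key=sort_key)
        i, j = sorted(best)
        h = dist[best]
        result.merges.append((tuple(sorted(clusters[i])), tuple(sorted(clusters[j])), h))
        merged_members = clusters[i] + clusters[j]
        merged_order = order[i] + order[j]
        for cid in (i, j):
            del clusters[cid]
            del order[cid]
        new_dists = {}
        for cid in clusters:
            new_dists[frozenset((next_id, cid))] = max(
                dist[frozenset((i, cid))], dist[frozenset((j, cid))]
            )
        dist = {p: d for p, d in dist.items() if i not in p and j not in p}
        dist.update(new_dists)
        clusters[next_id] = merged_members
        order[next_id] = merged_order
        next_id += 1
    result.leaf_order = order[next_id - 1] if n else []
    return result


def bicluster(matrix: BinaryMutationMatrix, variant: str = "asymmetric"):
    """Cluster genes and strains; returns (gene_linkage, strain_linkage)."""
    Dg, genes = distance_matrix(matrix, "genes", variant)
    Ds, strains = distance_matrix(matrix, "strains", variant)
    return complete_linkage(Dg, genes), complete_linkage(Ds, strains)
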