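"""Hierarchical clustering of top-drug meta-signatures.

Complete-linkage agglomeration on cosine distance (d = 1 - cosine),
with deterministic lexicographic tie-breaking so the merge order and
leaf order are reproducible across runs. The agglomeration is written
out directly (Lance-Williams max update) rather than delegated to a
library routine because the tie-break rule is part of the contract.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class LinkageResult:
    """Merge history, leaf order and the distance matrix that produced it.

    ``merges`` lists (cluster_a, cluster_b, height, size) where each
    cluster is the sorted tuple of its leaf names; heights are
    non-decreasing under complete linkage.
    """

    merges: list[tuple[tuple[str, ...], tuple[str, ...], float, int]]
    leaf_order: list[str]
    distance: pd.DataFrame

    def to_newick(self) -> str:
        """Newick string with branch heights as merge heights."""
        node: dict[tuple[str, ...], str] = {}
        height: dict[tuple[str, ...], float] = {}
        for leaf in self.distance.index:
            node[(leaf,)] = leaf
            height[(leaf,)] = 0.0
        rep = None
        for a, b, h, _size in self.merges:
            la = h - height[a]
            lb = h - height[b]
            merged = tuple(sorted(a + b))
            node[merged] = f"({node[a]}:{la:.10g},{node[b]}:{lb:.10g})"
            height[merged] = h
            rep = merged
        return (node[rep] if rep is not None else node[(self.leaf_order[0],)]) + ";"

    def merge_table(self) -> pd.DataFrame:
        rows = [
            {"cluster_a": "|".join(a), "cluster_b": "|".join(b),
             "height": h, "size": s}
            for a, b, h, s in self.merges
        ]
        return pd.DataFrame(rows, columns=["cluster_a", "cluster_b", "height", "size"])


def cosine_distance_matrix(meta_signatures: pd.DataFrame) -> pd.DataFrame:
    """Pairwise cosine distance d = 1 - cos between drug columns."""
    if meta_signatures.shape[1] < 2:
        raise ValueError("need >=2 signatures")
    X = meta_signatures.to_numpy(dtype=float)
    norms = np.linalg.norm(X, axis=0)
    zero = norms == 0
    if zero.any():
        bad = list(meta_signatures.columns[zero])
        raise ValueError(f"zero-norm signature(s): {bad}")
    cos = (X.T @ X) / np.outer(norms, norms)
    np.clip(cos, -1.0, 1.0, out=cos)
    d = 1.0 - cos
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # enforce exact symmetry
    return pd.DataFrame(d, index=meta_signatures.columns,
                        columns=meta_signatures.columns)


def complete_linkage(distance: pd.DataFrame) -> LinkageResult:
    """Agglomerative clustering with max inter-cluster distance.

    Ties in the minimum distance are broken by the lexicographically
    smallest (cluster_a, cluster_b) pair of sorted leaf-name tuples, so
    the merge order is a pure function of the distance matrix.
    """
    names = [str(c) for c in distance.columns]
    if list(distance.index) != list(distance.columns):
        raise ValueError("distance matrix must be square with matching labels")
    D = distance.to_numpy(dtype=float)
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")

    clusters: dict[tuple[str, ...], dict[tuple[str, ...], float]] = {}
    keys = [(n,) for n in names]
    for i, ki in enumerate(keys):
        clusters[ki] = {kj: D[i, j] for j, kj in enumerate(keys) if j != i}

    merges: list[tuple[tuple[str, ...], tuple[str, ...], float, int]] = []
    order: dict[tuple[str, ...], list[str]] = {k: list(k) for k in keys}
    while len(clusters) > 1:
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters[a]):
                if b <= a:
                    continue
                cand = (clusters[a][b], a, b)
                if best is None or cand < best:
                    best = cand
        h, a, b = best
        merged = tuple(sorted(a + b))
        merges.append((a, b, float(h), len(merged)))
        new_row = {}
        for c in clusters:
            if c in (a, b):
                continue
            new_row[c] = max(clusters[a][c], clusters[b][c])
        del clusters[a], clusters[b]
        for c in clusters:
            clusters[c].pop(a, None)
            clusters[c].pop(b, None)
            clusters[c][merged] = new_row[c]
        clusters[merged] = new_row
        order[merged] = order.pop(a) + order.pop(b)
    leaf_order = next(iter(order.values())) if order else []
    return LinkageResult(merges=merges, leaf_order=leaf_order, distance=distance)


def top_k_signatures(meta_signatures: pd.DataFrame, records: pd.DataFrame,
                     k: int = 50) -> pd.DataFrame:
    """Signatures of the k most anti-similar drugs (cosine ascending)."""
    ranked = records.sort_values(["cosine", "drug"]).head(k)["drug"]
    return meta_signatures.loc[:, list(ranked)]


def similarity_matrix(meta_signatures: pd.DataFrame,
                      leaf_order: list[str]) -> pd.DataFrame:
    """Cosine *similarity* matrix in dendrogram leaf order."""
    d = cosine_distance_matrix(meta_signatures.loc[:, leaf_order])
    return 1.0 - d
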