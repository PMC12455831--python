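"""Base gene-graph construction.

The unweighted base network G = (V, A, X) is built by k-nearest
neighbors on Euclidean distance between gene expression profiles: each
gene points to its k closest genes, and the directed result is
OR-symmetrized (an edge exists if either endpoint selected the other).
Self-loops are on by default so every node attends to itself during
message passing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .data_io import ExpressionMatrix

__all__ = ["GeneGraph", "build_knn_graph", "graph_degree_stats"]

DEFAULT_KNN_K = 15


@dataclass
class GeneGraph:
    """Node set, binary adjacency and node features of the base network."""

    gene_ids: list[str]
    adjacency: np.ndarray  # {0,1}^{N×N}
    features: np.ndarray   # N × d
    k_used: int

    @property
    def n_nodes(self) -> int:
        return len(self.gene_ids)


def build_knn_graph(expr: ExpressionMatrix, k: int = DEFAULT_KNN_K,
                    self_loops: bool = True, mutual: bool = False) -> GeneGraph:
    """Build the k-NN gene graph from expression profiles.

    For each gene the k nearest other genes by Euclidean distance are
    linked; ties in distance are broken by ascending gene index so the
    construction is deterministic. The directed neighbor relation is
    symmetrized by OR (default) or AND (``mutual=True``).
    """
    X = np.asarray(expr.values, dtype=np.float64)
    n = X.shape[0]
    if n < 2:
        raise ValueError(f"need at least 2 genes, got {n}")
    if not 1 <= k <= n - 1:
        raise ValueError(f"k must satisfy 1 <= k <= N-1 = {n - 1}, got {k}")
    if np.isnan(X).any():
        raise ValueError("NaN values in expression features")

    D = cdist(X, X, metric="euclidean")
    np.fill_diagonal(D, np.inf)  # self never a neighbor
    # argsort is stable, so equal distances resolve to the lower index
    order = np.argsort(D, axis=1, kind="stable")
    neighbors = order[:, :k]

    directed = np.zeros((n, n), dtype=np.int8)
    rows = np.repeat(np.arange(n), k)
    directed[rows, neighbors.ravel()] = 1

    if mutual:
        adj = directed & directed.T
    else:
        adj = directed | directed.T
    adj = adj.astype(np.int8)
    np.fill_diagonal(adj, 1 if self_loops else 0)
    return GeneGraph(gene_ids=list(expr.gene_ids), adjacency=adj,
                     features=X.copy(), k_used=k)


def graph_degree_stats(g: GeneGraph) -> pd.DataFrame:
    """Per-node in/out degree table (diagonal excluded), with totals.

    The adjacency is symmetric by construction so in and out degree
    coincide; both columns are kept for generality.
    """
    adj = np.asarray(g.adjacency)
    off = adj.copy()
    np.fill_diagonal(off, 0)
    out_deg = off.sum(axis=1)
    in_deg = off.sum(axis=0)
    df = pd.DataFrame({"gene": g.gene_ids, "out_degree": out_deg, "in_degree": in_deg})
    df.attrs["summary"] = {
        "min": int(out_deg.min()),
        "median": float(np.median(out_deg)),
        "max": int(out_deg.max()),
    }
    return df
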