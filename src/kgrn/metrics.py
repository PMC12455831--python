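"""Evaluation metrics and driver-gene scoring.

The early precision ratio (EPR) follows the BEELINE convention: take
the top-k predicted edges with k equal to the number of ground-truth
edges inside the candidate universe; early precision is the fraction of
those that are true, and the EPR divides it by the density of the truth
in the universe (the precision of a random predictor), so EPR = 1 means
random and 1/density means perfect.

When a regulator (TF) list is supplied, the candidate universe is
TF × genes minus self-pairs; otherwise all ordered gene pairs. Truth
edges outside the universe are dropped with a logged count.

AUROC uses the Mann–Whitney formulation (ties count 1/2); AUPR uses
step-wise precision-recall integration and is reported as a ratio to
the random-predictor AUPR (the positive-class prevalence).

The regulation score of a gene sums the weights of its top 200 targets;
genes with the highest scores are reported as drivers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .data_io import EdgeSet

logger = logging.getLogger("kgrn")

__all__ = [
    "RankedPredictions",
    "early_precision_ratio",
    "auroc",
    "aupr_ratio",
    "edge_scores_and_labels",
    "regulation_score",
    "regulation_score_table",
    "driver_genes",
]

DEFAULT_TOP_TARGETS = 200
DEFAULT_TOP_DRIVERS = 30


@dataclass
class RankedPredictions:
    """Weighted edges ordered by weight (desc), tie-broken lexicographically,
    over an explicit candidate-pair universe."""

    edges: list[tuple[str, str, float]]
    universe: set[tuple[str, str]]

    def __post_init__(self):
        self.edges = sorted(self.edges, key=lambda e: (-e[2], e[0], e[1]))
        outside = [e for e in self.edges if (e[0], e[1]) not in self.universe]
        if outside:
            raise ValueError(f"{len(outside)} predicted edges outside the universe")

    @staticmethod
    def from_weight_matrix(gene_ids: list[str], weights: np.ndarray,
                           tf_list: list[str] | None = None) -> "RankedPredictions":
        """Rank every candidate pair by its weight-matrix entry.

        With a TF list, candidates are (tf, gene) ordered pairs (self
        excluded); without one, all ordered pairs.
        """
        weights = np.asarray(weights, dtype=np.float64)
        index = {g: i for i, g in enumerate(gene_ids)}
        if tf_list is not None:
            sources = [g for g in tf_list if g in index]
            if not sources:
                raise ValueError("no TF from the list is present among the genes")
        else:
            sources = list(gene_ids)
        edges = [(s, t, float(weights[index[s], index[t]]))
                 for s in sources for t in gene_ids if s != t]
        universe = {(s, t) for s, t, _ in edges}
        return RankedPredictions(edges=edges, universe=universe)


def early_precision_ratio(pred: RankedPredictions, truth: EdgeSet) -> float:
    """Early precision of the top-k predictions over random-predictor
    precision, with k = number of in-universe truth edges."""
    truth_in = truth.edges & pred.universe
    n_dropped = len(truth.edges) - len(truth_in)
    if n_dropped:
        logger.info("dropped %d truth edges outside the candidate universe", n_dropped)
    k = len(truth_in)
    if k == 0:
        raise ValueError("no ground-truth edge inside the candidate universe")
    top_k = {(s, t) for s, t, _ in pred.edges[:k]}
    early_precision = len(top_k & truth_in) / k
    density = k / len(pred.universe)
    return early_precision / density


def auroc(scores, labels) -> float:
    """Probability a random positive outranks a random negative (ties 1/2)."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    if labels.min() == labels.max():
        raise ValueError("AUROC needs both classes present")
    return float(roc_auc_score(labels, scores))


def aupr_ratio(scores, labels) -> float:
    """Step-wise AUPR divided by prevalence (random-predictor AUPR)."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    if labels.min() == labels.max():
        raise ValueError("AUPR needs both classes present")
    aupr = float(average_precision_score(labels, scores))
    prevalence = labels.mean()
    return aupr / prevalence


def edge_scores_and_labels(pred: RankedPredictions,
                           truth: EdgeSet) -> tuple[np.ndarray, np.ndarray]:
    """Score/label vectors over the candidate universe for AUROC/AUPR."""
    truth_in = truth.edges & pred.universe
    if not truth_in:
        raise ValueError("no ground-truth edge inside the candidate universe")
    scores = np.array([w for _, _, w in pred.edges])
    labels = np.array([1 if (s, t) in truth_in else 0 for s, t, _ in pred.edges])
    return scores, labels


def regulation_score(gene_ids: list[str], weights: np.ndarray, gene: str,
                     top_n: int = DEFAULT_TOP_TARGETS) -> float:
    """Sum of the gene's top_n largest off-diagonal outgoing weights
    (all of them when the gene has fewer than top_n targets)."""
    index = {g: i for i, g in enumerate(gene_ids)}
    if gene not in index:
        raise KeyError(f"unknown gene {gene!r}")
    i = index[gene]
    row = np.delete(np.asarray(weights, dtype=np.float64)[i], i)
    top = np.sort(row)[::-1][:top_n]
    return float(top.sum())


def regulation_score_table(gene_ids: list[str], weights: np.ndarray,
                           top_n: int = DEFAULT_TOP_TARGETS) -> pd.DataFrame:
    """Regulation score for every gene, ranked (ties lexicographic)."""
    scores = [regulation_score(gene_ids, weights, g, top_n) for g in gene_ids]
    df = pd.DataFrame({"gene": gene_ids, "score": scores})
    df = df.sort_values(["score", "gene"], ascending=[False, True],
                        ignore_index=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def driver_genes(scores: pd.DataFrame, restrict_to: list[str] | None = None,
                 top_n: int = DEFAULT_TOP_DRIVERS) -> list[str]:
    """Top-scoring genes, optionally restricted to a regulator list."""
    df = scores
    if restrict_to is not None:
        allowed = set(restrict_to)
        df = df[df["gene"].isin(allowed)]
    df = df.sort_values(["score", "gene"], ascending=[False, True])
    return df["gene"].head(top_n).tolist()
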