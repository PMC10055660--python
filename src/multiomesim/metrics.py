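"""Evaluation metrics and dataset summary statistics.

These are the statistics used to validate simulator output and to score
downstream methods: pseudotime R^2 and kNN purity for trajectories, graph
connectivity and batch average silhouette width for integration, cosine
similarity for RNA velocity, plus per-cell / per-gene count summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_samples
from sklearn.neighbors import kneighbors_graph

__all__ = [
    "r_squared",
    "knn_purity",
    "graph_connectivity",
    "batch_asw",
    "velocity_cosine",
    "SummaryStats",
    "summarize_dataset",
    "pca_embedding",
]


def r_squared(true_pt: np.ndarray, inferred_pt: np.ndarray) -> float:
    """Squared Pearson correlation between true and inferred pseudotime."""
    t = np.asarray(true_pt, dtype=float)
    th = np.asarray(inferred_pt, dtype=float)
    if t.size != th.size or t.size < 2:
        raise ValueError("need two equal-length vectors with n >= 2")
    if np.std(t) == 0 or np.std(th) == 0:
        return float("nan")
    rho = np.corrcoef(t, th)[0, 1]
    return float(rho ** 2)


def knn_purity(true_pt: np.ndarray, inferred_pt: np.ndarray,
               k: int = 50) -> np.ndarray:
    """Per-cell Jaccard index of the k-nearest-neighbor sets under the true
    and inferred pseudotime orderings (neighborhoods on the 1-D values)."""
    t = np.asarray(true_pt, dtype=float)
    th = np.asarray(inferred_pt, dtype=float)
    n = t.size
    if k >= n:
        raise ValueError("k must be < n")
    nbrs_t = _knn_sets_1d(t, k)
    nbrs_i = _knn_sets_1d(th, k)
    out = np.empty(n)
    for i in range(n):
        a, b = nbrs_t[i], nbrs_i[i]
        out[i] = len(a & b) / len(a | b)
    return out


def _knn_sets_1d(values: np.ndarray, k: int):
    n = values.size
    dists = np.abs(values[:, None] - values[None, :])
    np.fill_diagonal(dists, np.inf)
    idx = np.argsort(dists, axis=1, kind="stable")[:, :k]
    return [set(row) for row in idx]


def graph_connectivity(embedding: np.ndarray, type_labels: np.ndarray,
                       k: int = 15,
                       graph: Optional[np.ndarray] = None) -> float:
    """Mean, over cell types, of the largest-connected-component fraction
    of the type's cells within the kNN graph of the embedding."""
    labels = np.asarray(type_labels)
    if graph is None:
        graph = kneighbors_graph(embedding, n_neighbors=min(k, len(labels) - 1),
                                 include_self=False)
    graph = graph + graph.T  # symmetrise
    scores = []
    for t in np.unique(labels):
        mask = labels == t
        if mask.sum() == 0:
            raise ValueError(f"empty cell type {t}")
        sub = graph[mask][:, mask]
        n_comp, comp = connected_components(sub, directed=False)
        largest = np.bincount(comp).max()
        scores.append(largest / mask.sum())
    return float(np.mean(scores))


def batch_asw(embedding: np.ndarray, batch_labels: np.ndarray,
              type_labels: np.ndarray) -> float:
    """Batch-mixing score: per cell type, the mean of 1 - |silhouette|
    computed on batch labels; averaged over types. 1 = perfectly mixed."""
    batch = np.asarray(batch_labels)
    types = np.asarray(type_labels)
    per_type = []
    for t in np.unique(types):
        mask = types == t
        sub_batches = batch[mask]
        if np.unique(sub_batches).size < 2:
            per_type.append(1.0)  # single batch: trivially mixed
            continue
        sil = silhouette_samples(embedding[mask], sub_batches)
        per_type.append(float(np.mean(1.0 - np.abs(sil))))
    return float(np.mean(per_type))


def velocity_cosine(v_true: np.ndarray, v_est: np.ndarray) -> float:
    """Mean per-cell cosine similarity between two velocity fields.

    Cells with a zero-norm row in either field are excluded.
    """
    v_true = np.asarray(v_true, dtype=float)
    v_est = np.asarray(v_est, dtype=float)
    if v_true.shape != v_est.shape:
        raise ValueError("velocity fields must have matching shapes")
    nt = np.linalg.norm(v_true, axis=1)
    ne = np.linalg.norm(v_est, axis=1)
    keep = (nt > 0) & (ne > 0)
    if not keep.any():
        raise ValueError("all rows have zero norm")
    cos = np.sum(v_true[keep] * v_est[keep], axis=1) / (nt[keep] * ne[keep])
    return float(np.mean(cos))


@dataclass
class SummaryStats:
    """Per-cell and per-gene count summaries of one count matrix."""

    library_size: np.ndarray        # per cell
    cell_zero_fraction: np.ndarray  # per cell
    gene_zero_fraction: np.ndarray  # per gene
    gene_mean: np.ndarray           # per gene
    gene_variance: np.ndarray       # per gene

    def to_frame(self) -> Dict[str, pd.DataFrame]:
        return {
            "cells": pd.DataFrame({
                "library_size": self.library_size,
                "zero_fraction": self.cell_zero_fraction,
            }),
            "genes": pd.DataFrame({
                "zero_fraction": self.gene_zero_fraction,
                "mean": self.gene_mean,
                "variance": self.gene_variance,
            }),
        }


def summarize_dataset(counts: np.ndarray) -> SummaryStats:
    """Library sizes, zero fractions and per-gene moments of a cells x
    genes count matrix."""
    counts = np.asarray(counts)
    return SummaryStats(
        library_size=counts.sum(axis=1),
        cell_zero_fraction=np.mean(counts == 0, axis=1),
        gene_zero_fraction=np.mean(counts == 0, axis=0),
        gene_mean=counts.mean(axis=0),
        gene_variance=counts.var(axis=0),
    )


def pca_embedding(counts: np.ndarray, n_components: int = 20,
                  random_state: int = 0) -> np.ndarray:
    """Standard embedding for scoring: PCA of log1p counts."""
    x = np.log1p(np.asarray(counts, dtype=float))
    n_components = min(n_components, min(x.shape) - 1)
    return PCA(n_components=n_components,
               random_state=random_state).fit_transform(x)
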