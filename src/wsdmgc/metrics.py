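"""Clustering evaluation statistics and the cluster-number sweep.

Purity, best-map accuracy (optimal one-to-one cluster-to-class assignment
via the Hungarian algorithm), normalised mutual information (geometric
normalisation, natural logs) and the silhouette coefficient, plus a
silhouette sweep over candidate cluster counts. All four statistics are
invariant to relabeling of the predicted cluster ids.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import pdist, squareform

from .datasets import DataValidationError


def _check_lengths(pred, true) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred, dtype=np.int64)
    true = np.asarray(true, dtype=np.int64)
    if pred.shape != true.shape or pred.ndim != 1 or len(pred) == 0:
        raise DataValidationError(
            "pred and true must be equal-length non-empty 1-D label vectors")
    return pred, true


def contingency(pred: np.ndarray, true: np.ndarray) -> np.ndarray:
    """Counts[c, j] = |cluster c ∩ class j| (dense ids assumed >= 0)."""
    k_p, k_t = pred.max() + 1, true.max() + 1
    table = np.zeros((k_p, k_t), dtype=np.int64)
    np.add.at(table, (pred, true), 1)
    return table


def purity(pred, true) -> float:
    """(1/N) * sum_k max_j |cluster_k ∩ class_j|."""
    pred, true = _check_lengths(pred, true)
    table = contingency(pred, true)
    return float(table.max(axis=1).sum() / len(pred))


def best_map(pred, true) -> dict[int, int]:
    """Optimal one-to-one cluster-id -> class-id assignment.

    Solved as a maximum-agreement linear assignment on the contingency
    table (padded square when the partitions have different sizes); among
    equally good assignments, lower cluster ids take lower class ids.
    """
    pred, true = _check_lengths(pred, true)
    table = contingency(pred, true)
    k = max(table.shape)
    padded = np.zeros((k, k), dtype=np.float64)
    padded[: table.shape[0], : table.shape[1]] = table
    # secondary objective, total < 1 so integer agreement counts dominate:
    # pair low cluster ids with low class ids among equally good assignments
    tie = np.outer(k - np.arange(k), k - np.arange(k)) / (k ** 4 + 1.0)
    rows, cols = linear_sum_assignment(padded + tie, maximize=True)
    return {int(r): int(c) for r, c in zip(rows, cols)}


def accuracy_best_map(pred, true) -> float:
    """Label-match accuracy maximised over one-to-one cluster→class maps."""
    pred, true = _check_lengths(pred, true)
    mapping = best_map(pred, true)
    mapped = np.array([mapping[int(r)] for r in pred])
    return float(np.mean(mapped == true))


def nmi(pred, true) -> float:
    """I(X,Y) / sqrt(H(X) H(Y)) with natural-log entropies.

    Conventions for degenerate partitions: 1.0 when the two label vectors
    induce identical partitions (including the all-one-cluster case),
    0.0 when either entropy is zero and the partitions differ.
    """
    pred, true = _check_lengths(pred, true)
    table = contingency(pred, true).astype(np.float64)
    n = table.sum()
    p_xy = table / n
    p_x = p_xy.sum(axis=1)
    p_y = p_xy.sum(axis=0)
    h_x = float(-np.sum(p_x[p_x > 0] * np.log(p_x[p_x > 0])))
    h_y = float(-np.sum(p_y[p_y > 0] * np.log(p_y[p_y > 0])))
    if h_x <= 0 or h_y <= 0:
        # identical-as-partitions iff one nonzero cell per row and column
        same = (np.count_nonzero(table, axis=1).max(initial=0) <= 1
                and np.count_nonzero(table, axis=0).max(initial=0) <= 1)
        return 1.0 if same else 0.0
    mask = p_xy > 0
    mi = float(np.sum(p_xy[mask] * np.log(p_xy[mask] /
                                          np.outer(p_x, p_y)[mask])))
    return float(mi / np.sqrt(h_x * h_y))


def silhouette(dist: np.ndarray, labels: np.ndarray,
               ) -> tuple[np.ndarray, float]:
    """Per-sample silhouette values S(i) and their mean.

    ``dist`` is a symmetric pairwise distance matrix (or an (N, d) point
    matrix, in which case Euclidean distances are computed). For sample i
    in cluster C_i, a(i) is the mean distance to the other members of C_i
    and b(i) the minimum over other clusters of the mean distance to that
    cluster; S(i) = (b - a)/max(a, b). Members of singleton clusters get
    S(i) = 0, as does the 0/0 case.
    """
    labels = np.asarray(labels, dtype=np.int64)
    dist = np.asarray(dist, dtype=np.float64)
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        dist = squareform(pdist(dist))
    n = len(labels)
    if dist.shape[0] != n:
        raise DataValidationError("distance matrix does not match labels")
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise DataValidationError("silhouette requires >= 2 clusters")
    sizes = {c: int(np.sum(labels == c)) for c in uniq}
    S = np.zeros(n)
    for i in range(n):
        c = labels[i]
        if sizes[c] == 1:
            continue
        a = dist[i, labels == c].sum() / (sizes[c] - 1)
        b = min(dist[i, labels == c2].mean() for c2 in uniq if c2 != c)
        denom = max(a, b)
        S[i] = 0.0 if denom <= 0 else (b - a) / denom
    return S, float(S.mean())


@dataclass
class MetricsReport:
    """Evaluation bundle written to ``report.json``."""

    purity: float
    acc: float
    nmi: float
    mean_silhouette: float | None = None
    sweep: list[tuple[int, float]] | None = None

    def to_dict(self) -> dict:
        return {
            "purity": self.purity,
            "acc": self.acc,
            "nmi": self.nmi,
            "mean_silhouette": self.mean_silhouette,
            "sweep": self.sweep,
        }


def evaluate_labels(pred, true, points: np.ndarray | None = None) -> MetricsReport:
    """Purity/ACC/NMI (and silhouette when points are given) in one call."""
    sil = None
    if points is not None and len(np.unique(pred)) >= 2:
        _, sil = silhouette(np.asarray(points), pred)
    return MetricsReport(purity=purity(pred, true),
                         acc=accuracy_best_map(pred, true),
                         nmi=nmi(pred, true),
                         mean_silhouette=sil)


def sweep_cluster_number(embeddings: np.ndarray, k_range, seed: int = 0,
                         eigvec_order: str = "smallest",
                         labels: np.ndarray | None = None,
                         ) -> tuple[pd.DataFrame, int]:
    """Mean silhouette of the spectral partition for each candidate k.

    Builds an unconstrained similarity graph over the embeddings,
    partitions at every k in ``k_range`` and scores the partition by mean
    silhouette on embedding-space Euclidean distances. When ``labels``
    are given (class ids, -1 for unlabeled) they calibrate the kernel
    bandwidth to the within-class scale; the graph itself stays
    unconstrained since the candidate k need not match the class count.
    Returns the (k, mean_silhouette) table and the argmax k (ties toward
    the smaller k).
    """
    from .graph import (build_similarity, graph_laplacian, spectral_partition,
                        within_class_sigma)

    emb = np.asarray(embeddings, dtype=np.float64)
    k_range = [int(k) for k in k_range]
    if not k_range or min(k_range) < 2 or max(k_range) > len(emb) - 1:
        raise DataValidationError(
            "k_range must be non-empty and within [2, n_samples - 1]")
    sigma = within_class_sigma(emb, labels) if labels is not None else "auto"
    graph = graph_laplacian(build_similarity(emb, labels=None, sigma=sigma))
    dist = squareform(pdist(emb))
    rows = []
    for k in k_range:
        labels = spectral_partition(graph, k, seed=seed, order=eigvec_order)
        if len(np.unique(labels)) < 2:
            sc = -1.0  # degenerate partition: every sample in one cluster
        else:
            _, sc = silhouette(dist, labels)
        rows.append({"k": k, "mean_silhouette": sc})
    table = pd.DataFrame(rows)
    best_k = int(table.loc[table["mean_silhouette"].idxmax(), "k"])
    return table, best_k
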