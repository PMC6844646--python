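"""Unsupervised functional clustering of ROIs and AldC-label coincidence.

Whole-session ΔF/F traces are standardised per ROI, projected onto their
first three principal components, and partitioned by k-means; the cluster
number is selected by the largest mean silhouette over a small k range.
Agreement with aldolase-C expression is the coincidence rate: per cluster,
the percentage of ROIs carrying the cluster's majority label, averaged
(unweighted) over clusters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

DEFAULT_K_RANGE = range(2, 7)


@dataclass
class ClusterResult:
    pc_scores: np.ndarray  # ROIs × 3
    assignment: np.ndarray  # cluster id per ROI
    k_selected: int
    silhouette_mean: float
    silhouette_by_k: dict[int, float]
    coincidence_rate: float = float("nan")


def standardize_traces(dff: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-variance rows; constant traces raise."""
    dff = np.atleast_2d(np.asarray(dff, dtype=float))
    sd = dff.std(axis=1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("constant trace: zero variance")
    return (dff - dff.mean(axis=1, keepdims=True)) / sd


def pca_traces(dff: np.ndarray, n_components: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Project standardised ROI traces onto their top principal axes.

    ROIs are observations, frames are features. The sign of each component
    is fixed so its largest-magnitude loading is positive, making scores
    deterministic. Returns (scores ROIs × k, components k × frames).
    """
    z = standardize_traces(dff)
    if z.shape[0] < n_components + 1:
        raise ValueError(f"need at least {n_components + 1} ROIs")
    if z.shape[1] < n_components:
        raise ValueError("need at least as many frames as components")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(z)
    components = pca.components_
    for c in range(n_components):
        pivot = np.argmax(np.abs(components[c]))
        if components[c, pivot] < 0:
            components[c] *= -1
            scores[:, c] *= -1
    return scores, components


def kmeans_silhouette(
    scores: np.ndarray,
    k_range=DEFAULT_K_RANGE,
    restarts: int = 50,
    seed: int = 0,
) -> tuple[np.ndarray, int, float, dict[int, float]]:
    """Best-of-restarts k-means per k; keep the k with the best silhouette.

    Ties go to the smaller k. k values that cannot produce a valid
    partition (k ≥ n, or a degenerate run collapsing to fewer clusters) are
    skipped.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    n = scores.shape[0]
    best = None
    silhouettes: dict[int, float] = {}
    for k in k_range:
        if k < 2 or k > n - 1:
            continue
        km = KMeans(n_clusters=k, n_init=restarts, init="random", random_state=seed)
        labels = km.fit_predict(scores)
        if len(np.unique(labels)) < k:
            continue
        sil = float(silhouette_score(scores, labels))
        silhouettes[k] = sil
        if best is None or sil > best[2]:
            best = (labels, k, sil)
    if best is None:
        raise ValueError("no k in the range produced a valid clustering")
    labels, k_selected, sil = best
    return labels, k_selected, sil, silhouettes


def coincidence_rate(assignment: np.ndarray, aldc_labels) -> float:
    """Unweighted cluster-mean percentage of majority-AldC-profile ROIs."""
    assignment = np.asarray(assignment)
    labels = np.asarray(aldc_labels)
    if assignment.shape != labels.shape:
        raise ValueError("assignment and labels must align")
    binary = np.unique(labels)
    if binary.size > 2:
        raise ValueError("AldC labels must be binary (+/−)")
    rates = []
    for cluster in np.unique(assignment):
        members = labels[assignment == cluster]
        if members.size == 0:
            raise ValueError("empty cluster")
        majority = max(np.sum(members == v) for v in binary)
        rates.append(100.0 * majority / members.size)
    return float(np.mean(rates))


def cluster_session(
    dff: np.ndarray,
    aldc_signs,
    k_range=DEFAULT_K_RANGE,
    restarts: int = 50,
    seed: int = 0,
) -> ClusterResult:
    """Full clustering pipeline for one session's ΔF/F matrix."""
    scores, _ = pca_traces(dff)
    assignment, k_selected, sil, by_k = kmeans_silhouette(scores, k_range, restarts, seed)
    rate = coincidence_rate(assignment, np.asarray(aldc_signs))
    return ClusterResult(
        pc_scores=scores,
        assignment=assignment,
        k_selected=k_selected,
        silhouette_mean=sil,
        silhouette_by_k=by_k,
        coincidence_rate=rate,
    )


def sort_correlation_matrix(
    dff: np.ndarray, assignment: np.ndarray, roi_ids=None
) -> tuple[np.ndarray, np.ndarray]:
    """ΔF/F Pearson correlation matrix ordered by cluster then roi_id.

    Returns (matrix, order) where ``order`` indexes the original rows.
    """
    dff = np.atleast_2d(np.asarray(dff, dtype=float))
    if dff.shape[0] < 2:
        raise ValueError("need at least 2 ROIs")
    assignment = np.asarray(assignment)
    if roi_ids is None:
        roi_ids = np.arange(dff.shape[0])
    order = np.lexsort((np.asarray(roi_ids), assignment))
    corr = np.corrcoef(dff)
    return corr[np.ix_(order, order)], order


def summarize_clusters(result: ClusterResult, roi_ids, aldc_labels) -> pd.DataFrame:
    """One row per ROI: id, cluster, label — the CSV export layout."""
    return pd.DataFrame(
        {
            "roi_id": np.asarray(roi_ids),
            "cluster": result.assignment,
            "aldc_label": np.asarray(aldc_labels),
        }
    )
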