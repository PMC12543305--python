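"""Hierarchical clustering of link-length profiles and ensemble co-clustering.

Each region is described by the column of the link-length matrix
l_ij = −ln w_ij — its profile of incoming information flow.  Regions with
similar incoming profiles are agglomerated (Ward by default); absent links
get a large finite fill value (1.05 × the maximum observed length) so they
read as "very weak" without breaking Euclidean/correlation geometry.

For model ensembles, each network is clustered independently into k clusters
and the co-clustering contingency matrix P_ij (fraction of networks placing
i and j together) is itself clustered via the 1−P distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

DEFAULT_FILL_FACTOR = 1.05

_LINKAGES = ("ward", "average", "complete")
_METRICS = ("euclidean", "correlation", "cosine")


@dataclass(frozen=True)
class FeatureMatrix:
    """Per-region column feature vectors of link lengths, with fill policy."""

    features: np.ndarray  # (N, N): column k -> feature vector features[:, k]
    labels: tuple
    fill_value: float
    n_filled: int


@dataclass(frozen=True)
class Dendrogram:
    """Agglomerative merge sequence (scipy linkage matrix) with leaf labels."""

    Z: np.ndarray
    labels: tuple
    linkage_method: str
    metric: str

    @property
    def heights(self) -> np.ndarray:
        return self.Z[:, 2]


def feature_matrix(
    w: np.ndarray, labels=None, fill_factor: float = DEFAULT_FILL_FACTOR
) -> FeatureMatrix:
    """Link-length features with absent links filled by fill_factor × max(l)."""
    w = np.asarray(w, float)
    n = w.shape[0]
    if labels is None:
        labels = tuple(f"n{i}" for i in range(n))
    if not (w > 0).any():
        raise ValueError("weight matrix has no positive entries")
    l = np.full(w.shape, np.nan)
    pos = w > 0
    l[pos] = -np.log(w[pos])
    fill = float(fill_factor * np.nanmax(l)) if np.isfinite(np.nanmax(l)) else 1.0
    if fill <= 0:  # all weights 1: degenerate but finite
        fill = 1.0
    n_filled = int((~pos).sum())
    l[~pos] = fill
    return FeatureMatrix(features=l, labels=tuple(labels), fill_value=fill, n_filled=n_filled)


def hier_cluster(
    features: FeatureMatrix | np.ndarray,
    linkage_method: str = "ward",
    metric: str = "euclidean",
) -> Dendrogram:
    """Agglomerate the column vectors of the feature matrix.

    Similarity metrics (correlation, cosine) are converted to distances as
    1 − similarity by scipy's pdist.  Ward requires Euclidean distances.
    """
    if linkage_method not in _LINKAGES:
        raise ValueError(f"linkage must be one of {_LINKAGES}")
    if metric not in _METRICS:
        raise ValueError(f"metric must be one of {_METRICS}")
    if linkage_method == "ward" and metric != "euclidean":
        raise ValueError("Ward linkage requires the euclidean metric")
    if isinstance(features, FeatureMatrix):
        X = features.features.T  # rows = observations = regions (column profiles)
        labels = features.labels
    else:
        X = np.asarray(features, float).T
        labels = tuple(f"n{i}" for i in range(X.shape[0]))
    d = pdist(X, metric=metric)
    Z = linkage(d, method=linkage_method)
    return Dendrogram(Z=Z, labels=labels, linkage_method=linkage_method, metric=metric)


def cut_clusters(dendrogram: Dendrogram, k: int) -> np.ndarray:
    """Partition the leaves into exactly k clusters (labels 1..k)."""
    n = len(dendrogram.labels)
    if not (1 <= k <= n):
        raise ValueError(f"k must be in [1, {n}]")
    return fcluster(dendrogram.Z, t=k, criterion="maxclust")


def cocluster_contingency(
    networks,
    k: int,
    linkage_method: str = "ward",
    metric: str = "euclidean",
    labels=None,
    contingency_linkage: str = "complete",
) -> tuple[np.ndarray, Dendrogram]:
    """Co-clustering probability matrix of an ensemble, plus its dendrogram.

    Each network is clustered independently into k clusters; P_ij is the
    fraction of networks co-clustering regions i and j (symmetric, unit
    diagonal).  P is then clustered using 1−P as a precomputed distance with
    ``contingency_linkage`` (Ward is not applicable to non-Euclidean
    precomputed distances, hence the complete-linkage default).
    """
    networks = list(networks)
    if not networks:
        raise ValueError("empty ensemble")
    n = np.asarray(networks[0], float).shape[0]
    if labels is None:
        labels = tuple(f"n{i}" for i in range(n))
    P = np.zeros((n, n))
    for w in networks:
        fm = feature_matrix(np.asarray(w, float), labels=labels)
        part = cut_clusters(hier_cluster(fm, linkage_method, metric), k)
        P += (part[:, None] == part[None, :]).astype(float)
    P /= len(networks)
    D = 1.0 - P
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method=contingency_linkage)
    dend = Dendrogram(
        Z=Z, labels=tuple(labels), linkage_method=contingency_linkage, metric="precomputed"
    )
    return P, dend
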