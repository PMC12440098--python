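"""Evaluation metrics.

Jaccard neighborhood similarity (unsupervised agreement between an
embedding and the original data space), the log2 fold change of top
Pearson correlations that attributes a topic to one of two modalities,
and thin wrappers over the six standard supervised clustering scores.
"""

from __future__ import annotations

import warnings

import numpy as np

from .datatypes import MetricReport

__all__ = [
    "jaccard_similarity",
    "fold_change_top_correlations",
    "supervised_scores",
    "MetricReport",
]


def _knn_sets(x: np.ndarray, k: int) -> list[set]:
    from scipy.spatial.distance import cdist

    d = cdist(x, x)
    np.fill_diagonal(d, np.inf)
    order = np.argsort(d, axis=1, kind="stable")[:, :k]
    return [set(map(int, row)) for row in order]


def jaccard_similarity(embedding: np.ndarray, data: np.ndarray, k: int = 50) -> float:
    """Mean over spots of |kNN(embedding) ∩ kNN(data)| / |union|, with
    Euclidean k-nearest neighbors computed in each space."""
    embedding = np.atleast_2d(np.asarray(embedding, dtype=float))
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if embedding.shape[0] != data.shape[0]:
        raise ValueError("embedding and data must share the spot axis")
    n = embedding.shape[0]
    if k >= n:
        raise ValueError("k must be smaller than the number of spots")
    a = _knn_sets(embedding, k)
    b = _knn_sets(data, k)
    return float(
        np.mean([len(s & t) / len(s | t) for s, t in zip(a, b)])
    )


def _top_mean_correlation(topic: np.ndarray, x: np.ndarray, m: int) -> float:
    """Mean of the top-m Pearson correlations (by signed value) between
    the topic and each feature column; constant columns get r = 0."""
    topic = topic - topic.mean()
    t_norm = np.sqrt(topic @ topic)
    if t_norm == 0:
        raise ValueError("topic vector is constant")
    xc = x - x.mean(axis=0, keepdims=True)
    col_norm = np.sqrt((xc**2).sum(axis=0))
    bad = col_norm == 0
    if bad.any():
        warnings.warn(f"{int(bad.sum())} constant feature column(s): r set to 0",
                      stacklevel=2)
    col_norm[bad] = 1.0
    r = (xc.T @ topic) / (col_norm * t_norm)
    r[bad] = 0.0
    top = np.sort(r)[-m:]
    return float(top.mean())


def fold_change_top_correlations(topic: np.ndarray, x1: np.ndarray, x2: np.ndarray,
                                 m1: int = 10, m2: int = 10) -> float:
    """log2 of the ratio between the mean top-m1 correlation with modality
    1 features and the mean top-m2 correlation with modality 2 features.
    Positive values attribute the topic to modality 1.  If either top-mean
    is non-positive the ratio is undefined and NaN is returned."""
    topic = np.asarray(topic, dtype=float).ravel()
    x1 = np.atleast_2d(np.asarray(x1, dtype=float))
    x2 = np.atleast_2d(np.asarray(x2, dtype=float))
    if not (1 <= m1 <= x1.shape[1] and 1 <= m2 <= x2.shape[1]):
        raise ValueError("top-m exceeds the number of features")
    t1 = _top_mean_correlation(topic, x1, m1)
    t2 = _top_mean_correlation(topic, x2, m2)
    if t1 <= 0 or t2 <= 0:
        warnings.warn("non-positive top-mean correlation: fold change undefined",
                      stacklevel=2)
        return float("nan")
    return float(np.log2(t1 / t2))


def supervised_scores(labels, truth) -> dict:
    """ARI, MI, AMI, NMI, homogeneity and V-measure (off-the-shelf
    scikit-learn implementations)."""
    from sklearn import metrics as skm

    labels = np.asarray(labels).ravel()
    truth = np.asarray(truth).ravel()
    if labels.shape != truth.shape:
        raise ValueError("label vectors must have equal length")
    return {
        "ARI": float(skm.adjusted_rand_score(truth, labels)),
        "MI": float(skm.mutual_info_score(truth, labels)),
        "AMI": float(skm.adjusted_mutual_info_score(truth, labels)),
        "NMI": float(skm.normalized_mutual_info_score(truth, labels)),
        "HOM": float(skm.homogeneity_score(truth, labels)),
        "VME": float(skm.v_measure_score(truth, labels)),
    }
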