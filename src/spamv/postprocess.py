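"""From trained posteriors to deliverables.

Clustering mode: concatenate the mixture-mean shared embedding with every
private embedding and cluster with a full-covariance Gaussian mixture
(the classical mclust-style model).  Topic mode: each latent dimension is
an interpretable topic; dimensions whose spatial autocorrelation
(Moran's I z-score) or standard deviation is low are pruned, and feature
rankings come from the column-softmaxed loading matrices.
"""

from __future__ import annotations

import numpy as np

from .datatypes import NeighborGraph, SpatialMultiOmics, TopicResult
from .model_core import SpaMVModel

__all__ = [
    "embeddings_for_clustering",
    "cluster_domains",
    "morans_i_z",
    "extract_topics",
    "prune_topics",
    "rank_features",
]


def embeddings_for_clustering(model: SpaMVModel, data: SpatialMultiOmics,
                              graphs: list[NeighborGraph]) -> np.ndarray:
    """spots x (d_s + sum d_p): mixture-mean shared embedding concatenated
    with the private posterior means."""
    post = model.posteriors(data, graphs)
    shared = np.mean(np.stack(post.mu_s), axis=0)
    return np.concatenate([shared] + list(post.mu_p), axis=1)


def cluster_domains(embeddings: np.ndarray, n_clusters: int, seed: int = 0) -> np.ndarray:
    """Full-covariance Gaussian-mixture clustering (EM, k-means init)."""
    from sklearn.mixture import GaussianMixture

    embeddings = np.asarray(embeddings, dtype=float)
    if n_clusters > embeddings.shape[0]:
        raise ValueError("n_clusters exceeds the number of spots")
    # covariance regularization must track the data scale: latent
    # embeddings can legitimately live at very small amplitudes
    reg = max(1e-4 * float(embeddings.var(axis=0).mean()), 1e-12)
    gm = GaussianMixture(
        n_components=n_clusters,
        covariance_type="full",
        init_params="kmeans",
        n_init=20,
        random_state=seed,
        reg_covar=reg,
    )
    return gm.fit_predict(embeddings)


def morans_i_z(values: np.ndarray, graph: NeighborGraph) -> tuple[float, float, bool]:
    """Moran's I of per-spot values on row-standardized spatial weights,
    with the analytic mean/variance under the normality assumption.

    Returns ``(I, z, degenerate)``; constant input gives z = 0 with the
    degenerate flag set.
    """
    x = np.asarray(values, dtype=float).ravel()
    n = x.size
    if n != graph.n_spots:
        raise ValueError("values length must equal the number of spots")
    z = x - x.mean()
    denom = float(z @ z)
    if denom == 0.0:
        return 0.0, 0.0, True

    w = graph.adjacency().astype(float)
    row_sums = np.asarray(w.sum(axis=1)).ravel()
    row_sums[row_sums == 0] = 1.0
    from scipy import sparse

    w = sparse.diags(1.0 / row_sums) @ w

    s0 = w.sum()
    wt = w.T.tocsr()
    s1 = 0.5 * ((w + wt).power(2)).sum()
    r = np.asarray(w.sum(axis=1)).ravel() + np.asarray(w.sum(axis=0)).ravel()
    s2 = float((r**2).sum())

    num = float(z @ (w @ z))
    i_val = (n / s0) * (num / denom)
    e_i = -1.0 / (n - 1)
    var_i = (n**2 * s1 - n * s2 + 3 * s0**2) / ((n**2 - 1) * s0**2) - e_i**2
    if var_i <= 0:
        return i_val, 0.0, True
    return i_val, (i_val - e_i) / np.sqrt(var_i), False


def extract_topics(model: SpaMVModel, data: SpatialMultiOmics,
                   graphs: list[NeighborGraph],
                   spatial_graph: NeighborGraph | None = None) -> TopicResult:
    """Posterior-mean topics with provenance and pruning diagnostics.

    Topic order: the d_s shared dimensions first, then each modality's
    private block.  Moran's I z-scores use the spatial-only adjacency of
    the first modality's graph unless a dedicated graph is passed.
    """
    if model.config.mode != "topic":
        raise ValueError("extract_topics requires a topic-mode model")
    post = model.posteriors(data, graphs)
    shared = np.mean(np.stack(post.mu_s), axis=0)
    blocks = [shared] + list(post.mu_p)
    latent = np.concatenate(blocks, axis=1)

    d_s, d_p = model.config.d_s, model.config.d_p
    provenance = ["shared"] * d_s
    names = [f"shared_{k + 1}" for k in range(d_s)]
    for i in range(model.m):
        provenance += [f"private_{i + 1}"] * d_p
        names += [f"private_{i + 1}_topic_{k + 1}" for k in range(d_p)]

    e = np.exp(latent - latent.max(axis=1, keepdims=True))
    weights = e / e.sum(axis=1, keepdims=True)

    graph = spatial_graph if spatial_graph is not None else _spatial_only(graphs[0])
    moran = np.array([morans_i_z(latent[:, t], graph)[1] for t in range(latent.shape[1])])
    std = latent.std(axis=0)

    return TopicResult(
        weights=weights,
        latent_means=latent,
        beta_softmax=[dec.beta_softmax() for dec in model.decoders],
        provenance=provenance,
        topic_names=names,
        moran_z=moran,
        std=std,
    )


def _spatial_only(graph: NeighborGraph) -> NeighborGraph:
    keep = [k for k, tag in enumerate(graph.source_tag) if tag in ("spatial", "both")]
    return NeighborGraph(
        n_spots=graph.n_spots,
        edges=graph.edges[keep],
        source_tag=[graph.source_tag[k] for k in keep],
    )


def _two_means_split(z: np.ndarray, seed: int = 0) -> np.ndarray:
    """1-D 2-means; returns a boolean mask of the lower-center cluster."""
    from sklearn.cluster import KMeans

    km = KMeans(n_clusters=2, n_init=10, random_state=seed)
    labels = km.fit_predict(z.reshape(-1, 1))
    low = int(np.argmin(km.cluster_centers_.ravel()))
    return labels == low


def prune_topics(result: TopicResult, z_threshold: float = 0.3,
                 std_threshold: float = 1.0, seed: int = 0) -> TopicResult:
    """Flag noisy topics: if the minimum Moran z-score is below
    ``z_threshold``, split the z-scores by 1-D 2-means and prune the
    lower-center cluster; independently prune topics whose pre-softmax
    latent standard deviation is below ``std_threshold``.  Flags are
    recomputed from the full topic set, so the operation is idempotent.
    """
    if result.moran_z is None or result.std is None:
        raise ValueError("moran_z and std must be computed before pruning")
    z = np.asarray(result.moran_z, dtype=float)
    kept = np.ones(result.n_topics, dtype=bool)
    info: dict = {"z_threshold": z_threshold, "std_threshold": std_threshold}
    if z.min() < z_threshold:
        low = _two_means_split(z, seed)
        kept &= ~low
        info["z_pruned"] = np.flatnonzero(low).tolist()
    else:
        info["z_pruned"] = []
    low_std = result.std < std_threshold
    kept &= ~low_std
    info["std_pruned"] = np.flatnonzero(low_std).tolist()
    if not kept.any():
        import warnings

        warnings.warn("all topics pruned", stacklevel=2)
    result.kept = kept
    result.pruning_info = info
    return result


def rank_features(beta_softmax: np.ndarray, topic: int, top_n: int | None = None,
                  feature_names: list[str] | None = None):
    """Features sorted by their loading on one topic column (descending,
    ties broken by index)."""
    col = np.asarray(beta_softmax)[:, topic]
    order = np.argsort(-col, kind="stable")
    if top_n is not None:
        order = order[:top_n]
    if feature_names is not None:
        return [feature_names[j] for j in order]
    return order
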