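"""Mode-specific preprocessing and neighbor-graph construction.

Clustering mode feeds the model dimensionally reduced matrices (HVG →
normalize → log1p → PCA for counts; CLR → PCA for marker intensities;
TF-IDF + truncated SVD for peak matrices).  Topic mode keeps filtered
counts (for the count-likelihood decoder) alongside normalized encoder
inputs.  Both modes attach a mixed neighbor graph per modality: spatial
adjacency united with k-nearest neighbors in the preprocessed data space.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial.distance import cdist

from .datatypes import NeighborGraph, SpatialMultiOmics

__all__ = [
    "PreprocessConfig",
    "preprocess_clustering",
    "preprocess_topic",
    "clr_transform",
    "lsi_transform",
    "pca_reduce",
    "build_graph",
]


@dataclass
class PreprocessConfig:
    min_spots_per_gene: int = 20       # transcriptome gene filter (clustering mode)
    min_genes_per_spot: int = 100      # transcriptome spot filter (clustering mode)
    n_hvg_clustering: int = 3000
    n_hvg_topic: int = 1000
    filter_frac: float = 0.01          # topic-mode 1%/1% feature & spot filter
    n_pca: int = 50
    k: int = 10                        # data-space kNN for the mixed graph
    n_spatial_neighbors: int = 6       # non-lattice spatial adjacency
    spatial_rule: str = "auto"         # auto | grid | knn
    clr_margin: str = "spot"           # spot (across features) | feature


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def clr_transform(x: np.ndarray, margin: str = "spot") -> np.ndarray:
    """Centered log-ratio transform, Seurat-style on zero-inflated counts:
    y = log1p(x / exp(mean(log1p(x)))) with the mean taken across features
    of each spot (``margin="spot"``) or across spots of each feature.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("CLR expects non-negative input")
    axis = 1 if margin == "spot" else 0
    log_x = np.log1p(x)
    geo = np.exp(log_x.mean(axis=axis, keepdims=True))
    return np.log1p(x / geo)


def pca_reduce(x: np.ndarray, n_components: int, seed: int = 0) -> np.ndarray:
    """PCA with a deterministic sign convention: in each component the
    loading of largest magnitude is made positive."""
    from sklearn.decomposition import PCA

    x = np.asarray(x, dtype=float)
    if float(x.var(axis=0).sum()) == 0.0:
        raise ValueError("PCA input has zero variance (constant matrix)")
    n_components = min(n_components, x.shape[1] - 1, x.shape[0] - 1)
    if n_components < 1:
        raise ValueError("not enough features/spots for PCA")
    pca = PCA(n_components=n_components, svd_solver="full", random_state=seed)
    scores = pca.fit_transform(x)
    for j in range(n_components):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, j] = -scores[:, j]
    return scores


def lsi_transform(x: np.ndarray, n_components: int = 50, seed: int = 0,
                  drop_first: bool = True) -> np.ndarray:
    """Latent semantic indexing for peak/fragment matrices: term frequency
    scaled by log IDF, truncated SVD, first component dropped (it tracks
    sequencing depth)."""
    from sklearn.decomposition import TruncatedSVD

    x = np.asarray(x, dtype=float)
    libsize = x.sum(axis=1, keepdims=True)
    if np.any(libsize == 0):
        raise ValueError("LSI input has empty spots")
    tf = x / libsize
    df = (x > 0).sum(axis=0)
    idf = np.log1p(x.shape[0] / (1.0 + df))
    mat = tf * idf
    n_out = n_components + (1 if drop_first else 0)
    n_out = min(n_out, min(mat.shape) - 1)
    svd = TruncatedSVD(n_components=n_out, random_state=seed)
    scores = svd.fit_transform(mat)
    for j in range(scores.shape[1]):
        load = svd.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, j] = -scores[:, j]
    return scores[:, 1:] if drop_first else scores


def _hvg_indices(counts: np.ndarray, n_top: int) -> np.ndarray:
    """Highly variable features chosen on a log1p-normalized copy
    (dispersion-based); returns sorted column indices."""
    import anndata as ad
    import scanpy as sc

    if n_top >= counts.shape[1]:
        return np.arange(counts.shape[1])
    adata = ad.AnnData(X=np.asarray(counts, dtype=np.float32).copy())
    sc.pp.normalize_total(adata)
    sc.pp.log1p(adata)
    sc.pp.highly_variable_genes(adata, n_top_genes=n_top, flavor="seurat")
    return np.sort(np.flatnonzero(adata.var["highly_variable"].to_numpy()))


def _normalize_log(counts: np.ndarray) -> np.ndarray:
    import anndata as ad
    import scanpy as sc

    adata = ad.AnnData(X=np.asarray(counts, dtype=np.float64).copy())
    sc.pp.normalize_total(adata)
    sc.pp.log1p(adata)
    return np.asarray(adata.X, dtype=float)


def _subset(data: SpatialMultiOmics, spot_keep: np.ndarray,
            feature_keep: list[np.ndarray]) -> SpatialMultiOmics:
    return SpatialMultiOmics(
        matrices=[m[np.ix_(spot_keep, fk)] for m, fk in zip(data.matrices, feature_keep)],
        coords=data.coords[spot_keep],
        feature_names=[
            [names[j] for j in fk] for names, fk in zip(data.feature_names, feature_keep)
        ],
        spot_ids=[data.spot_ids[i] for i in np.flatnonzero(spot_keep)],
        modality_kinds=list(data.modality_kinds),
    )


# ---------------------------------------------------------------------------
# mode pipelines
# ---------------------------------------------------------------------------

def preprocess_clustering(
    data: SpatialMultiOmics, cfg: PreprocessConfig | None = None
) -> SpatialMultiOmics:
    """Reduce each modality to a PCA/LSI embedding appropriate to its kind.

    Transcriptome: drop genes seen in < ``min_spots_per_gene`` spots and
    spots with < ``min_genes_per_spot`` expressed genes (spot removal is
    applied jointly so modalities stay aligned), keep the top HVGs,
    total-count normalize, log1p, PCA.  Proteome: CLR then PCA.  Peak
    matrices: LSI.  Metabolome / gene activity: transcriptome recipe
    without the HVG step / without normalization respectively.
    """
    cfg = cfg or PreprocessConfig()

    # feature filters first, then a joint spot filter
    feature_keep = []
    for mat, kind in zip(data.matrices, data.modality_kinds):
        if kind in ("transcriptome", "metabolome"):
            keep = np.flatnonzero((mat > 0).sum(axis=0) >= cfg.min_spots_per_gene)
        else:
            keep = np.arange(mat.shape[1])
        if keep.size == 0:
            raise ValueError(f"{kind} modality emptied by the feature filter")
        feature_keep.append(keep)

    spot_keep = np.ones(data.n_spots, dtype=bool)
    for mat, kind, fk in zip(data.matrices, data.modality_kinds, feature_keep):
        if kind == "transcriptome":
            spot_keep &= (mat[:, fk] > 0).sum(axis=1) >= cfg.min_genes_per_spot
    if not spot_keep.any():
        raise ValueError("all spots removed by the spot filter")
    filtered = _subset(data, spot_keep, feature_keep)

    reduced = []
    for mat, kind in zip(filtered.matrices, filtered.modality_kinds):
        mat = np.asarray(mat, dtype=float)
        if kind == "transcriptome":
            hvg = _hvg_indices(mat, cfg.n_hvg_clustering)
            x = _normalize_log(mat[:, hvg])
            reduced.append(pca_reduce(x, cfg.n_pca))
        elif kind == "proteome":
            reduced.append(pca_reduce(clr_transform(mat, cfg.clr_margin), cfg.n_pca))
        elif kind == "epigenome_peaks":
            reduced.append(lsi_transform(mat, cfg.n_pca))
        elif kind == "epigenome_gas":
            hvg = _hvg_indices(mat, cfg.n_hvg_clustering)
            reduced.append(pca_reduce(np.log1p(mat[:, hvg]), cfg.n_pca))
        elif kind == "metabolome":
            reduced.append(pca_reduce(_normalize_log(mat), cfg.n_pca))
        else:
            raise ValueError(f"no clustering recipe for {kind}")

    out = SpatialMultiOmics(
        matrices=reduced,
        coords=filtered.coords,
        feature_names=[
            [f"dim_{j}" for j in range(r.shape[1])] for r in reduced
        ],
        spot_ids=filtered.spot_ids,
        modality_kinds=filtered.modality_kinds,
    )
    return out


def preprocess_topic(
    data: SpatialMultiOmics, cfg: PreprocessConfig | None = None
) -> SpatialMultiOmics:
    """Filter features in < 1% of spots and spots with < 1% of features
    (jointly across modalities), then produce normalized encoder inputs
    while retaining the filtered counts and per-spot library sizes for the
    count-likelihood decoder."""
    cfg = cfg or PreprocessConfig()

    feature_keep = []
    for mat in data.matrices:
        frac = (mat > 0).mean(axis=0)
        keep = np.flatnonzero(frac >= cfg.filter_frac)
        if keep.size == 0:
            raise ValueError("modality emptied by the 1% feature filter")
        feature_keep.append(keep)

    spot_keep = np.ones(data.n_spots, dtype=bool)
    for mat, fk in zip(data.matrices, feature_keep):
        sub = mat[:, fk]
        spot_keep &= (sub > 0).mean(axis=1) >= cfg.filter_frac
    if not spot_keep.any():
        raise ValueError("all spots removed by the 1% spot filter")
    filtered = _subset(data, spot_keep, feature_keep)

    inputs, counts, libsizes, names = [], [], [], []
    for mat, kind, fnames in zip(
        filtered.matrices, filtered.modality_kinds, filtered.feature_names
    ):
        mat = np.asarray(mat, dtype=float)
        if kind == "proteome":
            keep = np.arange(mat.shape[1])
            x = clr_transform(mat, cfg.clr_margin)
        elif kind in ("transcriptome", "metabolome"):
            keep = _hvg_indices(mat, cfg.n_hvg_topic)
            x = _normalize_log(mat[:, keep])
        elif kind == "epigenome_gas":
            keep = _hvg_indices(mat, cfg.n_hvg_topic)
            x = mat[:, keep]  # pre-normalized upstream
        else:
            raise ValueError(f"no topic recipe for {kind}")
        c = mat[:, keep]
        inputs.append(x)
        counts.append(c)
        libsizes.append(c.sum(axis=1))
        names.append([fnames[j] for j in keep])

    # the HVG subset can leave a spot with zero counts in one modality;
    # the count decoder needs a positive library size, so drop such spots
    ok = np.ones(filtered.n_spots, dtype=bool)
    for l in libsizes:
        ok &= l > 0
    if not ok.all():
        import warnings

        warnings.warn(
            f"dropping {int((~ok).sum())} spot(s) with empty libraries after "
            "feature selection",
            stacklevel=2,
        )
        inputs = [x[ok] for x in inputs]
        counts = [c[ok] for c in counts]
        libsizes = [l[ok] for l in libsizes]

    return SpatialMultiOmics(
        matrices=inputs,
        coords=filtered.coords[ok],
        feature_names=names,
        spot_ids=[s for s, good in zip(filtered.spot_ids, ok) if good],
        modality_kinds=filtered.modality_kinds,
        counts=counts,
        library_sizes=libsizes,
    )


# ---------------------------------------------------------------------------
# neighbor graph
# ---------------------------------------------------------------------------

def _is_lattice(coords: np.ndarray) -> bool:
    return bool(np.allclose(coords, np.round(coords)))


def _knn_pairs(x: np.ndarray, k: int) -> set[tuple[int, int]]:
    """k nearest neighbors by Euclidean distance; ties broken by index."""
    d = cdist(x, x)
    np.fill_diagonal(d, np.inf)
    order = np.argsort(d, axis=1, kind="stable")[:, :k]
    pairs = set()
    for i in range(x.shape[0]):
        for j in order[i]:
            pairs.add((min(i, int(j)), max(i, int(j))))
    return pairs


def build_graph(
    data_matrix: np.ndarray,
    coords: np.ndarray,
    k: int = 10,
    spatial_rule: str = "auto",
    n_spatial_neighbors: int = 6,
) -> NeighborGraph:
    """Union of spatial adjacency and data-space kNN, symmetrized.

    Spatial adjacency is rook (4-neighborhood) on lattice coordinates and
    ``n_spatial_neighbors``-nearest otherwise; ``spatial_rule`` forces
    either branch.  Data kNN uses Euclidean distance with ties broken by
    spot index.
    """
    data_matrix = np.asarray(data_matrix, dtype=float)
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n < 2:
        raise ValueError("need at least 2 spots")
    if k >= n:
        raise ValueError("k must be smaller than the number of spots")

    if spatial_rule == "grid" or (spatial_rule == "auto" and _is_lattice(coords)):
        ic = np.round(coords).astype(int)
        index = {(int(r), int(c)): i for i, (r, c) in enumerate(ic)}
        spatial = set()
        for i, (r, c) in enumerate(ic):
            for dr, dc in ((0, 1), (1, 0)):
                j = index.get((int(r) + dr, int(c) + dc))
                if j is not None:
                    spatial.add((min(i, j), max(i, j)))
    else:
        spatial = _knn_pairs(coords, min(n_spatial_neighbors, n - 1))

    data_pairs = _knn_pairs(data_matrix, k)

    all_pairs = sorted(spatial | data_pairs)
    tags = [
        "both" if p in spatial and p in data_pairs else ("spatial" if p in spatial else "knn")
        for p in all_pairs
    ]
    return NeighborGraph(n_spots=n, edges=np.array(all_pairs), source_tag=tags)


def build_graphs(
    data: SpatialMultiOmics, cfg: PreprocessConfig | None = None
) -> list[NeighborGraph]:
    cfg = cfg or PreprocessConfig()
    return [
        build_graph(
            m, data.coords, k=cfg.k, spatial_rule=cfg.spatial_rule,
            n_spatial_neighbors=cfg.n_spatial_neighbors,
        )
        for m in data.matrices
    ]
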