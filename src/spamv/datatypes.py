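"""Core containers shared across the package."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MODALITY_KINDS = (
    "transcriptome",
    "proteome",
    "epigenome_gas",
    "epigenome_peaks",
    "metabolome",
)


@dataclass
class SpatialMultiOmics:
    """Two (or more) spot-matched omics matrices with 2-D coordinates.

    ``matrices[i]`` is spots x features for modality ``i``; all modalities
    share ``spot_ids`` in the same order.  ``counts`` and ``library_sizes``
    are populated by topic-mode preprocessing, which keeps the filtered raw
    counts for the count-likelihood decoder alongside the normalized
    encoder inputs.
    """

    matrices: list[np.ndarray]
    coords: np.ndarray
    feature_names: list[list[str]]
    spot_ids: list[str]
    modality_kinds: list[str]
    counts: list[np.ndarray] | None = None
    library_sizes: list[np.ndarray] | None = None

    def __post_init__(self):
        n = len(self.spot_ids)
        for m in self.matrices:
            if m.shape[0] != n:
                raise ValueError("all modalities must share the spot axis")
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (n, 2):
            raise ValueError("coords must be spots x 2")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords must be finite")
        for kind in self.modality_kinds:
            if kind not in MODALITY_KINDS:
                raise ValueError(f"unknown modality kind {kind!r}")

    @property
    def n_spots(self) -> int:
        return len(self.spot_ids)

    @property
    def n_modalities(self) -> int:
        return len(self.matrices)


@dataclass
class NeighborGraph:
    """Symmetric spot adjacency with per-edge provenance.

    Edges are stored once per unordered pair in ``edges``; ``source_tag``
    says whether the pair came from spatial proximity, data-space kNN, or
    both.  ``directed()`` expands to both directions plus self-loops for
    the attention layers (self-attention is handled there, so no
    self-loops are stored here).
    """

    n_spots: int
    edges: np.ndarray  # (E, 2) with u < v
    source_tag: list[str]

    def __post_init__(self):
        self.edges = np.asarray(self.edges, dtype=int).reshape(-1, 2)
        if np.any(self.edges[:, 0] == self.edges[:, 1]):
            raise ValueError("self-loops must not be stored")
        if np.any(self.edges[:, 0] >= self.edges[:, 1]):
            raise ValueError("edges must be canonical (u < v)")

    def directed(self, self_loops: bool = True) -> tuple[np.ndarray, np.ndarray]:
        src = np.concatenate([self.edges[:, 0], self.edges[:, 1]])
        dst = np.concatenate([self.edges[:, 1], self.edges[:, 0]])
        if self_loops:
            loops = np.arange(self.n_spots)
            src = np.concatenate([src, loops])
            dst = np.concatenate([dst, loops])
        return src, dst

    def adjacency(self):
        """Sparse symmetric 0/1 adjacency (no self-loops)."""
        from scipy import sparse

        e = self.edges
        data = np.ones(2 * len(e))
        rows = np.concatenate([e[:, 0], e[:, 1]])
        cols = np.concatenate([e[:, 1], e[:, 0]])
        return sparse.coo_matrix(
            (data, (rows, cols)), shape=(self.n_spots, self.n_spots)
        ).tocsr()


@dataclass
class LatentPosteriors:
    """Per-spot Gaussian posterior parameters and drawn samples."""

    mu_s: list[np.ndarray]
    sigma_s: list[np.ndarray]
    mu_p: list[np.ndarray]
    sigma_p: list[np.ndarray]
    z_s: np.ndarray | None = None
    z_p: list[np.ndarray] | None = None

    def shared_mean(self) -> np.ndarray:
        """Posterior mean of the uniform mixture of shared experts."""
        return np.mean(np.stack(self.mu_s), axis=0)


@dataclass
class TopicResult:
    """Spots x topics weights plus per-modality loadings and pruning state."""

    weights: np.ndarray               # spots x T, row-softmaxed for reporting
    latent_means: np.ndarray          # spots x T, pre-softmax posterior means
    beta_softmax: list[np.ndarray]    # per modality: features x T_i (column-stochastic)
    provenance: list[str]             # per topic: shared / private_1 / private_2
    topic_names: list[str]
    moran_z: np.ndarray | None = None
    std: np.ndarray | None = None
    kept: np.ndarray | None = None
    pruning_info: dict = field(default_factory=dict)

    @property
    def n_topics(self) -> int:
        return self.weights.shape[1]

    def kept_indices(self) -> np.ndarray:
        if self.kept is None:
            return np.arange(self.n_topics)
        return np.flatnonzero(self.kept)


@dataclass
class MetricReport:
    jaccard: dict = field(default_factory=dict)
    fold_change: dict = field(default_factory=dict)
    supervised: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "jaccard": {k: float(v) for k, v in self.jaccard.items()},
            "fold_change": {k: float(v) for k, v in self.fold_change.items()},
            "supervised": {k: float(v) for k, v in self.supervised.items()},
        }
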