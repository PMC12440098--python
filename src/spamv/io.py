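"""Readers/writers for standard on-disk formats and the run configuration.

h5ad is the canonical container (one file per modality, spot coordinates
in ``obsm["spatial"]``); MatrixMarket (matrix.mtx + features.tsv +
barcodes.tsv) and dense CSV are supported with a coordinate sidecar CSV.
Modalities are aligned by spot ID: a permuted order is fixed with a
warning, a genuine mismatch is an error.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .datatypes import SpatialMultiOmics
from .model_core import ModelConfig
from .preprocessing import PreprocessConfig

__all__ = ["RunConfig", "read_modality", "load_dataset", "write_labels", "write_topics"]


@dataclass
class RunConfig:
    """Everything a run needs; round-trips losslessly through YAML."""

    mode: str = "clustering"
    seed: int = 0
    n_clusters: int | None = None
    jaccard_k: int = 50
    top_m: list[int] = field(default_factory=lambda: [10, 10])
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    inputs: list[str] = field(default_factory=list)
    output_dir: str = "."

    def to_yaml(self, path):
        import yaml

        d = asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        d = yaml.safe_load(Path(path).read_text())
        d["preprocess"] = PreprocessConfig(**d.get("preprocess", {}))
        d["model"] = ModelConfig(**d.get("model", {}))
        return cls(**d)


def _read_h5ad(path: Path):
    import anndata as ad

    adata = ad.read_h5ad(path)
    x = np.asarray(
        adata.X.toarray() if hasattr(adata.X, "toarray") else adata.X, dtype=float
    )
    coords = None
    if "spatial" in adata.obsm:
        coords = np.asarray(adata.obsm["spatial"], dtype=float)
    kind = adata.uns.get("modality_kind", "transcriptome")
    return x, list(adata.var_names), list(adata.obs_names), coords, str(kind)


def _read_mtx(path: Path):
    from scipy.io import mmread

    d = path if path.is_dir() else path.parent
    mat = mmread(d / "matrix.mtx")
    x = np.asarray(mat.todense() if hasattr(mat, "todense") else mat, dtype=float)
    features = (d / "features.tsv").read_text().strip().splitlines()
    features = [line.split("\t")[0] for line in features]
    barcodes = (d / "barcodes.tsv").read_text().strip().splitlines()
    barcodes = [line.split("\t")[0] for line in barcodes]
    # convention: features x spots on disk (10x style); transpose to spots x features
    if x.shape == (len(features), len(barcodes)):
        x = x.T
    elif x.shape != (len(barcodes), len(features)):
        raise ValueError(
            f"MTX dims {x.shape} disagree with features/barcodes "
            f"({len(features)}, {len(barcodes)})"
        )
    coords = _read_coords_sidecar(d, barcodes)
    return x, features, barcodes, coords, "transcriptome"


def _read_csv(path: Path):
    import pandas as pd

    df = pd.read_csv(path, index_col=0)
    coords = _read_coords_sidecar(path.parent, list(df.index))
    return (
        df.to_numpy(dtype=float),
        list(df.columns),
        list(df.index.astype(str)),
        coords,
        "transcriptome",
    )


def _read_coords_sidecar(d: Path, spot_ids: list[str]):
    import pandas as pd

    f = d / "coordinates.csv"
    if not f.exists():
        return None
    cdf = pd.read_csv(f, index_col=0)
    cdf.index = cdf.index.astype(str)
    return cdf.loc[spot_ids].to_numpy(dtype=float)


def read_modality(path, fmt: str | None = None):
    """Read one modality; returns (matrix, feature_names, spot_ids,
    coords-or-None, modality_kind)."""
    path = Path(path)
    if fmt is None:
        if path.suffix == ".h5ad":
            fmt = "h5ad"
        elif path.suffix == ".csv":
            fmt = "csv"
        elif path.is_dir() or path.suffix == ".mtx":
            fmt = "mtx"
        else:
            raise ValueError(f"cannot infer format of {path}")
    if fmt == "h5ad":
        return _read_h5ad(path)
    if fmt == "mtx":
        return _read_mtx(path)
    if fmt == "csv":
        return _read_csv(path)
    raise ValueError(f"unknown format {fmt!r}")


def load_dataset(paths, kinds: list[str] | None = None) -> SpatialMultiOmics:
    """Read several modality files and align them by spot ID."""
    mods = [read_modality(p) for p in paths]
    ref_ids = mods[0][2]
    ref_set = set(ref_ids)
    matrices, names, coords = [], [], None
    for k, (x, fnames, ids, c, kind) in enumerate(mods):
        if ids != ref_ids:
            if set(ids) != ref_set:
                raise ValueError("spot IDs differ between modalities")
            warnings.warn("modalities have permuted spot order; realigning by ID",
                          stacklevel=2)
            lookup = {s: i for i, s in enumerate(ids)}
            order = [lookup[s] for s in ref_ids]
            x = x[order]
            c = c[order] if c is not None else None
        matrices.append(x)
        names.append(fnames)
        if coords is None and c is not None:
            coords = c
    if coords is None:
        raise ValueError("no modality provides spot coordinates")
    resolved_kinds = kinds if kinds is not None else [m[4] for m in mods]
    return SpatialMultiOmics(
        matrices=matrices,
        coords=coords,
        feature_names=names,
        spot_ids=list(ref_ids),
        modality_kinds=resolved_kinds,
    )


def write_labels(path, spot_ids, labels):
    import pandas as pd

    pd.DataFrame({"spot_id": spot_ids, "cluster": np.asarray(labels)}).to_csv(
        path, index=False
    )


def write_topics(out_dir, result, spot_ids, feature_names):
    """Topic weights and per-modality loading matrices as CSV plus a JSON
    pruning report."""
    import json

    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(result.weights, index=spot_ids, columns=result.topic_names).to_csv(
        out / "topic_weights.csv"
    )
    try:
        import anndata as ad

        adata = ad.AnnData(
            X=result.weights.astype(np.float32),
            obs=pd.DataFrame(index=[str(s) for s in spot_ids]),
            var=pd.DataFrame(
                {"provenance": result.provenance}, index=result.topic_names
            ),
        )
        adata.layers["latent_means"] = result.latent_means.astype(np.float32)
        if result.kept is not None:
            adata.var["kept"] = result.kept
        adata.write_h5ad(out / "topics.h5ad")
    except ImportError:
        pass
    d_s = sum(1 for p in result.provenance if p == "shared")
    d_p = (len(result.provenance) - d_s) // max(1, len(result.beta_softmax))
    for i, (beta, fnames) in enumerate(zip(result.beta_softmax, feature_names), start=1):
        cols = result.topic_names[:d_s] + [
            f"private_{i}_topic_{k + 1}" for k in range(d_p)
        ]
        pd.DataFrame(beta, index=fnames, columns=cols).to_csv(out / f"beta_{i}.csv")
    report = {
        "topic_names": result.topic_names,
        "provenance": result.provenance,
        "moran_z": result.moran_z.tolist() if result.moran_z is not None else None,
        "std": result.std.tolist() if result.std is not None else None,
        "kept": result.kept.tolist() if result.kept is not None else None,
        "pruning_info": result.pruning_info,
    }
    (out / "pruning_report.json").write_text(json.dumps(report, indent=2))
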