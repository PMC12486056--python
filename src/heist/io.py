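"""Readers, writers, config schema and run manifests.

Accepted input formats: an AnnData-style HDF5 container (expression in
``X``, coordinates in ``obsm['spatial']``, labels in
``obs['cell_type']``), a CSV triplet (``expression.csv`` cells × genes,
``coords.csv`` with columns cell_id,x,y, optional ``types.csv`` with
cell_id,cell_type), or MTX + two index files for sparse expression.
The hierarchical graph serializes to a single HDF5 file; writes disable
HDF5 timestamps so identical graphs produce byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict

from .graph_construction import (ExpressionMatrix, GeneCoexpressionNetwork,
                                 HierarchicalGraph, SpatialCellGraph)

__all__ = ["read_dataset", "write_hierarchical_graph",
           "read_hierarchical_graph", "RunConfig", "load_config",
           "config_hash", "write_manifest", "export_embeddings"]


# ---------------------------------------------------------------------------
# dataset readers
# ---------------------------------------------------------------------------

def _check_ids(expr_ids, other_ids, what: str):
    missing = [i for i in expr_ids if i not in set(other_ids)]
    extra = [i for i in other_ids if i not in set(expr_ids)]
    offenders = missing + extra
    if offenders:
        raise ValueError(
            f"cell-id mismatch between expression and {what}: "
            f"first offenders {offenders[:5]}")


def _read_csv_triplet(folder: Path):
    return read_csv_files(folder / "expression.csv", folder / "coords.csv",
                          folder / "types.csv")


def read_csv_files(expr_path, coords_path, types_path=None):
    """CSV triplet given as explicit file paths (types optional)."""
    df = pd.read_csv(expr_path, index_col=0)
    if not all(np.issubdtype(dt, np.number) for dt in df.dtypes):
        bad = [c for c, dt in df.dtypes.items()
               if not np.issubdtype(dt, np.number)][:5]
        raise ValueError(f"non-numeric expression columns: {bad}")
    coords = pd.read_csv(coords_path)
    for col in ("cell_id", "x", "y"):
        if col not in coords.columns:
            raise ValueError(f"coords.csv is missing required column {col!r}")
    _check_ids(df.index.tolist(), coords["cell_id"].tolist(), "coords.csv")
    coords = coords.set_index("cell_id").loc[df.index]
    positions = coords[["x", "y"]].to_numpy(dtype=np.float64)

    labels = None
    if types_path is not None and Path(types_path).exists():
        types = pd.read_csv(types_path)
        _check_ids(df.index.tolist(), types["cell_id"].tolist(), "types.csv")
        labels = types.set_index("cell_id").loc[df.index, "cell_type"].to_numpy()

    expr = ExpressionMatrix(values=df.to_numpy(dtype=np.float64),
                            gene_ids=df.columns.to_numpy(),
                            cell_ids=df.index.to_numpy(), layer_tag="raw")
    return expr, positions, labels


def _read_mtx_triplet(folder: Path):
    import scipy.io as sio
    mat = sio.mmread(str(folder / "expression.mtx")).toarray()
    cells = pd.read_csv(folder / "cells.txt", header=None)[0].to_numpy()
    genes = pd.read_csv(folder / "genes.txt", header=None)[0].to_numpy()
    if mat.shape != (len(cells), len(genes)):
        raise ValueError("MTX shape does not match index files")
    coords = pd.read_csv(folder / "coords.csv")
    _check_ids(cells.tolist(), coords["cell_id"].tolist(), "coords.csv")
    coords = coords.set_index("cell_id").loc[cells]
    labels = None
    types_path = folder / "types.csv"
    if types_path.exists():
        types = pd.read_csv(types_path)
        _check_ids(cells.tolist(), types["cell_id"].tolist(), "types.csv")
        labels = types.set_index("cell_id").loc[cells, "cell_type"].to_numpy()
    expr = ExpressionMatrix(values=mat.astype(np.float64), gene_ids=genes,
                            cell_ids=cells, layer_tag="raw")
    return expr, coords[["x", "y"]].to_numpy(dtype=np.float64), labels


def _read_anndata(path: Path):
    import anndata
    ad = anndata.read_h5ad(path)
    X = ad.X.toarray() if hasattr(ad.X, "toarray") else np.asarray(ad.X)
    if "spatial" not in ad.obsm:
        raise ValueError("AnnData container lacks obsm['spatial'] coordinates")
    labels = ad.obs["cell_type"].to_numpy() if "cell_type" in ad.obs else None
    expr = ExpressionMatrix(values=X.astype(np.float64),
                            gene_ids=ad.var_names.to_numpy(),
                            cell_ids=ad.obs_names.to_numpy(), layer_tag="raw")
    return expr, np.asarray(ad.obsm["spatial"], dtype=np.float64)[:, :2], labels


def read_dataset(path):
    """Load (ExpressionMatrix, positions, optional labels) from any
    recognized format (see module docstring)."""
    path = Path(path)
    if path.is_file() and path.suffix in (".h5ad", ".h5"):
        return _read_anndata(path)
    if path.is_dir():
        if (path / "expression.mtx").exists():
            return _read_mtx_triplet(path)
        if (path / "expression.csv").exists():
            return _read_csv_triplet(path)
    raise ValueError(f"unrecognized dataset format at {path}")


# ---------------------------------------------------------------------------
# hierarchical-graph HDF5 store
# ---------------------------------------------------------------------------

def _ds(group, name, data):
    group.create_dataset(name, data=data, track_times=False)


def write_hierarchical_graph(hg: HierarchicalGraph, path) -> None:
    """Serialize to one HDF5 file; cell-type labels are stored as strings."""
    import h5py
    with h5py.File(path, "w", track_order=True) as f:
        cg = f.create_group("cell_graph")
        _ds(cg, "positions", hg.cell_graph.positions)
        _ds(cg, "edges", hg.cell_graph.edges)
        _ds(cg, "types", np.array([str(t) for t in hg.cell_graph.cell_types],
                                  dtype="S64"))
        gn = f.create_group("gene_networks")
        for t in sorted(hg.gene_networks, key=str):
            net = hg.gene_networks[t]
            g = gn.create_group(str(t))
            _ds(g, "edges", net.edges)
            _ds(g, "mi_weights", net.mi_weights)
            g.attrs["threshold_used"] = float(net.threshold_used)
        ex = f.create_group("expression")
        _ds(ex, "values", hg.expression.values)
        _ds(ex, "gene_ids", np.asarray(hg.expression.gene_ids, dtype="S64"))
        _ds(ex, "cell_ids", np.asarray(hg.expression.cell_ids, dtype="S64"))
        ex.attrs["layer_tag"] = hg.expression.layer_tag


def read_hierarchical_graph(path) -> HierarchicalGraph:
    import h5py
    with h5py.File(path, "r") as f:
        types = f["cell_graph/types"][:].astype(str)
        cg = SpatialCellGraph(positions=f["cell_graph/positions"][:],
                              edges=f["cell_graph/edges"][:],
                              cell_types=types)
        gene_ids = f["expression/gene_ids"][:].astype(str)
        networks = {}
        for t in f["gene_networks"]:
            g = f["gene_networks"][t]
            networks[t] = GeneCoexpressionNetwork(
                cell_type=t, gene_ids=gene_ids, edges=g["edges"][:],
                mi_weights=g["mi_weights"][:],
                threshold_used=float(g.attrs["threshold_used"]))
        expr = ExpressionMatrix(values=f["expression/values"][:],
                                gene_ids=gene_ids,
                                cell_ids=f["expression/cell_ids"][:].astype(str),
                                layer_tag=str(f["expression"].attrs["layer_tag"]))
    return HierarchicalGraph(cell_graph=cg, gene_networks=networks,
                             expression=expr)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GraphSection(_Section):
    n_hvg: int | None = None
    outlier_mads: float = 3.0
    magic_k: int = 15
    magic_t: int = 3
    tau_mode: str = "adaptive"
    tau_value_or_target_degree: float = 10.0
    prune_quantile: float = 0.99
    resolution: float = 1.0


class ModelSection(_Section):
    d: int = 64
    L: int = 2
    heads: int = 4
    agg: str = "mean"
    cross_residual: bool = True
    cross_level: bool = True


class ObjectivesSection(_Section):
    radius: float | None = None
    temperature: float = 0.1
    similarity: str = "cosine"
    cell_mask_rate: float = 0.1
    gene_mask_rate: float = 0.3
    ortho_lambda: float = 1e-3


class TrainingSection(_Section):
    max_epochs: int = 10
    patience: int = 3
    learning_rate: float = 1e-3
    patch_cells: int = 512
    validation_fraction: float = 0.1


class EvalSection(_Section):
    task: str = "cluster"
    mask_fraction: float = 0.1
    resolution: float = 1.0


class SimulateSection(_Section):
    n_cells: int = 1500
    n_genes: int = 60
    n_types: int = 3
    n_niches: int = 3
    modules_per_type: int = 2
    niche_effect_size: float = 0.8
    dropout_rate: float = 0.4
    noise_sd: float = 0.3


class RunConfig(_Section):
    graph: GraphSection = GraphSection()
    model: ModelSection = ModelSection()
    objectives: ObjectivesSection = ObjectivesSection()
    training: TrainingSection = TrainingSection()
    eval: EvalSection = EvalSection()
    simulate: SimulateSection = SimulateSection()
    seed: int = 0

    @property
    def config_hash(self) -> str:
        return config_hash(self.model_dump())


def config_hash(obj) -> str:
    """Stable hash of a config mapping (key order independent)."""
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


def load_config(path) -> RunConfig:
    import yaml
    data = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig(**data)


def write_manifest(outdir, config: RunConfig | dict, seeds: dict,
                   extra: dict | None = None) -> Path:
    """Write a reproducibility manifest next to a run's outputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = config.model_dump() if isinstance(config, RunConfig) else dict(config)
    manifest = {
        "config": cfg,
        "config_hash": config_hash(cfg),
        "seeds": seeds,
        "versions": {"python": platform.python_version(),
                     "numpy": np.__version__},
    }
    if extra:
        manifest.update(extra)
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return path


def export_embeddings(outdir, cell_ids, Zc, gene_ids=None, Zg=None) -> dict:
    """Tab-separated embedding tables: cells always, genes when given."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    d = Zc.shape[1]
    cols = [f"dim_{i}" for i in range(d)]
    out = {"cells": outdir / "cell_embeddings.tsv"}
    df = pd.DataFrame(Zc, columns=cols)
    df.insert(0, "cell_id", cell_ids)
    df.to_csv(out["cells"], sep="\t", index=False, float_format="%.6g")
    if Zg is not None and gene_ids is not None:
        V = len(gene_ids)
        df = pd.DataFrame(Zg, columns=cols)
        df.insert(0, "gene_id", np.tile(gene_ids, len(cell_ids)))
        df.insert(0, "cell_id", np.repeat(cell_ids, V))
        out["genes"] = outdir / "gene_embeddings.tsv"
        df.to_csv(out["genes"], sep="\t", index=False, float_format="%.6g")
    return out
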