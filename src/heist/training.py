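"""Pretraining: spatial patch batching, optimization, early stopping.

Batches are spatial neighbourhoods, not random cell subsets — each patch
is a seeded anchor cell plus its breadth-first spatial neighbourhood,
truncated at ``patch_cells`` cells, so every batch carries
microenvironmental context.  Training minimises the combined
contrastive + masked-autoencoding + orthogonality loss with Adam
(including the learnable balance γ), and stops early on validation loss.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import _tensor as T
from .graph_construction import (ExpressionMatrix, HierarchicalGraph,
                                 SpatialCellGraph)
from .model import (ModelConfig, GraphTensors, init_params, flatten_params,
                    encode, decode)
from .objectives import (ContrastiveConfig, positive_negative_sets,
                         contrastive_loss, make_masks, apply_masks,
                         mae_loss, ortho_reg, total_loss)

__all__ = ["TrainConfig", "TrainState", "Checkpoint", "make_patches",
           "pretrain", "save_checkpoint", "load_checkpoint",
           "default_radius", "induced_subgraph"]


@dataclass(frozen=True)
class TrainConfig:
    max_epochs: int = 10
    patience: int = 3
    learning_rate: float = 1e-3
    patch_cells: int = 512
    optimizer: str = "adam"
    seed: int = 0
    validation_fraction: float = 0.1
    mask_rates: tuple = (0.1, 0.3)     # (cell-coordinate rate, gene rate)
    ortho_lambda: float = 1e-3
    clip_norm: float = 5.0

    def __post_init__(self):
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")
        if self.patch_cells < 32:
            raise ValueError("patch_cells must be >= 32")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")


@dataclass
class TrainState:
    step: int = 0
    epoch: int = 0
    best_val_loss: float = np.inf
    epochs_since_best: int = 0


@dataclass
class Checkpoint:
    """Best parameter snapshot plus the config needed to rebuild the model."""

    model_cfg: ModelConfig
    params_flat: dict                  # name -> np.ndarray
    gamma: float
    best_val_loss: float
    seed: int
    history: pd.DataFrame = field(repr=False, default=None)

    def materialize(self):
        """Parameter dict with tensors set to the checkpointed values."""
        params = init_params(self.model_cfg)
        flat = flatten_params(params)
        for name, arr in self.params_flat.items():
            flat[name].data = np.asarray(arr, dtype=np.float32).copy()
        return params


def default_radius(cg: SpatialCellGraph) -> float:
    """Contrastive radius: twice the median spatial-edge length."""
    e = cg.edges
    if e.shape[0] == 0:
        return 1.0
    lengths = np.linalg.norm(cg.positions[e[:, 0]] - cg.positions[e[:, 1]], axis=1)
    return 2.0 * float(np.median(lengths))


# ---------------------------------------------------------------------------
# spatial patches
# ---------------------------------------------------------------------------

def induced_subgraph(hg: HierarchicalGraph, cells: np.ndarray) -> HierarchicalGraph:
    """Induced sub-hierarchical-graph on the given (sorted) cell indices."""
    cells = np.asarray(sorted(cells), dtype=np.int64)
    remap = -np.ones(hg.n_cells, dtype=np.int64)
    remap[cells] = np.arange(cells.size)
    e = hg.cell_graph.edges
    keep = (remap[e[:, 0]] >= 0) & (remap[e[:, 1]] >= 0)
    sub_edges = np.stack([remap[e[keep, 0]], remap[e[keep, 1]]], axis=1)
    types = hg.cell_graph.cell_types[cells]
    cg = SpatialCellGraph(positions=hg.cell_graph.positions[cells],
                          edges=sub_edges, cell_types=types)
    networks = {t: hg.gene_networks[t] for t in np.unique(types)}
    expr = ExpressionMatrix(values=hg.expression.values[cells],
                            gene_ids=hg.expression.gene_ids,
                            cell_ids=hg.expression.cell_ids[cells],
                            layer_tag=hg.expression.layer_tag)
    return HierarchicalGraph(cell_graph=cg, gene_networks=networks,
                             expression=expr)


def make_patches(hg: HierarchicalGraph, patch_cells: int, seed: int = 0):
    """Seeded anchors + BFS neighbourhoods until every cell is covered.

    Disconnected components smaller than ``patch_cells`` become whole-
    component patches.  Returns (list of HierarchicalGraph patches,
    list of original-index arrays).
    """
    if patch_cells > hg.n_cells:
        patch_cells = hg.n_cells
    rng = np.random.default_rng(seed)
    n = hg.n_cells
    adj = [[] for _ in range(n)]
    for i, j in hg.cell_graph.edges:
        adj[i].append(j)
        adj[j].append(i)

    uncovered = np.ones(n, dtype=bool)
    patches, index_sets = [], []
    while uncovered.any():
        candidates = np.where(uncovered)[0]
        anchor = int(rng.choice(candidates))
        seen = {anchor}
        frontier = [anchor]
        while frontier and len(seen) < patch_cells:
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if v not in seen:
                        seen.add(v)
                        nxt.append(v)
                        if len(seen) >= patch_cells:
                            break
                if len(seen) >= patch_cells:
                    break
            frontier = nxt
        cells = np.asarray(sorted(seen), dtype=np.int64)
        uncovered[cells] = False
        patches.append(induced_subgraph(hg, cells))
        index_sets.append(cells)
    return patches, index_sets


# ---------------------------------------------------------------------------
# pretraining loop
# ---------------------------------------------------------------------------

def _patch_loss(patch, gt, sets, contrastive_cfg, params, gamma, model_cfg,
                train_cfg, mask_seed, rng):
    masks = make_masks(patch, rates=train_cfg.mask_rates, seed=mask_seed)
    Xm, Pm = apply_masks(patch, masks)
    state = encode(patch, model_cfg, params, gt=gt, expression=Xm, positions=Pm)
    recon = decode(gt, state, params["decoder"])
    l_con = contrastive_loss(state, sets, patch, contrastive_cfg, rng=rng)
    l_mae = mae_loss(recon, patch, masks)
    l_orth = ortho_reg(state.cell_emb, state.gene_emb)
    return total_loss(l_con, l_mae, l_orth, gamma, lam=train_cfg.ortho_lambda)


def pretrain(hg: HierarchicalGraph, model_cfg: ModelConfig | None = None,
             obj_cfg: ContrastiveConfig | None = None,
             train_cfg: TrainConfig | None = None) -> Checkpoint:
    """Full pretraining run; returns the best checkpoint with history."""
    model_cfg = model_cfg or ModelConfig()
    train_cfg = train_cfg or TrainConfig()
    rng = np.random.default_rng(train_cfg.seed)

    patches, _ = make_patches(hg, train_cfg.patch_cells,
                              seed=int(rng.integers(2 ** 31)))
    n_val = max(1, int(round(train_cfg.validation_fraction * len(patches))))
    order = rng.permutation(len(patches))
    if len(patches) == 1:
        train_ids, val_ids = [0], [0]
    else:
        val_ids = list(order[:n_val])
        train_ids = list(order[n_val:]) or [int(order[-1])]

    prepared = []
    for p in patches:
        gt = GraphTensors.from_graph(p)
        if obj_cfg is None or obj_cfg.radius is None:
            r = default_radius(p.cell_graph)
            base = obj_cfg or ContrastiveConfig(radius=r)
            cfg_p = ContrastiveConfig(**{**asdict(base), "radius": r})
        else:
            cfg_p = obj_cfg
        sets = positive_negative_sets(p.cell_graph, cfg_p)
        prepared.append((p, gt, sets, cfg_p))

    params = init_params(model_cfg, np.random.default_rng(model_cfg.seed))
    gamma = T.parameter(np.array(0.0))
    leaves = list(flatten_params(params).values()) + [gamma]
    opt = T.Adam(leaves, lr=train_cfg.learning_rate,
                 clip_norm=train_cfg.clip_norm)

    state = TrainState()
    history = []
    best_flat = {k: v.data.copy() for k, v in flatten_params(params).items()}
    best_gamma = float(gamma.data)

    for epoch in range(1, train_cfg.max_epochs + 1):
        state.epoch = epoch
        for pid in rng.permutation(train_ids):
            patch, gt, sets, cfg_p = prepared[pid]
            mask_seed = int(rng.integers(2 ** 31))
            loss, report = _patch_loss(patch, gt, sets, cfg_p, params, gamma,
                                       model_cfg, train_cfg, mask_seed, rng)
            if not np.isfinite(report.total):
                warnings.warn("training diverged (non-finite loss); "
                              "keeping last good checkpoint")
                hist = pd.DataFrame(history)
                return Checkpoint(model_cfg, best_flat, best_gamma,
                                  state.best_val_loss, train_cfg.seed, hist)
            opt.zero_grad()
            loss.backward()
            opt.step()
            state.step += 1
            history.append({"step": state.step, "epoch": epoch, "split": "train",
                            **{k: getattr(report, k) for k in
                               ("l_contrastive", "l_mae", "l_ortho", "gamma",
                                "total")}})

        # validation (forward only; fixed epoch-keyed mask seed)
        val_total = 0.0
        for pid in val_ids:
            patch, gt, sets, cfg_p = prepared[pid]
            with T.no_grad():
                _, report = _patch_loss(patch, gt, sets, cfg_p, params, gamma,
                                        model_cfg, train_cfg,
                                        mask_seed=10_000 + epoch,
                                        rng=np.random.default_rng(10_000 + epoch))
            val_total += report.total
        val_total /= len(val_ids)
        history.append({"step": state.step, "epoch": epoch, "split": "val",
                        "l_contrastive": np.nan, "l_mae": np.nan,
                        "l_ortho": np.nan, "gamma": float(gamma.data),
                        "total": val_total})

        if val_total < state.best_val_loss:
            state.best_val_loss = val_total
            state.epochs_since_best = 0
            best_flat = {k: v.data.copy()
                         for k, v in flatten_params(params).items()}
            best_gamma = float(gamma.data)
        else:
            state.epochs_since_best += 1
        if state.epochs_since_best >= train_cfg.patience:
            break

    return Checkpoint(model_cfg, best_flat, best_gamma, state.best_val_loss,
                      train_cfg.seed, pd.DataFrame(history))


# ---------------------------------------------------------------------------
# checkpoint persistence
# ---------------------------------------------------------------------------

def save_checkpoint(ckpt: Checkpoint, outdir) -> dict:
    from pathlib import Path
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    np.savez(outdir / "params.npz", gamma=np.asarray(ckpt.gamma),
             **ckpt.params_flat)
    manifest = {
        "model_config": asdict(ckpt.model_cfg),
        "best_val_loss": float(ckpt.best_val_loss),
        "seed": int(ckpt.seed),
        "param_shapes": {k: list(v.shape) for k, v in ckpt.params_flat.items()},
    }
    (outdir / "checkpoint.json").write_text(json.dumps(manifest, indent=1,
                                                       sort_keys=True))
    if ckpt.history is not None:
        ckpt.history.to_csv(outdir / "history.csv", index=False)
    return {"params": str(outdir / "params.npz"),
            "manifest": str(outdir / "checkpoint.json")}


def load_checkpoint(outdir) -> Checkpoint:
    from pathlib import Path
    outdir = Path(outdir)
    manifest = json.loads((outdir / "checkpoint.json").read_text())
    with np.load(outdir / "params.npz") as z:
        arrays = {k: z[k] for k in z.files}
    gamma = float(arrays.pop("gamma"))
    cfg = ModelConfig(**manifest["model_config"])
    hist_path = outdir / "history.csv"
    history = pd.read_csv(hist_path) if hist_path.exists() else None
    return Checkpoint(cfg, arrays, gamma, manifest["best_val_loss"],
                      manifest["seed"], history)
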