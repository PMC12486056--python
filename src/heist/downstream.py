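"""Downstream evaluation on frozen embeddings.

Four heads: cell clustering scored by NMI against labels, cell-type
annotation with an MLP head scored by macro-F1, tissue-level
classification from mean cell embeddings scored by AUROC under
leave-one-tissue-out cross-validation, and gene imputation (zero-shot or
decoder fine-tuning) scored by Pearson correlation on masked entries
with sparsity-stratified masking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import _tensor as T
from .graph_construction import HierarchicalGraph
from .model import GraphTensors, encode, decode, flatten_params
from .training import Checkpoint

__all__ = ["TaskResult", "cluster_cells", "annotate_cells", "classify_tissue",
           "impute_genes", "embed_graph", "mean_imputation_baseline"]

_METRIC_RANGES = {"NMI": (0, 1), "macroF1": (0, 1), "AUROC": (0, 1),
                  "Pearson": (-1, 1)}


@dataclass
class TaskResult:
    task: str
    metric_name: str
    value: float
    split_descriptor: str = ""
    seed: int = 0

    def __post_init__(self):
        lo, hi = _METRIC_RANGES[self.metric_name]
        if not (lo - 1e-9 <= self.value <= hi + 1e-9):
            raise ValueError(f"{self.metric_name}={self.value} out of range")


def embed_graph(hg: HierarchicalGraph, ckpt: Checkpoint):
    """Frozen-encoder embeddings (Zc, Zg) for a whole graph as arrays."""
    params = ckpt.materialize()
    state = encode(hg, ckpt.model_cfg, params)
    return state.cell_emb.data.copy(), state.gene_emb.data.copy()


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def cluster_cells(Zc: np.ndarray, true_labels, method: str = "leiden",
                  seed: int = 0, resolution: float = 1.0,
                  n_clusters: int | None = None,
                  k_neighbors: int = 15) -> TaskResult:
    """Leiden (default) or spectral clustering of embeddings, scored by NMI."""
    from sklearn.metrics import normalized_mutual_info_score

    true_labels = np.asarray(true_labels)
    n = Zc.shape[0]
    if len(true_labels) != n:
        raise ValueError("one label per embedded cell required")

    if method == "leiden":
        import igraph
        import leidenalg
        from sklearn.neighbors import NearestNeighbors
        k = min(k_neighbors, n - 1)
        nn = NearestNeighbors(n_neighbors=k + 1).fit(Zc)
        _, idx = nn.kneighbors(Zc)
        src = np.repeat(np.arange(n), k)
        pairs = np.unique(np.sort(np.stack([src, idx[:, 1:].ravel()], 1), 1), axis=0)
        g = igraph.Graph(n=n, edges=pairs.tolist())
        part = leidenalg.find_partition(
            g, leidenalg.RBConfigurationVertexPartition,
            resolution_parameter=resolution, seed=seed)
        pred = np.asarray(part.membership)
    elif method == "spectral":
        from sklearn.cluster import SpectralClustering
        k = n_clusters if n_clusters is not None else len(np.unique(true_labels))
        pred = SpectralClustering(n_clusters=k, random_state=seed,
                                  affinity="nearest_neighbors",
                                  n_neighbors=min(k_neighbors, n - 1)
                                  ).fit_predict(Zc)
    else:
        raise ValueError("method must be 'leiden' or 'spectral'")

    if len(np.unique(pred)) == 1:
        warnings.warn("clustering produced a single cluster")
    nmi = float(normalized_mutual_info_score(true_labels, pred))
    return TaskResult("clustering", "NMI", nmi,
                      split_descriptor=f"method={method}", seed=seed)


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def annotate_cells(Zc: np.ndarray, labels, split_seed: int = 0) -> TaskResult:
    """2-layer MLP head on frozen embeddings; macro-F1 on a held-out 20%."""
    from sklearn.metrics import f1_score
    from sklearn.model_selection import train_test_split
    from sklearn.neural_network import MLPClassifier

    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("annotation needs at least 2 classes")
    try:
        Xtr, Xte, ytr, yte = train_test_split(
            Zc, labels, test_size=0.2, random_state=split_seed, stratify=labels)
    except ValueError:
        warnings.warn("stratified split failed (a class is too small); "
                      "falling back to a plain shuffled split")
        Xtr, Xte, ytr, yte = train_test_split(
            Zc, labels, test_size=0.2, random_state=split_seed)
    if set(np.unique(yte)) - set(np.unique(ytr)):
        warnings.warn("a class is absent from the training split; re-splitting")
        Xtr, Xte, ytr, yte = train_test_split(
            Zc, labels, test_size=0.2, random_state=split_seed + 1,
            stratify=labels)
    clf = MLPClassifier(hidden_layer_sizes=(64,), max_iter=500,
                        random_state=split_seed)
    clf.fit(Xtr, ytr)
    f1 = float(f1_score(yte, clf.predict(Xte), average="macro"))
    return TaskResult("annotation", "macroF1", f1,
                      split_descriptor="stratified-80/20", seed=split_seed)


# ---------------------------------------------------------------------------
# tissue classification
# ---------------------------------------------------------------------------

def classify_tissue(tissue_embeddings, tissue_labels,
                    split_seed: int = 0) -> TaskResult:
    """AUROC of an MLP on mean cell embeddings, leave-one-tissue-out CV."""
    from sklearn.metrics import roc_auc_score
    from sklearn.neural_network import MLPClassifier

    means = np.stack([np.asarray(z).mean(axis=0) for z in tissue_embeddings])
    y = np.asarray(tissue_labels)
    n = means.shape[0]
    if n < 4:
        raise ValueError("tissue classification needs at least 4 tissues")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("tissue classification expects exactly 2 classes")
    if counts.min() < 2:
        raise ValueError("a class with a single tissue leaves AUROC undefined "
                         "under leave-one-out cross-validation")

    pos = classes[1]
    probs = np.empty(n)
    for i in range(n):
        mask = np.ones(n, bool)
        mask[i] = False
        clf = MLPClassifier(hidden_layer_sizes=(32,), max_iter=500,
                            random_state=split_seed)
        clf.fit(means[mask], y[mask])
        j = list(clf.classes_).index(pos)
        probs[i] = clf.predict_proba(means[i:i + 1])[0, j]
    auc = float(roc_auc_score((y == pos).astype(int), probs))
    return TaskResult("tissue_classification", "AUROC", auc,
                      split_descriptor="leave-one-tissue-out", seed=split_seed)


# ---------------------------------------------------------------------------
# gene imputation
# ---------------------------------------------------------------------------

def sparsity_strata(X: np.ndarray, n_bins: int = 4) -> np.ndarray:
    """Quartile bins of per-gene zero-fraction (rank-based, always n_bins)."""
    zero_frac = (X <= 1e-12).mean(axis=0)
    order = np.argsort(np.argsort(zero_frac, kind="stable"), kind="stable")
    return (order * n_bins // X.shape[1]).astype(np.int64)


def _stratified_entry_mask(X: np.ndarray, mask_fraction: float,
                           seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    strata = sparsity_strata(X)
    mask = np.zeros(X.shape, dtype=bool)
    for b in np.unique(strata):
        genes = np.where(strata == b)[0]
        entries = X.shape[0] * genes.size
        if entries == 0:
            warnings.warn(f"sparsity bin {b} has no maskable entries; skipped")
            continue
        k = int(round(mask_fraction * entries))
        flat = rng.choice(entries, size=k, replace=False)
        mask[flat // genes.size, genes[flat % genes.size]] = True
    return mask


def _pearson(pred: np.ndarray, truth: np.ndarray) -> float:
    if pred.std() < 1e-12 or truth.std() < 1e-12:
        warnings.warn("constant predictions or targets; Pearson reported as 0")
        return 0.0
    return float(np.corrcoef(pred, truth)[0, 1])


def mean_imputation_baseline(X: np.ndarray, mask: np.ndarray) -> float:
    """Pearson r of per-gene-mean imputation computed from unmasked entries."""
    pred = np.zeros(X.shape)
    for g in range(X.shape[1]):
        vis = ~mask[:, g]
        pred[:, g] = X[vis, g].mean() if vis.any() else 0.0
    return _pearson(pred[mask], X[mask])


def impute_genes(hg: HierarchicalGraph, ckpt: Checkpoint,
                 mask_fraction: float = 0.1, mode: str = "zero_shot",
                 seed: int = 0, fine_tune_steps: int = 150,
                 fine_tune_lr: float = 3e-3) -> TaskResult:
    """Predict masked expression entries; Pearson r pooled over the mask.

    Genes are stratified into sparsity quartiles and entries masked per
    stratum.  ``zero_shot`` runs the frozen encoder + decoder;
    ``fine_tune`` retrains the decoder only (encoder frozen), minimising
    reconstruction error on unmasked entries.
    """
    if mode not in ("zero_shot", "fine_tune"):
        raise ValueError("mode must be 'zero_shot' or 'fine_tune'")
    X = hg.expression.values
    mask = _stratified_entry_mask(X, mask_fraction, seed)
    Xm = X.copy()
    Xm[mask] = 0.0

    params = ckpt.materialize()
    gt = GraphTensors.from_graph(hg)
    state = encode(hg, ckpt.model_cfg, params, gt=gt, expression=Xm)

    if mode == "fine_tune":
        # freeze embeddings; only decoder parameters receive gradients.
        # steps cycle spatial patches — the decoder is graph-size
        # independent, so patch-level steps converge at a fraction of
        # the full-graph cost
        from .model import EmbeddingState
        from .training import make_patches
        zc_data = state.cell_emb.data.copy()
        zg_data = state.gene_emb.data.copy()
        V = state.n_genes
        patches, index_sets = make_patches(hg, patch_cells=512, seed=seed)
        prepared = []
        for patch, cells in zip(patches, index_sets):
            pgt = GraphTensors.from_graph(patch)
            rows = (cells[:, None] * V + np.arange(V)[None, :]).ravel()
            frozen_p = EmbeddingState(T.Tensor(zc_data[cells]),
                                      T.Tensor(zg_data[rows]),
                                      len(cells), V)
            pvis = (~mask[cells]).astype(np.float64)
            prepared.append((pgt, frozen_p, pvis, max(pvis.sum(), 1.0),
                             X[cells]))
        dec_params = list(flatten_params(params["decoder"]).values())
        opt = T.Adam(dec_params, lr=fine_tune_lr, clip_norm=5.0)
        for step in range(fine_tune_steps):
            pgt, frozen_p, pvis, n_vis, Xp = prepared[step % len(prepared)]
            recon = decode(pgt, frozen_p, params["decoder"])
            diff = (recon.expression_hat - Xp) * pvis
            loss = T.tsum(T.square(diff)) * (1.0 / n_vis)
            opt.zero_grad()
            loss.backward()
            opt.step()
        state = EmbeddingState(T.Tensor(zc_data), T.Tensor(zg_data),
                               state.n_cells, V)

    recon = decode(gt, state, params["decoder"])
    pred = recon.expression_hat.data
    r = _pearson(pred[mask], X[mask])
    return TaskResult("imputation", "Pearson", r,
                      split_descriptor=f"mode={mode},frac={mask_fraction}",
                      seed=seed)
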