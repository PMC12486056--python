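"""Self-supervised pretraining objectives.

Four components: a spatially-aware contrastive loss with three terms
(cell–cell, gene–gene, cell–gene), a masked-autoencoding reconstruction
loss over hidden coordinates and gene values, an orthogonality penalty
on the embedding Gram matrices, and their combination with a learnable
sigmoid balance.

Positive cell pairs are same-type cells within a spatial radius r;
negatives for cell i are different-type cells within r.  The printed
per-pair terms are log-softmax ratios; they are implemented in negated
(InfoNCE) form so minimisation pulls positives together.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from . import _tensor as T
from ._tensor import Tensor
from .graph_construction import HierarchicalGraph, SpatialCellGraph
from .model import EmbeddingState

__all__ = [
    "ContrastiveConfig", "MaskSpec", "LossReport",
    "positive_negative_sets", "contrastive_loss",
    "make_masks", "apply_masks", "mae_loss", "ortho_reg", "total_loss",
]


@dataclass(frozen=True)
class ContrastiveConfig:
    """Radius, temperature and similarity for the contrastive terms.

    The temperature here is the contrastive τ — distinct from the MI
    threshold used in graph construction.  Subsampling caps keep the
    gene–gene sum (nominally over |V|²) tractable per batch.
    """

    radius: float | None = None   # None = twice the median spatial-edge length
    temperature: float = 0.1
    similarity: str = "cosine"          # "cosine" | "dot"
    max_cell_pairs: int = 128
    gene_pairs_per_cell_pair: int = 64
    seed: int = 0

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.radius is not None and self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.similarity not in ("cosine", "dot"):
            raise ValueError("similarity must be 'cosine' or 'dot'")


@dataclass
class MaskSpec:
    """Boolean masks driving the MAE objective (True = hidden)."""

    cell_mask: np.ndarray    # (|C|,) coordinates hidden
    gene_masks: np.ndarray   # (|C|, |V|) expression entries hidden
    rates: tuple
    seed: int


@dataclass
class LossReport:
    l_contrastive: float
    l_mae: float
    l_ortho: float
    gamma: float
    total: float

    def recombine(self, lam: float) -> float:
        s = 1.0 / (1.0 + np.exp(-self.gamma))
        return s * self.l_contrastive + (1.0 - s) * self.l_mae + lam * self.l_ortho


# ---------------------------------------------------------------------------
# positive / negative sets
# ---------------------------------------------------------------------------

def positive_negative_sets(cg: SpatialCellGraph, cfg: ContrastiveConfig):
    """𝒫 = same-type pairs within r;  𝒩_i = different-type cells within r.

    Computed with a KD-tree; equal to brute-force enumeration.
    Returns (pairs (n,2) int array, list of neighbour arrays per cell).
    """
    if cfg.radius is None:
        raise ValueError("resolve ContrastiveConfig.radius before building sets")
    tree = cKDTree(cg.positions)
    pairs = tree.query_pairs(cfg.radius, output_type="ndarray")
    types = np.asarray(cg.cell_types)
    n = cg.n_cells
    same = types[pairs[:, 0]] == types[pairs[:, 1]] if pairs.size else np.empty(0, bool)
    positives = pairs[same] if pairs.size else pairs.reshape(0, 2)
    negatives = [[] for _ in range(n)]
    if pairs.size:
        for i, j in pairs[~same]:
            negatives[i].append(j)
            negatives[j].append(i)
    negatives = [np.asarray(sorted(v), dtype=np.int64) for v in negatives]
    if positives.shape[0] == 0:
        warnings.warn("no positive pairs within the contrastive radius; "
                      "the contrastive term will be skipped")
    return positives, negatives


def _similarity_rows(a: Tensor, b: Tensor, kind: str) -> Tensor:
    if kind == "cosine":
        a, b = T.l2_normalize(a), T.l2_normalize(b)
    return T.tsum(a * b, axis=1)


def _info_nce(pos: Tensor, neg: Tensor, neg_seg: np.ndarray, n_pairs: int) -> Tensor:
    """Mean over pairs of -log( e^pos / (e^pos + Σ_{neg in pair} e^neg) ).

    Scores are already divided by the temperature.  Pairs with no
    negatives contribute exactly 0.
    """
    shift = pos.data.copy()
    if neg_seg.size:
        mx = T.segment_max_const(neg.data, neg_seg, n_pairs)
        shift = np.maximum(shift, np.where(np.isfinite(mx), mx, -np.inf))
    e_pos = T.exp(pos - shift)
    if neg_seg.size:
        neg_sum = T.segment_sum(T.exp(neg - shift[neg_seg]), neg_seg, n_pairs)
    else:
        neg_sum = T.Tensor(np.zeros(n_pairs))
    terms = T.log(e_pos + neg_sum) - (pos - shift)
    return T.tmean(terms)


def contrastive_loss(state: EmbeddingState, sets, hg: HierarchicalGraph,
                     cfg: ContrastiveConfig,
                     rng: np.random.Generator | None = None) -> Tensor:
    """Sum of the three contrastive terms, each a mean over sampled pairs.

    c↔c compares cell rows; g↔g compares gene rows of co-expression-
    adjacent gene pairs across a positive cell pair against non-adjacent
    genes in negative cells; c↔g compares a cell row with the aggregated
    gene row of its positive partner against aggregates of negative
    cells.  Sampling is seeded, so the loss is reproducible.
    """
    positives, negatives = sets
    if positives.shape[0] == 0:
        return T.Tensor(0.0)
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    tau = cfg.temperature
    C, V = state.n_cells, state.n_genes
    Zc, Zg = state.cell_emb, state.gene_emb

    if positives.shape[0] > cfg.max_cell_pairs:
        sel = rng.choice(positives.shape[0], cfg.max_cell_pairs, replace=False)
        positives = positives[np.sort(sel)]
    n_pairs = positives.shape[0]
    ai, pj = positives[:, 0], positives[:, 1]

    neg_flat, neg_seg = [], []
    for p, i in enumerate(ai):
        ks = negatives[i]
        neg_flat.append(ks)
        neg_seg.append(np.full(ks.size, p, dtype=np.int64))
    neg_flat = np.concatenate(neg_flat) if neg_flat else np.empty(0, np.int64)
    neg_seg = np.concatenate(neg_seg) if neg_seg else np.empty(0, np.int64)

    # ---- cell <-> cell ----
    pos_cc = _similarity_rows(T.take(Zc, ai), T.take(Zc, pj), cfg.similarity) * (1 / tau)
    anchors_rep = T.take(Zc, ai[neg_seg] if neg_seg.size else np.empty(0, np.int64))
    neg_cells = T.take(Zc, neg_flat)
    neg_cc = _similarity_rows(anchors_rep, neg_cells, cfg.similarity) * (1 / tau)
    l_cc = _info_nce(pos_cc, neg_cc, neg_seg, n_pairs)

    # ---- cell <-> gene (aggregated gene rows) ----
    if state.gene_agg is not None:
        zbar = state.gene_agg
    else:
        zbar = T.tmean(T.reshape(Zg, (C, V, Zg.shape[1])), axis=1)
    pos_cg = _similarity_rows(T.take(Zc, ai), T.take(zbar, pj), cfg.similarity) * (1 / tau)
    neg_cg = _similarity_rows(anchors_rep, T.take(zbar, neg_flat),
                              cfg.similarity) * (1 / tau)
    l_cg = _info_nce(pos_cg, neg_cg, neg_seg, n_pairs)

    # ---- gene <-> gene ----
    types = np.asarray(hg.cell_graph.cell_types)
    type_order = sorted(hg.gene_networks, key=str)
    tcode_map = {t: c for c, t in enumerate(type_order)}
    tcode = np.array([tcode_map[t] for t in types], dtype=np.int64)
    adj = np.zeros((len(type_order), V, V), dtype=bool)
    for t, net in hg.gene_networks.items():
        if net.edges.size:
            c = tcode_map[t]
            adj[c, net.edges[:, 0], net.edges[:, 1]] = True
            adj[c, net.edges[:, 1], net.edges[:, 0]] = True

    g_anchor, g_pos = [], []
    gneg_anchor, gneg_other, gneg_seg = [], [], []
    term_id = 0
    for idx in range(n_pairs):
        i, j = ai[idx], pj[idx]
        net = hg.gene_networks[types[i]]
        if net.edges.shape[0] == 0:
            continue
        m = min(cfg.gene_pairs_per_cell_pair, net.edges.shape[0])
        rows = rng.choice(net.edges.shape[0], m, replace=False)
        p, q = net.edges[rows, 0], net.edges[rows, 1]
        g_anchor.append(i * V + p)
        g_pos.append(j * V + q)
        ks = negatives[i]
        if ks.size:
            # one non-adjacent gene r per (term, negative cell), drawn by
            # seeded rejection against the negative cell's network
            p_rep = np.repeat(p, ks.size)
            k_rep = np.tile(ks, m)
            cand = rng.integers(V, size=p_rep.size)
            for _ in range(4):
                bad = (cand == p_rep) | adj[tcode[k_rep], p_rep, cand]
                if not bad.any():
                    break
                cand[bad] = rng.integers(V, size=int(bad.sum()))
            gneg_anchor.append(np.repeat(i * V + p, ks.size))
            gneg_other.append(k_rep * V + cand)
            gneg_seg.append(term_id + np.repeat(np.arange(m), ks.size))
        term_id += m
    if term_id:
        g_anchor = np.concatenate(g_anchor)
        g_pos = np.concatenate(g_pos)
        pos_gg = _similarity_rows(T.take(Zg, g_anchor), T.take(Zg, g_pos),
                                  cfg.similarity) * (1 / tau)
        if gneg_seg:
            gneg_seg = np.concatenate(gneg_seg).astype(np.int64)
            neg_gg = _similarity_rows(
                T.take(Zg, np.concatenate(gneg_anchor)),
                T.take(Zg, np.concatenate(gneg_other)),
                cfg.similarity) * (1 / tau)
        else:
            gneg_seg = np.empty(0, np.int64)
            neg_gg = T.Tensor(np.zeros(0))
        l_gg = _info_nce(pos_gg, neg_gg, gneg_seg, term_id)
    else:
        l_gg = T.Tensor(0.0)

    return l_cc + l_cg + l_gg


# ---------------------------------------------------------------------------
# masked autoencoding
# ---------------------------------------------------------------------------

def make_masks(hg: HierarchicalGraph, rates=(0.1, 0.3), seed: int = 0) -> MaskSpec:
    """Independent Bernoulli masks over cell coordinates and gene entries."""
    cell_rate, gene_rate = rates
    for r in rates:
        if not (0.0 < r < 1.0):
            raise ValueError("mask rates must be in (0, 1)")
    rng = np.random.default_rng(seed)
    C, V = hg.n_cells, hg.n_genes
    cell_mask = rng.uniform(size=C) < cell_rate
    gene_masks = rng.uniform(size=(C, V)) < gene_rate
    if not cell_mask.any() and not gene_masks.any():
        warnings.warn("all masks are empty; the MAE loss will be 0")
    return MaskSpec(cell_mask=cell_mask, gene_masks=gene_masks,
                    rates=tuple(rates), seed=seed)


def apply_masks(hg: HierarchicalGraph, masks: MaskSpec):
    """Masked inputs for the encoder: hidden entries are replaced by zero."""
    X = hg.expression.values.copy()
    X[masks.gene_masks] = 0.0
    P = hg.cell_graph.positions.copy()
    P[masks.cell_mask] = 0.0
    return X, P


def normalized_positions(P: np.ndarray) -> np.ndarray:
    span = P.max(axis=0) - P.min(axis=0)
    return (P - P.min(axis=0)) / np.maximum(span, 1e-12)


def mae_loss(recon, hg: HierarchicalGraph, masks: MaskSpec) -> Tensor:
    """MSE restricted to masked entries.

    Positions are min-max normalized to the unit square before the MSE
    so the coordinate and expression terms share a scale; the position
    term is the mean squared Euclidean error over masked cells, and the
    expression term averages each cell's masked-entry MSE over all cells.
    """
    C, V = hg.n_cells, hg.n_genes
    if not masks.cell_mask.any() and not masks.gene_masks.any():
        warnings.warn("MAE loss evaluated over an empty mask set; returning 0")
        return T.Tensor(0.0)

    total = T.Tensor(0.0)
    if masks.cell_mask.any():
        Pn = normalized_positions(hg.cell_graph.positions)
        w = masks.cell_mask.astype(np.float64)[:, None]
        diff = (recon.positions_hat - Pn) * w
        total = total + T.tsum(T.square(diff)) * (1.0 / masks.cell_mask.sum())

    if masks.gene_masks.any():
        Xm = masks.gene_masks.astype(np.float64)
        diff = (recon.expression_hat - hg.expression.values) * Xm
        counts = np.maximum(masks.gene_masks.sum(axis=1), 1)
        per_cell = T.tsum(T.square(diff), axis=1) / counts
        total = total + T.tsum(per_cell) * (1.0 / C)
    return total


# ---------------------------------------------------------------------------
# orthogonality regularization and total loss
# ---------------------------------------------------------------------------

def ortho_reg(Zc: Tensor, Zg: Tensor) -> Tensor:
    """‖I − Z̃cᵀZ̃c‖²_F + ‖I − Z̃gᵀZ̃g‖²_F with columns scaled to unit norm.

    Column scaling makes the identity target attainable and the penalty
    scale independent of the number of rows.
    """
    def term(Z: Tensor) -> Tensor:
        d = Z.shape[1]
        norms = T.sqrt(T.tsum(T.square(Z), axis=0, keepdims=True) + 1e-12)
        Zn = Z / norms
        G = T.matmul(T.transpose(Zn), Zn)
        eye = np.eye(d, dtype=np.float32)
        return T.tsum(T.square(T.Tensor(eye) - G))

    return term(Zc) + term(Zg)


def total_loss(l_contrastive: Tensor, l_mae: Tensor, l_ortho: Tensor,
               gamma: Tensor, lam: float = 1e-3):
    """σ(γ)·contrastive + (1−σ(γ))·mae + λ·ortho, with trainable γ.

    Returns (scalar loss tensor, LossReport).
    """
    for name, part in (("contrastive", l_contrastive), ("mae", l_mae),
                       ("ortho", l_ortho)):
        if not np.isfinite(part.data).all():
            raise FloatingPointError(f"non-finite loss component: {name}")
    s = T.sigmoid(gamma)
    total = s * l_contrastive + (1.0 - s) * l_mae + lam * l_ortho
    report = LossReport(
        l_contrastive=float(l_contrastive.data),
        l_mae=float(l_mae.data),
        l_ortho=float(l_ortho.data),
        gamma=float(gamma.data),
        total=float(total.data),
    )
    return total, report
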