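"""Hierarchical graph-transformer encoder and GIN decoder.

The encoder alternates, L times, an intra-level step (multi-head
attention restricted to graph neighbours, separately on the spatial cell
graph and on each cell's gene co-expression graph) with a cross-level
step (a directional, row-wise attention gate that lets each gene row see
its parent cell and each cell see the aggregate of its gene rows).
Gene node states are per cell even though the co-expression topology is
shared per type; because gene sets are small, the gene level runs as
dense masked attention batched over cells (BLAS-friendly), while the
spatial level uses sparse edge-list attention.

Embeddings are initialized from sinusoidal positional encodings: gene
rows encode the within-cell expression rank, cell rows encode min-max
normalized spatial coordinates; raw values are added directly to fixed
coordinates without a learned map.

The decoder is a 3-layer graph isomorphism network (GIN) — one stack on
the cell graph predicting 2-D positions, one on the gene graphs
predicting per-gene expression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _tensor as T
from ._tensor import Tensor
from .graph_construction import HierarchicalGraph

__all__ = [
    "ModelConfig", "EmbeddingState", "Reconstruction", "GraphTensors",
    "init_embeddings", "init_params", "intra_level_step",
    "cross_message_passing", "cross_level_step", "encode", "decode",
    "sinusoidal_encoding",
]

_NEG_BIG = -1e9


@dataclass(frozen=True)
class ModelConfig:
    d: int = 64
    L: int = 2
    heads: int = 4
    agg: str = "mean"                 # "mean" | "diffpool"
    cross_residual: bool = True
    cross_level: bool = True          # False = ablate cross-level messages
    ff_mult: int = 1
    pe_coord_scale: float = 4.0       # spreads unit-square coords over PE bands
    cell_raw_expression: bool = True  # add raw expression into cell rows
    seed: int = 0

    def __post_init__(self):
        if self.L < 1:
            raise ValueError("L must be >= 1")
        if self.d % self.heads != 0:
            raise ValueError("d must be divisible by heads")
        if self.d < 4:
            raise ValueError("d must be >= 4 (two coordinate encodings)")
        if self.agg not in ("mean", "diffpool"):
            raise ValueError("agg must be 'mean' or 'diffpool'")


@dataclass
class EmbeddingState:
    """Per-layer cell and gene embeddings, aligned by row = cell*|V| + gene."""

    cell_emb: Tensor      # (|C|, d)
    gene_emb: Tensor      # (|C|*|V|, d)
    n_cells: int
    n_genes: int
    layer: int = 0
    gene_agg: Tensor | None = None   # z̄g, set by encode (final AGG per cell)

    def index_of(self, cell: int, gene: int) -> int:
        return cell * self.n_genes + gene

    def validate(self):
        assert self.cell_emb.shape[0] == self.n_cells
        assert self.gene_emb.shape[0] == self.n_cells * self.n_genes
        assert np.isfinite(self.cell_emb.data).all()
        assert np.isfinite(self.gene_emb.data).all()


@dataclass
class Reconstruction:
    positions_hat: Tensor   # (|C|, 2)
    expression_hat: Tensor  # (|C|, |V|)


# ---------------------------------------------------------------------------
# static graph tensors
# ---------------------------------------------------------------------------

def _sorted_by_dst(src, dst):
    order = np.argsort(dst, kind="stable")
    return src[order], dst[order]


class GraphTensors:
    """Precomputed index arrays and dense gene adjacencies for one graph.

    Cell-level attention uses sorted edge lists; gene-level attention and
    the gene GIN use per-type dense |V|×|V| adjacency masks broadcast
    over cells (cheap because |V| is small).
    """

    def __init__(self, hg: HierarchicalGraph):
        C, V = hg.n_cells, hg.n_genes
        self.n_cells, self.n_genes = C, V

        e = hg.cell_graph.edges
        src = np.concatenate([e[:, 0], e[:, 1]])
        dst = np.concatenate([e[:, 1], e[:, 0]])
        self.cell_src_ns, self.cell_dst_ns = _sorted_by_dst(src, dst)
        self.cell_src, self.cell_dst = _sorted_by_dst(
            np.concatenate([src, np.arange(C)]),
            np.concatenate([dst, np.arange(C)]))

        self.type_order = sorted(hg.gene_networks, key=str)
        t_index = {t: i for i, t in enumerate(self.type_order)}
        self.type_index = np.array([t_index[t] for t in hg.cell_graph.cell_types],
                                   dtype=np.int64)
        n_t = len(self.type_order)
        self.gene_adj = np.zeros((n_t, V, V), dtype=np.float32)
        for t, i in t_index.items():
            ed = hg.gene_networks[t].edges
            if ed.size:
                self.gene_adj[i, ed[:, 0], ed[:, 1]] = 1.0
                self.gene_adj[i, ed[:, 1], ed[:, 0]] = 1.0
        # additive attention bias: 0 on edges and the diagonal, -1e9 elsewhere
        eye = np.eye(V, dtype=np.float32)
        self.attn_bias = np.where(self.gene_adj + eye > 0, 0.0, _NEG_BIG
                                  ).astype(np.float32)
        self._bias_full = None
        self._adj_full = None

    @classmethod
    def from_graph(cls, hg: HierarchicalGraph) -> "GraphTensors":
        return cls(hg)

    @property
    def bias_full(self) -> np.ndarray:
        """(|C|, 1, V, V) attention bias, materialized once."""
        if self._bias_full is None:
            self._bias_full = self.attn_bias[self.type_index][:, None, :, :]
        return self._bias_full

    @property
    def adj_full(self) -> np.ndarray:
        """(|C|, V, V) gene adjacency per cell, materialized once."""
        if self._adj_full is None:
            self._adj_full = self.gene_adj[self.type_index]
        return self._adj_full


# ---------------------------------------------------------------------------
# positional-encoding initialization
# ---------------------------------------------------------------------------

def sinusoidal_encoding(pos: np.ndarray, d: int, base: float = 10000.0) -> np.ndarray:
    """Standard transformer sin/cos encoding of scalar positions into d dims."""
    pos = np.asarray(pos, dtype=np.float64).ravel()
    half = d // 2
    freqs = base ** (-np.arange(half) / max(half, 1))
    ang = pos[:, None] * freqs[None, :]
    enc = np.zeros((pos.size, d))
    enc[:, 0:2 * half:2] = np.sin(ang)
    enc[:, 1:2 * half:2] = np.cos(ang)
    return enc


def expression_ranks(X: np.ndarray) -> np.ndarray:
    """Within-cell rank of each gene's expression (ties broken by gene index)."""
    order = np.argsort(X, axis=1, kind="stable")
    ranks = np.empty_like(order)
    np.put_along_axis(ranks, order, np.arange(X.shape[1])[None, :], axis=1)
    return ranks


def init_embeddings(hg: HierarchicalGraph, cfg: ModelConfig,
                    expression: np.ndarray | None = None,
                    positions: np.ndarray | None = None) -> EmbeddingState:
    """Rank-based gene PEs and coordinate-based cell PEs.

    Gene row (k, v) = sinusoid of the rank of gene v's expression within
    cell k, with the raw expression value added to coordinate 0.  Cell
    row k = concatenated sinusoids of min-max-normalized x and y, with
    the raw normalized coordinates added to coordinates 0 and d/2, and
    (by default) the cell's raw expression vector folded in modulo d.
    Raw values are added directly — no learned map.  Without raw
    expression in the cell rows, the only expression→cell path is the
    scalar cross-level gate, which cannot carry a type signature.
    """
    d = cfg.d
    X = hg.expression.values if expression is None else np.asarray(expression)
    P = hg.cell_graph.positions if positions is None else np.asarray(positions)
    C, V = X.shape

    ranks = expression_ranks(X)
    gene = sinusoidal_encoding(ranks.ravel(), d)
    gene[:, 0] += X.ravel()

    span = P.max(axis=0) - P.min(axis=0)
    norm = (P - P.min(axis=0)) / np.maximum(span, 1e-12)
    half = d // 2
    cell = np.concatenate(
        [sinusoidal_encoding(norm[:, 0] * cfg.pe_coord_scale, half),
         sinusoidal_encoding(norm[:, 1] * cfg.pe_coord_scale, d - half)], axis=1)
    cell[:, 0] += norm[:, 0]
    cell[:, half] += norm[:, 1]
    if cfg.cell_raw_expression:
        for start in range(0, V, d):
            chunk = X[:, start:start + d]
            cell[:, :chunk.shape[1]] += chunk

    return EmbeddingState(cell_emb=Tensor(cell), gene_emb=Tensor(gene),
                          n_cells=C, n_genes=V, layer=0)


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

def _attn_block(rng, d, ff):
    # output projections start small so each block is near-identity at
    # init and the input features survive to the final embeddings
    return {
        "Wq": T.parameter(None, rng, (d, d)), "Wk": T.parameter(None, rng, (d, d)),
        "Wv": T.parameter(None, rng, (d, d)),
        "Wo": T.parameter(None, rng, (d, d), scale=0.1 / np.sqrt(d)),
        "ln1_g": T.parameter(np.ones(d)), "ln1_b": T.parameter(np.zeros(d)),
        "W1": T.parameter(None, rng, (d, ff * d)), "b1": T.parameter(np.zeros(ff * d)),
        "W2": T.parameter(None, rng, (ff * d, d), scale=0.1 / np.sqrt(ff * d)),
        "b2": T.parameter(np.zeros(d)),
        "ln2_g": T.parameter(np.ones(d)), "ln2_b": T.parameter(np.zeros(d)),
    }


def _cross_block(rng, d):
    return {"Wq": T.parameter(None, rng, (d, d)),
            "Wk": T.parameter(None, rng, (d, d)),
            "Wv": T.parameter(None, rng, (d, d))}


def _gin_block(rng, d, scale):
    # sum aggregation inflates magnitudes by ~the mean degree per layer;
    # a small weight scale keeps fresh-decoder outputs near the data scale
    return {"W1": T.parameter(None, rng, (d, d), scale=scale),
            "b1": T.parameter(np.zeros(d)),
            "W2": T.parameter(None, rng, (d, d), scale=scale),
            "b2": T.parameter(np.zeros(d))}


def init_params(cfg: ModelConfig, rng: np.random.Generator | None = None) -> dict:
    """Nested parameter dict for encoder, cross-level blocks and decoder."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    d, ff = cfg.d, cfg.ff_mult
    gin_scale = 1.0 / (np.sqrt(d) * 4.0)
    params = {"layers": []}
    for _ in range(cfg.L):
        layer = {"cell": _attn_block(rng, d, ff),
                 "gene": _attn_block(rng, d, ff),
                 "gene_dir": _cross_block(rng, d),
                 "cell_dir": _cross_block(rng, d)}
        if cfg.agg == "diffpool":
            layer["pool_w"] = T.parameter(None, rng, (d, 1))
        params["layers"].append(layer)
    params["decoder"] = {
        "cell_gin": [_gin_block(rng, d, gin_scale) for _ in range(3)],
        "gene_gin": [_gin_block(rng, d, gin_scale) for _ in range(3)],
        "pos_head_W": T.parameter(None, rng, (d, 2), scale=0.1 / np.sqrt(d)),
        "pos_head_b": T.parameter(np.zeros(2)),
        "expr_head_W": T.parameter(None, rng, (d, 1), scale=0.1 / np.sqrt(d)),
        "expr_head_b": T.parameter(np.zeros(1)),
    }
    return params


def flatten_params(params, prefix="") -> dict:
    out = {}
    if isinstance(params, Tensor):
        out[prefix.rstrip(".")] = params
    elif isinstance(params, dict):
        for k, v in params.items():
            out.update(flatten_params(v, f"{prefix}{k}."))
    elif isinstance(params, list):
        for i, v in enumerate(params):
            out.update(flatten_params(v, f"{prefix}{i}."))
    return out


# ---------------------------------------------------------------------------
# intra-level step
# ---------------------------------------------------------------------------

def _sparse_mha(x: Tensor, src, dst, n, blk, heads):
    """Edge-list multi-head attention (spatial level)."""
    d = x.shape[1]
    dh = d // heads
    q = T.reshape(x @ blk["Wq"], (n, heads, dh))
    k = T.reshape(x @ blk["Wk"], (n, heads, dh))
    v = T.reshape(x @ blk["Wv"], (n, heads, dh))
    qd, ks = T.take(q, dst), T.take(k, src)
    scores = T.tsum(qd * ks, axis=-1) * (1.0 / np.sqrt(dh))   # (E, heads)
    shift = T.segment_max_const(scores.data, dst, n)          # constant offset
    ex = T.exp(scores - shift[dst])
    denom = T.segment_sum(ex, dst, n)                         # (n, heads)
    alpha = ex / (T.take(denom, dst) + 1e-12)
    weighted = T.take(v, src) * T.reshape(alpha, (alpha.shape[0], heads, 1))
    pooled = T.segment_sum(weighted, dst, n)
    return T.reshape(pooled, (n, d)) @ blk["Wo"]


def _dense_gene_mha(x: Tensor, gt: GraphTensors, blk, heads):
    """Per-cell dense attention over genes, masked to co-expression edges
    plus self (batched over cells)."""
    C, V = gt.n_cells, gt.n_genes
    d = x.shape[1]
    dh = d // heads

    def split(w):
        return T.transpose(T.reshape(x @ w, (C, V, heads, dh)), (0, 2, 1, 3))

    q, k, v = split(blk["Wq"]), split(blk["Wk"]), split(blk["Wv"])
    out = T.masked_attention(q, k, v, gt.bias_full, 1.0 / np.sqrt(dh))
    out = T.reshape(T.transpose(out, (0, 2, 1, 3)), (C * V, d))
    return out @ blk["Wo"]


def _block_tail(x: Tensor, attn_out: Tensor, blk):
    h = T.layer_norm(x + attn_out, blk["ln1_g"], blk["ln1_b"])
    ffo = T.relu(h @ blk["W1"] + blk["b1"]) @ blk["W2"] + blk["b2"]
    return T.layer_norm(h + ffo, blk["ln2_g"], blk["ln2_b"])


def intra_level_step(state: EmbeddingState, gt: GraphTensors,
                     layer_params: dict, cfg: ModelConfig) -> EmbeddingState:
    """One intra-level update on both levels (spatial graph, gene graphs).

    Attention is restricted to graph neighbours plus self, so an isolated
    node simply attends to itself.
    """
    C, V = gt.n_cells, gt.n_genes
    cblk, gblk = layer_params["cell"], layer_params["gene"]
    cell = _block_tail(state.cell_emb,
                       _sparse_mha(state.cell_emb, gt.cell_src, gt.cell_dst,
                                   C, cblk, cfg.heads), cblk)
    gene = _block_tail(state.gene_emb,
                       _dense_gene_mha(state.gene_emb, gt, gblk, cfg.heads),
                       gblk)
    return EmbeddingState(cell, gene, C, V, layer=state.layer)


# ---------------------------------------------------------------------------
# cross-level step: directional attention gate
# ---------------------------------------------------------------------------

def cross_message_passing(h_to: Tensor, h_from: Tensor, params: dict) -> Tensor:
    """Row-wise directional attention:
    out_i = (<(h_to Wq)_i, (h_from Wk)_i> / d) * (h_to Wv)_i.

    The denominator is d (the embedding width), and each output row is a
    scalar multiple of the corresponding value row.
    """
    if h_to.shape[0] != h_from.shape[0]:
        raise ValueError("h_to and h_from must have the same number of rows")
    d = h_to.shape[1]
    gate = T.tsum((h_to @ params["Wq"]) * (h_from @ params["Wk"]),
                  axis=1, keepdims=True) * (1.0 / d)
    return gate * (h_to @ params["Wv"])


def aggregate_genes(gene_emb: Tensor, C: int, V: int, cfg: ModelConfig,
                    layer_params: dict | None = None) -> Tensor:
    """AGG over each cell's gene rows: mean, or learned soft pooling."""
    d = gene_emb.shape[1]
    cube = T.reshape(gene_emb, (C, V, d))
    if cfg.agg == "mean" or layer_params is None or "pool_w" not in layer_params:
        return T.tmean(cube, axis=1)
    scores = T.reshape(gene_emb @ layer_params["pool_w"], (C, V))
    shift = scores.data.max(axis=1, keepdims=True)
    ex = T.exp(scores - shift)
    alpha = ex / T.tsum(ex, axis=1, keepdims=True)
    return T.tsum(cube * T.reshape(alpha, (C, V, 1)), axis=1)


def cross_level_step(state: EmbeddingState, gt: GraphTensors,
                     layer_params: dict, cfg: ModelConfig) -> EmbeddingState:
    """Bidirectional cross-level update.

    Gene rows receive their parent cell's embedding (repeated |V| times);
    cell rows receive the AGG of their gene rows.  With
    ``cfg.cross_residual`` the gated message is added to the input —
    without it the literal gate can annihilate the state.
    """
    if not cfg.cross_level:
        return state
    C, V = gt.n_cells, gt.n_genes
    hbar = aggregate_genes(state.gene_emb, C, V, cfg, layer_params)
    gene_msg = cross_message_passing(state.gene_emb,
                                     T.repeat_rows(state.cell_emb, V),
                                     layer_params["gene_dir"])
    cell_msg = cross_message_passing(state.cell_emb, hbar,
                                     layer_params["cell_dir"])
    if cfg.cross_residual:
        gene = state.gene_emb + gene_msg
        cell = state.cell_emb + cell_msg
    else:
        gene, cell = gene_msg, cell_msg
    return EmbeddingState(cell, gene, C, V, layer=state.layer)


# ---------------------------------------------------------------------------
# full encoder / decoder
# ---------------------------------------------------------------------------

def encode(hg: HierarchicalGraph, cfg: ModelConfig, params: dict,
           gt: GraphTensors | None = None,
           expression: np.ndarray | None = None,
           positions: np.ndarray | None = None) -> EmbeddingState:
    """init → L × (intra-level ∘ cross-level) → final (Zc, Zg)."""
    gt = gt if gt is not None else GraphTensors.from_graph(hg)
    state = init_embeddings(hg, cfg, expression=expression, positions=positions)
    for l, layer_params in enumerate(params["layers"], start=1):
        state = intra_level_step(state, gt, layer_params, cfg)
        state = cross_level_step(state, gt, layer_params, cfg)
        state.layer = l
        for name, t in (("cell", state.cell_emb), ("gene", state.gene_emb)):
            if not np.isfinite(t.data).all():
                raise FloatingPointError(
                    f"non-finite {name} embeddings after layer {l}")
    state.gene_agg = aggregate_genes(state.gene_emb, gt.n_cells, gt.n_genes,
                                     cfg, params["layers"][-1])
    return state


def _cell_gin(x: Tensor, src, dst, n, blocks, eps: float = 0.0):
    for blk in blocks:
        agg = (1.0 + eps) * x + T.segment_sum(T.take(x, src), dst, n)
        x = T.relu(agg @ blk["W1"] + blk["b1"]) @ blk["W2"] + blk["b2"]
    return x


def _gene_gin(x: Tensor, gt: GraphTensors, blocks, eps: float = 0.0):
    C, V = gt.n_cells, gt.n_genes
    d = x.shape[1]
    A = Tensor(gt.adj_full)                                   # (C, V, V)
    cube = T.reshape(x, (C, V, d))
    for blk in blocks:
        agg = (1.0 + eps) * cube + T.bmm(A, cube)
        flat = T.reshape(agg, (C * V, d))
        flat = T.relu(flat @ blk["W1"] + blk["b1"]) @ blk["W2"] + blk["b2"]
        cube = T.reshape(flat, (C, V, d))
    return T.reshape(cube, (C * V, d))


def decode(gt: GraphTensors, state: EmbeddingState, decoder_params: dict
           ) -> Reconstruction:
    """3-layer GIN decoder: positions from Zc on the cell graph, per-gene
    expression from Zg on the gene graphs."""
    C, V = gt.n_cells, gt.n_genes
    hc = _cell_gin(state.cell_emb, gt.cell_src_ns, gt.cell_dst_ns, C,
                   decoder_params["cell_gin"])
    pos_hat = hc @ decoder_params["pos_head_W"] + decoder_params["pos_head_b"]
    hgn = _gene_gin(state.gene_emb, gt, decoder_params["gene_gin"])
    expr = T.reshape(hgn @ decoder_params["expr_head_W"]
                     + decoder_params["expr_head_b"], (C, V))
    return Reconstruction(positions_hat=pos_hat, expression_hat=expr)
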