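"""Two-level graph construction for spatial omics data.

The pipeline turns a raw cells × genes matrix plus 2-D coordinates into

* a spatial cell graph (Voronoi adjacency via its Delaunay dual), and
* one gene co-expression network per cell type (pairwise mutual
  information on denoised expression, thresholded constantly or
  adaptively),

bundled as a :class:`HierarchicalGraph`.  Preprocessing follows the
standard single-cell recipe: outlier removal on total counts,
library-size normalization, log1p, highly-variable-gene selection, then
diffusion denoising to shrink dropout noise.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import Delaunay, QhullError

logger = logging.getLogger("heist")

LAYER_TAGS = ("raw", "normalized", "denoised")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Cells × genes nonnegative matrix with aligned identifiers."""

    values: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    layer_tag: str = "raw"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.gene_ids = np.asarray(self.gene_ids)
        self.cell_ids = np.asarray(self.cell_ids)
        if self.layer_tag not in LAYER_TAGS:
            raise ValueError(f"layer_tag must be one of {LAYER_TAGS}")
        n, g = self.values.shape
        if len(self.cell_ids) != n or len(self.gene_ids) != g:
            raise ValueError("id lengths do not match matrix shape")
        if len(set(self.gene_ids)) != g:
            raise ValueError("gene_ids are not unique")
        if len(set(self.cell_ids)) != n:
            raise ValueError("cell_ids are not unique")
        if (self.values < 0).any():
            raise ValueError("expression values must be nonnegative")

    @property
    def n_cells(self):
        return self.values.shape[0]

    @property
    def n_genes(self):
        return self.values.shape[1]


@dataclass
class SpatialCellGraph:
    """Undirected cell graph over 2-D positions, with per-cell types."""

    positions: np.ndarray            # (n, 2)
    edges: np.ndarray                # (E, 2) int, i < j, no self-loops
    cell_types: np.ndarray           # (n,) labels

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.float64)
        self.edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        self.cell_types = np.asarray(self.cell_types)
        n = self.positions.shape[0]
        if len(self.cell_types) != n:
            raise ValueError("every cell needs a type")
        if self.edges.size:
            if (self.edges[:, 0] == self.edges[:, 1]).any():
                raise ValueError("self-loops are not allowed")
            if self.edges.min() < 0 or self.edges.max() >= n:
                raise ValueError("edge references an invalid cell index")
            # canonical undirected form: sorted pairs, unique, lexsorted
            e = np.sort(self.edges, axis=1)
            self.edges = np.unique(e, axis=0)

    @property
    def n_cells(self):
        return self.positions.shape[0]


@dataclass
class GeneCoexpressionNetwork:
    """Gene graph for one cell type; edges carry MI weights in nats."""

    cell_type: object
    gene_ids: np.ndarray
    edges: np.ndarray                # (E, 2) int over gene indices
    mi_weights: np.ndarray           # (E,)
    threshold_used: float

    def __post_init__(self):
        self.gene_ids = np.asarray(self.gene_ids)
        self.edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        self.mi_weights = np.asarray(self.mi_weights, dtype=np.float64)
        if self.edges.size and (self.edges[:, 0] == self.edges[:, 1]).any():
            raise ValueError("gene self-loops are not allowed")
        if self.edges.shape[0] != self.mi_weights.shape[0]:
            raise ValueError("one MI weight per edge required")
        if self.mi_weights.size and self.mi_weights.min() < self.threshold_used:
            raise ValueError("all MI weights must be >= threshold_used")

    @property
    def n_genes(self):
        return len(self.gene_ids)

    def mean_degree(self):
        return 2.0 * self.edges.shape[0] / max(1, self.n_genes)


@dataclass
class HierarchicalGraph:
    """Spatial cell graph + per-type gene networks + denoised expression."""

    cell_graph: SpatialCellGraph
    gene_networks: dict
    expression: ExpressionMatrix = field(repr=False)

    def __post_init__(self):
        present = set(np.unique(self.cell_graph.cell_types).tolist())
        missing = present - set(self.gene_networks)
        if missing:
            raise ValueError(f"missing gene network(s) for cell type(s): {sorted(map(str, missing))}")
        for t, net in self.gene_networks.items():
            if list(net.gene_ids) != list(self.expression.gene_ids):
                raise ValueError(f"gene set of network {t!r} differs from expression matrix")

    @property
    def n_cells(self):
        return self.cell_graph.n_cells

    @property
    def n_genes(self):
        return self.expression.n_genes


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def preprocess(raw: ExpressionMatrix, n_hvg: int = 2000,
               outlier_mads: float = 3.0) -> ExpressionMatrix:
    """Outlier removal, library-size normalization, log1p, HVG selection.

    Cells whose log1p total count deviates from the median by more than
    ``outlier_mads`` median absolute deviations are dropped; remaining
    rows are scaled to the median total and log1p-transformed; the
    ``n_hvg`` genes of highest normalized dispersion (variance / mean on
    the normalized scale) are retained.
    """
    if raw.layer_tag != "raw":
        raise ValueError("preprocess expects a raw-layer matrix")
    if n_hvg > raw.n_genes:
        raise ValueError("n_hvg exceeds the number of genes")

    totals = raw.values.sum(axis=1)
    lt = np.log1p(totals)
    med = np.median(lt)
    mad = np.median(np.abs(lt - med))
    keep = np.abs(lt - med) <= outlier_mads * max(mad, 1e-12)
    if not keep.any():
        raise ValueError("outlier filter removed every cell")
    x = raw.values[keep]
    totals = totals[keep]

    target = np.median(totals)
    scaled = x * (target / np.maximum(totals, 1e-12))[:, None]

    mean = scaled.mean(axis=0)
    var = scaled.var(axis=0)
    dispersion = np.where(mean > 0, var / np.maximum(mean, 1e-12), 0.0)
    order = np.argsort(-dispersion, kind="stable")
    hvg_idx = np.sort(order[:n_hvg])
    if hvg_idx.size == 0:
        raise ValueError("HVG selection removed every gene")

    values = np.log1p(scaled[:, hvg_idx])
    return ExpressionMatrix(values=values,
                            gene_ids=raw.gene_ids[hvg_idx],
                            cell_ids=raw.cell_ids[keep],
                            layer_tag="normalized")


def magic_denoise(X: ExpressionMatrix, k_neighbors: int = 15,
                  t_steps: int = 3) -> ExpressionMatrix:
    """Diffusion denoising: powers of a cell-similarity Markov operator.

    Builds an adaptive-Gaussian kNN affinity over cells in expression
    space (bandwidth = distance to the k-th neighbor), symmetrizes it,
    and balances it to a doubly stochastic Markov matrix ``M`` (Sinkhorn),
    then returns ``M^t X``.  The doubly stochastic convention makes
    per-gene column mass exactly conserved, so denoising redistributes —
    never creates or destroys — each gene's total signal.
    """
    if X.layer_tag != "normalized":
        raise ValueError("magic_denoise expects a normalized-layer matrix")
    n = X.n_cells
    if k_neighbors >= n:
        raise ValueError("k_neighbors must be smaller than the cell count")
    if t_steps == 0:
        logger.info("magic_denoise: t_steps=0, returning input unchanged")
        return replace(X, layer_tag="denoised")

    from scipy.spatial import cKDTree
    tree = cKDTree(X.values)
    dist, idx = tree.query(X.values, k=k_neighbors + 1)
    sigma = np.maximum(dist[:, -1], 1e-12)
    A = np.zeros((n, n))
    rows = np.repeat(np.arange(n), k_neighbors + 1)
    A[rows, idx.ravel()] = np.exp(-(dist.ravel() / sigma[rows]) ** 2)
    A = 0.5 * (A + A.T)
    np.fill_diagonal(A, 1.0)

    # Sinkhorn balancing to doubly stochastic: find d with d∘(A(d)) = 1 so
    # M = diag(d) A diag(d); damped fixed-point iteration (geometric mean)
    d = 1.0 / np.sqrt(np.maximum(A.sum(1), 1e-300))
    for _ in range(1000):
        r = np.maximum(A @ d, 1e-300)
        d = np.sqrt(d / r)
        M = A * d[:, None] * d[None, :]
        err = np.abs(M.sum(1) - 1).max()
        if err < 1e-12:
            break

    values = X.values
    for _ in range(t_steps):
        values = M @ values
    values = np.maximum(values, 0.0)
    return ExpressionMatrix(values=values, gene_ids=X.gene_ids,
                            cell_ids=X.cell_ids, layer_tag="denoised")


# ---------------------------------------------------------------------------
# cell-type partition
# ---------------------------------------------------------------------------

def _merge_small_classes(X: np.ndarray, labels: np.ndarray, min_size: int = 3):
    """Merge classes with < min_size members into the nearest centroid class."""
    labels = np.asarray(labels).copy()
    while True:
        uniq, counts = np.unique(labels, return_counts=True)
        small = uniq[counts < min_size]
        big = uniq[counts >= min_size]
        if small.size == 0 or big.size == 0:
            break
        s = small[0]
        centroids = {b: X[labels == b].mean(axis=0) for b in big}
        sc = X[labels == s].mean(axis=0)
        nearest = min(centroids, key=lambda b: float(((centroids[b] - sc) ** 2).sum()))
        warnings.warn(
            f"cell-type class {s!r} has fewer than {min_size} cells; "
            f"merged into {nearest!r} (MI estimation needs >= {min_size} samples)",
            stacklevel=3)
        labels[labels == s] = nearest
    return labels


def partition_cell_types(X: ExpressionMatrix, labels=None,
                         resolution: float = 1.0, k_neighbors: int = 15,
                         seed: int = 0) -> np.ndarray:
    """Given labels verbatim, or Leiden communities of a kNN expression graph.

    Classes smaller than 3 cells are merged into the nearest class by
    centroid distance (MI estimation needs at least 3 samples).
    """
    if labels is not None:
        labels = np.asarray(labels)
        if len(labels) != X.n_cells:
            raise ValueError("need one label per cell")
        return _merge_small_classes(X.values, labels)

    import igraph
    import leidenalg
    from sklearn.neighbors import NearestNeighbors

    k = min(k_neighbors, X.n_cells - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X.values)
    _, idx = nn.kneighbors(X.values)
    src = np.repeat(np.arange(X.n_cells), k)
    dst = idx[:, 1:].ravel()
    pairs = np.unique(np.sort(np.stack([src, dst], axis=1), axis=1), axis=0)
    g = igraph.Graph(n=X.n_cells, edges=pairs.tolist())
    part = leidenalg.find_partition(
        g, leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution, seed=seed)
    labels = np.asarray(part.membership, dtype=np.int64)
    return _merge_small_classes(X.values, labels)


# ---------------------------------------------------------------------------
# mutual-information co-expression networks
# ---------------------------------------------------------------------------

def discretize_equal_frequency(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency codes; identical values always share a bin."""
    edges = np.quantile(values, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(edges, values, side="right").astype(np.int64)


def _entropy_from_counts(counts: np.ndarray) -> float:
    p = counts[counts > 0].astype(np.float64)
    p /= p.sum()
    return float(-(p * np.log(p)).sum())


def pairwise_mutual_information(X: np.ndarray, n_bins: int | None = None):
    """Plug-in MI (nats) between all gene pairs on equal-frequency codes.

    ``n_bins`` defaults to ``min(16, floor(sqrt(n_cells)))``.  Genes with
    constant expression get MI 0 against everything.  Returns the
    symmetric (G, G) matrix with marginal entropies on the diagonal.
    """
    n, g = X.shape
    if n_bins is None:
        n_bins = min(16, int(np.floor(np.sqrt(n))))
    n_bins = max(n_bins, 1)
    codes = np.empty((n, g), dtype=np.int64)
    constant = np.zeros(g, dtype=bool)
    for j in range(g):
        col = X[:, j]
        if col.max() == col.min():
            constant[j] = True
            codes[:, j] = 0
        else:
            codes[:, j] = discretize_equal_frequency(col, n_bins)
    H = np.array([_entropy_from_counts(np.bincount(codes[:, j])) for j in range(g)])
    mi = np.zeros((g, g))
    np.fill_diagonal(mi, H)
    for p in range(g):
        if constant[p]:
            continue
        cp = codes[:, p] * n_bins
        for q in range(p + 1, g):
            if constant[q]:
                continue
            joint = np.bincount(cp + codes[:, q], minlength=n_bins * n_bins)
            hpq = _entropy_from_counts(joint)
            val = max(H[p] + H[q] - hpq, 0.0)
            mi[p, q] = mi[q, p] = val
    mi[constant, :] = 0.0
    mi[:, constant] = 0.0
    np.fill_diagonal(mi, H)
    return mi


def build_coexpression_network(X_type: ExpressionMatrix, tau_mode: str = "adaptive",
                               tau_value_or_target_degree: float = 10.0,
                               cell_type=None, n_bins: int | None = None,
                               ) -> GeneCoexpressionNetwork:
    """Threshold the pairwise-MI matrix into a gene graph.

    ``constant`` mode keeps pairs with MI strictly above the given τ;
    ``adaptive`` mode sets τ per cell type to the smallest value whose
    kept edges have mean degree at most the given target.
    """
    if X_type.n_cells < 3:
        raise ValueError("MI estimation needs at least 3 cells of the type")
    if tau_mode not in ("constant", "adaptive"):
        raise ValueError("tau_mode must be 'constant' or 'adaptive'")

    g = X_type.n_genes
    mi = pairwise_mutual_information(X_type.values, n_bins=n_bins)
    iu, ju = np.triu_indices(g, k=1)
    vals = mi[iu, ju]

    if tau_mode == "constant":
        tau = float(tau_value_or_target_degree)
    else:
        target = float(tau_value_or_target_degree)
        max_edges = int(np.floor(target * g / 2.0))
        order = np.argsort(-vals, kind="stable")
        if vals.size <= max_edges:
            tau = 0.0
        else:
            # smallest tau whose kept edges (MI > tau) satisfy the degree cap
            tau = float(vals[order[max_edges]])

    keep = vals > tau
    edges = np.stack([iu[keep], ju[keep]], axis=1)
    return GeneCoexpressionNetwork(
        cell_type=cell_type, gene_ids=X_type.gene_ids,
        edges=edges, mi_weights=vals[keep], threshold_used=tau)


# ---------------------------------------------------------------------------
# spatial graph
# ---------------------------------------------------------------------------

def build_spatial_graph(positions: np.ndarray, prune_quantile: float = 0.99,
                        cell_types=None, seed: int = 0) -> SpatialCellGraph:
    """Voronoi adjacency via the Delaunay dual, with long-edge pruning.

    Edges longer than the ``prune_quantile`` quantile of Delaunay edge
    lengths are removed (convex-hull artifacts); ``prune_quantile=1.0``
    keeps the full triangulation.  Duplicate coordinates are jittered by
    a seeded perturbation of 1e-9 × the bounding-box diagonal.
    """
    positions = np.asarray(positions, dtype=np.float64)
    n = positions.shape[0]
    if n < 3:
        raise ValueError("spatial graph needs at least 3 cells")

    pts = positions
    _, inverse, counts = np.unique(pts, axis=0, return_inverse=True,
                                   return_counts=True)[0:3]
    if (counts > 1).any():
        diag = np.linalg.norm(pts.max(0) - pts.min(0))
        rng = np.random.default_rng(seed)
        jitter = rng.standard_normal(pts.shape) * max(diag, 1.0) * 1e-9
        dup = counts[inverse] > 1
        pts = pts.copy()
        pts[dup] += jitter[dup]
        logger.warning("build_spatial_graph: %d duplicate coordinates jittered",
                       int(dup.sum()))

    try:
        tri = Delaunay(pts)
    except QhullError as exc:
        raise ValueError("Delaunay triangulation failed: points are "
                         "degenerate (collinear or coincident)") from exc

    simp = tri.simplices
    e = np.concatenate([simp[:, [0, 1]], simp[:, [1, 2]], simp[:, [0, 2]]], axis=0)
    e = np.unique(np.sort(e, axis=1), axis=0)

    lengths = np.linalg.norm(pts[e[:, 0]] - pts[e[:, 1]], axis=1)
    if prune_quantile < 1.0 and lengths.size:
        cutoff = np.quantile(lengths, prune_quantile)
        e = e[lengths <= cutoff]

    if cell_types is None:
        cell_types = np.zeros(n, dtype=np.int64)
    return SpatialCellGraph(positions=positions, edges=e,
                            cell_types=np.asarray(cell_types))


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def assemble(cell_graph: SpatialCellGraph, gene_networks: dict,
             expression: ExpressionMatrix) -> HierarchicalGraph:
    """Validated hierarchical graph; cell k links to its type's gene network."""
    return HierarchicalGraph(cell_graph=cell_graph,
                             gene_networks=dict(gene_networks),
                             expression=expression)


def build_hierarchical_graph(expression: ExpressionMatrix, positions,
                             labels=None, n_hvg: int | None = None,
                             outlier_mads: float = 3.0,
                             magic_k: int = 15, magic_t: int = 3,
                             tau_mode: str = "adaptive",
                             tau_value_or_target_degree: float = 10.0,
                             prune_quantile: float = 0.99,
                             resolution: float = 1.0,
                             seed: int = 0) -> HierarchicalGraph:
    """End-to-end convenience pipeline: preprocess → denoise → partition →
    per-type MI networks → spatial graph → assemble."""
    n_hvg = n_hvg if n_hvg is not None else expression.n_genes
    norm = preprocess(expression, n_hvg=min(n_hvg, expression.n_genes),
                      outlier_mads=outlier_mads)
    # align positions/labels with surviving cells
    keep = np.isin(expression.cell_ids, norm.cell_ids)
    positions = np.asarray(positions, dtype=np.float64)[keep]
    if labels is not None:
        labels = np.asarray(labels)[keep]
    den = magic_denoise(norm, k_neighbors=min(magic_k, norm.n_cells - 1),
                        t_steps=magic_t)
    types = partition_cell_types(den, labels=labels, resolution=resolution,
                                 seed=seed)
    networks = {}
    for t in np.unique(types):
        sub = ExpressionMatrix(values=den.values[types == t],
                               gene_ids=den.gene_ids,
                               cell_ids=den.cell_ids[types == t],
                               layer_tag="denoised")
        networks[t] = build_coexpression_network(
            sub, tau_mode=tau_mode,
            tau_value_or_target_degree=tau_value_or_target_degree,
            cell_type=t)
    cg = build_spatial_graph(positions, prune_quantile=prune_quantile,
                             cell_types=types, seed=seed)
    return assemble(cg, networks, den)
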