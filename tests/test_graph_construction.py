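"""Preprocessing, denoising, MI networks and the spatial graph."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from heist.graph_construction import (ExpressionMatrix,
                                      assemble, build_coexpression_network,
                                      build_spatial_graph,
                                      discretize_equal_frequency,
                                      _entropy_from_counts, magic_denoise,
                                      pairwise_mutual_information,
                                      partition_cell_types, preprocess)


def _em(values, tag="raw"):
    values = np.asarray(values, dtype=float)
    n, g = values.shape
    return ExpressionMatrix(values=values,
                            gene_ids=[f"g{j}" for j in range(g)],
                            cell_ids=[f"c{i}" for i in range(n)],
                            layer_tag=tag)


# ---------------------------------------------------------------------------
# preprocess
# ---------------------------------------------------------------------------

class TestPreprocess:
    def test_zero_count_cell_dropped(self):
        m = _em([[5, 5], [6, 4], [0, 0]])
        out = preprocess(m, n_hvg=2, outlier_mads=3.0)
        assert out.n_cells == 2
        assert "c2" not in out.cell_ids

    def test_gene_set_unchanged_when_already_n_hvg(self):
        rng = np.random.default_rng(0)
        m = _em(rng.poisson(5.0, (20, 8)))
        out = preprocess(m, n_hvg=8)
        assert list(out.gene_ids) == list(m.gene_ids)
        assert out.layer_tag == "normalized"

    def test_informative_genes_survive_hvg_selection(self):
        # 50 planted informative genes + 50 constant genes
        rng = np.random.default_rng(1)
        n = 200
        groups = rng.integers(0, 2, n)
        info = rng.poisson(np.where(groups[:, None] == 0, 2.0, 20.0),
                           (n, 50))
        const = np.full((n, 50), 5.0)
        m = _em(np.hstack([info, const]))
        out = preprocess(m, n_hvg=50)
        kept_informative = sum(1 for g in out.gene_ids if int(g[1:]) < 50)
        assert kept_informative >= 45

    def test_everything_filtered_raises_named_error(self):
        m = _em([[0, 0], [0, 0], [0, 0]])
        # all totals identical -> none dropped; then n_hvg > genes errors
        with pytest.raises(ValueError):
            preprocess(m, n_hvg=5)

    def test_requires_raw_layer(self):
        m = _em(np.ones((5, 3)), tag="normalized")
        with pytest.raises(ValueError, match="raw"):
            preprocess(m, n_hvg=3)


# ---------------------------------------------------------------------------
# diffusion denoising
# ---------------------------------------------------------------------------

class TestMagicDenoise:
    def test_zero_steps_is_identity(self):
        m = _em(np.random.default_rng(0).uniform(0, 2, (30, 5)), "normalized")
        out = magic_denoise(m, k_neighbors=5, t_steps=0)
        assert np.array_equal(out.values, m.values)
        assert out.layer_tag == "denoised"

    def test_identical_cells_are_a_fixed_point(self):
        X = np.tile(np.random.default_rng(1).uniform(1, 2, (1, 6)), (25, 1))
        out = magic_denoise(_em(X, "normalized"), k_neighbors=5, t_steps=4)
        assert np.allclose(out.values, X, atol=1e-9)

    def test_denoising_reduces_mse_to_clean_signal(self):
        rng = np.random.default_rng(2)
        base = np.linspace(0, 1, 100)[:, None]
        clean = np.hstack([np.abs(np.sin(base * 3 + k)) + 0.5
                           for k in range(10)])
        dropout = rng.uniform(size=clean.shape) < 0.4
        noisy = clean * ~dropout
        out = magic_denoise(_em(noisy, "normalized"), k_neighbors=10, t_steps=3)
        assert ((out.values - clean) ** 2).mean() < ((noisy - clean) ** 2).mean()

    def test_per_gene_column_mass_is_conserved(self):
        # doubly stochastic diffusion redistributes but never creates signal
        rng = np.random.default_rng(3)
        m = _em(rng.uniform(0, 3, (60, 8)), "normalized")
        out = magic_denoise(m, k_neighbors=8, t_steps=3)
        before, after = m.values.sum(axis=0), out.values.sum(axis=0)
        assert np.allclose(after, before, rtol=1e-6)
        assert (out.values >= 0).all()

    def test_k_must_be_below_cell_count(self):
        m = _em(np.ones((4, 3)), "normalized")
        with pytest.raises(ValueError):
            magic_denoise(m, k_neighbors=4, t_steps=1)


# ---------------------------------------------------------------------------
# cell-type partition
# ---------------------------------------------------------------------------

class TestPartition:
    def test_given_labels_returned_verbatim(self):
        m = _em(np.random.default_rng(0).uniform(0, 1, (10, 4)), "denoised")
        labels = np.array(["a", "b"] * 5)
        assert np.array_equal(partition_cell_types(m, labels=labels), labels)

    def test_two_separated_blobs_give_two_clusters(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 0.3, (100, 10)),
                       rng.normal(5, 0.3, (100, 10))])
        m = _em(np.abs(X), "denoised")
        labels = partition_cell_types(m, resolution=1.0, seed=0)
        assert len(np.unique(labels)) == 2
        # verify separation quality on the generator's own design
        from sklearn.metrics import silhouette_score
        assert silhouette_score(m.values, labels) > 0.5

    def test_tiny_class_merged_with_warning(self):
        rng = np.random.default_rng(1)
        m = _em(rng.uniform(0, 1, (12, 4)), "denoised")
        labels = np.array(["big"] * 10 + ["tiny"] * 2)
        with pytest.warns(UserWarning, match="merged"):
            merged = partition_cell_types(m, labels=labels)
        assert set(merged) == {"big"}


# ---------------------------------------------------------------------------
# mutual information
# ---------------------------------------------------------------------------

def _brute_force_mi(x, y, n_bins):
    cx = discretize_equal_frequency(x, n_bins)
    cy = discretize_equal_frequency(y, n_bins)
    joint = np.zeros((n_bins, n_bins))
    for a, b in zip(cx, cy):
        joint[a, b] += 1
    hx = _entropy_from_counts(joint.sum(1))
    hy = _entropy_from_counts(joint.sum(0))
    hxy = _entropy_from_counts(joint.ravel())
    return max(hx + hy - hxy, 0.0)


class TestMutualInformation:
    def test_matches_brute_force_and_is_symmetric(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            X = rng.standard_normal((40, 5))
            mi = pairwise_mutual_information(X, n_bins=4)
            assert np.abs(mi - mi.T).max() <= 1e-12
            for p in range(5):
                for q in range(p + 1, 5):
                    assert mi[p, q] == pytest.approx(
                        _brute_force_mi(X[:, p], X[:, q], 4), abs=1e-12)

    def test_deterministic_bijection_attains_marginal_entropy(self):
        # gene q = -p is a per-cell bijection of p's values
        rng = np.random.default_rng(1)
        vals = rng.standard_normal(500)
        X = np.column_stack([vals, -vals])
        mi = pairwise_mutual_information(X, n_bins=16)
        h = _entropy_from_counts(
            np.bincount(discretize_equal_frequency(vals, 16)))
        assert mi[0, 1] == pytest.approx(h, abs=1e-12)
        assert mi[0, 0] == pytest.approx(h, abs=1e-12)

    def test_independent_noise_mi_stays_below_plugin_bias_bound(self):
        # plug-in MI of independent genes concentrates near the
        # (B-1)^2 / (2n) bias (~0.225 nats at B=16, n=500)
        rng = np.random.default_rng(2)
        X = rng.uniform(size=(500, 12))
        mi = pairwise_mutual_information(X, n_bins=16)
        iu = np.triu_indices(12, 1)
        bound = (16 - 1) ** 2 / (2 * 500)
        assert np.quantile(mi[iu], 0.95) < 2 * bound

    def test_constant_gene_has_zero_mi_everywhere(self):
        rng = np.random.default_rng(3)
        X = np.column_stack([np.full(50, 2.0), rng.uniform(size=50)])
        net = build_coexpression_network(_em(X, "denoised").__class__(
            values=X, gene_ids=["a", "b"], cell_ids=[f"c{i}" for i in range(50)],
            layer_tag="denoised"), tau_mode="constant",
            tau_value_or_target_degree=0.0)
        assert net.edges.shape[0] == 0

    def test_adaptive_tau_respects_target_degree(self):
        rng = np.random.default_rng(4)
        X = np.abs(rng.standard_normal((100, 20)))
        net = build_coexpression_network(_em(X, "denoised"),
                                         tau_mode="adaptive",
                                         tau_value_or_target_degree=4.0)
        assert net.mean_degree() <= 4.0
        assert net.threshold_used >= 0
        assert (net.mi_weights > net.threshold_used).all()

    def test_planted_modules_have_denser_within_module_edges(self):
        rng = np.random.default_rng(5)
        n = 300
        f1, f2 = rng.standard_normal(n), rng.standard_normal(n)
        X = np.hstack([f1[:, None] + 0.4 * rng.standard_normal((n, 10)),
                       f2[:, None] + 0.4 * rng.standard_normal((n, 10))])
        net = build_coexpression_network(_em(np.abs(X), "denoised"),
                                         tau_mode="adaptive",
                                         tau_value_or_target_degree=6.0)
        module = net.edges // 10
        within = (module[:, 0] == module[:, 1]).sum() / (2 * 45)
        cross = (module[:, 0] != module[:, 1]).sum() / 100
        assert within > cross


# ---------------------------------------------------------------------------
# spatial graph (Voronoi adjacency via Delaunay)
# ---------------------------------------------------------------------------

def voronoi_adjacency_oracle(points: np.ndarray) -> set:
    """Brute-force Voronoi adjacency by half-plane intersection.

    Cells i, j are adjacent iff a positive-length stretch of their
    bisector is closer to i and j than to every other point.
    """
    n = len(points)
    adj = set()
    for i in range(n):
        for j in range(i + 1, n):
            mid = (points[i] + points[j]) / 2
            diff = points[j] - points[i]
            u = np.array([-diff[1], diff[0]])
            u = u / np.linalg.norm(u)
            lo, hi = -1e9, 1e9
            for k in range(n):
                if k in (i, j):
                    continue
                # |x - p_i|^2 <= |x - p_k|^2 for x = mid + t*u
                a = 2 * np.dot(u, points[k] - points[i])
                b = (np.dot(points[k], points[k])
                     - np.dot(points[i], points[i])
                     - 2 * np.dot(mid, points[k] - points[i]))
                if abs(a) < 1e-14:
                    if b < 0:
                        lo, hi = 1, -1
                        break
                elif a > 0:
                    hi = min(hi, b / a)
                else:
                    lo = max(lo, b / a)
            if hi - lo > 1e-9:
                adj.add((i, j))
    return adj


class TestSpatialGraph:
    def test_unit_square_has_five_delaunay_edges(self):
        pts = np.array([[0, 0], [1, 0], [0, 1], [1, 1]], dtype=float)
        g = build_spatial_graph(pts, prune_quantile=1.0)
        assert g.edges.shape[0] == 5

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(4, 12))
    def test_matches_brute_force_voronoi_oracle(self, seed, n):
        pts = np.random.default_rng(seed).uniform(0, 1, (n, 2))
        g = build_spatial_graph(pts, prune_quantile=1.0)
        got = {tuple(e) for e in g.edges}
        assert got == voronoi_adjacency_oracle(pts)

    def test_regular_grid_interior_degree_at_least_four(self):
        xs, ys = np.meshgrid(np.arange(5.0), np.arange(5.0))
        pts = np.column_stack([xs.ravel(), ys.ravel()])
        g = build_spatial_graph(pts, prune_quantile=1.0)
        deg = np.bincount(g.edges.ravel(), minlength=25)
        interior = [i for i in range(25)
                    if 0 < i % 5 < 4 and 0 < i // 5 < 4]
        assert (deg[interior] >= 4).all()

    def test_collinear_points_fail_explicitly(self):
        pts = np.column_stack([np.arange(5.0), np.arange(5.0)])
        with pytest.raises(ValueError, match="degenerate"):
            build_spatial_graph(pts)

    def test_fewer_than_three_points_fail(self):
        with pytest.raises(ValueError):
            build_spatial_graph(np.array([[0.0, 0], [1, 1]]))

    def test_duplicates_are_jittered_deterministically(self):
        pts = np.array([[0, 0], [0, 0], [1, 0], [0, 1], [1, 1]], dtype=float)
        a = build_spatial_graph(pts, seed=5)
        b = build_spatial_graph(pts, seed=5)
        assert np.array_equal(a.edges, b.edges)
        assert a.n_cells == 5

    def test_pruning_removes_long_hull_edges(self):
        rng = np.random.default_rng(0)
        pts = np.vstack([rng.uniform(0, 1, (50, 2)), [[10.0, 10.0]]])
        full = build_spatial_graph(pts, prune_quantile=1.0)
        pruned = build_spatial_graph(pts, prune_quantile=0.9)
        assert pruned.edges.shape[0] < full.edges.shape[0]
        deg = np.bincount(pruned.edges.ravel(), minlength=51)
        assert deg[50] == 0  # the far outlier is disconnected


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

class TestAssemble:
    def _net(self, gene_ids, cell_type="t0"):
        from heist.graph_construction import GeneCoexpressionNetwork
        return GeneCoexpressionNetwork(cell_type=cell_type, gene_ids=gene_ids,
                                       edges=np.array([[0, 1]]),
                                       mi_weights=np.array([1.0]),
                                       threshold_used=0.5)

    def test_single_type_shares_one_network(self):
        m = _em(np.random.default_rng(0).uniform(0, 1, (5, 3)), "denoised")
        cg = build_spatial_graph(np.random.default_rng(1).uniform(0, 1, (5, 2)),
                                 cell_types=np.array(["t0"] * 5))
        hg = assemble(cg, {"t0": self._net(m.gene_ids)}, m)
        assert len(hg.gene_networks) == 1

    def test_missing_network_fails_naming_the_type(self):
        m = _em(np.random.default_rng(0).uniform(0, 1, (5, 3)), "denoised")
        cg = build_spatial_graph(np.random.default_rng(1).uniform(0, 1, (5, 2)),
                                 cell_types=np.array(["t0", "t0", "t1", "t1", "t1"]))
        with pytest.raises(ValueError, match="t1"):
            assemble(cg, {"t0": self._net(m.gene_ids)}, m)

    def test_three_type_tissue_gets_three_networks(self, small_graph):
        assert len(small_graph.gene_networks) == 3
        present = set(np.unique(small_graph.cell_graph.cell_types))
        assert present == set(small_graph.gene_networks)
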