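"""The two-branch classifier: GraphSAGE layers, forward pass, checkpoints."""

from collections import deque

import numpy as np
import pytest

from graphphos.autodiff import Tensor
from graphphos.model import (ModelConfig, SiteSet, forward, init_params,
                             load_checkpoint, sage_branch, sage_layer,
                             save_checkpoint, sites_from_sequence)
from graphphos.structure_graph import ContactGraph


def random_graph(n, p, seed):
    rng = np.random.default_rng(seed)
    edges = frozenset((i, j) for i in range(n) for j in range(i + 1, n)
                      if rng.random() < p)
    return ContactGraph(n, edges)


def sage_layer_oracle(features, graph, weight, bias=None, normalize=True):
    """Explicit per-node loop: gather, mean, concat, multiply, ReLU, L2."""
    adj = graph.neighbors()
    out = []
    for v in range(graph.n_nodes):
        neigh = adj[v]
        agg = (np.mean([features[u] for u in neigh], axis=0) if neigh
               else np.zeros(features.shape[1]))
        z = np.concatenate([features[v], agg]) @ weight
        if bias is not None:
            z = z + bias
        z = np.maximum(z, 0.0)
        if normalize:
            norm = np.linalg.norm(z)
            if norm > 1e-12:
                z = z / norm
        out.append(z)
    return np.array(out)


def bfs_distances(graph, source):
    dist = {source: 0}
    q = deque([source])
    adj = graph.neighbors()
    while q:
        u = q.popleft()
        for w in adj[u]:
            if w not in dist:
                dist[w] = dist[u] + 1
                q.append(w)
    return dist


class TestSageLayer:
    def test_hand_computed_mean_aggregation(self):
        # path 0-1-2, scalar features (1,2,3), W sums self and neighbor mean
        graph = ContactGraph(3, frozenset({(0, 1), (1, 2)}))
        features = np.array([[1.0], [2.0], [3.0]])
        w = np.array([[1.0], [1.0]])
        out = sage_layer(features, graph, w, norm="none")
        # node 1: self 2 + mean(1, 3) = 4; ends: self + sole neighbor
        np.testing.assert_allclose(out[:, 0], [1 + 2, 2 + 2, 3 + 2])

    def test_isolated_node_keeps_own_features(self):
        graph = ContactGraph(2, frozenset())
        features = np.array([[1.5, -2.0], [0.5, 3.0]])
        w = np.vstack([np.eye(2), np.zeros((2, 2))])  # reads the self half only
        out = sage_layer(features, graph, w, norm="none")
        np.testing.assert_allclose(out, np.maximum(features, 0.0))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_explicit_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        graph = random_graph(8, 0.35, seed)
        features = rng.standard_normal((8, 6))
        w = rng.standard_normal((12, 5))
        b = rng.standard_normal(5)
        out = sage_layer(features, graph, w, bias=b)
        np.testing.assert_allclose(
            out, sage_layer_oracle(features, graph, w, b), atol=1e-5)

    def test_l2_normalized_rows_have_unit_or_zero_norm(self):
        rng = np.random.default_rng(3)
        graph = random_graph(10, 0.3, 3)
        out = sage_layer(rng.standard_normal((10, 6)), graph,
                         rng.standard_normal((12, 6)))
        norms = np.linalg.norm(out, axis=1)
        assert np.all((norms < 1e-7) | (np.abs(norms - 1) < 1e-5))

    def test_shape_mismatch_rejected(self):
        graph = ContactGraph(3, frozenset({(0, 1)}))
        with pytest.raises(ValueError, match="graph nodes"):
            sage_layer(np.zeros((4, 2)), graph, np.zeros((4, 2)))


class TestSageBranch:
    def _params(self, config, seed=0, feat_dim=6):
        return init_params(config, feature_dim=feat_dim, emb_dim=4)

    def test_edgeless_graph_is_per_node_map(self):
        config = ModelConfig(use_plm_cnn=False, sage_hidden=6, seed=0)
        params = self._params(config)
        rng = np.random.default_rng(0)
        features = rng.standard_normal((5, 6))
        graph = ContactGraph(5, frozenset())
        out = sage_branch(features, graph, params, config)
        perm = np.array([3, 1, 4, 0, 2])
        out_perm = sage_branch(features[perm], graph, params, config)
        np.testing.assert_allclose(out_perm, out[perm], atol=1e-12)

    def test_two_layer_receptive_field_is_graph_distance_two(self):
        config = ModelConfig(use_plm_cnn=False, sage_hidden=6, seed=1)
        params = self._params(config)
        rng = np.random.default_rng(1)
        graph = random_graph(12, 0.2, 5)
        features = rng.standard_normal((12, 6))
        base = sage_branch(features, graph, params, config)
        u = 4
        perturbed = features.copy()
        perturbed[u] += rng.standard_normal(6)
        moved = sage_branch(perturbed, graph, params, config)
        dist = bfs_distances(graph, u)
        changed = np.abs(moved - base).max(axis=1) > 1e-9
        for v in range(12):
            if dist.get(v, np.inf) > 2:
                assert not changed[v], f"node {v} beyond 2 hops changed"

    def test_complete_graph_identical_features_identical_rows(self):
        config = ModelConfig(use_plm_cnn=False, sage_hidden=6, seed=2)
        params = self._params(config)
        n = 6
        graph = ContactGraph(n, frozenset((i, j) for i in range(n)
                                          for j in range(i + 1, n)))
        features = np.tile(np.linspace(0.1, 0.6, 6), (n, 1))
        out = sage_branch(features, graph, params, config)
        np.testing.assert_allclose(out, np.tile(out[0], (n, 1)), atol=1e-10)


class TestForward:
    def _inputs(self, seed=0, L=12):
        rng = np.random.default_rng(seed)
        features = rng.standard_normal((L, 57))
        graph = random_graph(L, 0.3, seed)
        emb = rng.standard_normal((L, 16))
        sites = SiteSet("p", np.arange(0, L, 3), np.zeros(len(range(0, L, 3)), int))
        return features, graph, emb, sites

    def test_zero_weights_give_half_probability_all_positive_calls(self):
        features, graph, emb, sites = self._inputs()
        config = ModelConfig(seed=0)
        params = init_params(config, emb_dim=16)
        for p in params.values():
            if p.data.ndim == 2:
                p.data[:] = 0.0
        result = forward(features, graph, emb, sites, params, config)
        np.testing.assert_allclose(result.probabilities, 0.5)
        assert np.all(result.calls == 1)  # ties at 0.5 are positive

    def test_deterministic_given_params(self):
        features, graph, emb, sites = self._inputs(seed=3)
        config = ModelConfig(seed=3)
        params = init_params(config, emb_dim=16)
        a = forward(features, graph, emb, sites, params, config)
        b = forward(features, graph, emb, sites, params, config)
        np.testing.assert_array_equal(a.probabilities, b.probabilities)

    def test_wo_sage_ablation_ignores_the_graph(self):
        features, graph, emb, sites = self._inputs(seed=4)
        config = ModelConfig(use_sage=False, seed=4)
        params = init_params(config, emb_dim=16)
        dense = random_graph(12, 0.9, 99)
        a = forward(features, graph, emb, sites, params, config)
        b = forward(features, dense, emb, sites, params, config)
        np.testing.assert_array_equal(a.probabilities, b.probabilities)

    def test_wo_cnn_ablation_ignores_embeddings(self):
        features, graph, emb, sites = self._inputs(seed=5)
        config = ModelConfig(use_plm_cnn=False, seed=5)
        params = init_params(config, emb_dim=16)
        a = forward(features, graph, emb, sites, params, config)
        b = forward(features, graph, emb * 100, sites, params, config)
        np.testing.assert_array_equal(a.probabilities, b.probabilities)

    def test_probabilities_strictly_inside_unit_interval(self):
        features, graph, emb, sites = self._inputs(seed=6)
        config = ModelConfig(seed=6)
        params = init_params(config, emb_dim=16)
        p = forward(features, graph, emb, sites, params, config).probabilities
        assert np.all((p > 0) & (p < 1))

    def test_node_relabeling_equivariance(self):
        # pointwise CNN kernels: a sequence convolution wider than one
        # residue is position-aware by design, so equivariance is asserted
        # for the graph branch plus a per-residue embedding map
        features, graph, emb, sites = self._inputs(seed=7)
        config = ModelConfig(seed=7, cnn_kernels=(1, 1))
        params = init_params(config, emb_dim=16)
        base = forward(features, graph, emb, sites, params, config)
        rng = np.random.default_rng(7)
        perm = rng.permutation(12)
        inv = np.argsort(perm)
        graph_p = ContactGraph(12, frozenset(
            (min(inv[i], inv[j]), max(inv[i], inv[j])) for i, j in graph.edges))
        order = np.argsort(inv[sites.site_indices])
        sites_p = SiteSet("p", np.sort(inv[sites.site_indices]),
                          sites.labels[order])
        moved = forward(features[perm], graph_p, emb[perm], sites_p, params, config)
        np.testing.assert_allclose(
            moved.probabilities, base.probabilities[order], atol=1e-9)

    def test_empty_site_set_rejected(self):
        features, graph, emb, _ = self._inputs()
        config = ModelConfig(seed=0)
        params = init_params(config, emb_dim=16)
        empty = SiteSet("p", np.array([], dtype=int), np.array([], dtype=int))
        with pytest.raises(ValueError, match="no S/T/Y"):
            forward(features, graph, emb, empty, params, config)


class TestConfigAndSites:
    def test_both_branches_disabled_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(use_sage=False, use_plm_cnn=False)

    def test_sites_from_sequence_finds_sty_only(self):
        ss = sites_from_sequence("p", "ASTAYG", labels={1: 1, 4: 0})
        np.testing.assert_array_equal(ss.site_indices, [1, 2, 4])
        np.testing.assert_array_equal(ss.labels, [1, -1, 0])
        ss.validate_against("ASTAYG")

    def test_site_at_non_sty_residue_rejected(self):
        ss = SiteSet("p", np.array([0]), np.array([1]))
        with pytest.raises(ValueError, match="not S/T/Y"):
            ss.validate_against("AST")


def test_checkpoint_round_trip(tmp_path):
    config = ModelConfig(seed=5, cnn_hidden=8, cnn_kernels=(3, 3))
    params = init_params(config, emb_dim=16)
    path = tmp_path / "model.ckpt.npz"
    save_checkpoint(path, params, config, extra={"note": "test"})
    loaded, config2, extra = load_checkpoint(path)
    assert config2 == config
    assert extra == {"note": "test"}
    assert set(loaded) == set(params)
    for k in params:
        np.testing.assert_array_equal(loaded[k].data, params[k].data)
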