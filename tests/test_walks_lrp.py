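"""Walk enumeration and relevance propagation: counts, conservation, oracles."""

import numpy as np
import pytest

import walklrp as w
from walklrp.lrp import WalkRelevanceMap


def _complete_triangle():
    return w.Conformer(["C"] * 3, [[0, 0, 0], [1.2, 0, 0], [0.6, 1.0, 0]])


class TestEnumeration:
    def test_complete_graph_power_law(self):
        g = w.build_neighbor_graph(_complete_triangle(), cutoff=5.0)
        walks = w.enumerate_walks(g, depth=2)
        assert len(walks) == 27 == w.walk_count(g, 2)

    def test_path_graph_explicit_listing(self):
        conf = w.Conformer(["C"] * 3, [[0, 0, 0], [0, 0, 1.0], [0, 0, 2.0]])
        g = w.build_neighbor_graph(conf, cutoff=1.5)
        walks = set(w.enumerate_walks(g, depth=1))
        assert walks == {(0, 0), (0, 1), (1, 0), (1, 1), (1, 2), (2, 1), (2, 2)}

    def test_single_atom_single_walk(self):
        g = w.build_neighbor_graph(w.Conformer(["C"], [[0, 0, 0]]), cutoff=3.0)
        assert w.enumerate_walks(g, depth=4) == [(0, 0, 0, 0, 0)]

    @pytest.mark.parametrize("depth", [1, 2, 3])
    def test_count_matches_adjacency_power(self, depth, small_cluster):
        g = w.build_neighbor_graph(small_cluster, cutoff=2.5)
        A = np.eye(g.n_atoms) + np.zeros((g.n_atoms, g.n_atoms))
        for j, k in g.edges:
            A[j, k] = 1.0
        expected = int(np.linalg.matrix_power(A, depth).sum())
        assert len(w.enumerate_walks(g, depth)) == expected

    def test_cap_exceeded_is_explicit(self):
        g = w.build_neighbor_graph(_complete_triangle(), cutoff=5.0)
        with pytest.raises(w.WalkCapExceededError, match="exponential"):
            w.enumerate_walks(g, depth=10, cap=100)


class TestConservation:
    def test_trained_models_conserve(self, trained6, trained9, cluster6_data, cluster9_test):
        for est, conf in ((trained6, cluster6_data[0]), (trained9, cluster9_test[0])):
            rmap = w.walk_relevances(est.params_, est.config_, conf)
            assert w.conservation_residual(rmap) <= 1e-4

    def test_exact_map_zero_residual(self, small_cluster):
        rmap = WalkRelevanceMap(
            walks=[(0, 1), (1, 0)],
            relevances=np.array([0.75, 0.25]),
            y=1.0,
            depth=1,
            rule=w.RuleConfig(),
            conformer=small_cluster,
        )
        assert w.conservation_residual(rmap) == 0.0

    def test_residual_monotone_in_epsilon(self, small_config, small_cluster):
        params = w.init_params(small_config, seed=3)
        res = [
            w.conservation_residual(
                w.walk_relevances(
                    params, small_config, small_cluster, w.RuleConfig(epsilon=e)
                )
            )
            for e in (0.0, 1e-6, 1e-3, 1e-1, 1.0)
        ]
        assert all(a < b for a, b in zip(res, res[1:]))

    def test_zero_readout_gives_zero_everything(self, small_config, small_cluster):
        params = w.init_params(small_config, seed=1)
        params.wout = np.zeros_like(params.wout)
        rmap = w.walk_relevances(params, small_config, small_cluster)
        assert rmap.y == 0.0
        assert np.all(rmap.relevances == 0.0)

    def test_marginalising_walks_recovers_atom_energies(self, trained6, cluster6_data):
        conf = cluster6_data[1]
        trace = w.forward_energy(trained6.params_, trained6.config_, conf)
        rmap = w.walk_relevances(trained6.params_, trained6.config_, conf)
        for k in range(conf.n_atoms):
            summed = sum(
                r for walk, r in zip(rmap.walks, rmap.relevances) if walk[-1] == k
            )
            assert summed == pytest.approx(trace.atom_energies[k], rel=1e-4, abs=1e-10)

    def test_permutation_equivariance_of_relevances(self, small_config, small_cluster):
        params = w.init_params(small_config, seed=6)
        rmap = w.walk_relevances(params, small_config, small_cluster)
        perm = np.array([4, 2, 0, 5, 3, 1])
        inv = np.argsort(perm)
        rmapP = w.walk_relevances(
            params, small_config, small_cluster.permuted(perm)
        )
        lookup = rmapP.to_dict()
        for walk, r in zip(rmap.walks, rmap.relevances):
            relabeled = tuple(int(inv[v]) for v in walk)
            assert lookup[relabeled] == pytest.approx(float(r), rel=1e-9, abs=1e-12)


class TestLinearOracle:
    def _linear_setup(self, depth, seed):
        cfg = w.ModelConfig(
            depth=depth, cutoff=4.0, embedding_dim=6, filter_hidden=6,
            readout_hidden=6, elements=("C",), activation="identity",
        )
        return cfg, w.init_params(cfg, seed=seed)

    @pytest.mark.parametrize("depth", [1, 2])
    def test_engine_matches_algebraic_expansion(self, depth, small_cluster):
        cfg, params = self._linear_setup(depth, seed=depth)
        oracle = w.linear_oracle_relevances(params, cfg, small_cluster)
        engine = w.walk_relevances(
            params, cfg, small_cluster, w.RuleConfig(epsilon=0.0)
        )
        od, ed = oracle.to_dict(), engine.to_dict()
        assert od.keys() == ed.keys()
        scale = max(abs(v) for v in od.values())
        for walk in od:
            assert abs(od[walk] - ed[walk]) <= 1e-10 * max(scale, 1.0)

    def test_oracle_total_equals_prediction(self, small_cluster):
        cfg, params = self._linear_setup(2, seed=5)
        oracle = w.linear_oracle_relevances(params, cfg, small_cluster)
        assert oracle.total() == pytest.approx(oracle.y, rel=1e-12, abs=1e-12)

    def test_doubled_readout_doubles_relevances(self, small_cluster):
        cfg, params = self._linear_setup(1, seed=7)
        base = w.linear_oracle_relevances(params, cfg, small_cluster)
        doubled = params.copy()
        doubled.wout = 2.0 * doubled.wout
        twice = w.linear_oracle_relevances(doubled, cfg, small_cluster)
        assert np.allclose(twice.relevances, 2.0 * base.relevances)

    def test_zero_embeddings_zero_relevances(self, small_cluster):
        cfg, params = self._linear_setup(1, seed=8)
        params.emb = np.zeros_like(params.emb)
        oracle = w.linear_oracle_relevances(params, cfg, small_cluster)
        assert np.all(oracle.relevances == 0.0)

    def test_nonlinear_model_rejected(self, small_config, small_cluster):
        params = w.init_params(small_config, seed=0)
        with pytest.raises(w.lrp.NonlinearModelError):
            w.linear_oracle_relevances(params, small_config, small_cluster)

    def test_pair_sum_network_attributes_each_edge_gate(self):
        """A 1-layer linear net with identity combine/readout and unit message
        transform decomposes y into one term per edge: the filter gate value."""
        conf = w.Conformer(["C"] * 3, [[0, 0, 0], [0, 0, 1.6], [0, 0, 3.2]])
        cfg = w.ModelConfig(
            depth=1, cutoff=2.0, embedding_dim=1, filter_hidden=4,
            readout_hidden=1, elements=("C",), activation="identity",
        )
        params = w.init_params(cfg, seed=3)
        params.emb = np.ones_like(params.emb)
        params.layers[0]["C"] = np.zeros((1, 1))
        params.layers[0]["U"] = np.ones((1, 1))
        params.Wr = np.ones((1, 1))
        params.wout = np.ones(1)
        trace = w.forward_energy(params, cfg, conf)
        rmap = w.walk_relevances(params, cfg, conf, w.RuleConfig(epsilon=0.0))
        gates = {tuple(e): g for e, g in zip(trace.graph.edges, trace.gamma[0][:, 0])}
        lookup = rmap.to_dict()
        for (j, k), gate in gates.items():
            assert lookup[(j, k)] == pytest.approx(gate, rel=1e-12)
        for k in range(3):
            assert lookup[(k, k)] == 0.0  # combine weight is zero


class TestSerialization:
    def test_csv_round_trip(self, small_config, small_cluster, tmp_path):
        params = w.init_params(small_config, seed=2)
        rmap = w.walk_relevances(params, small_config, small_cluster)
        path = tmp_path / "walks.csv"
        rmap.to_csv(path)
        back = WalkRelevanceMap.from_csv(path)
        assert back.walks == rmap.walks
        assert np.array_equal(back.relevances, rmap.relevances)
        assert back.y == rmap.y
        assert back.depth == rmap.depth
        assert back.rule.epsilon == rmap.rule.epsilon
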