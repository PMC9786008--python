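"""GIN channel vs a brute-force double-loop message-passing oracle."""

import numpy as np
import pytest

from adrnet.errors import ConfigurationError
from adrnet.featurize import (
    BondDirection,
    BondType,
    Chirality,
    MolecularGraph,
    smiles_to_graph,
)
from adrnet.graph_channel import (
    GinParams,
    batch_graphs,
    edge_discrimination_accuracy,
    encode_three_objectives,
    gin_encode,
    gin_encode_batch,
    gin_message_pass,
    gin_node_states,
    init_gin_params,
    load_weights,
    save_weights,
    toy_pretrain,
)


def random_graph(rng: np.random.Generator, n_nodes: int) -> MolecularGraph:
    """Random connected-ish molecular graph with random attributes."""
    nodes = [
        (int(rng.integers(1, 119)), Chirality(int(rng.integers(0, 4))))
        for _ in range(n_nodes)
    ]
    edges, attrs = [], []
    for v in range(1, n_nodes):  # random spanning tree
        u = int(rng.integers(0, v))
        edges.append((u, v))
        attrs.append(
            (BondType(int(rng.integers(0, 4))), BondDirection(int(rng.integers(0, 3))))
        )
    return MolecularGraph(nodes, edges, attrs)


def oracle_states(graph: MolecularGraph, params: GinParams) -> np.ndarray:
    """Direct per-node evaluation of the update equations.

    m_u = sum_{v in N(u)} W (h_v + e_uv); h_u' = W (h_u + m_u), iterated T
    times from the attribute-embedding initial states.
    """
    dim = params.dim
    h = np.zeros((graph.num_nodes, dim))
    for u, (a, c) in enumerate(graph.node_attrs):
        h[u] = params.atom_emb.data[a] + params.chirality_emb.data[int(c)]
    neighbors: dict[int, list[tuple[int, int]]] = {
        u: [] for u in range(graph.num_nodes)
    }
    for k, (u, v) in enumerate(graph.edges):
        neighbors[u].append((v, k))
        neighbors[v].append((u, k))
    for t in range(params.T):
        W = params.Ws[t].data
        new_h = np.zeros_like(h)
        for u in range(graph.num_nodes):
            m = np.zeros(dim)
            for v, k in neighbors[u]:
                bt, bd = graph.edge_attrs[k]
                e = (
                    params.bond_type_emb.data[int(bt)]
                    + params.bond_dir_emb.data[int(bd)]
                )
                m += (h[v] + e) @ W
            new_h[u] = (h[u] + m) @ W
        h = new_h
    return h


@pytest.fixture
def params64():
    return init_gin_params(dim=16, T=3, seed=1, dtype=np.float64)


class TestMessagePassing:
    def test_single_node_identity_update(self):
        graph = MolecularGraph([(6, Chirality.UNSPECIFIED)], [], [])
        params = init_gin_params(dim=4, T=1, seed=0, dtype=np.float64)
        params.Ws[0].data = np.eye(4)
        h0 = np.array([[1.0, -2.0, 0.5, 3.0]])
        h1 = gin_message_pass(graph, h0, params, 0)
        np.testing.assert_allclose(h1, h0)  # empty neighbor sum, identity W

    def test_symmetric_two_node_path_stays_symmetric(self, params64):
        graph = MolecularGraph(
            [(6, Chirality.UNSPECIFIED), (6, Chirality.UNSPECIFIED)],
            [(0, 1)],
            [(BondType.SINGLE, BondDirection.NONE)],
        )
        h = gin_node_states(batch_graphs([graph]), params64).data
        np.testing.assert_allclose(h[0], h[1], rtol=1e-10)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_bruteforce_oracle_small_graphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 6))
        graph = random_graph(rng, n)
        params = init_gin_params(dim=12, T=3, seed=seed + 100, dtype=np.float64)
        expected = oracle_states(graph, params)
        actual = gin_node_states(batch_graphs([graph]), params).data
        np.testing.assert_allclose(actual, expected, rtol=1e-8, atol=1e-10)

    def test_single_iteration_oracle(self, params64):
        rng = np.random.default_rng(0)
        graph = random_graph(rng, 3)
        h0 = rng.normal(size=(3, 16))
        one_step = init_gin_params(dim=16, T=1, seed=1, dtype=np.float64)
        one_step.Ws[0].data = params64.Ws[0].data
        one_step.bond_type_emb.data = params64.bond_type_emb.data
        one_step.bond_dir_emb.data = params64.bond_dir_emb.data
        got = gin_message_pass(graph, h0, params64, 0)
        # brute force one step from the supplied states
        W = params64.Ws[0].data
        expected = np.zeros_like(h0)
        for u in range(3):
            m = np.zeros(16)
            for k, (a, b) in enumerate(graph.edges):
                for x, v in ((a, b), (b, a)):
                    if x == u:
                        bt, bd = graph.edge_attrs[k]
                        e = (
                            params64.bond_type_emb.data[int(bt)]
                            + params64.bond_dir_emb.data[int(bd)]
                        )
                        m += (h0[v] + e) @ W
            expected[u] = (h0[u] + m) @ W
        np.testing.assert_allclose(got, expected, rtol=1e-10)

    def test_state_shape_mismatch_rejected(self, params64):
        graph = smiles_to_graph("CCO")
        with pytest.raises(ConfigurationError):
            gin_message_pass(graph, np.zeros((2, 16)), params64, 0)


class TestEncode:
    def test_single_node_embedding_is_final_state(self, params64):
        graph = MolecularGraph([(8, Chirality.UNSPECIFIED)], [], [])
        emb = gin_encode(graph, params64)
        states = gin_node_states(batch_graphs([graph]), params64).data
        np.testing.assert_allclose(emb.vector, states[0])

    @pytest.mark.parametrize("seed", range(4))
    def test_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        graph = random_graph(rng, 5)
        params = init_gin_params(dim=16, T=3, seed=seed, dtype=np.float64)
        perm = rng.permutation(5)
        inv = np.argsort(perm)
        relabeled = MolecularGraph(
            [graph.node_attrs[j] for j in perm],
            [(int(inv[u]), int(inv[v])) for u, v in graph.edges],
            list(graph.edge_attrs),
        )
        a = gin_encode(graph, params).vector
        b = gin_encode(relabeled, params).vector
        np.testing.assert_allclose(a, b, atol=1e-6)

    def test_encode_matches_oracle_maxpool(self):
        rng = np.random.default_rng(7)
        graph = random_graph(rng, 4)
        params = init_gin_params(dim=12, T=3, seed=8, dtype=np.float64)
        expected = oracle_states(graph, params).max(axis=0)
        np.testing.assert_allclose(
            gin_encode(graph, params).vector, expected, rtol=1e-8, atol=1e-10
        )

    def test_maxpool_monotone_under_positive_scaling(self, params64):
        graph = smiles_to_graph("CCO")
        batch = batch_graphs([graph])
        states = np.abs(gin_node_states(batch, params64).data)
        from adrnet.autodiff import Tensor

        pooled = Tensor(states).segment_max(batch.graph_index, 1).data
        scaled = Tensor(3.0 * states).segment_max(batch.graph_index, 1).data
        np.testing.assert_allclose(scaled, 3.0 * pooled, rtol=1e-10)

    def test_three_objectives_order_and_tags(self, params64):
        graph = smiles_to_graph("c1ccccc1")
        pe = init_gin_params(dim=16, T=3, objective_tag="e", seed=2, dtype=np.float64)
        pc = init_gin_params(dim=16, T=3, objective_tag="c", seed=3, dtype=np.float64)
        xm, xe, xc = encode_three_objectives(graph, params64, pe, pc)
        assert (xm.objective_tag, xe.objective_tag, xc.objective_tag) == ("m", "e", "c")
        assert not np.allclose(xm.vector, xe.vector)

    def test_identical_params_identical_embeddings(self, params64):
        graph = smiles_to_graph("CCN")
        xm, xe, xc = encode_three_objectives(graph, params64, params64, params64)
        np.testing.assert_array_equal(xm.vector, xe.vector)
        np.testing.assert_array_equal(xe.vector, xc.vector)

    def test_batch_equals_individual(self, params64):
        graphs = [smiles_to_graph(s) for s in ("CCO", "c1ccccc1", "CC(=O)O")]
        batched = gin_encode_batch(batch_graphs(graphs), params64).data
        for i, g in enumerate(graphs):
            np.testing.assert_allclose(
                batched[i], gin_encode(g, params64).vector, rtol=1e-10
            )


class TestWeightsIO:
    def test_roundtrip_exact(self, tmp_path, params64):
        path = tmp_path / "gin.npz"
        save_weights(params64, path)
        loaded = load_weights(path)
        assert loaded.dim == params64.dim and loaded.T == params64.T
        for a, b in zip(params64.tensors(), loaded.tensors()):
            np.testing.assert_array_equal(a.data, b.data)
        graph = smiles_to_graph("CCO")
        np.testing.assert_array_equal(
            gin_encode(graph, params64).vector, gin_encode(graph, loaded).vector
        )

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_weights(tmp_path / "absent.npz")

    def test_dim_mismatch_named(self, tmp_path, params64):
        path = tmp_path / "gin.npz"
        save_weights(params64, path)
        import numpy as _np

        with _np.load(path) as npz:
            data = {k: npz[k] for k in npz.files}
        data["W_0"] = data["W_0"][:8, :8]
        with open(path, "wb") as f:
            _np.savez(f, **data)
        with pytest.raises(ConfigurationError, match="dim"):
            load_weights(path)

    def test_truncated_file(self, tmp_path):
        path = tmp_path / "junk.npz"
        path.write_bytes(b"PK\x03\x04broken")
        with pytest.raises(IOError):
            load_weights(path)


@pytest.fixture(scope="module")
def path_graphs():
    rng = np.random.default_rng(0)
    return [random_graph(rng, int(rng.integers(4, 9))) for _ in range(20)]


class TestToyPretrain:
    def test_edge_objective_beats_chance(self, path_graphs):
        params = init_gin_params(dim=16, T=2, seed=0, dtype=np.float64)
        trained = toy_pretrain(path_graphs, "edge", params, epochs=50, seed=1)
        acc = edge_discrimination_accuracy(path_graphs, trained, seed=99)
        assert acc > 0.5

    def test_seeded_determinism(self, path_graphs):
        params = init_gin_params(dim=8, T=2, seed=0, dtype=np.float64)
        a = toy_pretrain(path_graphs, "edge", params, epochs=3, seed=4)
        b = toy_pretrain(path_graphs, "edge", params, epochs=3, seed=4)
        for x, y in zip(a.tensors(), b.tensors()):
            np.testing.assert_array_equal(x.data, y.data)

    def test_zero_epochs_is_noop(self, path_graphs):
        params = init_gin_params(dim=8, T=2, seed=0, dtype=np.float64)
        out = toy_pretrain(path_graphs, "infomax", params, epochs=0, seed=0)
        for x, y in zip(params.tensors(), out.tensors()):
            np.testing.assert_array_equal(x.data, y.data)

    def test_infomax_runs_and_changes_params(self, path_graphs):
        params = init_gin_params(dim=8, T=2, seed=0, dtype=np.float64)
        out = toy_pretrain(path_graphs, "infomax", params, epochs=2, seed=0)
        assert any(
            not np.array_equal(x.data, y.data)
            for x, y in zip(params.tensors(), out.tensors())
        )

    def test_context_not_implemented(self, path_graphs):
        params = init_gin_params(dim=8, T=2, seed=0, dtype=np.float64)
        with pytest.raises(NotImplementedError):
            toy_pretrain(path_graphs, "context", params, epochs=1, seed=0)

    def test_needs_two_graphs(self, path_graphs):
        params = init_gin_params(dim=8, T=2, seed=0, dtype=np.float64)
        with pytest.raises(ConfigurationError):
            toy_pretrain(path_graphs[:1], "edge", params, epochs=1, seed=0)
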