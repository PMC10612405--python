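import numpy as np
import pytest

from structfunc.model import (AttentionScores, FunctionPredictor, GraphBatch,
                              ModelConfig, ProteinSample, attention_score,
                              graph_conv, normalized_adjacency, readout,
                              top_rank_indices, top_rank_pool, train)
from structfunc.structure import ContactGraph

from conftest import random_graph


def dense_conv_oracle(features, graph, weights):
    """Independent dense D̃^{-1/2} Ã D̃^{-1/2} h Θ computation."""
    n = graph.n_nodes
    a_tilde = np.zeros((n, n))
    for i, j in graph.edges:
        a_tilde[i, j] = a_tilde[j, i] = 1.0
    a_tilde += np.eye(n)
    d = np.diag(a_tilde.sum(axis=1))
    d_inv_sqrt = np.diag(1.0 / np.sqrt(np.diag(d)))
    return d_inv_sqrt @ a_tilde @ d_inv_sqrt @ features @ weights


class TestGraphConv:
    def test_single_node_identity(self):
        g = ContactGraph("n1", 1, set())
        x = np.array([[1.0, 2.0]])
        np.testing.assert_allclose(graph_conv(x, g, np.eye(2)), x)

    def test_disconnected_nodes_identity(self):
        g = ContactGraph("n2", 2, set())
        x = np.array([[1.0, 2.0], [3.0, 4.0]])
        np.testing.assert_allclose(graph_conv(x, g, np.eye(2)), x)

    def test_matches_dense_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(2, 7))
            g = random_graph(rng, n)
            x = rng.standard_normal((n, 4))
            w = rng.standard_normal((4, 3))
            got = graph_conv(x, g, w)
            np.testing.assert_allclose(got, dense_conv_oracle(x, g, w), atol=1e-10)

    def test_activation_applied(self, rng):
        g = random_graph(rng, 5)
        x = rng.standard_normal((5, 3))
        w = rng.standard_normal((3, 3))
        got = graph_conv(x, g, w, activation=np.tanh)
        np.testing.assert_allclose(got, np.tanh(dense_conv_oracle(x, g, w)))

    def test_dimension_mismatch_errors(self, rng):
        g = random_graph(rng, 4)
        with pytest.raises(ValueError):
            graph_conv(rng.standard_normal((4, 3)), g, rng.standard_normal((5, 2)))
        with pytest.raises(ValueError):
            graph_conv(rng.standard_normal((3, 3)), g, rng.standard_normal((3, 2)))


class TestAttentionScore:
    def test_identical_heads_mean_equals_head(self, rng):
        g = random_graph(rng, 6)
        x = rng.standard_normal((6, 4))
        w = rng.standard_normal((4, 1))
        scores = attention_score(x, g, [w, w])
        np.testing.assert_allclose(scores.mean, scores.per_head[0])

    def test_single_head_degenerate_mean(self, rng):
        g = random_graph(rng, 5)
        x = rng.standard_normal((5, 3))
        w = rng.standard_normal((3, 1))
        scores = attention_score(x, g, [w])
        np.testing.assert_allclose(scores.mean, scores.per_head[0])

    def test_permutation_equivariance(self, rng):
        n = 7
        g = random_graph(rng, n)
        x = rng.standard_normal((n, 4))
        ws = [rng.standard_normal((4, 1)) for _ in range(2)]
        base = attention_score(x, g, ws).mean
        perm = rng.permutation(n)
        inv = np.argsort(perm)
        g_perm = ContactGraph("perm", n, {
            (min(int(inv[i]), int(inv[j])), max(int(inv[i]), int(inv[j])))
            for i, j in g.edges
        })
        permuted = attention_score(x[perm], g_perm, ws).mean
        np.testing.assert_allclose(permuted, base[perm], atol=1e-12)


class TestTopRankPool:
    def test_k_one_is_identity(self, rng):
        g = random_graph(rng, 6)
        x = rng.standard_normal((6, 3))
        scores = AttentionScores(rng.standard_normal((1, 6)))
        feats, sub = top_rank_pool(x, g, scores, k=1.0)
        assert sub.n_nodes == 6
        assert sub.edges == g.edges
        np.testing.assert_allclose(feats, x * np.tanh(scores.mean)[:, None])

    def test_top_half_matches_exhaustive_sort(self, rng):
        g = random_graph(rng, 8)
        x = rng.standard_normal((8, 3))
        z = rng.permutation(8).astype(float)    # distinct scores
        scores = AttentionScores(z[None, :])
        feats, sub = top_rank_pool(x, g, scores, k=0.5)
        expected_idx = np.sort(np.argsort(-z)[:4])
        np.testing.assert_array_equal(top_rank_indices(z, 0.5), expected_idx)
        np.testing.assert_allclose(
            feats, x[expected_idx] * np.tanh(z[expected_idx])[:, None])
        assert sub.n_nodes == 4

    @pytest.mark.parametrize("n,k", [(n, k) for n in range(1, 11)
                                     for k in (0.25, 0.5, 0.75, 1.0)])
    def test_retained_count_is_ceiling(self, n, k, rng):
        z = rng.standard_normal(n)
        idx = top_rank_indices(z, k)
        assert len(idx) == max(1, int(np.ceil(k * n)))
        # retained set equals exhaustive sort
        order = sorted(range(n), key=lambda i: (-z[i], i))
        assert set(idx.tolist()) == set(order[:len(idx)])

    def test_tie_break_prefers_lower_index(self):
        z = np.array([1.0, 1.0, 1.0, 0.0])
        np.testing.assert_array_equal(top_rank_indices(z, 0.5), [0, 1])

    def test_minimum_one_node_retained(self):
        assert top_rank_indices(np.array([0.3]), 0.25).tolist() == [0]

    def test_induced_subgraph_edges(self, rng):
        g = ContactGraph("g", 4, {(0, 1), (1, 2), (2, 3), (0, 3)})
        scores = AttentionScores(np.array([[3.0, 2.0, 1.0, 0.0]]))
        _, sub = top_rank_pool(rng.standard_normal((4, 2)), g, scores, 0.75)
        # nodes 0,1,2 retained; edges (0,1),(1,2) survive
        assert sub.n_nodes == 3
        assert sub.edges == {(0, 1), (1, 2)}


class TestReadout:
    def test_single_node_doubles_feature(self):
        x = np.array([[1.0, -2.0, 3.0]])
        np.testing.assert_array_equal(readout(x), np.array([1, -2, 3, 1, -2, 3]))

    def test_permutation_invariance_exact(self, rng):
        x = rng.standard_normal((9, 4))
        base = readout(x)
        for _ in range(25):
            np.testing.assert_array_equal(readout(x[rng.permutation(9)]), base)

    def test_matches_column_loop_oracle(self, rng):
        x = rng.standard_normal((5, 3))
        mean = [sum(x[i, j] for i in range(5)) / 5 for j in range(3)]
        mx = [max(x[i, j] for i in range(5)) for j in range(3)]
        np.testing.assert_allclose(readout(x), np.array(mean + mx))

    def test_sum_mode(self, rng):
        x = rng.standard_normal((4, 2))
        out = readout(x, mode="sum_max")
        np.testing.assert_allclose(out[:2], x.sum(axis=0))
        np.testing.assert_allclose(out[2:], x.max(axis=0))

    def test_empty_graph_errors(self):
        with pytest.raises(ValueError):
            readout(np.zeros((0, 3)))


def make_samples(rng, n, n_nodes=12, n_labels=3):
    samples = []
    for i in range(n):
        g = random_graph(rng, n_nodes, p=0.3, protein_id=f"P{i}")
        x = rng.standard_normal((n_nodes, 50))
        seq = rng.standard_normal(1024)
        flag = i % 2 == 0
        seq[:8] += 2.0 * flag
        y = np.array([1.0 * flag, 1.0 - flag, 1.0])[:n_labels]
        samples.append(ProteinSample(f"P{i}", g, x, seq, y))
    return samples


SMALL = dict(hidden_dim=16, mlp_hidden=32, learning_rate=1e-3,
             batch_size=4, eval_every=5)


class TestForward:
    def test_output_shape_and_sigmoid_range(self, rng):
        samples = make_samples(rng, 5)
        model = FunctionPredictor(50, 3, ModelConfig(**SMALL, seed=1))
        probs = model.predict(samples)
        assert probs.shape == (5, 3)
        assert np.all((probs > 0) & (probs < 1))

    def test_deterministic_given_seed(self, rng):
        samples = make_samples(rng, 4)
        p1 = FunctionPredictor(50, 3, ModelConfig(**SMALL, seed=2)).predict(samples)
        p2 = FunctionPredictor(50, 3, ModelConfig(**SMALL, seed=2)).predict(samples)
        np.testing.assert_array_equal(p1, p2)

    def test_batched_equals_per_protein(self, rng):
        samples = make_samples(rng, 6)
        model = FunctionPredictor(50, 3, ModelConfig(**SMALL, seed=3))
        batched = model.predict(samples)
        singles = np.concatenate([model.predict([s]) for s in samples])
        np.testing.assert_allclose(batched, singles, atol=1e-5)

    def test_missing_embedding_shape_errors(self, rng):
        samples = make_samples(rng, 2)
        model = FunctionPredictor(50, 3, ModelConfig(**SMALL, seed=0))
        batch = GraphBatch([s.graph for s in samples],
                           [s.residue_features for s in samples])
        with pytest.raises(ValueError):
            model.forward(batch, np.zeros((2, 512)))

    def test_hierarchical_pooling_strictly_reduces_nodes(self, rng):
        g = random_graph(rng, 16, p=0.4)
        k = 0.75
        n1 = len(top_rank_indices(rng.standard_normal(16), k))
        assert n1 == int(np.ceil(0.75 * 16)) == 12
        n2 = len(top_rank_indices(rng.standard_normal(n1), k))
        assert n2 == int(np.ceil(0.75 * 12)) == 9

    def test_graph_batch_membership_and_block_adjacency(self, rng):
        samples = make_samples(rng, 3, n_nodes=5)
        batch = GraphBatch([s.graph for s in samples],
                           [s.residue_features for s in samples])
        assert batch.membership.tolist() == [0] * 5 + [1] * 5 + [2] * 5
        blk = batch.block_adjacency().toarray()
        assert blk.shape == (15, 15)
        np.testing.assert_array_equal(blk[:5, :5], samples[0].graph.adjacency())
        assert np.all(blk[:5, 5:] == 0)


class TestTraining:
    def test_overfits_small_dataset(self, rng):
        samples = make_samples(rng, 12)
        cfg = ModelConfig(**SMALL, epochs=60, dropout=0.0, seed=4)
        _model, hist = train(samples, [], cfg)
        assert hist["loss"][-1] < 0.1 * hist["loss"][0]

    def test_same_seed_identical_loss_curves(self, rng):
        samples = make_samples(rng, 8)
        cfg = ModelConfig(**SMALL, epochs=5, seed=5)
        _m1, h1 = train(samples, [], cfg)
        _m2, h2 = train(samples, [], cfg)
        assert h1["loss"] == h2["loss"]

    def test_validation_selection_recorded(self, rng):
        samples = make_samples(rng, 12)
        cfg = ModelConfig(**SMALL, epochs=11, seed=6)
        _m, hist = train(samples[:8], samples[8:], cfg)
        assert "best_epoch" in hist
        assert hist["val_fmax"]

    def test_empty_training_set_errors(self):
        with pytest.raises(ValueError):
            train([], [], ModelConfig(**SMALL))

    def test_structure_ablation_changes_predictions(self, rng):
        samples = make_samples(rng, 6)
        cfg = ModelConfig(**SMALL, epochs=3, seed=7)
        m_full, _ = train(samples, [], cfg)
        m_abl, _ = train(samples, [], cfg, ablate_structure=True)
        assert not np.allclose(m_full.predict(samples), m_abl.predict(samples))


def test_normalized_adjacency_row_symmetry(rng):
    g = random_graph(rng, 6)
    norm = normalized_adjacency(g)
    np.testing.assert_allclose(norm, norm.T, atol=1e-12)


def test_config_validation():
    with pytest.raises(ValueError):
        ModelConfig(pooling_ratio=0.0)
    with pytest.raises(ValueError):
        ModelConfig(dropout=1.0)
    with pytest.raises(NotImplementedError):
        ModelConfig(conv_type="gat")
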