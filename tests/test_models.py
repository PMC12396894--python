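"""Architecture contracts for the three graph classifiers: output
normalization, permutation invariance, pooling behaviour, determinism,
analytic-vs-numeric gradients and oracle equivalence on toy graphs."""

import numpy as np
import pytest

import fcgnn
from fcgnn import autodiff as ad
from fcgnn.models import (ModelConfig, build_model, batch_graphs,
                          normalized_adjacency, load_model, SAGPoolClassifier)

from conftest import toy_graphs, random_connectivity

ARCHS = ("gcn", "gat", "sagpool")


def small_config(arch: str, n: int, seed: int = 0) -> ModelConfig:
    """Downsized layer widths: contracts are size-independent."""
    return ModelConfig(architecture=arch, input_dim=n, seed=seed,
                       gcn_hidden=(8, 6), gat_units=(4, 4, 4),
                       gat_heads=(2, 2, 1), sag_hidden=6)


@pytest.mark.parametrize("arch", ARCHS)
def test_output_is_probability_simplex(arch):
    graphs = toy_graphs(0, 5, 7)
    model = build_model(small_config(arch, 7))
    p = model.predict_proba(graphs)
    assert p.shape == (5, 2)
    assert np.allclose(p.sum(axis=1), 1.0)
    assert np.all((p > 0) & (p < 1))


@pytest.mark.parametrize("arch", ARCHS)
def test_zeroed_output_layer_gives_uniform_probabilities(arch):
    graphs = toy_graphs(1, 3, 6)
    model = build_model(small_config(arch, 6))
    model._params["Wout"].data[:] = 0.0
    model._params["bout"].data[:] = 0.0
    p = model.predict_proba(graphs)
    assert np.allclose(p, 0.5)


@pytest.mark.parametrize("arch", ARCHS)
def test_evaluation_mode_is_deterministic(arch):
    graphs = toy_graphs(2, 4, 8)
    model = build_model(small_config(arch, 8))
    p1 = model.predict_proba(graphs)
    p2 = model.predict_proba(graphs)
    assert np.array_equal(p1, p2)


@pytest.mark.parametrize("arch", ARCHS)
def test_permutation_invariance_of_graph_output(arch):
    """Consistently relabeling nodes (rows of X, both axes of A) leaves the
    graph-level output unchanged to 1e-5."""
    rng = np.random.default_rng(7)
    graphs = toy_graphs(3, 2, 9)
    X, A = batch_graphs(graphs)
    model = build_model(small_config(arch, 9))
    p0 = model.predict_proba_arrays(X, A)
    perm = rng.permutation(9)
    Xp = X[:, perm, :]
    Ap = A[:, perm][:, :, perm]
    p1 = model.predict_proba_arrays(Xp, Ap)
    assert np.allclose(p0, p1, atol=1e-5)


@pytest.mark.parametrize("arch", ARCHS)
def test_numeric_vs_analytic_gradients(arch):
    """Backprop gradients of the cross-entropy match central finite
    differences to 1e-4 on a 5-node toy."""
    rng = np.random.default_rng(5)
    graphs = toy_graphs(4, 3, 5, k=2)
    X, A = batch_graphs(graphs)
    y = np.array([0, 1, 0])
    model = build_model(small_config(arch, 5, seed=2))
    loss = ad.softmax_cross_entropy(model.logits(X, A), y)
    loss.backward()
    for name, p in model._params.items():
        grad = p.grad if p.grad is not None else np.zeros_like(p.data)
        flat = p.data.ravel()
        for ii in rng.choice(flat.size, size=min(4, flat.size), replace=False):
            eps = 1e-6
            orig = flat[ii]
            flat[ii] = orig + eps
            fp = float(ad.softmax_cross_entropy(model.logits(X, A), y).data)
            flat[ii] = orig - eps
            fm = float(ad.softmax_cross_entropy(model.logits(X, A), y).data)
            flat[ii] = orig
            num = (fp - fm) / (2 * eps)
            assert abs(num - grad.ravel()[ii]) <= 1e-4 * max(1.0, abs(num)), name


def test_gcn_single_node_equals_mlp_oracle():
    """On a single self-looped node the GCN collapses to a plain two-layer
    perceptron, reproduced here with loop-free matrix arithmetic."""
    rng = np.random.default_rng(9)
    x = rng.normal(size=(1, 1, 4))
    A = np.zeros((1, 1, 1))
    model = build_model(ModelConfig(architecture="gcn", input_dim=4,
                                    gcn_hidden=(6, 5), seed=3))
    p = model.predict_proba_arrays(x, A)
    W1 = model._params["W1"].data
    b1 = model._params["b1"].data
    W2 = model._params["W2"].data
    b2 = model._params["b2"].data
    Wo = model._params["Wout"].data
    bo = model._params["bout"].data
    h = np.maximum(x[0] @ W1 + b1, 0)
    h = np.maximum(h @ W2 + b2, 0)
    logits = h @ Wo + bo
    expected = np.exp(logits) / np.exp(logits).sum()
    assert np.allclose(p[0], expected.ravel(), atol=1e-12)


class TestGAT:
    def test_attention_rows_sum_to_one_with_single_neighbor(self):
        # node 0 has one neighbour (node 1) plus its self-loop
        m = fcgnn.ConnectivityMatrix(
            np.array([[0, 0.5, 0.0], [0.5, 0, 0.4], [0.0, 0.4, 0]]), "t")
        g = fcgnn.build_graph(m, 1)
        X, A = batch_graphs([g])
        model = build_model(small_config("gat", 3))
        alpha = model.attention(X, A, layer=0)
        assert np.allclose(alpha.sum(axis=-1), 1.0)
        # masked entries carry (numerically) zero attention
        assert alpha[0, 0, 0, 2] < 1e-12

    def test_attention_matches_enumeration_oracle(self):
        """Attention coefficients on a 3-node toy equal a direct evaluation
        of the LeakyReLU scoring formula."""
        rng = np.random.default_rng(13)
        m = random_connectivity(rng, 3)
        g = fcgnn.build_graph(m, 2)  # complete graph
        X, A = batch_graphs([g])
        model = build_model(small_config("gat", 3))
        alpha = model.attention(X, A, layer=0)
        W = model._params["W0"].data        # (heads, F, U)
        asrc = model._params["asrc0"].data  # (heads, U, 1)
        adst = model._params["adst0"].data
        for h in range(W.shape[0]):
            Z = X[0] @ W[h]
            for i in range(3):
                scores = []
                for j in range(3):
                    e = float((Z[i] @ asrc[h] + Z[j] @ adst[h]).item())
                    scores.append(e if e > 0 else 0.2 * e)
                ex = np.exp(scores - np.max(scores))
                expected = ex / ex.sum()
                assert np.allclose(alpha[0, h, i], expected, atol=1e-10)


class TestSAGPool:
    def test_hundred_node_graph_keeps_eighty(self):
        graphs = toy_graphs(6, 1, 100, k=5)
        X, A = batch_graphs(graphs)
        model = build_model(ModelConfig(architecture="sagpool", input_dim=100,
                                        sag_blocks=1, seed=0))
        scores = np.random.default_rng(0).normal(size=(1, 100))
        idx = SAGPoolClassifier.top_k_indices(scores, 0.8)
        assert idx.shape == (1, 80)
        # and the full forward with 3 blocks runs 100 -> 80 -> 64 -> 52
        p = model.predict_proba_arrays(X, A)
        assert p.shape == (1, 2)

    def test_keep_ratio_one_preserves_graph(self):
        scores = np.array([[3.0, 1.0, 2.0, 0.5]])
        idx = SAGPoolClassifier.top_k_indices(scores, 1.0)
        assert np.array_equal(idx, [[0, 1, 2, 3]])

    def test_retained_set_matches_argsort_oracle(self):
        rng = np.random.default_rng(17)
        scores = rng.normal(size=(4, 6))
        idx = SAGPoolClassifier.top_k_indices(scores, 0.8)  # ceil(4.8) = 5
        for b in range(4):
            expected = np.sort(np.argsort(-scores[b], kind="stable")[:5])
            assert np.array_equal(idx[b], expected)

    def test_tie_break_prefers_lower_node_index(self):
        scores = np.array([[1.0, 2.0, 1.0, 1.0]])
        idx = SAGPoolClassifier.top_k_indices(scores, 0.5)  # keep 2
        assert np.array_equal(idx, [[0, 1]])

    def test_invalid_keep_ratio_rejected(self):
        with pytest.raises(ValueError, match="keep-ratio"):
            ModelConfig(architecture="sagpool", input_dim=5, sag_keep_ratio=0.0)
        with pytest.raises(ValueError, match="keep-ratio"):
            ModelConfig(architecture="sagpool", input_dim=5, sag_keep_ratio=1.2)


def test_normalized_adjacency_symmetric_with_self_loops():
    rng = np.random.default_rng(23)
    g = toy_graphs(8, 1, 6)[0]
    A = g.adjacency()[None]
    Ahat = normalized_adjacency(A)[0]
    assert np.allclose(Ahat, Ahat.T)
    # oracle: explicit D^{-1/2} (A + I) D^{-1/2}
    Ai = A[0] + np.eye(6)
    d = Ai.sum(1)
    expected = np.diag(d**-0.5) @ Ai @ np.diag(d**-0.5)
    assert np.allclose(Ahat, expected, atol=1e-12)
    assert rng is not None


@pytest.mark.parametrize("arch", ARCHS)
def test_checkpoint_round_trip(tmp_path, arch):
    graphs = toy_graphs(10, 2, 6)
    model = build_model(small_config(arch, 6, seed=4))
    p0 = model.predict_proba(graphs)
    model.save(tmp_path / "m.npz")
    restored = load_model(tmp_path / "m.npz")
    assert np.array_equal(restored.predict_proba(graphs), p0)


def test_float32_cast_matches_float64_forward():
    graphs = toy_graphs(11, 3, 10)
    X, A = batch_graphs(graphs)
    model = build_model(small_config("sagpool", 10))
    p64 = model.predict_proba_arrays(X, A)
    p32 = model.astype(np.float32).predict_proba_arrays(
        X.astype(np.float32), A.astype(np.float32))
    assert np.allclose(p64, p32, atol=1e-5)
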