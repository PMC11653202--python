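import math

import numpy as np
import pytest

import morehg as mh
from morehg.autodiff import Tensor
from morehg.model import MoheEncoder, MosaFusion


class TestHgnnLayer:
    def test_identity_operator_and_weights(self):
        X = np.random.default_rng(0).normal(size=(4, 3))
        out = mh.hgnn_layer(X, np.eye(4), np.eye(3), activation="identity")
        np.testing.assert_array_equal(out, X)

    def test_linear_in_input_with_identity_activation(self):
        rng = np.random.default_rng(1)
        G = rng.random(size=(5, 5))
        theta = rng.normal(size=(3, 2))
        X1, X2 = rng.normal(size=(5, 3)), rng.normal(size=(5, 3))
        a, b = 2.5, -1.25
        lhs = mh.hgnn_layer(a * X1 + b * X2, G, theta, activation="identity")
        rhs = a * mh.hgnn_layer(X1, G, theta, activation="identity") + b * mh.hgnn_layer(
            X2, G, theta, activation="identity"
        )
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)

    def test_matches_naive_triple_loop(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(3, 2))
        G = rng.normal(size=(3, 3))
        theta = rng.normal(size=(2, 2))
        got = mh.hgnn_layer(X, G, theta, activation="identity")
        expected = np.zeros((3, 2))
        for i in range(3):
            for j in range(2):
                expected[i, j] = sum(
                    G[i, a] * X[a, b] * theta[b, j] for a in range(3) for b in range(2)
                )
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_dimension_mismatch_errors(self):
        with pytest.raises(ValueError):
            mh.hgnn_layer(np.ones((3, 2)), np.eye(3), np.ones((5, 4)))


class TestMoheEncoder:
    def test_eval_forward_is_reproducible(self):
        rng = np.random.default_rng(3)
        enc = MoheEncoder(6, mh.ModelConfig(), 2, np.random.default_rng(0))
        X, G = rng.random((8, 6)), np.eye(8)
        e1, l1 = enc.forward(Tensor(X), Tensor(G))
        e2, l2 = enc.forward(Tensor(X), Tensor(G))
        np.testing.assert_array_equal(e1.data, e2.data)
        np.testing.assert_array_equal(l1.data, l2.data)

    def test_logit_shape_and_finiteness(self):
        enc = MoheEncoder(10, mh.ModelConfig(embed_dim=16), 3, np.random.default_rng(1))
        X = np.random.default_rng(4).random((12, 10))
        emb, logits = enc.forward(Tensor(X), Tensor(np.eye(12)))
        assert emb.data.shape == (12, 16)
        assert logits.data.shape == (12, 3)
        assert np.isfinite(logits.data).all()


class TestMosaHead:
    def test_single_modality_attention_is_one(self):
        rng = np.random.default_rng(5)
        tok = rng.normal(size=(1, 4))
        w = {k: rng.normal(size=(4, 3)) for k in ("w_q", "w_k", "w_v")}
        b = {k: rng.normal(size=3) for k in ("b_q", "b_k", "b_v")}
        A, V = mh.mosa_head(tok, w["w_q"], b["b_q"], w["w_k"], b["b_k"], w["w_v"], b["b_v"])
        np.testing.assert_allclose(A, [[1.0]])
        np.testing.assert_allclose(V, tok @ w["w_v"] + b["b_v"])

    def test_equal_scores_give_uniform_attention(self):
        tok = np.ones((3, 4))  # identical tokens -> identical q/k rows
        rng = np.random.default_rng(6)
        wq, wk, wv = (rng.normal(size=(4, 2)) for _ in range(3))
        A, _ = mh.mosa_head(tok, wq, np.zeros(2), wk, np.zeros(2), wv, np.zeros(2))
        np.testing.assert_allclose(A, 1.0 / 3.0)

    def test_two_omics_integer_worked_example(self):
        """Fixed integer weights, d_f = 2: the attention and aggregation
        are computed here literally from the softmax closed form."""
        tok = np.array([[1.0, 0.0], [0.0, 2.0]])  # I=2, embed_dim=2
        wq = np.array([[1.0, 0.0], [0.0, 1.0]])
        wk = np.array([[2.0, 0.0], [0.0, 1.0]])
        wv = np.array([[1.0, 1.0], [0.0, 1.0]])
        z = np.zeros(2)
        A, V = mh.mosa_head(tok, wq, z, wk, z, wv, z)

        q = tok  # identity projection
        k = np.array([[2.0, 0.0], [0.0, 2.0]])
        v = np.array([[1.0, 1.0], [0.0, 2.0]])
        s = np.sqrt(2.0)
        # row 0: scores (q0.k0, q0.k1)/sqrt(2) = (2, 0)/sqrt(2)
        e00, e01 = math.exp(2 / s), math.exp(0.0)
        # row 1: scores (0, 4)/sqrt(2)
        e10, e11 = math.exp(0.0), math.exp(4 / s)
        expected_A = np.array(
            [[e00 / (e00 + e01), e01 / (e00 + e01)],
             [e10 / (e10 + e11), e11 / (e10 + e11)]]
        )
        np.testing.assert_allclose(A, expected_A, atol=1e-8)
        np.testing.assert_allclose(V, expected_A @ v, atol=1e-8)
        assert np.allclose(A.sum(axis=1), 1.0)
        del q  # documented: identity projection keeps q == tokens

    def test_rows_sum_to_one_on_random_inputs(self):
        rng = np.random.default_rng(7)
        for _ in range(250):
            i, d, f = rng.integers(1, 5), rng.integers(1, 6), rng.integers(1, 6)
            tok = rng.normal(size=(i, d)) * rng.uniform(0.1, 10)
            A, _ = mh.mosa_head(
                tok,
                rng.normal(size=(d, f)), rng.normal(size=f),
                rng.normal(size=(d, f)), rng.normal(size=f),
                rng.normal(size=(d, f)), rng.normal(size=f),
            )
            np.testing.assert_allclose(A.sum(axis=1), 1.0, atol=1e-6)
            # strictly in (0,1) in exact arithmetic; extreme scores can
            # underflow a float to exactly 0
            assert (A >= 0).all() and (A <= 1 + 1e-12).all()

    def test_key_scaling_changes_attention_as_closed_form_predicts(self):
        rng = np.random.default_rng(8)
        tok = rng.normal(size=(3, 4))
        wq, wk, wv = (rng.normal(size=(4, 2)) for _ in range(3))
        zeros = np.zeros(2)
        c = 3.0
        A_scaled, _ = mh.mosa_head(tok, wq, zeros, c * wk, zeros, wv, zeros)
        q, k = tok @ wq, tok @ wk
        scores = c * (q @ k.T) / np.sqrt(2)
        e = np.exp(scores - scores.max(axis=1, keepdims=True))
        np.testing.assert_allclose(A_scaled, e / e.sum(axis=1, keepdims=True), atol=1e-10)


class TestMosaFusion:
    def test_single_head_reduces_to_mosa_head_plus_classifier(self):
        cfg = mh.ModelConfig(embed_dim=4, n_heads=1, d_head=3)
        fusion = MosaFusion(2, cfg, 2, np.random.default_rng(9))
        tokens = np.random.default_rng(10).normal(size=(5, 2, 4))
        logits, attn = fusion.forward(Tensor(tokens))
        h = fusion.heads[0]
        for j in range(5):
            A, V = mh.mosa_head(
                tokens[j],
                h["w_q"].data, h["b_q"].data,
                h["w_k"].data, h["b_k"].data,
                h["w_v"].data, h["b_v"].data,
            )
            np.testing.assert_allclose(attn[0][j], A, atol=1e-12)
            expected = V.reshape(-1) @ fusion.clf_w.data + fusion.clf_b.data
            np.testing.assert_allclose(logits.data[j], expected, atol=1e-12)

    @pytest.mark.parametrize("n_heads", [1, 2, 4])
    def test_logit_shape_for_any_head_count(self, n_heads):
        cfg = mh.ModelConfig(embed_dim=4, n_heads=n_heads)
        fusion = MosaFusion(3, cfg, 5, np.random.default_rng(11))
        logits, attn = fusion.forward(
            Tensor(np.random.default_rng(12).normal(size=(6, 3, 4)))
        )
        assert logits.data.shape == (6, 5)
        assert len(attn) == n_heads and attn[0].shape == (6, 3, 3)


class TestFullModel:
    def _data(self, n=10):
        rng = np.random.default_rng(13)
        X_list = [rng.random((n, 6)), rng.random((n, 4))]
        op, _ = mh.build_fused_operator(X_list, [f"v{i}" for i in range(n)], 3)
        return X_list, op.G

    def test_sample_permutation_equivariance(self):
        X_list, G = self._data()
        model = mh.MoreModel([6, 4], 2, mh.ModelConfig(embed_dim=8), seed=1)
        _, fused = model.predict_logits(X_list, G)
        perm = np.random.default_rng(14).permutation(10)
        _, fused_p = model.predict_logits(
            [x[perm] for x in X_list], G[np.ix_(perm, perm)]
        )
        np.testing.assert_allclose(fused_p, fused[perm], atol=1e-10)

    def test_modality_permutation_permutes_attention(self):
        X_list, G = self._data()
        cfg = mh.ModelConfig(embed_dim=8, n_heads=2)
        model = mh.MoreModel([6, 4], 2, cfg, seed=2)
        _, _, attn = model.forward(X_list, G)
        swapped = mh.MoreModel([4, 6], 2, cfg, seed=3)
        # mirror the parameters so modality order is the only difference
        swapped.encoders[0].__dict__.update(
            {k: v for k, v in model.encoders[1].__dict__.items() if k != "cfg"}
        )
        swapped.encoders[1].__dict__.update(
            {k: v for k, v in model.encoders[0].__dict__.items() if k != "cfg"}
        )
        swapped.fusion.heads = model.fusion.heads
        _, _, attn_s = swapped.forward(X_list[::-1], G)
        for a, b in zip(attn, attn_s):
            np.testing.assert_allclose(b, a[:, ::-1, :][:, :, ::-1], atol=1e-12)

    def test_probabilities_normalise(self):
        X_list, G = self._data()
        model = mh.MoreModel([6, 4], 3, mh.ModelConfig(embed_dim=8), seed=4)
        proba = model.predict_proba(X_list, G)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-12)
        assert (proba >= 0).all()

    def test_state_dict_round_trip(self):
        X_list, G = self._data()
        model = mh.MoreModel([6, 4], 2, mh.ModelConfig(embed_dim=8), seed=5)
        _, fused = model.predict_logits(X_list, G)
        clone = mh.MoreModel([6, 4], 2, mh.ModelConfig(embed_dim=8), seed=99)
        clone.load_state_dict(model.state_dict())
        _, fused_c = clone.predict_logits(X_list, G)
        np.testing.assert_array_equal(fused, fused_c)
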