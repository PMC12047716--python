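"""Token embedding, masked attention, and the set-encoder invariances."""

import numpy as np
import pytest

import dotrecon as dr
from dotrecon._nn import TransformerEncoderNet
from dotrecon._nn.transformer import MultiHeadSelfAttention, _softmax_lastaxis


@pytest.fixture
def small_net(rng):
    return TransformerEncoderNet(d_meas=6, d_embed=16, n_heads=2, n_layers=2,
                                 d_latent=8, rng=rng)


class TestEmbedding:
    def test_identical_inputs_give_identical_tokens(self, rng, small_net):
        X = np.tile(rng.normal(size=(1, 1, 6)), (1, 4, 1))
        P = np.tile(rng.normal(size=(1, 1, 4)), (1, 4, 1))
        tokens = dr.encoder.embed_tokens(small_net, X, P)
        assert np.all(tokens == tokens[:, :1])

    def test_output_shape(self, rng, small_net):
        tokens = dr.encoder.embed_tokens(
            small_net, rng.normal(size=(2, 5, 6)), rng.normal(size=(2, 5, 4)))
        assert tokens.shape == (2, 5, 16)

    def test_matches_explicit_affine_arithmetic(self, rng):
        """Toy 2-feature -> 3-embed weights: token = Em(x) + Ep([Em(x); p])."""
        net = TransformerEncoderNet(d_meas=2, d_embed=3, n_heads=1, n_layers=1,
                                    d_latent=2, rng=rng)
        Wm, bm = net.embed_m.W.value, net.embed_m.b.value
        Wp, bp = net.embed_p.W.value, net.embed_p.b.value
        x = np.array([0.3, -1.2])
        p = np.array([0.1, 0.9, 0.6, 0.8])
        h = np.array([sum(x[i] * Wm[i, j] for i in range(2)) + bm[j]
                      for j in range(3)])
        hp = np.concatenate([h, p])
        e = np.array([sum(hp[i] * Wp[i, j] for i in range(7)) + bp[j]
                      for j in range(3)])
        expected = h + e
        got = dr.encoder.embed_tokens(net, x[None, None], p[None, None])[0, 0]
        np.testing.assert_allclose(got, expected, rtol=1e-12)


class TestAttention:
    def test_single_active_token_attends_only_to_itself(self, rng):
        attn = MultiHeadSelfAttention(d_embed=8, n_heads=2, rng=rng)
        x = rng.normal(size=(1, 5, 8))
        mask = np.zeros((1, 5))
        mask[0, 2] = 1.0
        out, A, _ = attn.forward(x, mask)
        np.testing.assert_allclose(A[0, :, :, 2], 1.0)
        assert np.all(A[0, :, :, [0, 1, 3, 4]] == 0)
        # output row equals the token's own projected value through W_o
        v, _ = attn.Wv.forward(x[0, 2])
        expected, _ = attn.Wo.forward(v)
        np.testing.assert_allclose(out[0, 2], expected, rtol=1e-10)

    def test_rows_sum_to_one_over_active_keys(self, rng):
        attn = MultiHeadSelfAttention(d_embed=8, n_heads=2, rng=rng)
        x = rng.normal(size=(3, 6, 8))
        mask = np.ones((3, 6))
        mask[1, 4:] = 0
        _, A, _ = attn.forward(x, mask)
        np.testing.assert_allclose(A.sum(axis=-1), 1.0, atol=1e-6)
        assert np.all(A[1, :, :, 4:] == 0)

    def test_all_masked_input_rejected(self, rng):
        attn = MultiHeadSelfAttention(d_embed=8, n_heads=2, rng=rng)
        with pytest.raises(ValueError):
            attn.forward(rng.normal(size=(1, 4, 8)), np.zeros((1, 4)))

    def test_matches_explicit_loop_computation(self, rng):
        """3 tokens, 1 head, d_embed = 2: brute-force softmax/matmul oracle."""
        attn = MultiHeadSelfAttention(d_embed=2, n_heads=1, rng=rng)
        x = rng.normal(size=(1, 3, 2))
        mask = np.ones((1, 3))
        out, A, _ = attn.forward(x, mask)

        def affine(W, b, v):
            return np.array([sum(v[i] * W[i, j] for i in range(2)) + b[j]
                             for j in range(2)])

        q = [affine(attn.Wq.W.value, attn.Wq.b.value, x[0, t]) for t in range(3)]
        k = [affine(attn.Wk.W.value, attn.Wk.b.value, x[0, t]) for t in range(3)]
        v = [affine(attn.Wv.W.value, attn.Wv.b.value, x[0, t]) for t in range(3)]
        scale = 1.0 / np.sqrt(2.0)
        for t in range(3):
            logits = np.array([np.dot(q[t], k[s]) * scale for s in range(3)])
            weights = np.exp(logits - logits.max())
            weights /= weights.sum()
            np.testing.assert_allclose(A[0, 0, t], weights, rtol=1e-10)
            combined = sum(weights[s] * v[s] for s in range(3))
            expected = affine(attn.Wo.W.value, attn.Wo.b.value, combined)
            np.testing.assert_allclose(out[0, t], expected, rtol=1e-10)

    def test_unscaled_attention_flag(self, rng):
        """The literal printed attention omits the 1/sqrt(d_head) temperature."""
        x = rng.normal(size=(1, 3, 4))
        mask = np.ones((1, 3))
        seed_rng = lambda: np.random.default_rng(0)  # noqa: E731
        a_scaled = MultiHeadSelfAttention(4, 1, seed_rng(), scale=True)
        a_literal = MultiHeadSelfAttention(4, 1, seed_rng(), scale=False)
        _, A1, _ = a_scaled.forward(x, mask)
        _, A2, _ = a_literal.forward(x, mask)
        assert not np.allclose(A1, A2)


class TestEncodeScan:
    def test_permutation_invariance(self, rng, small_net):
        """Jointly permuting rows of (X, P, mask) leaves the latent unchanged."""
        X = rng.normal(size=(1, 10, 6))
        P = rng.normal(size=(1, 10, 4))
        mask = np.ones((1, 10)); mask[0, 7:] = 0
        Z, _ = small_net.forward(X, P, mask)
        perm = rng.permutation(10)
        Z2, _ = small_net.forward(X[:, perm], P[:, perm], mask[:, perm])
        np.testing.assert_allclose(Z2, Z, rtol=1e-5, atol=1e-8)

    def test_padding_invariance(self, rng, small_net):
        """Appending fully masked rows never changes the output."""
        X = rng.normal(size=(1, 6, 6))
        P = rng.normal(size=(1, 6, 4))
        Z, _ = small_net.forward(X, P, np.ones((1, 6)))
        Xp = np.concatenate([X, np.zeros((1, 4, 6))], axis=1)
        Pp = np.concatenate([P, np.zeros((1, 4, 4))], axis=1)
        maskp = np.concatenate([np.ones((1, 6)), np.zeros((1, 4))], axis=1)
        Zp, _ = small_net.forward(Xp, Pp, maskp)
        np.testing.assert_allclose(Zp, Z, rtol=1e-5, atol=1e-8)

    def test_masked_row_contents_never_influence_output(self, rng, small_net):
        X = rng.normal(size=(2, 8, 6))
        P = rng.normal(size=(2, 8, 4))
        mask = np.ones((2, 8)); mask[:, 5:] = 0
        Z, _ = small_net.forward(X, P, mask)
        X2, P2 = X.copy(), P.copy()
        X2[:, 5:] = rng.normal(size=(2, 3, 6)) * 100
        P2[:, 5:] = rng.normal(size=(2, 3, 4)) * 100
        Z2, _ = small_net.forward(X2, P2, mask)
        np.testing.assert_array_equal(Z, Z2)

    def test_one_layer_one_head_matches_brute_force(self, rng):
        """End-to-end hand computation of the minimal encoder configuration
        (no layernorm/feed-forward sublayers)."""
        net = TransformerEncoderNet(d_meas=2, d_embed=2, n_heads=1, n_layers=1,
                                    d_latent=3, rng=rng, use_layernorm=False,
                                    use_ffn=False)
        X = rng.normal(size=(1, 3, 2))
        P = rng.normal(size=(1, 3, 4))
        mask = np.ones((1, 3))
        Z, _ = net.forward(X, P, mask)

        # reference: embedding, attention + residual, masked mean, projection
        tokens = np.stack([
            (X[0, t] @ net.embed_m.W.value + net.embed_m.b.value)
            + (np.concatenate([X[0, t] @ net.embed_m.W.value + net.embed_m.b.value,
                               P[0, t]]) @ net.embed_p.W.value + net.embed_p.b.value)
            for t in range(3)
        ])
        attn = net.layers[0].attn
        q = tokens @ attn.Wq.W.value + attn.Wq.b.value
        k = tokens @ attn.Wk.W.value + attn.Wk.b.value
        v = tokens @ attn.Wv.W.value + attn.Wv.b.value
        out_rows = []
        for t in range(3):
            logits = np.array([q[t] @ k[s] / np.sqrt(2.0) for s in range(3)])
            A = _softmax_lastaxis(logits)
            out_rows.append(sum(A[s] * v[s] for s in range(3)))
        attn_out = np.stack(out_rows) @ attn.Wo.W.value + attn.Wo.b.value
        tokens = tokens + attn_out
        pooled = tokens.mean(axis=0)
        expected = pooled @ net.proj.W.value + net.proj.b.value
        np.testing.assert_allclose(Z[0], expected, rtol=1e-10)

    def test_empty_scan_rejected(self):
        with pytest.raises(dr.data.FormatError):
            dr.ScanRecord(X=np.zeros((0, 6)), P=np.zeros((0, 4)))


class TestScanEncoderEstimator:
    def test_predict_through_estimator_is_permutation_invariant(self, toy_model):
        model = toy_model["model"]
        enc = model.encoder_
        cfg = toy_model["cfg"]
        rng = np.random.default_rng(3)
        rec = dr.simulate_dataset(cfg, 1, rng, n_positions=6,
                                  homogeneous_only=True)[0]
        z1 = enc.predict([rec])
        perm = rng.permutation(rec.d_scan)
        rec2 = dr.ScanRecord(X=rec.X[perm], P=rec.P[perm])
        z2 = enc.predict([rec2])
        np.testing.assert_allclose(z1, z2, rtol=1e-5, atol=1e-10)

    def test_unfitted_predict_raises(self):
        with pytest.raises(dr.data.NotFittedError):
            dr.ScanEncoder().predict([])
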