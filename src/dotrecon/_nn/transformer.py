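"""Set-transformer encoder: embedding, masked multi-head attention, pooling.

The network maps a zero-padded batch of measurement/context tokens to one
latent vector per scan.  Spatial information enters only through the
per-measurement context features, never through sequence order, so the
encoder is permutation invariant over active rows and independent of
padding length.  The mask (1 = active) is re-applied to the token matrix
at the input of every layer, masked keys receive additive -1e9 attention
logits, and the final pooling averages active tokens only.
"""

from __future__ import annotations

import numpy as np

from .core import Dense, LayerNorm, relu, relu_grad

_NEG = 1e9


def _softmax_lastaxis(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class MultiHeadSelfAttention:
    """Masked scaled dot-product self-attention with head concatenation.

    Attention weights are the row-wise softmax of Q K^T (optionally scaled
    by 1/sqrt(d_head); the unscaled variant is the literal printed form),
    restricted to active keys; outputs are attention-weighted combinations
    of Value vectors, heads concatenated and linearly recombined.
    """

    def __init__(self, d_embed: int, n_heads: int, rng, scale: bool = True):
        if d_embed % n_heads != 0:
            raise ValueError(f"d_embed={d_embed} not divisible by n_heads={n_heads}")
        self.n_heads = n_heads
        self.d_head = d_embed // n_heads
        self.scale = 1.0 / np.sqrt(self.d_head) if scale else 1.0
        self.Wq = Dense(d_embed, d_embed, rng)
        self.Wk = Dense(d_embed, d_embed, rng)
        self.Wv = Dense(d_embed, d_embed, rng)
        self.Wo = Dense(d_embed, d_embed, rng)

    def params(self):
        return self.Wq.params() + self.Wk.params() + self.Wv.params() + self.Wo.params()

    def _split(self, x):  # (B,S,D) -> (B,H,S,dh)
        B, S, D = x.shape
        return x.reshape(B, S, self.n_heads, self.d_head).transpose(0, 2, 1, 3)

    def _merge(self, x):  # (B,H,S,dh) -> (B,S,D)
        B, H, S, dh = x.shape
        return x.transpose(0, 2, 1, 3).reshape(B, S, H * dh)

    def forward(self, x: np.ndarray, mask: np.ndarray):
        if not np.all(mask.sum(axis=-1) >= 1):
            raise ValueError("attention needs at least one active token per scan")
        q_full, cq = self.Wq.forward(x)
        k_full, ck = self.Wk.forward(x)
        v_full, cv = self.Wv.forward(x)
        q, k, v = self._split(q_full), self._split(k_full), self._split(v_full)
        logits = np.matmul(q, k.transpose(0, 1, 3, 2)) * self.scale
        logits = logits + (mask[:, None, None, :] - 1.0) * _NEG
        A = _softmax_lastaxis(logits)
        heads = np.matmul(A, v)
        merged = self._merge(heads)
        out, co = self.Wo.forward(merged)
        cache = (cq, ck, cv, co, q, k, v, A)
        return out, A, cache

    def backward(self, dout: np.ndarray, cache):
        cq, ck, cv, co, q, k, v, A = cache
        dmerged = self.Wo.backward(dout, co)
        dheads = self._split(dmerged)
        dA = np.matmul(dheads, v.transpose(0, 1, 3, 2))
        dv = np.matmul(A.transpose(0, 1, 3, 2), dheads)
        # softmax backward (row-wise over keys)
        dlogits = A * (dA - np.sum(dA * A, axis=-1, keepdims=True))
        dq = np.matmul(dlogits, k) * self.scale
        dk = np.matmul(dlogits.transpose(0, 1, 3, 2), q) * self.scale
        dx = self.Wq.backward(self._merge(dq), cq)
        dx += self.Wk.backward(self._merge(dk), ck)
        dx += self.Wv.backward(self._merge(dv), cv)
        return dx


class TransformerLayer:
    """Attention sublayer (+ optional pre-LN and feed-forward sublayer).

    Residual connections, layer normalization, and the position-wise
    feed-forward block are standard-transformer defaults around the printed
    attention core; each is toggleable.  The active-row mask multiplies
    every sublayer output so padded/masked rows stay identically zero.
    """

    def __init__(self, d_embed, n_heads, d_ff, rng, scale_attention=True,
                 use_layernorm=True, use_ffn=True):
        self.attn = MultiHeadSelfAttention(d_embed, n_heads, rng, scale_attention)
        self.use_layernorm = use_layernorm
        self.use_ffn = use_ffn
        if use_layernorm:
            self.ln1 = LayerNorm(d_embed)
            self.ln2 = LayerNorm(d_embed) if use_ffn else None
        if use_ffn:
            self.ff1 = Dense(d_embed, d_ff, rng)
            self.ff2 = Dense(d_ff, d_embed, rng)

    def params(self):
        out = self.attn.params()
        if self.use_layernorm:
            out += self.ln1.params()
            if self.use_ffn:
                out += self.ln2.params()
        if self.use_ffn:
            out += self.ff1.params() + self.ff2.params()
        return out

    def forward(self, x, mask):
        m = mask[..., None]
        x = x * m  # re-apply mask to the layer input
        if self.use_layernorm:
            h, c_ln1 = self.ln1.forward(x)
        else:
            h, c_ln1 = x, None
        attn_out, A, c_attn = self.attn.forward(h, mask)
        x1 = x + attn_out * m
        if self.use_ffn:
            if self.use_layernorm:
                g, c_ln2 = self.ln2.forward(x1)
            else:
                g, c_ln2 = x1, None
            f1, c_f1 = self.ff1.forward(g)
            a1 = relu(f1)
            f2, c_f2 = self.ff2.forward(a1)
            x2 = x1 + f2 * m
            cache = (mask, c_ln1, c_attn, c_ln2, c_f1, f1, c_f2)
        else:
            x2 = x1
            cache = (mask, c_ln1, c_attn, None, None, None, None)
        return x2, A, cache

    def backward(self, dout, cache):
        mask, c_ln1, c_attn, c_ln2, c_f1, f1, c_f2 = cache
        m = mask[..., None]
        dx1 = dout
        if self.use_ffn:
            df2 = dout * m
            da1 = self.ff2.backward(df2, c_f2)
            df1 = relu_grad(da1, f1)
            dg = self.ff1.backward(df1, c_f1)
            if self.use_layernorm:
                dg = self.ln2.backward(dg, c_ln2)
            dx1 = dx1 + dg
        dattn = dx1 * m
        dh = self.attn.backward(dattn, c_attn)
        if self.use_layernorm:
            dh = self.ln1.backward(dh, c_ln1)
        dx = (dx1 + dh) * m
        return dx


class TransformerEncoderNet:
    """Full measurement encoder: embed, N transformer layers, masked mean, project.

    The token for measurement i is ``E_m(X_i) + E_p([E_m(X_i); P_i])``: the
    embedded measurement plus a context-fusion embedding of the measurement
    embedding concatenated with its positional context.
    """

    def __init__(self, d_meas: int, d_embed: int = 128, n_heads: int = 8,
                 n_layers: int = 4, d_latent: int = 256, d_ff: int | None = None,
                 d_pos: int = 4, rng: np.random.Generator | None = None,
                 scale_attention: bool = True, use_layernorm: bool = True,
                 use_ffn: bool = True):
        rng = rng if rng is not None else np.random.default_rng(0)
        d_ff = d_ff or 2 * d_embed
        self.d_meas, self.d_embed, self.d_latent = d_meas, d_embed, d_latent
        self.embed_m = Dense(d_meas, d_embed, rng)
        self.embed_p = Dense(d_embed + d_pos, d_embed, rng)
        self.layers = [
            TransformerLayer(d_embed, n_heads, d_ff, rng, scale_attention,
                             use_layernorm, use_ffn)
            for _ in range(n_layers)
        ]
        self.proj = Dense(d_embed, d_latent, rng)

    def params(self):
        out = self.embed_m.params() + self.embed_p.params()
        for layer in self.layers:
            out += layer.params()
        return out + self.proj.params()

    def embed(self, X: np.ndarray, P: np.ndarray):
        """Per-token embedding (independent across tokens)."""
        h, c_m = self.embed_m.forward(X)
        hp = np.concatenate([h, P], axis=-1)
        e, c_p = self.embed_p.forward(hp)
        return h + e, (c_m, c_p)

    def forward(self, X: np.ndarray, P: np.ndarray, mask: np.ndarray,
                return_attention: bool = False):
        """Map (B, S, d_meas) measurements + (B, S, 4) context to (B, d_latent)."""
        tokens, c_embed = self.embed(X, P)
        tokens = tokens * mask[..., None]
        layer_caches = []
        attentions = []
        for layer in self.layers:
            tokens, A, cache = layer.forward(tokens, mask)
            layer_caches.append(cache)
            attentions.append(A)
        counts = mask.sum(axis=-1, keepdims=True)
        pooled = (tokens * mask[..., None]).sum(axis=1) / counts
        Z, c_proj = self.proj.forward(pooled)
        cache = (mask, c_embed, layer_caches, counts, c_proj)
        if return_attention:
            return Z, cache, attentions
        return Z, cache

    def backward(self, dZ: np.ndarray, cache):
        mask, c_embed, layer_caches, counts, c_proj = cache
        dpooled = self.proj.backward(dZ, c_proj)
        dtokens = (dpooled[:, None, :] / counts[..., None]) * mask[..., None]
        for layer, c in zip(reversed(self.layers), reversed(layer_caches)):
            dtokens = layer.backward(dtokens, c)
        dtokens = dtokens * mask[..., None]
        c_m, c_p = c_embed
        dhp = self.embed_p.backward(dtokens, c_p)
        dh = dtokens + dhp[..., : self.d_embed]
        dP = dhp[..., self.d_embed:]
        dX = self.embed_m.backward(dh, c_m)
        return dX, dP
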