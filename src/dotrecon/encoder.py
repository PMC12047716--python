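"""Transformer scan encoder: unstructured measurements -> latent volume vector.

Stage 2 of the training pipeline.  The estimator wraps the NumPy
set-transformer network with the feature scaling, dynamic scan masking,
and latent-target standardization needed to regress autoencoder latents
from variable-length measurement sets.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from ._nn import Adam, TransformerEncoderNet
from ._nn.core import cast_params
from .autoencoder import cosine_lr, minibatch_indices, params_hash
from .data import (
    FeatureScaler,
    NotFittedError,
    ScanRecord,
    batch_scans,
)


def sample_training_mask(
    rng: np.random.Generator,
    d_batch: int,
    d_seq: int,
    count_distribution=None,
    lengths: np.ndarray | None = None,
) -> np.ndarray:
    """Randomised binary masks emulating scans of varying sparsity.

    Each row receives ``k`` ones at uniformly chosen positions, with ``k``
    drawn from ``count_distribution`` (default: uniform on {1..d_seq}).
    When per-example ``lengths`` are given, positions are restricted to each
    example's own first ``lengths[i]`` (active) slots and ``k`` is capped by
    the scan length, so a mask never activates a padded row.
    """
    mask = np.zeros((d_batch, d_seq))
    for i in range(d_batch):
        limit = int(lengths[i]) if lengths is not None else d_seq
        if count_distribution is None:
            k = int(rng.integers(1, limit + 1))
        else:
            k = int(np.clip(count_distribution(rng), 1, limit))
        pos = rng.choice(limit, size=k, replace=False)
        mask[i, pos] = 1.0
    return mask


class ScanEncoder(BaseEstimator, RegressorMixin):
    """Set-transformer regression from masked measurement sets to latents.

    Spatial information enters only through the per-measurement context
    features, making the encoder permutation invariant over scan rows and
    able to process scans of any length up to ``d_seq`` with one set of
    weights.  Training minimizes the MSE between predicted and saved
    (standardized) latent vectors under dynamically resampled binary masks.

    Parameters
    ----------
    d_embed, n_heads, n_layers, d_latent : transformer dimensions.
    d_seq : int
        Maximum number of probe positions per scan.
    scale_attention : bool
        Include the customary 1/sqrt(d_head) logit temperature; disable for
        the literal unscaled attention form.
    use_layernorm, use_ffn : bool
        Toggle the standard-transformer sublayers around the attention core.
    epochs, batch_size, lr, validation_fraction, patience, random_state :
        training-loop controls, as in :class:`VolumeAutoencoder`.
    """

    def __init__(self, d_embed: int = 128, n_heads: int = 8, n_layers: int = 4,
                 d_latent: int = 256, d_seq: int = 256, d_ff: int | None = None,
                 scale_attention: bool = True, use_layernorm: bool = True,
                 use_ffn: bool = True, epochs: int = 100, batch_size: int = 32,
                 lr: float = 1e-3, validation_fraction: float = 0.1,
                 patience: int = 10, random_state: int = 0,
                 dtype: str = "float32", verbose: bool = False):
        self.d_embed = d_embed
        self.n_heads = n_heads
        self.n_layers = n_layers
        self.d_latent = d_latent
        self.d_seq = d_seq
        self.d_ff = d_ff
        self.scale_attention = scale_attention
        self.use_layernorm = use_layernorm
        self.use_ffn = use_ffn
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.validation_fraction = validation_fraction
        self.patience = patience
        self.random_state = random_state
        self.dtype = dtype
        self.verbose = verbose

    def _check_fitted(self):
        if not hasattr(self, "net_"):
            raise NotFittedError("ScanEncoder used before fit()")

    def _prepare(self, records: list[ScanRecord]):
        normed = [self.scaler_.transform(r) for r in records]
        batch = batch_scans(normed, self.d_seq)
        batch.X = batch.X.astype(self.dtype)
        batch.P = batch.P.astype(self.dtype)
        batch.mask = batch.mask.astype(self.dtype)
        return batch

    def fit(self, records: list[ScanRecord], Z: np.ndarray, scan_area=None):
        """Train on scans and their saved latent targets (stage 2)."""
        Z = np.asarray(Z, dtype=float)
        if len(records) != len(Z):
            raise ValueError("record/latent count mismatch")
        if Z.shape[1] != self.d_latent:
            raise ValueError(f"latent width {Z.shape[1]} != d_latent {self.d_latent}")
        rng = np.random.default_rng(self.random_state)
        if scan_area is None and records[0].target is not None:
            scan_area = records[0].target.scan_area
        self.scaler_ = FeatureScaler(scan_area).fit(records)
        self.latent_mean_ = Z.mean(axis=0)
        zstd = Z.std(axis=0)
        self.latent_std_ = np.where(zstd > 0, zstd, 1.0)
        Zs = ((Z - self.latent_mean_) / self.latent_std_).astype(self.dtype)

        batch = self._prepare(records)
        d_meas = batch.X.shape[-1]
        self.net_ = TransformerEncoderNet(
            d_meas, self.d_embed, self.n_heads, self.n_layers, self.d_latent,
            self.d_ff, batch.P.shape[-1], rng, self.scale_attention,
            self.use_layernorm, self.use_ffn,
        )
        cast_params(self.net_.params(), self.dtype)
        opt = Adam(self.net_.params(), lr=self.lr)

        n = len(records)
        n_val = int(round(self.validation_fraction * n)) if n > 1 else 0
        order = rng.permutation(n)
        val_idx, train_idx = order[:n_val], order[n_val:]
        # static validation masks: comparable loss across epochs
        val_mask = (
            sample_training_mask(rng, n_val, self.d_seq,
                                 lengths=batch.lengths[val_idx]).astype(self.dtype)
            if n_val else None
        )

        self.loss_curve_, self.val_loss_curve_ = [], []
        best = (np.inf, None)
        bad_epochs = 0
        for epoch in range(self.epochs):
            lr = cosine_lr(self.lr, epoch, self.epochs)
            losses = []
            for idx in minibatch_indices(len(train_idx), self.batch_size, rng):
                rows = train_idx[idx]
                mask = sample_training_mask(
                    rng, len(rows), self.d_seq, lengths=batch.lengths[rows]
                ).astype(self.dtype)
                opt.zero_grad()
                zp, cache = self.net_.forward(batch.X[rows], batch.P[rows], mask)
                err = zp - Zs[rows]
                losses.append(float(np.mean(err**2)))
                self.net_.backward(2.0 * err / err.size, cache)
                opt.step(lr)
            self.loss_curve_.append(float(np.mean(losses)))
            if n_val:
                zp, _ = self.net_.forward(batch.X[val_idx], batch.P[val_idx], val_mask)
                val_loss = float(np.mean((zp - Zs[val_idx]) ** 2))
                self.val_loss_curve_.append(val_loss)
                if val_loss < best[0]:
                    best = (val_loss, [p.value.copy() for p in self.net_.params()])
                    bad_epochs = 0
                else:
                    bad_epochs += 1
                    if bad_epochs > self.patience:
                        break
            if self.verbose:
                val = self.val_loss_curve_[-1] if n_val else float("nan")
                print(f"[encoder] epoch {epoch:3d} train {self.loss_curve_[-1]:.3e} "
                      f"val {val:.3e}")
        if best[1] is not None:
            for p, v in zip(self.net_.params(), best[1]):
                p.value = v
        self.params_hash_ = params_hash(self.net_.params())
        return self

    def predict(self, records: list[ScanRecord], mask: np.ndarray | None = None):
        """Latent vectors for a list of scans (rows beyond each scan masked)."""
        self._check_fitted()
        batch = self._prepare(records)
        use_mask = batch.mask if mask is None else np.asarray(mask).astype(self.dtype)
        zp, _ = self.net_.forward(batch.X, batch.P, use_mask)
        return zp * self.latent_std_ + self.latent_mean_


def embed_tokens(net: TransformerEncoderNet, X: np.ndarray, P: np.ndarray):
    """Per-measurement token embedding (independent across tokens)."""
    tokens, _ = net.embed(np.asarray(X, dtype=float), np.asarray(P, dtype=float))
    return tokens


def attention_layer(layer, tokens: np.ndarray, mask: np.ndarray):
    """Apply one transformer layer; returns (tokens, attention weights)."""
    out, A, _ = layer.forward(tokens, np.asarray(mask, dtype=float))
    return out, A


def encode_scan(encoder: ScanEncoder, record: ScanRecord,
                mask: np.ndarray | None = None) -> np.ndarray:
    """Latent vector of a single (unnormalized) scan."""
    return encoder.predict([record], mask=mask)[0]
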