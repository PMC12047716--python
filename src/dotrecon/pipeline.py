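"""Two-stage training pipeline and the assembled scan-to-volume model.

Stage 1 trains the volume autoencoder (self-supervised on ground-truth
volumes); stage 2 freezes it, saves every example's latent vector, and
trains the transformer encoder to regress those latents from dynamically
masked scan measurements.  The deployed model is the trained transformer
encoder composed with the frozen CNN decoder.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .autoencoder import VolumeAutoencoder, params_hash
from .data import NotFittedError, ScanRecord
from .encoder import ScanEncoder, sample_training_mask  # noqa: F401  (module surface)
from .simulate import OpticalVolume


class ProvenanceError(RuntimeError):
    """Latents and autoencoder checkpoint do not match."""


@dataclass
class LatentDataset:
    """Saved latent targets for stage-2 training, with provenance."""

    Z: np.ndarray  # (n, d_latent)
    ids: list[str]
    checkpoint_hash: str

    def __post_init__(self):
        if len(self.Z) != len(self.ids):
            raise ValueError("one latent per example required")


def encode_targets(records: list[ScanRecord], autoencoder: VolumeAutoencoder,
                   batch_size: int = 64) -> LatentDataset:
    """Encode every example's ground-truth volume into its latent target."""
    if any(r.target is None for r in records):
        raise ValueError("all records need ground-truth targets to encode")
    current = params_hash(autoencoder.decoder_net_.params())
    if current != autoencoder.params_hash_:
        raise ProvenanceError("autoencoder parameters changed since fit()")
    vols = np.stack([r.target.as_tensor() for r in records])
    chunks = [
        autoencoder.transform(vols[i:i + batch_size])
        for i in range(0, len(vols), batch_size)
    ]
    ids = [r.example_id if r.example_id is not None else str(i)
           for i, r in enumerate(records)]
    return LatentDataset(Z=np.concatenate(chunks), ids=ids,
                         checkpoint_hash=autoencoder.params_hash_)


def train_autoencoder(records: list[ScanRecord], autoencoder=None,
                      **kwargs) -> VolumeAutoencoder:
    """Stage 1: fit the volume autoencoder on the records' ground truths."""
    if any(r.target is None for r in records):
        raise ValueError("stage-1 training needs labeled records")
    model = autoencoder or VolumeAutoencoder(**kwargs)
    vols = np.stack([r.target.as_tensor() for r in records])
    return model.fit(vols)


def train_encoder(records: list[ScanRecord], latents: LatentDataset,
                  autoencoder: VolumeAutoencoder | None = None,
                  encoder: ScanEncoder | None = None, **kwargs) -> ScanEncoder:
    """Stage 2: fit the transformer encoder against saved latent targets."""
    if autoencoder is not None:
        current = params_hash(autoencoder.decoder_net_.params())
        if latents.checkpoint_hash != current:
            raise ProvenanceError("stale latents: regenerate with encode_targets()")
    model = encoder or ScanEncoder(**kwargs)
    if model.d_latent != latents.Z.shape[1]:
        raise ValueError("encoder d_latent does not match latent width")
    return model.fit(records, latents.Z)


def training_log(model) -> pd.DataFrame:
    """Per-epoch train/validation losses of a fitted estimator."""
    val = getattr(model, "val_loss_curve_", [])
    rows = [
        {"epoch": i, "train_loss": tr,
         "val_loss": val[i] if i < len(val) else np.nan}
        for i, tr in enumerate(model.loss_curve_)
    ]
    return pd.DataFrame(rows)


class ScanReconstructor(BaseEstimator):
    """End-to-end reconstruction model: unstructured scan -> optical volume.

    ``fit`` runs the full two-stage pipeline on labeled scans; ``predict``
    composes the trained transformer encoder with the frozen CNN decoder.
    Sub-estimator hyper-parameters are supplied as constructed instances so
    the reconstructor stays a thin, inspectable composition.
    """

    def __init__(self, autoencoder: VolumeAutoencoder | None = None,
                 encoder: ScanEncoder | None = None):
        self.autoencoder = autoencoder
        self.encoder = encoder

    def fit(self, records: list[ScanRecord], y=None):
        self.autoencoder_ = self.autoencoder or VolumeAutoencoder()
        enc = self.encoder or ScanEncoder(d_latent=self.autoencoder_.d_latent)
        if enc.d_latent != self.autoencoder_.d_latent:
            raise ValueError("autoencoder and encoder d_latent must match")
        train_autoencoder(records, self.autoencoder_)
        self.latents_ = encode_targets(records, self.autoencoder_)
        self.encoder_ = train_encoder(records, self.latents_, self.autoencoder_,
                                      encoder=enc)
        self._template_target = records[0].target
        return self

    @classmethod
    def from_parts(cls, encoder: ScanEncoder, autoencoder: VolumeAutoencoder,
                   template_target: OpticalVolume | None = None):
        """Assemble a deployed model from separately trained halves."""
        if encoder.d_latent != autoencoder.d_latent:
            raise ValueError(
                f"d_latent mismatch: encoder {encoder.d_latent} vs "
                f"autoencoder {autoencoder.d_latent}"
            )
        model = cls()
        model.autoencoder_ = autoencoder
        model.encoder_ = encoder
        model.latents_ = None
        model._template_target = template_target
        return model

    def _check_fitted(self):
        if not hasattr(self, "encoder_"):
            raise NotFittedError("ScanReconstructor used before fit()")

    def predict_tensor(self, records: list[ScanRecord],
                       mask: np.ndarray | None = None) -> np.ndarray:
        """(n, nx, ny, nz, 2) reconstructed volumes in physical units."""
        self._check_fitted()
        Z = self.encoder_.predict(records, mask=mask)
        return self.autoencoder_.inverse_transform(Z)

    def predict(self, records: list[ScanRecord]) -> list[OpticalVolume]:
        tensors = self.predict_tensor(records)
        tmpl = self._template_target
        kwargs = {}
        if tmpl is not None:
            kwargs = {"voxel_size": tmpl.voxel_size, "origin": tmpl.origin,
                      "scan_area": tmpl.scan_area}
        out = []
        for t in tensors:
            # clip already applied; guard exact zeros for the positivity invariant
            t = np.maximum(t, 1e-12)
            out.append(OpticalVolume.from_tensor(t, **kwargs))
        return out

    # -- persistence -------------------------------------------------------
    def save(self, path) -> None:
        """Single-file checkpoint: all parameters + config + scaler."""
        import json

        self._check_fitted()
        enc, ae = self.encoder_, self.autoencoder_
        arrays = {}
        for i, p in enumerate(enc.net_.params()):
            arrays[f"enc_{i}"] = p.value
        for i, p in enumerate(ae.encoder_net_.params()):
            arrays[f"ae_enc_{i}"] = p.value
        for i, p in enumerate(ae.decoder_net_.params()):
            arrays[f"ae_dec_{i}"] = p.value
        meta = {
            "encoder_params": enc.get_params(),
            "autoencoder_params": ae.get_params(),
            "scaler": enc.scaler_.to_dict(),
            "latent_mean": enc.latent_mean_.tolist(),
            "latent_std": enc.latent_std_.tolist(),
            "channel_mean": ae.channel_mean_.tolist(),
            "channel_std": ae.channel_std_.tolist(),
            "grid": list(ae.grid_),
            "d_meas": int(enc.net_.d_meas),
        }
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "ScanReconstructor":
        import json

        from ._nn import CNNDecoderNet, CNNEncoderNet, TransformerEncoderNet
        from .data import FeatureScaler

        with np.load(path) as f:
            meta = json.loads(bytes(f["__meta__"]).decode())
            arrays = {k: f[k] for k in f.files if k != "__meta__"}
        ae = VolumeAutoencoder(**meta["autoencoder_params"])
        ae.grid_ = tuple(meta["grid"])
        ae.channel_mean_ = np.asarray(meta["channel_mean"])
        ae.channel_std_ = np.asarray(meta["channel_std"])
        rng = np.random.default_rng(0)
        ae.encoder_net_ = CNNEncoderNet(ae.grid_, ae.d_latent, ae.channels, rng)
        ae.decoder_net_ = CNNDecoderNet(ae.grid_, ae.d_latent, ae.channels, rng)
        for i, p in enumerate(ae.encoder_net_.params()):
            p.value = arrays[f"ae_enc_{i}"]
        for i, p in enumerate(ae.decoder_net_.params()):
            p.value = arrays[f"ae_dec_{i}"]
        ae.params_hash_ = params_hash(ae.decoder_net_.params())

        enc = ScanEncoder(**meta["encoder_params"])
        enc.net_ = TransformerEncoderNet(
            meta["d_meas"], enc.d_embed, enc.n_heads, enc.n_layers, enc.d_latent,
            enc.d_ff, 4, rng, enc.scale_attention, enc.use_layernorm, enc.use_ffn,
        )
        for i, p in enumerate(enc.net_.params()):
            p.value = arrays[f"enc_{i}"]
        enc.scaler_ = FeatureScaler.from_dict(meta["scaler"])
        enc.latent_mean_ = np.asarray(meta["latent_mean"])
        enc.latent_std_ = np.asarray(meta["latent_std"])
        enc.params_hash_ = params_hash(enc.net_.params())
        return cls.from_parts(enc, ae)


def assemble_model(encoder: ScanEncoder, autoencoder: VolumeAutoencoder,
                   template_target: OpticalVolume | None = None) -> ScanReconstructor:
    """Combine trained encoder and decoder halves into the deployed model."""
    return ScanReconstructor.from_parts(encoder, autoencoder, template_target)
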