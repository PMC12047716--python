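"""Shared fixtures: tiny configurations and a quickly trained toy model."""

import numpy as np
import pytest

import dotrecon as dr


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def desk_cfg():
    return dr.desk_config()


@pytest.fixture
def tiny_cfg():
    """Very small world for fast end-to-end exercises."""
    return dr.desk_config(
        grid_dims=(7, 7, 4),
        voxel_size=4.0,
        scan_area=dr.ScanArea(0.0, 24.0, 0.0, 24.0),
        max_positions=8,
        scan_resolution=2.0,
    )


def make_tiny_scans(cfg, n, rng, homogeneous=True, n_positions=None):
    return dr.simulate_dataset(cfg, n, rng, n_positions=n_positions,
                               homogeneous_only=homogeneous)


@pytest.fixture(scope="session")
def toy_model():
    """A small reconstructor trained briefly on homogeneous scans.

    Deliberately tiny: enough training for smooth, deterministic behaviour
    (composition, streaming, invariance tests), not for accuracy claims.
    """
    cfg = dr.desk_config(
        grid_dims=(7, 7, 4),
        voxel_size=4.0,
        scan_area=dr.ScanArea(0.0, 24.0, 0.0, 24.0),
        max_positions=8,
        scan_resolution=2.0,
    )
    rng = np.random.default_rng(7)
    train = dr.simulate_dataset(cfg, 96, rng, homogeneous_only=True)
    ae = dr.VolumeAutoencoder(d_latent=16, channels=(8, 16, 32), epochs=200,
                              batch_size=16, lr=5e-3, patience=50, random_state=0)
    dr.train_autoencoder(train, ae)
    latents = dr.encode_targets(train, ae)
    enc = dr.ScanEncoder(d_embed=16, n_heads=2, n_layers=1, d_latent=16,
                         d_seq=8, epochs=20, batch_size=16, random_state=0)
    dr.train_encoder(train, latents, ae, encoder=enc)
    model = dr.assemble_model(enc, ae, train[0].target)
    return {"model": model, "cfg": cfg, "train": train}
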