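"""YAML configuration mirroring the simulated-world parameter names."""

from __future__ import annotations

import yaml

from .simulate import NoiseModel, PhantomConfig, ProbeGeometry, ScanArea, desk_config

DEFAULT_MODEL = {
    "d_embed": 128, "n_heads": 8, "n_layers": 4, "d_latent": 256, "d_seq": 256,
}
DESK_MODEL = {
    "d_embed": 64, "n_heads": 4, "n_layers": 2, "d_latent": 128, "d_seq": 64,
}
DEFAULT_TRAINING = {
    "seed": 0, "epochs": 50, "batch_size": 32, "lr": 1e-3,
    "n_train": 50_000, "n_val": 5_000, "n_test": 5_000, "scale": 1.0,
}


def phantom_config_from_dict(cfg: dict) -> PhantomConfig:
    """Build a :class:`PhantomConfig` from a (possibly partial) mapping."""
    base = desk_config() if cfg.get("profile", "full") == "desk" else PhantomConfig()
    sub = cfg.get("substrate", {})
    anom = cfg.get("anomalies", {})
    scan = cfg.get("scan", {})
    probe = cfg.get("probe", {})
    noise = cfg.get("noise", {})
    target = cfg.get("target", {})
    kwargs = {}
    if "mua" in sub:
        kwargs["substrate_mua_mean"] = sub["mua"].get("mean", base.substrate_mua_mean)
        kwargs["substrate_mua_sd"] = sub["mua"].get("sd", base.substrate_mua_sd)
    if "musp" in sub:
        kwargs["substrate_musp_mean"] = sub["musp"].get("mean", base.substrate_musp_mean)
        kwargs["substrate_musp_sd"] = sub["musp"].get("sd", base.substrate_musp_sd)
    for src, dst in (("count", "n_anomalies_range"), ("radius_mm", "radius_range"),
                     ("min_depth_mm", "min_depth_range"),
                     ("mua_contrast", "mua_contrast_range"),
                     ("musp_contrast", "musp_contrast_range")):
        if src in anom:
            kwargs[dst] = tuple(anom[src])
    if "shapes" in anom:
        kwargs["anomaly_shapes"] = tuple(anom["shapes"])
    if "area_mm" in scan:
        size = float(scan["area_mm"])
        kwargs["scan_area"] = ScanArea(0.0, size, 0.0, size)
    if "resolution_mm" in scan:
        kwargs["scan_resolution"] = float(scan["resolution_mm"])
    if "max_positions" in scan:
        kwargs["max_positions"] = int(scan["max_positions"])
    if probe:
        kwargs["geometry"] = ProbeGeometry(
            sds_list=tuple(probe.get("sds_mm", (20.0, 30.0, 40.0))),
            mod_freq=float(probe.get("modulation_frequency_mhz", 100.0)) * 1e6,
        )
    if noise:
        kwargs["noise"] = NoiseModel(
            floor_dbm=float(noise.get("floor_dbm", -51.0)),
            floor_var=float(noise.get("floor_var", 1e-11)),
            slope_db_per_db=float(noise.get("slope_db_per_db", 1.2)),
        )
    if "dims" in target:
        kwargs["grid_dims"] = tuple(target["dims"])
    if "voxel_size_mm" in target:
        kwargs["voxel_size"] = float(target["voxel_size_mm"])
    return base.replace(**kwargs)


def load_config(path) -> dict:
    with open(path) as f:
        cfg = yaml.safe_load(f) or {}
    profile_model = DESK_MODEL if cfg.get("profile") == "desk" else DEFAULT_MODEL
    return {
        "phantom": phantom_config_from_dict(cfg),
        "model": {**profile_model, **cfg.get("model", {})},
        "training": {**DEFAULT_TRAINING, **cfg.get("training", {})},
        "raw": cfg,
    }
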