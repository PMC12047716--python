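# Desk-scale profile: same physical world as the full configuration,
# 4 mm voxels and 64-position scans so everything runs on one CPU.
profile: desk

substrate:
  mua: {mean: 0.005, sd: 0.002}     # mm^-1
  musp: {mean: 0.98, sd: 0.2}       # mm^-1

anomalies:
  count: [0, 5]
  radius_mm: [5, 15]
  min_depth_mm: [0, 20]
  mua_contrast: [1.5, 3.5]
  musp_contrast: [1.5, 2.5]
  shapes: [sphere, cylinder, cuboid]

scan:
  resolution_mm: 1
  area_mm: 50
  max_positions: 64

probe:
  sds_mm: [20, 30, 40]
  modulation_frequency_mhz: 100

noise:
  floor_dbm: -51
  floor_var: 1.0e-11
  slope_db_per_db: 1.2

target:
  dims: [13, 13, 6]
  voxel_size_mm: 4

model:
  d_embed: 64
  n_heads: 4
  n_layers: 2
  d_latent: 128
  d_seq: 64

training:
  seed: 0
  epochs: 30
  batch_size: 32
  lr: 1.0e-3
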