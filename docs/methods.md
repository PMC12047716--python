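# Methods

`dotrecon` reconstructs absolute absorption (μa) and reduced scattering
(μs′) voxel volumes directly from spatially unstructured frequency-domain
diffuse optical tomography (FD-DOT) scan measurements. This note records
the model, the synthetic world it is trained in, and the numerical and
design choices a maintainer would want to know.

## Problem setting

A handheld FD-DOT probe carries one intensity-modulated source (100 MHz)
and three detectors collinear at 20, 30, and 40 mm. At each probe position
the instrument yields log-amplitude and phase lag at each separation — six
numbers — plus the probe's position and orientation. A freehand scan is
therefore a *set* of (measurement, context) pairs of arbitrary length and
order. The inverse problem is to map this set to the optical-property
volume beneath a 50 × 50 mm scan area to 24 mm depth.

## Model

**Measurement encoder (set transformer).** Each measurement row `X_i` is
embedded by a fully connected layer; the embedding is concatenated with the
normalized context `P_i = [x, y, cos θ, sin θ]`, passed through a second
fully connected layer, and added back to the measurement embedding to form
one token. A stack of multi-head self-attention layers mixes tokens; the
attention weights are the row-wise softmax of QKᵀ restricted to active
(unmasked) keys. After the last layer, active tokens are averaged and
projected to a latent vector `Z ∈ R^{d_latent}`. Because spatial
information enters only through `P`, the encoder is permutation invariant
over scan rows and handles any scan length up to `d_seq` with one set of
weights: padded or masked rows are excluded from attention keys, zeroed at
every layer input, and excluded from the mean pool.

Design choices where the printed architecture is silent or minimal:

* The attention logits include the customary 1/√d_head temperature by
  default; `scale_attention=False` gives the literal unscaled form. The
  two differ only by a reparameterization of Q/K scale but the scaled
  variant trains more reliably.
* Residual connections, pre-layer normalization, and a position-wise
  feed-forward sublayer (ReLU, width 2·d_embed) are included as
  standard-transformer defaults; each is toggleable (`use_layernorm`,
  `use_ffn`). A pure attention stack is known to train poorly.
* Defaults: d_embed 128, 8 heads, 4 layers, d_latent 256, d_seq 256
  (full profile); the desk profile halves each (64/4/2/128, d_seq 64).
* Parameters are initialized fan-in-scaled uniform from a seeded
  generator; training is single-threaded NumPy, so same-seed runs are
  bit-identical.

**Volume decoder (3D CNN).** A self-supervised autoencoder is trained on
ground-truth volumes: shape-preserving 3×3×3 convolutions with 2×2×2
ceiling-mode max pooling (25×25×12 → 13×13×6 → 7×7×3, channels 16/32/64;
desk profile 13×13×6 → 7×7×3 → 4×4×2, channels 8/16/32), flattened to the
`d_latent` bottleneck, mirrored upward by nearest-neighbour resizing to the
exact pre-pool shapes. Targets are z-scored per channel over the training
set before the voxel MSE loss; the inverse scaling plus a non-negativity
clip is applied at inference (optical coefficients are physical).

**Two-stage training.** Stage 1 fits the autoencoder (voxel MSE). Stage 2
freezes it, saves every training example's latent vector (with a parameter
hash for staleness detection), and fits the transformer to regress those
latents (MSE) from the scans. Scans are under-sampled *dynamically*: every
batch draws a fresh binary mask per example with k ~ Uniform{1..d_scan}
active positions, so one model serves all scan densities. The deployed
model is the transformer encoder composed with the frozen CNN decoder.
Both stages use Adam (initial rate 1e-3, cosine decay), early stopping on
validation loss (patience 10), and best-checkpoint restoration. All of
this is configuration; nothing here is prescribed by the printed method.

The networks are implemented in NumPy with hand-written backpropagation
(`dotrecon._nn`); no deep-learning framework is required. Gradients of
every layer are verified against central finite differences in the tests.

## Synthetic world

The simulator emulates breast-tissue statistics: substrate
μa ~ N(0.005, 0.002) mm⁻¹ and μs′ ~ N(0.98, 0.2) mm⁻¹ truncated positive;
0–5 anomalies per phantom (sphere / vertical cylinder / cuboid), radius
5–15 mm, top depth 0–20 mm, μa contrast 1.5–3.5, μs′ contrast 1.5–2.5,
centred uniformly over the scan area; probe positions drawn uniformly
without replacement from the 1 mm grid, orientations uniform on [0, 2π).
Held-out sets draw a static scan length uniformly on [1, 256] per example;
training scans are full length and masked dynamically instead.

**Forward model.** A finite-element photon-transport solve is replaced by
the analytic frequency-domain diffusion Green's function for a semi-infinite
medium with an extrapolated boundary (refractive index 1.4, isotropic point
source at depth 1/μs′, extrapolation length 2AD with A from the effective
reflection coefficient), plus a first-Born perturbation summed over voxels:
absorption contrast enters through δμa weighted by the product of source
and detector Green's functions, scattering contrast through δD weighted by
the dot product of their gradients. This preserves the measurement schema
and the qualitative physics (amplitude decay and phase-lag growth with
separation, depth-dependent sensitivity, both-parameter coupling) at desk
scale. It is *not* transport-accurate for strong perturbations: Born
linearization underestimates large contrasts, and the laterally infinite
slab ignores the physical phantom's tapered shape. Green's-function
measurements are treated as mW-scale powers for the dBm noise model, with a
fixed source power scale (40.0) chosen once so the 40 mm-separation signal
of a mean-property substrate sits ~10 dB above the noise floor.

**Noise.** Complex Gaussian noise, independent equal-variance real and
imaginary parts. Per-component variance in dB is piecewise linear in signal
amplitude (dBm): constant floor below −51 dBm, linear increase above. The
floor variance (1e-11, i.e. −110 dB) and slope (1.2 dB/dB) are not printed
anywhere and were chosen once to give far-detector amplitude SNR of roughly
4–10 and near-detector SNR of tens — a plausible regime for a scanning FD
instrument. The breakpoint, floor, and slope are recoverable from simulated
data by the provided piecewise fit (`fit_noise_model`).

A green test on this world establishes that the pipeline can invert *this*
forward model under *this* noise; it does not establish transport accuracy,
hardware calibration, or in-vivo generalisation.

## Evaluation

Per parameter and example: voxelwise RMSE; the Sørensen–Dice coefficient of
anomaly masks obtained by min-max normalizing a channel and thresholding at
0.5 (values exactly 0.5 count as background — the printed rule uses strict
inequalities on both sides, leaving the boundary unassigned); and the
contrast ratio — each volume's anomaly/background mean ratio using its own
mask, reconstruction over truth. Constant channels make min-max
normalization degenerate: SDC and CR are then *undefined* (NaN) and
excluded from aggregates, never coerced to zero. Bulk recovery on
homogeneous short scans (≤5 measurements) is reported as RMSE and RMSE as
percent of the true value, mean ± sd. Metric-versus-density trends use
LOESS: degree-1 weighted least squares with a tricube kernel in a
±20-measurement window, no robustness iterations, evaluated on the integer
grid (reported over 1–200 measurements).

## Scaling for desk runs

The reference experiment (50,000 training scans, 256-position scans,
25×25×12 grid, GPU training) is out of reach on one CPU. The desk profile
(`desk_config()`) keeps the same physical region and distributions with
4 mm voxels (13×13×6), 64-position scans, and thousands of examples, and is
what the acceptance script and the training-dependent tests run. Quantities
tied to paper-scale training (high-density SDC on complex multi-anomaly
phantoms) are checked as scaled-down twins and are expected to be weaker
than the full-scale numbers.

## Known limitations

* First-Born forward linearization; no transport or FEM cross-check.
* The slab geometry has no lateral boundary; detectors may extend beyond
  the scan area without penalty.
* Anomaly overlap resolution is last-writer-wins.
* The noise model's slope/floor defaults are plausible but not empirical.
* The streaming demo recomputes the full encoder per step (correctness over
  speed); no attention-state caching.
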