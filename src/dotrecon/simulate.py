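"""Synthetic phantom and frequency-domain scan simulation.

Generates the training world for the reconstruction model: breast-emulating
digital phantoms (substrate optical properties drawn from population-level
distributions, 0-5 geometric anomalies), random unstructured scan pathways
on a 1 mm grid, noisy complex FD measurements from the analytic Born
forward model, and voxelised ground-truth volumes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from . import forward
from .data import ScanRecord


class ConfigError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclass(frozen=True)
class ScanArea:
    """Lateral rectangular region (mm) the probe may visit."""

    x_min: float = 0.0
    x_max: float = 50.0
    y_min: float = 0.0
    y_max: float = 50.0

    def contains(self, x: float, y: float) -> bool:
        return (self.x_min <= x <= self.x_max) and (self.y_min <= y <= self.y_max)

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    def grid(self, resolution: float = 1.0) -> np.ndarray:
        """All (x, y) points of the resolution-spaced scan grid, row-major."""
        xs = np.arange(self.x_min, self.x_max + resolution / 2, resolution)
        ys = np.arange(self.y_min, self.y_max + resolution / 2, resolution)
        gx, gy = np.meshgrid(xs, ys, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel()])


@dataclass(frozen=True)
class ProbeGeometry:
    """Collinear source-detector arrangement of the scanning probe."""

    sds_list: tuple[float, ...] = (20.0, 30.0, 40.0)
    mod_freq: float = 1e8

    def __post_init__(self):
        seps = np.asarray(self.sds_list, dtype=float)
        if len(seps) == 0 or np.any(seps <= 0) or np.any(np.diff(seps) <= 0):
            raise ConfigError(
                "source-detector separations must be positive and strictly increasing"
            )
        if self.mod_freq < 0:
            raise ConfigError("modulation frequency must be >= 0")

    @property
    def n_detectors(self) -> int:
        return len(self.sds_list)


@dataclass(frozen=True)
class NoiseModel:
    """Two-segment piecewise log-linear complex-noise variance model.

    Per-component (real/imaginary) variance, in dB (``10*log10``), is
    constant at ``10*log10(floor_var)`` for amplitudes at or below
    ``floor_dbm`` and rises linearly with slope ``slope_db_per_db`` above
    it, making the variance curve continuous at the floor.  Amplitude in
    dBm is ``10*log10(|m|)`` with the measurement treated as mW-scaled.
    """

    floor_dbm: float = -51.0
    floor_var: float = 1e-11
    slope_db_per_db: float = 1.2

    def __post_init__(self):
        if self.floor_var < 0:
            raise ConfigError("floor variance must be >= 0")

    def variance(self, amp_dbm) -> np.ndarray:
        """Per-component linear variance at the given amplitude(s) in dBm."""
        amp_dbm = np.asarray(amp_dbm, dtype=float)
        if self.floor_var == 0.0:
            return np.zeros_like(amp_dbm)
        var_db = 10.0 * np.log10(self.floor_var) + self.slope_db_per_db * np.maximum(
            amp_dbm - self.floor_dbm, 0.0
        )
        return 10.0 ** (var_db / 10.0)


@dataclass(frozen=True)
class AnomalySpec:
    """One tumor-emulating inclusion."""

    shape: str  # sphere | cylinder | cuboid
    radius: float  # characteristic half-size (mm)
    min_depth: float  # surface to top of anomaly (mm)
    center: tuple[float, float]  # lateral position (mm)
    mua_contrast: float  # anomaly/substrate ratio
    musp_contrast: float

    def __post_init__(self):
        if self.shape not in ("sphere", "cylinder", "cuboid"):
            raise ConfigError(f"unknown anomaly shape {self.shape!r}")

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean membership of (N, 3) points (x, y, depth z)."""
        cx, cy = self.center
        cz = self.min_depth + self.radius  # vertical center
        d = points - np.array([cx, cy, cz])
        if self.shape == "sphere":
            return np.sum(d**2, axis=-1) <= self.radius**2
        if self.shape == "cylinder":  # vertical axis, height 2*radius
            lateral = d[:, 0] ** 2 + d[:, 1] ** 2 <= self.radius**2
            return lateral & (np.abs(d[:, 2]) <= self.radius)
        # cuboid: axis-aligned, half-edge = radius
        return np.all(np.abs(d) <= self.radius, axis=-1)


@dataclass
class OpticalVolume:
    """Voxel grid of absorption and reduced scattering (mm^-1).

    The grid covers the reconstruction target region below the scan area,
    ``dims * voxel_size`` mm on each axis, with ``origin`` the lateral
    coordinate of the grid corner and z measured as depth from the surface.
    """

    mua_grid: np.ndarray  # (nx, ny, nz)
    musp_grid: np.ndarray
    voxel_size: float = 2.0
    origin: tuple[float, float] = (0.0, 0.0)
    substrate_mua: float | None = None
    substrate_musp: float | None = None
    scan_area: ScanArea = field(default_factory=ScanArea)

    def __post_init__(self):
        self.mua_grid = np.asarray(self.mua_grid, dtype=float)
        self.musp_grid = np.asarray(self.musp_grid, dtype=float)
        if self.mua_grid.shape != self.musp_grid.shape:
            raise ValueError("mua and musp grids must share a shape")
        if np.any(self.mua_grid <= 0) or np.any(self.musp_grid <= 0):
            raise ValueError("optical properties must be strictly positive")
        if self.substrate_mua is None:
            self.substrate_mua = float(np.median(self.mua_grid))
        if self.substrate_musp is None:
            self.substrate_musp = float(np.median(self.musp_grid))

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.mua_grid.shape

    def voxel_centers(self) -> np.ndarray:
        """(N, 3) voxel-center coordinates (x, y, depth), C-order raveled."""
        nx, ny, nz = self.dims
        xs = self.origin[0] + (np.arange(nx) + 0.5) * self.voxel_size
        ys = self.origin[1] + (np.arange(ny) + 0.5) * self.voxel_size
        zs = (np.arange(nz) + 0.5) * self.voxel_size
        gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    def as_tensor(self) -> np.ndarray:
        """(nx, ny, nz, 2) array, channel 0 = mua, channel 1 = musp."""
        return np.stack([self.mua_grid, self.musp_grid], axis=-1)

    @classmethod
    def from_tensor(cls, tensor: np.ndarray, voxel_size: float = 2.0, **kwargs):
        return cls(
            mua_grid=tensor[..., 0],
            musp_grid=tensor[..., 1],
            voxel_size=voxel_size,
            **kwargs,
        )

    def to_nifti(self, path) -> None:
        """Export both channels as a NIfTI image with isotropic spacing."""
        import nibabel as nib

        affine = np.diag([self.voxel_size] * 3 + [1.0])
        img = nib.Nifti1Image(self.as_tensor().astype(np.float32), affine)
        nib.save(img, str(path))


@dataclass(frozen=True)
class ScanPath:
    """Probe positions (mm) and orientations (radians) of one scan."""

    positions: np.ndarray  # (n, 2)
    angles: np.ndarray  # (n,)

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class PhantomConfig:
    """Distribution parameters of the simulated world.

    Defaults restate the breast-tissue-emulating population statistics:
    substrate mua ~ N(0.005, 0.002) mm^-1 and musp ~ N(0.98, 0.2) mm^-1
    (truncated positive), 0-5 anomalies with radius 5-15 mm, minimum depth
    0-20 mm, mua contrast 1.5-3.5 and musp contrast 1.5-2.5, a 100 MHz
    modulated source with detectors at 20/30/40 mm, a 1 mm scan grid over
    50 x 50 mm, and a 25 x 25 x 12 voxel target at 2 mm resolution.
    """

    substrate_mua_mean: float = 0.005
    substrate_mua_sd: float = 0.002
    substrate_musp_mean: float = 0.98
    substrate_musp_sd: float = 0.2
    n_anomalies_range: tuple[int, int] = (0, 5)
    anomaly_shapes: tuple[str, ...] = ("sphere", "cylinder", "cuboid")
    radius_range: tuple[float, float] = (5.0, 15.0)
    min_depth_range: tuple[float, float] = (0.0, 20.0)
    mua_contrast_range: tuple[float, float] = (1.5, 3.5)
    musp_contrast_range: tuple[float, float] = (1.5, 2.5)
    scan_area: ScanArea = field(default_factory=ScanArea)
    scan_resolution: float = 1.0
    grid_dims: tuple[int, int, int] = (25, 25, 12)
    voxel_size: float = 2.0
    geometry: ProbeGeometry = field(default_factory=ProbeGeometry)
    noise: NoiseModel = field(default_factory=NoiseModel)
    max_positions: int = 256
    refractive_index: float = forward.DEFAULT_REFRACTIVE_INDEX
    source_scale: float = forward.DEFAULT_SOURCE_SCALE

    def __post_init__(self):
        for name in ("radius_range", "min_depth_range", "mua_contrast_range",
                     "musp_contrast_range", "n_anomalies_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ConfigError(f"{name} bounds out of order: {lo} > {hi}")
        if self.substrate_mua_sd < 0 or self.substrate_musp_sd < 0:
            raise ConfigError("substrate standard deviations must be >= 0")
        if self.voxel_size <= 0 or self.scan_resolution <= 0:
            raise ConfigError("voxel size and scan resolution must be > 0")

    @property
    def grid_origin(self) -> tuple[float, float]:
        """Lateral corner placing the voxel grid centred on the scan area."""
        ox = self.scan_area.x_min + (self.scan_area.width - self.grid_dims[0] * self.voxel_size) / 2
        oy = self.scan_area.y_min + (self.scan_area.height - self.grid_dims[1] * self.voxel_size) / 2
        return (ox, oy)

    def replace(self, **kwargs) -> "PhantomConfig":
        return dataclasses.replace(self, **kwargs)


def desk_config(**overrides) -> PhantomConfig:
    """Reduced-resolution profile for CPU-scale runs: 13 x 13 x 6 voxels at
    4 mm covering the same 24 mm-deep target region, at most 64 positions."""
    cfg = PhantomConfig(grid_dims=(13, 13, 6), voxel_size=4.0, max_positions=64)
    return cfg.replace(**overrides) if overrides else cfg


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lower: float = 1e-4) -> float:
    """Normal draw rejected below ``lower`` (keeps optical properties physical)."""
    for _ in range(1000):
        value = rng.normal(mean, sd)
        if value > lower:
            return float(value)
    raise RuntimeError("truncated normal sampling failed; check distribution scale")


def sample_phantom(
    rng: np.random.Generator, config: PhantomConfig | None = None
) -> tuple[OpticalVolume, list[AnomalySpec]]:
    """Draw one digital phantom from the configured distributions.

    Substrate properties are truncated-normal draws; the anomaly count is
    uniform on its integer range, and each anomaly's shape, radius, depth,
    lateral centre, and contrasts are drawn independently.  Anomaly voxels
    take substrate x contrast; later anomalies overwrite earlier ones where
    they overlap.
    """
    config = config or PhantomConfig()
    mua0 = _truncated_normal(rng, config.substrate_mua_mean, config.substrate_mua_sd)
    musp0 = _truncated_normal(rng, config.substrate_musp_mean, config.substrate_musp_sd)
    n_anom = int(rng.integers(config.n_anomalies_range[0], config.n_anomalies_range[1] + 1))
    area = config.scan_area
    anomalies = []
    for _ in range(n_anom):
        anomalies.append(
            AnomalySpec(
                shape=str(rng.choice(config.anomaly_shapes)),
                radius=float(rng.uniform(*config.radius_range)),
                min_depth=float(rng.uniform(*config.min_depth_range)),
                center=(
                    float(rng.uniform(area.x_min, area.x_max)),
                    float(rng.uniform(area.y_min, area.y_max)),
                ),
                mua_contrast=float(rng.uniform(*config.mua_contrast_range)),
                musp_contrast=float(rng.uniform(*config.musp_contrast_range)),
            )
        )
    mua = np.full(config.grid_dims, mua0)
    musp = np.full(config.grid_dims, musp0)
    volume = OpticalVolume(
        mua_grid=mua,
        musp_grid=musp,
        voxel_size=config.voxel_size,
        origin=config.grid_origin,
        substrate_mua=mua0,
        substrate_musp=musp0,
        scan_area=config.scan_area,
    )
    centers = volume.voxel_centers()
    for anom in anomalies:
        inside = anom.contains(centers).reshape(config.grid_dims)
        volume.mua_grid[inside] = mua0 * anom.mua_contrast
        volume.musp_grid[inside] = musp0 * anom.musp_contrast
    return volume, anomalies


def sample_scan_path(
    rng: np.random.Generator,
    n_positions: int,
    area: ScanArea | None = None,
    resolution: float = 1.0,
) -> ScanPath:
    """Uniform without-replacement draw of probe positions on the scan grid,
    with orientations uniform on [0, 2pi)."""
    area = area or ScanArea()
    grid = area.grid(resolution)
    if not 1 <= n_positions <= len(grid):
        raise ValueError(
            f"n_positions must be in [1, {len(grid)}], got {n_positions}"
        )
    idx = rng.choice(len(grid), size=n_positions, replace=False)
    angles = rng.uniform(0.0, 2.0 * np.pi, size=n_positions)
    return ScanPath(positions=grid[idx], angles=angles)


def add_noise(
    measurement, noise: NoiseModel, rng: np.random.Generator
) -> np.ndarray | complex:
    """Add complex Gaussian noise with amplitude-dependent variance.

    The per-component variance follows the two-segment piecewise log-linear
    model evaluated at the measurement amplitude in dBm; real and imaginary
    parts are independent with equal variance.
    """
    m = np.asarray(measurement, dtype=complex)
    var = noise.variance(10.0 * np.log10(np.abs(m)))
    sd = np.sqrt(var)
    noisy = m + sd * rng.standard_normal(m.shape) + 1j * sd * rng.standard_normal(m.shape)
    return noisy if m.shape else complex(noisy)


def measure_noise_variances(
    noise: NoiseModel,
    rng: np.random.Generator,
    amps_dbm=None,
    n_samples: int = 100_000,
) -> tuple[np.ndarray, np.ndarray]:
    """Empirical per-component noise variances across an amplitude sweep.

    For each amplitude (dBm) a real-valued carrier of that amplitude is
    noise-corrupted ``n_samples`` times; the returned variances are the
    average of the real- and imaginary-part sample variances, in dB.
    """
    if amps_dbm is None:
        amps_dbm = np.arange(-80.0, -19.0, 1.0)
    amps_dbm = np.asarray(amps_dbm, dtype=float)
    var_db = np.empty_like(amps_dbm)
    for i, a in enumerate(amps_dbm):
        carrier = complex(10.0 ** (a / 10.0))
        noisy = add_noise(np.full(n_samples, carrier), noise, rng)
        v = 0.5 * (np.var(noisy.real) + np.var(noisy.imag))
        var_db[i] = 10.0 * np.log10(v)
    return amps_dbm, var_db


def fit_noise_model(amps_dbm: np.ndarray, var_db: np.ndarray) -> NoiseModel:
    """Fit a continuous two-segment piecewise linear variance model.

    Model: ``var_db(a) = floor_db + slope * max(a - breakpoint, 0)``.
    The breakpoint is located by profiling candidate values on a 0.01 dBm
    grid, solving the (then linear) least-squares problem at each, and
    keeping the minimum-SSE fit.
    """
    amps_dbm = np.asarray(amps_dbm, dtype=float)
    var_db = np.asarray(var_db, dtype=float)
    candidates = np.arange(amps_dbm.min(), amps_dbm.max(), 0.01)
    best = (np.inf, None)
    for b in candidates:
        hinge = np.maximum(amps_dbm - b, 0.0)
        A = np.column_stack([np.ones_like(amps_dbm), hinge])
        coef, *_ = np.linalg.lstsq(A, var_db, rcond=None)
        sse = float(np.sum((A @ coef - var_db) ** 2))
        if sse < best[0]:
            best = (sse, (b, coef))
    b, (floor_db, slope) = best[1][0], (best[1][1][0], best[1][1][1])
    return NoiseModel(
        floor_dbm=float(b),
        floor_var=float(10.0 ** (floor_db / 10.0)),
        slope_db_per_db=float(slope),
    )


def generate_scan(
    volume: OpticalVolume,
    path: ScanPath,
    geometry: ProbeGeometry | None = None,
    noise: NoiseModel | None = None,
    rng: np.random.Generator | None = None,
    refractive_index: float = forward.DEFAULT_REFRACTIVE_INDEX,
    source_scale: float = forward.DEFAULT_SOURCE_SCALE,
    example_id: str | None = None,
) -> ScanRecord:
    """Simulate the noisy measurement matrix of one unstructured scan.

    Each row of X holds the natural-log amplitude at every separation
    followed by the phase lag (radians) at every separation, of the
    noise-added Born measurement at that probe position; the matching row
    of P is the raw context [x, y, cos theta, sin theta] with positions in
    mm (mapped to [0, 1] later by the model's feature scaler).
    """
    geometry = geometry or ProbeGeometry()
    noise = noise or NoiseModel()
    rng = rng if rng is not None else np.random.default_rng()
    n_det = geometry.n_detectors
    X = np.empty((len(path), 2 * n_det))
    P = np.empty((len(path), 4))
    for i, ((x, y), theta) in enumerate(zip(path.positions, path.angles)):
        m = forward.born_measurement(
            volume, (x, y, theta), geometry, refractive_index, source_scale
        )
        m = add_noise(m, noise, rng)
        X[i, :n_det] = np.log(np.abs(m))
        X[i, n_det:] = -np.angle(m)
        P[i] = (x, y, np.cos(theta), np.sin(theta))
    return ScanRecord(X=X, P=P, target=volume, example_id=example_id)


def simulate_dataset(
    config: PhantomConfig,
    n_scans: int,
    rng: np.random.Generator,
    n_positions: int | None = None,
    undersample: bool = False,
    homogeneous_only: bool = False,
) -> list[ScanRecord]:
    """Generate a dataset of scans with ground-truth volumes.

    Training sets use full-length scans (``config.max_positions`` probe
    positions, later under-sampled dynamically during training); held-out
    sets pass ``undersample=True`` to draw a static scan length uniformly
    on [1, max_positions] per example, emulating varying scan durations.
    """
    cfg = config.replace(n_anomalies_range=(0, 0)) if homogeneous_only else config
    records = []
    for i in range(n_scans):
        volume, _ = sample_phantom(rng, cfg)
        n_pos = n_positions or cfg.max_positions
        if undersample:
            n_pos = int(rng.integers(1, cfg.max_positions + 1))
        path = sample_scan_path(rng, n_pos, cfg.scan_area, cfg.scan_resolution)
        records.append(
            generate_scan(
                volume, path, cfg.geometry, cfg.noise, rng,
                cfg.refractive_index, cfg.source_scale, example_id=str(i),
            )
        )
    return records
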