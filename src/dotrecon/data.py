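"""Scan data model: records, normalization, padding/masking, and HDF5 I/O."""

from __future__ import annotations

from dataclasses import dataclass, replace

import h5py
import numpy as np


class FormatError(ValueError):
    """Raised for malformed dataset containers."""


class NotFittedError(RuntimeError):
    """Raised when a scaler or estimator is used before fitting."""


@dataclass
class ScanRecord:
    """One unstructured scan.

    Attributes
    ----------
    X : (d_scan, d_meas) ndarray
        Per-position measurements: log-amplitude at each source-detector
        separation followed by phase lag (radians) at each separation.
    P : (d_scan, 4) ndarray
        Per-position context [x, y, cos(theta), sin(theta)]; positions in mm
        until normalized by a :class:`FeatureScaler`.
    target : OpticalVolume or None
        Ground-truth voxel volume, present for training/evaluation data.
    """

    X: np.ndarray
    P: np.ndarray
    target: object | None = None
    example_id: str | None = None

    def __post_init__(self):
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.P = np.atleast_2d(np.asarray(self.P, dtype=float))
        if self.X.shape[0] != self.P.shape[0]:
            raise FormatError(
                f"scan {self.example_id!r}: X has {self.X.shape[0]} rows but "
                f"P has {self.P.shape[0]}"
            )
        if self.X.shape[0] < 1:
            raise FormatError("a scan needs at least one measurement row")

    @property
    def d_scan(self) -> int:
        return self.X.shape[0]

    @property
    def d_meas(self) -> int:
        return self.X.shape[1]


@dataclass
class SequenceBatch:
    """Zero-padded stack of scans with an active-position mask (1 = active)."""

    X: np.ndarray  # (d_batch, d_seq, d_meas)
    P: np.ndarray  # (d_batch, d_seq, 4)
    mask: np.ndarray  # (d_batch, d_seq) float 0/1
    lengths: np.ndarray  # (d_batch,) original scan lengths

    def __post_init__(self):
        if not np.all(self.mask.sum(axis=1) >= 1):
            raise ValueError("every batch row needs at least one active position")


class FeatureScaler:
    """Standardizes measurement columns and maps probe positions to [0, 1].

    Measurement columns are z-scored against training-set statistics;
    the x, y context columns are min-max mapped over the scan area and the
    orientation columns (cos, sin) pass through unchanged.  Fit on training
    data only; apply everywhere.
    """

    def __init__(self, scan_area=None):
        if scan_area is None:
            from .simulate import ScanArea

            scan_area = ScanArea()
        self.scan_area = scan_area
        self.x_mean_ = None
        self.x_scale_ = None

    @property
    def is_fitted(self) -> bool:
        return self.x_mean_ is not None

    def fit(self, records: list[ScanRecord]) -> "FeatureScaler":
        rows = np.concatenate([r.X for r in records], axis=0)
        self.x_mean_ = rows.mean(axis=0)
        scale = rows.std(axis=0)
        self.x_scale_ = np.where(scale > 0, scale, 1.0)
        return self

    def _require_fitted(self):
        if not self.is_fitted:
            raise NotFittedError("FeatureScaler used before fit()")

    def transform(self, record: ScanRecord) -> ScanRecord:
        self._require_fitted()
        X = (record.X - self.x_mean_) / self.x_scale_
        P = record.P.copy()
        a = self.scan_area
        P[:, 0] = (P[:, 0] - a.x_min) / a.width
        P[:, 1] = (P[:, 1] - a.y_min) / a.height
        return replace(record, X=X, P=P)

    def inverse_transform(self, record: ScanRecord) -> ScanRecord:
        self._require_fitted()
        X = record.X * self.x_scale_ + self.x_mean_
        P = record.P.copy()
        a = self.scan_area
        P[:, 0] = P[:, 0] * a.width + a.x_min
        P[:, 1] = P[:, 1] * a.height + a.y_min
        return replace(record, X=X, P=P)

    def to_dict(self) -> dict:
        self._require_fitted()
        return {
            "x_mean": self.x_mean_.tolist(),
            "x_scale": self.x_scale_.tolist(),
            "area": [self.scan_area.x_min, self.scan_area.x_max,
                     self.scan_area.y_min, self.scan_area.y_max],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureScaler":
        from .simulate import ScanArea

        x0, x1, y0, y1 = d["area"]
        scaler = cls(ScanArea(x0, x1, y0, y1))
        scaler.x_mean_ = np.asarray(d["x_mean"], dtype=float)
        scaler.x_scale_ = np.asarray(d["x_scale"], dtype=float)
        return scaler


def normalize_scan(record: ScanRecord, scaler: FeatureScaler) -> ScanRecord:
    """Apply a fitted :class:`FeatureScaler` to one scan."""
    return scaler.transform(record)


def undersample_scan(
    record: ScanRecord, n_keep: int, rng: np.random.Generator
) -> ScanRecord:
    """Restrict a scan to a uniform without-replacement subset of its rows,
    keeping each (X_i, P_i) pair aligned."""
    if not 1 <= n_keep <= record.d_scan:
        raise ValueError(f"n_keep must be in [1, {record.d_scan}], got {n_keep}")
    idx = rng.choice(record.d_scan, size=n_keep, replace=False)
    return replace(record, X=record.X[idx], P=record.P[idx])


def batch_scans(records: list[ScanRecord], d_seq: int) -> SequenceBatch:
    """Zero-pad scans of varying length into one mask-annotated batch."""
    for r in records:
        if r.d_scan > d_seq:
            raise ValueError(
                f"scan {r.example_id!r} has {r.d_scan} rows > d_seq={d_seq}; "
                "under-sample it first"
            )
    d_meas = records[0].d_meas
    B = len(records)
    X = np.zeros((B, d_seq, d_meas))
    P = np.zeros((B, d_seq, records[0].P.shape[1]))
    mask = np.zeros((B, d_seq))
    lengths = np.array([r.d_scan for r in records])
    for i, r in enumerate(records):
        X[i, : r.d_scan] = r.X
        P[i, : r.d_scan] = r.P
        mask[i, : r.d_scan] = 1.0
    return SequenceBatch(X=X, P=P, mask=mask, lengths=lengths)


def unbatch_scans(batch: SequenceBatch) -> list[ScanRecord]:
    """Recover the original records (without targets) from a batch."""
    out = []
    for i, n in enumerate(batch.lengths):
        out.append(ScanRecord(X=batch.X[i, :n].copy(), P=batch.P[i, :n].copy()))
    return out


def write_dataset(records: list[ScanRecord], path, meta: dict | None = None) -> None:
    """Write scans (and targets, where present) to an HDF5 container.

    Layout: ``/scans/<i>/X``, ``/scans/<i>/P``, ``/targets/<i>`` (optional,
    ``nx x ny x nz x 2``), and config/seed metadata as ``/meta`` attributes.
    Units: mm, mm^-1, radians, natural-log amplitude.
    """
    with h5py.File(path, "w") as f:
        scans = f.create_group("scans")
        targets = f.create_group("targets")
        for i, r in enumerate(records):
            g = scans.create_group(str(i))
            g.create_dataset("X", data=r.X)
            g.create_dataset("P", data=r.P)
            if r.example_id is not None:
                g.attrs["example_id"] = r.example_id
            if r.target is not None:
                t = targets.create_dataset(str(i), data=r.target.as_tensor())
                t.attrs["voxel_size"] = r.target.voxel_size
                t.attrs["origin"] = r.target.origin
        m = f.create_group("meta")
        for key, value in (meta or {}).items():
            m.attrs[key] = value


def read_dataset(path) -> tuple[list[ScanRecord], dict]:
    """Read an HDF5 scan container back into records plus metadata.

    Datasets without a ``/targets`` group (or with missing entries) load as
    unlabeled scans for inference.
    """
    from .simulate import OpticalVolume

    records = []
    with h5py.File(path, "r") as f:
        if "scans" not in f:
            raise FormatError(f"{path}: missing /scans group")
        targets = f["targets"] if "targets" in f else {}
        keys = sorted(f["scans"].keys(), key=int)
        for key in keys:
            g = f["scans"][key]
            if "X" not in g or "P" not in g:
                raise FormatError(f"{path}: /scans/{key} missing X or P")
            X, P = g["X"][()], g["P"][()]
            if X.shape[0] != P.shape[0]:
                raise FormatError(
                    f"{path}: /scans/{key} row mismatch (X {X.shape[0]}, P {P.shape[0]})"
                )
            target = None
            if key in targets:
                t = targets[key]
                target = OpticalVolume.from_tensor(
                    t[()], voxel_size=float(t.attrs.get("voxel_size", 2.0)),
                    origin=tuple(t.attrs.get("origin", (0.0, 0.0))),
                )
            records.append(
                ScanRecord(X=X, P=P, target=target,
                           example_id=g.attrs.get("example_id", key))
            )
        meta = dict(f["meta"].attrs) if "meta" in f else {}
    return records, meta
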