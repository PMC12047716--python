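"""Reconstruction quality metrics and scan-density curve fitting.

Three per-parameter metrics: voxelwise RMSE (absolute accuracy), the
Sørensen-Dice coefficient over min-max-thresholded anomaly masks (spatial
similarity), and the contrast ratio (recovered vs true anomaly/background
contrast).  Metric-vs-scan-density trends are summarised by local linear
(LOESS) regression inside a ±20-measurement sliding window.

Degenerate channels (constant volumes) have no min-max normalization, so
SDC and CR are *undefined* there: they return NaN and are excluded from
aggregates rather than coerced to zero.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

PARAM_NAMES = ("mua", "musp")


def rmse(y_hat: np.ndarray, y: np.ndarray) -> float:
    """Root-mean-squared voxelwise error."""
    y_hat, y = np.asarray(y_hat, dtype=float), np.asarray(y, dtype=float)
    if y_hat.shape != y.shape:
        raise ValueError(f"shape mismatch: {y_hat.shape} vs {y.shape}")
    return float(np.sqrt(np.mean((y_hat - y) ** 2)))


def anomaly_mask(x: np.ndarray) -> np.ndarray | None:
    """Anomaly voxels: min-max normalized values strictly above 0.5.

    Values at exactly 0.5 count as background.  Returns ``None`` (undefined)
    for constant channels, where the normalization is degenerate.
    """
    x = np.asarray(x, dtype=float)
    lo, hi = x.min(), x.max()
    if hi == lo:
        return None
    return (x - lo) / (hi - lo) > 0.5


def sdc(y_hat: np.ndarray, y: np.ndarray) -> float:
    """Sørensen-Dice coefficient between the two volumes' anomaly masks.

    NaN when either mask is undefined; by convention 2*0/(0+0) is also
    undefined (no anomaly voxels on either side).
    """
    a, b = anomaly_mask(y_hat), anomaly_mask(y)
    if a is None or b is None:
        return float("nan")
    denom = a.sum() + b.sum()
    if denom == 0:
        return float("nan")
    return float(2.0 * np.sum(a & b) / denom)


def contrast_ratio(y_hat: np.ndarray, y: np.ndarray) -> float:
    """Recovered anomaly/background contrast over the true contrast.

    Each volume's contrast uses its *own* anomaly mask.  NaN when either
    mask is undefined, empty, fills the volume, or a background mean is 0.
    """

    def _contrast(x):
        m = anomaly_mask(x)
        if m is None or not m.any() or m.all():
            return float("nan")
        bg = np.mean(np.asarray(x, dtype=float)[~m])
        if bg == 0:
            return float("nan")
        return float(np.mean(np.asarray(x, dtype=float)[m]) / bg)

    c_hat, c_true = _contrast(y_hat), _contrast(y)
    if np.isnan(c_hat) or np.isnan(c_true) or c_true == 0:
        return float("nan")
    return c_hat / c_true


def evaluate_pair(y_hat_vol, y_vol, n_measurements: int | None = None,
                  example_id: str | None = None) -> pd.DataFrame:
    """Per-parameter metric rows for one (reconstruction, truth) pair.

    Accepts OpticalVolume instances or (nx, ny, nz, 2) tensors.  RMSE is in
    mm^-1; the ``rmse_percent`` column scales it by the true channel mean.
    """
    yh = y_hat_vol.as_tensor() if hasattr(y_hat_vol, "as_tensor") else np.asarray(y_hat_vol)
    yt = y_vol.as_tensor() if hasattr(y_vol, "as_tensor") else np.asarray(y_vol)
    rows = []
    for c, name in enumerate(PARAM_NAMES):
        err = rmse(yh[..., c], yt[..., c])
        rows.append(
            {
                "example_id": example_id,
                "parameter": name,
                "rmse_mm_inv": err,
                "rmse_percent": 100.0 * err / np.mean(yt[..., c]),
                "sdc": sdc(yh[..., c], yt[..., c]),
                "cr": contrast_ratio(yh[..., c], yt[..., c]),
                "n_measurements": n_measurements,
            }
        )
    return pd.DataFrame(rows)


def metric_report(reconstructions, truths, n_measurements=None) -> pd.DataFrame:
    """Stacked metric rows for paired lists of volumes."""
    frames = []
    for i, (yh, yt) in enumerate(zip(reconstructions, truths)):
        n = None if n_measurements is None else int(n_measurements[i])
        frames.append(evaluate_pair(yh, yt, n, example_id=str(i)))
    return pd.concat(frames, ignore_index=True)


def density_curve(reports: pd.DataFrame, metric: str,
                  window: float = 20.0, grid=None) -> pd.DataFrame:
    """LOESS curve of a metric against scan density (measurement count).

    Local degree-1 weighted least squares with a tricube kernel inside a
    ±``window`` sliding window, evaluated on the integer measurement grid
    (1..max(n) by default).  Undefined metric values are dropped.
    """
    d = reports.dropna(subset=[metric, "n_measurements"])
    x = d["n_measurements"].to_numpy(dtype=float)
    y = d[metric].to_numpy(dtype=float)
    if len(np.unique(x)) < 2:
        raise ValueError("density_curve needs >= 2 distinct measurement counts")
    if grid is None:
        grid = np.arange(1, int(x.max()) + 1)
    out = np.full(len(grid), np.nan)
    for i, x0 in enumerate(grid):
        dist = np.abs(x - x0)
        w = np.clip(1.0 - (dist / window) ** 3, 0.0, None) ** 3
        sel = w > 0
        if sel.sum() == 0:
            continue
        xs, ys, ws = x[sel], y[sel], w[sel]
        if len(np.unique(xs)) < 2:
            out[i] = np.average(ys, weights=ws)
            continue
        # weighted linear fit evaluated at x0
        sw = np.sqrt(ws)
        Xd = np.column_stack([np.ones_like(xs), xs - x0])
        beta = np.linalg.lstsq(sw[:, None] * Xd, sw * ys, rcond=None)[0]
        out[i] = beta[0]
    return pd.DataFrame({"n_measurements": grid, metric: out})


def bulk_recovery_report(model, records, max_measurements: int = 5) -> pd.DataFrame:
    """Bulk-property recovery on homogeneous short scans (Table-2 schema).

    Restricts to homogeneous examples with at most ``max_measurements``
    rows, reconstructs each, and reports per-parameter RMSE (mm^-1) and
    RMSE as a percentage of the true value, mean ± sd across examples.
    """
    eligible = [
        r for r in records
        if r.d_scan <= max_measurements and r.target is not None
        and _is_homogeneous(r.target)
    ]
    if not eligible:
        raise ValueError(
            f"no homogeneous examples with <= {max_measurements} measurements"
        )
    tensors = model.predict_tensor(eligible)
    per_param = {name: {"rmse": [], "pct": []} for name in PARAM_NAMES}
    for t, r in zip(tensors, eligible):
        truth = r.target.as_tensor()
        for c, name in enumerate(PARAM_NAMES):
            err = rmse(t[..., c], truth[..., c])
            per_param[name]["rmse"].append(err)
            per_param[name]["pct"].append(100.0 * err / truth[..., c].mean())
    rows = []
    for name in PARAM_NAMES:
        e = np.array(per_param[name]["rmse"])
        p = np.array(per_param[name]["pct"])
        rows.append(
            {
                "parameter": name,
                "rmse_mm_inv_mean": e.mean(), "rmse_mm_inv_sd": e.std(),
                "rmse_percent_mean": p.mean(), "rmse_percent_sd": p.std(),
                "n_examples": len(e),
            }
        )
    return pd.DataFrame(rows)


def _is_homogeneous(volume) -> bool:
    return (np.ptp(volume.mua_grid) == 0) and (np.ptp(volume.musp_grid) == 0)
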