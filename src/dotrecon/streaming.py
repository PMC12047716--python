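"""Progressive image-guided scanning: reconstruct as measurements arrive.

Each incoming (measurement, context) row is appended to the accumulated
scan and the full model is re-run on the prefix, so the step-k image is
exactly the batch reconstruction of the first k measurements (no hidden
state).  Streams longer than the model's ``d_seq`` fall back to a sliding
window over the most recent ``d_seq`` positions.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from .data import ScanRecord


@dataclass
class StreamState:
    """Accumulated rows, reconstruction history, and per-step latencies."""

    X_rows: list = field(default_factory=list)
    P_rows: list = field(default_factory=list)
    history: list = field(default_factory=list)
    latencies: list = field(default_factory=list)


def stream_reconstruct(model, incoming, stride: int = 1,
                       state: StreamState | None = None):
    """Yield one reconstructed volume tensor per appended measurement.

    Parameters
    ----------
    model : ScanReconstructor
        Assembled (fitted) reconstruction model.
    incoming : iterable of (X_row, P_row)
        Raw measurement and context rows (the model's own scaler is applied).
    stride : int
        Recompute every ``stride`` measurements (1 = every step); a
        reconstruction is always emitted for the final row.

    Yields
    ------
    (nx, ny, nz, 2) ndarray per emitted step.
    """
    state = state if state is not None else StreamState()
    d_seq = model.encoder_.d_seq
    rows = list(incoming)
    for k, (x_row, p_row) in enumerate(rows, start=1):
        state.X_rows.append(np.asarray(x_row, dtype=float))
        state.P_rows.append(np.asarray(p_row, dtype=float))
        if k % stride and k != len(rows):
            continue
        t0 = time.perf_counter()
        record = ScanRecord(
            X=np.stack(state.X_rows[-d_seq:]),
            P=np.stack(state.P_rows[-d_seq:]),
        )
        volume = model.predict_tensor([record])[0]
        state.latencies.append(time.perf_counter() - t0)
        state.history.append(volume)
        yield volume
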