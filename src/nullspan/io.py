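"""Plain-text serialization of activity, weights and spike trains.

Matrices travel as delimited text with a JSON sidecar carrying the timing
and provenance metadata (time step, smoothing window, seeds); spike trains
as two-column (neuron_id, time_ms) text with a small header.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .rate_network import ActivityMatrix
from .spiking_network import SpikeTrain

__all__ = ["save_activity", "load_activity", "save_matrix", "load_matrix",
           "save_spike_train", "load_spike_train"]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def save_activity(activity: ActivityMatrix, path) -> None:
    """Write rates as CSV (first column neuron id) plus a JSON sidecar."""
    path = Path(path)
    ids = np.arange(activity.n_neurons)[:, None]
    np.savetxt(path, np.hstack([ids, activity.rates]), delimiter=",",
               fmt=["%d"] + ["%.8g"] * activity.n_bins)
    meta = {"dt": activity.dt, "smoothed_window": activity.smoothed_window,
            "seed": activity.seed, "n_neurons": activity.n_neurons,
            "n_bins": activity.n_bins}
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def load_activity(path) -> ActivityMatrix:
    path = Path(path)
    arr = np.loadtxt(path, delimiter=",", ndmin=2)
    meta = json.loads(_sidecar(path).read_text())
    return ActivityMatrix(rates=arr[:, 1:], dt=meta["dt"],
                          smoothed_window=meta.get("smoothed_window"),
                          seed=meta.get("seed"))


def save_matrix(matrix: np.ndarray, path, **meta) -> None:
    """Write a weight matrix as CSV with arbitrary metadata in the sidecar."""
    path = Path(path)
    np.savetxt(path, np.asarray(matrix, dtype=float), delimiter=",",
               fmt="%.17g")
    if meta:
        clean = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                 for k, v in meta.items()}
        _sidecar(path).write_text(json.dumps(clean, indent=1))


def load_matrix(path) -> np.ndarray:
    return np.loadtxt(Path(path), delimiter=",", ndmin=2)


def save_spike_train(train: SpikeTrain, path) -> None:
    path = Path(path)
    header = f"duration_ms={train.duration} n_neurons={train.n_neurons}"
    np.savetxt(path, train.events, delimiter=",", fmt=["%d", "%.4f"],
               header=header)


def load_spike_train(path) -> SpikeTrain:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().lstrip("# ").strip()
    fields = dict(kv.split("=") for kv in header.split())
    events = np.loadtxt(path, delimiter=",", ndmin=2)
    if events.size == 0:
        events = np.empty((0, 2))
    return SpikeTrain(events=events, duration=float(fields["duration_ms"]),
                      n_neurons=int(float(fields["n_neurons"])))
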