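"""Multi-channel demodulated trace container and on-disk formats.

A :class:`Trace` holds one voltage time series per excitation frequency plus
the sampling and frequency-panel metadata needed to interpret it.  The
canonical container is an HDF5 file (one dataset per channel, metadata as
root attributes); a CSV file with a JSON sidecar serves as a plain-text
fallback.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .circuit import FrequencyPanel
from .errors import ParameterError, SchemaError


@dataclass
class Trace:
    """Demodulated multi-frequency voltage time series.

    ``channels`` is an array of shape ``(n_frequencies, n_samples)`` in volts,
    row order matching ``panel.frequencies``.
    """

    channels: np.ndarray
    sampling_rate: float
    panel: FrequencyPanel
    baseline_volts: np.ndarray | None = None
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=float)
        if self.channels.ndim != 2:
            raise ParameterError("channels must be a 2-D array (n_channels, n_samples)")
        if self.channels.shape[0] != len(self.panel):
            raise ParameterError(
                f"{self.channels.shape[0]} channels but panel has {len(self.panel)} frequencies"
            )
        if not self.sampling_rate > 0:
            raise ParameterError("sampling_rate must be > 0")
        if self.baseline_volts is not None:
            self.baseline_volts = np.asarray(self.baseline_volts, dtype=float)
            if self.baseline_volts.shape != (self.channels.shape[0],):
                raise ParameterError("baseline_volts must have one entry per channel")

    @property
    def n_samples(self) -> int:
        return self.channels.shape[1]

    @property
    def n_channels(self) -> int:
        return self.channels.shape[0]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def time(self) -> np.ndarray:
        """Sample times in seconds (sample k at k / sampling_rate)."""
        return np.arange(self.n_samples) / self.sampling_rate

    def reference_channel(self) -> np.ndarray:
        return self.channels[self.panel.reference_index]


_H5_ATTRS = ("sampling_rate_hz", "frequencies_hz")


def write_trace(trace: Trace, path: str | Path) -> None:
    """Write a trace to HDF5 (``.h5``/``.hdf5``) or CSV+JSON sidecar."""
    path = Path(path)
    if path.suffix in {".h5", ".hdf5"}:
        with h5py.File(path, "w") as f:
            f.attrs["sampling_rate_hz"] = trace.sampling_rate
            f.attrs["frequencies_hz"] = np.asarray(trace.panel.frequencies)
            f.attrs["reference_index"] = trace.panel.reference_index
            if trace.baseline_volts is not None:
                f.attrs["baseline_volts"] = trace.baseline_volts
            if trace.seed is not None:
                f.attrs["seed"] = trace.seed
            for i in range(trace.n_channels):
                f.create_dataset(f"channel_{i:02d}", data=trace.channels[i])
    else:
        _write_trace_csv(trace, path)


def read_trace(path: str | Path) -> Trace:
    path = Path(path)
    if path.suffix in {".h5", ".hdf5"}:
        with h5py.File(path, "r") as f:
            for attr in _H5_ATTRS:
                if attr not in f.attrs:
                    raise SchemaError(f"trace file {path} is missing attribute {attr!r}")
            panel = FrequencyPanel(
                frequencies=tuple(f.attrs["frequencies_hz"]),
                reference_index=int(f.attrs.get("reference_index", 0)),
            )
            names = sorted(k for k in f.keys() if k.startswith("channel_"))
            channels = np.stack([f[name][()] for name in names])
            baseline = f.attrs.get("baseline_volts")
            seed = f.attrs.get("seed")
            return Trace(
                channels=channels,
                sampling_rate=float(f.attrs["sampling_rate_hz"]),
                panel=panel,
                baseline_volts=None if baseline is None else np.asarray(baseline),
                seed=None if seed is None else int(seed),
            )
    return _read_trace_csv(path)


def _write_trace_csv(trace: Trace, path: Path) -> None:
    cols = {"time_s": trace.time}
    for i, f in enumerate(trace.panel.frequencies):
        cols[f"v_{i:02d}"] = trace.channels[i]
    pd.DataFrame(cols).to_csv(path, index=False)
    sidecar = {
        "sampling_rate_hz": trace.sampling_rate,
        "frequencies_hz": list(trace.panel.frequencies),
        "reference_index": trace.panel.reference_index,
        "baseline_volts": None
        if trace.baseline_volts is None
        else list(trace.baseline_volts),
        "seed": trace.seed,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def _read_trace_csv(path: Path) -> Trace:
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise SchemaError(f"metadata sidecar {sidecar_path} not found")
    meta = json.loads(sidecar_path.read_text())
    for key in ("sampling_rate_hz", "frequencies_hz"):
        if key not in meta:
            raise SchemaError(f"trace sidecar is missing attribute {key!r}")
    df = pd.read_csv(path)
    vcols = [c for c in df.columns if c.startswith("v_")]
    panel = FrequencyPanel(
        frequencies=tuple(meta["frequencies_hz"]),
        reference_index=int(meta.get("reference_index", 0)),
    )
    baseline = meta.get("baseline_volts")
    return Trace(
        channels=df[vcols].to_numpy().T,
        sampling_rate=float(meta["sampling_rate_hz"]),
        panel=panel,
        baseline_volts=None if baseline is None else np.asarray(baseline),
        seed=meta.get("seed"),
    )
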