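"""Spike rasters: per-electrode spike-time containers and plain-text I/O.

The raster is the common currency between the simulator, the spike-detection
path, and the feature extractor: a list of sorted spike-time arrays (seconds),
one per electrode, plus the recording duration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SpikeRaster", "read_raster_csv", "write_raster_csv"]


@dataclass
class SpikeRaster:
    spikes: list[np.ndarray]   # per-electrode sorted spike times, seconds
    duration: float            # seconds

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        cleaned = []
        for st in self.spikes:
            st = np.asarray(st, dtype=float)
            if st.size and (np.any(st < 0) or np.any(st > self.duration)):
                raise ValueError("spike times outside [0, duration]")
            if st.size and np.any(np.diff(st) < 0):
                st = np.sort(st)
            cleaned.append(st)
        self.spikes = cleaned

    @property
    def n_electrodes(self) -> int:
        return len(self.spikes)

    @property
    def n_spikes(self) -> int:
        return int(sum(len(s) for s in self.spikes))

    def firing_rates(self) -> np.ndarray:
        """Mean firing rate per electrode, Hz."""
        return np.array([len(s) / self.duration for s in self.spikes])

    def shifted(self, dt_s: float) -> "SpikeRaster":
        """Raster with all spikes shifted by ``dt_s`` (clipped to the window)."""
        return SpikeRaster(
            [s[(s + dt_s >= 0) & (s + dt_s <= self.duration)] + dt_s for s in self.spikes],
            self.duration,
        )

    def permuted(self, order) -> "SpikeRaster":
        return SpikeRaster([self.spikes[i] for i in order], self.duration)


def write_raster_csv(raster: SpikeRaster, path) -> None:
    """Write ``electrode,time_s`` rows (0-based ids, seconds, time-sorted)."""
    rows = [
        (e, t)
        for e, st in enumerate(raster.spikes)
        for t in st
    ]
    df = pd.DataFrame(rows, columns=["electrode", "time_s"])
    df = df.sort_values(["time_s", "electrode"], kind="mergesort")
    df.to_csv(path, index=False)


def read_raster_csv(path, duration: float | None = None, n_electrodes: int = 12) -> SpikeRaster:
    """Read a raster CSV written by :func:`write_raster_csv`.

    ``duration`` defaults to the last spike time rounded up to the next second.
    """
    df = pd.read_csv(path)
    if not {"electrode", "time_s"}.issubset(df.columns):
        raise ValueError("raster CSV needs columns electrode,time_s")
    n_el = max(n_electrodes, int(df["electrode"].max()) + 1 if len(df) else 0)
    if duration is None:
        duration = float(np.ceil(df["time_s"].max())) if len(df) else 1.0
        duration = max(duration, 1.0)
    spikes = [
        np.sort(df.loc[df["electrode"] == e, "time_s"].to_numpy(dtype=float))
        for e in range(n_el)
    ]
    return SpikeRaster(spikes, duration)
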