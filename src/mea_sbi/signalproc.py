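"""Raw extracellular signal processing: band-pass filtering and spike detection.

Recordings are filtered between 100 and 3500 Hz with a fifth-order
Butterworth filter (applied forward-backward so spike times carry no group
delay), and spikes are detected wherever the absolute filtered signal
exceeds four times its root-mean-square amplitude.  A synthetic-trace
generator embeds known spike templates in Gaussian noise so the whole
detection path is testable without any recording.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .raster import SpikeRaster

__all__ = [
    "RawTrace",
    "bandpass",
    "detect_spikes",
    "default_template",
    "synth_extracellular",
    "save_trace_h5",
    "load_trace_h5",
]

log = logging.getLogger(__name__)

BAND = (100.0, 3500.0)
FILTER_ORDER = 5
THRESHOLD_RMS = 4.0
DEAD_TIME_S = 2e-3


@dataclass
class RawTrace:
    """Multi-electrode voltage traces in uV; ``samples`` is (n_electrodes, T)."""

    samples: np.ndarray
    fs: float  # Hz

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("non-finite samples")
        if self.fs <= 2 * BAND[1]:
            raise ValueError(f"fs={self.fs} must exceed twice the 3500 Hz band edge")

    @property
    def n_electrodes(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        return self.samples.shape[1] / self.fs


def bandpass(trace: RawTrace) -> RawTrace:
    """Zero-phase 5th-order Butterworth band-pass, 100-3500 Hz."""
    sos = sps.butter(FILTER_ORDER, BAND, btype="bandpass", fs=trace.fs, output="sos")
    out = sps.sosfiltfilt(sos, trace.samples, axis=1)
    return RawTrace(out, trace.fs)


def detect_spikes(trace: RawTrace) -> list[np.ndarray]:
    """Amplitude-threshold spike detection on an already band-passed trace.

    The threshold is 4x the RMS of each electrode's whole trace, applied to
    the absolute signal (both polarities).  Suprathreshold runs closer than
    a 2 ms dead time collapse to one event timed at the absolute extremum.
    Returns per-electrode sorted spike times in seconds.
    """
    dead = max(int(round(DEAD_TIME_S * trace.fs)), 1)
    out: list[np.ndarray] = []
    for row in trace.samples:
        rms = np.sqrt(np.mean(row**2))
        if rms == 0.0:
            out.append(np.empty(0))
            continue
        absr = np.abs(row)
        over = np.nonzero(absr > THRESHOLD_RMS * rms)[0]
        if len(over) == 0:
            out.append(np.empty(0))
            continue
        # split suprathreshold samples into events separated by >= dead time
        breaks = np.nonzero(np.diff(over) >= dead)[0]
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [len(over) - 1]])
        times = np.empty(len(starts))
        for j, (a, b) in enumerate(zip(starts, ends)):
            seg = over[a] + np.argmax(absr[over[a] : over[b] + 1])
            times[j] = seg / trace.fs
        out.append(np.sort(times))
    return out


def default_template(fs: float, peak: float = 1.0) -> np.ndarray:
    """A biphasic extracellular spike waveform (~1.5 ms, negative main phase)."""
    t = np.arange(int(round(1.5e-3 * fs))) / fs
    w = -np.exp(-((t - 4e-4) ** 2) / (2 * (1.2e-4) ** 2)) + 0.35 * np.exp(
        -((t - 8.5e-4) ** 2) / (2 * (2.5e-4) ** 2)
    )
    return peak * w / np.max(np.abs(w))


def synth_extracellular(
    raster: SpikeRaster,
    noise_sd: float,
    template: np.ndarray | None = None,
    fs: float = 10000.0,
    seed: int = 0,
) -> RawTrace:
    """Synthetic extracellular traces: templates at raster times + white noise.

    Artifact plumbing for testing the filter/detection path; overlapping
    templates are summed and logged, not rejected.
    """
    rng = np.random.default_rng(seed)
    T = int(round(raster.duration * fs))
    if template is None:
        template = default_template(fs, peak=8.0 * max(noise_sd, 1.0))
    L = len(template)
    x = rng.normal(0.0, noise_sd, size=(raster.n_electrodes, T)) if noise_sd > 0 else np.zeros(
        (raster.n_electrodes, T)
    )
    n_overlap = 0
    for e, st in enumerate(raster.spikes):
        idx = np.round(st * fs).astype(int)
        idx = idx[(idx >= 0) & (idx + L <= T)]
        if len(idx) > 1 and np.any(np.diff(idx) < L):
            n_overlap += int(np.sum(np.diff(idx) < L))
        for i0 in idx:
            x[e, i0 : i0 + L] += template
    if n_overlap:
        log.warning("synth_extracellular: %d overlapping template placements", n_overlap)
    return RawTrace(x, fs)


def save_trace_h5(trace: RawTrace, path) -> None:
    """Store per-electrode signals under /electrodes/<i>/signal with fs attr."""
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["fs"] = trace.fs
        g = f.create_group("electrodes")
        for i, row in enumerate(trace.samples):
            g.create_group(str(i)).create_dataset("signal", data=row)


def load_trace_h5(path) -> RawTrace:
    import h5py

    with h5py.File(path, "r") as f:
        keys = sorted(f["electrodes"], key=int)
        samples = np.vstack([f["electrodes"][k]["signal"][()] for k in keys])
        return RawTrace(samples, float(f.attrs["fs"]))
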