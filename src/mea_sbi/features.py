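"""MEA summary statistics: network bursts, ISI features, and the feature vector.

The extractor reduces a 12-electrode spike raster to the 13 features used to
train the density estimator (plus two optional binarized-correlation
features).  One code path serves simulated and measured rasters alike.

Network-burst (NB) detection works on the network firing rate (spikes of all
electrodes binned at 25 ms): an NB opens when the rate stays at or above
1/4 of the maximum rate for 50 ms, closes when it stays below 1/50 of the
maximum for 50 ms, and is kept only if at least half of the active
electrodes (mean rate > 0.02 Hz) fire inside it.  Fragments are peaks of the
Gaussian-smoothed in-burst rate with height >= max/16 and prominence >=
max/20.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from .raster import SpikeRaster

__all__ = [
    "NetworkRate",
    "NetworkBurst",
    "FeatureVector",
    "FEATURE_NAMES",
    "FEATURE_NAMES_EXT",
    "network_rate",
    "detect_bursts",
    "detect_fragments",
    "isi_series",
    "isi_distance",
    "mac",
    "binarized_cc",
    "compute_features",
]

log = logging.getLogger(__name__)

BIN_MS = 25.0
SUSTAIN_BINS = 2            # 50 ms expressed in 25 ms bins
START_FRACTION = 1.0 / 4.0
STOP_FRACTION = 1.0 / 50.0
ACTIVE_RATE_HZ = 0.02
PARTICIPATION = 0.5
FRAGMENT_HEIGHT = 1.0 / 16.0
FRAGMENT_PROMINENCE = 1.0 / 20.0
FRAGMENT_SIGMA_MS = 50.0
MAC_MIN_LAG_S = 0.1

FEATURE_NAMES: tuple[str, ...] = (
    "MFR", "NBR", "NBD", "PSIB", "n_FBs", "CV_IBI",
    "mean_ISI_CC", "sd_ISI_CC", "ISI_dist",
    "mean_ISI", "sd_ISI_temp", "sd_ISI_elec", "MAC",
)
FEATURE_NAMES_EXT: tuple[str, ...] = FEATURE_NAMES + ("mean_binCC", "sd_binCC")


@dataclass
class NetworkRate:
    counts: np.ndarray   # spikes per bin, summed over electrodes
    bin_ms: float
    duration: float

    @property
    def max_rate(self) -> float:
        return float(self.counts.max()) if len(self.counts) else 0.0

    @property
    def bin_s(self) -> float:
        return self.bin_ms / 1000.0


@dataclass
class NetworkBurst:
    start: float                 # s
    stop: float                  # s
    electrodes: set[int] = field(default_factory=set)
    n_fragments: int = 1

    @property
    def duration(self) -> float:
        return self.stop - self.start


def network_rate(raster: SpikeRaster, bin_ms: float = BIN_MS) -> NetworkRate:
    """Network firing rate: spikes of all electrodes binned at ``bin_ms``."""
    n_bins = max(int(np.ceil(raster.duration * 1000.0 / bin_ms)), 1)
    counts = np.zeros(n_bins)
    edges = np.arange(n_bins + 1) * bin_ms / 1000.0
    for st in raster.spikes:
        if len(st):
            c, _ = np.histogram(st, bins=edges)
            counts += c
    return NetworkRate(counts, bin_ms, raster.duration)


def active_electrodes(raster: SpikeRaster) -> list[int]:
    return [e for e, r in enumerate(raster.firing_rates()) if r > ACTIVE_RATE_HZ]


def detect_bursts(raster: SpikeRaster, rate: NetworkRate | None = None) -> list[NetworkBurst]:
    """Detect network bursts with the dual-threshold / participation rule."""
    if rate is None:
        rate = network_rate(raster)
    r = rate.counts
    mx = rate.max_rate
    if mx <= 0:
        return []
    thr_start = START_FRACTION * mx
    thr_stop = STOP_FRACTION * mx
    active = active_electrodes(raster)
    if not active:
        return []
    need = int(np.ceil(PARTICIPATION * len(active)))
    bin_s = rate.bin_s

    bursts: list[NetworkBurst] = []
    n = len(r)
    i = 0
    while i <= n - SUSTAIN_BINS:
        if np.all(r[i : i + SUSTAIN_BINS] >= thr_start):
            j = i + SUSTAIN_BINS
            stop_bin = n
            while j <= n - SUSTAIN_BINS:
                if np.all(r[j : j + SUSTAIN_BINS] < thr_stop):
                    stop_bin = j
                    break
                j += 1
            start_t, stop_t = i * bin_s, stop_bin * bin_s
            firing = {
                e
                for e in active
                if np.any(
                    (raster.spikes[e] >= start_t) & (raster.spikes[e] < stop_t)
                )
            }
            if len(firing) >= need:
                bursts.append(NetworkBurst(start_t, stop_t, firing))
            i = stop_bin + SUSTAIN_BINS
        else:
            i += 1
    for b in bursts:
        b.n_fragments = detect_fragments(b, rate)
    return bursts


def detect_fragments(burst: NetworkBurst, rate: NetworkRate) -> int:
    """Count sub-peaks of the smoothed in-burst network rate (>= 1)."""
    sigma_bins = FRAGMENT_SIGMA_MS / rate.bin_ms
    smoothed = gaussian_filter1d(rate.counts.astype(float), sigma_bins, mode="constant")
    i0 = int(burst.start / rate.bin_s)
    i1 = max(int(np.ceil(burst.stop / rate.bin_s)), i0 + 1)
    seg = smoothed[i0:i1]
    mx = rate.max_rate
    peaks, _ = find_peaks(
        seg, height=FRAGMENT_HEIGHT * mx, prominence=FRAGMENT_PROMINENCE * mx
    )
    return max(len(peaks), 1)


def isi_series(raster: SpikeRaster, bin_ms: float = BIN_MS) -> np.ndarray:
    """Continuous inter-spike-interval time series per electrode.

    For every 25 ms grid point between an electrode's first and last spike,
    the value is the interval between the previous and the next spike
    straddling that point.  Electrodes with fewer than two spikes are
    excluded (NaN everywhere); points outside the covered range are NaN.
    Returns an (n_electrodes, n_bins) array in seconds.
    """
    n_bins = max(int(np.ceil(raster.duration * 1000.0 / bin_ms)), 1)
    t = (np.arange(n_bins) + 0.5) * bin_ms / 1000.0
    out = np.full((raster.n_electrodes, n_bins), np.nan)
    for e, st in enumerate(raster.spikes):
        if len(st) < 2:
            continue
        valid = (t >= st[0]) & (t < st[-1])
        idx = np.searchsorted(st, t[valid], side="right")
        out[e, valid] = st[idx] - st[idx - 1]
    return out


def isi_distance(a: np.ndarray, b: np.ndarray, bin_ms: float = BIN_MS) -> float:
    """Time-averaged ISI-ratio dissimilarity between two spike trains.

    At each grid point in the overlap of the two trains' covered ranges,
    I(t) = ISI_a/ISI_b - 1 if ISI_a <= ISI_b else -(ISI_b/ISI_a - 1); the
    distance is the mean of |I|.  Zero iff the instantaneous ISIs agree
    everywhere on the overlap.
    """
    a = np.sort(np.asarray(a, dtype=float))
    b = np.sort(np.asarray(b, dtype=float))
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both trains need >= 2 spikes")
    lo = max(a[0], b[0])
    hi = min(a[-1], b[-1])
    if hi <= lo:
        return np.nan
    t = np.arange(lo, hi, bin_ms / 1000.0) + bin_ms / 2000.0
    t = t[t < hi]
    if len(t) == 0:
        return np.nan

    def _isi_at(st, tt):
        idx = np.searchsorted(st, tt, side="right")
        idx = np.clip(idx, 1, len(st) - 1)
        return st[idx] - st[idx - 1]

    ia, ib = _isi_at(a, t), _isi_at(b, t)
    ratio = np.where(ia <= ib, ia / ib, ib / ia)
    return float(np.mean(1.0 - ratio))


def mac(rate: NetworkRate, min_lag_s: float = MAC_MIN_LAG_S) -> float:
    """Maximum autocorrelation component of the network rate.

    Maximum of the mean-removed, variance-normalized autocorrelation over
    lags in [``min_lag_s``, duration/2]; 0 for a zero-variance rate and
    clamped to [0, 1].
    """
    x = rate.counts.astype(float)
    n = len(x)
    x = x - x.mean()
    var = np.dot(x, x) / n
    if var == 0 or n < 4:
        return 0.0
    lag0 = max(int(np.ceil(min_lag_s / rate.bin_s)), 1)
    lag1 = n // 2
    if lag0 > lag1:
        return 0.0
    full = np.correlate(x, x, mode="full")[n - 1 :]
    lags = np.arange(lag0, lag1 + 1)
    ac = full[lags] / (n - lags) / var
    return float(np.clip(ac.max(), 0.0, 1.0))


def binarized_cc(raster: SpikeRaster, bin_ms: float = BIN_MS) -> tuple[float, float]:
    """Mean and sd of pairwise Pearson correlations of binarized spike trains.

    Trains are binarized at 25 ms; zero-variance trains are excluded.  With
    fewer than one usable pair the convention is (0, 0).
    """
    n_bins = max(int(np.ceil(raster.duration * 1000.0 / bin_ms)), 1)
    edges = np.arange(n_bins + 1) * bin_ms / 1000.0
    trains = []
    for st in raster.spikes:
        c, _ = np.histogram(st, bins=edges)
        trains.append((c > 0).astype(float))
    usable = [tr for tr in trains if tr.std() > 0]
    ccs = []
    for i in range(len(usable)):
        for j in range(i + 1, len(usable)):
            ccs.append(np.corrcoef(usable[i], usable[j])[0, 1])
    if not ccs:
        return 0.0, 0.0
    return float(np.mean(ccs)), float(np.std(ccs))


@dataclass
class FeatureVector:
    """The MEA summary statistics (standard field abbreviations as names)."""

    MFR: float = 0.0          # Hz, mean firing rate per electrode
    NBR: float = 0.0          # network bursts per minute
    NBD: float = 0.0          # mean network-burst duration, s
    PSIB: float = 0.0         # % of spikes inside network bursts
    n_FBs: float = 0.0        # mean fragments per burst
    CV_IBI: float = 0.0       # CV of inter-burst (onset-to-onset) intervals
    mean_ISI_CC: float = 0.0
    sd_ISI_CC: float = 0.0
    ISI_dist: float = 0.0
    mean_ISI: float = 0.0     # s
    sd_ISI_temp: float = 0.0  # s
    sd_ISI_elec: float = 0.0  # s
    MAC: float = 0.0
    mean_binCC: float = 0.0
    sd_binCC: float = 0.0

    def to_array(self, include_binarized: bool = False) -> np.ndarray:
        names = FEATURE_NAMES_EXT if include_binarized else FEATURE_NAMES
        return np.array([getattr(self, n) for n in names], dtype=float)

    def to_dict(self, include_binarized: bool = True) -> dict[str, float]:
        names = FEATURE_NAMES_EXT if include_binarized else FEATURE_NAMES
        return {n: float(getattr(self, n)) for n in names}


def compute_features(raster: SpikeRaster, bin_ms: float = BIN_MS) -> FeatureVector:
    """Compute the full feature vector with degenerate-raster conventions.

    Burst-dependent features are 0 when no burst is detected; CV_IBI is 0
    with fewer than 3 bursts; ISI statistics cover only electrodes with at
    least two spikes and are 0 when no electrode qualifies.  All outputs are
    finite for any valid raster.
    """
    rate = network_rate(raster, bin_ms)
    bursts = detect_bursts(raster, rate)
    n_spikes = raster.n_spikes
    fv = FeatureVector()
    fv.MFR = n_spikes / raster.n_electrodes / raster.duration if raster.n_electrodes else 0.0
    fv.MAC = mac(rate)

    if bursts:
        fv.NBR = len(bursts) / raster.duration * 60.0
        fv.NBD = float(np.mean([b.duration for b in bursts]))
        fv.n_FBs = float(np.mean([b.n_fragments for b in bursts]))
        if n_spikes:
            inside = 0
            for st in raster.spikes:
                for b in bursts:
                    inside += int(np.sum((st >= b.start) & (st < b.stop)))
            fv.PSIB = 100.0 * inside / n_spikes
        if len(bursts) >= 3:
            ibi = np.diff([b.start for b in bursts])
            m = ibi.mean()
            fv.CV_IBI = float(ibi.std() / m) if m > 0 else 0.0

    series = isi_series(raster, bin_ms)
    if np.any(np.isfinite(series)):
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore", RuntimeWarning)  # all-NaN grid columns
            fv.mean_ISI = float(np.nanmean(series))
            pooled = np.nanmean(series, axis=0)  # average series across electrodes
            per_el = np.nanmean(series, axis=1)  # average across time per electrode
        if np.sum(np.isfinite(pooled)) > 1:
            fv.sd_ISI_temp = float(np.nanstd(pooled))
        ok = np.isfinite(per_el)
        if np.sum(ok) > 1:
            fv.sd_ISI_elec = float(np.std(per_el[ok]))
        ccs = []
        n_el = series.shape[0]
        for i in range(n_el):
            for j in range(i + 1, n_el):
                both = np.isfinite(series[i]) & np.isfinite(series[j])
                if both.sum() < 3:
                    continue
                si, sj = series[i, both], series[j, both]
                if si.std() == 0 or sj.std() == 0:
                    continue
                ccs.append(np.corrcoef(si, sj)[0, 1])
        if ccs:
            fv.mean_ISI_CC = float(np.mean(ccs))
            fv.sd_ISI_CC = float(np.std(ccs))
        dists = []
        trains = [st for st in raster.spikes if len(st) >= 2]
        for i in range(len(trains)):
            for j in range(i + 1, len(trains)):
                d = isi_distance(trains[i], trains[j], bin_ms)
                if np.isfinite(d):
                    dists.append(d)
        if dists:
            fv.ISI_dist = float(np.mean(dists))

    fv.mean_binCC, fv.sd_binCC = binarized_cc(raster, bin_ms)

    arr = fv.to_array(include_binarized=True)
    if not np.all(np.isfinite(arr)):  # belt and braces: conventions never leak NaN
        for name, v in zip(FEATURE_NAMES_EXT, arr):
            if not np.isfinite(v):
                log.warning("feature %s non-finite; imputing 0", name)
                setattr(fv, name, 0.0)
    return fv
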