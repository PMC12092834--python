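"""Deterministic fixtures: crafted rasters, toy simulators, reduced model.

Everything every stage of the pipeline needs for testing is generated here
programmatically: rasters with known burst structure for the feature tests,
synthetic extracellular traces for the detection tests, an analytically
tractable linear-Gaussian toy simulator for the inference tests, and a
reduced 5-parameter network model (50 neurons, 60 s) for full-loop recovery
experiments at desk scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .inference import TrainingSet, build_training_set
from .params import PARAM_NAMES, PRIOR_HIGH, PRIOR_LOW, FixedParams, FreeParams
from .raster import SpikeRaster
from .signalproc import RawTrace, synth_extracellular
from .simulate import SimulationError, SimulationResult, simulate_network

__all__ = [
    "FixtureSpec",
    "make_fixture",
    "crafted_raster",
    "toy_training_set",
    "toy_posterior_moments",
    "REDUCED_PARAM_NAMES",
    "reduced_prior_bounds",
    "reduced_to_full",
    "sample_reduced_prior",
    "simulate_reduced",
    "reduced_training_set",
]

log = logging.getLogger(__name__)


@dataclass
class FixtureSpec:
    kind: str                      # crafted-raster | synthetic-trace | toy-simulator | reduced-model
    seed: int = 0
    options: dict = field(default_factory=dict)


def make_fixture(spec: FixtureSpec):
    """Dispatch on ``spec.kind``; unknown kinds raise."""
    if spec.kind == "crafted-raster":
        return crafted_raster(seed=spec.seed, **spec.options)
    if spec.kind == "synthetic-trace":
        opts = dict(spec.options)
        raster = opts.pop("raster", None) or crafted_raster(seed=spec.seed)
        return synth_extracellular(raster, seed=spec.seed, **opts)
    if spec.kind == "toy-simulator":
        return toy_training_set(seed=spec.seed, **spec.options)
    if spec.kind == "reduced-model":
        return reduced_training_set(seed=spec.seed, **spec.options)
    raise ValueError(f"unknown fixture kind {spec.kind!r}")


def crafted_raster(
    n_bursts: int = 3,
    period_s: float = 10.0,
    burst_duration: float = 0.3,
    duration: float = 60.0,
    n_electrodes: int = 12,
    in_burst_rate: float = 100.0,
    background_rate: float = 0.5,
    participating: int | None = None,
    first_burst: float = 1.0,
    seed: int = 0,
) -> SpikeRaster:
    """Raster with ``n_bursts`` equally spaced synchronous network bursts.

    During a burst every participating electrode fires regularly at
    ``in_burst_rate`` Hz (tiny per-electrode phase offsets); between bursts
    each electrode emits homogeneous Poisson background spikes.  With
    ``participating`` < n_electrodes the remaining electrodes stay at
    background level during bursts.
    """
    rng = np.random.default_rng(seed)
    if participating is None:
        participating = n_electrodes
    spikes: list[np.ndarray] = []
    onsets = first_burst + period_s * np.arange(n_bursts)
    for e in range(n_electrodes):
        st = []
        if background_rate > 0:
            n_bg = rng.poisson(background_rate * duration)
            st.append(rng.uniform(0, duration, n_bg))
        if e < participating:
            for t0 in onsets:
                times = t0 + np.arange(0.0, burst_duration, 1.0 / in_burst_rate)
                times = times + e * 1e-4  # de-synchronize electrodes slightly
                st.append(times[times < duration])
        merged = np.sort(np.concatenate(st)) if st else np.empty(0)
        spikes.append(np.unique(merged))
    return SpikeRaster(spikes, duration)


# ---------------------------------------------------------------------------
# linear-Gaussian toy simulator: x = theta + eps, eps ~ N(0, sigma^2),
# theta ~ U([0,1]^d).  The posterior given x_o is the N(x_o, sigma^2)
# truncated to [0,1]^d, so every inference operation has an analytic oracle.

TOY_SIGMA = 0.1


def toy_training_set(
    n: int = 5000, d: int = 1, sigma: float = TOY_SIGMA, seed: int = 0
) -> TrainingSet:
    rng = np.random.default_rng(seed)
    theta = rng.uniform(0.0, 1.0, size=(n, d))
    x = theta + rng.normal(0.0, sigma, size=(n, d))
    names = tuple(f"theta_{i}" for i in range(d))
    fnames = tuple(f"x_{i}" for i in range(d))
    return TrainingSet(
        theta, x, names, fnames, np.zeros(d), np.ones(d), {"kind": "toy", "sigma": sigma}
    )


def toy_posterior_moments(x_o: float, sigma: float = TOY_SIGMA) -> tuple[float, float]:
    """Mean and sd of the analytic truncated-Gaussian posterior on [0, 1]."""
    from scipy.stats import truncnorm

    a, b = (0.0 - x_o) / sigma, (1.0 - x_o) / sigma
    rv = truncnorm(a, b, loc=x_o, scale=sigma)
    return float(rv.mean()), float(rv.std())


# ---------------------------------------------------------------------------
# reduced network model: 5 free parameters, the rest clamped at prior midpoints

REDUCED_PARAM_NAMES: tuple[str, ...] = ("noise_sd", "g_AMPA", "conn_p", "tau_D", "U_std")
_REDUCED_IDX = tuple(PARAM_NAMES.index(n) for n in REDUCED_PARAM_NAMES)


def reduced_prior_bounds() -> tuple[np.ndarray, np.ndarray]:
    idx = list(_REDUCED_IDX)
    return PRIOR_LOW[idx].copy(), PRIOR_HIGH[idx].copy()


def reduced_to_full(theta_sub: np.ndarray) -> FreeParams:
    """Embed a 5-vector into the full parameter space (others at midpoints)."""
    full = (PRIOR_LOW + PRIOR_HIGH) / 2.0
    for k, i in enumerate(_REDUCED_IDX):
        full[i] = theta_sub[k]
    return FreeParams.from_array(full)


def sample_reduced_prior(n: int, seed: int | np.random.Generator = 0) -> np.ndarray:
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lo, hi = reduced_prior_bounds()
    return rng.uniform(lo, hi, size=(n, len(lo)))


def simulate_reduced(
    theta_sub: np.ndarray,
    seed: int = 0,
    duration: float = 60.0,
    n_neurons: int = 50,
    dt: float = 0.1,
    fixed: FixedParams | None = None,
) -> SimulationResult:
    fixed = (fixed or FixedParams()).replace(dt=dt)
    return simulate_network(
        reduced_to_full(np.asarray(theta_sub, float)),
        fixed=fixed,
        duration=duration,
        seed=seed,
        n_neurons=n_neurons,
    )


def reduced_training_set(
    n: int = 2000,
    seed: int = 0,
    duration: float = 60.0,
    n_neurons: int = 50,
    dt: float = 0.1,
    progress: bool = False,
) -> TrainingSet:
    """Simulate ``n`` reduced-model draws and assemble the training set.

    Simulations that blow up numerically are dropped (logged); silent ones
    are retained with convention-imputed features.
    """
    rng = np.random.default_rng(seed)
    thetas = sample_reduced_prior(n, rng)
    seeds = rng.integers(0, 2**31 - 1, size=n)
    kept_theta, rasters = [], []
    for i in range(n):
        try:
            sim = simulate_reduced(
                thetas[i], seed=int(seeds[i]), duration=duration,
                n_neurons=n_neurons, dt=dt,
            )
        except SimulationError as exc:
            log.warning("reduced sim %d dropped: %s", i, exc)
            continue
        kept_theta.append(thetas[i])
        rasters.append(sim.raster)
        if progress and (i + 1) % 50 == 0:
            log.info("reduced training set: %d/%d simulations", i + 1, n)
    lo, hi = reduced_prior_bounds()
    return build_training_set(
        kept_theta, rasters, duration,
        param_names=REDUCED_PARAM_NAMES, prior_low=lo, prior_high=hi,
        provenance={"kind": "reduced-model", "n_neurons": n_neurons, "dt": dt,
                    "seed": seed, "n_requested": n},
    )
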