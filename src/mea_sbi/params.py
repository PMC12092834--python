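"""Model parameters: the 10 inferred biophysical parameters and the fixed constants.

The model describes a cultured network of ~100 excitatory Hodgkin-Huxley
neurons on a multi-electrode array.  Ten parameters are treated as free and
inferred (membrane-noise amplitude, Na/K/sAHP conductances, AMPA/NMDA
conductances, connection probability, and the three short-term-plasticity
parameters); everything else (geometry, capacitance, Nernst potentials, time
constants) is fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, fields
from typing import Iterator

import numpy as np

__all__ = [
    "FreeParams",
    "FixedParams",
    "PRIOR_LOW",
    "PRIOR_HIGH",
    "PARAM_NAMES",
    "prior_ranges",
    "sample_prior",
]

#: Order of the free parameters everywhere in the package (arrays, posteriors).
PARAM_NAMES: tuple[str, ...] = (
    "noise_sd",
    "g_K",
    "g_Na",
    "g_AHP",
    "g_AMPA",
    "g_NMDA",
    "conn_p",
    "tau_D",
    "U_std",
    "U_asyn",
)

# Uniform box prior.  g_K and g_Na bounds are stored as absolute conductance
# densities (mS/cm^2), i.e. the multiplier ranges times their base values.
PRIOR_LOW = np.array(
    [1.5, 0.5, 25.0, 0.5, 0.05, 0.0, 0.1, 150.0, 0.005, 0.0]
)
PRIOR_HIGH = np.array(
    [7.0, 50.0, 100.0, 10.0, 1.0, 1.0, 0.6, 1200.0, 0.3, 0.005]
)


def prior_ranges() -> dict[str, tuple[float, float]]:
    """Prior bounds per parameter, in the package's canonical order."""
    return {n: (float(lo), float(hi)) for n, lo, hi in zip(PARAM_NAMES, PRIOR_LOW, PRIOR_HIGH)}


@dataclass(frozen=True)
class FreeParams:
    """The 10 free (inferred) biophysical parameters.

    Units: noise_sd mV; g_K, g_Na mS/cm^2; g_AHP, g_AMPA, g_NMDA nS;
    conn_p dimensionless; tau_D ms; U_std, U_asyn dimensionless.
    """

    noise_sd: float = 3.0
    g_K: float = 5.0
    g_Na: float = 50.0
    g_AHP: float = 2.0
    g_AMPA: float = 0.3
    g_NMDA: float = 0.2
    conn_p: float = 0.3
    tau_D: float = 500.0
    U_std: float = 0.1
    U_asyn: float = 0.001

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v):
                raise ValueError(f"non-finite parameter {f.name}={v}")
        if self.noise_sd < 0 or self.tau_D <= 0:
            raise ValueError("noise_sd must be >= 0 and tau_D > 0")
        for name in ("g_K", "g_Na", "g_AHP", "g_AMPA", "g_NMDA", "U_std", "U_asyn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.conn_p <= 1.0:
            raise ValueError(f"conn_p={self.conn_p} outside [0, 1]")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, a) -> "FreeParams":
        a = np.asarray(a, dtype=float)
        if a.shape != (len(PARAM_NAMES),):
            raise ValueError(f"expected {len(PARAM_NAMES)} parameters, got shape {a.shape}")
        return cls(**dict(zip(PARAM_NAMES, a.tolist())))

    def to_dict(self) -> dict[str, float]:
        return asdict(self)

    def in_prior(self) -> bool:
        a = self.to_array()
        return bool(np.all(a >= PRIOR_LOW) and np.all(a <= PRIOR_HIGH))


@dataclass(frozen=True)
class FixedParams:
    """Fixed model constants (geometry, passive properties, kinetics).

    Units noted per field; tau_AHP is in seconds, synaptic time constants in ms.
    """

    area: float = 300.0            # um^2, neuron size
    C_m: float = 1.0               # uF/cm^2
    g_l: float = 0.3               # mS/cm^2
    E_K: float = -80.0             # mV
    E_Na: float = 70.0             # mV
    E_l: float = -39.2             # mV
    V_T: float = -30.4             # mV, spike-threshold shift of the HH rates
    alpha_Ca: float = 0.00035      # sAHP increment per spike
    tau_AHP: float = 6.0           # s
    E_AMPA: float = 0.0            # mV
    E_NMDA: float = 0.0            # mV
    alpha_NMDA: float = 0.5        # kHz, NMDA activation rate constant
    tau_AMPA: float = 2.0          # ms
    tau_NMDA_decay: float = 100.0  # ms
    tau_NMDA_rise: float = 2.0     # ms
    max_delay: float = 25.0        # ms, conduction delay at maximal grid distance
    sd_w: float = 0.7              # coefficient of variation of synaptic weights
    tau_asyn: float = 700.0        # ms, recovery of asynchronous release
    U_max: float = 0.5             # 1/ms, saturation of asynchronous release rate
    x_0: float = 5.0               # transmitter per vesicle (release gain)

    # Reimplementation choices not pinned by the published constants; exposed
    # in config so they can be overridden without touching code.
    noise_tau: float = 5.0         # ms, correlation time of the OU voltage noise
    input_mean: float = 9.0        # pA, mean heterogeneous constant input current
    input_sd: float = 3.0          # pA, spread of the input current
    mg_conc: float = 1.0           # mM, extracellular Mg for the NMDA block
    dt: float = 0.05               # ms, integration step
    v_spike: float = 0.0           # mV, threshold-crossing level for event extraction
    refractory: float = 2.0        # ms, dead time for event extraction

    def __post_init__(self) -> None:
        if not self.tau_NMDA_rise < self.tau_NMDA_decay:
            raise ValueError("tau_NMDA_rise must be < tau_NMDA_decay")

    def to_dict(self) -> dict[str, float]:
        return asdict(self)

    def replace(self, **kw) -> "FixedParams":
        d = self.to_dict()
        d.update(kw)
        return FixedParams(**d)


def sample_prior(n: int, seed: int | np.random.Generator = 0) -> list[FreeParams]:
    """Draw ``n`` independent parameter vectors from the uniform box prior.

    Parameters
    ----------
    n : number of draws (>= 0).
    seed : integer seed or an existing :class:`numpy.random.Generator`.
    """
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    theta = rng.uniform(PRIOR_LOW, PRIOR_HIGH, size=(n, len(PARAM_NAMES)))
    return [FreeParams.from_array(row) for row in theta]
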