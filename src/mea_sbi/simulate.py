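"""Network simulation driver: stochastic HH network -> per-electrode raster.

The model: 100 point neurons (fixed constants in
:class:`~mea_sbi.params.FixedParams`) with leak, transient Na, delayed
rectifier K, and a slow AHP current whose conductance increments at every
action potential and relaxes over seconds.  Excitatory synapses carry fast
AMPA and slow, Mg-blocked NMDA components; release is depressed by the
Tsodyks-Markram resource model and an activity-dependent asynchronous
release pathway.  Neurons live on a grid with distance-dependent conduction
delays, and 12 virtual electrodes pool the spikes of nearby neurons into
the raster that the feature extractor consumes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from . import simcore
from .params import FixedParams, FreeParams
from .raster import SpikeRaster
from .topology import N_ELECTRODES, NetworkTopology, build_topology

__all__ = [
    "SimulationError",
    "SimulationResult",
    "simulate_network",
    "synapse_step",
    "asynchronous_release_rate",
    "save_result_h5",
    "load_result_h5",
]

# mS/cm^2 -> nS for a cell of `area` um^2:  g * area * 1e-8 cm^2 * 1e6 nS/mS
def _density_to_nS(g_density: float, area_um2: float) -> float:
    return g_density * area_um2 * 1e-2


class SimulationError(RuntimeError):
    """Numerical failure of the network integration (voltage blow-up)."""


@dataclass
class SimulationResult:
    raster: SpikeRaster
    neuron_spikes: list[np.ndarray]  # per-neuron sorted spike times, s
    duration: float                  # s
    dt: float                        # ms
    seed: int
    params: FreeParams
    fixed: FixedParams
    topology: NetworkTopology | None = None

    @property
    def n_neurons(self) -> int:
        return len(self.neuron_spikes)


def synapse_step(x: float, dt_since_spike: float, tau_D: float, U_std: float):
    """One presynaptic event of the Tsodyks-Markram depression model.

    Resources recover towards 1 as dx/dt = (1 - x)/tau_D for
    ``dt_since_spike`` ms, then a spike releases the fraction ``U_std * x``
    and depletes x by the same amount.  Returns ``(released, x_after)``.
    """
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"resource fraction x={x} outside [0, 1]")
    if tau_D <= 0:
        raise ValueError("tau_D must be positive")
    x_rec = 1.0 - (1.0 - x) * np.exp(-dt_since_spike / tau_D)
    released = U_std * x_rec
    return released, x_rec * (1.0 - U_std)


def asynchronous_release_rate(
    spike_times_ms: np.ndarray,
    t_grid_ms: np.ndarray,
    U_asyn: float,
    tau_asyn: float = 700.0,
    U_max: float = 0.5,
) -> np.ndarray:
    """Asynchronous release rate (1/ms) along ``t_grid_ms``.

    A residual release variable jumps by ``U_asyn`` at each presynaptic
    spike, saturates at ``U_max``, and decays exponentially with
    ``tau_asyn``; the instantaneous event rate equals that residual.
    """
    if U_asyn < 0:
        raise ValueError("U_asyn must be >= 0")
    spike_times_ms = np.sort(np.asarray(spike_times_ms, dtype=float))
    rate = np.zeros_like(np.asarray(t_grid_ms, dtype=float))
    u = 0.0
    t_prev = -np.inf
    j = 0
    for i, t in enumerate(np.asarray(t_grid_ms, dtype=float)):
        while j < len(spike_times_ms) and spike_times_ms[j] <= t:
            ts = spike_times_ms[j]
            if np.isfinite(t_prev):
                u *= np.exp(-(ts - t_prev) / tau_asyn)
            u = min(u + U_asyn, U_max)
            t_prev = ts
            j += 1
        rate[i] = u * np.exp(-(t - t_prev) / tau_asyn) if np.isfinite(t_prev) else 0.0
    return rate


def _csr(topology: NetworkTopology, dt: float):
    order = np.argsort(topology.pre, kind="mergesort")
    pre = topology.pre[order]
    n = topology.n_neurons
    out_start = np.zeros(n + 1, dtype=np.int64)
    np.add.at(out_start, pre + 1, 1)
    out_start = np.cumsum(out_start)
    dstep = np.maximum(np.round(topology.delays[order] / dt).astype(np.int64), 1)
    return (
        out_start,
        topology.post[order].astype(np.int64),
        topology.weights[order].astype(np.float64),
        dstep,
    )


def simulate_network(
    params: FreeParams,
    fixed: FixedParams | None = None,
    duration: float = 180.0,
    seed: int = 0,
    n_neurons: int = 100,
    topology: NetworkTopology | None = None,
    keep_topology: bool = False,
) -> SimulationResult:
    """Simulate the network for ``duration`` seconds.

    Randomness is split into named substreams derived from ``seed``
    (topology & heterogeneous input, initial conditions, dynamics noise +
    asynchronous events) so topology can be held fixed while the dynamics
    vary.  Passing an explicit ``topology`` bypasses the first substream.
    """
    if fixed is None:
        fixed = FixedParams()
    if duration <= 0:
        raise ValueError("duration must be positive")
    if not np.all(np.isfinite(params.to_array())):
        raise ValueError("non-finite parameter")
    dt = fixed.dt

    ss = np.random.SeedSequence(seed)
    topo_seed, init_seed, dyn_seed = ss.spawn(3)
    if topology is None:
        topology = build_topology(
            params, fixed, n_neurons=n_neurons, seed=np.random.default_rng(topo_seed)
        )
    N = topology.n_neurons

    tabs = simcore.build_gating_tables(fixed.V_T, dt, fixed.mg_conc)

    irng = np.random.default_rng(init_seed)
    V = irng.normal(fixed.E_l, 2.0, size=N)
    vidx = np.clip(
        ((V - simcore.V_MIN) / simcore.V_STEP).astype(int), 0, len(tabs["m_inf"]) - 1
    )
    m = tabs["m_inf"][vidx].copy()
    h = tabs["h_inf"][vidx].copy()
    n_g = tabs["n_inf"][vidx].copy()
    c = np.zeros(N)
    gA = np.zeros(N)
    xr = np.zeros(N)
    sN = np.zeros(N)
    eta = irng.normal(0.0, params.noise_sd, size=N)
    xstd = np.ones(N)
    ua = np.zeros(N)

    out_start, out_tgt, out_w, out_dstep = _csr(topology, dt)

    nsteps = int(round(duration * 1000.0 / dt))
    refr_steps = max(int(round(fixed.refractory / dt)), 1)
    cap = int(N * nsteps // refr_steps) + N

    spike_neuron = np.empty(cap, dtype=np.int64)
    spike_step = np.empty(cap, dtype=np.int64)

    noise_a = np.exp(-dt / fixed.noise_tau)
    noise_b = params.noise_sd * np.sqrt(1.0 - noise_a**2)

    n_spk, status = simcore.run_network(
        int(dyn_seed.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF),
        nsteps,
        dt,
        V, m, h, n_g, c, gA, xr, sN, eta, xstd, ua,
        topology.input_current.astype(np.float64),
        out_start, out_tgt, out_w, out_dstep,
        _density_to_nS(fixed.g_l, fixed.area),
        _density_to_nS(params.g_Na, fixed.area),
        _density_to_nS(params.g_K, fixed.area),
        params.g_AHP, params.g_AMPA, params.g_NMDA,
        fixed.E_l, fixed.E_Na, fixed.E_K, fixed.E_AMPA, fixed.E_NMDA,
        fixed.C_m * fixed.area * 1e-2,  # uF/cm^2 * um^2 -> pF
        params.U_std, params.U_asyn, fixed.U_max, fixed.x_0, fixed.alpha_Ca,
        np.exp(-dt / (fixed.tau_AHP * 1000.0)),
        np.exp(-dt / fixed.tau_AMPA),
        np.exp(-dt / fixed.tau_NMDA_rise),
        fixed.tau_NMDA_decay,
        fixed.alpha_NMDA,
        np.exp(-dt / params.tau_D),
        np.exp(-dt / fixed.tau_asyn),
        noise_a, noise_b,
        tabs["m_inf"], tabs["m_mul"], tabs["h_inf"], tabs["h_mul"],
        tabs["n_inf"], tabs["n_mul"], tabs["mg_block"],
        fixed.v_spike, refr_steps,
        spike_neuron, spike_step,
    )
    if status >= 0:
        raise SimulationError(
            f"voltage blow-up at step {status} (t={status * dt:.2f} ms); "
            "check parameters / dt"
        )

    t_spk = spike_step[:n_spk] * dt / 1000.0
    who = spike_neuron[:n_spk]
    neuron_spikes = [np.sort(t_spk[who == i]) for i in range(N)]
    emap = topology.electrode_map
    spikes = [
        np.sort(t_spk[np.isin(who, np.nonzero(emap == e)[0])])
        for e in range(N_ELECTRODES)
    ]
    raster = SpikeRaster(spikes, duration)
    return SimulationResult(
        raster=raster,
        neuron_spikes=neuron_spikes,
        duration=duration,
        dt=dt,
        seed=seed,
        params=params,
        fixed=fixed,
        topology=topology if keep_topology else None,
    )


def save_result_h5(result: SimulationResult, path) -> None:
    """HDF5 container: per-neuron spikes, raster, parameters, provenance."""
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["duration_s"] = result.duration
        f.attrs["dt_ms"] = result.dt
        f.attrs["seed"] = result.seed
        f.attrs["params_json"] = json.dumps(result.params.to_dict())
        f.attrs["fixed_json"] = json.dumps(result.fixed.to_dict())
        g = f.create_group("neurons")
        for i, st in enumerate(result.neuron_spikes):
            g.create_dataset(str(i), data=st)
        r = f.create_group("electrodes")
        for e, st in enumerate(result.raster.spikes):
            r.create_dataset(str(e), data=st)


def load_result_h5(path) -> SimulationResult:
    import h5py

    with h5py.File(path, "r") as f:
        duration = float(f.attrs["duration_s"])
        neuron_spikes = [
            f["neurons"][k][()] for k in sorted(f["neurons"], key=int)
        ]
        spikes = [f["electrodes"][k][()] for k in sorted(f["electrodes"], key=int)]
        return SimulationResult(
            raster=SpikeRaster(spikes, duration),
            neuron_spikes=neuron_spikes,
            duration=duration,
            dt=float(f.attrs["dt_ms"]),
            seed=int(f.attrs["seed"]),
            params=FreeParams(**json.loads(f.attrs["params_json"])),
            fixed=FixedParams(**json.loads(f.attrs["fixed_json"])),
        )
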