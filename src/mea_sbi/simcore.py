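"""Numba kernel for the Hodgkin-Huxley network integrator.

The heavy loop lives here: per-neuron membrane/gating updates via
Rush-Larsen exponential integration with voltage-indexed lookup tables,
an Ornstein-Uhlenbeck voltage noise term (Euler-Maruyama), ring-buffered
delayed synaptic delivery, presynaptic short-term depression, and
asynchronous release drawn as a per-synapse Poisson process.

All randomness inside the kernel goes through numba's global NumPy-compatible
RNG seeded once at kernel entry, so a run is bit-reproducible for fixed
(parameters, seed, dt, duration) on a single thread.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# voltage grid for the gating-rate lookup tables
V_MIN = -150.0
V_MAX = 100.0
V_STEP = 0.02


def build_gating_tables(V_T: float, dt: float, mg_conc: float):
    """Tabulate steady states, Rush-Larsen decay factors, and the Mg block.

    The rate functions are the Traub-Miles-style modified HH kinetics in
    which every alpha/beta depends on V - V_T (m^3 h sodium, n^4 potassium);
    V_T shifts the effective spike threshold.
    """
    v = np.arange(V_MIN, V_MAX + V_STEP, V_STEP)
    x = v - V_T

    def _ratio(num, den_arg, scale):
        # num / (exp(den_arg/scale) - 1) with the analytic limit at 0
        out = np.empty_like(den_arg)
        small = np.abs(den_arg) < 1e-9
        with np.errstate(over="ignore"):
            out[~small] = num[~small] / np.expm1(den_arg[~small] / scale)
        out[small] = scale  # lim_{y->0} y / (exp(y/s) - 1) * (num=y) -> s
        return out

    a_m = 0.32 * _ratio(13.0 - x, 13.0 - x, 4.0)
    b_m = 0.28 * _ratio(x - 40.0, x - 40.0, 5.0)
    a_h = 0.128 * np.exp(np.clip((17.0 - x) / 18.0, -50, 50))
    b_h = 4.0 / (1.0 + np.exp(np.clip((40.0 - x) / 5.0, -50, 50)))
    a_n = 0.032 * _ratio(15.0 - x, 15.0 - x, 5.0)
    b_n = 0.5 * np.exp(np.clip((10.0 - x) / 40.0, -50, 50))

    tabs = {}
    for name, a, b in (("m", a_m, b_m), ("h", a_h, b_h), ("n", a_n, b_n)):
        tau = 1.0 / (a + b)
        tabs[name + "_inf"] = (a * tau).astype(np.float64)
        tabs[name + "_mul"] = np.exp(-dt / tau).astype(np.float64)
    # Jahr-Stevens sigmoidal magnesium block of the NMDA conductance
    tabs["mg_block"] = (1.0 / (1.0 + mg_conc / 3.57 * np.exp(-0.062 * v))).astype(np.float64)
    return tabs


@njit(cache=True)
def run_network(
    seed,
    nsteps,
    dt,
    # state (modified in place), one entry per neuron
    V, m, h, n, c, gA, xr, sN, eta, xstd, ua,
    # per-neuron constants
    I_ext,
    # CSR connectivity: out_start[N+1], targets/weights/delay-steps per edge
    out_start, out_tgt, out_w, out_dstep,
    # conductances and reversal potentials (absolute, nS / mV)
    G_l, G_Na, G_K, g_AHP, g_AMPA, g_NMDA,
    E_l, E_Na, E_K, E_AMPA, E_NMDA,
    C_mem,
    # plasticity / release parameters
    U_std, U_asyn, U_max, x_0, alpha_Ca,
    # precomputed per-step decay factors
    a_AHP, a_AMPA, a_rise, tau_NMDA_decay, alpha_NMDA, a_D, a_UA,
    noise_a, noise_b,
    # lookup tables
    m_inf, m_mul, h_inf, h_mul, n_inf, n_mul, mg_block,
    v_spike, refr_steps,
    # outputs
    spike_neuron, spike_step,
):
    """Integrate the network for ``nsteps``; returns (n_spikes, status_step).

    status_step is -1 on success, else the step index where |V| blew up.
    """
    np.random.seed(seed)
    N = V.shape[0]
    L = 0
    for e in range(out_dstep.shape[0]):
        if out_dstep[e] + 1 > L:
            L = out_dstep[e] + 1
    if L < 1:
        L = 1
    bufA = np.zeros((L, N))
    bufN = np.zeros((L, N))
    above = np.zeros(N, dtype=np.bool_)
    last_spike = np.full(N, -10 * refr_steps, dtype=np.int64)
    n_spk = 0
    cap = spike_neuron.shape[0]

    inv_dv = 1.0 / V_STEP
    ntab = m_inf.shape[0]

    for k in range(nsteps):
        slot = k % L
        for i in range(N):
            # deliver ring-buffered synaptic events scheduled for this step
            gA[i] += bufA[slot, i]
            xr[i] += bufN[slot, i]
            bufA[slot, i] = 0.0
            bufN[slot, i] = 0.0

            Vi = V[i]
            idx = int((Vi - V_MIN) * inv_dv)
            if idx < 0:
                idx = 0
            elif idx >= ntab:
                idx = ntab - 1

            m[i] = m_inf[idx] + (m[i] - m_inf[idx]) * m_mul[idx]
            h[i] = h_inf[idx] + (h[i] - h_inf[idx]) * h_mul[idx]
            n[i] = n_inf[idx] + (n[i] - n_inf[idx]) * n_mul[idx]
            c[i] *= a_AHP
            gA[i] *= a_AMPA
            xr[i] *= a_rise
            sN[i] += dt * (alpha_NMDA * xr[i] * (1.0 - sN[i]) - sN[i] / tau_NMDA_decay)

            # exponential-Euler membrane update: conductances frozen over the
            # step, so V relaxes towards V_inf with rate g_tot/C -- stable for
            # any dt despite the stiff Na conductance during the spike
            gNa_eff = G_Na * m[i] * m[i] * m[i] * h[i]
            n2 = n[i] * n[i]
            gK_eff = G_K * n2 * n2
            g_ahp_eff = g_AHP * c[i]
            gN_eff = g_NMDA * sN[i] * mg_block[idx]
            g_tot = G_l + gNa_eff + gK_eff + g_ahp_eff + gA[i] + gN_eff
            num = (
                G_l * E_l
                + gNa_eff * E_Na
                + (gK_eff + g_ahp_eff) * E_K
                + gA[i] * E_AMPA
                + gN_eff * E_NMDA
                + I_ext[i]
            )
            V_inf = num / g_tot
            e_old = eta[i]
            eta[i] = eta[i] * noise_a + noise_b * np.random.normal()
            Vi = V_inf + (Vi - V_inf) * np.exp(-dt * g_tot / C_mem) + (eta[i] - e_old)
            V[i] = Vi
            if Vi > 200.0 or Vi < -200.0 or not np.isfinite(Vi):
                return n_spk, k

            is_above = Vi >= v_spike
            if is_above and not above[i] and (k - last_spike[i]) >= refr_steps:
                # action potential: record, increment sAHP, trigger release
                last_spike[i] = k
                if n_spk < cap:
                    spike_neuron[n_spk] = i
                    spike_step[n_spk] = k
                    n_spk += 1
                c[i] += alpha_Ca
                rel = U_std * xstd[i]
                xstd[i] *= 1.0 - U_std
                ua[i] = min(ua[i] + U_asyn, U_max)
                amt = x_0 * rel
                for e in range(out_start[i], out_start[i + 1]):
                    s2 = (k + out_dstep[e]) % L
                    tgt = out_tgt[e]
                    bufA[s2, tgt] += g_AMPA * out_w[e] * amt
                    bufN[s2, tgt] += out_w[e] * amt
            above[i] = is_above

        # short-term depression recovery and asynchronous release
        for i in range(N):
            xstd[i] = 1.0 - (1.0 - xstd[i]) * a_D
            ua[i] *= a_UA
            K = out_start[i + 1] - out_start[i]
            if K > 0 and ua[i] > 0.0:
                lam = K * ua[i] * dt
                nev = np.random.poisson(lam)
                for _ in range(nev):
                    e = out_start[i] + int(np.random.random() * K)
                    if e >= out_start[i + 1]:
                        e = out_start[i + 1] - 1
                    # one vesicle: a spike-triggered release scaled down by x_0
                    rel_a = U_std * xstd[i] / x_0
                    xstd[i] *= 1.0 - U_std / x_0
                    amt = x_0 * rel_a
                    s2 = (k + out_dstep[e]) % L
                    tgt = out_tgt[e]
                    bufA[s2, tgt] += g_AMPA * out_w[e] * amt
                    bufN[s2, tgt] += out_w[e] * amt

    return n_spk, -1
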