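"""Network topology: grid placement, random connectivity, delays, electrodes.

Neurons sit on a square grid (default 10x10 for 100 neurons).  Each ordered
pair of distinct neurons is connected independently with probability
``conn_p``.  Conduction delays grow linearly with Euclidean grid distance and
are scaled so that the largest possible distance maps onto ``max_delay``.
Twelve virtual electrodes form a 4x3 interior grid (the layout of a 12-site
MEA well); each neuron reports to its nearest electrode.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import FixedParams, FreeParams

__all__ = ["NetworkTopology", "build_topology"]

N_ELECTRODES = 12


@dataclass
class NetworkTopology:
    positions: np.ndarray      # (N, 2) grid coordinates
    pre: np.ndarray            # (E,) presynaptic neuron per connection
    post: np.ndarray           # (E,) postsynaptic neuron per connection
    weights: np.ndarray        # (E,) multiplicative weight, mean 1, positive
    delays: np.ndarray         # (E,) conduction delay in ms, in (0, max_delay]
    electrode_map: np.ndarray  # (N,) electrode index in [0, 12)
    input_current: np.ndarray  # (N,) constant external drive, pA

    @property
    def n_neurons(self) -> int:
        return len(self.positions)

    @property
    def n_connections(self) -> int:
        return len(self.pre)


def _grid_positions(n: int) -> np.ndarray:
    side = int(np.ceil(np.sqrt(n)))
    xs, ys = np.meshgrid(np.arange(side), np.arange(side), indexing="ij")
    pos = np.column_stack([xs.ravel(), ys.ravel()]).astype(float)
    return pos[:n]


def _electrode_positions(pos: np.ndarray) -> np.ndarray:
    """12 electrodes on a 4x3 grid spanning the interior of the culture area."""
    x0, x1 = pos[:, 0].min(), pos[:, 0].max()
    y0, y1 = pos[:, 1].min(), pos[:, 1].max()
    # keep electrodes away from the rim, as on a physical well
    ex = np.linspace(x0 + 0.15 * (x1 - x0), x1 - 0.15 * (x1 - x0), 4)
    ey = np.linspace(y0 + 0.15 * (y1 - y0), y1 - 0.15 * (y1 - y0), 3)
    gx, gy = np.meshgrid(ex, ey, indexing="ij")
    return np.column_stack([gx.ravel(), gy.ravel()])


def build_topology(
    params: FreeParams,
    fixed: FixedParams | None = None,
    n_neurons: int = 100,
    seed: int | np.random.Generator = 0,
) -> NetworkTopology:
    """Sample a random directed network for one simulation.

    Weights are lognormal with mean 1 and coefficient of variation ``sd_w``
    (lognormality keeps them positive).  The per-neuron constant input current
    that makes neurons heterogeneously excitable is drawn here as well, so a
    fixed topology seed pins both connectivity and excitability.
    """
    if fixed is None:
        fixed = FixedParams()
    if n_neurons < 2:
        raise ValueError("n_neurons must be >= 2")
    p = params.conn_p
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"conn_p={p} outside [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    pos = _grid_positions(n_neurons)
    mask = rng.random((n_neurons, n_neurons)) < p
    np.fill_diagonal(mask, False)
    pre, post = np.nonzero(mask)

    # lognormal(mu, s) with mean 1 and CV = sd_w:  s^2 = ln(1 + CV^2), mu = -s^2/2
    s2 = np.log1p(fixed.sd_w**2)
    weights = rng.lognormal(mean=-s2 / 2.0, sigma=np.sqrt(s2), size=len(pre))

    dvec = pos[pre] - pos[post]
    dist = np.hypot(dvec[:, 0], dvec[:, 1])
    span = pos.max(axis=0) - pos.min(axis=0)
    max_dist = float(np.hypot(span[0], span[1]))
    delays = fixed.max_delay * dist / max_dist if max_dist > 0 else np.full(len(pre), fixed.dt)
    delays = np.maximum(delays, fixed.dt)  # delivery strictly after emission

    epos = _electrode_positions(pos)
    d2 = ((pos[:, None, :] - epos[None, :, :]) ** 2).sum(axis=2)
    electrode_map = np.argmin(d2, axis=1).astype(np.int64)

    input_current = rng.normal(fixed.input_mean, fixed.input_sd, size=n_neurons)

    return NetworkTopology(
        positions=pos,
        pre=pre.astype(np.int64),
        post=post.astype(np.int64),
        weights=weights,
        delays=delays,
        electrode_map=electrode_map,
        input_current=input_current,
    )
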