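"""Amortized posterior estimation over the model parameters.

Workflow: sample the box prior, simulate, reduce each simulation to the MEA
feature vector, fit the conditional density estimator on the standardized
(theta, x) pairs, then condition on the features of any new observation to
obtain its posterior in seconds.  The posterior-analysis toolkit (mode,
conditionals, conditional correlations, sensitivity, posterior-predictive
checks, parameter-recovery error) operates on the conditioned handle.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.stats import gaussian_kde, pearsonr, ttest_1samp

from .features import FEATURE_NAMES, FeatureVector, compute_features
from .nde import ConditionalGaussianMixture, GaussianMixturePosterior
from .params import PARAM_NAMES, PRIOR_HIGH, PRIOR_LOW, FreeParams
from .raster import SpikeRaster

__all__ = [
    "TrainingSet",
    "PosteriorModel",
    "Posterior",
    "ConditionalDensity",
    "ConditionalCorrMatrix",
    "build_training_set",
    "train_nde",
    "posterior_for",
    "posterior_mode",
    "conditional_posterior",
    "conditional_corr_matrix",
    "sensitivity_scores",
    "feature_sensitivity",
    "ppc_check",
    "parameter_recovery_error",
]

log = logging.getLogger(__name__)


@dataclass
class TrainingSet:
    """Aligned (theta, features) matrices plus the feature standardizer."""

    theta: np.ndarray                 # (n, d_theta)
    x: np.ndarray                     # (n, d_x)
    param_names: tuple[str, ...]
    feature_names: tuple[str, ...]
    prior_low: np.ndarray
    prior_high: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        if self.theta.shape[0] != self.x.shape[0]:
            raise ValueError("theta and x row counts differ")
        if not np.all(np.isfinite(self.theta)) or not np.all(np.isfinite(self.x)):
            raise ValueError("training set contains non-finite entries")

    @property
    def n(self) -> int:
        return self.theta.shape[0]


def build_training_set(
    params,
    sims,
    duration: float | None = None,
    param_names: tuple[str, ...] = PARAM_NAMES,
    prior_low: np.ndarray = PRIOR_LOW,
    prior_high: np.ndarray = PRIOR_HIGH,
    feature_names: tuple[str, ...] = FEATURE_NAMES,
    provenance: dict | None = None,
) -> TrainingSet:
    """Assemble the (theta, x) matrices from parameters and simulations.

    ``sims`` may be rasters (features computed here, through the same path
    used for measured data), FeatureVector instances, or a ready (n, d_x)
    array.  Silent simulations are retained with their convention-imputed
    burst features rather than dropped, so the prior predictive stays intact.
    """
    theta = np.array(
        [p.to_array() if isinstance(p, FreeParams) else np.asarray(p, float) for p in params]
    )
    if isinstance(sims, np.ndarray):
        x = np.asarray(sims, dtype=float)
    else:
        rows = []
        for s in sims:
            if isinstance(s, SpikeRaster):
                fv = compute_features(s)
                rows.append([getattr(fv, n) for n in feature_names])
            elif isinstance(s, FeatureVector):
                rows.append([getattr(s, n) for n in feature_names])
            else:
                rows.append(np.asarray(s, dtype=float))
        x = np.array(rows, dtype=float)
    if theta.shape[0] != x.shape[0]:
        raise ValueError(
            f"{theta.shape[0]} parameter rows but {x.shape[0]} simulations"
        )
    prov = dict(provenance or {})
    if duration is not None:
        prov["duration_s"] = duration
    return TrainingSet(
        theta, x, tuple(param_names), tuple(feature_names),
        np.asarray(prior_low, float), np.asarray(prior_high, float), prov,
    )


@dataclass
class PosteriorModel:
    """Trained amortized posterior: estimator + prior box + standardizer."""

    cde: ConditionalGaussianMixture
    param_names: tuple[str, ...]
    feature_names: tuple[str, ...]
    prior_low: np.ndarray
    prior_high: np.ndarray
    x_mean: np.ndarray
    x_sd: np.ndarray
    theta_mean: np.ndarray
    theta_sd: np.ndarray
    metadata: dict = field(default_factory=dict)

    @property
    def d_theta(self) -> int:
        return len(self.param_names)


def train_nde(
    ts: TrainingSet,
    seed: int = 0,
    n_components: int | str = "bic",
    max_components: int = 12,
    min_n: int = 500,
    metadata: dict | None = None,
) -> PosteriorModel:
    """Fit the conditional density estimator on a training set.

    Both blocks are z-scored by training-set mean/sd before the fit (the
    same convention used when features are displayed in prior-sd units).
    A constant feature column cannot be standardized and raises with the
    offending column's name.
    """
    if ts.n < min_n:
        raise ValueError(f"training set has {ts.n} rows; minimum is {min_n}")
    x_sd = ts.x.std(axis=0)
    for j, s in enumerate(x_sd):
        if s == 0:
            raise ValueError(
                f"feature column '{ts.feature_names[j]}' is constant over the "
                "training set; the estimator cannot standardize it"
            )
    th_sd = ts.theta.std(axis=0)
    th_sd = np.where(th_sd == 0, 1.0, th_sd)
    x_mean, th_mean = ts.x.mean(axis=0), ts.theta.mean(axis=0)
    z_theta = (ts.theta - th_mean) / th_sd
    z_x = (ts.x - x_mean) / x_sd
    cde = ConditionalGaussianMixture(
        n_components=n_components, max_components=max_components, seed=seed
    ).fit(z_theta, z_x)
    log.info(
        "trained conditional density estimator: n=%d, components=%d",
        ts.n, cde.n_components_,
    )
    md = dict(metadata or {})
    md.setdefault("n_train", ts.n)
    md.update(ts.provenance)
    return PosteriorModel(
        cde, ts.param_names, ts.feature_names,
        ts.prior_low.copy(), ts.prior_high.copy(),
        x_mean, x_sd, th_mean, th_sd, md,
    )


MODEL_FORMAT_VERSION = 1


def save_model(model: PosteriorModel, path) -> None:
    """Serialize a trained model (mixture parameters + standardizer) to .npz."""
    import json

    np.savez(
        path,
        format_version=MODEL_FORMAT_VERSION,
        weights=model.cde.weights_,
        means=model.cde.means_,
        covs=model.cde.covs_,
        d_theta=model.cde.d_theta,
        param_names=np.array(model.param_names),
        feature_names=np.array(model.feature_names),
        prior_low=model.prior_low,
        prior_high=model.prior_high,
        x_mean=model.x_mean,
        x_sd=model.x_sd,
        theta_mean=model.theta_mean,
        theta_sd=model.theta_sd,
        metadata=json.dumps(model.metadata, default=str),
    )


def load_model(path) -> PosteriorModel:
    import json

    with np.load(path, allow_pickle=False) as f:
        if int(f["format_version"]) != MODEL_FORMAT_VERSION:
            raise ValueError(f"unsupported model format {int(f['format_version'])}")
        cde = ConditionalGaussianMixture.__new__(ConditionalGaussianMixture)
        cde.weights_ = f["weights"]
        cde.means_ = f["means"]
        cde.covs_ = f["covs"]
        cde.d_theta = int(f["d_theta"])
        return PosteriorModel(
            cde,
            tuple(str(s) for s in f["param_names"]),
            tuple(str(s) for s in f["feature_names"]),
            f["prior_low"], f["prior_high"],
            f["x_mean"], f["x_sd"], f["theta_mean"], f["theta_sd"],
            json.loads(str(f["metadata"])),
        )


class Posterior:
    """Posterior over parameters conditioned on one observation's features.

    Supports ``sample(n, seed)`` and ``log_prob(theta)`` in natural parameter
    units; samples are truncated to the prior box by rejection.
    """

    def __init__(self, model: PosteriorModel, x_obs: np.ndarray, observation_id=None):
        self.model = model
        self.x_obs = np.asarray(x_obs, dtype=float).ravel()
        self.observation_id = observation_id
        z = (self.x_obs - model.x_mean) / model.x_sd
        if np.any(np.abs(z) > 10):
            bad = [model.feature_names[j] for j in np.nonzero(np.abs(z) > 10)[0]]
            warnings.warn(
                f"observation features {bad} lie >10 training sd from the "
                "training mean; the observation may be misspecified for the model",
                stacklevel=2,
            )
        self._mix: GaussianMixturePosterior = model.cde.condition(z)

    @property
    def param_names(self):
        return self.model.param_names

    def _to_z(self, theta: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(theta) - self.model.theta_mean) / self.model.theta_sd

    def log_prob(self, theta) -> np.ndarray:
        """Log posterior density (natural units); -inf outside the prior box."""
        theta = np.atleast_2d(np.asarray(theta, dtype=float))
        lp = self._mix.log_prob(self._to_z(theta)) - np.sum(np.log(self.model.theta_sd))
        inside = np.all(
            (theta >= self.model.prior_low) & (theta <= self.model.prior_high), axis=1
        )
        return np.where(inside, lp, -np.inf)

    def grad_log_prob(self, theta) -> np.ndarray:
        g = self._mix.grad_log_prob(self._to_z(theta))
        return g / self.model.theta_sd

    def sample(self, n: int, seed: int | np.random.Generator = 0) -> np.ndarray:
        """Draw ``n`` samples inside the prior box (rejection, then clip)."""
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        lo, hi = self.model.prior_low, self.model.prior_high
        out = np.empty((n, self.model.d_theta))
        got = 0
        for _ in range(200):
            need = n - got
            z = self._mix.sample(max(need * 2, 16), rng)
            th = z * self.model.theta_sd + self.model.theta_mean
            ok = np.all((th >= lo) & (th <= hi), axis=1)
            th = th[ok][:need]
            out[got : got + len(th)] = th
            got += len(th)
            if got == n:
                break
        if got < n:  # pathological mass outside the box: fill with clipped draws
            z = self._mix.sample(n - got, rng)
            th = np.clip(z * self.model.theta_sd + self.model.theta_mean, lo, hi)
            out[got:] = th
        return out


def posterior_for(observation, model: PosteriorModel, observation_id=None) -> Posterior:
    """Condition the trained model on one observation's features."""
    if isinstance(observation, FeatureVector):
        x = np.array([getattr(observation, n) for n in model.feature_names])
    elif isinstance(observation, SpikeRaster):
        fv = compute_features(observation)
        x = np.array([getattr(fv, n) for n in model.feature_names])
    else:
        x = np.asarray(observation, dtype=float).ravel()
    if not np.all(np.isfinite(x)):
        raise ValueError("observation features must be finite")
    return Posterior(model, x, observation_id)


def posterior_mode(
    handle: Posterior, n_starts: int = 10_000, seed: int = 0, refine: bool = True
) -> np.ndarray:
    """Joint posterior mode: best of ``n_starts`` samples, then L-BFGS-B."""
    rng = np.random.default_rng(seed)
    cand = handle.sample(n_starts, rng)
    lp = handle.log_prob(cand)
    best = cand[int(np.argmax(lp))]
    if refine:
        lo, hi = handle.model.prior_low, handle.model.prior_high

        def neg(th):
            v = handle.log_prob(th[None, :])[0]
            return -v if np.isfinite(v) else 1e30

        res = optimize.minimize(
            neg, best, method="L-BFGS-B", bounds=list(zip(lo, hi))
        )
        if res.success and -res.fun >= handle.log_prob(best[None, :])[0]:
            best = np.clip(res.x, lo, hi)
    return best


@dataclass
class ConditionalDensity:
    """Normalized conditional posterior on a 1-D or 2-D grid."""

    free: tuple[int, ...]
    grids: tuple[np.ndarray, ...]    # axis grids over the prior range
    density: np.ndarray              # normalized (integrates to 1 on the grid)
    fixed_values: np.ndarray

    def mean(self) -> np.ndarray:
        cell = np.prod([g[1] - g[0] for g in self.grids])
        if self.density.ndim == 1:
            return np.array([np.sum(self.grids[0] * self.density) * cell])
        px = self.density.sum(axis=1) * (self.grids[1][1] - self.grids[1][0])
        py = self.density.sum(axis=0) * (self.grids[0][1] - self.grids[0][0])
        dx0 = self.grids[0][1] - self.grids[0][0]
        dy0 = self.grids[1][1] - self.grids[1][0]
        return np.array(
            [np.sum(self.grids[0] * px) * dx0, np.sum(self.grids[1] * py) * dy0]
        )

    def sd(self) -> np.ndarray:
        mu = self.mean()
        if self.density.ndim == 1:
            dx0 = self.grids[0][1] - self.grids[0][0]
            var = np.sum((self.grids[0] - mu[0]) ** 2 * self.density) * dx0
            return np.array([np.sqrt(max(var, 0.0))])
        dx0 = self.grids[0][1] - self.grids[0][0]
        dy0 = self.grids[1][1] - self.grids[1][0]
        px = self.density.sum(axis=1) * dy0
        py = self.density.sum(axis=0) * dx0
        vx = np.sum((self.grids[0] - mu[0]) ** 2 * px) * dx0
        vy = np.sum((self.grids[1] - mu[1]) ** 2 * py) * dy0
        return np.sqrt(np.maximum([vx, vy], 0.0))

    def sample(self, n: int, seed: int | np.random.Generator = 0) -> np.ndarray:
        """Inverse-CDF (1-D) / categorical-cell (2-D) sampling with jitter."""
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        p = self.density.ravel()
        p = p / p.sum()
        idx = rng.choice(len(p), size=n, p=p)
        if self.density.ndim == 1:
            dx0 = self.grids[0][1] - self.grids[0][0]
            return (self.grids[0][idx] + rng.uniform(-dx0 / 2, dx0 / 2, n))[:, None]
        ncol = self.density.shape[1]
        i, j = idx // ncol, idx % ncol
        dx0 = self.grids[0][1] - self.grids[0][0]
        dy0 = self.grids[1][1] - self.grids[1][0]
        return np.column_stack(
            [
                self.grids[0][i] + rng.uniform(-dx0 / 2, dx0 / 2, n),
                self.grids[1][j] + rng.uniform(-dy0 / 2, dy0 / 2, n),
            ]
        )


def conditional_posterior(
    handle: Posterior, fixed: np.ndarray, free: tuple[int, ...], grid_n: int = 100
) -> ConditionalDensity:
    """Conditional posterior over 1 or 2 free parameters, others clamped.

    ``fixed`` supplies the clamped values (entries at the free indices are
    ignored).  The density is evaluated on a grid spanning the free
    parameters' prior ranges and renormalized; if the clamped point carries
    near-zero posterior mass a warning is logged and the renormalized shape
    is still returned.
    """
    free = tuple(int(i) for i in (free if np.iterable(free) else [free]))
    if len(free) not in (1, 2):
        raise ValueError("free must name 1 or 2 parameters (none fixed is not a conditional)")
    model = handle.model
    d = model.d_theta
    fixed = np.asarray(fixed, dtype=float)
    lo, hi = model.prior_low, model.prior_high
    clamped = np.clip(fixed, lo, hi)
    grids = tuple(np.linspace(lo[i], hi[i], grid_n) for i in free)
    if len(free) == 1:
        pts = np.tile(clamped, (grid_n, 1))
        pts[:, free[0]] = grids[0]
    else:
        g0, g1 = np.meshgrid(grids[0], grids[1], indexing="ij")
        pts = np.tile(clamped, (grid_n * grid_n, 1))
        pts[:, free[0]] = g0.ravel()
        pts[:, free[1]] = g1.ravel()
    lp = handle.log_prob(pts)
    lp = np.where(np.isfinite(lp), lp, -1e300)
    mx = lp.max()
    if mx < -1e200 or mx - np.median(lp[np.isfinite(lp)]) > 700:
        log.warning("conditional_posterior: clamped point has near-zero density")
    dens = np.exp(lp - mx)
    cell = np.prod([g[1] - g[0] for g in grids])
    Z = dens.sum() * cell
    if Z <= 0:
        dens = np.ones_like(dens)
        Z = dens.sum() * cell
    dens = dens / Z
    if len(free) == 2:
        dens = dens.reshape(grid_n, grid_n)
    return ConditionalDensity(free, grids, dens, clamped)


@dataclass
class ConditionalCorrMatrix:
    mean_r: np.ndarray           # (d, d), symmetric, unit diagonal
    r_values: dict               # (i, j) -> array of per-conditional r
    p_values: np.ndarray         # (d, d) one-sample t-test p vs 0
    param_names: tuple[str, ...]


def conditional_corr_matrix(
    handle: Posterior,
    n_conditionals: int = 50,
    n_points: int = 50,
    seed: int = 0,
    grid_n: int = 50,
) -> ConditionalCorrMatrix:
    """Mean conditional correlation per parameter pair.

    For every pair, draw ``n_conditionals`` clamping points from the
    posterior, form the 2-D conditional, sample ``n_points`` from each, and
    record the Pearson r; report the mean matrix and a one-sample t-test of
    the r values against zero.
    """
    rng = np.random.default_rng(seed)
    d = handle.model.d_theta
    conds = handle.sample(n_conditionals, rng)
    mean_r = np.eye(d)
    p_values = np.zeros((d, d))
    r_values: dict = {}
    for i in range(d):
        for j in range(i + 1, d):
            rs = np.empty(n_conditionals)
            for c in range(n_conditionals):
                cd = conditional_posterior(handle, conds[c], (i, j), grid_n=grid_n)
                pts = cd.sample(n_points, rng)
                rs[c] = pearsonr(pts[:, 0], pts[:, 1])[0]
            rs = rs[np.isfinite(rs)]
            r_values[(i, j)] = rs
            mean_r[i, j] = mean_r[j, i] = rs.mean() if len(rs) else 0.0
            if len(rs) >= 3 and rs.std() > 0:
                p = ttest_1samp(rs, 0.0).pvalue
            else:
                p = 0.0 if len(rs) and abs(rs.mean()) > 0 else 1.0
            p_values[i, j] = p_values[j, i] = p
    return ConditionalCorrMatrix(mean_r, r_values, p_values, handle.param_names)


def sensitivity_scores(
    handle: Posterior, n_samples: int = 500, seed: int = 0
) -> np.ndarray:
    """Active-subspace sensitivity of the posterior per parameter, in [0, 1].

    Eigen-decomposition of the covariance of the log-density gradient over
    posterior samples (gradients taken w.r.t. prior-range-normalized
    parameters so units cancel); each parameter's score aggregates the
    eigenvector loadings weighted by their eigenvalues, normalized to a
    maximum of 1.
    """
    rng = np.random.default_rng(seed)
    th = handle.sample(n_samples, rng)
    scale = handle.model.prior_high - handle.model.prior_low
    G = handle.grad_log_prob(th) * scale  # d/d(theta_normalized)
    if not np.all(np.isfinite(G)):  # finite-difference fallback
        log.warning("analytic gradient failed; falling back to finite differences")
        eps = 1e-4 * scale
        G = np.empty_like(th)
        for i in range(th.shape[1]):
            up, dn = th.copy(), th.copy()
            up[:, i] += eps[i]
            dn[:, i] -= eps[i]
            G[:, i] = (handle.log_prob(up) - handle.log_prob(dn)) / (2 * eps[i]) * scale[i]
        G = np.nan_to_num(G)
    M = (G[:, :, None] * G[:, None, :]).mean(axis=0)
    w, V = np.linalg.eigh(M)
    scores = (V**2) @ np.abs(w)
    mx = scores.max()
    return scores / mx if mx > 0 else scores


def feature_sensitivity(
    params0: FreeParams,
    feature_name: str,
    step_fraction: float = 0.05,
    n_seeds: int = 3,
    simulate_fn=None,
    seed: int = 0,
    param_indices=None,
    **sim_kwargs,
):
    """Central-difference sensitivity of one MEA feature to each parameter.

    Steps are a fraction of each parameter's prior range; estimates are
    averaged over ``n_seeds`` simulation seeds and reported with their Monte
    Carlo standard error.  Probe points that fail to simulate are dropped.
    ``param_indices`` restricts probing to a subset (others report 0).
    Returns ``(sensitivity, mc_error)`` arrays over PARAM_NAMES.
    """
    from .simulate import SimulationError, simulate_network

    if simulate_fn is None:
        simulate_fn = simulate_network
    th0 = params0.to_array()
    span = PRIOR_HIGH - PRIOR_LOW
    d = len(th0)
    probe = range(d) if param_indices is None else param_indices
    vals = np.full((d, n_seeds), np.nan)
    for i in probe:
        delta = step_fraction * span[i]
        up = np.clip(th0.copy(), PRIOR_LOW, PRIOR_HIGH)
        dn = up.copy()
        up[i] = min(th0[i] + delta, PRIOR_HIGH[i])
        dn[i] = max(th0[i] - delta, PRIOR_LOW[i])
        h = up[i] - dn[i]
        if h == 0:
            continue
        for s in range(n_seeds):
            try:
                fu = compute_features(
                    simulate_fn(FreeParams.from_array(up), seed=seed + s, **sim_kwargs).raster
                )
                fd = compute_features(
                    simulate_fn(FreeParams.from_array(dn), seed=seed + s, **sim_kwargs).raster
                )
            except SimulationError as exc:
                log.warning("probe dropped for %s seed %d: %s", PARAM_NAMES[i], s, exc)
                continue
            vals[i, s] = (getattr(fu, feature_name) - getattr(fd, feature_name)) / (h / span[i])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # unprobed rows are all-NaN
        sens = np.nanmean(vals, axis=1)
        spread = np.nanstd(vals, axis=1)
    cnt = np.sum(np.isfinite(vals), axis=1)
    mc = np.where(cnt > 1, spread / np.sqrt(np.maximum(cnt, 1)), np.inf)
    return np.nan_to_num(sens), mc


def ppc_check(
    model: PosteriorModel,
    theta_star: np.ndarray,
    x_obs: np.ndarray | None = None,
    seed: int = 0,
    n_samples: int = 1000,
    simulate_fn=None,
    **sim_kwargs,
) -> dict:
    """Posterior-predictive check against a known ground truth.

    Simulate with ``theta_star`` (or take precomputed features ``x_obs``),
    condition the posterior, and require for every univariate and pairwise
    marginal that the kernel-density estimate (Scott's rule, ``n_samples``
    samples) at the ground truth is at least half the marginal's maximum
    density.  Returns per-marginal booleans and the overall verdict.
    """
    theta_star = np.asarray(theta_star, dtype=float).ravel()
    if x_obs is None:
        from .simulate import simulate_network

        sim = (simulate_fn or simulate_network)(
            FreeParams.from_array(theta_star), seed=seed, **sim_kwargs
        )
        fv = compute_features(sim.raster)
        x_obs = np.array([getattr(fv, n) for n in model.feature_names])
    handle = posterior_for(x_obs, model)
    samples = handle.sample(n_samples, seed)
    d = model.d_theta
    results: dict = {"univariate": {}, "pairwise": {}}
    ok_all = True
    for i in range(d):
        s = samples[:, i]
        if s.std() == 0:
            ok = bool(abs(theta_star[i] - s.mean()) < 1e-12)
        else:
            kde = gaussian_kde(s)
            grid = np.linspace(s.min(), s.max(), 200)
            ok = bool(kde(theta_star[i])[0] >= 0.5 * kde(grid).max())
        results["univariate"][model.param_names[i]] = ok
        ok_all &= ok
    for i in range(d):
        for j in range(i + 1, d):
            pts = samples[:, [i, j]].T
            if np.linalg.matrix_rank(np.cov(pts)) < 2:
                ok = True
            else:
                kde = gaussian_kde(pts)
                dmax = kde(pts).max()
                ok = bool(kde(theta_star[[i, j]])[0] >= 0.5 * dmax)
            results["pairwise"][(model.param_names[i], model.param_names[j])] = ok
            ok_all &= ok
    results["pass"] = ok_all
    uni = list(results["univariate"].values())
    pair = list(results["pairwise"].values())
    results["univariate_fraction"] = float(np.mean(uni))
    results["pairwise_fraction"] = float(np.mean(pair)) if pair else 1.0
    results["x_obs"] = x_obs
    return results


def parameter_recovery_error(
    handle: Posterior, theta_star: np.ndarray, n: int = 1000, seed: int = 0
) -> np.ndarray:
    """PRE per parameter: mean |theta - theta*| over marginal samples,
    normalized by the prior range; 0 is perfect concentration at the truth,
    0.25 matches a uniform marginal with the truth at the prior midpoint."""
    theta_star = np.asarray(theta_star, dtype=float).ravel()
    samples = handle.sample(n, seed)
    span = handle.model.prior_high - handle.model.prior_low
    return np.mean(np.abs(samples - theta_star), axis=0) / span
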