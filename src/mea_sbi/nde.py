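"""Conditional density estimation for amortized posterior inference.

The estimator fits a full-covariance Gaussian mixture to the joint
standardized (parameters, features) space by EM and conditions it on a
feature vector in closed form: given x, the posterior over theta is again a
Gaussian mixture whose component weights, means, and covariances follow from
the standard Gaussian conditioning identities.  This gives the amortized
contract a neural density estimator provides -- exact log-density, cheap
sampling, no per-observation retraining -- with a deterministic, dependency-
light fit.  The number of mixture components is selected by BIC by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp
from sklearn.mixture import GaussianMixture

__all__ = ["ConditionalGaussianMixture", "GaussianMixturePosterior"]


@dataclass
class GaussianMixturePosterior:
    """A Gaussian mixture over the parameter block, conditioned on one x."""

    log_weights: np.ndarray   # (K,)
    means: np.ndarray         # (K, d)
    covs: np.ndarray          # (K, d, d)
    _chols: np.ndarray | None = None
    _precs: np.ndarray | None = None

    def _prepare(self) -> None:
        if self._chols is None:
            self._chols = np.linalg.cholesky(self.covs)
            self._precs = np.array([np.linalg.inv(c) for c in self.covs])

    def log_prob(self, theta: np.ndarray) -> np.ndarray:
        """Log density at points ``theta`` of shape (n, d) or (d,)."""
        self._prepare()
        theta = np.atleast_2d(np.asarray(theta, dtype=float))
        d = theta.shape[1]
        comp = np.empty((len(self.log_weights), theta.shape[0]))
        for k, (mu, chol) in enumerate(zip(self.means, self._chols)):
            diff = theta - mu
            y = np.linalg.solve(chol, diff.T)
            maha = np.sum(y**2, axis=0)
            logdet = 2.0 * np.sum(np.log(np.diag(chol)))
            comp[k] = -0.5 * (maha + logdet + d * np.log(2 * np.pi)) + self.log_weights[k]
        return logsumexp(comp, axis=0)

    def grad_log_prob(self, theta: np.ndarray) -> np.ndarray:
        """Analytic gradient of the log density, shape like ``theta``."""
        self._prepare()
        theta = np.atleast_2d(np.asarray(theta, dtype=float))
        K = len(self.log_weights)
        comp = np.empty((K, theta.shape[0]))
        grads = np.empty((K, *theta.shape))
        d = theta.shape[1]
        for k in range(K):
            diff = theta - self.means[k]
            y = np.linalg.solve(self._chols[k], diff.T)
            maha = np.sum(y**2, axis=0)
            logdet = 2.0 * np.sum(np.log(np.diag(self._chols[k])))
            comp[k] = -0.5 * (maha + logdet + d * np.log(2 * np.pi)) + self.log_weights[k]
            grads[k] = -diff @ self._precs[k].T
        lse = logsumexp(comp, axis=0)
        resp = np.exp(comp - lse)  # (K, n)
        return np.einsum("kn,knd->nd", resp, grads)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        self._prepare()
        w = np.exp(self.log_weights - logsumexp(self.log_weights))
        ks = rng.choice(len(w), size=n, p=w)
        z = rng.standard_normal((n, self.means.shape[1]))
        out = np.empty_like(z)
        for k in np.unique(ks):
            sel = ks == k
            out[sel] = self.means[k] + z[sel] @ self._chols[k].T
        return out


class ConditionalGaussianMixture:
    """Joint GMM over (theta, x) with closed-form posterior conditioning."""

    def __init__(self, n_components: int | str = "bic", max_components: int = 12,
                 reg_covar: float = 1e-3, seed: int = 0, n_init: int = 1):
        self.n_components = n_components
        self.max_components = max_components
        self.reg_covar = reg_covar
        self.seed = seed
        self.n_init = n_init
        self.d_theta: int | None = None

    def fit(self, theta: np.ndarray, x: np.ndarray) -> "ConditionalGaussianMixture":
        theta = np.asarray(theta, dtype=float)
        x = np.asarray(x, dtype=float)
        z = np.hstack([theta, x])
        self.d_theta = theta.shape[1]
        # a full-covariance component in d dimensions carries ~d^2/2 + d
        # parameters; cap the component count so EM cannot chase clusters it
        # cannot support, which yields near-singular conditionals
        n, d = z.shape
        cap = max(1, min(self.max_components, n // (10 * d)))
        if self.n_components == "bic":
            best, best_bic = None, np.inf
            k = 1
            while k <= cap:
                gm = GaussianMixture(
                    n_components=k, covariance_type="full",
                    reg_covar=self.reg_covar, random_state=self.seed,
                    n_init=self.n_init, max_iter=500,
                ).fit(z)
                bic = gm.bic(z)
                if bic < best_bic - 1e-9:
                    best, best_bic = gm, bic
                k += 1
            self._gm = best
        else:
            self._gm = GaussianMixture(
                n_components=int(self.n_components), covariance_type="full",
                reg_covar=self.reg_covar, random_state=self.seed,
                n_init=self.n_init, max_iter=500,
            ).fit(z)
        self.weights_ = self._gm.weights_
        self.means_ = self._gm.means_
        self.covs_ = self._gm.covariances_
        return self

    @property
    def n_components_(self) -> int:
        return len(self.weights_)

    def condition(self, x: np.ndarray) -> GaussianMixturePosterior:
        """Posterior mixture over theta given one feature vector ``x``."""
        x = np.asarray(x, dtype=float).ravel()
        d = self.d_theta
        lw = np.empty(self.n_components_)
        means = np.empty((self.n_components_, d))
        covs = np.empty((self.n_components_, d, d))
        dx = len(x)
        for k in range(self.n_components_):
            mu_t, mu_x = self.means_[k][:d], self.means_[k][d:]
            S = self.covs_[k]
            Stt, Stx, Sxx = S[:d, :d], S[:d, d:], S[d:, d:]
            Sxx = Sxx + 1e-10 * np.eye(dx)
            chol = np.linalg.cholesky(Sxx)
            diff = x - mu_x
            y = np.linalg.solve(chol, diff)
            maha = float(y @ y)
            logdet = 2.0 * np.sum(np.log(np.diag(chol)))
            lw[k] = np.log(self.weights_[k] + 1e-300) - 0.5 * (
                maha + logdet + dx * np.log(2 * np.pi)
            )
            gain = np.linalg.solve(Sxx, Stx.T).T  # Stx @ Sxx^-1
            means[k] = mu_t + gain @ diff
            Ck = Stt - gain @ Stx.T
            Ck = 0.5 * (Ck + Ck.T) + 1e-10 * np.eye(d)
            covs[k] = Ck
        lw = lw - logsumexp(lw)
        return GaussianMixturePosterior(lw, means, covs)

    def marginal_x_logpdf(self, x: np.ndarray) -> float:
        """Log density of the feature marginal (misspecification hint)."""
        x = np.asarray(x, dtype=float).ravel()
        d = self.d_theta
        lps = np.empty(self.n_components_)
        for k in range(self.n_components_):
            mu_x = self.means_[k][d:]
            Sxx = self.covs_[k][d:, d:] + 1e-10 * np.eye(len(x))
            chol = np.linalg.cholesky(Sxx)
            y = np.linalg.solve(chol, x - mu_x)
            lps[k] = np.log(self.weights_[k] + 1e-300) - 0.5 * (
                y @ y + 2.0 * np.sum(np.log(np.diag(chol))) + len(x) * np.log(2 * np.pi)
            )
        return float(logsumexp(lps))
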