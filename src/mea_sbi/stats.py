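"""Condition-comparison statistics for drug / disease / gene-edit analyses.

Per network, two posteriors are compared marginal-by-marginal with a
two-sample Kolmogorov-Smirnov test on 50 samples per side; features are
compared across recording groups with Mann-Whitney tests; conditional
correlation coefficients are tested against zero with a one-sample t-test
(Shapiro-Wilk normality gate logged).  Posteriors carrying different MEA
batch labels refuse to be compared unless explicitly overridden, because
batch effects dominate posterior shape.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sst

from .features import FEATURE_NAMES
from .inference import Posterior

__all__ = [
    "MarginalComparison",
    "BatchAggregate",
    "BatchMismatchError",
    "compare_marginals",
    "compare_features",
    "corr_vs_zero",
    "normalize_features",
    "aggregate_by_line",
]

log = logging.getLogger(__name__)


class BatchMismatchError(RuntimeError):
    """Raised when comparing posteriors from different MEA batches."""


@dataclass
class MarginalComparison:
    parameter: str
    p_value: float
    direction: int       # sign of median(B) - median(A)
    network: object = None
    batch: object = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value outside [0, 1]")


def _batch_of(post: Posterior):
    return post.model.metadata.get("batch") if hasattr(post, "model") else None


def _content_digest(post: Posterior) -> int:
    """Stable digest of a conditioned posterior (mixture params + observation).

    Used to seed each side's sample stream so that the KS comparison is
    exactly symmetric in (A, B): swapping the arguments swaps the sample
    sets instead of re-drawing them.
    """
    import hashlib

    h = hashlib.sha256()
    mix = post._mix
    for a in (mix.log_weights, mix.means, mix.covs, post.x_obs):
        h.update(np.ascontiguousarray(a, dtype=float).tobytes())
    return int.from_bytes(h.digest()[:8], "little")


def compare_marginals(
    post_a: Posterior,
    post_b: Posterior,
    n: int = 50,
    seed: int = 0,
    network=None,
    allow_batch_mismatch: bool = False,
    holm: bool = False,
) -> list[MarginalComparison]:
    """Per-parameter two-sample KS test on ``n`` samples from each posterior.

    Posteriors from different MEA batches should not be compared (batch
    effects confound the parameters); a hard error enforces this unless
    ``allow_batch_mismatch`` is set.  P-values are reported raw by default;
    ``holm`` applies a Holm step-down correction across parameters.
    """
    if post_a.param_names != post_b.param_names:
        raise ValueError("posteriors are over different parameter sets")
    ba, bb = _batch_of(post_a), _batch_of(post_b)
    if ba is not None and bb is not None and ba != bb and not allow_batch_mismatch:
        raise BatchMismatchError(
            f"posteriors come from different MEA batches ({ba!r} vs {bb!r}); "
            "pass allow_batch_mismatch=True to override"
        )
    da, db = _content_digest(post_a), _content_digest(post_b)
    if da != db:
        rng_a = np.random.default_rng([seed, da])
        rng_b = np.random.default_rng([seed, db])
    else:  # identical posteriors: fall back to independent side streams
        rng_a = np.random.default_rng([seed, 0])
        rng_b = np.random.default_rng([seed, 1])
    sa = post_a.sample(n, rng_a)
    sb = post_b.sample(n, rng_b)
    out = []
    for i, name in enumerate(post_a.param_names):
        ks = sst.ks_2samp(sa[:, i], sb[:, i])
        direction = int(np.sign(np.median(sb[:, i]) - np.median(sa[:, i])))
        out.append(
            MarginalComparison(name, float(ks.pvalue), direction, network=network, batch=ba)
        )
    if holm:
        order = np.argsort([c.p_value for c in out])
        m = len(out)
        adj_prev = 0.0
        for rank, idx in enumerate(order):
            adj = min(1.0, (m - rank) * out[idx].p_value)
            adj = max(adj, adj_prev)
            out[idx].p_value = adj
            adj_prev = adj
    return out


def compare_features(
    group_a: pd.DataFrame | np.ndarray,
    group_b: pd.DataFrame | np.ndarray,
    feature_names=FEATURE_NAMES,
) -> dict[str, float]:
    """Two-sided Mann-Whitney test per feature between two recording groups."""
    A = pd.DataFrame(group_a, columns=None if isinstance(group_a, pd.DataFrame) else feature_names)
    B = pd.DataFrame(group_b, columns=None if isinstance(group_b, pd.DataFrame) else feature_names)
    if len(A) < 3 or len(B) < 3:
        raise ValueError("need at least 3 recordings per group")
    out = {}
    for name in feature_names:
        a, b = A[name].to_numpy(float), B[name].to_numpy(float)
        if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
            log.warning("feature %s fully tied; reporting p=1", name)
            out[name] = 1.0
            continue
        out[name] = float(sst.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    return out


def corr_vs_zero(r_values: np.ndarray) -> float:
    """One-sample t-test of correlation coefficients against zero.

    A Shapiro-Wilk normality check is logged (the t-test is reported either
    way, as in standard practice for ~50 coefficients).  Degenerate
    zero-variance inputs fall back to a sign rule.
    """
    r = np.asarray(r_values, dtype=float)
    r = r[np.isfinite(r)]
    if len(r) < 3:
        raise ValueError("need at least 3 correlation values")
    if r.std() == 0:
        return 0.0 if r[0] != 0 else 1.0
    sw = sst.shapiro(r)
    if sw.pvalue < 0.05:
        log.warning("corr_vs_zero: Shapiro-Wilk rejects normality (p=%.3g)", sw.pvalue)
    return float(sst.ttest_1samp(r, 0.0).pvalue)


def normalize_features(fv: np.ndarray, prior_sd: np.ndarray) -> np.ndarray:
    """Express features in units of their prior-predictive standard deviation."""
    fv = np.asarray(fv, dtype=float)
    prior_sd = np.asarray(prior_sd, dtype=float)
    bad = np.nonzero(prior_sd <= 0)[0]
    if len(bad):
        names = [FEATURE_NAMES[i] if i < len(FEATURE_NAMES) else str(i) for i in bad]
        raise ValueError(f"zero prior sd for feature(s) {names}")
    return fv / prior_sd


@dataclass
class BatchAggregate:
    line: object
    mea: object
    features: pd.Series
    n_wells: int


def aggregate_by_line(table: pd.DataFrame, feature_names=FEATURE_NAMES) -> list[BatchAggregate]:
    """Average features per (cell line, MEA batch) group.

    ``table`` needs 'line' and 'mea' label columns plus the feature columns.
    Empty groups are skipped with a warning; group sizes are logged.
    """
    for col in ("line", "mea"):
        if col not in table.columns:
            raise ValueError(f"missing label column '{col}'")
    out = []
    for (line, mea), grp in table.groupby(["line", "mea"], sort=True):
        if len(grp) == 0:
            log.warning("empty group (%s, %s) skipped", line, mea)
            continue
        log.info("aggregating line=%s mea=%s over %d wells", line, mea, len(grp))
        out.append(
            BatchAggregate(line, mea, grp[list(feature_names)].mean(axis=0), len(grp))
        )
    return out
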