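"""Shared 1-D Gaussian-mixture EM primitives."""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp

_LOG_2PI = np.log(2.0 * np.pi)


def quantile_init(x: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Means at k spread quantiles, equal weights, pooled standard deviation.

    For k = 6 the quantiles are {10, 25, 40, 60, 75, 90}%; other k use an
    even interior spread.
    """
    if k == 6:
        qs = np.array([10.0, 25.0, 40.0, 60.0, 75.0, 90.0])
    else:
        qs = 100.0 * (np.arange(k) + 0.5) / k
    means = np.percentile(x, qs)
    # heavily unbalanced classes can make quantiles coincide, starting two
    # components on one mode and none on another; fall back to an even
    # spread over the observed range
    spread = float(np.ptp(x))
    if spread > 0 and np.any(np.diff(np.sort(means)) < 1e-6 * spread):
        means = np.min(x) + spread * (np.arange(k) + 0.5) / k
    sd = float(np.std(x))
    sds = np.full(k, sd if sd > 0 else 1.0)
    weights = np.full(k, 1.0 / k)
    return means, sds, weights


def log_responsibilities(
    x: np.ndarray,
    means: np.ndarray,
    sds: np.ndarray,
    weights: np.ndarray,
    extra_log_joint: float | None = None,
) -> tuple[np.ndarray, float]:
    """Posterior log-memberships (n, k[+1]) and the total log-likelihood.

    ``extra_log_joint`` appends one constant-density component (e.g. a
    uniform outlier class) as the last column.
    """
    z = (x[:, None] - means[None, :]) / sds[None, :]
    log_joint = np.log(weights[None, :]) - np.log(sds[None, :]) - 0.5 * (z**2 + _LOG_2PI)
    if extra_log_joint is not None:
        log_joint = np.concatenate(
            [log_joint, np.full((len(x), 1), extra_log_joint)], axis=1
        )
    log_norm = logsumexp(log_joint, axis=1)
    return log_joint - log_norm[:, None], float(np.sum(log_norm))


def m_step(
    x: np.ndarray, gamma: np.ndarray, variance_floor: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Closed-form mixture updates from responsibilities ``gamma`` (n, k).

    Weights are normalised over the k components, so responsibilities
    need not sum to 1 per observation (an outlier class may hold the
    remainder).
    """
    nk = gamma.sum(axis=0)
    nk = np.maximum(nk, 1e-300)
    means = (gamma * x[:, None]).sum(axis=0) / nk
    var = (gamma * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / nk
    sds = np.sqrt(np.maximum(var, variance_floor))
    weights = nk / nk.sum()
    return means, sds, weights
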