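"""Multiplicative bias-field estimation by EM with a polynomial field.

Receive-coil inhomogeneity appears as a smooth multiplicative gain on
the M0 map.  In the log-intensity domain the model is additive:

    log S(v) = b(v) + mixture noise,

where ``b`` is a low-order 3-D polynomial (tensor Legendre basis, total
degree <= 4 by default, 35 terms) and the residual intensities follow a
K-component Gaussian mixture (K = 6 by default).  EM alternates

* E-step: posterior component memberships of the field-corrected
  log-intensities,
* M-step: closed-form mixture updates, then a weighted least-squares
  refit of the polynomial coefficients to the per-voxel residual-field
  estimate, with precision weights from the mixture.

Voxels outside the estimation mask (e.g. the reference vials, which
would otherwise drag the smooth field up) contribute nothing to the
estimate; the exponential of the fitted polynomial is evaluated on the
full grid so the correction still applies everywhere.  The field is
normalised to mean 1 over the estimation mask, which also makes the
estimate invariant to global intensity scaling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy.special import eval_legendre

from bbpcmap._mixture import log_responsibilities, m_step, quantile_init
from bbpcmap.recovery import M0Map

logger = logging.getLogger(__name__)


@dataclass
class MixtureModel:
    """Gaussian mixture over log-intensities: per-component parameters."""

    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=np.float64)
        self.sds = np.asarray(self.sds, dtype=np.float64)
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if not (len(self.means) == len(self.sds) == len(self.weights)):
            raise ValueError("mixture parameter arrays must have equal length")
        if np.any(self.weights < 0) or not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("mixture weights must be nonnegative and sum to 1")

    @property
    def k(self) -> int:
        return len(self.means)


@dataclass
class BiasField:
    """A fitted multiplicative gain field.

    ``log_coefficients`` are the polynomial coefficients in the
    log-intensity domain on the scaled Legendre basis; ``field`` is the
    multiplicative gain evaluated on the full grid, mean-1 over the
    estimation mask.
    """

    log_coefficients: np.ndarray
    field: np.ndarray
    estimation_mask: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.field <= 0):
            raise ValueError("bias field must be strictly positive")


def polynomial_basis_indices(order: int) -> list[tuple[int, int, int]]:
    """Exponent triples with total degree <= ``order`` (35 for order 4)."""
    return [
        (i, j, k)
        for i, j, k in product(range(order + 1), repeat=3)
        if i + j + k <= order
    ]


def _scaled_coords(shape: tuple[int, int, int]) -> list[np.ndarray]:
    """Per-axis coordinates rescaled to [-1, 1] over the full grid."""
    coords = []
    for ax in range(3):
        half = max((shape[ax] - 1) / 2.0, 0.5)
        coords.append((np.arange(shape[ax], dtype=np.float64) - (shape[ax] - 1) / 2.0) / half)
    return coords


def evaluate_basis(
    shape: tuple[int, int, int], order: int, where: np.ndarray | None = None
) -> np.ndarray:
    """Design matrix of the tensor Legendre basis.

    Rows are the voxels selected by ``where`` (default: the whole grid),
    columns the basis terms.  Coordinates are scaled to [-1, 1] over the
    full grid, not the estimation-mask bounding box: the field is later
    evaluated at voxels far from the mask (the reference vials), and
    keeping those coordinates inside [-1, 1] bounds the Legendre terms
    there, where a bbox-scaled polynomial would extrapolate explosively.
    """
    coords = _scaled_coords(shape)
    if where is None:
        where = np.ones(shape, dtype=bool)
    vx, vy, vz = np.nonzero(where)
    terms = polynomial_basis_indices(order)
    max_deg = max(order, 1)
    # cache 1-D Legendre evaluations per axis and degree
    leg = [
        np.stack([eval_legendre(d, coords[ax]) for d in range(max_deg + 1)], axis=0)
        for ax in range(3)
    ]
    cols = [leg[0][i][vx] * leg[1][j][vy] * leg[2][k][vz] for (i, j, k) in terms]
    return np.stack(cols, axis=1)


def estimate_bias(
    m0: M0Map | np.ndarray,
    estimation_mask: np.ndarray,
    k: int = 6,
    order: int = 4,
    tol: float = 1e-5,
    max_iter: int = 100,
    ridge: float = 1e-3,
    outlier_weight: float = 1e-3,
) -> tuple[BiasField, MixtureModel]:
    """Estimate the multiplicative bias field of an M0 map.

    Parameters
    ----------
    m0 : M0Map or ndarray
        Intensity volume; only finite, positive in-mask voxels are used.
    estimation_mask : ndarray of bool
        Voxels the field is estimated from.  Must exclude the reference
        vials and blood sample.
    k, order : int
        Mixture components and polynomial total degree.
    tol : float
        Relative log-likelihood change declaring convergence.
    max_iter : int
        EM iteration cap.
    ridge : float
        Tikhonov strength for the coefficient solve, relative to the
        mean eigenvalue of the weighted Gram matrix.  Basis directions
        with little support inside the estimation mask are otherwise
        unconstrained and explode when the field is evaluated at distant
        voxels (the vial row); a small ridge pins them near zero.
    outlier_weight : float
        Fixed weight of a uniform background component alongside the K
        Gaussians.  Voxels no Gaussian accounts for (small classes the
        quantile initialisation misses) otherwise acquire enormous
        precision weights and bend the field toward them.

    Returns
    -------
    (BiasField, MixtureModel)
    """
    values = m0.values if isinstance(m0, M0Map) else np.asarray(m0, dtype=np.float64)
    mask = np.asarray(estimation_mask, dtype=bool)
    if mask.shape != values.shape:
        raise ValueError("estimation mask and volume shapes differ")
    usable = mask & np.isfinite(values) & (values > 0)
    n_terms = len(polynomial_basis_indices(order))
    if not usable.any():
        raise ValueError("empty estimation mask")
    if usable.sum() < 10 * n_terms:
        raise ValueError(
            f"estimation mask too small: {int(usable.sum())} voxels for {n_terms} coefficients "
            f"(need >= {10 * n_terms})"
        )

    y = np.log(values[usable])
    phi = evaluate_basis(values.shape, order, where=usable)  # (n, p)

    means, sds, weights = quantile_init(y, k)
    variance_floor = 1e-4 * max(float(np.var(y)), 1e-30)
    sds = np.maximum(sds, np.sqrt(variance_floor))
    coef = np.zeros(n_terms)
    b = phi @ coef

    # uniform outlier density over twice the observed log-intensity range
    log_uniform = -np.log(2.0 * (float(np.ptp(y)) + 1e-12))

    prev_ll = -np.inf
    for iteration in range(max_iter):
        gamma_log, ll = log_responsibilities(
            y - b, means, sds, weights * (1.0 - outlier_weight),
            extra_log_joint=np.log(outlier_weight) + log_uniform,
        )
        gamma = np.exp(gamma_log[:, :k])  # Gaussian responsibilities only
        means, sds, weights = m_step(y - b, gamma, variance_floor)

        # per-voxel residual-field target and precision weight; outlier
        # voxels have near-zero Gaussian responsibility and drop out
        prec = gamma / sds[None, :] ** 2
        w = prec.sum(axis=1)
        target = y - (prec * means[None, :]).sum(axis=1) / np.maximum(w, 1e-300)

        wphi = phi * w[:, None]
        gram = phi.T @ wphi
        lam = ridge * np.trace(gram) / gram.shape[0]
        try:
            coef = np.linalg.solve(gram + lam * np.eye(gram.shape[0]), wphi.T @ target)
        except np.linalg.LinAlgError as exc:
            raise ValueError("singular polynomial design; degenerate mask geometry") from exc
        b = phi @ coef
        # identifiability: keep the field zero-mean in log over the mask,
        # pushing any global offset into the mixture means
        shift = float(b.mean())
        b -= shift
        coef = coef.copy()
        coef[0] -= shift  # term (0,0,0) is the constant 1
        means = means + shift

        if prev_ll > -np.inf and abs(ll - prev_ll) <= tol * abs(prev_ll):
            logger.debug("bias EM converged after %d iterations", iteration + 1)
            break
        prev_ll = ll

    full_log = evaluate_basis(values.shape, order) @ coef
    field = np.exp(full_log).reshape(values.shape)
    field /= field[usable].mean()
    return BiasField(coef, field, usable), MixtureModel(means, sds, weights)


def apply_bias(m0: M0Map, field: BiasField | np.ndarray) -> M0Map:
    """Divide an M0 map by the multiplicative field, everywhere.

    The correction applies to all voxels, including those (vials, blood)
    excluded from estimation.
    """
    gains = field.field if isinstance(field, BiasField) else np.asarray(field, dtype=np.float64)
    if gains.shape != m0.values.shape:
        raise ValueError("field and map shapes differ")
    if np.any(gains <= 0):
        raise ValueError("bias field must be strictly positive")
    return m0.with_values(m0.values / gains)
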