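"""BBPC maps, CBF correction, and summary statistics.

The partition coefficient of a voxel compares its measured water content
with the water content of whole blood:

    BBPC(v) = WC_brain(v) / (WC_blood * 1.04 g/mL)

with 1.04 g/mL the assumed brain-tissue density.  Uncorrected CBF maps
quantified with a fixed assumed coefficient (0.9 mL/g) are corrected by
dividing out the assumption and multiplying by the measured map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

BRAIN_DENSITY_G_PER_ML = 1.04
DEFAULT_ASSUMED_LAMBDA = 0.9  # mL/g, typical value assumed by CBF quantification


@dataclass
class WCMap:
    """Water-content map: fraction of voxel volume that is water (~0-1)."""

    values: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    units: str = "g/mL-fraction"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        finite = self.values[np.isfinite(self.values)]
        n_high = int(np.sum(finite > 1.2))
        if n_high:
            logger.warning("WC map has %d voxels above the 1.2 sanity bound", n_high)


@dataclass
class BBPCMap:
    """Partition-coefficient map in mL/g."""

    values: np.ndarray
    wc_blood_used: float = np.nan
    density_g_per_ml: float = BRAIN_DENSITY_G_PER_ML
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)


@dataclass
class CBFMap:
    """Cerebral blood flow map in mL/100 g/min."""

    values: np.ndarray
    assumed_lambda: float = DEFAULT_ASSUMED_LAMBDA
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)


def compute_bbpc(wc_brain: WCMap, wc_blood: float, density_g_per_ml: float = BRAIN_DENSITY_G_PER_ML) -> BBPCMap:
    """Voxel-wise partition coefficient from a water-content map."""
    if not 0.0 < wc_blood < 1.0:
        raise ValueError(f"blood water content must be in (0, 1), got {wc_blood}")
    values = wc_brain.values / (wc_blood * density_g_per_ml)
    return BBPCMap(values, wc_blood_used=float(wc_blood), density_g_per_ml=density_g_per_ml,
                   voxel_size=wc_brain.voxel_size)


def correct_cbf(cbf: CBFMap, bbpc: BBPCMap, assumed_lambda: float = DEFAULT_ASSUMED_LAMBDA) -> CBFMap:
    """Replace the assumed partition coefficient with the measured map.

    ``corrected(v) = cbf(v) / assumed_lambda * bbpc(v)``.
    """
    if assumed_lambda <= 0:
        raise ValueError("assumed_lambda must be positive")
    if cbf.values.shape != bbpc.values.shape:
        raise ValueError(f"grid mismatch: CBF {cbf.values.shape} vs BBPC {bbpc.values.shape}")
    values = cbf.values / assumed_lambda * bbpc.values
    return CBFMap(values, assumed_lambda=assumed_lambda, voxel_size=cbf.voxel_size)


def roi_mean(values: np.ndarray, mask: np.ndarray) -> float:
    """Mean over in-mask voxels, NaN voxels excluded."""
    vals = np.asarray(values)[np.asarray(mask, dtype=bool)]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("ROI contains no finite voxels")
    return float(vals.mean())


def contrast_to_noise(values: np.ndarray, gm_mask: np.ndarray, wm_mask: np.ndarray) -> float:
    """Signed CNR between two ROIs with the pooled (Bessel-corrected) SD.

    ``CNR = (mean_gm - mean_wm) / sqrt(((n_g-1) s_g^2 + (n_w-1) s_w^2) / (n_g + n_w - 2))``
    """
    gm_mask = np.asarray(gm_mask, dtype=bool)
    wm_mask = np.asarray(wm_mask, dtype=bool)
    if np.any(gm_mask & wm_mask):
        raise ValueError("ROIs must be disjoint")
    g = np.asarray(values)[gm_mask]
    w = np.asarray(values)[wm_mask]
    g = g[np.isfinite(g)]
    w = w[np.isfinite(w)]
    n_g, n_w = g.size, w.size
    if n_g == 0 or n_w == 0 or n_g + n_w < 3:
        raise ValueError("need non-empty ROIs with at least 3 voxels combined")
    s2_g = g.var(ddof=1) if n_g > 1 else 0.0
    s2_w = w.var(ddof=1) if n_w > 1 else 0.0
    pooled = np.sqrt(((n_g - 1) * s2_g + (n_w - 1) * s2_w) / (n_g + n_w - 2))
    if pooled == 0:
        raise ValueError("zero pooled standard deviation")
    return float((g.mean() - w.mean()) / pooled)


@dataclass
class Agreement:
    """Method-agreement summary: Pearson R^2 plus Bland-Altman statistics."""

    r_squared: float
    bias: float
    limits: tuple[float, float]
    bias_p_value: float = np.nan


def method_agreement(first: np.ndarray, second: np.ndarray) -> Agreement:
    """Compare paired ROI means from two methods.

    Bias is ``mean(second - first)``; limits of agreement are
    ``bias +/- 1.96 * SD(differences)``.  The one-sample t-test p-value
    for zero bias is included.
    """
    a = np.asarray(first, dtype=np.float64)
    b = np.asarray(second, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("paired lists must have equal length")
    if a.size < 3:
        raise ValueError("need >= 3 pairs")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        r_squared = 1.0 if np.allclose(a - a.mean(), b - b.mean()) else 0.0
    else:
        r_squared = float(stats.pearsonr(a, b).statistic ** 2)
    diff = b - a
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    if sd == 0:
        p = 1.0 if bias == 0 else 0.0
    else:
        p = float(stats.ttest_1samp(diff, 0.0).pvalue)
    return Agreement(r_squared=r_squared, bias=bias, limits=(bias - 1.96 * sd, bias + 1.96 * sd), bias_p_value=p)


def age_regression(
    values: np.ndarray, ages: np.ndarray, covariate_sex: np.ndarray | None = None
) -> tuple[float, float, float]:
    """OLS of a measurement on age, optionally with sex as additive covariate.

    Returns ``(slope, intercept, p_value)`` where the p-value is the
    two-sided test of zero age slope.
    """
    y = np.asarray(values, dtype=np.float64)
    x = np.asarray(ages, dtype=np.float64)
    if y.shape != x.shape or y.size < 3:
        raise ValueError("need >= 3 paired (value, age) observations")
    if np.ptp(x) == 0:
        raise ValueError("ages are constant; slope is unidentifiable")
    if np.ptp(y) == 0:
        return 0.0, float(y[0]), 1.0
    if covariate_sex is None:
        fit = stats.linregress(x, y)
        return float(fit.slope), float(fit.intercept), float(fit.pvalue)

    sex = np.asarray(covariate_sex, dtype=np.float64)
    design = np.column_stack([np.ones_like(x), x, sex])
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    dof = y.size - design.shape[1]
    if dof <= 0:
        raise ValueError("not enough observations for covariate-adjusted regression")
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(design.T @ design)
    t_stat = coef[1] / np.sqrt(cov[1, 1])
    p = 2.0 * stats.t.sf(abs(t_stat), dof)
    return float(coef[1]), float(coef[0]), float(p)
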