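"""Calibration of arbitrary-unit M0 maps to absolute water content.

Two routes are provided:

* **Phantom route** — five reference vials of heavy-water/distilled-water
  mixtures span a known 60-100% water-concentration scale; an ordinary
  least-squares line through (per-vial mean M0, known water fraction)
  converts every voxel.  Because some scanners inflate high-intensity
  vial signal quadratically with overall image gain, a cohort-level
  correction first regresses the tissue/vial M0 ratio on the vial mean
  and subtracts the implied per-subject quadratic error term from brain
  and blood voxels before the line is fitted.
* **Hematocrit route** — the blood sample's water content follows
  ``WC_blood = -0.271 * Hct + 0.912``; the map is rescaled so the
  blood-ROI mean matches that value.  No vials required.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from bbpcmap.recovery import M0Map
from bbpcmap.quantify import WCMap

logger = logging.getLogger(__name__)

D2O_FRACTIONS = (0.40, 0.30, 0.20, 0.10, 0.00)
WATER_FRACTIONS = tuple(1.0 - f for f in D2O_FRACTIONS)
GADOBUTROL_MM = 0.18

# blood water content as a linear function of hematocrit
HCT_SLOPE = -0.271
HCT_INTERCEPT = 0.912


@dataclass
class PhantomSet:
    """The five reference-vial masks and their known water fractions."""

    masks: list[np.ndarray]
    d2o_fractions: tuple[float, ...] = D2O_FRACTIONS
    gadobutrol_mM: float = GADOBUTROL_MM

    def __post_init__(self) -> None:
        if len(self.masks) != len(self.d2o_fractions):
            raise ValueError("one mask per phantom fraction required")
        self.masks = [np.asarray(m, dtype=bool) for m in self.masks]
        total = np.sum([m.astype(int) for m in self.masks], axis=0)
        if np.any(total > 1):
            raise ValueError("phantom masks must be disjoint")

    @property
    def water_fractions(self) -> np.ndarray:
        return 1.0 - np.asarray(self.d2o_fractions)


@dataclass
class BloodSample:
    """In-scanner blood vial: mask, mean M0 and hematocrit-derived water content."""

    mask: np.ndarray
    mean_m0: float
    hct: float
    wc_blood: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.wc_blood is None:
            self.wc_blood = hct_blood_water(self.hct)
        if not 0.0 < self.wc_blood < 1.0:
            raise ValueError(f"blood water content {self.wc_blood} outside (0, 1)")
        if not np.isfinite(self.mean_m0) or self.mean_m0 <= 0:
            raise ValueError(f"blood mean M0 must be positive, got {self.mean_m0}")

    @classmethod
    def from_map(cls, m0: M0Map, mask: np.ndarray, hct: float) -> "BloodSample":
        mask = np.asarray(mask, dtype=bool)
        vals = m0.values[mask & m0.fit_mask]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise ValueError("blood mask contains no fitted voxels")
        return cls(mask=mask, mean_m0=float(vals.mean()), hct=hct)


@dataclass
class CalibrationLine:
    """OLS line mapping M0 (arbitrary units) to water fraction."""

    slope: float
    intercept: float
    r_squared: float

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError(f"calibration slope must be positive, got {self.slope}")
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError(f"r_squared {self.r_squared} outside [0, 1]")


@dataclass
class RatioRegression:
    """Cohort regression of tissue/vial M0 ratio on vial mean M0.

    ``per_subject_error`` maps subject id to the quadratic error term
    ``delta_i = beta * P_i**2`` (negative when the vials inflate), which
    callers subtract from brain and blood M0 values.
    """

    alpha: float
    beta: float
    per_subject_error: dict[str, float]


def hct_blood_water(hct: float) -> float:
    """Blood water content from hematocrit: ``-0.271 * Hct + 0.912``.

    ``hct`` is a fraction; percent-style inputs in (2, 100) are divided
    by 100 with a warning.  Values in [1, 2] or outside (0, 100) are
    rejected as neither interpretation is physiological (the closed
    endpoints 0 and 1 are allowed as formula anchors).
    """
    hct = float(hct)
    if 2.0 < hct < 100.0:
        logger.warning("hematocrit %.3g looks like a percentage; dividing by 100", hct)
        hct /= 100.0
    if not 0.0 <= hct <= 1.0:
        raise ValueError(f"hematocrit {hct} outside [0, 1]")
    return HCT_SLOPE * hct + HCT_INTERCEPT


def phantom_means(m0: M0Map, phantoms: PhantomSet, min_voxels: int = 10) -> np.ndarray:
    """Per-vial mean of fitted M0 voxels, in vial order."""
    means = np.empty(len(phantoms.masks))
    for i, mask in enumerate(phantoms.masks):
        vals = m0.values[mask & m0.fit_mask]
        vals = vals[np.isfinite(vals)]
        if vals.size < min_voxels:
            raise ValueError(
                f"phantom vial {i + 1}: only {vals.size} fitted voxels (need >= {min_voxels})"
            )
        means[i] = vals.mean()
    return means


def fit_phantom_line(means: np.ndarray, water_fractions: np.ndarray = None) -> CalibrationLine:
    """OLS of known water fraction on vial mean M0."""
    means = np.asarray(means, dtype=np.float64)
    if water_fractions is None:
        water_fractions = np.asarray(WATER_FRACTIONS)
    water_fractions = np.asarray(water_fractions, dtype=np.float64)
    if means.size != water_fractions.size or means.size < 2:
        raise ValueError("need >= 2 paired (mean, fraction) values")
    if np.ptp(means) == 0:
        raise ValueError("degenerate phantom means: all identical")
    fit = stats.linregress(means, water_fractions)
    line = CalibrationLine(float(fit.slope), float(fit.intercept), float(fit.rvalue**2))
    predicted_top = line.slope * means.max() + line.intercept
    if predicted_top > 1.2:
        raise ValueError(f"calibration predicts water fraction {predicted_top:.3f} > 1.2 at the top vial")
    return line


def fit_ratio_regression(cohort: list[tuple[str, float, float]]) -> RatioRegression:
    """Fit the cohort tissue/vial-ratio regression.

    Parameters
    ----------
    cohort : list of (subject_id, tissue_mean_m0, phantom_mean_m0)
        ``phantom_mean_m0`` is the unweighted mean of the five per-vial
        means for that subject; must be positive.

    Returns
    -------
    RatioRegression
        With ``delta_i = beta * P_i**2`` per subject.
    """
    if len(cohort) < 3:
        raise ValueError(f"ratio regression needs >= 3 subjects, got {len(cohort)}")
    ids = [sid for sid, _, _ in cohort]
    t = np.array([ti for _, ti, _ in cohort], dtype=np.float64)
    p = np.array([pi for _, _, pi in cohort], dtype=np.float64)
    if np.any(p <= 0):
        raise ValueError("phantom mean M0 must be positive for all subjects")
    ratio = t / p
    fit = stats.linregress(p, ratio)
    beta = float(fit.slope)
    errors = {sid: beta * float(pi) ** 2 for sid, pi in zip(ids, p)}
    return RatioRegression(alpha=float(fit.intercept), beta=beta, per_subject_error=errors)


def apply_error_correction(
    m0: M0Map, brain_mask: np.ndarray, blood: BloodSample, delta_i: float
) -> tuple[M0Map, BloodSample]:
    """Subtract the per-subject quadratic error term from brain and blood.

    Every voxel inside the brain or blood mask has ``delta_i`` subtracted
    (``delta_i`` is negative when the vials inflate, so values increase);
    vial voxels are untouched.  Returns the shifted map and blood sample.
    """
    if not np.isfinite(delta_i):
        raise ValueError("delta_i must be finite")
    new_blood_mean = blood.mean_m0 - delta_i
    if new_blood_mean <= 0:
        raise ValueError(f"error correction drives blood mean M0 to {new_blood_mean} <= 0")
    shift_mask = np.asarray(brain_mask, dtype=bool) | blood.mask
    values = m0.values.copy()
    values[shift_mask] = values[shift_mask] - delta_i
    corrected = m0.with_values(values)
    return corrected, BloodSample(mask=blood.mask, mean_m0=new_blood_mean, hct=blood.hct, wc_blood=blood.wc_blood)


def normalize_phantom(m0: M0Map, line: CalibrationLine) -> WCMap:
    """Map every fitted voxel through the phantom calibration line."""
    return WCMap(line.slope * m0.values + line.intercept, voxel_size=m0.voxel_size)


def normalize_hct(m0: M0Map, blood: BloodSample) -> WCMap:
    """Rescale the map so the blood-ROI mean equals the Hct-derived water content."""
    if blood.mean_m0 <= 0:
        raise ValueError("blood mean M0 must be positive")
    return WCMap(m0.values * (blood.wc_blood / blood.mean_m0), voxel_size=m0.voxel_size)
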