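"""Tissue segmentation and ROI geometry.

Gray/white/CSF labels come from a 3-class Gaussian-mixture EM on the
in-mask intensities.  Class-to-tissue assignment is by mean-intensity
rank under a contrast convention: on T1-weighted volumes WM > GM > CSF,
on proton-density/water-content volumes CSF > GM > WM.  ROIs are eroded
per slice to limit partial-volume contamination, and analysis can be
restricted to the centermost slices of the brain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from bbpcmap._mixture import log_responsibilities, m_step, quantile_init
from bbpcmap.volio import VolumeImage

logger = logging.getLogger(__name__)

LABEL_GM, LABEL_WM, LABEL_CSF = 1, 2, 3

# tissue order from brightest to darkest mean intensity, per contrast
_CONTRAST_RANKS = {
    "t1w": (LABEL_WM, LABEL_GM, LABEL_CSF),
    "pd": (LABEL_CSF, LABEL_GM, LABEL_WM),
}


@dataclass
class TissueLabels:
    """Label volume (0 background, 1 GM, 2 WM, 3 CSF) with class posteriors."""

    labels: np.ndarray
    posteriors: dict[int, np.ndarray]

    def mask(self, label: int) -> np.ndarray:
        return self.labels == label


def em_segment(
    intensity: VolumeImage | np.ndarray,
    brain_mask: np.ndarray,
    n_classes: int = 3,
    contrast: str = "t1w",
    tol: float = 1e-6,
    max_iter: int = 500,
) -> TissueLabels:
    """Segment in-mask intensities with an EM-fit Gaussian mixture.

    Raises ``ValueError`` on degenerate input (too few voxels, too few
    distinct intensities) or if a mixture component collapses below
    weight 1e-4 — a sign that fewer classes should be used.
    """
    if contrast not in _CONTRAST_RANKS:
        raise ValueError(f"contrast must be one of {sorted(_CONTRAST_RANKS)}, got {contrast!r}")
    values = intensity.data if isinstance(intensity, VolumeImage) else np.asarray(intensity)
    mask = np.asarray(brain_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty brain mask")
    x = values[mask]
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite intensities inside brain mask")
    # 3 parameters per class
    if x.size < 10 * 3 * n_classes:
        raise ValueError(f"too few in-mask voxels ({x.size}) for {n_classes}-class EM")
    if np.unique(x).size < n_classes:
        raise ValueError("class collapse: fewer distinct intensities than classes; use fewer classes")

    means, sds, weights = quantile_init(x, n_classes)
    variance_floor = 1e-4 * max(float(np.var(x)), 1e-30)
    sds = np.maximum(sds, np.sqrt(variance_floor))

    prev_ll = -np.inf
    for _ in range(max_iter):
        gamma_log, ll = log_responsibilities(x, means, sds, weights)
        gamma = np.exp(gamma_log)
        means, sds, weights = m_step(x, gamma, variance_floor)
        if np.any(weights < 1e-4):
            raise ValueError("class collapse during EM (component weight < 1e-4); use fewer classes")
        if prev_ll > -np.inf and abs(ll - prev_ll) <= tol * abs(prev_ll):
            break
        prev_ll = ll

    gamma_log, _ = log_responsibilities(x, means, sds, weights)
    gamma = np.exp(gamma_log)

    # map mixture components to tissue labels by mean-intensity rank
    order_desc = np.argsort(means)[::-1]
    ranks = _CONTRAST_RANKS[contrast]
    component_label = {int(comp): ranks[r] for r, comp in enumerate(order_desc)}

    labels = np.zeros(values.shape, dtype=np.int16)
    argmax = np.argmax(gamma, axis=1)
    labels[mask] = np.array([component_label[int(c)] for c in range(n_classes)])[argmax]

    posteriors = {}
    for comp in range(n_classes):
        vol = np.zeros(values.shape)
        vol[mask] = gamma[:, comp]
        posteriors[component_label[comp]] = vol
    return TissueLabels(labels, posteriors)


def _disk_element(radius: int) -> np.ndarray:
    yy, xx = np.ogrid[-radius : radius + 1, -radius : radius + 1]
    return (xx**2 + yy**2) <= radius**2


def erode_roi(mask: np.ndarray, pixels: int = 2, element: str = "cross") -> np.ndarray:
    """Erode a binary mask slice-by-slice (2-D within each z slice).

    ``element="cross"`` applies ``pixels`` iterations of the 4-connected
    cross; ``element="disk"`` applies a single disk of radius ``pixels``.
    Never grows the mask; may return an empty mask (with a warning).
    """
    mask = np.asarray(mask, dtype=bool)
    if pixels < 0:
        raise ValueError("pixels must be >= 0")
    if pixels == 0 or not mask.any():
        return mask.copy()
    if element == "cross":
        structure = ndimage.generate_binary_structure(2, 1)
        iterations = pixels
    elif element == "disk":
        structure = _disk_element(pixels)
        iterations = 1
    else:
        raise ValueError(f"unknown structuring element {element!r}")
    out = np.zeros_like(mask)
    for z in range(mask.shape[2]):
        if mask[:, :, z].any():
            out[:, :, z] = ndimage.binary_erosion(
                mask[:, :, z], structure=structure, iterations=iterations, border_value=0
            )
    if not out.any():
        logger.warning("erosion by %d pixels emptied the mask", pixels)
    return out


def select_center_slices(brain_mask: np.ndarray, n: int = 10) -> np.ndarray:
    """Keep the ``n`` slices centered on the brain's slice extent.

    The retained block starts at ``z_min + (span - n + 1) // 2``, i.e.
    ties round the block toward the lower slice.  Raises if the brain
    spans fewer than ``n`` slices.
    """
    mask = np.asarray(brain_mask, dtype=bool)
    occupied = np.flatnonzero(mask.any(axis=(0, 1)))
    if occupied.size == 0:
        raise ValueError("empty brain mask")
    z_min, z_max = int(occupied[0]), int(occupied[-1])
    span = z_max - z_min + 1
    if span < n:
        raise ValueError(f"brain spans {span} slices, fewer than the requested {n}")
    start = z_min + (span - n + 1) // 2
    out = np.zeros_like(mask)
    out[:, :, start : start + n] = mask[:, :, start : start + n]
    return out
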