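"""End-to-end orchestration: fit, bias-correct, calibrate, quantify.

Works on in-memory subjects (anything exposing ``tr_series``, ``masks``,
``hct``, and optionally ``cbf_uncorrected``/``age``/``sex``) — both the
synthetic simulator's subjects and manifest-loaded real data fit this
shape.  The phantom-route quadratic error correction is a cohort-level
step, so cohort processing runs in two passes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from bbpcmap import bias as bias_mod
from bbpcmap import calibration as cal
from bbpcmap import quantify as qt
from bbpcmap import segmentation as seg
from bbpcmap.recovery import M0Map, T1Map, TRSeries, fit_recovery_volume
from bbpcmap.volio import SubjectManifest, VolumeImage, read_volume

logger = logging.getLogger(__name__)


@dataclass
class PipelineOptions:
    bias_correct: bool = True
    ratio_correction: bool = True
    erode_px: int = 2
    center_slices: int = 10
    mixture_k: int = 6
    poly_order: int = 4
    roi_source: str = "masks"  # "masks": use provided GM/WM; "segment": EM on anatomical
    assumed_lambda: float = qt.DEFAULT_ASSUMED_LAMBDA
    # T1 window (seconds) restricting the bias-estimation mask to a single
    # tissue class (gray matter).  A mask spanning tissues with different
    # proton densities lets the polynomial field absorb the smooth part of
    # the tissue contrast itself; a one-class mask has no contrast to
    # absorb.  Set to None to estimate over the whole brain mask.
    bias_t1_window_s: tuple[float, float] | None = (1.05, 1.55)


@dataclass
class LoadedSubject:
    """Manifest-backed subject in the shape the pipeline consumes."""

    subject_id: str
    tr_series: TRSeries
    masks: dict[str, np.ndarray]
    hct: float | None
    cbf_uncorrected: qt.CBFMap | None = None
    anatomical: VolumeImage | None = None
    age: float | None = None
    sex: int | None = None


def load_subject(manifest: SubjectManifest) -> LoadedSubject:
    volumes = [read_volume(p) for p in manifest.tr_series_paths]
    series = TRSeries(volumes, manifest.tr_values_ms)
    masks = {name: read_volume(p).data > 0.5 for name, p in manifest.mask_paths.items()}
    missing = [m for m in SubjectManifest.REQUIRED_MASKS if m not in masks]
    if missing:
        raise ValueError(f"subject {manifest.subject_id}: missing masks {missing}")
    cbf = qt.CBFMap(read_volume(manifest.cbf_path).data) if manifest.cbf_path else None
    anat = read_volume(manifest.anatomical_path) if manifest.anatomical_path else None
    return LoadedSubject(
        subject_id=manifest.subject_id,
        tr_series=series,
        masks=masks,
        hct=manifest.hct,
        cbf_uncorrected=cbf,
        anatomical=anat,
        age=manifest.age_years,
        sex=manifest.sex,
    )


@dataclass
class SubjectResult:
    subject_id: str
    m0: M0Map  # bias- (and, after cohort pass, error-) corrected
    t1: T1Map
    bias_field: bias_mod.BiasField | None
    vial_means: np.ndarray
    phantom_mean: float  # unweighted mean of the five vial means
    tissue_mean: float  # brain-mask mean M0
    blood: cal.BloodSample
    line: cal.CalibrationLine | None = None
    wc_phantom: qt.WCMap | None = None
    wc_hct: qt.WCMap | None = None
    bbpc_phantom: qt.BBPCMap | None = None
    bbpc_hct: qt.BBPCMap | None = None
    cbf_corrected: qt.CBFMap | None = None
    gm_roi: np.ndarray | None = None
    wm_roi: np.ndarray | None = None
    stats: dict = field(default_factory=dict)
    delta: float = 0.0
    age: float | None = None
    sex: int | None = None


def _vial_union(masks: dict[str, np.ndarray]) -> np.ndarray:
    return np.any([masks[f"phantom_{i}"] for i in range(1, 6)], axis=0)


def fit_and_correct(subject, options: PipelineOptions) -> SubjectResult:
    """First pass: recovery fit, bias correction, ROI-mean bookkeeping."""
    masks = subject.masks
    vials = _vial_union(masks)
    fit_mask = masks["brain"] | masks["blood"] | vials
    m0, t1 = fit_recovery_volume(subject.tr_series, fit_mask)

    bias_field = None
    if options.bias_correct:
        estimation_mask = masks["brain"] & m0.fit_mask
        if options.bias_t1_window_s is not None:
            lo, hi = options.bias_t1_window_s
            windowed = estimation_mask & (t1.values > lo) & (t1.values < hi)
            n_terms = len(bias_mod.polynomial_basis_indices(options.poly_order))
            if windowed.sum() >= 10 * n_terms:
                estimation_mask = windowed
            else:
                logger.warning(
                    "subject %s: T1 window leaves %d voxels; estimating bias over the whole brain mask",
                    subject.subject_id,
                    int(windowed.sum()),
                )
        bias_field, _ = bias_mod.estimate_bias(
            m0, estimation_mask, k=options.mixture_k, order=options.poly_order
        )
        m0 = bias_mod.apply_bias(m0, bias_field)

    phantoms = cal.PhantomSet(masks=[masks[f"phantom_{i}"] for i in range(1, 6)])
    vial_means = cal.phantom_means(m0, phantoms)
    tissue_mean = qt.roi_mean(m0.values, masks["brain"] & m0.fit_mask)
    blood = cal.BloodSample.from_map(m0, masks["blood"], subject.hct)
    return SubjectResult(
        subject_id=subject.subject_id,
        m0=m0,
        t1=t1,
        bias_field=bias_field,
        vial_means=vial_means,
        phantom_mean=float(vial_means.mean()),
        tissue_mean=tissue_mean,
        blood=blood,
        age=getattr(subject, "age", None),
        sex=getattr(subject, "sex", None),
    )


def _analysis_rois(subject, result: SubjectResult, options: PipelineOptions) -> tuple[np.ndarray, np.ndarray]:
    """Eroded, center-slice-restricted GM and WM analysis masks."""
    masks = subject.masks
    if options.roi_source == "segment":
        if subject.anatomical is None:
            raise ValueError(f"subject {result.subject_id}: no anatomical volume to segment")
        labels = seg.em_segment(subject.anatomical, masks["brain"], contrast="t1w")
        gm, wm = labels.mask(seg.LABEL_GM), labels.mask(seg.LABEL_WM)
    else:
        gm, wm = masks["gm"], masks["wm"]
    gm = seg.erode_roi(gm, options.erode_px)
    wm = seg.erode_roi(wm, options.erode_px)
    if options.center_slices:
        central = seg.select_center_slices(masks["brain"], options.center_slices)
        keep = central.any(axis=(0, 1))
        gm = gm & keep[None, None, :]
        wm = wm & keep[None, None, :]
    return gm, wm


def quantify_subject(subject, result: SubjectResult, options: PipelineOptions) -> SubjectResult:
    """Second pass: calibration lines, BBPC maps, CBF correction, stats."""
    result.line = cal.fit_phantom_line(result.vial_means)
    result.wc_phantom = cal.normalize_phantom(result.m0, result.line)
    result.wc_hct = cal.normalize_hct(result.m0, result.blood)

    # phantom route measures blood water content off its own calibrated map
    wc_blood_phantom = qt.roi_mean(result.wc_phantom.values, result.blood.mask & result.m0.fit_mask)
    result.bbpc_phantom = qt.compute_bbpc(result.wc_phantom, wc_blood_phantom)
    result.bbpc_hct = qt.compute_bbpc(result.wc_hct, result.blood.wc_blood)

    gm, wm = _analysis_rois(subject, result, options)
    result.gm_roi, result.wm_roi = gm, wm

    stats = {
        "subject_id": result.subject_id,
        "age": result.age,
        "sex": result.sex,
        "delta": result.delta,
        "r_squared_line": result.line.r_squared,
        "bbpc_gm_phantom": qt.roi_mean(result.bbpc_phantom.values, gm),
        "bbpc_wm_phantom": qt.roi_mean(result.bbpc_phantom.values, wm),
        "bbpc_gm_hct": qt.roi_mean(result.bbpc_hct.values, gm),
        "bbpc_wm_hct": qt.roi_mean(result.bbpc_hct.values, wm),
    }
    cbf = getattr(subject, "cbf_uncorrected", None)
    if cbf is not None:
        result.cbf_corrected = qt.correct_cbf(cbf, result.bbpc_phantom, options.assumed_lambda)
        corrected = result.cbf_corrected.values
        stats.update(
            {
                "cbf_gm_uncorrected": qt.roi_mean(cbf.values, gm),
                "cbf_wm_uncorrected": qt.roi_mean(cbf.values, wm),
                "cbf_gm_corrected": qt.roi_mean(corrected, gm),
                "cbf_wm_corrected": qt.roi_mean(corrected, wm),
            }
        )
        try:
            cnr_pair = (qt.contrast_to_noise(cbf.values, gm, wm), qt.contrast_to_noise(corrected, gm, wm))
            stats["cnr_uncorrected"], stats["cnr_corrected"] = cnr_pair
        except ValueError:
            logger.info("subject %s: CNR undefined (zero pooled SD)", result.subject_id)
    result.stats = stats
    return result


def process_cohort(
    subjects: list, options: PipelineOptions | None = None
) -> tuple[list[SubjectResult], cal.RatioRegression | None]:
    """Run the full pipeline over a cohort.

    Pass 1 fits and bias-corrects every subject; the cohort-level ratio
    regression then yields per-subject quadratic error terms which are
    subtracted from brain and blood before calibration and
    quantification in pass 2.  With fewer than 3 subjects the ratio
    correction is skipped (single-subject runs raise only if it was
    explicitly requested).
    """
    options = options or PipelineOptions()
    results = [fit_and_correct(s, options) for s in subjects]

    regression = None
    if options.ratio_correction:
        if len(results) >= 3:
            cohort_triples = [(r.subject_id, r.tissue_mean, r.phantom_mean) for r in results]
            regression = cal.fit_ratio_regression(cohort_triples)
            for subject, r in zip(subjects, results):
                delta = regression.per_subject_error[r.subject_id]
                r.m0, r.blood = cal.apply_error_correction(r.m0, subject.masks["brain"], r.blood, delta)
                r.delta = delta
                r.tissue_mean = qt.roi_mean(r.m0.values, subject.masks["brain"] & r.m0.fit_mask)
        else:
            logger.warning(
                "cohort has %d subject(s); quadratic error correction needs >= 3 and was skipped",
                len(results),
            )

    for subject, r in zip(subjects, results):
        quantify_subject(subject, r, options)
    return results, regression


def cohort_summary(results: list[SubjectResult]) -> dict:
    """Cohort-level statistics table: means, agreement, age regressions."""
    stats = [r.stats for r in results]

    def col(name):
        return np.array([s[name] for s in stats if name in s and s[name] is not None])

    summary: dict = {"n_subjects": len(results)}
    for name in ("bbpc_gm_phantom", "bbpc_wm_phantom", "bbpc_gm_hct", "bbpc_wm_hct"):
        vals = col(name)
        summary[f"{name}_mean"] = float(vals.mean())
        summary[f"{name}_sd"] = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    if len(results) >= 3:
        gm_agree = qt.method_agreement(col("bbpc_gm_phantom"), col("bbpc_gm_hct"))
        wm_agree = qt.method_agreement(col("bbpc_wm_phantom"), col("bbpc_wm_hct"))
        summary.update(
            {
                "agreement_gm_r_squared": gm_agree.r_squared,
                "agreement_gm_bias": gm_agree.bias,
                "agreement_gm_bias_p": gm_agree.bias_p_value,
                "agreement_wm_r_squared": wm_agree.r_squared,
                "agreement_wm_bias": wm_agree.bias,
                "agreement_wm_bias_p": wm_agree.bias_p_value,
            }
        )
    ages = col("age")
    if ages.size >= 3 and np.ptp(ages) > 0 and "cbf_gm_uncorrected" in stats[0]:
        for name, key in (
            ("cbf_gm_uncorrected", "age_slope_cbf_gm"),
            ("cbf_gm_corrected", "age_slope_ccbf_gm"),
        ):
            slope, intercept, p = qt.age_regression(col(name), ages)
            summary[key] = slope
            summary[key.replace("slope", "intercept")] = intercept
            summary[key.replace("slope", "p")] = p
    cnr_u, cnr_c = col("cnr_uncorrected"), col("cnr_corrected")
    if cnr_u.size:
        summary["cnr_uncorrected_mean"] = float(cnr_u.mean())
        summary["cnr_corrected_mean"] = float(cnr_c.mean())
        if np.all(cnr_u != 0):
            summary["cnr_improvement_percent"] = float(np.mean((cnr_c - cnr_u) / np.abs(cnr_u)) * 100.0)
    return summary
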