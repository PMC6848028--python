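"""Synthetic-cohort simulator with known ground truth.

Generates subjects with an ellipsoidal brain (WM core, GM shell, central
CSF), five water-fraction reference vials plus a blood vial above the
head, a smooth multiplicative coil-profile bias field, a per-subject
global gain, an optional gain-dependent inflation of vial signal
(emulating the quadratic vial-intensity nonlinearity some scanners
show), and Rician or Gaussian noise.  Every generated quantity is kept
as ground truth so each pipeline stage can be tested by parameter
recovery.

Generative model per voxel and repetition time:

    S(v, TR) = gain * bias(v) * WC(v) * (1 - exp(-TR / T1(v)))    [+ noise]

The scanner nonlinearity that makes vial intensity grow quadratically
*relative to tissue* with overall image gain is injected as an additive
per-subject deficit ``c * gain * P`` on brain and blood M0 (``P`` the
mean vial M0).  Under this surrogate the tissue/vial ratio is exactly
linear in ``P`` — the model the cohort ratio regression fits — and the
scalar-subtraction correction is its exact inverse, while a
multiplicative vial inflation would cancel out of the BBPC ratio and
leave nothing for the correction to fix.  The
uncorrected CBF map carries the configured age line in GM (it is the
map a scanner quantified with the assumed partition coefficient would
output); the corrected-truth map follows from the true BBPC.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from bbpcmap.bias import evaluate_basis, polynomial_basis_indices
from bbpcmap.calibration import WATER_FRACTIONS, hct_blood_water
from bbpcmap.quantify import BRAIN_DENSITY_G_PER_ML, DEFAULT_ASSUMED_LAMBDA, BBPCMap, CBFMap, WCMap
from bbpcmap.recovery import TRSeries
from bbpcmap.volio import SubjectManifest, VolumeImage, save_cohort_manifest, write_volume


@dataclass
class SimulationConfig:
    """All generative knobs, with defaults matching the target protocol."""

    n_subjects: int = 15
    shape: tuple[int, int, int] = (96, 88, 30)
    voxel_size: tuple[float, float, float] = (1.4, 1.4, 3.0)
    tr_ms: tuple[float, ...] = (125.0, 250.0, 500.0, 1000.0, 2000.0)
    te_ms: float = 1.9
    # tissue truth
    bbpc_gm: float = 0.83  # mL/g, population mean
    bbpc_wm: float = 0.78
    # real cohorts vary around the mean (reported spread ~0.05 mL/g); one
    # shared offset per subject moves GM and WM together, preserving their
    # difference.  Without it the two calibration routes have no common
    # between-subject signal and their agreement R^2 is meaningless.
    bbpc_subject_sd: float = 0.04
    csf_water: float = 0.99
    t1_gm_s: float = 1.3
    t1_wm_s: float = 0.9
    t1_csf_s: float = 3.5
    t1_blood_s: float = 1.6
    t1_phantom_s: float = 1.2
    # subject distributions
    hct_mean: float = 0.45
    hct_sd: float = 0.03
    hct_range: tuple[float, float] = (0.2, 0.7)
    age_range: tuple[float, float] = (5.0, 8.0)
    male_fraction: float = 0.24
    # CBF truth (values as they appear in uncorrected, lambda=0.9 maps)
    cbf_gm_intercept: float = 128.0  # mL/100 g/min at age 0
    cbf_gm_age_slope: float = -7.5  # per year
    cbf_wm_mean: float = 56.0
    # artifacts
    bias_amplitude: float = 0.2  # peak |field - 1| over the brain
    nonlinearity_c: float = 0.002  # tissue/blood deficit per gain unit
    gain_range: tuple[float, float] = (60.0, 140.0)
    snr: float = 50.0  # np.inf disables noise
    noise_model: str = "rician"
    cbf_snr: float = 2.5  # perfusion maps are far noisier than structural ones
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError(f"noise_model must be 'gaussian' or 'rician', got {self.noise_model!r}")
        if self.snr <= 0:
            raise ValueError("snr must be positive (np.inf disables noise)")


@dataclass
class SyntheticTruth:
    """Ground-truth quantities behind one simulated subject."""

    wc_map: WCMap
    bbpc_map: BBPCMap
    bbpc_gm: float
    bbpc_wm: float
    bias_field: np.ndarray
    t1_map: np.ndarray
    m0_map: np.ndarray  # noiseless arbitrary-unit M0 incl. gain, bias, vial inflation
    hct: float
    wc_blood: float
    gain: float
    nonlinearity_c: float
    cbf_truth: CBFMap
    age: float
    sex: int


@dataclass
class SyntheticSubject:
    """One simulated subject: inputs as the pipeline sees them, plus truth."""

    subject_id: str
    tr_series: TRSeries
    cbf_uncorrected: CBFMap
    anatomical: VolumeImage
    masks: dict[str, np.ndarray]
    hct: float
    age: float
    sex: int
    truth: SyntheticTruth


def _ellipsoid(shape: tuple[int, int, int], center: np.ndarray, semi: np.ndarray) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(n, dtype=np.float64) for n in shape], indexing="ij")
    d = sum(((g - c) / s) ** 2 for g, c, s in zip(grids, center, semi))
    return d <= 1.0


def make_geometry(shape: tuple[int, int, int]) -> dict[str, np.ndarray]:
    """Deterministic layout: ellipsoidal brain, vial arc hugging the head.

    Returns masks ``brain, gm, wm, csf, blood, phantom_1..phantom_5``.
    The six vials (five water-fraction references plus the blood sample,
    placed mid-arc) sit on an arc just outside the scalp — close to the
    imaged tissue, as they are taped to the head in practice — and span
    the central 60% of slices.  Vial order 1..5 follows increasing water
    fraction.
    """
    nx, ny, nz = shape
    center = np.array([nx / 2.0, 0.62 * ny, nz / 2.0])
    semi = np.array([0.34 * nx, 0.28 * ny, 0.44 * nz])
    brain = _ellipsoid(shape, center, semi)
    # wavy GM/WM interface: without gyrus-like high-frequency structure the
    # concentric layout is itself a smooth radial pattern, degenerate with a
    # polynomial bias field (the EM correction would soak up tissue contrast)
    grids = np.meshgrid(*[np.arange(n, dtype=np.float64) for n in shape], indexing="ij")
    u = [(g - c) / s for g, c, s in zip(grids, center, semi)]
    phi = np.arctan2(u[1], u[0])
    wobble = 1.0 + 0.2 * np.sin(5.0 * phi + 1.3) * np.cos(2.0 * np.pi * u[2] + 0.7)
    d2 = u[0] ** 2 + u[1] ** 2 + u[2] ** 2
    wm_core = d2 <= (0.62 * wobble) ** 2
    # lateral-ventricle-like CSF and deep gray nuclei inside the WM core
    csf = _ellipsoid(shape, center + np.array([0.22 * semi[0], 0, 0]), semi * 0.24) | _ellipsoid(
        shape, center - np.array([0.22 * semi[0], 0, 0]), semi * 0.24
    )
    csf &= wm_core
    nuclei = _ellipsoid(
        shape, center + np.array([0.30 * semi[0], 0.15 * semi[1], 0]), semi * 0.20
    ) | _ellipsoid(shape, center + np.array([-0.30 * semi[0], 0.15 * semi[1], 0]), semi * 0.20)
    nuclei &= wm_core & ~csf
    gm = (brain & ~wm_core) | nuclei
    wm = wm_core & ~csf & ~nuclei

    radius = max(2.0, 0.032 * nx)
    z_lo, z_hi = int(round(0.20 * nz)), int(round(0.80 * nz))
    # vial centers on a scaled ellipse around the top of the head
    angles = np.deg2rad(np.linspace(25.0, 155.0, 6))
    arc_scale = 1.0 + (radius + 2.0) / min(semi[0], semi[1])
    xx, yy = np.meshgrid(np.arange(nx, dtype=np.float64), np.arange(ny, dtype=np.float64), indexing="ij")
    masks: dict[str, np.ndarray] = {"brain": brain, "gm": gm, "wm": wm, "csf": csf}
    # blood mid-arc (slot 3); references 1..5 fill the remaining slots
    names = ["phantom_1", "phantom_2", "phantom_3", "blood", "phantom_4", "phantom_5"]
    for name, theta in zip(names, angles):
        cx = center[0] + arc_scale * semi[0] * np.cos(theta)
        cy = center[1] - arc_scale * semi[1] * np.sin(theta)
        disk = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius**2
        vol = np.zeros(shape, dtype=bool)
        vol[:, :, z_lo:z_hi] = disk[:, :, None]
        if vol.sum() == 0:
            raise ValueError(f"geometry overflows the grid {shape}; vial {name} is empty")
        masks[name] = vol
    vial_union = masks["blood"] | np.any([masks[f"phantom_{j}"] for j in range(1, 6)], axis=0)
    if (brain & vial_union).any():
        raise ValueError(f"geometry overflows the grid {shape}; vials intersect the brain")
    if sum(int(masks[n].sum()) for n in names) != int(vial_union.sum()):
        raise ValueError(f"geometry overflows the grid {shape}; vials overlap each other")
    return masks


def make_bias_field(
    shape: tuple[int, int, int],
    amplitude: float,
    rng: np.random.Generator,
    reference_mask: np.ndarray,
    order: int = 4,
    degree_decay: float = 0.5,
) -> np.ndarray:
    """Random smooth 4th-order log-polynomial gain field.

    Coefficient scale decays with total degree (coil profiles are
    dominated by low-order structure).  Scaled so the peak log-gain
    magnitude over ``reference_mask`` equals ``log(1 + amplitude)``,
    then normalised to mean 1 over the mask.  ``amplitude = 0`` gives a
    flat field.
    """
    if amplitude == 0:
        return np.ones(shape)
    terms = polynomial_basis_indices(order)
    degrees = np.array([sum(t) for t in terms])
    coef = rng.standard_normal(len(terms)) * degree_decay**degrees
    coef[0] = 0.0  # no global offset; scale is the subject gain's job
    log_field = (evaluate_basis(shape, order) @ coef).reshape(shape)
    peak = np.max(np.abs(log_field[reference_mask]))
    if peak == 0:
        return np.ones(shape)
    log_field *= np.log1p(amplitude) / peak
    fieldvol = np.exp(log_field)
    return fieldvol / fieldvol[reference_mask].mean()


def add_noise(
    volume: np.ndarray,
    snr: float,
    model: str = "rician",
    rng: np.random.Generator | None = None,
    reference_signal: float | None = None,
) -> np.ndarray:
    """Add measurement noise at a given SNR.

    ``sd = reference_signal / snr`` (default reference: mean of the
    volume's positive voxels).  Rician noise takes the magnitude of a
    complex Gaussian perturbation, as in magnitude MR images;
    ``snr = inf`` returns the input unchanged.
    """
    volume = np.asarray(volume, dtype=np.float64)
    if not np.isfinite(snr):
        return volume.copy()
    if snr <= 0:
        raise ValueError("snr must be positive")
    if rng is None:
        rng = np.random.default_rng()
    if reference_signal is None:
        positive = volume[volume > 0]
        reference_signal = float(positive.mean()) if positive.size else 1.0
    sd = reference_signal / snr
    if model == "gaussian":
        return volume + rng.normal(0.0, sd, volume.shape)
    if model == "rician":
        real = volume + rng.normal(0.0, sd, volume.shape)
        imag = rng.normal(0.0, sd, volume.shape)
        return np.hypot(real, imag)
    raise ValueError(f"unknown noise model {model!r}")


def make_subject(
    config: SimulationConfig,
    subject_seed: int | np.random.SeedSequence,
    subject_id: str = "sub-01",
    age: float | None = None,
    sex: int | None = None,
) -> SyntheticSubject:
    """Generate one subject; deterministic given (config, subject_seed)."""
    rng = np.random.default_rng(subject_seed)
    shape = tuple(config.shape)
    masks = make_geometry(shape)

    age = float(rng.uniform(*config.age_range)) if age is None else float(age)
    sex = int(rng.random() < config.male_fraction) if sex is None else int(sex)
    hct = float(np.clip(rng.normal(config.hct_mean, config.hct_sd), *config.hct_range))
    wc_blood = hct_blood_water(hct)
    gain = float(rng.uniform(*config.gain_range))
    bbpc_offset = float(np.clip(rng.normal(0.0, config.bbpc_subject_sd), -2.5 * config.bbpc_subject_sd, 2.5 * config.bbpc_subject_sd)) if config.bbpc_subject_sd > 0 else 0.0
    bbpc_gm_i = config.bbpc_gm + bbpc_offset
    bbpc_wm_i = config.bbpc_wm + bbpc_offset

    # ground-truth water content and T1 per voxel
    wc = np.zeros(shape)
    t1 = np.full(shape, np.inf)
    wc_gm = bbpc_gm_i * wc_blood * BRAIN_DENSITY_G_PER_ML
    wc_wm = bbpc_wm_i * wc_blood * BRAIN_DENSITY_G_PER_ML
    for name, wc_val, t1_val in [
        ("gm", wc_gm, config.t1_gm_s),
        ("wm", wc_wm, config.t1_wm_s),
        ("csf", config.csf_water, config.t1_csf_s),
        ("blood", wc_blood, config.t1_blood_s),
    ]:
        wc[masks[name]] = wc_val
        t1[masks[name]] = t1_val
    for i, wf in enumerate(WATER_FRACTIONS, start=1):
        wc[masks[f"phantom_{i}"]] = wf
        t1[masks[f"phantom_{i}"]] = config.t1_phantom_s

    bias = make_bias_field(shape, config.bias_amplitude, rng, masks["brain"])

    m0 = gain * bias * wc
    # gain-dependent vial-vs-tissue nonlinearity (see module docstring):
    # brain and blood lose c * gain * P of intrinsic signal, with P the
    # mean vial M0.  The deficit sits inside the coil-profile
    # multiplication (it is a scanner-gain effect), so the observed image
    # stays exactly multiplicative in the bias field.
    vials = np.any([masks[f"phantom_{i}"] for i in range(1, 6)], axis=0)
    if config.nonlinearity_c != 0.0:
        p_mean = float((gain * wc)[vials].mean())
        deficit = config.nonlinearity_c * gain * p_mean
        shift_mask = masks["brain"] | masks["blood"]
        m0[shift_mask] = m0[shift_mask] - bias[shift_mask] * deficit
        if np.any(m0[shift_mask] <= 0):
            raise ValueError("nonlinearity deficit drove tissue M0 nonpositive; reduce c or gain")

    active = t1 < np.inf
    volumes = []
    signal_ref = None
    for tr in config.tr_ms:
        signal = np.zeros(shape)
        signal[active] = m0[active] * (1.0 - np.exp(-(tr / 1000.0) / t1[active]))
        volumes.append(signal)
    # noise sd referenced to mean in-brain signal at the longest TR
    signal_ref = float(volumes[-1][masks["brain"]].mean())
    noisy = [
        VolumeImage(
            add_noise(s, config.snr, config.noise_model, rng, signal_ref),
            config.voxel_size,
            units="a.u.",
        )
        for s in volumes
    ]
    series = TRSeries(noisy, list(config.tr_ms), te_ms=config.te_ms)

    # CBF: uncorrected map carries the configured GM age line; truth is
    # what that map becomes under the true partition coefficient
    bbpc_vol = np.full(shape, np.nan)
    bbpc_vol[masks["brain"]] = wc[masks["brain"]] / (wc_blood * BRAIN_DENSITY_G_PER_ML)
    cbf_unc = np.zeros(shape)
    cbf_unc[masks["gm"]] = config.cbf_gm_intercept + config.cbf_gm_age_slope * age
    cbf_unc[masks["wm"]] = config.cbf_wm_mean
    cbf_truth_vals = np.zeros(shape)
    inb = masks["gm"] | masks["wm"]
    cbf_truth_vals[inb] = cbf_unc[inb] / DEFAULT_ASSUMED_LAMBDA * bbpc_vol[inb]
    cbf_snr = config.cbf_snr if np.isfinite(config.snr) else np.inf
    cbf_unc_noisy = add_noise(cbf_unc, cbf_snr, "gaussian", rng, float(cbf_unc[inb].mean()))
    cbf_unc_noisy[~inb] = 0.0

    # T1-weighted-like anatomical: WM bright, GM mid, CSF dark
    anat = np.zeros(shape)
    anat[masks["wm"]] = 1.0
    anat[masks["gm"]] = 0.7
    anat[masks["csf"]] = 0.3
    anat = add_noise(anat, max(config.snr, 20.0), "gaussian", rng, 1.0)
    anat[~masks["brain"]] = 0.0

    truth = SyntheticTruth(
        wc_map=WCMap(wc, config.voxel_size),
        bbpc_map=BBPCMap(bbpc_vol, wc_blood_used=wc_blood, voxel_size=config.voxel_size),
        bbpc_gm=bbpc_gm_i,
        bbpc_wm=bbpc_wm_i,
        bias_field=bias,
        t1_map=np.where(active, t1, np.nan),
        m0_map=m0,
        hct=hct,
        wc_blood=wc_blood,
        gain=gain,
        nonlinearity_c=config.nonlinearity_c,
        cbf_truth=CBFMap(cbf_truth_vals, voxel_size=config.voxel_size),
        age=age,
        sex=sex,
    )
    return SyntheticSubject(
        subject_id=subject_id,
        tr_series=series,
        cbf_uncorrected=CBFMap(cbf_unc_noisy, voxel_size=config.voxel_size),
        anatomical=VolumeImage(anat, config.voxel_size, units="a.u."),
        masks=masks,
        hct=hct,
        age=age,
        sex=sex,
        truth=truth,
    )


def make_cohort(config: SimulationConfig) -> list[SyntheticSubject]:
    """Generate ``config.n_subjects`` subjects from one cohort seed.

    Each subject gets an independent child seed (splittable scheme), so
    any subject can be regenerated in isolation from its spawn key.
    """
    root = np.random.SeedSequence(config.seed)
    subject_seeds = root.spawn(config.n_subjects)
    meta_rng = np.random.default_rng(root.spawn(1)[0])
    ages = meta_rng.uniform(*config.age_range, size=config.n_subjects)
    sexes = (meta_rng.random(config.n_subjects) < config.male_fraction).astype(int)
    return [
        make_subject(config, seed, subject_id=f"sub-{i + 1:02d}", age=ages[i], sex=int(sexes[i]))
        for i, seed in enumerate(subject_seeds)
    ]


def write_cohort(cohort: list[SyntheticSubject], out_dir: str | Path) -> Path:
    """Write a cohort to disk as NIfTI volumes plus a YAML manifest.

    Returns the manifest path; the manifest is directly usable by the
    CLI pipeline commands.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifests = []
    truth_rows = []
    for subj in cohort:
        sdir = out_dir / subj.subject_id
        sdir.mkdir(exist_ok=True)
        tr_paths = []
        for tr, vol in zip(subj.tr_series.tr_ms, subj.tr_series.volumes):
            p = sdir / f"tr_{int(tr)}ms.nii"
            write_volume(p, vol)
            tr_paths.append(str(p))
        mask_paths = {}
        for name, mask in subj.masks.items():
            p = sdir / f"mask_{name}.nii"
            write_volume(p, VolumeImage(mask.astype(np.float64), vol.voxel_size))
            mask_paths[name] = str(p)
        cbf_path = sdir / "cbf_uncorrected.nii"
        write_volume(cbf_path, VolumeImage(subj.cbf_uncorrected.values, vol.voxel_size))
        anat_path = sdir / "anatomical.nii"
        write_volume(anat_path, subj.anatomical)
        for truth_name in ("wc_map", "bbpc_map"):
            write_volume(sdir / f"truth_{truth_name}.nii", VolumeImage(getattr(subj.truth, truth_name).values, vol.voxel_size))
        write_volume(sdir / "truth_bias_field.nii", VolumeImage(subj.truth.bias_field, vol.voxel_size))
        manifests.append(
            SubjectManifest(
                subject_id=subj.subject_id,
                tr_series_paths=tr_paths,
                tr_values_ms=list(subj.tr_series.tr_ms),
                mask_paths=mask_paths,
                cbf_path=str(cbf_path),
                anatomical_path=str(anat_path),
                hct=subj.hct,
                age_years=subj.age,
                sex=subj.sex,
            )
        )
        truth_rows.append(
            {
                "subject_id": subj.subject_id,
                "hct": subj.hct,
                "wc_blood": subj.truth.wc_blood,
                "bbpc_gm": subj.truth.bbpc_gm,
                "bbpc_wm": subj.truth.bbpc_wm,
                "gain": subj.truth.gain,
                "age": subj.age,
                "sex": subj.sex,
                "nonlinearity_c": subj.truth.nonlinearity_c,
            }
        )
    manifest_path = out_dir / "cohort.yaml"
    save_cohort_manifest(manifest_path, manifests)
    import pandas as pd

    pd.DataFrame(truth_rows).to_csv(out_dir / "truth.csv", index=False)
    return manifest_path


def noiseless(config: SimulationConfig) -> SimulationConfig:
    """Copy of a config with noise, bias and vial nonlinearity disabled."""
    return replace(config, snr=np.inf, bias_amplitude=0.0, nonlinearity_c=0.0)
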