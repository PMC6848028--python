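# bbpcmap

Voxel-wise mapping of the brain–blood partition coefficient (BBPC) of
water from a multi-TR spoiled gradient-echo series, with two calibration
routes and voxel-wise correction of arterial-spin-labeling CBF maps.

The pipeline:

1. **Recovery fit** — fit `S = M0·(1 − exp(−TR/T1))` voxel-wise across
   the TR series (vectorised variable projection), producing M0 (a.u.)
   and T1 (s) maps.
2. **Bias-field correction** — remove smooth multiplicative coil-profile
   inhomogeneity by EM with a 4th-order 3-D Legendre polynomial field
   and a 6-component Gaussian mixture (plus a uniform outlier class).
   Reference vials and blood are excluded from estimation; the
   correction is applied to the whole volume.
3. **Calibration to absolute water content** — either
   * *phantom route*: an OLS line through the five heavy-water/distilled-
     water reference vials (60–100% water), with a cohort-level
     quadratic-error correction (tissue/vial ratio regressed on vial
     mean; the per-subject error term is subtracted from brain and blood
     M0 before normalisation), or
   * *hematocrit route*: rescale so the blood-vial mean matches
     `WC_blood = −0.271·Hct + 0.912`.
4. **BBPC** — `BBPC(v) = WC_brain(v) / (WC_blood · 1.04 g/mL)`.
5. **CBF correction** — `cCBF(v) = CBF(v) / 0.9 · BBPC(v)` for maps
   quantified with the common assumed coefficient of 0.9 mL/g.
6. **Statistics** — eroded, center-slice-restricted GM/WM ROI means,
   gray/white contrast-to-noise ratio (pooled SD), Bland–Altman method
   agreement, and age regressions.

A synthetic-cohort simulator (`bbpcmap.synth`) generates subjects with
known ground truth — wavy-interface brain geometry, a reference-vial arc,
smooth polynomial bias fields, per-subject gain and scanner nonlinearity,
Rician noise — so every stage is verified by parameter recovery.

## Test

```sh
python -m pytest -q tests/
```

The suite includes `tests/test_acceptance.py`, which re-derives every
acceptance property (noiseless closed loop, grid-search fit oracle,
bias-field recovery, cohort parameter recovery, correction efficacy,
method agreement, CNR) from freshly simulated data.

## CLI

```sh
# simulate a cohort with ground truth + manifest
bbpcmap --seed 7 --out-dir cohort simulate --n 15 --snr 50

# full pipeline over a cohort manifest -> subject/cohort report CSVs
bbpcmap --out-dir results report --manifest cohort/cohort.yaml

# individual stages
bbpcmap --out-dir out fit --manifest cohort/cohort.yaml --subject sub-01
bbpcmap --out-dir out bias-correct --m0 out/sub-01_m0.nii --mask cohort/sub-01/mask_gm.nii
bbpcmap --out-dir out calibrate --m0 out/sub-01_m0_corrected.nii \
        --manifest cohort/cohort.yaml --subject sub-01 --method phantom
bbpcmap --out-dir out bbpc --wc out/sub-01_wc_phantom.nii --hct 0.45
bbpcmap --out-dir out correct-cbf --cbf cohort/sub-01/cbf_uncorrected.nii \
        --bbpc out/sub-01_wc_phantom_bbpc.nii
bbpcmap --out-dir out segment --volume cohort/sub-01/anatomical.nii \
        --mask cohort/sub-01/mask_brain.nii --contrast t1w
```

All volumes are NIfTI-1/2; manifests are YAML; tabular outputs are CSV
with a header row.

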