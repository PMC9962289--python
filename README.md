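# aptasl

Quantification and prognostic analysis of paired pH-weighted (APT) and
perfusion (pCASL) MR images of stroke lesions:

* **MTRasym maps** from a Z-spectrum stack (saturated images at ±3.5 ppm
  plus an unsaturated reference): `(s(−3.5) − s(+3.5)) / s0`, with voxels
  having `s0 ≤ 0` flagged invalid rather than imputed.
* **CBF maps** from a single-PLD pCASL control/label pair, with the
  equilibrium arterial magnetization calibrated from a ventricular CSF
  signal (`M0a = Scsf / (λa · (1 − exp(−TR/T1csf)))`). All model
  constants (PLD, TE, T1a, T2a, α, ρ, λa, unit scale) are configurable;
  negative ΔM is kept as negative CBF.
* **ROI histogram biomarkers**: ten first-order statistics (mean, max,
  min, kurtosis, skewness, 10/25/50/75/90th percentiles) on a lesion ROI
  and a mirrored contralateral ROI, combined into signed
  lesion-minus-contralateral biomarkers (`rAPT_*` in %, `rASL_*` in
  mL/100 g/min). rAPT uses the single lesion-maximal slice (2D APT
  acquisition); rASL uses the full 3D mask. Maps can be resampled to a
  reference (DWI) grid with conservative validity propagation.
* **Prognosis statistics**: per-feature Mann–Whitney U screening (exact
  p for small tie-free samples, tie/continuity-corrected normal
  approximation otherwise), 10-fold-CV LASSO marker selection, an
  unpenalized logistic combination, and ROC evaluation (rank-identity
  AUC, DeLong SE, logit-scale 95% CI, Youden-index cutoff), plus a
  demographic cohort summary with group-difference tests.
* **Synthetic data**: image phantoms built by algebraically inverting
  the quantification equations (noiseless quantification recovers the
  programmed MTRasym/CBF to machine precision) and feature-level
  cohorts sampled from per-group Gaussians whose defaults follow
  published group means/SDs (18 favorable vs 40 unfavorable outcomes).

> **Note on the M0a calibration.** The published form of the CSF
> calibration equation is typographically garbled; this package
> implements the standard saturation-recovery reading shown above and
> documents it in `aptasl/asl.py`.

## CLI

```bash
aptasl simulate  --outdir out            # phantom NIfTI set + cohort.csv
aptasl quantify  out/phantom --outdir out/maps
aptasl features  out/maps/mtrasym.nii out/maps/cbf.nii out/phantom/lesion_mask.nii
aptasl analyze   out/cohort.csv --outdir out/analysis
aptasl full-run  --outdir out/full
```

All commands accept `--config config.yaml` (schema-validated; unknown
keys rejected — see `aptasl/config.py` for every field) and `--quiet`.
Exit codes: 0 success, 2 config error, 3 data error. Reports embed the
full config, its SHA-256 hash, the seed and the package version, and
identical configs reproduce byte-identical outputs.

## Layout

| Module | Contents |
| --- | --- |
| `aptasl.grids` | `ParametricMap`, `ZSpectrumStack`, `AslAcquisition`, `AslQuantParams`, NIfTI I/O |
| `aptasl.apt` | MTRasym map computation, lesion-maximal slice selection |
| `aptasl.asl` | M0a calibration and CBF quantification |
| `aptasl.features` | resampling, histogram features, relative biomarkers |
| `aptasl.stats` | Mann–Whitney, LASSO selection, logistic combination, ROC/DeLong, cohort summary |
| `aptasl.synthetic` | phantom and cohort generators with ground truth |
| `aptasl.config` / `aptasl.cli` | validated configuration and the `aptasl` command |
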