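"""Synthetic phantoms and feature-level cohorts with known ground truth.

Two generators back the test pyramid:

* :func:`generate_phantom_subject` builds image-level inputs (Z-spectrum
  stack, pCASL control/label pair, lesion mask) by algebraically
  inverting the quantification equations, so that noiseless
  quantification recovers the programmed MTRasym and CBF exactly.
* :func:`generate_feature_cohort` samples per-subject relative-feature
  rows (10 rAPT + 10 rASL statistics) from configurable per-group
  Gaussians, defaulting to published group means/SDs for a favorable
  (n=18) versus unfavorable (n=40) outcome split.

All randomness flows from one integer seed through counter-based
per-subject streams, so cohorts are reproducible regardless of
generation order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd

from .asl import cbf_scale_factor, compute_m0a
from .features import STAT_NAMES, feature_columns
from .grids import AslAcquisition, AslQuantParams, ZSpectrumStack

__all__ = [
    "PhantomSpec",
    "PhantomSubject",
    "GroupFeatureParams",
    "generate_phantom_subject",
    "mirror_mask",
    "generate_feature_cohort",
    "write_phantom",
]

# unsaturated reference amplitude (a.u.) used by the forward model
_S0_LEVEL = 1000.0
# saturated baseline as a fraction of s0 (direct water saturation floor)
_SAT_FRACTION = 0.7
# CSF calibration signal (a.u.) and perfusion baseline fraction of M0a
_SCSF_LEVEL = 760.0
_PERFUSION_BASE = 0.3


@dataclass
class PhantomSpec:
    """Geometry, contrast and noise of a single synthetic subject.

    The spherical lesion must lie entirely in the left half of the grid
    (indices below ``grid_shape[0] // 2`` along axis 0) so that
    mirroring across the midline yields a disjoint contralateral ROI.
    """

    grid_shape: tuple[int, int, int] = (32, 32, 8)
    voxel_spacing: tuple[float, float, float] = (2.0, 2.0, 4.0)
    lesion_center: tuple[float, float, float] = (8.0, 16.0, 4.0)  # voxels
    lesion_radius: float = 8.0  # mm
    lesion_mtrasym: float = 0.03
    background_mtrasym: float = 0.0
    lesion_cbf: float = 20.0
    background_cbf: float = 45.0
    noise_sd: float = 0.0  # fraction of s0
    seed: int = 0
    asl_params: AslQuantParams = field(default_factory=AslQuantParams)

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3:
            raise ValueError("grid_shape must be a voxel triple")
        if self.grid_shape[0] % 2 != 0:
            raise ValueError("grid_shape[0] must be even to define a midline")
        if self.lesion_radius <= 0:
            raise ValueError("lesion_radius must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        center_mm = np.asarray(self.lesion_center) * np.asarray(self.voxel_spacing)
        extent_mm = (np.asarray(self.grid_shape) - 1) * np.asarray(self.voxel_spacing)
        if np.any(center_mm - self.lesion_radius < 0) or np.any(
            center_mm + self.lesion_radius > extent_mm
        ):
            raise ValueError(
                f"lesion (center {self.lesion_center} vox, radius "
                f"{self.lesion_radius} mm) extends outside the grid"
            )
        midline_mm = (self.grid_shape[0] / 2 - 0.5) * self.voxel_spacing[0]
        if center_mm[0] + self.lesion_radius >= midline_mm:
            raise ValueError(
                "lesion crosses the midline; it must lie entirely in the "
                "left half of the grid so the mirrored ROI is disjoint"
            )

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag([*self.voxel_spacing, 1.0]).astype(float)
        return aff

    def lesion_mask(self) -> np.ndarray:
        spacing = np.asarray(self.voxel_spacing)
        grids = np.indices(self.grid_shape, dtype=float)
        dist2 = sum(
            ((grids[i] - self.lesion_center[i]) * spacing[i]) ** 2 for i in range(3)
        )
        mask = dist2 <= self.lesion_radius**2
        if not mask.any():
            raise ValueError("lesion radius smaller than half a voxel: empty mask")
        return mask


@dataclass
class PhantomSubject:
    """One generated subject: raw inputs plus ground truth for checks."""

    zspec: ZSpectrumStack
    asl: AslAcquisition
    lesion_mask: np.ndarray
    truth_mtrasym: np.ndarray
    truth_cbf: np.ndarray
    spec: PhantomSpec


def generate_phantom_subject(spec: PhantomSpec) -> PhantomSubject:
    """Forward-simulate raw signals whose quantification recovers ``spec``.

    The Z-spectrum stack is built so the MTRasym formula gives exactly
    the programmed fractions before noise; the control-label difference
    is the programmed CBF divided by the quantification scale factor, so
    the CBF equation inverts exactly.  Gaussian noise of SD
    ``noise_sd * s0`` is added to every raw image (never to derived
    maps).  Same seed, same spec: bit-identical output.
    """
    rng = np.random.default_rng([spec.seed, 0])
    shape = spec.grid_shape
    affine = spec.affine
    lesion = spec.lesion_mask()

    truth_mtr = np.where(lesion, spec.lesion_mtrasym, spec.background_mtrasym).astype(float)
    truth_cbf = np.where(lesion, spec.lesion_cbf, spec.background_cbf).astype(float)

    # APT forward model: s0 flat, s(+3.5) a flat saturated floor, and
    # s(-3.5) raised by mtrasym * s0 so the asymmetry quotient is exact.
    s0 = np.full(shape, _S0_LEVEL)
    s_pos = _SAT_FRACTION * s0
    s_neg = s_pos + truth_mtr * s0

    # ASL forward model: invert CBF = scale * dM.
    m0a = compute_m0a(_SCSF_LEVEL, spec.asl_params)
    scale = cbf_scale_factor(spec.asl_params, m0a)
    delta_m = truth_cbf / scale
    label = np.full(shape, _PERFUSION_BASE * m0a)
    control = label + delta_m

    if spec.noise_sd > 0:
        sd = spec.noise_sd * _S0_LEVEL
        s_neg = s_neg + rng.normal(0.0, sd, shape)
        s_pos = s_pos + rng.normal(0.0, sd, shape)
        s0 = s0 + rng.normal(0.0, sd, shape)
        control = control + rng.normal(0.0, sd, shape)
        label = label + rng.normal(0.0, sd, shape)

    zspec = ZSpectrumStack(signals={-3.5: s_neg, 3.5: s_pos}, s0=s0, affine=affine)
    asl = AslAcquisition(
        control=control, label=label, scsf=_SCSF_LEVEL, params=spec.asl_params, affine=affine
    )
    return PhantomSubject(
        zspec=zspec,
        asl=asl,
        lesion_mask=lesion,
        truth_mtrasym=truth_mtr,
        truth_cbf=truth_cbf,
        spec=spec,
    )


def mirror_mask(mask: np.ndarray, axis: int = 0) -> np.ndarray:
    """Reflect a binary mask across the grid midline along ``axis``.

    Automates contralateral ROI placement: a lesion mask in one
    hemisphere maps to the homologous region of the other.  The grid
    must have even extent along ``axis`` so the midline falls between
    voxels; voxel count is preserved and the operation is an involution.
    """
    arr = np.asarray(mask)
    uniq = np.unique(arr)
    if not np.all(np.isin(uniq, (0, 1))):
        raise ValueError(f"mask must be binary, found values {uniq[:5]}")
    if arr.shape[axis] % 2 != 0:
        raise ValueError(
            f"axis {axis} has odd extent {arr.shape[axis]}; no inter-voxel midline"
        )
    return np.flip(arr.astype(bool), axis=axis)


# Published per-group relative-feature distributions (mean, SD) used as
# cohort defaults: favorable outcome group first, then unfavorable.
_DEFAULT_GROUP_STATS: dict[str, tuple[float, float, float, float]] = {
    "rAPT_mean": (0.14, 0.68, 0.21, 0.73),
    "rAPT_max": (-0.39, 1.70, -1.34, 7.91),
    "rAPT_min": (0.46, 1.26, 0.89, 2.37),
    "rAPT_kurtosis": (-0.59, 1.62, 0.23, 2.84),
    "rAPT_skewness": (-0.17, 0.95, -0.03, 1.12),
    "rAPT_p10": (0.26, 0.86, 0.48, 1.05),
    "rAPT_p25": (0.17, 0.63, 0.38, 0.73),
    "rAPT_p50": (0.18, 0.72, 0.32, 0.76),
    "rAPT_p75": (0.08, 0.93, 0.11, 0.80),
    "rAPT_p90": (0.07, 1.17, -0.22, 2.21),
    "rASL_mean": (27.45, 36.55, -7.86, 39.80),
    "rASL_max": (30.61, 36.44, -11.55, 79.45),
    "rASL_min": (18.94, 30.58, -6.60, 12.58),
    "rASL_kurtosis": (-0.11, 0.49, -0.11, 0.78),
    "rASL_skewness": (-0.25, 0.62, 0.06, 0.77),
    "rASL_p10": (21.72, 31.83, -9.48, 14.95),
    "rASL_p25": (25.56, 37.41, -10.73, 17.93),
    "rASL_p50": (28.25, 39.63, -7.91, 37.39),
    "rASL_p75": (29.63, 38.30, -5.57, 65.93),
    "rASL_p90": (31.04, 35.69, -8.42, 73.87),
}


@dataclass
class GroupFeatureParams:
    """Per-feature Gaussian parameters of the two outcome groups.

    ``stats`` maps each feature column name to
    ``(mean_favorable, sd_favorable, mean_unfavorable, sd_unfavorable)``.
    Features within a family can be given a common pairwise correlation
    (``correlation``); the default of 0 samples them independently.

    Zero SDs are rejected unless ``allow_zero_sd`` is set (a degenerate
    configuration useful only for determinism tests).
    """

    stats: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_GROUP_STATS)
    )
    n_favorable: int = 18
    n_unfavorable: int = 40
    correlation: float = 0.0
    allow_zero_sd: bool = False

    def __post_init__(self) -> None:
        if self.n_favorable < 2 or self.n_unfavorable < 2:
            raise ValueError("each outcome group needs at least 2 subjects")
        if not -0.99 < self.correlation < 1.0:
            raise ValueError("correlation must lie in (-0.99, 1.0)")
        for name, (m_f, sd_f, m_u, sd_u) in self.stats.items():
            if (sd_f <= 0 or sd_u <= 0) and not self.allow_zero_sd:
                raise ValueError(f"feature {name!r} has a non-positive SD")
            if (sd_f < 0 or sd_u < 0):
                raise ValueError(f"feature {name!r} has a negative SD")

    @property
    def feature_names(self) -> list[str]:
        return list(self.stats)


def _family_blocks(names: list[str]) -> list[list[int]]:
    """Group feature indices by their family prefix (before '_')."""
    blocks: dict[str, list[int]] = {}
    for i, name in enumerate(names):
        blocks.setdefault(name.split("_")[0], []).append(i)
    return list(blocks.values())


def generate_feature_cohort(params: GroupFeatureParams, seed: int) -> pd.DataFrame:
    """Sample a per-subject feature table with a binary outcome column.

    Returns a DataFrame with columns ``subject_id``, ``outcome`` (0 =
    favorable, 1 = unfavorable) and the configured feature columns.
    Each subject is drawn from its own counter-based substream of
    ``seed``, so the table is reproducible row by row.
    """
    names = params.feature_names
    p = len(names)
    blocks = _family_blocks(names)

    rows = []
    subject_index = 0
    for outcome, n in ((0, params.n_favorable), (1, params.n_unfavorable)):
        means = np.array([params.stats[f][0 if outcome == 0 else 2] for f in names])
        sds = np.array([params.stats[f][1 if outcome == 0 else 3] for f in names])
        for _ in range(n):
            rng = np.random.default_rng([seed, subject_index])
            z = rng.standard_normal(p)
            if params.correlation != 0.0:
                x = np.array(z)
                for idx in blocks:
                    k = len(idx)
                    corr = np.full((k, k), params.correlation)
                    np.fill_diagonal(corr, 1.0)
                    chol = np.linalg.cholesky(corr)
                    x[idx] = chol @ z[idx]
                z = x
            values = means + sds * z
            rows.append(
                {"subject_id": f"S{subject_index + 1:03d}", "outcome": outcome,
                 **dict(zip(names, values))}
            )
            subject_index += 1
    return pd.DataFrame(rows, columns=["subject_id", "outcome", *names])


def default_cohort_columns() -> list[str]:
    """Documented cohort CSV header: id, outcome, rAPT then rASL stats."""
    return ["subject_id", "outcome", *feature_columns("rAPT"), *feature_columns("rASL")]


def write_phantom(subject: PhantomSubject, outdir) -> dict[str, str]:
    """Write one phantom subject as NIfTI volumes plus a JSON sidecar.

    Returns the mapping of artifact name to file path.  The sidecar
    records the generating spec and scalar ground truth; ground-truth
    maps are written as volumes for voxelwise comparison.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    aff = subject.spec.affine

    def _save(name: str, data: np.ndarray) -> str:
        path = outdir / f"{name}.nii"
        nib.Nifti1Image(np.asarray(data, dtype=np.float64), aff).to_filename(str(path))
        return str(path)

    paths = {
        "s_neg": _save("zspec_neg3p5ppm", subject.zspec.offset(-3.5)),
        "s_pos": _save("zspec_pos3p5ppm", subject.zspec.offset(3.5)),
        "s0": _save("zspec_s0", subject.zspec.s0),
        "asl_control": _save("asl_control", subject.asl.control),
        "asl_label": _save("asl_label", subject.asl.label),
        "lesion_mask": _save("lesion_mask", subject.lesion_mask.astype(np.float64)),
        "truth_mtrasym": _save("truth_mtrasym", subject.truth_mtrasym),
        "truth_cbf": _save("truth_cbf", subject.truth_cbf),
    }
    spec = subject.spec
    sidecar = {
        "offsets_ppm": [-3.5, 3.5],
        "scsf": subject.asl.scsf,
        "grid_shape": list(spec.grid_shape),
        "voxel_spacing": list(spec.voxel_spacing),
        "lesion_center": list(spec.lesion_center),
        "lesion_radius": spec.lesion_radius,
        "lesion_mtrasym": spec.lesion_mtrasym,
        "background_mtrasym": spec.background_mtrasym,
        "lesion_cbf": spec.lesion_cbf,
        "background_cbf": spec.background_cbf,
        "noise_sd": spec.noise_sd,
        "seed": spec.seed,
        "files": paths,
    }
    sidecar_path = outdir / "ground_truth.json"
    sidecar_path.write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    paths["sidecar"] = str(sidecar_path)
    return paths
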