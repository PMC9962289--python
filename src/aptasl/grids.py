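"""Core voxel-grid data types shared by the quantification stages.

All volumes are plain :class:`numpy.ndarray` grids with an accompanying
4x4 voxel-to-world affine (NIfTI convention).  A :class:`ParametricMap`
additionally carries a validity mask: quantification never imputes bad
voxels, it flags them so downstream ROI statistics can exclude them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np

__all__ = [
    "ParametricMap",
    "ZSpectrumStack",
    "AslQuantParams",
    "AslAcquisition",
    "load_map",
    "save_map",
]

#: units tag for MTRasym maps (dimensionless fraction)
UNITS_FRACTION = "fraction"
#: units tag for CBF maps
UNITS_CBF = "mL/100 g/min"


def _as_affine(affine) -> np.ndarray:
    aff = np.asarray(affine, dtype=float)
    if aff.shape != (4, 4):
        raise ValueError(f"affine must be 4x4, got shape {aff.shape}")
    return aff


@dataclass
class ParametricMap:
    """A voxel grid of quantified values with units and a validity mask.

    Parameters
    ----------
    values : ndarray
        Quantified voxel values.  Entries outside ``valid`` are
        meaningless and must not enter any statistic.
    units : str
        ``"fraction"`` for MTRasym, ``"mL/100 g/min"`` for CBF.
    affine : ndarray, shape (4, 4)
        Voxel-to-world transform.
    valid : ndarray of bool
        True where the value is trustworthy.
    """

    values: np.ndarray
    units: str
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.affine = _as_affine(self.affine)
        if self.valid is None:
            self.valid = np.ones(self.values.shape, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.values.shape:
                raise ValueError("valid mask shape must match values shape")
        if not self.units:
            raise ValueError("units tag is required")
        if not np.all(np.isfinite(self.values[self.valid])):
            raise ValueError("non-finite values inside the validity mask")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    @property
    def spacing(self) -> np.ndarray:
        """Voxel spacing in mm, from the affine column norms."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def with_values(self, values: np.ndarray, valid: np.ndarray | None = None) -> "ParametricMap":
        return replace(self, values=values, valid=self.valid if valid is None else valid)


@dataclass
class ZSpectrumStack:
    """Co-registered saturated images keyed by offset (ppm) plus the
    unsaturated reference ``s0``.

    ``signals`` maps a signed ppm offset to a voxel grid; the stack used
    for MTRasym must contain both -3.5 and +3.5 ppm.
    """

    signals: dict[float, np.ndarray]
    s0: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.s0 = np.asarray(self.s0, dtype=float)
        self.affine = _as_affine(self.affine)
        self.signals = {float(k): np.asarray(v, dtype=float) for k, v in self.signals.items()}
        for off, vol in self.signals.items():
            if vol.shape != self.s0.shape:
                raise ValueError(
                    f"signal at {off:+g} ppm has shape {vol.shape}, expected {self.s0.shape}"
                )

    @property
    def shape(self) -> tuple[int, ...]:
        return self.s0.shape

    def offset(self, ppm: float) -> np.ndarray:
        """Return the saturated image at ``ppm``, erroring by name if absent."""
        key = float(ppm)
        if key not in self.signals:
            raise KeyError(
                f"Z-spectrum stack has no offset at {ppm:+g} ppm "
                f"(available: {sorted(self.signals)})"
            )
        return self.signals[key]


@dataclass
class AslQuantParams:
    """Constants of the single-PLD pCASL quantification model.

    Times are milliseconds.  ``unit_scale`` converts the raw quotient to
    mL/100 g/min; the default 6000 is the usual seconds-to-minutes and
    grams-to-100-grams factor.  ``lambda_a`` is the volume of water per
    mL of arterial blood used in the CSF calibration of M0a.

    ``labeling_duration`` is recorded for provenance; the bolus term
    ``(1 - exp(-tau/T1a))`` is only applied when ``use_bolus_term`` is
    set, since the base model omits it.
    """

    w: float = 2000.0                 # post-labeling delay, ms
    TE: float = 13.58                 # echo time, ms
    TR: float = 5500.0                # repetition time, ms
    labeling_duration: float = 1800.0  # ms, provenance (bolus term opt-in)
    T1a: float = 1650.0               # T1 of arterial blood, ms
    T2a: float = 150.0                # T2 of arterial blood, ms
    alpha: float = 0.85               # labeling efficiency
    rho: float = 1.0                  # brain tissue density, g/mL
    lambda_a: float = 0.76            # water volume per mL arterial blood
    T1csf: float = 4300.0             # ms
    unit_scale: float = 6000.0        # converts to mL/100 g/min
    use_bolus_term: bool = False

    def __post_init__(self) -> None:
        for name in ("w", "TE", "TR", "labeling_duration", "T1a", "T2a", "T1csf"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if not 0 < self.alpha <= 1:
            raise ValueError(f"alpha must lie in (0, 1], got {self.alpha}")
        if self.rho <= 0 or self.lambda_a <= 0 or self.unit_scale <= 0:
            raise ValueError("rho, lambda_a and unit_scale must be positive")


@dataclass
class AslAcquisition:
    """A pCASL control/label pair with its CSF calibration signal."""

    control: np.ndarray
    label: np.ndarray
    scsf: float
    params: AslQuantParams = field(default_factory=AslQuantParams)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.control = np.asarray(self.control, dtype=float)
        self.label = np.asarray(self.label, dtype=float)
        self.affine = _as_affine(self.affine)
        if self.control.shape != self.label.shape:
            raise ValueError(
                f"control shape {self.control.shape} != label shape {self.label.shape}"
            )
        if self.scsf <= 0:
            raise ValueError(f"Scsf must be positive, got {self.scsf}")

    @property
    def delta_m(self) -> np.ndarray:
        """Control minus label difference signal."""
        return self.control - self.label


def load_map(path, units: str) -> ParametricMap:
    """Read a NIfTI volume into a :class:`ParametricMap`.

    NaN voxels are flagged invalid rather than propagated.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    valid = np.isfinite(data)
    data = np.where(valid, data, 0.0)
    return ParametricMap(values=data, units=units, affine=img.affine, valid=valid)


def save_map(pmap: ParametricMap, path) -> None:
    """Write a :class:`ParametricMap` as NIfTI, invalid voxels as NaN."""
    data = np.where(pmap.valid, pmap.values, np.nan)
    nib.Nifti1Image(data.astype(np.float64), pmap.affine).to_filename(str(path))
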