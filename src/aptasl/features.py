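"""First-order histogram features on ROIs and relative biomarkers.

The lesion ROI and its contralateral control are summarised by ten
first-order statistics (mean, max, min, kurtosis, skewness and the
10/25/50/75/90th percentiles); the relative biomarker of a subject is
the statistic-by-statistic lesion-minus-contralateral difference
(``rAPT`` for MTRasym maps, ``rASL`` for CBF maps).

Conventions (isolated here so they are auditable in one place):

* percentiles use linear interpolation at sorted position ``(n-1)*q``
  (``numpy.percentile`` default);
* skewness is the Fisher-Pearson moment coefficient ``m3 / m2**1.5``
  (biased, no small-sample correction);
* kurtosis is excess kurtosis ``m4 / m2**2 - 3``;
* a zero-variance ROI reports skewness and kurtosis of 0 and sets the
  ``degenerate`` flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy import stats as sps

from .grids import ParametricMap

__all__ = [
    "STAT_NAMES",
    "HistogramFeatureSet",
    "RelativeFeatureSet",
    "RoiPair",
    "resample_to_reference",
    "extract_histogram_features",
    "relative_features",
    "feature_columns",
]

#: canonical order of the ten first-order statistics
STAT_NAMES = ("mean", "max", "min", "kurtosis", "skewness", "p10", "p25", "p50", "p75", "p90")

#: percentile levels backing the p* statistics
_PERCENTILES = {"p10": 10, "p25": 25, "p50": 50, "p75": 75, "p90": 90}


def feature_columns(family: str) -> list[str]:
    """Column names for one biomarker family, e.g. ``rASL_mean``."""
    return [f"{family}_{s}" for s in STAT_NAMES]


@dataclass(frozen=True)
class HistogramFeatureSet:
    """The ten first-order statistics of one ROI, in map units."""

    mean: float
    max: float
    min: float
    kurtosis: float
    skewness: float
    p10: float
    p25: float
    p50: float
    p75: float
    p90: float
    n_voxels: int
    units: str
    degenerate: bool = False

    def as_dict(self) -> dict[str, float]:
        return {s: getattr(self, s) for s in STAT_NAMES}


@dataclass(frozen=True)
class RelativeFeatureSet:
    """Lesion-minus-contralateral differences of the ten statistics."""

    values: dict[str, float]
    family: str  # "rAPT" or "rASL"
    units: str

    def as_row(self) -> dict[str, float]:
        """Flat dict with prefixed column names (``rASL_mean``, ...)."""
        return {f"{self.family}_{s}": self.values[s] for s in STAT_NAMES}


@dataclass
class RoiPair:
    """Lesion mask and its disjoint contralateral control mask."""

    lesion: np.ndarray
    contralateral: np.ndarray

    def __post_init__(self) -> None:
        self.lesion = np.asarray(self.lesion, dtype=bool)
        self.contralateral = np.asarray(self.contralateral, dtype=bool)
        if self.lesion.shape != self.contralateral.shape:
            raise ValueError("lesion and contralateral masks must share a grid")
        if not self.lesion.any() or not self.contralateral.any():
            raise ValueError("both ROIs must be non-empty")
        if (self.lesion & self.contralateral).any():
            raise ValueError("lesion and contralateral ROIs overlap")


def resample_to_reference(
    pmap: ParametricMap,
    reference_shape: tuple[int, ...],
    reference_affine: np.ndarray,
    interpolation: str = "linear",
) -> ParametricMap:
    """Resample a parametric map onto a reference (e.g. DWI) grid.

    The affine alignment between grids is taken from the two headers
    (identity world alignment is assumed; an external registration
    supplies the affines).  Validity is propagated conservatively: a
    resampled voxel is valid only if every source voxel contributing to
    its interpolation is valid and inside the source grid.

    Parameters
    ----------
    interpolation : {"nearest", "linear"}
    """
    if interpolation not in ("nearest", "linear"):
        raise ValueError(f"unknown interpolation {interpolation!r}")
    ref_affine = np.asarray(reference_affine, dtype=float)
    if ref_affine.shape != (4, 4):
        raise ValueError("reference affine must be 4x4")
    if abs(np.linalg.det(pmap.affine)) < 1e-12 or abs(np.linalg.det(ref_affine)) < 1e-12:
        raise ValueError("singular affine")

    if tuple(reference_shape) == pmap.shape and np.allclose(ref_affine, pmap.affine):
        return ParametricMap(
            values=pmap.values.copy(), units=pmap.units,
            affine=ref_affine.copy(), valid=pmap.valid.copy(),
        )

    # voxel coordinates of every reference voxel expressed in the source grid
    src_from_ref = np.linalg.inv(pmap.affine) @ ref_affine
    idx = np.indices(reference_shape, dtype=float).reshape(len(reference_shape), -1)
    coords = src_from_ref[:3, :3] @ idx + src_from_ref[:3, 3:4]

    order = 0 if interpolation == "nearest" else 1
    values = ndimage.map_coordinates(
        pmap.values, coords, order=order, mode="constant", cval=0.0
    ).reshape(reference_shape)
    # a linear-interpolated validity of exactly 1 means all contributors valid;
    # out-of-domain voxels pick up the cval of 0 and drop out
    valid_frac = ndimage.map_coordinates(
        pmap.valid.astype(float), coords, order=order, mode="constant", cval=0.0
    ).reshape(reference_shape)
    valid = valid_frac >= 1.0 - 1e-9

    values = np.where(valid, values, 0.0)
    return ParametricMap(values=values, units=pmap.units, affine=ref_affine, valid=valid)


def extract_histogram_features(pmap: ParametricMap, mask: np.ndarray) -> HistogramFeatureSet:
    """First-order statistics of the valid in-mask voxels of a map."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != pmap.shape:
        raise ValueError(f"mask shape {mask.shape} != map shape {pmap.shape}")
    effective = mask & pmap.valid
    sample = pmap.values[effective]
    if sample.size == 0:
        raise ValueError("no valid voxels inside the ROI")

    degenerate = bool(np.ptp(sample) == 0)
    if degenerate:
        skew = kurt = 0.0
    else:
        skew = float(sps.skew(sample, bias=True))
        kurt = float(sps.kurtosis(sample, fisher=True, bias=True))

    pcts = np.percentile(sample, list(_PERCENTILES.values()), method="linear")
    return HistogramFeatureSet(
        mean=float(sample.mean()),
        max=float(sample.max()),
        min=float(sample.min()),
        kurtosis=kurt,
        skewness=skew,
        p10=float(pcts[0]),
        p25=float(pcts[1]),
        p50=float(pcts[2]),
        p75=float(pcts[3]),
        p90=float(pcts[4]),
        n_voxels=int(sample.size),
        units=pmap.units,
        degenerate=degenerate,
    )


def subject_feature_row(
    mtrasym_map: ParametricMap,
    cbf_map: ParametricMap,
    rois: RoiPair,
    slice_axis: int = -1,
) -> dict[str, float]:
    """Compute the 20-column rAPT/rASL feature row of one subject.

    rAPT statistics are taken on the single lesion-maximal slice of the
    MTRasym map (the APT acquisition is one 2D slice through the lesion
    maximum) and are reported in percent; rASL statistics use the full
    3D lesion mask on the CBF map.  Both maps must already live on the
    reference (lesion-mask) grid.
    """
    from .apt import lesion_maximal_slice

    axis = slice_axis % rois.lesion.ndim
    k = lesion_maximal_slice(rois.lesion, axis=axis)
    slicer = [slice(None)] * rois.lesion.ndim
    slicer[axis] = slice(k, k + 1)
    slicer = tuple(slicer)
    slice_lesion = np.zeros_like(rois.lesion)
    slice_lesion[slicer] = rois.lesion[slicer]
    slice_contra = np.zeros_like(rois.contralateral)
    slice_contra[slicer] = rois.contralateral[slicer]

    apt_lesion = extract_histogram_features(mtrasym_map, slice_lesion)
    apt_contra = extract_histogram_features(mtrasym_map, slice_contra)
    rapt = relative_features(apt_lesion, apt_contra, family="rAPT")

    asl_lesion = extract_histogram_features(cbf_map, rois.lesion)
    asl_contra = extract_histogram_features(cbf_map, rois.contralateral)
    rasl = relative_features(asl_lesion, asl_contra, family="rASL")

    # MTRasym is carried internally as a fraction; reports use percent.
    # Skewness and kurtosis are scale-invariant, so only the location
    # statistics pick up the factor of 100.
    row = {
        key: (v if key.endswith(("kurtosis", "skewness")) else 100.0 * v)
        for key, v in rapt.as_row().items()
    }
    row.update(rasl.as_row())
    return row


def relative_features(
    lesion: HistogramFeatureSet,
    contralateral: HistogramFeatureSet,
    family: str,
) -> RelativeFeatureSet:
    """Statistic-by-statistic lesion-minus-contralateral difference.

    The difference is taken between ROI-level statistics rather than on
    a voxelwise difference image, since the two ROIs need not contain
    the same number of voxels.
    """
    if family not in ("rAPT", "rASL"):
        raise ValueError(f"family must be 'rAPT' or 'rASL', got {family!r}")
    if lesion.units != contralateral.units:
        raise ValueError(
            f"unit mismatch: lesion in {lesion.units!r}, "
            f"contralateral in {contralateral.units!r}"
        )
    diffs = {
        s: getattr(lesion, s) - getattr(contralateral, s) for s in STAT_NAMES
    }
    return RelativeFeatureSet(values=diffs, family=family, units=lesion.units)
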