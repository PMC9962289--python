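"""MTRasym (APT-weighted) map computation from a Z-spectrum stack.

The map is the asymmetry of the saturated signal about the water line at
+/-3.5 ppm, normalised by the unsaturated reference::

    MTRasym = (s(-3.5 ppm) - s(+3.5 ppm)) / s0

expressed internally as a dimensionless fraction (report layers convert
to percent).  No B0 correction or Z-spectrum interpolation is applied:
the computation uses exactly the two offsets plus s0, so any correction
must happen upstream and be handed in as a pre-corrected stack.
"""

from __future__ import annotations

import numpy as np

from .grids import UNITS_FRACTION, ParametricMap, ZSpectrumStack

__all__ = ["compute_mtrasym_map", "lesion_maximal_slice"]

APT_OFFSET_PPM = 3.5


def compute_mtrasym_map(z: ZSpectrumStack, mask: np.ndarray | None = None) -> ParametricMap:
    """Compute the voxelwise MTRasym map at +/-3.5 ppm.

    Parameters
    ----------
    z : ZSpectrumStack
        Must contain offsets at -3.5 and +3.5 ppm; a missing offset
        raises ``KeyError`` naming it.
    mask : ndarray of bool, optional
        Analysis mask; voxels outside it are flagged invalid.

    Returns
    -------
    ParametricMap
        Units ``"fraction"``.  Voxels with ``s0 <= 0`` (or outside the
        mask) are flagged invalid, never silently zeroed.
    """
    s_neg = z.offset(-APT_OFFSET_PPM)
    s_pos = z.offset(+APT_OFFSET_PPM)
    s0 = z.s0

    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != s0.shape:
            raise ValueError(f"mask shape {mask.shape} != grid shape {s0.shape}")

    valid = s0 > 0
    if mask is not None:
        valid &= mask

    values = np.zeros_like(s0)
    np.divide(s_neg - s_pos, s0, out=values, where=valid)
    return ParametricMap(values=values, units=UNITS_FRACTION, affine=z.affine, valid=valid)


def lesion_maximal_slice(mask: np.ndarray, axis: int = -1) -> int:
    """Index of the slice along ``axis`` with the largest lesion area.

    The APT acquisition is a single 2D slice positioned at the maximum
    lesion extent; this picks the matching slice of a 3D lesion mask.
    Ties resolve to the lowest index.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("lesion mask is empty")
    counts = mask.sum(axis=tuple(i for i in range(mask.ndim) if i != axis % mask.ndim))
    return int(np.argmax(counts))
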