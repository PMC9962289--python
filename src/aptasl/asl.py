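"""Single-PLD pCASL CBF quantification with CSF-calibrated M0a.

Model
-----
The equilibrium arterial magnetization is calibrated from the mean CSF
signal ``Scsf`` of a ventricular reference region::

    M0a = Scsf / (lambda_a * (1 - exp(-TR / T1csf)))

and the voxelwise cerebral blood flow from the control-label difference
``dM``::

    CBF = unit_scale * dM * exp(w/T1a) * exp(TE/T2a)
          / (rho * 2 * alpha * T1a * M0a)

with an optional bolus-duration factor ``1 - exp(-tau/T1a)`` in the
denominator (off by default; the base model omits it).

.. warning::
   The source formulation of the M0a calibration is typographically
   ambiguous; the form above is the standard CSF-calibration reading
   (saturation-recovery correction of the CSF signal scaled by the
   blood-water fraction ``lambda_a``).  Likewise the CBF expression's
   grouping is chosen for dimensional consistency with the standard
   single-compartment model: all exponential terms in the numerator,
   ``rho * 2 * alpha * T1a * M0a`` in the denominator.

Negative ``dM`` yields negative CBF, which is retained: lesion-minus-
contralateral difference biomarkers are signed quantities.
"""

from __future__ import annotations

import numpy as np

from .grids import UNITS_CBF, AslAcquisition, AslQuantParams, ParametricMap

__all__ = ["compute_m0a", "compute_cbf_map", "cbf_scale_factor"]


def compute_m0a(scsf: float, params: AslQuantParams) -> float:
    """Equilibrium arterial-blood magnetization from the CSF signal.

    ``M0a = Scsf / (lambda_a * (1 - exp(-TR / T1csf)))`` — the CSF
    signal corrected for incomplete T1 recovery over TR and scaled by
    the arterial blood-water fraction.
    """
    if scsf <= 0:
        raise ValueError(f"Scsf must be positive, got {scsf}")
    if params.TR <= 0 or params.T1csf <= 0:
        raise ValueError("TR and T1csf must be positive")
    recovery = 1.0 - np.exp(-params.TR / params.T1csf)
    return float(scsf / (params.lambda_a * recovery))


def cbf_scale_factor(params: AslQuantParams, m0a: float) -> float:
    """Multiplier mapping dM (a.u.) to CBF in mL/100 g/min."""
    if m0a <= 0:
        raise ValueError(f"M0a must be positive, got {m0a}")
    numerator = params.unit_scale * np.exp(params.w / params.T1a) * np.exp(params.TE / params.T2a)
    denominator = params.rho * 2.0 * params.alpha * params.T1a * m0a
    if params.use_bolus_term:
        denominator *= 1.0 - np.exp(-params.labeling_duration / params.T1a)
    return float(numerator / denominator)


def compute_cbf_map(acq: AslAcquisition, mask: np.ndarray | None = None) -> ParametricMap:
    """Quantify the CBF map from a control/label pair.

    The map is linear in ``dM = control - label`` and inversely
    proportional to the CSF-calibrated M0a.  Voxels outside ``mask``
    are flagged invalid.
    """
    m0a = compute_m0a(acq.scsf, acq.params)
    scale = cbf_scale_factor(acq.params, m0a)
    values = scale * acq.delta_m

    valid = np.ones(values.shape, dtype=bool)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != values.shape:
            raise ValueError(f"mask shape {mask.shape} != grid shape {values.shape}")
        valid &= mask
        values = np.where(valid, values, 0.0)

    return ParametricMap(values=values, units=UNITS_CBF, affine=acq.affine, valid=valid)
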