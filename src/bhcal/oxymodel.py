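"""Biophysics of breath-hold calibrated BOLD and the OEF grid inversion.

Two independent expressions for the maximum BOLD signal (M) — the BOLD
signal increase that complete removal of deoxyhaemoglobin from a voxel
would produce — are combined to estimate the resting oxygen extraction
fraction (OEF0):

* ``m_calib``: the general BOLD-calibration expression, driven by the
  measured fractional BOLD and CBF responses to a vasodilatory stimulus
  (here, repeated breath-holding) and the arterial oxygen content at
  baseline and during the stimulus.

* ``m_diffusion``: a capillary oxygen-diffusion expression that links M
  to resting OEF, resting perfusion and the deoxyhaemoglobin
  concentration of venous blood.

For physiologic inputs the two curves cross exactly once as a function
of OEF0, so a dense grid search over OEF0 (1000 values, 0.001 to 1.000)
locates the voxel's resting OEF and its M simultaneously.  Resting
CMRO2 then follows from the Fick principle.

Unit conventions
----------------
CBF is expressed in mL blood/100 g tissue/min in all public interfaces
(1 g tissue = 1 mL).  Inside ``m_diffusion`` the oxygen delivery term
OEF0*CBF0*CaO2 is expressed in umol/mL tissue/min, converting mL O2 to
umol at 44.64 umol/mL (ideal gas at STP); this conversion factor is
exposed on :class:`ModelConstants` (``o2_umol_per_ml``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ModelConstants",
    "ArterialState",
    "VoxelResponse",
    "OefSolution",
    "severinghaus_saturation",
    "arterial_o2_content",
    "dhb_concentration",
    "capillary_po2",
    "m_calib",
    "m_diffusion",
    "oef_grid",
    "solve_oef_grid",
    "solve_oef_grid_arrays",
    "cmro2_fick",
]

#: number of points on the OEF search grid (0.001 .. 1.000 inclusive)
GRID_SIZE = 1000


@dataclass
class ModelConstants:
    """Fixed physiological and physical parameters of the signal model.

    Attributes
    ----------
    phi : float
        O2 binding capacity of haemoglobin, mL O2 per g Hb.
    alpha : float
        Grubb exponent coupling fractional CBF change to the change in
        deoxyhaemoglobin-weighted blood volume (dimensionless).
    beta : float
        Field-strength / vessel-geometry exponent (1.3 at 3 T).
    P50 : float
        O2 partial pressure at half haemoglobin saturation, mmHg.
    h : float
        Hill constant for cooperative O2 binding (dimensionless).
    epsilon : float
        Solubility of O2 in blood, mL O2/dL/mmHg.
    ArhoK : float
        Combined diffusion constant A*rho/K,
        s^-1 g^-beta dL^beta per (umol/mmHg/mL/min).
    PmO2 : float
        Mitochondrial O2 partial pressure, mmHg (0 in health).
    TE_bold : float
        Echo time of the BOLD-weighted acquisition, s.
    Ya : float
        Assumed arterial O2 saturation for venous oximetry (fraction).
    o2_umol_per_ml : float
        Conversion from mL O2 to umol O2 (ideal gas, 22.4 L/mol).
    """

    phi: float = 1.34
    alpha: float = 0.2
    beta: float = 1.3
    P50: float = 26.0
    h: float = 2.84
    epsilon: float = 0.003
    ArhoK: float = 8.85
    PmO2: float = 0.0
    TE_bold: float = 0.030
    Ya: float = 0.98
    o2_umol_per_ml: float = 44.64

    def __post_init__(self) -> None:
        for name in ("phi", "P50", "h", "epsilon", "ArhoK", "TE_bold",
                     "o2_umol_per_ml"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.PmO2 < 0:
            raise ValueError("PmO2 must be >= 0")
        if not 0 < self.Ya <= 1:
            raise ValueError("Ya must lie in (0, 1]")
        if self.beta < 1:
            raise ValueError("beta must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass
class ArterialState:
    """Arterial oxygenation at baseline and at the breath-hold peak.

    ``CaO2_0``/``CaO2_bh`` are the arterial O2 contents (mL/dL) at the
    baseline and breath-hold arterial O2 tensions.  Use
    :meth:`from_physiology` to derive saturations and contents from Hb
    and the two PaO2 values via the Severinghaus dissociation curve.
    """

    Hb: float
    PaO2_0: float = 127.0
    PaO2_bh: float = 104.0
    SaO2_0: float = float("nan")
    SaO2_bh: float = float("nan")
    CaO2_0: float = float("nan")
    CaO2_bh: float = float("nan")

    @classmethod
    def from_physiology(
        cls,
        Hb: float,
        PaO2_0: float = 127.0,
        PaO2_bh: float = 104.0,
        constants: ModelConstants | None = None,
    ) -> "ArterialState":
        c = constants or ModelConstants()
        if Hb < 0:
            raise ValueError("Hb must be non-negative")
        sa0 = float(severinghaus_saturation(PaO2_0))
        sab = float(severinghaus_saturation(PaO2_bh))
        return cls(
            Hb=Hb,
            PaO2_0=PaO2_0,
            PaO2_bh=PaO2_bh,
            SaO2_0=sa0,
            SaO2_bh=sab,
            CaO2_0=float(arterial_o2_content(Hb, sa0, PaO2_0, c)),
            CaO2_bh=float(arterial_o2_content(Hb, sab, PaO2_bh, c)),
        )


@dataclass
class VoxelResponse:
    """Per-voxel breath-hold response, absolute-calibrated.

    Attributes
    ----------
    cbf0 : float
        Baseline perfusion, mL/100 g/min.
    frac_cbf : float
        Fractional CBF change at the breath-hold peak
        (CBF/CBF0 = 1 + frac_cbf).
    frac_bold : float
        Fractional BOLD change at the breath-hold peak.
    delay : int
        Temporal shift relative to the global regressor, in samples.
    """

    cbf0: float
    frac_cbf: float
    frac_bold: float
    delay: int = 0


@dataclass
class OefSolution:
    """Result of the OEF grid search for one voxel."""

    oef0: float
    M: float
    residual: float
    valid: bool


# ---------------------------------------------------------------------------
# closed forms
# ---------------------------------------------------------------------------

def severinghaus_saturation(PaO2):
    """Haemoglobin O2 saturation from arterial O2 tension (mmHg).

    Empirical dissociation curve
    ``SaO2 = ((23400 / (PaO2^3 + 150*PaO2)) + 1)^-1``; strictly
    increasing and bounded in (0, 1).
    """
    p = np.asarray(PaO2, dtype=float)
    if np.any(p <= 0):
        raise ValueError("PaO2 must be strictly positive")
    out = 1.0 / (23400.0 / (p ** 3 + 150.0 * p) + 1.0)
    return out if out.ndim else float(out)


def arterial_o2_content(Hb, SaO2, PaO2, constants: ModelConstants | None = None):
    """Arterial O2 content (mL O2/dL blood): bound plus dissolved O2.

    ``CaO2 = Hb*phi*SaO2 + PaO2*epsilon``.
    """
    c = constants or ModelConstants()
    Hb = np.asarray(Hb, dtype=float)
    SaO2 = np.asarray(SaO2, dtype=float)
    PaO2 = np.asarray(PaO2, dtype=float)
    if np.any(Hb < 0) or np.any(PaO2 < 0):
        raise ValueError("Hb and PaO2 must be non-negative")
    if np.any((SaO2 < 0) | (SaO2 > 1)):
        raise ValueError("SaO2 must lie in [0, 1]")
    out = Hb * c.phi * SaO2 + PaO2 * c.epsilon
    return out if out.ndim else float(out)


def dhb_concentration(CaO2, Hb, oef, constants: ModelConstants | None = None):
    """Deoxyhaemoglobin concentration of venous blood, g/dL.

    ``(1 - (CaO2/(phi*Hb)) * (1 - oef)) * Hb``.  The saturation ratio
    CaO2/(phi*Hb) may slightly exceed 1 because of dissolved O2; it is
    deliberately not clamped.
    """
    c = constants or ModelConstants()
    Hb = np.asarray(Hb, dtype=float)
    if np.any(Hb <= 0):
        raise ValueError("Hb must be strictly positive")
    oef = np.asarray(oef, dtype=float)
    if np.any((oef < 0) | (oef > 1)):
        raise ValueError("oef must lie in [0, 1]")
    out = (1.0 - (np.asarray(CaO2, float) / (c.phi * Hb)) * (1.0 - oef)) * Hb
    return out if out.ndim else float(out)


def capillary_po2(oef, constants: ModelConstants | None = None):
    """Mean capillary O2 tension (mmHg) implied by the extraction fraction.

    ``P50 * (2/oef - 1)^(1/h)``; strictly decreasing in OEF and equal
    to P50 in the limit oef -> 1.
    """
    c = constants or ModelConstants()
    oef = np.asarray(oef, dtype=float)
    if np.any(oef <= 0):
        raise ValueError("oef must be strictly positive")
    if np.any(oef > 1):
        raise ValueError("oef must be <= 1")
    out = c.P50 * (2.0 / oef - 1.0) ** (1.0 / c.h)
    return out if out.ndim else float(out)


def m_calib(frac_bold, cbf_ratio, CaO2_bh, CaO2_0, Hb, oef0,
            constants: ModelConstants | None = None):
    """Maximum BOLD signal from the BOLD-calibration expression.

    ``M = frac_bold / {1 - cbf_ratio^alpha * bracket^beta}`` with

    ``bracket = (1 - (CaO2_bh/(phi*Hb)) * (1 - oef0*CaO2_0/(cbf_ratio*CaO2_bh)))
                / (1 - (CaO2_0/(phi*Hb)) * (1 - oef0))``

    The numerator is the venous desaturation term during the stimulus
    (the oxygen delivery term OEF0*CBF0*CaO2_0/(CBF*CaO2) reduces to
    oef0*CaO2_0/(cbf_ratio*CaO2_bh)).  A negative braced denominator
    corresponds to a net deoxyhaemoglobin increase (negative BOLD
    response), which is a valid model regime at low OEF with strong
    vasodilation: the division is still returned, and a measured BOLD
    response inconsistent with the flow response simply yields a
    negative M that can never match the diffusion expression.  NaN is
    returned (never an exception) where the expression is undefined
    (zero denominator, or a negative bracket under the non-integer
    exponent).
    """
    c = constants or ModelConstants()
    frac_bold = np.asarray(frac_bold, dtype=float)
    cbf_ratio = np.asarray(cbf_ratio, dtype=float)
    oef0 = np.asarray(oef0, dtype=float)
    phihb = c.phi * np.asarray(Hb, dtype=float)
    num = 1.0 - (CaO2_bh / phihb) * (1.0 - oef0 * CaO2_0 / (cbf_ratio * CaO2_bh))
    den = 1.0 - (CaO2_0 / phihb) * (1.0 - oef0)
    with np.errstate(invalid="ignore", divide="ignore"):
        bracket = np.asarray(num / den, dtype=float)
        # negative bracket ** non-integer beta -> nan (undefined)
        braced = 1.0 - cbf_ratio ** c.alpha * bracket ** c.beta
        out = np.where(braced != 0, frac_bold / braced, np.nan)
    return out if out.ndim else float(out)


def m_diffusion(oef0, cbf0, CaO2_0, Hb, constants: ModelConstants | None = None):
    """Maximum BOLD signal from the capillary oxygen-diffusion model.

    ``M = TE * (A*rho/K) * [oef0*cbf0*CaO2_0] * dHb^beta
          / (capillary_po2(oef0) - PmO2)``

    with the bracketed oxygen-consumption term in umol/mL tissue/min
    (CBF in mL/mL/min, CaO2 converted to umol/mL blood) and dHb in
    g/dL.  Strictly increasing in oef0 at fixed other inputs.
    """
    c = constants or ModelConstants()
    oef0 = np.asarray(oef0, dtype=float)
    cbf0 = np.asarray(cbf0, dtype=float)
    if np.any(cbf0 < 0):
        raise ValueError("cbf0 must be non-negative")
    if np.any((oef0 <= 0) | (oef0 > 1)):
        # oef0 = 1 is admitted as the closed-interval limit (dHb -> Hb)
        # so the full search grid can be evaluated; the solver flags
        # boundary solutions invalid.
        raise ValueError("oef0 must lie in (0, 1]")
    po2c = capillary_po2(oef0, c)
    if np.any(po2c <= c.PmO2):
        raise ValueError("capillary PO2 must exceed mitochondrial PO2")
    dhb = np.asarray(dhb_concentration(CaO2_0, Hb, oef0, c), dtype=float)
    consumption = oef0 * (cbf0 / 100.0) * (np.asarray(CaO2_0, float) / 100.0
                                           * c.o2_umol_per_ml)
    with np.errstate(invalid="ignore"):
        # dissolved O2 can push dHb below 0 at very small OEF; the
        # resulting NaN marks those grid points as non-physiologic
        out = (c.TE_bold * c.ArhoK * consumption * dhb ** c.beta
               / (po2c - c.PmO2))
    return out if out.ndim else float(out)


def cmro2_fick(CaO2, oef, cbf, constants: ModelConstants | None = None):
    """Resting CMRO2 via the Fick principle, umol O2/100 g/min.

    ``CMRO2 = CaO2 * OEF0 * CBF0`` with CaO2 in mL/dL converted to
    umol at ``o2_umol_per_ml`` and CBF in mL/100 g/min.
    """
    c = constants or ModelConstants()
    CaO2 = np.asarray(CaO2, dtype=float)
    oef = np.asarray(oef, dtype=float)
    cbf = np.asarray(cbf, dtype=float)
    if np.any(CaO2 < 0) or np.any(oef < 0) or np.any(cbf < 0):
        raise ValueError("CaO2, oef and cbf must be non-negative")
    out = oef * cbf * CaO2 * (c.o2_umol_per_ml / 100.0)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# grid search
# ---------------------------------------------------------------------------

def oef_grid() -> np.ndarray:
    """The OEF search grid: 1000 values, 0.001 to 1.000 in 0.001 steps."""
    return np.arange(1, GRID_SIZE + 1) / 1000.0


def solve_oef_grid_arrays(
    frac_bold: np.ndarray,
    frac_cbf: np.ndarray,
    cbf0: np.ndarray,
    arterial: ArterialState,
    constants: ModelConstants | None = None,
) -> dict[str, np.ndarray]:
    """Vectorised OEF grid search over many voxels.

    Parameters are 1-D arrays of equal length.  Returns a dict of
    arrays ``oef0``, ``M``, ``residual``, ``valid``.  Invalid voxels
    (no vasodilatory response, argmin on a grid boundary, or no finite
    residual anywhere on the grid) keep their numerical argmin values
    but are flagged ``valid=False``; callers typically mask them out.
    Grid ties are broken towards the smallest OEF.
    """
    c = constants or ModelConstants()
    frac_bold = np.atleast_1d(np.asarray(frac_bold, dtype=float))
    frac_cbf = np.atleast_1d(np.asarray(frac_cbf, dtype=float))
    cbf0 = np.atleast_1d(np.asarray(cbf0, dtype=float))
    grid = oef_grid()
    # grid axis last: (V, G)
    cbf_ratio = 1.0 + frac_cbf
    mc = m_calib(frac_bold[:, None], cbf_ratio[:, None],
                 arterial.CaO2_bh, arterial.CaO2_0, arterial.Hb,
                 grid[None, :], c)
    # the maximum BOLD signal is non-negative by definition: grid
    # points where the calibration expression turns negative (a
    # BOLD-vs-flow inconsistency at that OEF) are not candidates
    with np.errstate(invalid="ignore"):
        mc = np.where(mc > 0, mc, np.nan)
    # m_diffusion is linear in cbf0; evaluate the per-unit-CBF profile once
    md_unit = m_diffusion(grid, 1.0, arterial.CaO2_0, arterial.Hb, c)
    safe_cbf0 = np.where(np.isfinite(cbf0) & (cbf0 >= 0), cbf0, np.nan)
    md = safe_cbf0[:, None] * md_unit[None, :]
    diff = np.abs(mc - md)
    any_finite = np.any(np.isfinite(diff), axis=1)
    diff = np.where(np.isfinite(diff), diff, np.inf)
    idx = np.argmin(diff, axis=1)  # first occurrence == smallest OEF on ties
    oef = grid[idx]
    m_out = np.take_along_axis(md, idx[:, None], axis=1)[:, 0]
    residual = np.take_along_axis(diff, idx[:, None], axis=1)[:, 0]
    valid = (
        any_finite
        & np.isfinite(frac_bold)
        & np.isfinite(frac_cbf)
        & np.isfinite(safe_cbf0)
        & (frac_cbf > 0)
        & (idx > 0)
        & (idx < grid.size - 1)
    )
    return {"oef0": oef, "M": m_out, "residual": residual, "valid": valid}


def solve_oef_grid(
    resp: VoxelResponse,
    arterial: ArterialState,
    constants: ModelConstants | None = None,
) -> OefSolution:
    """Grid search for the OEF0 that reconciles ``m_calib`` and ``m_diffusion``.

    Evaluates both expressions for 1000 OEF values between 0.001 and 1
    in 0.001 steps and keeps the OEF with the minimum |difference|.
    Physiologic failure (no vasodilation, boundary argmin) is reported
    through ``valid=False`` rather than an exception.
    """
    out = solve_oef_grid_arrays(
        np.array([resp.frac_bold]),
        np.array([resp.frac_cbf]),
        np.array([resp.cbf0]),
        arterial,
        constants,
    )
    return OefSolution(
        oef0=float(out["oef0"][0]),
        M=float(out["M"][0]),
        residual=float(out["residual"][0]),
        valid=bool(out["valid"][0]),
    )
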