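"""Forward simulation of breath-hold calibrated fMRI sessions.

Generates complete dual-echo tag/control sessions (plus the
proton-density calibration volume and TRUST / inversion-recovery
signals) from a known :class:`GroundTruth`, so every processing stage
and the end-to-end OEF inversion can be tested without any acquisition.

The breath-hold paradigm defaults to the protocol used for the
estimator: 10 holds of 20 s separated by 30 s of recovery, sampled at
TR = 4.4 s, preceded by a 24 s lead-in (total 8 min 44 s).  The
haemodynamic response to each hold is modelled as a boxcar convolved
with a single-exponential kernel (time constant 8 s) — a deliberately
simple stand-in for the true respiratory physiology.

Response shape: by default voxel time courses scale the shared
respiratory regressor by the exact model-derived peak amplitudes
(``response="linearized"``), which matches the estimator's linear
observation model so that noiseless sessions invert exactly.  Setting
``response="exact"`` evaluates the full nonlinear BOLD forward model at
every time point instead, for sensitivity studies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .oxymodel import (
    ArterialState,
    ModelConstants,
    arterial_o2_content,
    m_diffusion,
    severinghaus_saturation,
)
from .pipeline import (
    AcquisitionSpec,
    CalibrationSpec,
    DualExcitationSeries,
    shift_regressor,
)

__all__ = [
    "ParadigmSpec",
    "GroundTruth",
    "make_paradigm_regressor",
    "bold_response_peak",
    "forward_bold",
    "forward_asl",
    "asl_difference_amplitude",
    "default_ground_truth",
    "sample_subject_truth",
    "visual_stimulation_truth",
    "assemble_synthetic_session",
    "synth_trust_ir",
]


@dataclass
class ParadigmSpec:
    """Breath-hold paradigm timing."""

    n_holds: int = 10
    hold_s: float = 20.0
    recovery_s: float = 30.0
    lead_in_s: float = 24.0
    TR: float = 4.4
    kernel_tau_s: float = 8.0

    def __post_init__(self) -> None:
        if self.n_holds < 0 or min(self.hold_s, self.recovery_s, self.TR) <= 0:
            raise ValueError("paradigm timings must be positive")
        if self.lead_in_s < 0 or self.kernel_tau_s < 0:
            raise ValueError("lead-in and kernel time constant must be >= 0")

    @property
    def duration_s(self) -> float:
        return self.lead_in_s + self.n_holds * (self.hold_s + self.recovery_s)

    @property
    def n_volumes(self) -> int:
        n = math.ceil(self.duration_s / self.TR)
        return n + (n % 2)  # complete tag/control pairs


@dataclass
class GroundTruth:
    """True parameter maps and noise levels for one synthetic session.

    ``noise_sigma_echo1``/``echo2`` are additive white Gaussian noise
    SDs per volume in raw signal units.  The defaults (with ``m0`` =
    1000 and ``bold_base`` = 500) give a grey-matter ASL tSNR of about
    4 after surround subtraction and a BOLD tSNR of about 80,
    representative of 3 T dual-excitation pCASL.
    """

    oef0: np.ndarray
    cbf0: np.ndarray
    frac_cbf: np.ndarray
    delay_samples: np.ndarray
    gm_truth: np.ndarray
    brain: np.ndarray
    Hb: float = 15.0
    PaO2_0: float = 127.0
    PaO2_bh: float = 104.0
    m0: float = 1000.0
    bold_base: float = 500.0
    static_echo1_frac: float = 0.30
    noise_sigma_echo1: float = 1.15
    noise_sigma_echo2: float = 6.25
    seed: int | None = None


def make_paradigm_regressor(p: ParadigmSpec, dt: float = 0.1) -> np.ndarray:
    """Unit-peak respiratory response time course sampled at the TR.

    A boxcar train (1 during each hold) is passed through a first-order
    exponential kernel and normalised to peak 1.  ``kernel_tau_s = 0``
    reduces to the pure boxcar; ``n_holds = 0`` returns zeros.
    """
    n_vol = p.n_volumes
    if p.n_holds == 0:
        return np.zeros(n_vol)
    n_fine = int(round(p.duration_s / dt)) + 1
    tt = np.arange(n_fine) * dt
    u = np.zeros(n_fine)
    for k in range(p.n_holds):
        start = p.lead_in_s + k * (p.hold_s + p.recovery_s)
        u[(tt >= start) & (tt < start + p.hold_s)] = 1.0
    if p.kernel_tau_s == 0:
        x = u
    else:
        decay = math.exp(-dt / p.kernel_tau_s)
        x = np.empty_like(u)
        x[0] = 0.0
        for i in range(1, n_fine):
            x[i] = u[i] + (x[i - 1] - u[i]) * decay
    sample_idx = np.minimum(np.round(np.arange(n_vol) * p.TR / dt).astype(int),
                            n_fine - 1)
    r = x[sample_idx]
    peak = r.max()
    return r / peak if peak > 0 else r


def bold_response_peak(
    oef0: float,
    cbf0: float,
    frac_cbf: float,
    Hb: float,
    PaO2_0: float = 127.0,
    PaO2_bh: float = 104.0,
    constants: ModelConstants | None = None,
) -> float:
    """Peak fractional BOLD response implied by the ground truth.

    Computes M from the diffusion expression and evaluates the
    calibration expression forwards at the breath-hold peak.
    """
    return float(forward_bold(np.array([1.0]), oef0, cbf0, frac_cbf, Hb,
                              PaO2_0, PaO2_bh, constants)[0])


def forward_bold(
    r: np.ndarray,
    oef0: float,
    cbf0: float,
    frac_cbf: float,
    Hb: float,
    PaO2_0: float = 127.0,
    PaO2_bh: float = 104.0,
    constants: ModelConstants | None = None,
) -> np.ndarray:
    """Exact fractional BOLD time course for a regressor trace ``r``.

    The arterial O2 tension follows the same normalised respiratory
    driver as the flow response (PaO2(t) = PaO2_0 + r*(PaO2_bh -
    PaO2_0)), and the BOLD calibration expression is evaluated
    algebraically at each time point with M taken from the diffusion
    model at the voxel's ground truth.  Returns 0 wherever r = 0.
    """
    c = constants or ModelConstants()
    r = np.asarray(r, dtype=float)
    arterial0 = ArterialState.from_physiology(Hb, PaO2_0, PaO2_bh, c)
    M = m_diffusion(oef0, cbf0, arterial0.CaO2_0, Hb, c)
    pao2_t = PaO2_0 + r * (PaO2_bh - PaO2_0)
    sao2_t = severinghaus_saturation(pao2_t)
    cao2_t = arterial_o2_content(Hb, sao2_t, pao2_t, c)
    cbf_ratio = 1.0 + frac_cbf * r
    phihb = c.phi * Hb
    num = 1.0 - (cao2_t / phihb) * (
        1.0 - oef0 * arterial0.CaO2_0 / (cbf_ratio * cao2_t))
    den = 1.0 - (arterial0.CaO2_0 / phihb) * (1.0 - oef0)
    return M * (1.0 - cbf_ratio ** c.alpha * (num / den) ** c.beta)


def asl_difference_amplitude(
    cbf: np.ndarray,
    m0,
    cal: CalibrationSpec | None = None,
    spec: AcquisitionSpec | None = None,
) -> np.ndarray:
    """Tag/control difference signal for a given CBF (inverse of the
    quantification equation)."""
    cal = cal or CalibrationSpec()
    spec = spec or AcquisitionSpec()
    t1b = cal.t1_blood
    return (np.asarray(cbf, float) * 2.0 * cal.efficiency * np.asarray(m0, float)
            * t1b * (1.0 - np.exp(-spec.label_duration / t1b))
            * np.exp(-spec.PLD / t1b) / (6000.0 * cal.lambda_bp))


def forward_asl(
    r: np.ndarray,
    cbf0: float,
    frac_cbf: float,
    m0: float,
    cal: CalibrationSpec | None = None,
    spec: AcquisitionSpec | None = None,
    static_frac: float = 0.30,
) -> np.ndarray:
    """Interleaved tag/control echo-1 series for one voxel (noiseless).

    Control volumes sit at the background-suppressed static level
    ``static_frac * m0``; tag volumes are reduced by the perfusion
    difference signal consistent with the CBF quantification equation,
    so that the pipeline's calibration recovers ``cbf0`` exactly.
    """
    cal = cal or CalibrationSpec()
    spec = spec or AcquisitionSpec()
    r = np.asarray(r, dtype=float)
    cbf_t = cbf0 * (1.0 + frac_cbf * r)
    dm_t = asl_difference_amplitude(cbf_t, m0, cal, spec)
    t = np.arange(r.size)
    is_tag = (t % 2 == 0) if spec.tag_first else (t % 2 == 1)
    return static_frac * m0 - np.where(is_tag, dm_t, 0.0)


# ---------------------------------------------------------------------------
# ground-truth construction
# ---------------------------------------------------------------------------

def default_ground_truth(
    shape: tuple[int, int, int] = (22, 22, 4),
    oef0: float = 0.37,
    cbf_gm: float = 54.0,
    cbf_wm: float = 22.0,
    frac_cbf_gm: float = 0.12,
    Hb: float = 15.0,
    noiseless: bool = False,
    vessels: bool = True,
) -> GroundTruth:
    """Deterministic phantom: elliptical brain with a white-matter bulk,
    an interior grey-matter band and (optionally) a few high-perfusion
    vessel voxels.

    The grey-matter band carries uniform perfusion ``cbf_gm``; the
    white matter outside it (including the brain edge, which in-plane
    smoothing blurs against the background) sits well below, so the
    pipeline's perfusion-percentile mask lands on grey matter.  Vessel
    voxels mimic macrovascular contamination; the upper mask
    percentile should reject them.  Pass ``vessels=False`` for a clean
    two-compartment phantom when testing exact parameter recovery.
    """
    nx, ny, nz = shape
    x, y = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    rr = np.sqrt(((x - cx) / (0.46 * nx)) ** 2 + ((y - cy) / (0.46 * ny)) ** 2)
    brain2d = rr < 1.0
    gm2d = brain2d & (rr > 0.40) & (rr < 0.85)
    # one bright vessel column deep in the white-matter core (draining
    # vein); its smoothing halo stays below the GM perfusion band
    vessel2d = np.zeros_like(brain2d)
    if vessels:
        vessel2d[nx // 2, ny // 2] = True

    brain = np.repeat(brain2d[:, :, None], nz, axis=2)
    gm = np.repeat(gm2d[:, :, None], nz, axis=2)
    vessel = np.repeat(vessel2d[:, :, None], nz, axis=2) & brain

    cbf = np.zeros(shape)
    cbf[brain] = cbf_wm
    cbf[gm] = cbf_gm
    cbf[vessel] = 4.0 * cbf_gm

    oef_map = np.where(brain, oef0, np.nan)
    frac = np.zeros(shape)
    frac[brain] = 0.5 * frac_cbf_gm
    frac[gm] = frac_cbf_gm
    frac[vessel] = frac_cbf_gm

    return GroundTruth(
        oef0=oef_map,
        cbf0=cbf,
        frac_cbf=frac,
        delay_samples=np.zeros(shape, dtype=int),
        gm_truth=gm,
        brain=brain,
        Hb=Hb,
        noise_sigma_echo1=0.0 if noiseless else 1.15,
        noise_sigma_echo2=0.0 if noiseless else 6.25,
    )


def sample_subject_truth(
    rng: np.random.Generator,
    shape: tuple[int, int, int] = (22, 22, 4),
    oef_mean: float = 0.37,
    oef_sd: float = 0.04,
    cbf_mean: float = 54.0,
    cbf_sd: float = 10.0,
    hb_mean: float = 14.0,
    hb_sd: float = 1.0,
) -> GroundTruth:
    """Draw one subject's ground truth from population distributions.

    The population means and SDs default to healthy-adult grey-matter
    values (OEF 0.37 +/- 0.04, CBF 54 +/- 10 mL/100 g/min).
    """
    oef = float(np.clip(rng.normal(oef_mean, oef_sd), 0.15, 0.65))
    cbf = float(np.clip(rng.normal(cbf_mean, cbf_sd), 25.0, 95.0))
    hb = float(np.clip(rng.normal(hb_mean, hb_sd), 10.0, 18.0))
    return default_ground_truth(shape=shape, oef0=oef, cbf_gm=cbf, Hb=hb)


def session_variation(
    gt: GroundTruth,
    rng: np.random.Generator,
    cbf_session_sd: float = 0.03,
    frac_cbf_sd: float = 0.02,
) -> GroundTruth:
    """Session-level physiological variation around a subject's truth.

    Models day-to-day perfusion drift (multiplicative, SD 3%) and
    variable breath-hold performance (the peak fractional CBF response
    varies between sessions, SD 0.02).  Breath-hold performance
    variability affects BOLD and ASL responses together, which is why
    it largely cancels in the OEF estimate.
    """
    cbf_factor = float(rng.normal(1.0, cbf_session_sd))
    frac_shift = float(rng.normal(0.0, frac_cbf_sd))
    frac = np.clip(gt.frac_cbf + np.where(gt.frac_cbf > 0, frac_shift, 0.0),
                   0.02, None)
    return replace(gt, cbf0=gt.cbf0 * cbf_factor, frac_cbf=frac)


def visual_stimulation_truth(
    gt: GroundTruth,
    roi: np.ndarray | None = None,
    cbf_gain: float = 1.16,
    cmro2_gain: float = 1.12,
) -> tuple[GroundTruth, np.ndarray]:
    """Second-condition truth: functional hyperaemia in an ROI.

    Within the ROI (default: the posterior half of the grey-matter
    band, mimicking visual cortex) baseline CBF rises by ``cbf_gain``
    and CMRO2 by ``cmro2_gain``; by the Fick principle OEF scales by
    cmro2_gain/cbf_gain (a decrease when flow outstrips metabolism).
    Returns the modified truth and the ROI mask.
    """
    if roi is None:
        roi = gt.gm_truth.copy()
        roi[:, : roi.shape[1] // 2, :] = False
    cbf = np.where(roi, gt.cbf0 * cbf_gain, gt.cbf0)
    oef = np.where(roi, gt.oef0 * (cmro2_gain / cbf_gain), gt.oef0)
    return replace(gt, cbf0=cbf, oef0=oef), roi


# ---------------------------------------------------------------------------
# session assembly
# ---------------------------------------------------------------------------

def assemble_synthetic_session(
    gt: GroundTruth,
    paradigm: ParadigmSpec | None = None,
    seed: int | None = None,
    response: str = "linearized",
    cal: CalibrationSpec | None = None,
    spec: AcquisitionSpec | None = None,
    constants: ModelConstants | None = None,
) -> tuple[DualExcitationSeries, np.ndarray, GroundTruth]:
    """Generate one complete dual-echo session from ground truth.

    Returns ``(series, pd_volume, ground_truth)``.  Output is fully
    deterministic given ``seed``; the seed actually used is recorded on
    the returned ground-truth object.
    """
    if response not in ("linearized", "exact"):
        raise ValueError("response must be 'linearized' or 'exact'")
    p = paradigm or ParadigmSpec()
    cal = cal or CalibrationSpec()
    spec = spec or AcquisitionSpec(TR=p.TR)
    c = constants or ModelConstants()
    rng = np.random.default_rng(seed)
    r = make_paradigm_regressor(p)
    T = r.size
    shape = gt.cbf0.shape

    echo1 = np.zeros(shape + (T,))
    echo2 = np.zeros(shape + (T,))
    t = np.arange(T)
    is_tag = (t % 2 == 0) if spec.tag_first else (t % 2 == 1)
    tag_sign = np.where(is_tag, 1.0, 0.0)

    brain_idx = np.argwhere(gt.brain)
    # group voxels by (delay, parameters) would over-engineer; the
    # phantom is small, loop per voxel with vectorised time axis
    for ix, iy, iz in brain_idx:
        d = int(gt.delay_samples[ix, iy, iz])
        r_v = shift_regressor(r, d) if d else r
        cbf0 = gt.cbf0[ix, iy, iz]
        frac = gt.frac_cbf[ix, iy, iz]
        oef = gt.oef0[ix, iy, iz]
        dm_t = asl_difference_amplitude(cbf0 * (1.0 + frac * r_v), gt.m0,
                                        cal, spec)
        echo1[ix, iy, iz] = gt.static_echo1_frac * gt.m0 - tag_sign * dm_t
        if response == "exact":
            bold_t = forward_bold(r_v, oef, cbf0, frac, gt.Hb,
                                  gt.PaO2_0, gt.PaO2_bh, c)
        else:
            peak = bold_response_peak(oef, cbf0, frac, gt.Hb,
                                      gt.PaO2_0, gt.PaO2_bh, c)
            bold_t = peak * r_v
        echo2[ix, iy, iz] = gt.bold_base * (1.0 + bold_t)

    if gt.noise_sigma_echo1 > 0:
        echo1 += rng.normal(0.0, gt.noise_sigma_echo1, echo1.shape)
    if gt.noise_sigma_echo2 > 0:
        echo2 += rng.normal(0.0, gt.noise_sigma_echo2, echo2.shape)

    pd_volume = np.where(gt.brain, gt.m0, 0.0)
    gt_out = replace(gt, seed=seed)
    series = DualExcitationSeries(echo1=echo1, echo2=echo2, spec=spec)
    return series, pd_volume, gt_out


# ---------------------------------------------------------------------------
# TRUST / inversion-recovery synthesis
# ---------------------------------------------------------------------------

def synth_trust_ir(
    t1: float,
    t2: float,
    noise_ir: float = 0.0,
    noise_trust: float = 0.0,
    seed: int | None = None,
    n_ir_voxels: int = 6,
    n_trust_voxels: int = 5,
):
    """Mono-exponential TRUST and inversion-recovery voxel sets.

    Returns ``(trust_series, ir_series)`` (see :mod:`bhcal.trust`).
    The first IR voxel and the two brightest TRUST voxels carry the
    requested ``t1``/``t2``; remaining voxels are dimmer decoys with
    perturbed relaxation times so that the automatic voxel selection
    has something to reject.  Noise levels are fractions of the signal
    amplitude; output is deterministic given ``seed``.
    """
    from .trust import InversionRecoverySeries, TrustSeries

    rng = np.random.default_rng(seed)
    tis = (np.arange(60) + 1) * 0.150
    amp = np.linspace(600.0, 300.0, n_ir_voxels)
    ir_signals = np.empty((n_ir_voxels, 16, tis.size))
    for v in range(n_ir_voxels):
        t1_v = t1 if v == 0 else t1 * (1.0 + 0.08 * ((v % 3) - 1))
        clean = np.abs(amp[v] - 2.0 * amp[v] * np.exp(-tis / t1_v))
        for rep in range(16):
            sig = clean.copy()
            if noise_ir > 0 or v > 0:
                level = max(noise_ir, 0.02 if v > 0 else noise_ir)
                sig = sig + rng.normal(0.0, level * amp[v], tis.size)
            ir_signals[v, rep] = sig
    ir = InversionRecoverySeries(TIs=tis, signals=ir_signals)

    etes = np.array([0.0, 0.040, 0.080, 0.160])
    s0 = np.linspace(1000.0, 300.0, n_trust_voxels)
    tr_signals = np.empty((n_trust_voxels, 3, etes.size))
    for v in range(n_trust_voxels):
        t2_v = t2 if v < 2 else t2 * (1.0 + 0.15 * ((v % 3) - 1))
        clean = s0[v] * np.exp(-etes / t2_v)
        for rep in range(3):
            sig = clean.copy()
            if noise_trust > 0:
                sig = sig + rng.normal(0.0, noise_trust * s0[v], etes.size)
            tr_signals[v, rep] = sig
    trust = TrustSeries(eTEs=etes, diffs=tr_signals)
    return trust, ir
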