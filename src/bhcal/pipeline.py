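"""Breath-hold dual-echo pCASL processing: raw series to parameter maps.

The pipeline turns an interleaved tag/control, two-echo time series into
voxelwise maps of baseline perfusion (CBF0), resting oxygen extraction
fraction (OEF0), resting CMRO2 and the maximum BOLD signal (M):

1. split echoes into perfusion-weighted (surround subtraction of echo 1)
   and BOLD-weighted (surround averaging of echo 2) series;
2. 2-D in-plane Gaussian smoothing and temporal high-pass filtering;
3. grey-matter mask from the perfusion percentile band;
4. data-driven global respiratory regressor (2:1 BOLD:ASL weighting of
   the z-normalised in-mask mean series);
5. voxelwise delay by cross-correlation, then OLS regression for the
   baseline and peak fractional responses;
6. absolute CBF calibration against a proton-density image, OEF grid
   search, and CMRO2 via the Fick principle.

Input data are assumed realigned (motion corrected); no registration is
performed here.  Volumes are indexed ``(x, y, z, t)`` with time last.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .oxymodel import (
    ArterialState,
    ModelConstants,
    cmro2_fick,
    solve_oef_grid_arrays,
)

__all__ = [
    "AcquisitionSpec",
    "CalibrationSpec",
    "PipelineOptions",
    "DualExcitationSeries",
    "GlobalRegressor",
    "ParameterMaps",
    "surround_pair",
    "smooth_inplane",
    "highpass_temporal",
    "brain_mask_from_signal",
    "gm_mask_from_perfusion",
    "build_global_regressor",
    "shift_regressor",
    "estimate_voxel_delay",
    "regress_responses",
    "calibrate_cbf",
    "map_parameters",
]

log = logging.getLogger("bhcal.pipeline")


@dataclass
class AcquisitionSpec:
    """Timing and geometry of the dual-excitation pCASL acquisition."""

    TR: float = 4.4
    TE1: float = 0.010
    TE2: float = 0.030
    label_duration: float = 1.5
    PLD: float = 1.5
    tag_first: bool = True

    def __post_init__(self) -> None:
        if self.TR <= self.label_duration + self.PLD:
            raise ValueError("TR must exceed label_duration + PLD")
        if self.TE1 >= self.TE2:
            raise ValueError("TE1 must be shorter than TE2")


@dataclass
class CalibrationSpec:
    """Constants for absolute ASL quantification against a PD image.

    ``lambda_bp`` is the blood-brain water partition coefficient
    (mL/g), ``efficiency`` the combined labeling/background-suppression
    inversion efficiency and ``t1_blood`` the longitudinal relaxation
    time of arterial blood at 3 T (s).
    """

    lambda_bp: float = 0.9
    efficiency: float = 0.72
    t1_blood: float = 1.65

    def __post_init__(self) -> None:
        for name in ("lambda_bp", "efficiency", "t1_blood"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass
class PipelineOptions:
    """Tunable processing options (defaults follow the acquisition protocol)."""

    smooth_sigma_px: float = 0.5
    highpass_cutoff_s: float = 100.0
    mask_percentiles: tuple[float, float] = (85.0, 99.0)
    brain_threshold_frac: float = 0.10
    max_lag: int = 5
    corr_floor: float = 0.2
    bold_asl_weights: tuple[float, float] = (2.0, 1.0)


@dataclass
class DualExcitationSeries:
    """Raw two-echo tag/control data plus acquisition timing."""

    echo1: np.ndarray
    echo2: np.ndarray
    spec: AcquisitionSpec = field(default_factory=AcquisitionSpec)

    def __post_init__(self) -> None:
        self.echo1 = np.asarray(self.echo1, dtype=float)
        self.echo2 = np.asarray(self.echo2, dtype=float)
        if self.echo1.shape != self.echo2.shape:
            raise ValueError("echo1 and echo2 must have identical shapes")
        if self.echo1.ndim != 4:
            raise ValueError("expected 4-D (x, y, z, t) arrays")
        if self.echo1.shape[-1] % 2:
            raise ValueError("volume count must be even (complete tag/control pairs)")

    @property
    def n_volumes(self) -> int:
        return self.echo1.shape[-1]


@dataclass
class GlobalRegressor:
    """Unit-peak respiratory regressor inferred from the data."""

    values: np.ndarray
    weights: tuple[float, float] = (2.0, 1.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class ParameterMaps:
    """Voxelwise outputs; masked-out or invalid voxels hold NaN."""

    cbf0: np.ndarray
    oef0: np.ndarray
    cmro2_0: np.ndarray
    M: np.ndarray
    delay: np.ndarray
    frac_cbf: np.ndarray
    frac_bold: np.ndarray
    gm_mask: np.ndarray
    brain_mask: np.ndarray
    regressor: GlobalRegressor
    summary: dict

    _MAP_NAMES = ("cbf0", "oef0", "cmro2_0", "M", "delay",
                  "frac_cbf", "frac_bold")


# ---------------------------------------------------------------------------
# stage 1: echo splitting
# ---------------------------------------------------------------------------

def _neighbour_mean(x: np.ndarray) -> np.ndarray:
    """Mean of the two temporally adjacent volumes; one-sided at the ends."""
    n = np.empty_like(x)
    n[..., 1:-1] = 0.5 * (x[..., :-2] + x[..., 2:])
    n[..., 0] = x[..., 1]
    n[..., -1] = x[..., -2]
    return n


def surround_pair(series: DualExcitationSeries) -> tuple[np.ndarray, np.ndarray]:
    """Perfusion- and BOLD-weighted series from the interleaved echoes.

    Perfusion comes from echo 1 by surround subtraction — each volume
    differenced against the mean of its two neighbours (which are the
    opposite tag/control condition), signed so that control minus tag
    is positive.  BOLD comes from echo 2 by surround averaging.  Both
    outputs keep the input length; series ends use one-sided
    differences/averages.
    """
    if series.n_volumes < 4:
        raise ValueError("need at least four volumes")
    t = np.arange(series.n_volumes)
    is_tag = (t % 2 == 0) if series.spec.tag_first else (t % 2 == 1)
    sign = np.where(is_tag, -1.0, 1.0)  # control - tag
    perfusion = sign * (series.echo1 - _neighbour_mean(series.echo1))
    bold = 0.5 * (series.echo2 + _neighbour_mean(series.echo2))
    return perfusion, bold


# ---------------------------------------------------------------------------
# stage 2: smoothing and temporal filtering
# ---------------------------------------------------------------------------

def smooth_inplane(vol4d: np.ndarray, sigma_px: float = 0.5) -> np.ndarray:
    """Slice-wise 2-D Gaussian smoothing (symmetric boundary handling)."""
    if sigma_px < 0:
        raise ValueError("sigma_px must be non-negative")
    vol4d = np.asarray(vol4d, dtype=float)
    if sigma_px == 0:
        return vol4d.copy()
    sigma = (sigma_px, sigma_px) + (0,) * (vol4d.ndim - 2)
    return gaussian_filter(vol4d, sigma=sigma, mode="reflect")


def _runline_smoother(n: int, sigma_samples: float) -> np.ndarray:
    """Gaussian-weighted running-line smoother matrix (n x n).

    Row t0 gives the weights of the locally weighted linear fit
    evaluated at t0, so ``L @ y`` is the low-frequency trend of ``y``.
    """
    t = np.arange(n, dtype=float)
    L = np.empty((n, n))
    for t0 in range(n):
        d = t - t0
        w = np.exp(-0.5 * (d / sigma_samples) ** 2)
        s0 = w.sum()
        s1 = (w * d).sum()
        s2 = (w * d * d).sum()
        L[t0] = w * (s2 - s1 * d) / (s0 * s2 - s1 * s1)
    return L


def highpass_temporal(vol4d: np.ndarray, TR: float,
                      cutoff_s: float = 100.0) -> np.ndarray:
    """Temporal high-pass: Gaussian-weighted running-line detrending.

    At each time point a locally weighted linear fit (Gaussian weights,
    sigma = cutoff FWHM / 2.355 converted to samples) is subtracted and
    the series mean restored afterwards.  Removes slow drift while
    passing oscillations faster than the cutoff essentially unchanged.
    """
    vol4d = np.asarray(vol4d, dtype=float)
    n = vol4d.shape[-1]
    if n <= 3:
        raise ValueError("series too short to filter")
    if cutoff_s <= 2 * TR:
        raise ValueError("cutoff must exceed twice the TR")
    sigma_samples = (cutoff_s / 2.355) / TR
    L = _runline_smoother(n, sigma_samples)
    flat = vol4d.reshape(-1, n)
    resid = flat - flat @ L.T
    # restore the series mean exactly
    out = resid - resid.mean(axis=-1, keepdims=True) + flat.mean(
        axis=-1, keepdims=True)
    return out.reshape(vol4d.shape)


# ---------------------------------------------------------------------------
# stage 3: masks and the global regressor
# ---------------------------------------------------------------------------

def brain_mask_from_signal(mean_signal: np.ndarray,
                           threshold_frac: float = 0.10) -> np.ndarray:
    """In-brain voxels: mean BOLD-weighted signal above a fraction of the
    robust maximum (99th percentile)."""
    mean_signal = np.asarray(mean_signal, dtype=float)
    robust_max = np.percentile(mean_signal, 99)
    if robust_max <= 0:
        raise ValueError("signal volume has no positive robust maximum")
    return mean_signal > threshold_frac * robust_max


def gm_mask_from_perfusion(
    mean_perfusion: np.ndarray,
    brain_mask: np.ndarray | None = None,
    percentiles: tuple[float, float] = (85.0, 99.0),
) -> np.ndarray:
    """Grey-matter mask: perfusion between the 85th and 99th percentiles.

    Percentiles are computed over in-brain voxels (all voxels when no
    brain mask is given) with the linear-interpolation convention.
    Perfusion is much higher in grey matter than white matter, so this
    band selects grey matter while the top percentile excludes
    macrovascular (large-vessel) voxels.
    """
    mean_perfusion = np.asarray(mean_perfusion, dtype=float)
    if brain_mask is None:
        brain_mask = np.ones(mean_perfusion.shape, dtype=bool)
    vals = mean_perfusion[brain_mask]
    if vals.size == 0:
        raise ValueError("empty in-brain voxel set")
    if np.ptp(vals) == 0:
        raise ValueError("degenerate (constant) perfusion image")
    lo, hi = np.percentile(vals, percentiles)
    # tiny relative slack keeps boundary ties stable under global
    # intensity rescaling (floating-point only; no visible widening)
    tol = 1e-9 * max(abs(lo), abs(hi), float(np.ptp(vals)))
    return (brain_mask & (mean_perfusion >= lo - tol)
            & (mean_perfusion <= hi + tol))


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        raise ValueError("zero-variance series cannot be z-scored")
    return (x - x.mean()) / sd


def build_global_regressor(
    perfusion: np.ndarray,
    bold: np.ndarray,
    mask: np.ndarray,
    weights: tuple[float, float] = (2.0, 1.0),
) -> GlobalRegressor:
    """Data-driven respiratory regressor from the in-mask mean series.

    The mean BOLD and mean ASL series are each z-normalised, combined
    with a 2:1 (BOLD:ASL) weighting, and affinely rescaled to [0, 1]
    so that the regression slope directly measures the peak response.
    """
    if not np.any(mask):
        raise ValueError("mask is empty")
    mb = _zscore(bold[mask].mean(axis=0))
    ma = _zscore(perfusion[mask].mean(axis=0))
    wb, wa = weights
    combined = (wb * mb + wa * ma) / (wb + wa)
    rng = combined.max() - combined.min()
    if rng == 0:
        raise ValueError("combined regressor has zero range")
    values = (combined - combined.min()) / rng
    return GlobalRegressor(values=values, weights=weights)


# ---------------------------------------------------------------------------
# stage 4: voxelwise delay and response regression
# ---------------------------------------------------------------------------

def shift_regressor(values: np.ndarray, lag: int) -> np.ndarray:
    """Shift a regressor by ``lag`` samples (positive = later), padding
    with the edge value so the length is preserved."""
    values = np.asarray(values, dtype=float)
    if lag == 0:
        return values.copy()
    if lag > 0:
        return np.concatenate([np.full(lag, values[0]), values[:-lag]])
    return np.concatenate([values[-lag:], np.full(-lag, values[-1])])


def _lag_order(max_lag: int) -> list[int]:
    """Tie-break order: smallest |lag| first, negative before positive."""
    order = [0]
    for k in range(1, max_lag + 1):
        order.extend([-k, k])
    return order


def estimate_voxel_delay(
    bold_ts: np.ndarray,
    perfusion_ts: np.ndarray,
    regressor: GlobalRegressor,
    max_lag: int = 5,
) -> tuple[int, float]:
    """Voxel delay relative to the global regressor, in samples.

    Cross-correlates the concatenation of the z-normalised voxel BOLD
    and ASL series against the correspondingly shifted, concatenated
    regressor for integer lags in [-max_lag, +max_lag] and returns
    ``(lag, peak_correlation)``.  Ties pick the smallest |lag|, then
    the negative one.  A zero-variance voxel returns lag 0 with
    correlation 0 (to be flagged by the caller's correlation floor).
    """
    bold_ts = np.asarray(bold_ts, dtype=float)
    perfusion_ts = np.asarray(perfusion_ts, dtype=float)
    if bold_ts.shape != regressor.values.shape:
        raise ValueError("series length must match the regressor")
    sb, sp = bold_ts.std(), perfusion_ts.std()
    if sb == 0 or sp == 0:
        return 0, 0.0
    v = np.concatenate([_zscore(bold_ts), _zscore(perfusion_ts)])
    best_lag, best_corr = 0, -np.inf
    for lag in _lag_order(max_lag):
        r = _zscore(shift_regressor(regressor.values, lag))
        corr = float(v @ np.concatenate([r, r]) / v.size)
        if corr > best_corr:
            best_lag, best_corr = lag, corr
    return best_lag, best_corr


def regress_responses(voxel_ts: np.ndarray,
                      shifted_regressor: np.ndarray) -> tuple[float, float]:
    """OLS of a voxel series on [intercept, regressor].

    With the regressor scaled to unit peak the slope equals the peak
    response, so the fractional change is slope/intercept.  Returns
    ``(baseline, fractional_change)``; a non-positive baseline marks
    the voxel invalid (fractional change NaN).
    """
    y = np.asarray(voxel_ts, dtype=float)
    x = np.asarray(shifted_regressor, dtype=float)
    xm, ym = x.mean(), y.mean()
    vx = ((x - xm) ** 2).mean()
    if vx == 0:
        raise ValueError("regressor has zero variance")
    slope = ((x - xm) * (y - ym)).mean() / vx
    intercept = ym - slope * xm
    if intercept <= 0:
        return float(intercept), float("nan")
    return float(intercept), float(slope / intercept)


# ---------------------------------------------------------------------------
# stage 5: absolute CBF calibration
# ---------------------------------------------------------------------------

def calibrate_cbf(
    asl_baseline,
    pd_volume,
    cal: CalibrationSpec | None = None,
    spec: AcquisitionSpec | None = None,
):
    """Single-PLD pCASL quantification, mL/100 g/min.

    ``CBF = 6000 * lambda * dM * exp(PLD/T1b)
          / (2 * eff * M0 * T1b * (1 - exp(-tau/T1b)))``

    with ``dM`` the baseline tag/control difference and ``M0`` from the
    proton-density image.  Voxels with non-positive M0 return NaN.
    """
    cal = cal or CalibrationSpec()
    spec = spec or AcquisitionSpec()
    dm = np.asarray(asl_baseline, dtype=float)
    m0 = np.asarray(pd_volume, dtype=float)
    t1b = cal.t1_blood
    denom_scale = (2.0 * cal.efficiency * t1b
                   * (1.0 - np.exp(-spec.label_duration / t1b)))
    with np.errstate(divide="ignore", invalid="ignore"):
        cbf = (6000.0 * cal.lambda_bp * dm * np.exp(spec.PLD / t1b)
               / (denom_scale * m0))
    out = np.where(m0 > 0, cbf, np.nan)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# stage 6: orchestration
# ---------------------------------------------------------------------------

def _delays_for_voxels(
    B: np.ndarray, P: np.ndarray, regressor: GlobalRegressor,
    max_lag: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised delay estimation for (V, T) BOLD and ASL blocks."""
    def zrows(x):
        sd = x.std(axis=1, keepdims=True)
        ok = sd[:, 0] > 0
        out = np.zeros_like(x)
        np.divide(x - x.mean(axis=1, keepdims=True), sd, out=out,
                  where=sd > 0)
        return out, ok

    zb, okb = zrows(B)
    zp, okp = zrows(P)
    v = np.concatenate([zb, zp], axis=1)
    n = v.shape[1]
    lags = _lag_order(max_lag)
    corrs = np.empty((len(lags), B.shape[0]))
    for i, lag in enumerate(lags):
        r = _zscore(shift_regressor(regressor.values, lag))
        corrs[i] = v @ np.concatenate([r, r]) / n
    best = np.argmax(corrs, axis=0)  # first max = preferred tie-break order
    lag_arr = np.asarray(lags)[best]
    corr_arr = corrs[best, np.arange(B.shape[0])]
    dead = ~(okb & okp)
    lag_arr[dead] = 0
    corr_arr[dead] = 0.0
    return lag_arr, corr_arr


def _group_regress(Y: np.ndarray, lags: np.ndarray,
                   regressor: GlobalRegressor) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel OLS against the lag-shifted regressor, grouped by lag."""
    base = np.full(Y.shape[0], np.nan)
    frac = np.full(Y.shape[0], np.nan)
    for lag in np.unique(lags):
        sel = lags == lag
        x = shift_regressor(regressor.values, int(lag))
        xm = x.mean()
        vx = ((x - xm) ** 2).mean()
        yb = Y[sel]
        ym = yb.mean(axis=1)
        slope = ((yb - ym[:, None]) * (x - xm)).mean(axis=1) / vx
        intercept = ym - slope * xm
        base[sel] = intercept
        with np.errstate(divide="ignore", invalid="ignore"):
            frac[sel] = np.where(intercept > 0, slope / intercept, np.nan)
    return base, frac


def map_parameters(
    series: DualExcitationSeries,
    pd_volume: np.ndarray,
    Hb: float,
    PaO2_0: float = 127.0,
    PaO2_bh: float = 104.0,
    calibration: CalibrationSpec | None = None,
    constants: ModelConstants | None = None,
    options: PipelineOptions | None = None,
) -> ParameterMaps:
    """Run the full breath-hold calibrated pipeline on one session.

    ``Hb`` (g/dL) is the subject's haemoglobin concentration, usually
    estimated from venous blood T1 (see :mod:`bhcal.trust`); the
    baseline and breath-hold arterial O2 tensions default to the group
    mean values for room air and end-expiration breath-holding.

    Returns :class:`ParameterMaps`; invalid voxels (no vasodilatory
    response, low regressor correlation, boundary grid solutions,
    non-positive baselines) carry NaN, and ``summary`` holds the
    grey-matter means/SDs over valid voxels plus rejection counts.
    """
    cal = calibration or CalibrationSpec()
    c = constants or ModelConstants()
    opt = options or PipelineOptions()
    pd_volume = np.asarray(pd_volume, dtype=float)
    if pd_volume.shape != series.echo1.shape[:3]:
        raise ValueError("PD volume grid does not match the series")

    perfusion, bold = surround_pair(series)
    perfusion = smooth_inplane(perfusion, opt.smooth_sigma_px)
    bold = smooth_inplane(bold, opt.smooth_sigma_px)
    perfusion = highpass_temporal(perfusion, series.spec.TR,
                                  opt.highpass_cutoff_s)
    bold = highpass_temporal(bold, series.spec.TR, opt.highpass_cutoff_s)

    brain = brain_mask_from_signal(bold.mean(axis=-1),
                                   opt.brain_threshold_frac)
    gm = gm_mask_from_perfusion(perfusion.mean(axis=-1), brain,
                                opt.mask_percentiles)
    if not np.any(gm):
        raise ValueError("grey-matter mask is empty")
    regressor = build_global_regressor(perfusion, bold, gm,
                                       opt.bold_asl_weights)

    B = bold[gm]
    P = perfusion[gm]
    lags, corrs = _delays_for_voxels(B, P, regressor, opt.max_lag)
    bold_base, frac_bold = _group_regress(B, lags, regressor)
    asl_base, frac_cbf = _group_regress(P, lags, regressor)
    cbf0 = calibrate_cbf(asl_base, pd_volume[gm], cal, series.spec)

    arterial = ArterialState.from_physiology(Hb, PaO2_0, PaO2_bh, c)
    sol = solve_oef_grid_arrays(frac_bold, frac_cbf, cbf0, arterial, c)
    good = sol["valid"] & (corrs >= opt.corr_floor)
    oef = np.where(good, sol["oef0"], np.nan)
    cbf_valid = np.where(good, cbf0, np.nan)
    cmro2 = np.where(good, cmro2_fick(arterial.CaO2_0, sol["oef0"],
                                      np.where(np.isfinite(cbf0), cbf0, 0.0),
                                      c), np.nan)
    m_map = np.where(good, sol["M"], np.nan)

    def to_map(values, dtype=float):
        vol = np.full(gm.shape, np.nan, dtype=float)
        vol[gm] = values
        return vol

    n_gm = int(gm.sum())
    n_lowcorr = int(np.sum(corrs < opt.corr_floor))
    n_novasc = int(np.sum(np.isfinite(frac_cbf) & (frac_cbf <= 0)))
    n_valid = int(good.sum())
    log.info("GM voxels: %d, valid: %d, low-correlation: %d, "
             "no vascular response: %d", n_gm, n_valid, n_lowcorr, n_novasc)

    def stats(v):
        v = v[np.isfinite(v)]
        return (float(v.mean()), float(v.std())) if v.size else (np.nan, np.nan)

    summary = {
        "n_gm_voxels": n_gm,
        "n_valid_voxels": n_valid,
        "n_low_correlation": n_lowcorr,
        "n_no_vascular_response": n_novasc,
        "gm_cbf0_mean": stats(cbf_valid)[0],
        "gm_cbf0_sd": stats(cbf_valid)[1],
        "gm_oef0_mean": stats(oef)[0],
        "gm_oef0_sd": stats(oef)[1],
        "gm_cmro2_mean": stats(cmro2)[0],
        "gm_cmro2_sd": stats(cmro2)[1],
        "gm_M_mean": stats(m_map)[0],
        "gm_M_sd": stats(m_map)[1],
        "CaO2_0": arterial.CaO2_0,
        "CaO2_bh": arterial.CaO2_bh,
        "Hb": Hb,
    }
    return ParameterMaps(
        cbf0=to_map(cbf_valid),
        oef0=to_map(oef),
        cmro2_0=to_map(cmro2),
        M=to_map(m_map),
        delay=to_map(lags.astype(float)),
        frac_cbf=to_map(frac_cbf),
        frac_bold=to_map(frac_bold),
        gm_mask=gm,
        brain_mask=brain,
        regressor=regressor,
        summary=summary,
    )
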