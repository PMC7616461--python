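"""Test-retest reliability and comparison statistics.

Implements the agreement statistics used to characterise the
breath-hold calibrated measurements: two-way mixed-effects ICC with
absolute agreement, Bland-Altman limits of agreement (with a normality
gate on the central estimate), between-measurement coefficient of
variation, a paired sign-flip permutation test (ROI-level analogue of
a paired t-test), and the flow-metabolism coupling ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import stats as sps

__all__ = [
    "PairedMeasurements",
    "icc_absolute_agreement",
    "bland_altman",
    "between_measure_cv",
    "paired_permutation_test",
    "coupling_ratio",
    "repeatability_report",
]


@dataclass
class PairedMeasurements:
    """Two repeated measurements per subject."""

    a: np.ndarray
    b: np.ndarray
    subjects: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.a.shape != self.b.shape or self.a.ndim != 1:
            raise ValueError("a and b must be equal-length 1-D arrays")
        if self.a.size < 3:
            raise ValueError("need at least 3 paired measurements")
        if not (np.all(np.isfinite(self.a)) and np.all(np.isfinite(self.b))):
            raise ValueError("measurements must be finite")


def _as_pairs(pairs, b=None) -> PairedMeasurements:
    if isinstance(pairs, PairedMeasurements):
        return pairs
    return PairedMeasurements(np.asarray(pairs, float), np.asarray(b, float))


def _as_arrays(pairs, b=None) -> tuple[np.ndarray, np.ndarray]:
    """Like ``_as_pairs`` but admits n = 2 (agreement stats only)."""
    if isinstance(pairs, PairedMeasurements):
        return pairs.a, pairs.b
    a = np.asarray(pairs, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need equal-length 1-D arrays with n >= 2")
    return a, b


def icc_absolute_agreement(pairs, b=None, ci: float = 0.95):
    """ICC(A,1): two-way mixed effects, absolute agreement, single rater.

    Computed from the two-way ANOVA mean squares (rows = subjects,
    columns = measurements)::

        ICC = (MSR - MSE) / (MSR + (k-1)*MSE + (k/n)*(MSC - MSE))

    The confidence interval is the standard F-based interval for the
    absolute-agreement single-measure ICC (Satterthwaite degrees of
    freedom for the lower-tail F).  Returns ``(icc, ci_low, ci_high)``.
    """
    p = _as_pairs(pairs, b)
    x = np.column_stack([p.a, p.b])
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    if np.allclose(x, grand):
        raise ValueError("zero total variance: ICC undefined")
    msr = k * ((row_means - grand) ** 2).sum() / (n - 1)
    msc = n * ((col_means - grand) ** 2).sum() / (k - 1)
    mse = (((x - row_means[:, None] - col_means[None, :] + grand) ** 2).sum()
           / ((n - 1) * (k - 1)))
    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)

    alpha = 1.0 - ci
    if icc >= 1.0 or np.isclose(mse, 0) and np.isclose(msc, msr):
        return float(icc), float(icc), float(icc)
    a_coef = k * icc / (n * (1.0 - icc))
    b_coef = 1.0 + k * icc * (n - 1) / (n * (1.0 - icc))
    v_num = (a_coef * msc + b_coef * mse) ** 2
    v_den = ((a_coef * msc) ** 2 / (k - 1)
             + (b_coef * mse) ** 2 / ((n - 1) * (k - 1)))
    v = v_num / v_den if v_den > 0 else 1.0
    f_l = sps.f.ppf(1.0 - alpha / 2, n - 1, v)
    f_u = sps.f.ppf(1.0 - alpha / 2, v, n - 1)
    lower = (n * (msr - f_l * mse)
             / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr))
    upper = (n * (f_u * msr - mse)
             / (k * msc + (k * n - k - n) * mse + n * f_u * msr))
    return float(icc), float(lower), float(upper)


def bland_altman(pairs, b=None,
                 central: Literal["mean", "median", "auto"] = "mean"):
    """Bland-Altman agreement: bias and 95% limits of agreement.

    With ``central="mean"`` the bias is the mean difference and the
    limits are bias +/- 1.96*SD of the differences.  With ``"median"``
    (used when either variable departs from normality) the bias is the
    median difference and the limits are the 2.5th/97.5th percentiles.
    ``"auto"`` applies a Shapiro-Wilk gate (p < 0.05 on either
    variable) to choose.  Returns ``(bias, loa_low, loa_high)``.
    """
    a, bb = _as_arrays(pairs, b)
    d = a - bb
    if central == "auto":
        if a.size < 3:
            central = "mean"
        else:
            normal = all(sps.shapiro(v).pvalue >= 0.05 for v in (a, bb))
            central = "mean" if normal else "median"
    if central == "mean":
        bias = float(d.mean())
        sd = float(d.std(ddof=1))
        return bias, bias - 1.96 * sd, bias + 1.96 * sd
    if central == "median":
        bias = float(np.median(d))
        lo, hi = np.percentile(d, [2.5, 97.5])
        return bias, float(lo), float(hi)
    raise ValueError("central must be 'mean', 'median' or 'auto'")


def between_measure_cv(pairs, b=None):
    """Within-subject coefficient of variation between two measurements.

    Per subject, ``CV = |A - B| / (sqrt(2) * mean(A, B)) * 100`` —
    the two-point SD (n-1 denominator) over the two-point mean.
    Returns ``(mean_cv, sd_cv)`` across subjects, in percent.
    """
    a, bb = _as_arrays(pairs, b)
    m = 0.5 * (a + bb)
    if np.any(m == 0):
        raise ValueError("zero subject mean: CV undefined")
    cv = np.abs(a - bb) / (np.sqrt(2.0) * m) * 100.0
    sd = float(cv.std(ddof=1)) if cv.size > 1 else float("nan")
    return float(cv.mean()), sd


def paired_permutation_test(pairs, b=None, n_perm: int = 10000,
                            seed: int | None = None) -> float:
    """Two-tailed paired test by sign-flipping of the differences.

    Under the null of no condition effect the sign of each paired
    difference is exchangeable; p is the proportion of sign
    assignments with |mean difference| at least the observed one.  All
    2^n assignments are enumerated when n <= 14, otherwise ``n_perm``
    random assignments are drawn (deterministic given ``seed``) and
    the observed assignment is included in the numerator and
    denominator.
    """
    if b is not None or isinstance(pairs, PairedMeasurements):
        p = _as_pairs(pairs, b)
        d = p.a - p.b
    else:
        d = np.asarray(pairs, dtype=float)
    n = d.size
    observed = abs(d.mean())
    tol = 1e-12 * max(1.0, observed)
    if n <= 14:
        bits = np.arange(2 ** n)[:, None] >> np.arange(n)[None, :] & 1
        signs = 1.0 - 2.0 * bits
        means = np.abs(signs @ d) / n
        return float(np.mean(means >= observed - tol))
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    means = np.abs(signs @ d) / n
    hits = int(np.sum(means >= observed - tol))
    return float((hits + 1) / (n_perm + 1))


def coupling_ratio(pct_cbf: float, pct_cmro2: float) -> float:
    """Flow-metabolism coupling: %CBF increase over %CMRO2 increase."""
    if pct_cmro2 <= 0:
        raise ValueError("CMRO2 change must be positive for a coupling ratio")
    return pct_cbf / pct_cmro2


def repeatability_report(pairs, b=None, seed: int | None = None) -> dict:
    """ICC, Bland-Altman, CV and sign-flip p for one paired variable."""
    p = _as_pairs(pairs, b)
    icc, lo, hi = icc_absolute_agreement(p)
    bias, loa_lo, loa_hi = bland_altman(p, central="auto")
    cv_mean, cv_sd = between_measure_cv(p)
    pval = paired_permutation_test(p, seed=seed)
    return {
        "n": int(p.a.size),
        "icc": icc, "icc_ci": [lo, hi],
        "bias": bias, "loa": [loa_lo, loa_hi],
        "cv_mean_pct": cv_mean, "cv_sd_pct": cv_sd,
        "p_sign_flip": pval,
    }
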