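"""Dipolar-recoupling (PITHIRDS-CT) decay curves and near-Lorentzian fits.

The PITHIRDS-CT experiment measures the decay of ¹³C NMR signal as a
function of dipolar recoupling time t (0–61.4 ms in the experiments this
package models).  Faster decay indicates shorter ¹³C–¹³C distances.  The
decay is summarized by fitting the near-Lorentzian

    y(t) = 1 / [1 + (t / t_d)**alpha]

where t_d (ms) is the half-decay time — y(t_d) = 1/2 exactly — and alpha
is a dimensionless shape exponent.  alpha may be fixed (a single value,
e.g. 1.84, shared across samples) or fitted freely.

Peak heights entering a decay curve come from 1D Gaussian fits of the NMR
peaks, with 95% confidence intervals from the asymptotic parameter
covariance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .errors import DecayFitError, PeakFitError

__all__ = [
    "DecayCurve",
    "NearLorentzianFit",
    "near_lorentzian",
    "fit_near_lorentzian",
    "normalize_decay",
    "gaussian_peak_height",
]


@dataclass
class DecayCurve:
    """Signal intensity versus dipolar recoupling time.

    t : recoupling times in ms, nonnegative and strictly increasing.
    y : intensities (normalized curves start at 1 for the first point).
    y_err : optional 95% CI half-widths on y.
    """

    t: np.ndarray
    y: np.ndarray
    y_err: np.ndarray | None = None
    label: str = ""

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.t.ndim != 1 or self.t.shape != self.y.shape:
            raise ValueError("t and y must be 1D arrays of equal length")
        if np.any(self.t < 0):
            raise ValueError("recoupling times must be nonnegative")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("recoupling times must be strictly increasing")
        if not np.all(np.isfinite(self.y)):
            raise ValueError("intensities must be finite")
        if self.y_err is not None:
            self.y_err = np.asarray(self.y_err, dtype=float)
            if self.y_err.shape != self.y.shape:
                raise ValueError("y_err must match y in shape")
            if np.any(self.y_err < 0):
                raise ValueError("y_err must be nonnegative")


@dataclass
class NearLorentzianFit:
    """Fitted near-Lorentzian parameters with 95% confidence intervals.

    ``ci_t_d`` / ``ci_alpha`` are CI half-widths; ``ci_alpha`` is 0 when
    alpha was held fixed (``alpha_fixed`` True).
    """

    t_d: float
    alpha: float
    ci_t_d: float
    ci_alpha: float
    alpha_fixed: bool
    residual_rms: float

    def __call__(self, t):
        return near_lorentzian(t, self.t_d, self.alpha)


def near_lorentzian(t, t_d: float, alpha: float):
    """Evaluate y = 1 / [1 + (t/t_d)**alpha].

    Strictly decreasing in t, with y(0) = 1 and y(t_d) = 1/2.
    """
    if t_d <= 0:
        raise ValueError("t_d must be positive")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be nonnegative")
    return 1.0 / (1.0 + (t / t_d) ** alpha)


def _initial_t_d(t: np.ndarray, y: np.ndarray) -> float:
    """Initial half-decay guess: where the curve crosses 1/2."""
    below = np.nonzero(y <= 0.5)[0]
    if below.size:
        i = below[0]
        if i == 0:
            return max(t[0], 0.5 * t[1] if t.size > 1 else 1.0)
        # linear interpolation between the bracketing points
        t0, t1 = t[i - 1], t[i]
        y0, y1 = y[i - 1], y[i]
        if y0 != y1:
            return t0 + (y0 - 0.5) * (t1 - t0) / (y0 - y1)
        return t1
    return float(t[-1])  # never reaches 1/2 within the window: slow decay


def fit_near_lorentzian(curve: DecayCurve, alpha: float | None = 1.84) -> NearLorentzianFit:
    """Weighted least-squares fit of the near-Lorentzian decay model.

    Parameters
    ----------
    curve
        Decay data; weights are taken from ``curve.y_err`` when present and
        strictly positive everywhere.
    alpha
        A number to hold the shape exponent fixed at that value (the
        default 1.84 is the shared exponent used to compare half-decay
        times across samples), or ``None`` to fit alpha freely.

    Returns
    -------
    NearLorentzianFit with 95% CIs from the asymptotic covariance.

    Raises
    ------
    DecayFitError
        For fewer than 4 points, a curve with no decay information
        (min y ≥ 0.9), non-convergence, or t_d at the search bound.
    """
    t, y = curve.t, curve.y
    if t.size < 4:
        raise DecayFitError(f"need at least 4 points, got {t.size}")
    if float(np.min(y)) >= 0.9:
        raise DecayFitError(
            "no decay information: all intensities >= 0.9",
            {"min_y": float(np.min(y))},
        )
    sigma = None
    if curve.y_err is not None and np.all(curve.y_err > 0):
        sigma = curve.y_err

    t_pos_max = float(t[-1])
    t_d_hi = 100.0 * t_pos_max
    t_d0 = float(np.clip(_initial_t_d(t, y), 1e-3 * t_pos_max, t_d_hi / 2))

    free_alpha = alpha is None
    if free_alpha:
        model = lambda tt, td, al: near_lorentzian(tt, td, al)
        p0 = [t_d0, 1.84]
        bounds = ([1e-9, 1e-3], [t_d_hi, 50.0])
    else:
        if alpha <= 0:
            raise ValueError("fixed alpha must be positive")
        model = lambda tt, td: near_lorentzian(tt, td, alpha)
        p0 = [t_d0]
        bounds = ([1e-9], [t_d_hi])

    try:
        popt, pcov = curve_fit(
            model, t, y, p0=p0, sigma=sigma, bounds=bounds,
            xtol=1e-14, ftol=1e-14, gtol=1e-14, maxfev=10000,
        )
    except RuntimeError as exc:
        raise DecayFitError(
            "near-Lorentzian fit did not converge",
            {"p0": p0, "message": str(exc)},
        ) from exc

    t_d = float(popt[0])
    if t_d >= t_d_hi * (1 - 1e-6):
        raise DecayFitError(
            "t_d hit the upper search bound — the data carry no decay on this window",
            {"t_d": t_d, "bound": t_d_hi},
        )
    perr = np.sqrt(np.diag(pcov))
    fitted_alpha = float(popt[1]) if free_alpha else float(alpha)
    resid = y - near_lorentzian(t, t_d, fitted_alpha)
    return NearLorentzianFit(
        t_d=t_d,
        alpha=fitted_alpha,
        ci_t_d=float(1.96 * perr[0]),
        ci_alpha=float(1.96 * perr[1]) if free_alpha else 0.0,
        alpha_fixed=not free_alpha,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
    )


def normalize_decay(t, y, y_err=None, label: str = "") -> DecayCurve:
    """Normalize raw peak heights to the t = 0 (or minimal-t) reference.

    All intensities are divided by the reference intensity; uncertainties
    are propagated by the first-order ratio rule

        sigma_out = (1/y_ref) * sqrt(sigma_i**2 + (y_i / y_ref)**2 * sigma_ref**2)

    so a reference with zero CI simply scales the CIs by 1/y_ref.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    order = np.argsort(t)
    t, y = t[order], y[order]
    ref = y[0]
    if ref <= 0:
        raise ValueError(f"reference intensity at t={t[0]} must be positive, got {ref}")
    out_err = None
    if y_err is not None:
        y_err = np.asarray(y_err, dtype=float)[order]
        ref_err = y_err[0]
        out_err = np.sqrt(y_err**2 + (y / ref) ** 2 * ref_err**2) / ref
        # the reference point itself is exactly 1 by construction
        out_err[0] = 0.0 if ref_err == 0 else out_err[0]
    return DecayCurve(t=t, y=y / ref, y_err=out_err, label=label)


def _gauss1d(x, amp, center, sigma, baseline):
    return amp * np.exp(-((x - center) ** 2) / (2.0 * sigma**2)) + baseline


def gaussian_peak_height(x, y, region: tuple[float, float] | None = None) -> tuple[float, float]:
    """Peak height from a 1D Gaussian-plus-baseline least-squares fit.

    Parameters
    ----------
    x, y
        1D signal, e.g. intensity versus ppm.
    region
        Optional (low, high) window on x; the fit uses points inside it.

    Returns
    -------
    (height, ci95) — the fitted amplitude above baseline and its 95% CI
    half-width from the asymptotic covariance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if region is not None:
        lo, hi = sorted(region)
        mask = (x >= lo) & (x <= hi)
        x, y = x[mask], y[mask]
    if x.size < 5:
        raise PeakFitError(f"need at least 5 points in the fit region, got {x.size}")
    span = np.ptp(y)
    if span == 0:
        raise PeakFitError("flat signal: no peak to fit")
    i_max = int(np.argmax(y))
    p0 = [span, float(x[i_max]), max(np.ptp(x) / 10.0, 1e-6), float(np.min(y))]
    try:
        popt, pcov = curve_fit(
            _gauss1d, x, y, p0=p0,
            bounds=([0, x.min(), 1e-9, -np.inf], [np.inf, x.max(), np.inf, np.inf]),
            maxfev=10000,
        )
    except RuntimeError as exc:
        raise PeakFitError("1D Gaussian fit did not converge", {"p0": p0}) from exc
    return float(popt[0]), float(1.96 * np.sqrt(pcov[0, 0]))
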