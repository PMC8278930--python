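"""Relative beta-sheet fraction from the 218 nm CD melt signal.

The 218 nm band reports beta-sheet content (more beta-sheet = more negative
MRE).  The raw melt signal y(T) is converted to a dimensionless relative
fraction

    f(T) = (y(T) - y0(T)) / (ymax(T) - y0(T))

where y0 and ymax are the reference signals of the minimum- and
maximum-beta-sheet conformers.  Two referencing modes exist:

* ``two_state`` — y0 and ymax are linear baselines extrapolated from the low-
  and high-temperature plateaus (sigmoidal, monotone melts);
* ``peak_referenced`` — y0 and ymax are constants: the endpoint signal of
  minimum magnitude and the strongest (most negative) signal over all
  temperatures (rise-then-fall melts whose beta-sheet content peaks at an
  interior temperature).

All downstream quantities are invariant under any affine transform of y, so
the choice of raw units (mdeg vs MRE) does not matter here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import linregress

from .io import MeltSignal, ValidationError

__all__ = [
    "BaselineFit",
    "BetaFractionCurve",
    "fit_baseline",
    "fraction_two_state",
    "fraction_peak_referenced",
    "rescale_unit_interval",
    "select_mode",
]


@dataclass(frozen=True)
class BaselineFit:
    """Ordinary least-squares line y = intercept + slope * T over ``T_range``."""

    intercept: float
    slope: float
    T_range: tuple[float, float]
    which: str  # "low_T" or "high_T"
    r_squared: float
    n_points: int = 0

    def __call__(self, T):
        return self.intercept + self.slope * np.asarray(T, dtype=float)


@dataclass
class BetaFractionCurve:
    """Relative beta-sheet fraction f versus temperature."""

    temperatures: np.ndarray
    f: np.ndarray
    mode: str  # "two_state" or "peak_referenced"
    y0_ref: object = None
    ymax_ref: object = None
    scaled: bool = False

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.f = np.asarray(self.f, dtype=float)
        if self.temperatures.shape != self.f.shape:
            raise ValidationError("temperatures and f must have equal length")


def fit_baseline(signal: MeltSignal, T_range: tuple[float, float],
                 which: str) -> BaselineFit:
    """Least-squares baseline over the temperatures inside ``T_range``."""
    if which not in ("low_T", "high_T"):
        raise ValueError("which must be 'low_T' or 'high_T'")
    lo, hi = min(T_range), max(T_range)
    mask = (signal.temperatures >= lo) & (signal.temperatures <= hi)
    n = int(mask.sum())
    if n < 3:
        raise ValidationError(
            f"baseline fit needs >= 3 points in [{lo:g}, {hi:g}] degC, found {n}"
        )
    T = signal.temperatures[mask]
    y = signal.y[mask]
    res = linregress(T, y)
    return BaselineFit(
        intercept=float(res.intercept), slope=float(res.slope),
        T_range=(lo, hi), which=which,
        r_squared=float(res.rvalue ** 2) if np.std(y) > 0 else 1.0,
        n_points=n,
    )


def fraction_two_state(signal: MeltSignal, low: BaselineFit, high: BaselineFit,
                       denom_floor_rel: float = 1e-6) -> BetaFractionCurve:
    """Baseline-referenced fraction for a two-state (sigmoidal) melt.

    f(T) = (y - y0(T)) / (ymax(T) - y0(T)) with y0, ymax the extrapolated low-
    and high-temperature baselines, so f = 0 on the low baseline and f = 1 on
    the high one.  Raises when the baselines (nearly) cross inside the data.
    """
    if low.which != "low_T" or high.which != "high_T":
        raise ValueError("pass the low-T baseline first and the high-T baseline second")
    T = signal.temperatures
    y0 = low(T)
    ymax = high(T)
    denom = ymax - y0
    floor = denom_floor_rel * abs(high(25.0) - low(25.0))
    bad = np.abs(denom) < max(floor, np.finfo(float).tiny)
    if np.any(bad):
        t_bad = T[bad][0]
        raise ValidationError(
            f"baselines degenerate at T = {t_bad:g} degC (|ymax - y0| below floor)"
        )
    f = (signal.y - y0) / denom
    return BetaFractionCurve(T.copy(), f, mode="two_state", y0_ref=low, ymax_ref=high)


def fraction_peak_referenced(signal: MeltSignal) -> BetaFractionCurve:
    """Constant-referenced fraction for rise-then-fall (non-monotone) melts.

    y0 is the endpoint signal of minimum magnitude; ymax is the strongest
    (most negative) signal anywhere on the curve, so f = 1 at the temperature
    of maximum beta-sheet content.
    """
    y = signal.y
    if y.size < 2:
        raise ValidationError("need at least 2 points")
    endpoints = np.array([y[0], y[-1]])
    y0 = float(endpoints[np.argmin(np.abs(endpoints))])
    ymax = float(y[np.argmax(np.abs(y - y0))]) if np.ptp(y) > 0 else y0
    # the strongest signal: for a negative 218 nm band this is the most
    # negative value; implemented as the value farthest from the reference so
    # the same code handles a sign-flipped input.
    if ymax == y0:
        raise ValidationError("flat signal: y0 equals ymax, fraction undefined")
    f = (y - y0) / (ymax - y0)
    return BetaFractionCurve(signal.temperatures.copy(), f,
                             mode="peak_referenced", y0_ref=y0, ymax_ref=ymax)


def rescale_unit_interval(curve: BetaFractionCurve) -> BetaFractionCurve:
    """Affine map of f onto [0, 1]; minimum-beta conformers get f = 0, maximum
    get f = 1.  Idempotent."""
    fmin, fmax = float(np.min(curve.f)), float(np.max(curve.f))
    if fmax <= fmin:
        raise ValidationError("constant fraction curve cannot be rescaled")
    f = (curve.f - fmin) / (fmax - fmin)
    return BetaFractionCurve(curve.temperatures.copy(), f, mode=curve.mode,
                             y0_ref=curve.y0_ref, ymax_ref=curve.ymax_ref,
                             scaled=True)


def _boltzmann(T, A1, A2, T0, dT):
    return A2 + (A1 - A2) / (1.0 + np.exp((T - T0) / dT))


def _bigauss(T, H, Tc, s1, s2, off):
    s = np.where(T <= Tc, s1, s2)
    return off + H * np.exp(-((T - Tc) ** 2) / (2.0 * s ** 2))


def select_mode(signal: MeltSignal) -> str:
    """Choose the referencing mode from the raw melt shape.

    A Boltzmann sigmoid and a bi-Gaussian are both fitted to y(T); the lower
    root-mean-square error wins (``peak_referenced`` when the bi-Gaussian is
    the better description, ``two_state`` otherwise or on any tie/failure).
    """
    T, y = signal.temperatures, signal.y
    if T.size < 6:
        return "two_state"
    span = float(y[-1] - y[0]) or 1.0

    def rmse(fun, p0, bounds=(-np.inf, np.inf)):
        try:
            popt, _ = curve_fit(fun, T, y, p0=p0, bounds=bounds, maxfev=20000)
        except (RuntimeError, ValueError):
            return np.inf
        r = y - fun(T, *popt)
        return float(np.sqrt(np.mean(r ** 2)))

    rm_sig = rmse(_boltzmann, [y[0], y[-1], float(T[T.size // 2]), (T[-1] - T[0]) / 10.0])
    i_ext = int(np.argmax(np.abs(y - (y[0] + y[-1]) / 2.0)))
    H0 = float(y[i_ext] - (y[0] + y[-1]) / 2.0)
    w0 = (T[-1] - T[0]) / 4.0
    rm_big = rmse(_bigauss, [H0, float(T[i_ext]), w0, w0, float((y[0] + y[-1]) / 2.0)],
                  bounds=([-np.inf, T[0] - 50, 1e-3, 1e-3, -np.inf],
                          [np.inf, T[-1] + 50, np.inf, np.inf, np.inf]))
    return "peak_referenced" if rm_big < rm_sig else "two_state"
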