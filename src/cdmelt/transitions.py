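"""Segmentation of beta-sheet-fraction melt curves.

A melt curve f(T) is decomposed into m near-linear plateau regions separated
by r sigmoidal transitions.  Each transition is modelled by a Boltzmann
sigmoid

    f(T) = A2 + (A1 - A2) / (1 + exp((T - T0) / dT))

whose midpoint T0 is the transition temperature T_m.  Adjacent sigmoids cross
at an intersection temperature T_I, interpreted as a local free-energy
minimum separating conformational regimes; the onset temperature T_onset
marks where the first transition departs from the low-temperature plateau.
The overall curve shape (parabolic / Gaussian / bi-Gaussian guide model) is
selected by minimum RMSE.

All fits use deterministic initial guesses; no random restarts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, curve_fit
from scipy.signal import find_peaks, savgol_filter
from scipy.stats import linregress

from .beta_fraction import BetaFractionCurve
from .io import ValidationError

__all__ = [
    "LinearPlateau",
    "BoltzmannSigmoid",
    "ShapeModel",
    "SegmentationResult",
    "SegmentationError",
    "boltzmann",
    "ChainModel",
    "detect_plateaus",
    "fit_sigmoid_chain",
    "refine_chain",
    "fit_shape_models",
    "intersection_temperature",
    "onset_temperature",
    "segment_curve",
    "rmse",
]


class SegmentationError(RuntimeError):
    """Raised when a curve cannot be decomposed into plateaus and sigmoids."""


def boltzmann(T, A1, A2, T0, dT):
    """Boltzmann sigmoid, Origin parameterisation; A1 is the low-T asymptote."""
    return A2 + (A1 - A2) / (1.0 + np.exp((np.asarray(T, dtype=float) - T0) / dT))


def rmse(residuals: np.ndarray) -> float:
    """Root-mean-square error sqrt(RSS / n)."""
    r = np.asarray(residuals, dtype=float)
    return float(np.sqrt(np.mean(r ** 2)))


@dataclass(frozen=True)
class LinearPlateau:
    T_range: tuple[float, float]
    slope: float
    intercept: float
    r_squared: float
    n_points: int

    def __call__(self, T):
        return self.intercept + self.slope * np.asarray(T, dtype=float)


@dataclass(frozen=True)
class BoltzmannSigmoid:
    A1: float
    A2: float
    T0: float
    dT: float
    fit_T_range: tuple[float, float]
    rmse: float
    stderr: tuple[float, float, float, float] | None = None

    def __call__(self, T):
        return boltzmann(T, self.A1, self.A2, self.T0, self.dT)

    @property
    def amplitude(self) -> float:
        return self.A2 - self.A1

    @property
    def midpoint_slope(self) -> float:
        """df/dT at T0 = (A2 - A1) / (4 dT)."""
        return (self.A2 - self.A1) / (4.0 * self.dT)


@dataclass(frozen=True)
class ShapeModel:
    kind: str  # "parabolic" | "gaussian" | "bigaussian"
    params: tuple
    rmse: float
    all_rmse: dict = field(default_factory=dict)

    def __call__(self, T):
        T = np.asarray(T, dtype=float)
        if self.kind == "parabolic":
            a, b, c = self.params
            return a * T ** 2 + b * T + c
        if self.kind == "gaussian":
            H, Tc, s, off = self.params
            return off + H * np.exp(-((T - Tc) ** 2) / (2 * s ** 2))
        H, Tc, s1, s2, off = self.params
        s = np.where(T <= Tc, s1, s2)
        return off + H * np.exp(-((T - Tc) ** 2) / (2 * s ** 2))


@dataclass(frozen=True)
class ChainModel:
    """Global model of a melt curve: linear baseline plus a sum of two-state
    van't Hoff components,

        f(T) = a + b T + sum_i delta_i p_i(T),
        p_i(T) = K_i / (1 + K_i),
        K_i(T) = exp(-(dH_i / R) (1/T_K - 1/T_m_i,K)),

    so p_i rises 0 -> 1 with midpoint exactly at T_m_i and van't Hoff
    enthalpy dH_i (J/mol).  Fitted jointly over the whole curve, it
    disentangles overlapping transitions: the region-local fraction of
    component i is the observed curve minus the baseline and every other
    component, scaled by delta_i.
    """

    a: float
    b: float
    components: tuple  # of (delta, T_m degC, dH_vH J/mol)
    rmse: float = np.nan

    @staticmethod
    def _p(T, T_m, dH):
        T_K = np.asarray(T, dtype=float) + 273.15
        lnK = -(dH / 8.314) * (1.0 / T_K - 1.0 / (T_m + 273.15))
        return 1.0 / (1.0 + np.exp(-lnK))

    def __call__(self, T):
        T = np.asarray(T, dtype=float)
        out = self.a + self.b * T
        for d, T_m, dH in self.components:
            out = out + d * self._p(T, T_m, dH)
        return out

    def level_before(self, i: int, T):
        """Reference level y0_i(T): baseline plus all completed lower-T
        components."""
        T = np.asarray(T, dtype=float)
        lvl = self.a + self.b * T
        for d, _, _ in self.components[:i]:
            lvl = lvl + d
        return lvl

    def component_fraction(self, i: int, T):
        """Model progress fraction p_i(T) of component i."""
        d, T_m, dH = self.components[i]
        return self._p(T, T_m, dH)

    def region_curve(self, i: int):
        """The full fitted curve of region i alone: reference level plus its
        own component (the analogue of one plotted sigmoid)."""
        d, T_m, dH = self.components[i]

        def curve(T):
            return self.level_before(i, T) + d * self._p(T, T_m, dH)

        return curve

    def region_fraction(self, i: int, T, f_obs):
        """Overlap-corrected progress fraction of component i from the data:
        observed curve minus baseline and all other components, over
        delta_i."""
        d, T_m, dH = self.components[i]
        other = self.a + self.b * np.asarray(T, dtype=float)
        for j, (dj, Tmj, dHj) in enumerate(self.components):
            if j < i:
                other = other + dj
            elif j > i:
                other = other + dj * self._p(T, Tmj, dHj)
        return (np.asarray(f_obs, dtype=float) - other) / d

    def effective_width(self, i: int) -> float:
        """Boltzmann-equivalent width dT = R T_m,K^2 / dH (degC)."""
        _, T_m, dH = self.components[i]
        return 8.314 * (T_m + 273.15) ** 2 / dH


@dataclass
class SegmentationResult:
    plateaus: list
    sigmoids: list
    T_m: list
    T_I: list
    T_onset: float | None
    shape: ShapeModel | None
    n: int
    chain: ChainModel | None = None

    @property
    def r(self) -> int:
        return len(self.sigmoids)

    @property
    def m(self) -> int:
        return len(self.plateaus)


# ---------------------------------------------------------------------------
# plateau detection


def _ols_window(T, f, i0, i1):
    """Line fit on the closed index window [i0, i1]; returns slope, icpt, r2, rms."""
    x, y = T[i0:i1 + 1], f[i0:i1 + 1]
    if np.ptp(y) == 0:
        return 0.0, float(y[0]), 1.0, 0.0
    res = linregress(x, y)
    pred = res.intercept + res.slope * x
    return float(res.slope), float(res.intercept), float(res.rvalue ** 2), rmse(y - pred)


def _noise_sd(f: np.ndarray) -> float:
    """Robust point-noise estimate from the residuals of a mild quadratic
    Savitzky-Golay smooth.  For white noise the 7-point order-2 filter leaves
    a residual with variance (2/3) sigma^2; the MAD makes the estimate robust
    to the model bias concentrated at sharp transitions."""
    n = f.size
    win = min(7, n if n % 2 else n - 1)
    if win < 5:
        return float(np.std(np.diff(f)) / np.sqrt(2.0))
    r = f - savgol_filter(f, win, 2)
    mad = float(np.median(np.abs(r - np.median(r))))
    return 1.4826 * mad / np.sqrt(2.0 / 3.0)


def _smooth_derivative(T, f):
    n = f.size
    win = min(7, n if n % 2 else n - 1)
    if win >= 5:
        order = min(2, win - 2)
        dt = float(np.mean(np.diff(T)))
        return savgol_filter(f, win, order, deriv=1, delta=dt)
    return np.gradient(f, T)


def detect_plateaus(curve: BetaFractionCurve, min_points: int = 5,
                    slope_tol: float = 0.005, r2_floor: float = 0.98,
                    resid_k: float = 1.6) -> list[LinearPlateau]:
    """Find the near-linear plateau regions of a melt curve.

    Seeds are placed at both data ends and at the flattest point of a smoothed
    |df/dT| between each pair of transition peaks; each seed window of
    ``min_points`` is grown greedily outwards while the window remains
    plateau-like, meaning the line fit's residual RMS stays consistent with
    the point-noise level (within a factor ``resid_k``) and |slope| <=
    ``slope_tol`` f-units/degC.  The residual criterion — not r^2, which is
    ill-defined on flat noisy data — is what stops growth at the curvature of
    an adjacent sigmoid; ``r2_floor`` is retained as an additional acceptance
    stamp on strongly sloped linear baselines.  Seed windows themselves are
    always kept: the flattest point between two transitions is the regime
    separator even when residual transition overlap leaves it slightly
    sloped.  Overlapping windows are merged.  ``slope_tol`` is calibrated for
    curves rescaled to a unit f span, where sigmoid midpoint slopes are an
    order of magnitude steeper.
    """
    T = curve.temperatures
    f = curve.f
    n = f.size
    if n < 2 * min_points:
        raise SegmentationError(f"need at least {2 * min_points} points, have {n}")

    deriv = _smooth_derivative(T, f)
    sigma = _noise_sd(f)
    ad = np.abs(deriv)
    # a transition peak must rise clearly above plateau slopes and above the
    # noise floor of the smoothed derivative (sd ~ 0.19 sigma per grid step
    # for the 7-point order-2 filter)
    dt = float(np.mean(np.diff(T)))
    peak_height = max(0.15 * float(ad.max()), 3.0 * slope_tol,
                      6.0 * 0.19 * sigma / dt)
    peaks, _ = find_peaks(ad, height=peak_height, distance=max(2, min_points // 2),
                          prominence=0.6 * peak_height)

    # seed indices: data ends plus the flattest point between adjacent peaks
    seeds = [0, n - 1]
    for a, b in zip(peaks[:-1], peaks[1:]):
        if b - a > 2:
            seeds.append(int(a + 1 + np.argmin(ad[a + 1:b])))
    seeds = sorted(set(seeds))

    resid_tol = max(resid_k * sigma, 1e-12)

    def plateau_like(slope, rms, i0, i1):
        # the slope criterion carries a noise allowance: on a short window
        # the fitted slope of pure noise fluctuates by ~sigma/sx, and a
        # single unlucky extension must not halt growth permanently
        x = T[i0:i1 + 1]
        sx = float(np.sqrt(np.sum((x - x.mean()) ** 2))) or 1.0
        return (rms <= resid_tol
                and abs(slope) <= slope_tol + 2.0 * sigma / sx)

    windows: list[tuple[int, int]] = []
    half = min_points // 2
    for s in seeds:
        i0 = max(0, min(s - half, n - min_points))
        i1 = i0 + min_points - 1
        grew = True
        while grew:
            grew = False
            for lo, hi in ((i0 - 1, i1), (i0, i1 + 1)):
                if lo < 0 or hi > n - 1:
                    continue
                sl, ic, r2n, rmsn = _ols_window(T, f, lo, hi)
                if plateau_like(sl, rmsn, lo, hi):
                    i0, i1 = lo, hi
                    grew = True
        windows.append((i0, i1))

    if not windows:
        raise SegmentationError(
            "no plateau region found; supply baseline T ranges manually"
        )
    # merge overlapping / touching windows
    windows.sort()
    merged = [windows[0]]
    for a, b in windows[1:]:
        la, lb = merged[-1]
        if a <= lb + 1:
            merged[-1] = (la, max(lb, b))
        else:
            merged.append((a, b))

    plateaus = []
    for i0, i1 in merged:
        slope, icpt, r2, _ = _ols_window(T, f, i0, i1)
        plateaus.append(LinearPlateau(
            T_range=(float(T[i0]), float(T[i1])), slope=slope, intercept=icpt,
            r_squared=r2, n_points=i1 - i0 + 1))
    return plateaus


# ---------------------------------------------------------------------------
# sigmoid chain


def _fit_boltzmann(T, f, deriv=None):
    if T.size < 4:
        return None
    A1_0 = float(np.mean(f[:max(2, T.size // 8)]))
    A2_0 = float(np.mean(f[-max(2, T.size // 8):]))
    if deriv is None:
        deriv = np.gradient(f, T)
    T0_0 = float(T[np.argmax(np.abs(deriv))])
    span = float(T[-1] - T[0])
    p0 = [A1_0, A2_0, T0_0, max(span / 10.0, 0.3)]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, pcov = curve_fit(
                boltzmann, T, f, p0=p0,
                bounds=([-np.inf, -np.inf, T[0] - span, 0.05],
                        [np.inf, np.inf, T[-1] + span, 5 * span]),
                maxfev=20000)
    except (RuntimeError, ValueError):
        return None
    resid = f - boltzmann(T, *popt)
    err = tuple(np.sqrt(np.diag(pcov)).tolist()) if np.all(np.isfinite(pcov)) else None
    return BoltzmannSigmoid(
        A1=float(popt[0]), A2=float(popt[1]), T0=float(popt[2]), dT=float(popt[3]),
        fit_T_range=(float(T[0]), float(T[-1])), rmse=rmse(resid), stderr=err)


def fit_sigmoid_chain(curve: BetaFractionCurve, plateaus: list[LinearPlateau],
                      shape: ShapeModel | None = None,
                      min_amplitude: float = 0.05) -> list[BoltzmannSigmoid]:
    """Fit one Boltzmann sigmoid between each sequential pair of plateaus.

    Spans are inclusive of the bounding plateau points.  When the last plateau
    does not reach the end of the data a final sigmoid is fitted from that
    plateau to the data end point — the minimum of the fitted (bi-)Gaussian
    guide model when one is supplied, else the last data point.  Fitted
    sigmoids whose amplitude is below ``min_amplitude`` (in f units, relative
    to a unit-span curve) are discarded as numerically spurious.
    """
    if not plateaus:
        raise SegmentationError("need at least one plateau")
    T, f = curve.temperatures, curve.f
    n = T.size

    def idx_of(t):
        return int(np.argmin(np.abs(T - t)))

    spans: list[tuple[int, int]] = []
    for p1, p2 in zip(plateaus[:-1], plateaus[1:]):
        spans.append((idx_of(p1.T_range[0]), idx_of(p2.T_range[1])))

    last_end = idx_of(plateaus[-1].T_range[1])
    if last_end < n - 2:
        end_idx = n - 1
        if shape is not None and shape.kind in ("gaussian", "bigaussian"):
            tail = T[last_end:]
            end_idx = last_end + int(np.argmin(shape(tail)))
            if end_idx <= last_end + 3:
                end_idx = n - 1
        spans.append((idx_of(plateaus[-1].T_range[0]), end_idx))

    sigmoids = []
    for i0, i1 in spans:
        if i1 - i0 + 1 < 4:
            warnings.warn(f"span [{T[i0]:g}, {T[i1]:g}] degC has <4 points; skipped")
            continue
        fit = _fit_boltzmann(T[i0:i1 + 1], f[i0:i1 + 1])
        if fit is None:
            raise SegmentationError(
                f"Boltzmann fit failed on span [{T[i0]:g}, {T[i1]:g}] degC")
        if abs(fit.amplitude) < min_amplitude * max(np.ptp(f), 1e-12):
            continue
        if not (fit.fit_T_range[0] <= fit.T0 <= fit.fit_T_range[1]):
            warnings.warn(
                f"sigmoid midpoint {fit.T0:.2f} degC outside its fit range "
                f"{fit.fit_T_range}")
        sigmoids.append(fit)
    sigmoids.sort(key=lambda s: s.T0)
    return sigmoids


def refine_chain(curve: BetaFractionCurve, sigmoids: list[BoltzmannSigmoid],
                 plateaus: list[LinearPlateau] | None = None
                 ) -> tuple[ChainModel | None, list[BoltzmannSigmoid]]:
    """Jointly refit all transitions as baseline + sum of van't Hoff
    two-state components.

    The per-span chain fit estimates each sigmoid from a local window, which
    biases asymptotes (and hence midpoints and widths) when neighbouring
    transitions overlap; the global fit removes that bias and replaces the
    empirical Boltzmann shape with the two-state van't Hoff temperature
    dependence the thermodynamic analysis assumes.  The residual baseline
    slope is co-estimated (initialised from the detected plateau windows,
    each detrended by its own level).  Deterministic.  Returns the fitted
    :class:`ChainModel` together with the sigmoid list rebuilt from the
    refined parameters.
    """
    T, f = curve.temperatures, curve.f
    r = len(sigmoids)
    span = float(T[-1] - T[0])
    R = 8.314

    # initial residual baseline slope from plateau windows, each detrended
    # by level.  Points closer than 4 effective widths to any transition
    # midpoint are excluded: the slowly decaying sigmoid tails otherwise
    # tilt the estimate.
    b0 = 0.0
    if plateaus:
        far = np.ones_like(T, dtype=bool)
        for s in sigmoids:
            far &= np.abs(T - s.T0) >= 4.0 * abs(s.dT)
        xs, ys = [], []
        for p in plateaus:
            m = (T >= p.T_range[0]) & (T <= p.T_range[1]) & far
            if m.sum() >= 3:
                xs.append(T[m] - T[m].mean())
                ys.append(f[m] - f[m].mean())
        if xs:
            x = np.concatenate(xs)
            y = np.concatenate(ys)
            denom = float(np.sum(x * x))
            if denom > 0 and x.size >= 6:
                b0 = float(np.sum(x * y) / denom)

    def model(T_, *p):
        out = p[0] + p[1] * T_
        T_K = T_ + 273.15
        for i in range(r):
            d, T_m, dH = p[2 + 3 * i: 5 + 3 * i]
            lnK = -(dH / R) * (1.0 / T_K - 1.0 / (T_m + 273.15))
            out = out + d / (1.0 + np.exp(-lnK))
        return out

    p0 = [sigmoids[0].A1 - b0 * T[0], b0]
    lb = [-np.inf, -1.0]
    ub = [np.inf, 1.0]
    for s in sigmoids:
        dH0 = R * (s.T0 + 273.15) ** 2 / max(abs(s.dT), 0.05)
        p0 += [s.amplitude, s.T0, dH0]
        lb += [-np.inf, T[0] - span, 1e3]
        ub += [np.inf, T[-1] + span, 1e8]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(model, T, f, p0=p0, bounds=(lb, ub), maxfev=40000)
    except (RuntimeError, ValueError):
        return None, sigmoids

    comps = sorted((tuple(popt[2 + 3 * i: 5 + 3 * i]) for i in range(r)),
                   key=lambda c: c[1])
    chain = ChainModel(a=float(popt[0]), b=float(popt[1]),
                       components=tuple(comps),
                       rmse=rmse(f - model(T, *popt)))
    refined = []
    for i, ((d, T_m, dH), old) in enumerate(zip(comps, sigmoids)):
        A1 = float(chain.level_before(i, T_m))
        refined.append(BoltzmannSigmoid(
            A1=A1, A2=A1 + float(d), T0=float(T_m),
            dT=float(chain.effective_width(i)),
            fit_T_range=old.fit_T_range, rmse=chain.rmse, stderr=old.stderr))
    return chain, refined


# ---------------------------------------------------------------------------
# shape models


def fit_shape_models(curve: BetaFractionCurve) -> ShapeModel:
    """Fit parabolic, Gaussian and bi-Gaussian guide models; keep the minimum
    RMSE (ties within 1e-9 broken toward fewer parameters)."""
    T, f = curve.temperatures, curve.f
    if T.size < 6:
        raise SegmentationError("need >= 6 points for shape-model selection")
    candidates: dict[str, tuple[tuple, float]] = {}

    coef = np.polyfit(T, f, 2)
    candidates["parabolic"] = (tuple(coef.tolist()),
                               rmse(f - np.polyval(coef, T)))

    i_ext = int(np.argmax(np.abs(f - np.median(f))))
    off0 = float(np.median(f))
    H0 = float(f[i_ext] - off0) or float(np.ptp(f)) or 1.0
    Tc0 = float(T[i_ext])
    w0 = float(T[-1] - T[0]) / 4.0

    def gauss(x, H, Tc, s, off):
        return off + H * np.exp(-((x - Tc) ** 2) / (2 * s ** 2))

    def bigauss(x, H, Tc, s1, s2, off):
        s = np.where(x <= Tc, s1, s2)
        return off + H * np.exp(-((x - Tc) ** 2) / (2 * s ** 2))

    span = float(T[-1] - T[0])
    for kind, fun, p0, lb, ub in (
        ("gaussian", gauss, [H0, Tc0, w0, off0],
         [-np.inf, T[0] - span, 1e-2, -np.inf], [np.inf, T[-1] + span, 10 * span, np.inf]),
        ("bigaussian", bigauss, [H0, Tc0, w0, w0, off0],
         [-np.inf, T[0] - span, 1e-2, 1e-2, -np.inf],
         [np.inf, T[-1] + span, 10 * span, 10 * span, np.inf]),
    ):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(fun, T, f, p0=p0, bounds=(lb, ub), maxfev=20000)
            candidates[kind] = (tuple(popt.tolist()), rmse(f - fun(T, *popt)))
        except (RuntimeError, ValueError):
            warnings.warn(f"{kind} shape fit did not converge; excluded")

    if not candidates:
        raise SegmentationError("no shape model converged")
    nparams = {"parabolic": 3, "gaussian": 4, "bigaussian": 5}
    best = min(candidates, key=lambda k: (round(candidates[k][1] / 1e-9) * 1e-9,
                                          nparams[k]))
    params, err = candidates[best]
    return ShapeModel(kind=best, params=params, rmse=err,
                      all_rmse={k: v[1] for k, v in candidates.items()})


# ---------------------------------------------------------------------------
# characteristic temperatures


def intersection_temperature(s1: BoltzmannSigmoid, s2: BoltzmannSigmoid) -> float:
    """Temperature at which two adjacent sigmoids predict equal f.

    Root of s1(T) - s2(T) bracketed on [s1.T0, s2.T0]; if the difference does
    not change sign there the bracket is widened once to the joint fit range.
    Two chained same-direction sigmoids sharing a plateau level approach each
    other asymptotically without a strict sign change; in that degenerate
    case the closest-approach temperature (the interior minimum of
    |s1 - s2|, where the two tails balance) is returned instead, provided
    the approach is a genuine interior dip.
    """
    if not s1.T0 < s2.T0:
        raise ValueError("s1 must be the lower-temperature sigmoid")
    wide = (min(s1.fit_T_range[0], s2.fit_T_range[0]),
            max(s1.fit_T_range[1], s2.fit_T_range[1]))
    return _intersect_curves(s1, s2, s1.T0, s2.T0, wide)


def _intersect_curves(c1, c2, T01: float, T02: float,
                      wide: tuple[float, float]) -> float:
    """Shared root/closest-approach search for two region curves."""

    def g(t):
        return float(c1(t) - c2(t))

    for a, b in ((T01, T02), wide):
        if g(a) == 0.0:
            return float(a)
        if g(b) == 0.0:
            return float(b)
        if g(a) * g(b) < 0:
            return float(brentq(g, a, b, xtol=1e-10))

    grid = np.linspace(T01, T02, 801)
    gap = np.abs(c1(grid) - c2(grid))
    i = int(np.argmin(gap))
    edge_gap = max(gap[0], gap[-1])
    if 0 < i < grid.size - 1 and gap[i] < 0.5 * edge_gap:
        return float(grid[i])
    raise SegmentationError(
        f"sigmoids at T0 = {T01:.2f} and {T02:.2f} degC do not cross")


def onset_temperature(curve: BetaFractionCurve, first_sigmoid: BoltzmannSigmoid,
                      low_plateau: LinearPlateau, mode: str = "tangent",
                      threshold: float = 0.05) -> float:
    """Onset of the first conformational transition.

    ``tangent`` (default): intersection of the low-temperature plateau line
    with the tangent to the first sigmoid at its midpoint — the standard
    thermal-analysis onset construction.  For a flat plateau at A1 this gives
    T_onset = T0 - 2 dT in closed form.  ``threshold``: first temperature at
    which f exceeds the plateau by ``threshold`` of the sigmoid amplitude
    (linear interpolation between grid points).

    The onset definition is an analysis convention, flagged as such in
    reports.
    """
    if mode == "tangent":
        m_t = first_sigmoid.midpoint_slope
        b_t = (first_sigmoid.A1 + first_sigmoid.A2) / 2.0 - m_t * first_sigmoid.T0
        dm = m_t - low_plateau.slope
        if abs(dm) < 1e-12 * max(abs(m_t), 1.0):
            raise SegmentationError("tangent parallel to plateau; onset undefined")
        return float((low_plateau.intercept - b_t) / dm)
    if mode == "threshold":
        T, f = curve.temperatures, curve.f
        level = low_plateau(T) + threshold * first_sigmoid.amplitude
        above = f - level
        idx = np.nonzero(above > 0)[0]
        if idx.size == 0:
            raise SegmentationError("f never exceeds the onset threshold")
        i = int(idx[0])
        if i == 0:
            return float(T[0])
        # linear interpolation of the crossing between grid points
        t = T[i - 1] + (T[i] - T[i - 1]) * (-above[i - 1]) / (above[i] - above[i - 1])
        return float(t)
    raise ValueError("mode must be 'tangent' or 'threshold'")


def segment_curve(curve: BetaFractionCurve, min_points: int = 5,
                  slope_tol: float = 0.005, r2_floor: float = 0.98,
                  onset_mode: str = "tangent",
                  onset_threshold: float = 0.05,
                  refine: bool = True) -> SegmentationResult:
    """Full decomposition: plateaus, shape model, sigmoid chain (with global
    refinement against overlap bias), T_m/T_I/T_onset."""
    plateaus = detect_plateaus(curve, min_points=min_points,
                               slope_tol=slope_tol, r2_floor=r2_floor)
    shape = fit_shape_models(curve) if curve.f.size >= 6 else None
    sigmoids = fit_sigmoid_chain(curve, plateaus, shape=shape)
    if not sigmoids:
        raise SegmentationError("no sigmoidal transition found")
    chain = None
    if refine:
        chain, sigmoids = refine_chain(curve, sigmoids, plateaus)
    T_m = [s.T0 for s in sigmoids]
    if chain is not None:
        # intersect the van't Hoff region curves themselves: near a shared
        # plateau the crossing is tail-dominated, and the Boltzmann
        # approximation of the tails can shift it by degrees
        T_I = [_intersect_curves(chain.region_curve(i), chain.region_curve(i + 1),
                                 sigmoids[i].T0, sigmoids[i + 1].T0,
                                 (float(curve.temperatures[0]),
                                  float(curve.temperatures[-1])))
               for i in range(len(sigmoids) - 1)]
    else:
        T_I = [intersection_temperature(a, b)
               for a, b in zip(sigmoids[:-1], sigmoids[1:])]
    try:
        T_onset = onset_temperature(curve, sigmoids[0], plateaus[0],
                                    mode=onset_mode, threshold=onset_threshold)
    except SegmentationError:
        T_onset = None
    return SegmentationResult(plateaus=plateaus, sigmoids=sigmoids, T_m=T_m,
                              T_I=T_I, T_onset=T_onset, shape=shape,
                              n=curve.f.size, chain=chain)
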