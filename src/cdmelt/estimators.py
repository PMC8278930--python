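"""Scikit-learn-style estimators wrapping the melt and kinetics pipelines.

`MeltThermogramAnalyzer` takes a single-wavelength melt signal (or an
already-computed fraction curve) and produces the full decomposition:
fraction referencing, plateau/sigmoid segmentation, characteristic
temperatures and per-region thermodynamics.  `BindingKineticsEstimator`
fits 1:1 or 1:2 binding kinetics to a sensorgram.  Both follow the sklearn
contract (``get_params``/``set_params``, fitted attributes with trailing
underscores) and therefore compose with sklearn model-selection tooling.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from . import beta_fraction as bf
from . import thermo as th
from . import transitions as tr
from .bli import Sensorgram, fit_sensorgram
from .io import MeltSignal

__all__ = ["MeltThermogramAnalyzer", "BindingKineticsEstimator"]


class MeltThermogramAnalyzer(BaseEstimator):
    """End-to-end analysis of a beta-sheet melt curve.

    Parameters
    ----------
    mode : {"auto", "two_state", "peak_referenced"}
        Fraction referencing mode; "auto" selects by comparing sigmoid and
        bi-Gaussian descriptions of the raw signal.
    baseline_low_range, baseline_high_range : tuple or None
        Manual baseline windows (degC) for two-state referencing; when None
        the detected first/last plateau of the raw signal is used.
    min_plateau_points, slope_tol, r2_floor : plateau-detection controls.
    onset_mode : {"tangent", "threshold"}; onset_threshold : float
        Onset-temperature convention.
    dG_window : float
        Half-width (kJ/mol) of the |dG| window of the transition-region fit.
    epsilon_f : float
        Region fractions outside (epsilon_f, 1 - epsilon_f) are excluded
        before forming equilibrium constants.
    convention : {"paper_celsius", "van_t_hoff"}
        Which enthalpy is primary in the summary.

    Attributes (after ``fit``)
    ----------
    curve_ : BetaFractionCurve         rescaled fraction curve
    segmentation_ : SegmentationResult plateaus, sigmoids, shape model
    summary_ : ThermoSummary           per-region thermodynamics and totals
    T_m_, T_I_, T_onset_ : characteristic temperatures (degC)
    """

    def __init__(self, mode: str = "auto",
                 baseline_low_range=None, baseline_high_range=None,
                 min_plateau_points: int = 5, slope_tol: float = 0.005,
                 r2_floor: float = 0.98, onset_mode: str = "tangent",
                 onset_threshold: float = 0.05, dG_window: float = 5.0,
                 epsilon_f: float = 0.02, convention: str = "paper_celsius"):
        self.mode = mode
        self.baseline_low_range = baseline_low_range
        self.baseline_high_range = baseline_high_range
        self.min_plateau_points = min_plateau_points
        self.slope_tol = slope_tol
        self.r2_floor = r2_floor
        self.onset_mode = onset_mode
        self.onset_threshold = onset_threshold
        self.dG_window = dG_window
        self.epsilon_f = epsilon_f
        self.convention = convention

    # -- internal -----------------------------------------------------------
    def _make_fraction(self, signal: MeltSignal, lo_rng=None, hi_rng=None,
                       mode=None) -> bf.BetaFractionCurve:
        mode = mode or self.mode
        if mode == "auto":
            mode = bf.select_mode(signal)
        if mode == "peak_referenced":
            curve = bf.fraction_peak_referenced(signal)
        elif mode == "two_state":
            lo_rng = lo_rng or self.baseline_low_range
            hi_rng = hi_rng or self.baseline_high_range
            if lo_rng is None or hi_rng is None:
                raw = bf.BetaFractionCurve(signal.temperatures,
                                           self._unit_span(signal.y),
                                           mode="two_state")
                plateaus = tr.detect_plateaus(
                    raw, min_points=self.min_plateau_points,
                    slope_tol=self.slope_tol, r2_floor=self.r2_floor)
                lo_rng = lo_rng or plateaus[0].T_range
                hi_rng = hi_rng or plateaus[-1].T_range
            low = bf.fit_baseline(signal, lo_rng, "low_T")
            high = bf.fit_baseline(signal, hi_rng, "high_T")
            curve = bf.fraction_two_state(signal, low, high)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        self.baseline_low_range_ = lo_rng if mode == "two_state" else None
        self.baseline_high_range_ = hi_rng if mode == "two_state" else None
        return bf.rescale_unit_interval(curve)

    def _trimmed_ranges(self, signal: MeltSignal, seg) -> tuple | None:
        """Shrink auto-detected baseline windows away from the fitted
        transitions (5.5 widths from every midpoint, where the sigmoid tail
        is below 0.5% of the amplitude).  Auto windows grow until the
        curvature is detectable, so they carry a few early-rise points whose
        tilt biases the extrapolated references."""
        lo, hi = self.baseline_low_range_, self.baseline_high_range_
        if lo is None or hi is None or not seg.sigmoids:
            return None
        t_first = min(s.T0 - 5.5 * abs(s.dT) for s in seg.sigmoids)
        t_last = max(s.T0 + 5.5 * abs(s.dT) for s in seg.sigmoids)
        new_lo = (lo[0], min(lo[1], t_first))
        new_hi = (max(hi[0], t_last), hi[1])
        T = signal.temperatures
        n_lo = int(np.sum((T >= new_lo[0]) & (T <= new_lo[1])))
        n_hi = int(np.sum((T >= new_hi[0]) & (T <= new_hi[1])))
        if n_lo < 3 or n_hi < 3 or (new_lo, new_hi) == (lo, hi):
            return None
        return new_lo, new_hi

    @staticmethod
    def _unit_span(y: np.ndarray) -> np.ndarray:
        span = np.ptp(y)
        return (y - y.min()) / span if span > 0 else np.zeros_like(y)

    # -- sklearn surface -----------------------------------------------------
    def fit(self, X, y=None):
        """Fit the decomposition.

        X may be a :class:`MeltSignal`, a ``BetaFractionCurve``, or an
        (n, 2) array of (temperature degC, signal) pairs.
        """
        if isinstance(X, bf.BetaFractionCurve):
            curve = X if X.scaled else bf.rescale_unit_interval(X)
            self.mode_used_ = X.mode
        else:
            if not isinstance(X, MeltSignal):
                arr = np.asarray(X, dtype=float)
                if arr.ndim != 2 or arr.shape[1] != 2:
                    raise ValueError("X must be (n, 2) (temperature, signal)")
                X = MeltSignal(arr[:, 0], arr[:, 1], wavelength=218.0)
            curve = self._make_fraction(X)
            self.mode_used_ = curve.mode
        self.curve_ = curve
        self.segmentation_ = tr.segment_curve(
            curve, min_points=self.min_plateau_points, slope_tol=self.slope_tol,
            r2_floor=self.r2_floor, onset_mode=self.onset_mode,
            onset_threshold=self.onset_threshold)
        # one baseline-refinement pass for auto-referenced two-state curves:
        # re-fit the reference lines on windows clear of the transitions,
        # then redo the fraction and the segmentation
        if (isinstance(X, MeltSignal) and self.mode_used_ == "two_state"
                and self.baseline_low_range is None
                and self.baseline_high_range is None):
            trimmed = self._trimmed_ranges(X, self.segmentation_)
            if trimmed is not None:
                curve = self._make_fraction(X, *trimmed, mode="two_state")
                self.curve_ = curve
                self.segmentation_ = tr.segment_curve(
                    curve, min_points=self.min_plateau_points,
                    slope_tol=self.slope_tol, r2_floor=self.r2_floor,
                    onset_mode=self.onset_mode,
                    onset_threshold=self.onset_threshold)
        self.summary_ = th.analyze_regions(
            curve, self.segmentation_, dG_window=self.dG_window,
            epsilon_f=self.epsilon_f, convention=self.convention)
        self.T_m_ = [r.T_m for r in self.summary_.regions]
        self.T_I_ = list(self.segmentation_.T_I)
        self.T_onset_ = self.segmentation_.T_onset
        self.n_features_in_ = 2
        return self

    def predict(self, T):
        """Evaluate the fitted piecewise sigmoid model at temperatures ``T``.

        Each temperature is evaluated with the sigmoid whose regime contains
        it, regimes being delimited by the intersection temperatures.
        """
        if not hasattr(self, "segmentation_"):
            raise RuntimeError("call fit first")
        T = np.asarray(T, dtype=float)
        sig = self.segmentation_.sigmoids
        bounds = self.segmentation_.T_I + [np.inf]
        idx = np.searchsorted(np.asarray(self.segmentation_.T_I), T, side="right")
        out = np.empty_like(T, dtype=float)
        for i, s in enumerate(sig):
            m = idx == i
            out[m] = s(T[m])
        return out

    def score(self, X=None, y=None):
        """Negative RMSE of the piecewise sigmoid model on the fitted curve."""
        f_hat = self.predict(self.curve_.temperatures)
        return -tr.rmse(self.curve_.f - f_hat)


class BindingKineticsEstimator(BaseEstimator):
    """Sensorgram kinetic fit under a 1:1 or 1:2 binding model.

    Parameters
    ----------
    model : {"one_to_two", "one_to_one"}
    compare : bool
        When True (default) the alternative model is also fitted and its RMSE
        stored in ``rmse_alternative_``, mirroring the model-rejection step
        in which a 1:1 description of a biphasic sensorgram is discarded.

    Attributes (after ``fit``)
    ----------
    fit_ : KineticFit ;  KD_ : float (M) ;  rmse_ : float
    kon1_, koff1_ (and kon2_, koff2_, Rmax2_ under 1:2), Rmax1_ : floats
    """

    def __init__(self, model: str = "one_to_two", compare: bool = True):
        self.model = model
        self.compare = compare

    def fit(self, X, y=None):
        """X is a :class:`Sensorgram`."""
        if not isinstance(X, Sensorgram):
            raise TypeError("X must be a Sensorgram")
        self.fit_ = fit_sensorgram(X, model=self.model)
        p = self.fit_.params
        if self.model == "one_to_one":
            self.kon1_, self.koff1_, self.Rmax1_ = p.kon, p.koff, p.Rmax
        else:
            self.kon1_, self.koff1_, self.Rmax1_ = p.kon1, p.koff1, p.Rmax1
            self.kon2_, self.koff2_, self.Rmax2_ = p.kon2, p.koff2, p.Rmax2
        self.KD_ = self.fit_.KD
        self.rmse_ = self.fit_.rmse
        if self.compare:
            other = "one_to_one" if self.model == "one_to_two" else "one_to_two"
            try:
                self.fit_alternative_ = fit_sensorgram(X, model=other)
                self.rmse_alternative_ = self.fit_alternative_.rmse
            except (ValueError, RuntimeError):
                self.fit_alternative_ = None
                self.rmse_alternative_ = np.nan
        return self

    def score(self, X, y=None):
        """Negative RMSE of the fitted model on ``X``'s annotated phases."""
        from .bli import _response_1to1
        if not hasattr(self, "fit_"):
            raise RuntimeError("call fit first")
        phases = {k: v for k, v in X.phases.items() if k != "baseline"}
        t = X.t
        p = self.fit_.params
        if self.model == "one_to_one":
            pred = _response_1to1(t, phases, X.C, p.kon, p.koff, p.Rmax)
        else:
            pred = (_response_1to1(t, phases, X.C, p.kon1, p.koff1, p.Rmax1)
                    + _response_1to1(t, phases, X.C, p.kon2, p.koff2, p.Rmax2))
        m = np.zeros(t.size, dtype=bool)
        for t0, t1 in phases.values():
            m |= (t >= t0) & (t <= t1)
        return -float(np.sqrt(np.mean((pred[m] - X.R[m]) ** 2)))
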