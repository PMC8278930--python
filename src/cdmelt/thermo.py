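"""Per-region two-state thermodynamics of melt-curve transitions.

Each sigmoidal region of a melt curve is treated as an independent two-state
equilibrium between its initial and final conformational ensembles.  Within
region i a local progress fraction f_i is computed by referencing the curve
against the bounding plateau lines; then

    K_i(T)  = f_i / (1 - f_i)
    dG_i(T) = -R T_K ln K_i          (T_K in kelvin, R = 8.314 J mol^-1 K^-1)

and dG_i is regressed linearly on temperature inside the transition window
(|dG| < 5 kJ/mol by default).  Two reporting conventions derive from the one
regression:

* ``paper_celsius`` (default): the regression is against temperature on the
  Celsius axis, dH is the intercept at 0 degC and dS the negative slope, so
  the identity dH = T_m(degC) * dS holds exactly at the fitted root
  T_m = dH/dS.  This is the convention under which the published
  region/total tables for the IgG4 formulations are internally consistent.
* ``van_t_hoff``: the physically conventional enthalpy
  dH_vH = T_m(K) * dS is reported as primary.

Both numbers are always computed; the convention only selects which is
labelled primary in summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import linregress

from .beta_fraction import BetaFractionCurve
from .io import ValidationError
from .transitions import BoltzmannSigmoid, LinearPlateau, SegmentationResult

R_GAS = 8.314  # J mol^-1 K^-1
KELVIN = 273.15

__all__ = [
    "R_GAS",
    "RegionThermo",
    "ThermoSummary",
    "region_fraction",
    "equilibrium_constant",
    "gibbs",
    "linear_transition_fit",
    "tm_from_thermo",
    "totals",
    "analyze_regions",
]


@dataclass
class RegionThermo:
    """Thermodynamic parameters of one two-state transition region.

    dH_paper (kJ/mol) is the Celsius-axis intercept, dS (J K^-1 mol^-1) the
    negative slope of the dG vs T line; dH_vH = T_m(K) * dS is the van't Hoff
    enthalpy from the same fit.
    """

    index: int
    T_m: float
    dS: float
    dH_paper: float
    dH_vH: float
    T_m_err: float = np.nan
    dS_err: float = np.nan
    dH_err: float = np.nan
    fit_window: tuple[float, float] = (np.nan, np.nan)
    n_points: int = 0


@dataclass
class ThermoSummary:
    """Totals over all transition regions."""

    regions: list
    dH_total: float
    dS_total: float
    dG_total: float
    T_ref: float
    convention: str = "paper_celsius"
    dH_total_err: float = np.nan
    dS_total_err: float = np.nan
    dG_total_err: float = np.nan


def region_fraction(curve: BetaFractionCurve, sigmoid: BoltzmannSigmoid,
                    low_plateau: LinearPlateau | None = None,
                    high_plateau: LinearPlateau | None = None,
                    T_range: tuple[float, float] | None = None,
                    denom_floor: float = 1e-9) -> tuple[np.ndarray, np.ndarray]:
    """Region-local progress fraction f_i over the sigmoid's span.

    The initial (lower-T) and final (higher-T) reference signals are the
    bounding plateau lines when available, else the sigmoid's own asymptotes
    A1/A2.  Returns ``(T, f_i)`` restricted to the span; f_i runs 0 -> 1 as
    the region's transition completes, regardless of whether the raw curve
    rises or falls there.
    """
    lo, hi = T_range if T_range is not None else sigmoid.fit_T_range
    mask = (curve.temperatures >= lo) & (curve.temperatures <= hi)
    T = curve.temperatures[mask]
    y = curve.f[mask]
    y0 = low_plateau(T) if low_plateau is not None else np.full_like(T, sigmoid.A1)
    y1 = high_plateau(T) if high_plateau is not None else np.full_like(T, sigmoid.A2)
    denom = y1 - y0
    if np.any(np.abs(denom) < denom_floor):
        raise ValidationError("degenerate region references (y0_i == ymax_i)")
    return T, (y - y0) / denom


def equilibrium_constant(f):
    """Two-state equilibrium constant K = f / (1 - f); domain 0 < f < 1."""
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0) or np.any(f >= 1):
        raise ValueError("fraction outside (0, 1); exclude such points upstream")
    return f / (1.0 - f)


def gibbs(K, T_celsius):
    """dG = -R T ln K in kJ/mol, with T in degrees Celsius (converted to K)."""
    K = np.asarray(K, dtype=float)
    if np.any(K <= 0):
        raise ValueError("K must be positive")
    T_K = np.asarray(T_celsius, dtype=float) + KELVIN
    return -R_GAS * T_K * np.log(K) / 1000.0


def linear_transition_fit(T_celsius, dG, window: float = 5.0,
                          index: int = 0) -> RegionThermo:
    """Fit dG = dH - T(degC) * dS inside the transition window |dG| < window.

    T_m = dH/dS is the Celsius root of the line (where dG = 0 and K = 1);
    dH_vH = dS * (T_m + 273.15).  Standard errors propagate from the
    regression covariance (T_m by the delta method).
    """
    T = np.asarray(T_celsius, dtype=float)
    dG = np.asarray(dG, dtype=float)
    mask = np.abs(dG) < window
    if mask.sum() < 3:
        raise ValidationError(
            f"only {int(mask.sum())} points with |dG| < {window:g} kJ/mol; need >= 3")
    x, y = T[mask], dG[mask]
    res = linregress(x, y)
    dS_kJ = -res.slope           # kJ K^-1 mol^-1 (Celsius-degree = kelvin-sized step)
    dH = float(res.intercept)    # kJ/mol at 0 degC
    if abs(dS_kJ) < 1e-12:
        raise ValidationError("zero slope: dG line never crosses zero")
    T_m = dH / dS_kJ
    dH_vH = dS_kJ * (T_m + KELVIN)
    # delta method for T_m = a / (-b); linregress gives se of slope/intercept
    se_b, se_a = float(res.stderr), float(res.intercept_stderr)
    T_m_err = abs(T_m) * np.sqrt((se_a / dH) ** 2 + (se_b / dS_kJ) ** 2) \
        if dH != 0 else np.nan
    return RegionThermo(
        index=index, T_m=float(T_m), dS=float(dS_kJ * 1000.0), dH_paper=dH,
        dH_vH=float(dH_vH), T_m_err=float(T_m_err),
        dS_err=float(se_b * 1000.0), dH_err=se_a,
        fit_window=(float(x.min()), float(x.max())), n_points=int(mask.sum()))


def tm_from_thermo(dH_kJ: float, dS_J: float) -> float:
    """Midpoint temperature (degC) implied by dH (kJ/mol) and dS (J K^-1 mol^-1)
    under the Celsius-axis convention: T_m = dH / dS."""
    if dS_J == 0:
        raise ValueError("dS must be nonzero")
    return 1000.0 * dH_kJ / dS_J


def totals(regions: list[RegionThermo], T_ref: float,
           convention: str = "paper_celsius") -> ThermoSummary:
    """Sum region enthalpies/entropies and evaluate dG_total at ``T_ref``.

    dH_total = sum dH_i (kJ/mol), dS_total = sum dS_i (J K^-1 mol^-1) and
    dG_total = dH_total - T_ref * dS_total / 1000 with T_ref on the axis the
    convention dictates (Celsius under ``paper_celsius``, kelvin under
    ``van_t_hoff`` using the dH_vH sums).  Uncertainties add in quadrature.
    """
    if not regions:
        raise ValidationError("no regions to summarise")
    dS_total = float(sum(r.dS for r in regions))
    dS_err = float(np.sqrt(np.nansum([r.dS_err ** 2 for r in regions])))
    if convention == "paper_celsius":
        dH_total = float(sum(r.dH_paper for r in regions))
        dH_err = float(np.sqrt(np.nansum([r.dH_err ** 2 for r in regions])))
        dG_total = dH_total - T_ref * dS_total / 1000.0
    elif convention == "van_t_hoff":
        dH_total = float(sum(r.dH_vH for r in regions))
        dH_err = float(np.sqrt(np.nansum([r.dH_err ** 2 for r in regions])))
        dG_total = dH_total - (T_ref + KELVIN) * dS_total / 1000.0
    else:
        raise ValueError("convention must be 'paper_celsius' or 'van_t_hoff'")
    dG_err = float(np.sqrt(dH_err ** 2 + (T_ref * dS_err / 1000.0) ** 2))
    return ThermoSummary(regions=list(regions), dH_total=dH_total,
                         dS_total=dS_total, dG_total=dG_total, T_ref=float(T_ref),
                         convention=convention, dH_total_err=dH_err,
                         dS_total_err=dS_err, dG_total_err=dG_err)


def analyze_regions(curve: BetaFractionCurve, seg: SegmentationResult,
                    dG_window: float = 5.0, epsilon_f: float = 0.02,
                    convention: str = "paper_celsius") -> ThermoSummary:
    """Run the per-region thermodynamic analysis over a segmentation.

    Points with region fraction outside (epsilon_f, 1 - epsilon_f) are
    excluded before forming K (ln K diverges at the rails).  The dG_total
    reference temperature is the last intersection temperature T_I (falling
    back to the last T_m for single-region curves) — an analysis convention
    recorded in every report.
    """
    regions: list[RegionThermo] = []

    def plateau_for(t, side):
        cands = [p for p in seg.plateaus
                 if (p.T_range[1] <= t + 1e-9 if side == "low" else p.T_range[0] >= t - 1e-9)]
        if not cands:
            return None
        return cands[-1] if side == "low" else cands[0]

    for i, sig in enumerate(seg.sigmoids):
        if seg.chain is not None:
            # fraction of the fitted region model evaluated on the grid,
            # restricted to the component's own regime: within ~6 widths of
            # its midpoint and no closer to a neighbouring transition than
            # the midway temperature.  Using the fitted two-state model
            # rather than pointwise noisy fractions pools the information of
            # every point in the transition into the dG line (the pointwise
            # route stays available by segmenting with refine=False).
            Tm_all = [s.T0 for s in seg.sigmoids]
            lo = (Tm_all[i - 1] + sig.T0) / 2.0 if i > 0 else -np.inf
            hi = (sig.T0 + Tm_all[i + 1]) / 2.0 if i < len(Tm_all) - 1 else np.inf
            Tc = curve.temperatures
            near = ((np.abs(Tc - sig.T0) <= 6.0 * abs(sig.dT))
                    & (Tc >= lo) & (Tc <= hi))
            T = Tc[near]
            f_i = seg.chain.component_fraction(i, T)
        else:
            lowp = plateau_for(sig.T0, "low")
            highp = plateau_for(sig.T0, "high")
            # a bounding plateau that is too short, or too steep to be a
            # genuine baseline (e.g. a separator window still carrying
            # transition tails, whose line extrapolated across the region
            # would corrupt the reference denominator), falls back to the
            # sigmoid's own asymptote
            max_ref_slope = 0.005 * max(np.ptp(curve.f), 1e-12)
            if lowp is not None and (lowp.n_points < 3 or abs(lowp.slope) > max_ref_slope):
                lowp = None
            if highp is not None and (highp.n_points < 3 or abs(highp.slope) > max_ref_slope):
                highp = None
            T, f_i = region_fraction(curve, sig, lowp, highp)
        ok = (f_i > epsilon_f) & (f_i < 1.0 - epsilon_f)
        if ok.sum() < 3:
            raise ValidationError(
                f"region {i + 1}: fewer than 3 usable points after excluding "
                f"f outside ({epsilon_f:g}, {1 - epsilon_f:g})")
        K = equilibrium_constant(f_i[ok])
        dG = gibbs(K, T[ok])
        regions.append(linear_transition_fit(T[ok], dG, window=dG_window, index=i + 1))

    T_ref = seg.T_I[-1] if seg.T_I else regions[-1].T_m
    return totals(regions, T_ref=T_ref, convention=convention)
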