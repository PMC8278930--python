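"""Seeded forward models: synthetic melt curves, CD spectra and sensorgrams.

The melt generator produces 1-3 sequential two-state (van't Hoff)
transitions riding on linear pre- and post-transition baselines with
homoscedastic Gaussian noise.  Each transition i contributes a population

    p_i(T) = K_i / (1 + K_i),
    K_i(T) = exp(-(dH_vH_i / R) (1/T_K - 1/T_m_i,K))

so p_i = 1/2 exactly at T_m_i, and the fraction curve is
f(T) = f_start_1 + sum_i (f_end_i - f_start_i) p_i(T).  Opposing transitions
(rise then fall) model melts whose beta-sheet content peaks at an interior
temperature.  Under the Celsius-axis reporting convention the generating
entropy of transition i is dS_i = dH_vH_i / T_m_i(K), which is the mapping
used to express published table rows as generator presets.

Every stochastic output takes a seed; identical seeds give identical bits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .bli import Kinetics1to1, Kinetics1to2, Sensorgram, simulate_1to1, simulate_1to2
from .io import MRE, CDSpectrumSeries, MeltSignal, SampleMeta, ValidationError
from .thermo import KELVIN, R_GAS

__all__ = [
    "TransitionSpec",
    "MeltSpec",
    "SpectrumBasis",
    "generate_fraction_curve",
    "generate_cd_signal",
    "generate_full_spectra",
    "generate_sensorgram",
    "preset",
    "PRESETS",
]


@dataclass(frozen=True)
class TransitionSpec:
    """One two-state transition: midpoint (degC), van't Hoff enthalpy (J/mol)
    and the fraction levels it connects."""

    T_m: float
    dH_vH: float
    f_start: float
    f_end: float

    def __post_init__(self) -> None:
        if self.dH_vH <= 0:
            raise ValidationError("dH_vH must be positive")

    @property
    def dS_celsius_convention(self) -> float:
        """Generating entropy in J K^-1 mol^-1 under the Celsius-axis
        reporting convention: dS = dH_vH / T_m(K)."""
        return self.dH_vH / (self.T_m + KELVIN)

    @property
    def width(self) -> float:
        """Effective Boltzmann width dT = R T_m(K)^2 / dH_vH (degC)."""
        return R_GAS * (self.T_m + KELVIN) ** 2 / self.dH_vH


@dataclass(frozen=True)
class MeltSpec:
    """Full specification of a synthetic melt experiment.

    ``baseline_low``/``baseline_high`` are (intercept, slope) pairs of the
    minimum- and maximum-beta-sheet reference signals in raw units;
    ``noise_sd`` is the Gaussian noise standard deviation in the same units.
    """

    transitions: tuple
    baseline_low: tuple[float, float] = (-4000.0, -5.0)
    baseline_high: tuple[float, float] = (-9000.0, -8.0)
    T_grid: tuple[float, float, float] = (25.0, 97.0, 1.0)  # start, stop, step
    noise_sd: float = 0.0
    seed: int = 0
    label: str = "synthetic"

    def __post_init__(self) -> None:
        tms = [t.T_m for t in self.transitions]
        if tms != sorted(tms):
            raise ValidationError("transitions must be ordered by T_m")
        if not 1 <= len(self.transitions) <= 3:
            raise ValidationError("1-3 transitions supported")
        if self.T_grid[2] <= 0 or self.T_grid[1] <= self.T_grid[0]:
            raise ValidationError("T_grid must be increasing")

    @property
    def temperatures(self) -> np.ndarray:
        lo, hi, step = self.T_grid
        return np.arange(lo, hi + step / 2, step)

    def baselines(self, T: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        a0, b0 = self.baseline_low
        a1, b1 = self.baseline_high
        return a0 + b0 * T, a1 + b1 * T

    def ground_truth(self) -> dict:
        """Generating parameters in reporting units, for recovery checks."""
        return {
            "T_m": [t.T_m for t in self.transitions],
            "dH_vH_kJ_mol": [t.dH_vH / 1000.0 for t in self.transitions],
            "dS_J_K_mol": [t.dS_celsius_convention for t in self.transitions],
            "dH_paper_kJ_mol": [t.dS_celsius_convention * t.T_m / 1000.0
                                for t in self.transitions],
            "f_levels": [(t.f_start, t.f_end) for t in self.transitions],
            "seed": self.seed,
        }


def generate_fraction_curve(spec: MeltSpec) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free fraction curve (T, f_true) of the specified transitions."""
    T = spec.temperatures
    T_K = T + KELVIN
    f = np.full_like(T, spec.transitions[0].f_start, dtype=float)
    for tr in spec.transitions:
        lnK = -(tr.dH_vH / R_GAS) * (1.0 / T_K - 1.0 / (tr.T_m + KELVIN))
        p = 1.0 / (1.0 + np.exp(-lnK))
        f = f + (tr.f_end - tr.f_start) * p
    if np.any(f < -1e-9) or np.any(f > 1 + 1e-9):
        warnings.warn("fraction curve leaves [0, 1]; overlapping transitions")
    return T, f


def generate_cd_signal(spec: MeltSpec, f_true: np.ndarray | None = None,
                       meta: SampleMeta | None = None) -> MeltSignal:
    """Map a fraction curve through the baselines and add seeded noise.

    y(T) = y0(T) + (ymax(T) - y0(T)) f(T) + eps,  eps ~ N(0, noise_sd^2).
    """
    T = spec.temperatures
    if f_true is None:
        _, f_true = generate_fraction_curve(spec)
    y0, ymax = spec.baselines(T)
    if np.any((ymax - y0) == 0) or (np.any(ymax > y0) and np.any(ymax < y0)):
        raise ValidationError("baselines cross inside the temperature grid")
    y = y0 + (ymax - y0) * f_true
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        y = y + rng.normal(0.0, spec.noise_sd, size=y.shape)
    return MeltSignal(temperatures=T, y=y, wavelength=218.0, meta=meta)


@dataclass(frozen=True)
class SpectrumBasis:
    """Gaussian band structure of the synthetic far-UV CD spectrum.

    Default: a strong negative band at 218 nm (beta-sheet) whose amplitude is
    driven by the melt signal, plus a positive band at 202 nm (beta-turn).
    Each band is (centre nm, width nm, baseline amplitude, amplitude per unit
    f).
    """

    bands: tuple = (
        (202.0, 5.0, 2500.0, 800.0),   # positive beta-turn band
        (218.0, 6.5, 0.0, 0.0),        # beta-sheet band; driven by the melt signal
    )
    driven_centre: float = 218.0

    def __post_init__(self) -> None:
        if any(b[1] <= 0 for b in self.bands):
            raise ValidationError("band widths must be positive")


def generate_full_spectra(spec: MeltSpec, basis: SpectrumBasis | None = None,
                          wavelengths: np.ndarray | None = None,
                          meta: SampleMeta | None = None) -> CDSpectrumSeries:
    """Synthesise full 190-260 nm spectra whose 218 nm column reproduces the
    single-wavelength melt signal exactly (noise included once, at 218 nm
    amplitude level).

    The driven band's amplitude is solved per temperature so that the summed
    band intensities at the driven centre equal the melt signal there.
    """
    basis = basis or SpectrumBasis()
    if wavelengths is None:
        wavelengths = np.arange(190.0, 261.0, 1.0)
    wavelengths = np.asarray(wavelengths, dtype=float)
    T, f = generate_fraction_curve(spec)
    y218 = generate_cd_signal(spec, f_true=f).y

    def g(centre, width, lam):
        return np.exp(-((lam - centre) ** 2) / (2.0 * width ** 2))

    static = np.zeros((T.size, wavelengths.size))
    static_at_centre = np.zeros(T.size)
    driven = None
    for centre, width, base, per_f in basis.bands:
        if centre == basis.driven_centre:
            driven = (centre, width)
            continue
        amp = base + per_f * f
        static += amp[:, None] * g(centre, width, wavelengths)[None, :]
        static_at_centre += amp * g(centre, width, basis.driven_centre)
    if driven is None:
        raise ValidationError("basis must contain the driven band")
    amp_driven = y218 - static_at_centre
    signal = static + amp_driven[:, None] * g(*driven, wavelengths)[None, :]
    return CDSpectrumSeries(temperatures=T, wavelengths=wavelengths,
                            signal=signal, units=MRE, meta=meta)


def generate_sensorgram(p: Kinetics1to1 | Kinetics1to2, C: float,
                        durations: dict | None = None, noise_sd: float = 0.0,
                        drift: float = 0.0, seed: int = 0,
                        dt: float = 0.2) -> Sensorgram:
    """Simulate a sensorgram and add seeded Gaussian noise and linear drift
    (nm per second)."""
    durations = durations or {"baseline": 60.0, "association": 120.0,
                              "dissociation": 120.0}
    if isinstance(p, Kinetics1to2):
        sg = simulate_1to2(p, C, durations, dt=dt)
    else:
        sg = simulate_1to1(p, C, durations, dt=dt)
    R = sg.R.copy()
    if drift:
        R = R + drift * (sg.t - sg.t[0])
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        R = R + rng.normal(0.0, noise_sd, size=R.shape)
    return Sensorgram(t=sg.t, R=R, phases=sg.phases, C=sg.C, states=sg.states)


# ---------------------------------------------------------------------------
# presets expressing published table rows as generator parameters


def _preset_transitions(rows, levels):
    """rows: (T_m degC, dS J/K/mol) pairs; dH_vH = dS * T_m(K)."""
    out = []
    for (tm, ds), (f0, f1) in zip(rows, levels):
        out.append(TransitionSpec(T_m=tm, dH_vH=ds * (tm + KELVIN),
                                  f_start=f0, f_end=f1))
    return tuple(out)


PRESETS: dict[str, MeltSpec] = {
    # hardest published case: three transitions, rise-rise-fall
    "f1il-like": MeltSpec(
        transitions=_preset_transitions(
            [(52.4, 910.0), (67.5, 2200.0), (86.8, 960.0)],
            [(0.0, 0.45), (0.45, 1.0), (1.0, 0.35)]),
        noise_sd=0.0, label="f1il-like"),
    # two-transition aqueous case; region 1 matches dH_vH ~ 430 kJ/mol
    "water-like": MeltSpec(
        transitions=_preset_transitions(
            [(75.5, 1230.0), (91.83, 3090.0)],
            [(0.0, 0.55), (0.55, 1.0)]),
        noise_sd=0.0, label="water-like"),
    # single sigmoidal transition (excipient-stabilised case)
    "f1-like": MeltSpec(
        transitions=_preset_transitions([(77.0, 1560.0)], [(0.0, 1.0)]),
        noise_sd=0.0, label="f1-like"),
}


def preset(name: str, *, seed: int = 0, noise_sd: float | None = None) -> MeltSpec:
    """Return a named preset, optionally overriding seed and noise level.

    ``noise_sd`` here is relative to the baseline span at the grid midpoint
    when given as a value < 1 (e.g. 0.01 = 1% of span), absolute otherwise.
    """
    try:
        spec = PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None
    kw: dict = {"seed": seed}
    if noise_sd is not None:
        if noise_sd < 1.0:
            T = spec.temperatures
            y0, ymax = spec.baselines(T)
            span = float(np.mean(np.abs(ymax - y0)))
            kw["noise_sd"] = noise_sd * span
        else:
            kw["noise_sd"] = noise_sd
    return replace(spec, **kw)
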