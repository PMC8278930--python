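"""Bio-layer interferometry sensorgram simulation and kinetic fitting.

A BLI assay has three phases: baseline (buffer), association (analyte at
molar concentration C binds immobilised ligand) and dissociation (buffer
again).  The 1:1 Langmuir model has the closed forms

    association:   R(t) = Req (1 - exp(-(kon C + koff) t)),
                   Req  = Rmax C / (C + koff/kon)
    dissociation:  R(t) = R_end exp(-koff (t - t_d))

A bivalent analyte such as an IgG antibody can bridge two ligand molecules
(avidity), producing biphasic sensorgrams that a 1:1 model cannot describe.
Two 1:2 model forms are provided:

* ``parallel_sites`` (default) — the response is the sum of two independent
  1:1 phases, each with its own (kon, koff, Rmax).  This matches the
  parameterisation commonly used when fitting biphasic sensorgrams.
* ``sequential_bivalent`` — mass-action ODEs for A + L <-> AL,
  AL + L <-> AL2, integrated numerically, with the free-site balance
  L + [AL] + 2[AL2] = Ltot conserved.

K_D = koff1 / kon1 characterises the first (analyte-ligand) binding step.
Analyte depletion is neglected (C constant during association).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

__all__ = [
    "Sensorgram",
    "Kinetics1to1",
    "Kinetics1to2",
    "KineticFit",
    "simulate_1to1",
    "simulate_1to2",
    "fit_sensorgram",
    "compute_KD",
    "mass_to_molar",
]

PHASES = ("baseline", "association", "dissociation")


@dataclass(frozen=True)
class Kinetics1to1:
    """1:1 Langmuir rate constants: kon (M^-1 s^-1), koff (s^-1), Rmax (nm)."""

    kon: float
    koff: float
    Rmax: float

    def __post_init__(self) -> None:
        if min(self.kon, self.koff, self.Rmax) <= 0:
            raise ValueError("kon, koff and Rmax must all be positive")


@dataclass(frozen=True)
class Kinetics1to2:
    """Rate constants of a 1:2 (bivalent-analyte) binding model.

    (kon1, koff1, Rmax1) govern the first binding phase, (kon2, koff2, Rmax2)
    the second; under ``sequential_bivalent`` Rmax2 is the bridging signal
    increment per AL2 complex.
    """

    kon1: float
    koff1: float
    Rmax1: float
    kon2: float
    koff2: float
    Rmax2: float
    model_form: str = "parallel_sites"

    def __post_init__(self) -> None:
        if min(self.kon1, self.koff1, self.Rmax1) <= 0:
            raise ValueError("first-phase parameters must be positive")
        if min(self.kon2, self.koff2) < 0 or self.Rmax2 < 0:
            raise ValueError("second-phase parameters must be non-negative")
        if self.model_form not in ("parallel_sites", "sequential_bivalent"):
            raise ValueError("model_form must be parallel_sites or sequential_bivalent")


@dataclass
class Sensorgram:
    """Time/response trace with phase annotations.

    ``phases`` maps phase name to its (t_start, t_end) interval; ``C`` is the
    molar analyte concentration during association.
    """

    t: np.ndarray
    R: np.ndarray
    phases: dict
    C: float
    states: dict | None = None  # sequential model: L, AL, AL2 trajectories

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.R = np.asarray(self.R, dtype=float)
        if self.t.shape != self.R.shape:
            raise ValueError("t and R must have equal length")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")
        if "association" in self.phases and self.C < 0:
            raise ValueError("analyte concentration C must be non-negative")

    def segment(self, phase: str) -> tuple[np.ndarray, np.ndarray]:
        t0, t1 = self.phases[phase]
        m = (self.t >= t0) & (self.t <= t1)
        return self.t[m], self.R[m]


@dataclass
class KineticFit:
    params: object  # Kinetics1to1 | Kinetics1to2
    KD: float
    rss: float
    rmse: float
    stderr: dict = field(default_factory=dict)
    converged: bool = True
    model: str = "one_to_one"


def _phase_grid(durations: dict, dt: float) -> tuple[np.ndarray, dict]:
    t0 = 0.0
    phases = {}
    ts = []
    for name in PHASES:
        d = float(durations.get(name, 0.0))
        if d < 0:
            raise ValueError(f"{name} duration must be >= 0")
        if d == 0:
            continue
        seg = np.arange(t0, t0 + d + dt / 2, dt)
        phases[name] = (t0, t0 + d)
        ts.append(seg)
        t0 += d
    t = np.unique(np.concatenate(ts))
    return t, phases


def _response_1to1(t, phases, C, kon, koff, Rmax):
    R = np.zeros_like(t)
    if "association" in phases:
        ta0, ta1 = phases["association"]
        m = (t >= ta0) & (t <= ta1)
        Req = Rmax * C / (C + koff / kon)
        kobs = kon * C + koff
        R[m] = Req * (1.0 - np.exp(-kobs * (t[m] - ta0)))
        R_end = Req * (1.0 - np.exp(-kobs * (ta1 - ta0)))
    else:
        R_end = 0.0
    if "dissociation" in phases:
        td0, td1 = phases["dissociation"]
        m = t > td0
        R[m] = R_end * np.exp(-koff * (t[m] - td0))
    return R


def simulate_1to1(p: Kinetics1to1, C: float, durations: dict,
                  dt: float = 0.2) -> Sensorgram:
    """Closed-form 1:1 sensorgram over baseline/association/dissociation.

    ``durations`` maps phase names to lengths in seconds, e.g.
    ``{"baseline": 60, "association": 120, "dissociation": 120}``.
    """
    if C < 0:
        raise ValueError("C must be >= 0")
    t, phases = _phase_grid(durations, dt)
    if C == 0:
        return Sensorgram(t, np.zeros_like(t), phases, C=0.0)
    R = _response_1to1(t, phases, C, p.kon, p.koff, p.Rmax)
    return Sensorgram(t, R, phases, C=C)


def _simulate_sequential(p: Kinetics1to2, C: float, t: np.ndarray, phases: dict):
    """Integrate the sequential bivalent scheme; state = (L, AL, AL2) with
    Ltot normalised to 1.  All three species are integrated so the balance
    L + AL + 2 AL2 = Ltot is a genuine numerical check, not an identity."""
    Ltot = 1.0

    def rhs(t_, s, conc):
        L, AL, AL2 = s
        form1 = p.kon1 * conc * L
        diss1 = p.koff1 * AL
        form2 = p.kon2 * AL * L
        diss2 = p.koff2 * AL2
        return [-form1 + diss1 - form2 + diss2,
                form1 - diss1 - form2 + diss2,
                form2 - diss2]

    R = np.zeros_like(t)
    L_t = np.full_like(t, Ltot)
    AL_t = np.zeros_like(t)
    AL2_t = np.zeros_like(t)
    state = np.array([Ltot, 0.0, 0.0])
    scale = p.Rmax1 / Ltot
    for name in ("association", "dissociation"):
        if name not in phases:
            continue
        t0, t1 = phases[name]
        m = (t >= t0) & (t <= t1)
        conc = C if name == "association" else 0.0
        sol = solve_ivp(rhs, (t0, t1), state, t_eval=t[m], args=(conc,),
                        method="LSODA", rtol=1e-10, atol=1e-12)
        if not sol.success:
            raise RuntimeError(f"stiff integration failed in {name}: {sol.message}")
        L, AL, AL2 = sol.y
        # first contacts scale to Rmax1; Rmax2 is the bridging increment per AL2
        R[m] = scale * (AL + AL2) + (p.Rmax2 / Ltot) * AL2
        L_t[m], AL_t[m], AL2_t[m] = L, AL, AL2
        state = sol.y[:, -1]
    return R, {"L": L_t, "AL": AL_t, "AL2": AL2_t, "Ltot": Ltot}


def simulate_1to2(p: Kinetics1to2, C: float, durations: dict,
                  dt: float = 0.2) -> Sensorgram:
    """Simulate a 1:2 sensorgram under the chosen model form.

    ``parallel_sites``: superposition of two independent 1:1 responses.
    ``sequential_bivalent``: mass-action ODE integration of the bridged
    complex scheme.
    """
    t, phases = _phase_grid(durations, dt)
    if p.model_form == "parallel_sites":
        R = _response_1to1(t, phases, C, p.kon1, p.koff1, p.Rmax1)
        if p.kon2 > 0 and p.Rmax2 > 0:
            R = R + _response_1to1(t, phases, C, p.kon2, max(p.koff2, 1e-300), p.Rmax2)
        return Sensorgram(t, R, phases, C=C)
    R, states = _simulate_sequential(p, C, t, phases)
    return Sensorgram(t, R, phases, C=C, states=states)


def compute_KD(kon1: float, koff1: float) -> float:
    """Equilibrium dissociation constant K_D = koff1 / kon1 (M)."""
    if kon1 <= 0:
        raise ValueError("kon1 must be positive")
    return koff1 / kon1


def mass_to_molar(conc_mg_per_mL: float, MW_g_per_mol: float) -> float:
    """Convert a mass concentration (mg/mL) to molarity (mol/L)."""
    if conc_mg_per_mL <= 0 or MW_g_per_mol <= 0:
        raise ValueError("concentration and molecular weight must be positive")
    return conc_mg_per_mL / MW_g_per_mol  # mg/mL == g/L; g/L / (g/mol) = mol/L


# ---------------------------------------------------------------------------
# fitting


def _initial_estimates(sg: Sensorgram):
    """koff from the log-linear dissociation tail, kobs from the association
    rise, Rmax from the association end level."""
    ta, Ra = sg.segment("association")
    td, Rd = sg.segment("dissociation")
    R_end = Ra[-1]
    pos = Rd > max(1e-4 * max(abs(R_end), 1e-12), 1e-12)
    if pos.sum() >= 3 and R_end > 0:
        slope = np.polyfit(td[pos] - td[0], np.log(Rd[pos]), 1)[0]
        koff0 = max(-slope, 1e-6)
    else:
        koff0 = 1e-3
    # kobs from time to ~63% of the end level
    target = 0.632 * R_end
    idx = np.nonzero(Ra >= target)[0]
    tau = (ta[idx[0]] - ta[0]) if idx.size else (ta[-1] - ta[0]) / 3.0
    kobs0 = 1.0 / max(tau, 1e-6)
    kon0 = max((kobs0 - koff0) / sg.C, 1e2)
    Req0 = max(R_end, 1e-6)
    Rmax0 = Req0 * (sg.C + koff0 / kon0) / sg.C
    return kon0, koff0, Rmax0


def fit_sensorgram(sg: Sensorgram, model: str = "one_to_two") -> KineticFit:
    """Fit a sensorgram by bounded nonlinear least squares.

    Rate constants are optimised on a log10 scale; initial values come from
    linearised estimates (dissociation tail for koff, observed association
    rate kobs = kon C + koff for kon).  The fit is performed jointly over the
    association and dissociation phases.  ``converged`` is set False when the
    optimiser terminates on a parameter bound, and the RMSE is reported so
    1:1 and 1:2 fits of the same trace can be compared directly.
    """
    if "dissociation" not in sg.phases:
        raise ValueError("cannot estimate koff without a dissociation phase")
    if "association" not in sg.phases:
        raise ValueError("sensorgram has no association phase")
    if not sg.C > 0:
        raise ValueError("analyte concentration must be positive to fit")
    ta, Ra = sg.segment("association")
    td, Rd = sg.segment("dissociation")
    if np.ptp(np.concatenate([Ra, Rd])) <= 0 or np.max(np.abs(Ra)) < 1e-12:
        raise ValueError("flat trace: no binding signal to fit")

    t_fit = np.concatenate([ta, td])
    R_obs = np.concatenate([Ra, Rd])
    phases = {"association": sg.phases["association"],
              "dissociation": sg.phases["dissociation"]}
    kon0, koff0, Rmax0 = _initial_estimates(sg)

    if model == "one_to_one":
        x0 = [np.log10(kon0), np.log10(koff0), Rmax0]
        lb = [0.0, -7.0, 1e-6]
        ub = [9.0, 2.0, 100.0 * Rmax0]

        def predict(x):
            kon, koff = 10 ** x[0], 10 ** x[1]
            return _response_1to1(t_fit, phases, sg.C, kon, koff, x[2])
    elif model == "one_to_two":
        x0 = [np.log10(kon0 * 2), np.log10(koff0), 0.7 * Rmax0,
              np.log10(max(kon0 / 10, 1e2)), np.log10(koff0 * 10), 0.5 * Rmax0]
        lb = [0.0, -7.0, 1e-6, 0.0, -7.0, 1e-6]
        ub = [9.0, 2.0, 100 * Rmax0, 9.0, 2.0, 100 * Rmax0]

        def predict(x):
            r1 = _response_1to1(t_fit, phases, sg.C, 10 ** x[0], 10 ** x[1], x[2])
            r2 = _response_1to1(t_fit, phases, sg.C, 10 ** x[3], 10 ** x[4], x[5])
            return r1 + r2
    else:
        raise ValueError("model must be 'one_to_one' or 'one_to_two'")

    res = least_squares(lambda x: predict(x) - R_obs, x0, bounds=(lb, ub),
                        method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14)
    x = res.x
    at_bound = bool(np.any(np.isclose(x, lb, atol=1e-9) |
                           np.isclose(x, ub, rtol=1e-9)))
    rss = float(np.sum(res.fun ** 2))
    n = R_obs.size
    fit_rmse = float(np.sqrt(rss / n))

    # standard errors from J^T J, propagated through the log10 scaling
    stderr: dict[str, float] = {}
    try:
        J = res.jac
        dof = max(n - x.size, 1)
        cov = np.linalg.inv(J.T @ J) * (rss / dof)
        se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        se = np.full(x.size, np.nan)

    ln10 = np.log(10.0)
    if model == "one_to_one":
        kon, koff, Rmax = 10 ** x[0], 10 ** x[1], x[2]
        params: object = Kinetics1to1(kon=kon, koff=koff, Rmax=Rmax)
        stderr = {"kon": kon * ln10 * se[0], "koff": koff * ln10 * se[1],
                  "Rmax": se[2]}
        KD = compute_KD(kon, koff)
    else:
        k = [10 ** x[0], 10 ** x[1], x[2], 10 ** x[3], 10 ** x[4], x[5]]
        # order the two phases so phase 1 is the faster-associating one
        if k[0] < k[3]:
            k = k[3:] + k[:3]
            se = np.concatenate([se[3:], se[:3]])
        params = Kinetics1to2(kon1=k[0], koff1=k[1], Rmax1=k[2],
                              kon2=k[3], koff2=max(k[4], 1e-300), Rmax2=k[5])
        stderr = {"kon1": k[0] * ln10 * se[0], "koff1": k[1] * ln10 * se[1],
                  "Rmax1": se[2], "kon2": k[3] * ln10 * se[3],
                  "koff2": k[4] * ln10 * se[4], "Rmax2": se[5]}
        KD = compute_KD(params.kon1, params.koff1)

    return KineticFit(params=params, KD=KD, rss=rss, rmse=fit_rmse,
                      stderr=stderr, converged=res.success and not at_bound,
                      model=model)
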