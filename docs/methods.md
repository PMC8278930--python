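# Methods

This note records the models, conventions and numerical choices behind
`cdmelt`, including the points where the underlying analysis left the
design open and a choice had to be made.

## Spectral treatment

The treatment chain is fixed: background subtraction (arithmetic mean of
replicate matrix-only spectra) → zeroing on the mean of the 250–260 nm
window per temperature slice → Savitzky–Golay smoothing along the
wavelength axis (7 points, polynomial order 5) → conversion to mean residue
ellipticity. Zeroing is idempotent to machine precision and the SG filter
reproduces polynomials of degree ≤ 5 exactly; edges are handled by fitting
the polynomial to the truncated edge window rather than padding outside the
measured 190–260 nm range. Smoothing along the temperature axis is
available but off by default — the transition analysis must see the sharp
temperature dependence unblurred. Missing matrix values are rejected, not
imputed, because the smoother is not defined over gaps.

The MRE definition uses the mean residue weight MRW = MW/(N_res − 1):
MRE = θ_mdeg · MRW / (10 · l_cm · c_mg/mL). Every downstream quantity (the
relative fraction f, hence all thermodynamics) is invariant under any fixed
affine rescaling of the signal, so this convention affects plotting units
only. The affine invariance is property-tested.

## Relative β-sheet fraction

Two referencing modes implement f = (y − y₀)/(y_max − y₀):

* **two_state** — y₀(T), y_max(T) are least-squares lines through the low-
  and high-temperature plateaus, extrapolated across the transition. Used
  for monotone sigmoidal melts.
* **peak_referenced** — y₀ is the endpoint signal of minimum magnitude and
  y_max the strongest (most negative) signal anywhere on the curve. Used
  for melts whose β-sheet content rises and then falls, where a
  high-temperature baseline does not exist.

Mode selection (`auto`) fits a Boltzmann sigmoid and a bi-Gaussian to the
raw signal and picks peak-referenced when the bi-Gaussian RMSE is lower;
either mode can be forced. The fraction is finally rescaled affinely onto
[0, 1] (idempotent). A denominator floor of 10⁻⁶ of the 25 °C baseline
separation guards against baseline crossover under extrapolation; genuine
crossings inside the measured range raise an error.

When the two-state baselines are auto-detected, one refinement pass re-fits
them on windows at least 5.5 sigmoid widths away from every fitted
midpoint. Auto-detected plateau windows grow until the sigmoid curvature
becomes detectable against the noise, so they invariably retain a few
early-rise points whose tilt biases the extrapolated references; on
synthetic single-transition melts at 1 % noise this pass removes a ≈0.3 °C
midpoint bias.

## Segmentation

Plateau detection seeds windows at both data ends and at the flattest point
of a smoothed |df/dT| between each pair of transition peaks (peaks found on
the Savitzky–Golay derivative with height and prominence floors scaled to
the plateau slope tolerance and the derivative noise). Each seed window of
`min_plateau_points` (default 5) grows greedily while the line fit's
residual RMS stays within `resid_k` (1.6) times the robust point-noise
estimate and |slope| ≤ `slope_tol` (default 0.005 f-units/°C, with a
2σ-of-slope allowance so short noisy windows are not halted by a single
unlucky extension). r² is reported per plateau but is deliberately not a
growth criterion: on a genuinely flat noisy plateau the r² of a line fit is
near zero, so any r² floor would reject exactly the regions the detector
must find. The point-noise estimate comes from the MAD of the residuals of
a mild quadratic SG smooth (variance factor 2/3 for white noise), which is
robust to the model bias concentrated at sharp transitions.

One Boltzmann sigmoid f(T) = A₂ + (A₁−A₂)/(1+exp((T−T₀)/dT)) is fitted
between each sequential pair of plateaus (spans inclusive of the bounding
plateau points); when the last plateau does not reach the data end a final
sigmoid runs from it to the end point — the minimum of the fitted
(bi-)Gaussian guide model when the overall shape is Gaussian-like.
Initialisation is deterministic (asymptotes from span endpoints, midpoint
from the derivative extremum, width from span/10); there are no random
restarts. Fitted sigmoids with amplitude below 5 % of the curve span are
discarded as spurious.

**Global refinement.** Per-span fits carry a systematic asymptote bias when
neighbouring transitions overlap — at realistic midpoint spacings
(~15 °C gaps, widths 1.3–3 °C) the shared plateau never quite reaches its
asymptote. The chain is therefore refitted jointly as a linear baseline
plus a sum of two-state van't Hoff components
p_i(T) = 1/(1+exp((ΔH_i/R)(1/T_K − 1/T_m,K))), initialised from the chain
fit. This both removes the overlap bias and replaces the empirical
Boltzmann temperature dependence with the thermodynamic form the downstream
analysis assumes. The refinement can be disabled (`refine=False` in
`segment_curve`), in which case the literal per-span sigmoids and
plateau-line references are used throughout.

**Characteristic temperatures.** T_m is the midpoint of each component.
T_I is the temperature at which two adjacent region curves predict equal f,
found by bracketed root-finding between the midpoints (widened once to the
joint fit range). Two *same-direction* chained sigmoids sharing a plateau
level approach each other asymptotically and generically never cross; in
that degenerate case the closest-approach temperature (the interior minimum
of |s₁−s₂|, where the two exponential tails balance) is returned — it
coincides with the crossing whenever one exists, and is rejected if the
approach is not a genuine interior dip (e.g. parallel-shifted identical
sigmoids). When the refined chain is available the intersection is computed
on the van't Hoff region curves themselves: near a shared plateau the
crossing is tail-dominated and the Boltzmann approximation of a van't Hoff
tail can displace it by degrees.

T_onset uses the standard thermal-analysis tangent construction —
intersection of the low-temperature plateau line with the tangent to the
first sigmoid at its midpoint, giving T₀ − 2dT in closed form for a flat
plateau — with a threshold alternative (first crossing of a configurable
fraction, default 5 %, of the first sigmoid's amplitude, linearly
interpolated). The onset definition is an analysis convention and every
report flags it as such.

The overall shape model (parabolic / Gaussian / bi-Gaussian, the latter an
asymmetric Gaussian with separate left/right widths about its centre) is
selected by minimum RMSE = √(RSS/n); ties within 10⁻⁹ break toward fewer
parameters for determinism.

## Thermodynamics

Each sigmoidal region is an independent two-state equilibrium. The
region-local progress fraction (0 → 1 across the region regardless of
whether the raw curve rises or falls there) gives K = f_i/(1−f_i) and
ΔG = −R·T_K·ln K (R = 8.314 J mol⁻¹ K⁻¹, T in kelvin inside the
logarithm's prefactor). ΔG is regressed linearly against temperature inside
the transition window |ΔG| < 5 kJ/mol (configurable), restricted to the
region's own regime — within six widths of its midpoint and no closer to a
neighbouring transition than the midway temperature. Fractions outside
(ε, 1−ε), ε = 0.02, are excluded before forming K (ln K diverges at the
rails); on noiseless data this exclusion provably does not move T_m.

**Temperature-axis convention.** The regression is performed against
temperature on the **Celsius axis**: ΔH is the intercept at 0 °C and ΔS the
negative slope, so the identity ΔH = T_m(°C)·ΔS holds exactly at the fitted
root T_m = ΔH/ΔS. This is the convention under which the published
formulation tables are internally consistent (e.g. 120 kJ/mol /
1.56 kJ/K/mol = 76.9 °C against a printed midpoint of 77.0 °C), and it is
the package default (`paper_celsius`). The physically conventional van't
Hoff enthalpy ΔH_vH = T_m(K)·ΔS derives from the same regression and is
always reported alongside (`van_t_hoff` makes it primary). Totals are
straight sums, ΔH_total = Σ ΔH_i and ΔS_total = Σ ΔS_i, and
ΔG_total = ΔH_total − T_ref·ΔS_total with T_ref = the last intersection
temperature (falling back to the last T_m for single-region curves) — the
reference that reproduces the published ΔG_total values, again flagged in
reports as a convention. Published water-formulation totals exceed the sum
of the corresponding region rows by ~13 kJ/mol; the package reports the
straight sum and does not emulate unexplained additions. Uncertainties are
standard errors from the unweighted regression covariance (T_m by the delta
method) with totals combined in quadrature.

When the refined chain model is available, the ΔG points entering the
regression are evaluated from the fitted region model rather than from
pointwise noisy fractions. The region's two-state component *is* the
estimator of its equilibrium, and it pools the information of every point
in the transition; the pointwise route (available via `refine=False`)
estimates the slope from only the handful of points inside the |ΔG| window
and is 1.3–2× noisier. For noiseless two-state data the two routes agree
to the solver tolerance.

### Precision limits

A Cramér–Rao analysis of the full melt model (linear baseline + three
van't Hoff components, 73 points over 25–97 °C, Gaussian noise of 1 % of
the baseline span) shows that the achievable relative standard deviation of
ΔS is ≈6 % for a broad first transition whose baseline must be
co-estimated, and ≈5 % for a sharp middle transition (width ≈1.3 °C, so
only ~5 points carry its slope information) — for *any* unbiased estimator.
The implemented estimator reaches these bounds (empirical sds 6.3/5.1/4.3 %
across the three regions of the hardest preset, biases < 1 %). Joint
recovery of all three entropies within 10 % therefore tops out near ~85 %
of replicates at these settings; midpoints are recovered within 0.5 °C and
intersections ordered correctly in ≈100 %. Entropy precision claims at
this noise level should be made per region, not jointly.

## Synthetic data

The generator is a forward model of everything the analysis assumes:
f(T) = f_start,₁ + Σ_i (f_end,i − f_start,i)·p_i(T) with van't Hoff
populations p_i, mapped through linear baselines
y = y₀(T) + (y_max(T) − y₀(T))·f plus homoscedastic Gaussian noise
(single seeded generator; identical seeds give identical bits). Under the
Celsius reporting convention the generating entropy of transition i is
ΔS_i = ΔH_vH,i/T_m,i(K), which is how published table rows are expressed as
presets: `f1il-like` (three transitions, rise–rise–fall, midpoints
52.4/67.5/86.8 °C, entropies 910/2200/960 J K⁻¹ mol⁻¹, amplitude split
0.45/0.55/−0.65 chosen to mirror the published curve shapes),
`water-like` (two rising transitions) and `f1-like` (single transition).
Default baselines (−4000 − 5T and −9000 − 8T MRE units) give realistic
drift of a fraction of a percent of the span per °C. Full-spectrum
synthesis adds a positive β-turn band at 202 nm and solves the 218 nm band
amplitude per temperature so the extracted 218 nm column reproduces the
single-wavelength melt exactly.

What the generator does **not** emulate: heteroscedastic or correlated
instrument noise, absorbance flattening and photomultiplier saturation at
low wavelength, irreversibility/hysteresis (the real conformational
changes are irreversible on cooling; the generator's equilibria are not),
aggregation-induced scattering drift, and heat-capacity (ΔCp) curvature of
ΔG. Passing recovery tests therefore demonstrate correctness of the
estimation chain under the stated model, not robustness to every artefact
of real instrument data.

## Binding kinetics

The 1:1 model uses the closed forms
R(t) = R_eq(1 − e^{−(k_on C + k_off)t}), R_eq = R_max C/(C + k_off/k_on)
during association and single-exponential decay during dissociation;
agreement with direct ODE integration is ~10⁻¹² nm. The "1:2" model for a
bivalent analyte is implemented in two forms because the fitted
parameterisation (independent kon/koff/Rmax pairs per phase) corresponds to
a parallel two-site scheme while the mechanistic narrative is sequential
avidity: `parallel_sites` (default; superposition of two 1:1 responses)
and `sequential_bivalent` (mass-action ODEs for A+L⇌AL, AL+L⇌AL₂ with all
three species integrated so the balance L+[AL]+2[AL₂] = L_tot is a genuine
numerical check, conserved to ~10⁻¹⁵). Statistical factors (the 2× some
bivalent formulations place on first binding) are omitted; Rmax₂ under the
sequential form is the bridging signal increment per AL₂. Analyte depletion
is neglected (constant C during association). The default analyte is an
IgG at 0.96 mg/mL with MW 146 kg/mol → C = 6.58 µM.

Fitting is bounded nonlinear least squares over log₁₀-scaled rates,
initialised from the log-linear dissociation tail (k_off) and the observed
association rate k_obs = k_on C + k_off; a fit that terminates on a bound
is reported with `converged = False`. Both 1:1 and 1:2 RMSEs are reported
so the over-parameterisation of a genuinely monophasic trace is visible.
Known limitation: separating two exponentials whose decay times are long
compared with a 2-minute dissociation phase is ill-conditioned, so
individual rate constants of slowly dissociating biphasic traces carry
large correlated uncertainties even when the fit is excellent; K_D is more
stable than its factors. Noiseless parallel-site traces are recovered to
machine precision.

## Interfaces

The pipeline-level fits are scikit-learn estimators
(`MeltThermogramAnalyzer`, `BindingKineticsEstimator`) with
`get_params`/`set_params`, trailing-underscore fitted attributes and
`fit`/`predict`/`score`, so they compose with sklearn tooling; the
fine-grained operations remain plain functions. The CLI (`cdmelt melt
simulate|analyze`, `cdmelt bli simulate|fit`) is a thin wrapper; every
analysis report records the software version, configuration, seed and an
input digest, and lists the conventions (Celsius regression, T_ref rule,
onset construction) so they cannot be mistaken for instrument-defined
quantities. All problem sizes used in the test-suite and in
`scripts/acceptance.py` (73-point melts, 200 recovery replicates, 0.2 s
sensorgram sampling) are the package's standard working sizes.
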