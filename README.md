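# cdmelt

Thermal-unfolding analysis of antibody circular-dichroism (CD) melt curves
and bio-layer-interferometry (BLI) binding kinetics.

High-concentration antibody formulations (IgG4 with sugars, amino acids,
surfactants, and ionic liquids such as choline dihydrogen phosphate) undergo
temperature-driven conformational transitions that show up as changes in the
218 nm β-sheet band of the far-UV CD spectrum. `cdmelt` turns
variable-temperature CD spectra into a quantitative description of those
transitions, and fits the 1:1 / 1:2 binding kinetics of the matching BLI
sensorgrams. It is written for formulation scientists and biophysicists who
want the full chain — instrument CSV to thermodynamic table — as tested,
scriptable code.

## What it computes

**Melt-curve pipeline.** Spectra are background-subtracted, zeroed on the
optically silent 250–260 nm region, Savitzky–Golay smoothed (7 points,
order 5) and converted to mean residue ellipticity,
MRE = θ·MRW / (10·l·c) with MRW = MW/(N<sub>res</sub>−1). The 218 nm signal
y(T) becomes a relative β-sheet fraction

f(T) = (y − y₀(T)) / (y_max(T) − y₀(T)),

with y₀, y_max either extrapolated linear baselines (monotone, two-state
melts) or the endpoint/peak signals (rise-then-fall melts), rescaled so the
maximum-β-sheet conformer has f = 1. The curve is decomposed into *m*
linear plateaus and *r* Boltzmann sigmoids
f(T) = A₂ + (A₁−A₂)/(1+exp((T−T₀)/dT)); a global refinement refits all
transitions jointly as two-state van't Hoff components. Each sigmoid
midpoint is a transition temperature T_m; adjacent sigmoids meet at
intersection temperatures T_I (local free-energy minima separating
conformational regimes); T_onset marks the departure from the
low-temperature plateau. Per region, the two-state equilibrium constant
K = f/(1−f) gives ΔG = −RT ln K, which is regressed linearly on temperature
inside the |ΔG| < 5 kJ/mol window to yield T_m, ΔH and ΔS and, summed over
regions, ΔH_total, ΔS_total and ΔG_total.

**BLI pipeline.** Sensorgrams (baseline / association / dissociation) are
simulated and fitted under a 1:1 Langmuir model or a 1:2 model for bivalent
analytes — either two parallel independent phases or a sequential bridged
(avidity) scheme integrated by mass-action ODEs. Fits report kon, koff and
Rmax per phase plus K_D = koff₁/kon₁, and the 1:1 vs 1:2 RMSE comparison
used to reject the 1:1 description of biphasic traces.

A seeded synthetic-data generator produces melt curves (1–3 sequential
van't Hoff transitions on linear baselines, Gaussian noise, optional full
190–260 nm spectra) and sensorgrams, providing ground truth for every
stage.

## Worked example

```bash
$ cdmelt melt simulate --preset f1il-like --seed 7 --noise 0.01 --out melt.csv
wrote melt.csv and melt.truth.json
$ cdmelt melt analyze melt.csv --out .
T_m: [52.29, 67.46, 86.82]
T_I: [61.79, 77.14]
wrote melt.report.json and melt.tables.tsv
```

The `f1il-like` preset is a three-transition melt (rise–rise–fall in
β-sheet content, midpoints 52.4 / 67.5 / 86.8 °C). The analysis recovers
the three midpoints to within a few tenths of a degree at 1 % noise and the
two intersection temperatures between them; the TSV report adds the
per-region ΔH/ΔS and totals.

The same pipeline as a library, in sklearn-style estimator form:

```python
from cdmelt import MeltThermogramAnalyzer, generate_cd_signal, preset

signal = generate_cd_signal(preset("f1il-like", seed=7, noise_sd=0.01))
an = MeltThermogramAnalyzer().fit(signal)
an.T_m_          # [52.29, 67.46, 86.82]  (degC)
an.T_I_          # [61.79, 77.14]
an.summary_.dH_total   # ~280 kJ/mol
```

For kinetics: `cdmelt bli simulate --model 1to2 --noise 0.003 --out sg.csv`
then `cdmelt bli fit sg.csv` prints the six rate/amplitude parameters, K_D
(≈2×10⁻⁹ M for the defaults) and the RMSE of both binding models.

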