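"""Published reference values for the six IgG4 formulations.

These are the reported transition temperatures and per-region/total
thermodynamic parameters from the variable-temperature CD study of a
chimeric IgG4 in water, a choline dihydrogen phosphate ionic-liquid (IL)
solution, two excipient formulations (F1, F2) and their IL-containing
variants (F1IL, F2IL).  They serve as consistency oracles: the analysis
conventions implemented here (Celsius-axis regression, totals by summation,
dG_total referenced at the last intersection temperature) reproduce the
internal identities of these tables.

Units: temperatures degC, dH kJ/mol, dS J K^-1 mol^-1, dG kJ/mol.
``None`` marks entries not reported for that formulation.
"""

from __future__ import annotations

__all__ = ["TRANSITION_TEMPERATURES", "REGION_THERMO", "TOTAL_THERMO"]

# T_m per sigmoidal region, onset temperature, and sigmoid intersections
TRANSITION_TEMPERATURES: dict[str, dict] = {
    "water": {"T_m": (75.5, 91.83, None), "T_onset": 72.0, "T_I": (86.3, None)},
    "IL":    {"T_m": (52.1, 68.8, 88.6),  "T_onset": 45.0, "T_I": (63.5, 76.5)},
    "F1":    {"T_m": (77.0, None, None),  "T_onset": 73.0, "T_I": (None, None)},
    "F2":    {"T_m": (76.1, None, None),  "T_onset": 72.0, "T_I": (None, None)},
    "F1IL":  {"T_m": (52.4, 67.5, 86.8),  "T_onset": 45.0, "T_I": (62.5, 73.5)},
    "F2IL":  {"T_m": (50.6, 63.3, 86.0),  "T_onset": 44.0, "T_I": (59.4, 73.1)},
}

# (dH_m_i kJ/mol, dS_m_i J/K/mol) per region
REGION_THERMO: dict[str, tuple] = {
    "water": ((93.0, 1230.0), (284.0, 3090.0), None),
    "IL":    ((47.0, 910.0), (260.0, 3800.0), (112.0, 1290.0)),
    "F1":    ((120.0, 1560.0), None, None),
    "F2":    ((104.0, 1360.0), None, None),
    "F1IL":  ((48.0, 910.0), (150.0, 2200.0), (81.0, 960.0)),
    "F2IL":  ((53.0, 1050.0), (134.0, 2120.0), (73.0, 870.0)),
}

# (dH_total kJ/mol, dS_total J/K/mol, dG_total kJ/mol)
TOTAL_THERMO: dict[str, tuple] = {
    "water": (390.0, 4500.0, 2.19),
    "IL":    (420.0, 6000.0, -40.5),
    "F1":    (120.0, 1560.0, None),
    "F2":    (104.0, 1360.0, None),
    "F1IL":  (280.0, 4100.0, -21.3),
    "F2IL":  (260.0, 4040.0, -35.1),
}
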