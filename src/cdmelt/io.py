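"""Reading, validation and reporting for variable-temperature CD data.

The canonical on-disk layout is a plain CSV (TSV accepted by sniffing) whose
first column is temperature in degrees Celsius and whose remaining column
headers are numeric wavelengths in nm.  Values are raw ellipticity in
millidegrees or mean residue ellipticity (MRE, deg cm^2 dmol^-1) depending on
``units``.  Single-wavelength melt series use a two-column
``temperature_C, signal`` layout.
"""

from __future__ import annotations

import csv
import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SampleMeta",
    "CDSpectrumSeries",
    "MeltSignal",
    "MeltParseError",
    "ValidationError",
    "read_melt_csv",
    "read_signal_csv",
    "extract_wavelength",
    "write_results",
]

MDEG = "millidegrees"
MRE = "MRE"


class MeltParseError(ValueError):
    """Malformed CSV input (bad header or non-numeric cell)."""


class ValidationError(ValueError):
    """Structurally parseable but physically invalid input."""


@dataclass(frozen=True)
class SampleMeta:
    """Sample metadata required for the mean-residue-ellipticity conversion.

    Parameters
    ----------
    protein_conc : float
        Mass concentration of protein, mg/mL.
    pathlength : float
        Cuvette path length, cm.
    molecular_weight : float
        Protein molar mass, g/mol.
    n_residues : int
        Number of amino-acid residues.
    label : str
        Free-text formulation name (e.g. ``"F1IL"``).
    """

    protein_conc: float
    pathlength: float
    molecular_weight: float
    n_residues: int
    label: str = ""

    def __post_init__(self) -> None:
        if not self.protein_conc > 0:
            raise ValidationError("protein_conc must be > 0 mg/mL")
        if not self.pathlength > 0:
            raise ValidationError("pathlength must be > 0 cm")
        if not self.molecular_weight > 0:
            raise ValidationError("molecular_weight must be > 0 g/mol")
        if self.n_residues < 2:
            raise ValidationError("n_residues must be >= 2")

    @property
    def mean_residue_weight(self) -> float:
        """MRW = MW / (n_residues - 1), g/mol per peptide bond."""
        return self.molecular_weight / (self.n_residues - 1)


@dataclass
class CDSpectrumSeries:
    """Temperature-indexed CD spectra.

    ``signal[i, j]`` is the ellipticity at ``temperatures[i]`` (deg C) and
    ``wavelengths[j]`` (nm), in the units named by ``units``.
    """

    temperatures: np.ndarray
    wavelengths: np.ndarray
    signal: np.ndarray
    units: str = MDEG
    meta: SampleMeta | None = None

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.units not in (MDEG, MRE):
            raise ValidationError(f"unknown units flag {self.units!r}")
        if self.signal.shape != (self.temperatures.size, self.wavelengths.size):
            raise ValidationError(
                f"signal shape {self.signal.shape} does not match "
                f"({self.temperatures.size}, {self.wavelengths.size})"
            )
        if self.temperatures.size and np.any(np.diff(self.temperatures) <= 0):
            raise ValidationError("temperatures must be strictly increasing")
        dw = np.diff(self.wavelengths)
        if dw.size and not (np.all(dw > 0) or np.all(dw < 0)):
            raise ValidationError("wavelengths must be strictly monotone")
        if not np.all(np.isfinite(self.signal)):
            raise ValidationError("signal contains non-finite entries")

    def copy_with(self, **kw) -> "CDSpectrumSeries":
        out = dataclasses.replace(self, **kw)
        return out


@dataclass
class MeltSignal:
    """Single-wavelength CD signal versus temperature."""

    temperatures: np.ndarray
    y: np.ndarray
    wavelength: float
    meta: SampleMeta | None = None

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.temperatures.shape != self.y.shape:
            raise ValidationError("temperatures and y must have equal length")
        if self.temperatures.size and np.any(np.diff(self.temperatures) <= 0):
            raise ValidationError("temperatures must be strictly increasing")


def _sniff_delimiter(path: Path) -> str:
    head = path.read_text(encoding="utf-8").splitlines()[0] if path.stat().st_size else ""
    return "\t" if head.count("\t") > head.count(",") else ","


def read_melt_csv(path: str | Path, units: str = MDEG,
                  meta: SampleMeta | None = None) -> CDSpectrumSeries:
    """Read a temperature x wavelength CD matrix from CSV/TSV.

    The first column is temperature (deg C); remaining headers must parse as
    wavelengths in nm.  Rows are sorted by temperature; duplicate temperatures
    are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    delim = _sniff_delimiter(path)
    with path.open(encoding="utf-8", newline="") as fh:
        rows = list(csv.reader(fh, delimiter=delim))
    rows = [r for r in rows if r and any(c.strip() for c in r)]
    if not rows:
        raise MeltParseError(f"{path}: empty file")
    header = rows[0]
    if len(header) < 2:
        raise MeltParseError(f"{path}: need a temperature column plus wavelengths")
    wavelengths = []
    for col in header[1:]:
        try:
            wavelengths.append(float(col))
        except ValueError:
            raise MeltParseError(
                f"{path}: header column {col!r} is not a numeric wavelength"
            ) from None
    data = np.empty((len(rows) - 1, len(header)), dtype=float)
    for i, row in enumerate(rows[1:], start=2):
        if len(row) != len(header):
            raise MeltParseError(f"{path}: row {i} has {len(row)} fields, expected {len(header)}")
        for j, cell in enumerate(row):
            try:
                data[i - 2, j] = float(cell)
            except ValueError:
                raise MeltParseError(
                    f"{path}: non-numeric value {cell!r} at row {i}, column {header[j]!r}"
                ) from None
    temps = data[:, 0]
    uniq, counts = np.unique(temps, return_counts=True)
    if np.any(counts > 1):
        dup = uniq[counts > 1][0]
        raise ValidationError(f"{path}: duplicate temperature {dup:g} degC")
    order = np.argsort(temps)
    return CDSpectrumSeries(
        temperatures=temps[order],
        wavelengths=np.asarray(wavelengths),
        signal=data[order, 1:],
        units=units,
        meta=meta,
    )


def read_signal_csv(path: str | Path, wavelength: float = 218.0,
                    meta: SampleMeta | None = None) -> MeltSignal:
    """Read a two-column ``temperature_C, signal`` melt series."""
    path = Path(path)
    delim = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=delim)
    if df.shape[1] < 2:
        raise MeltParseError(f"{path}: expected two columns (temperature, signal)")
    temps = df.iloc[:, 0].to_numpy(dtype=float)
    y = df.iloc[:, 1].to_numpy(dtype=float)
    order = np.argsort(temps)
    temps, y = temps[order], y[order]
    if np.any(np.diff(temps) == 0):
        raise ValidationError(f"{path}: duplicate temperatures")
    return MeltSignal(temperatures=temps, y=y, wavelength=wavelength, meta=meta)


def extract_wavelength(series: CDSpectrumSeries, wavelength: float) -> MeltSignal:
    """Project the spectral series onto the grid column nearest ``wavelength``.

    An exact grid match is used when present; otherwise the nearest column.
    The returned :class:`MeltSignal` records the wavelength actually used.
    """
    wmin = float(np.min(series.wavelengths))
    wmax = float(np.max(series.wavelengths))
    if not (wmin <= wavelength <= wmax):
        raise ValueError(
            f"wavelength {wavelength:g} nm outside measured range [{wmin:g}, {wmax:g}]"
        )
    j = int(np.argmin(np.abs(series.wavelengths - wavelength)))
    return MeltSignal(
        temperatures=series.temperatures.copy(),
        y=series.signal[:, j].copy(),
        wavelength=float(series.wavelengths[j]),
        meta=series.meta,
    )


# ---------------------------------------------------------------------------
# Reporting


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def input_digest(data: np.ndarray | bytes) -> str:
    """SHA-256 digest of the numeric payload, for provenance tracking."""
    if isinstance(data, np.ndarray):
        data = np.ascontiguousarray(data).tobytes()
    return hashlib.sha256(data).hexdigest()


def write_results(seg, thermo, path: str | Path, *, label: str = "sample",
                  config: dict | None = None, seed: int | None = None,
                  digest: str | None = None) -> tuple[Path, Path]:
    """Write a JSON report plus a flat TSV table for a segmentation + thermo run.

    The TSV mirrors the published table layout (one row per sample, columns
    ``T_m1..T_m3``, ``T_onset``, ``T_I1``, ``T_I2``, per-region dH/dS and the
    totals); transitions absent from the data are emitted as empty cells, the
    tabular equivalent of an em-dash.  Returns ``(json_path, tsv_path)``.
    """
    from . import __version__

    if seg is None or not getattr(seg, "sigmoids", None):
        raise ValidationError("empty segmentation result; nothing to report")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    report = {
        "software": {"name": "cdmelt", "version": __version__},
        "label": label,
        "seed": seed,
        "input_digest": digest,
        "config": config or {},
        "conventions": {
            "onset": "tangent construction (analysis convention, not instrument-defined)",
            "thermo_regression_axis": "Celsius",
            "dG_total_reference": "last sigmoid-intersection temperature",
        },
        "segmentation": dataclasses.asdict(seg),
        "thermodynamics": dataclasses.asdict(thermo) if thermo is not None else None,
    }
    json_path = path / f"{label}.report.json"
    tsv_path = path / f"{label}.tables.tsv"

    tm = list(seg.T_m) + [None] * (3 - len(seg.T_m))
    ti = list(seg.T_I) + [None] * (2 - len(seg.T_I))
    row: dict[str, object] = {"label": label}
    for k, v in zip(("T_m1", "T_m2", "T_m3"), tm):
        row[k] = v
    row["T_onset"] = seg.T_onset
    for k, v in zip(("T_I1", "T_I2"), ti):
        row[k] = v
    regions = list(getattr(thermo, "regions", []) or []) if thermo is not None else []
    for i in range(3):
        r = regions[i] if i < len(regions) else None
        row[f"dH_m{i + 1}_kJ_mol"] = None if r is None else r.dH_paper
        row[f"dS_m{i + 1}_J_K_mol"] = None if r is None else r.dS
    if thermo is not None:
        row["dH_total_kJ_mol"] = thermo.dH_total
        row["dS_total_J_K_mol"] = thermo.dS_total
        row["dG_total_kJ_mol"] = thermo.dG_total
        row["T_ref_C"] = thermo.T_ref

    json_path.write_text(
        json.dumps(report, indent=2, default=_json_default) + "\n", encoding="utf-8"
    )
    with tsv_path.open("w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(row.keys())
        w.writerow("" if v is None else repr(float(v)) if isinstance(v, float) else v
                   for v in row.values())
    return json_path, tsv_path


def write_melt_csv(series: CDSpectrumSeries, path: str | Path) -> Path:
    """Write a :class:`CDSpectrumSeries` in the canonical matrix CSV layout."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["temperature_C"] + [f"{wl:g}" for wl in series.wavelengths])
        for t, row in zip(series.temperatures, series.signal):
            w.writerow([repr(float(t))] + [repr(float(v)) for v in row])
    return path


def write_signal_csv(signal: MeltSignal, path: str | Path) -> Path:
    """Write a :class:`MeltSignal` as ``temperature_C, signal``."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["temperature_C", "signal"])
        for t, v in zip(signal.temperatures, signal.y):
            w.writerow([repr(float(t)), repr(float(v))])
    return path
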