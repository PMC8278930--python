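"""Spectral data treatment for variable-temperature CD series.

The treatment chain, in the order the instrument data is normally handled, is

1. subtraction of the averaged matrix-only background spectrum,
2. zeroing against the optically silent 250-260 nm region,
3. Savitzky-Golay smoothing along the wavelength axis (7 points, order 5),
4. conversion from millidegrees to mean residue ellipticity (MRE).

Every step returns a new :class:`~cdmelt.io.CDSpectrumSeries`; nothing is
modified in place.  Downstream relative-fraction quantities are invariant to
any fixed linear rescaling of the signal, so the MRE convention adopted here
(mean residue weight MRW = MW/(n_residues - 1)) affects plots, not the
extracted thermodynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .io import MDEG, MRE, CDSpectrumSeries, SampleMeta, ValidationError

__all__ = [
    "PreprocessConfig",
    "subtract_background",
    "zero_high_wavelength",
    "savitzky_golay_smooth",
    "to_mre",
    "run_pipeline",
]


@dataclass
class PreprocessConfig:
    """Configuration of the spectral treatment chain.

    zero_window : (low, high) wavelength interval in nm averaged to define the
        per-temperature zero offset; default (250, 260).
    sg_window : odd number of points of the Savitzky-Golay filter; default 7.
    sg_order : polynomial order of the filter; default 5.
    """

    zero_window: tuple[float, float] = (250.0, 260.0)
    sg_window: int = 7
    sg_order: int = 5
    smooth_temperature_axis: bool = False

    def __post_init__(self) -> None:
        if self.sg_window % 2 == 0:
            raise ValidationError("sg_window must be odd")
        if self.sg_window < self.sg_order + 1:
            raise ValidationError("sg_window must be >= sg_order + 1")
        if self.zero_window[0] >= self.zero_window[1]:
            raise ValidationError("zero_window must be a non-degenerate interval")


def subtract_background(series: CDSpectrumSeries,
                        background: np.ndarray | CDSpectrumSeries) -> CDSpectrumSeries:
    """Subtract an averaged matrix-only background spectrum from every slice.

    ``background`` is either a 1-D spectrum on the series' wavelength grid or a
    :class:`CDSpectrumSeries` of replicate background scans, which are averaged
    over their temperature axis first.
    """
    if isinstance(background, CDSpectrumSeries):
        if (background.wavelengths.size != series.wavelengths.size
                or not np.allclose(background.wavelengths, series.wavelengths)):
            raise ValidationError("background wavelength grid does not match series")
        bg = background.signal.mean(axis=0)
    else:
        bg = np.asarray(background, dtype=float)
        if bg.shape != (series.wavelengths.size,):
            raise ValidationError(
                f"background length {bg.shape} does not match wavelength grid "
                f"({series.wavelengths.size},)"
            )
    return series.copy_with(signal=series.signal - bg[None, :])


def zero_high_wavelength(series: CDSpectrumSeries,
                         window: tuple[float, float] = (250.0, 260.0)) -> CDSpectrumSeries:
    """Zero each temperature slice on its mean over the ``window`` interval.

    After the call the per-temperature mean over the window is zero to machine
    precision; the operation is idempotent.
    """
    lo, hi = min(window), max(window)
    mask = (series.wavelengths >= lo) & (series.wavelengths <= hi)
    if mask.sum() < 2:
        raise ValidationError(
            f"zero window [{lo:g}, {hi:g}] nm contains {int(mask.sum())} grid points; need >= 2"
        )
    offsets = series.signal[:, mask].mean(axis=1, keepdims=True)
    return series.copy_with(signal=series.signal - offsets)


def savitzky_golay_smooth(series: CDSpectrumSeries, window: int = 7,
                          order: int = 5) -> CDSpectrumSeries:
    """Savitzky-Golay filter each spectrum along the wavelength axis.

    Edges are handled by fitting the order-``order`` polynomial to the
    truncated edge window and evaluating it there (no padding outside the
    measured range); polynomials of degree <= ``order`` pass through unchanged.
    """
    if window % 2 == 0 or window < order + 1:
        raise ValidationError("window must be odd and >= order + 1")
    if window > series.wavelengths.size:
        raise ValidationError(
            f"window ({window}) exceeds number of wavelength points "
            f"({series.wavelengths.size})"
        )
    smoothed = savgol_filter(series.signal, window, order, axis=1, mode="interp")
    return series.copy_with(signal=smoothed)


def to_mre(series: CDSpectrumSeries, meta: SampleMeta | None = None) -> CDSpectrumSeries:
    """Convert millidegrees to mean residue ellipticity (deg cm^2 dmol^-1).

    MRE = theta_mdeg * MRW / (10 * pathlength_cm * conc_mg_per_mL), with
    MRW = molecular_weight / (n_residues - 1).
    """
    if series.units == MRE:
        raise ValidationError("series is already in MRE; refusing double conversion")
    meta = meta or series.meta
    if meta is None:
        raise ValidationError("sample metadata required for MRE conversion")
    factor = meta.mean_residue_weight / (10.0 * meta.pathlength * meta.protein_conc)
    return series.copy_with(signal=series.signal * factor, units=MRE, meta=meta)


def run_pipeline(series: CDSpectrumSeries, config: PreprocessConfig | None = None,
                 background: np.ndarray | CDSpectrumSeries | None = None,
                 meta: SampleMeta | None = None) -> CDSpectrumSeries:
    """Apply the full treatment chain in its fixed order.

    background subtraction (if given) -> high-wavelength zeroing -> smoothing
    -> MRE conversion (if the series is in millidegrees and metadata is
    available).  Deterministic: re-running with the same inputs is
    bit-reproducible.
    """
    config = config or PreprocessConfig()
    out = series
    if background is not None:
        out = subtract_background(out, background)
    out = zero_high_wavelength(out, config.zero_window)
    out = savitzky_golay_smooth(out, config.sg_window, config.sg_order)
    if config.smooth_temperature_axis and out.temperatures.size >= config.sg_window:
        out = out.copy_with(signal=savgol_filter(
            out.signal, config.sg_window, min(config.sg_order, config.sg_window - 1),
            axis=0, mode="interp"))
    if out.units == MDEG and (meta or out.meta) is not None:
        out = to_mre(out, meta or out.meta)
    return out
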