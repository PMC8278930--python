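import numpy as np
import pytest

from cdmelt import (CDSpectrumSeries, PreprocessConfig, savitzky_golay_smooth,
                    subtract_background, to_mre, zero_high_wavelength)
from cdmelt.io import MRE, ValidationError
from cdmelt.preprocess import run_pipeline


def series_from(signal, wl, temps=None, units="millidegrees", meta=None):
    temps = np.arange(25.0, 25.0 + signal.shape[0]) if temps is None else temps
    return CDSpectrumSeries(temperatures=temps, wavelengths=wl,
                            signal=np.asarray(signal, float), units=units,
                            meta=meta)


class TestBackground:
    def test_own_first_row_zeroes_it(self, wl_grid):
        rng = np.random.default_rng(0)
        sig = rng.normal(size=(3, wl_grid.size))
        s = series_from(sig, wl_grid)
        out = subtract_background(s, sig[0])
        np.testing.assert_allclose(out.signal[0], 0.0, atol=1e-15)

    def test_zero_background_is_identity(self, wl_grid):
        s = series_from(np.ones((2, wl_grid.size)), wl_grid)
        out = subtract_background(s, np.zeros(wl_grid.size))
        np.testing.assert_array_equal(out.signal, s.signal)

    def test_grid_mismatch_rejected(self, wl_grid):
        s = series_from(np.ones((2, wl_grid.size)), wl_grid)
        bg = series_from(np.ones((1, 36)), np.arange(190.0, 261.0, 2.0))
        with pytest.raises(ValidationError, match="grid"):
            subtract_background(s, bg)

    def test_replicates_averaged(self, wl_grid):
        s = series_from(np.full((2, wl_grid.size), 5.0), wl_grid)
        reps = series_from(np.stack([np.ones(wl_grid.size),
                                     3 * np.ones(wl_grid.size)]), wl_grid)
        out = subtract_background(s, reps)  # mean background = 2
        np.testing.assert_allclose(out.signal, 3.0)


class TestZeroing:
    def test_constant_spectrum_becomes_zero(self, wl_grid):
        s = series_from(np.full((2, wl_grid.size), 3.0), wl_grid)
        out = zero_high_wavelength(s)
        np.testing.assert_allclose(out.signal, 0.0, atol=1e-15)

    def test_already_zero_mean_unchanged(self, wl_grid):
        sig = np.zeros((1, wl_grid.size))
        sig[0, wl_grid < 250] = -4.0
        s = series_from(sig, wl_grid)
        out = zero_high_wavelength(s)
        np.testing.assert_allclose(out.signal, sig, atol=1e-15)

    def test_per_temperature_offsets_removed_independently(self):
        # 4-point toy spectrum, window covers the last two points
        wl = np.array([218.0, 230.0, 252.0, 258.0])
        sig = np.array([[5.0, 2.0, 1.0, 1.0],     # offset +1 in window
                        [3.0, 0.0, -1.0, -1.0]])  # offset -1 in window
        out = zero_high_wavelength(series_from(sig, wl), (250.0, 260.0))
        np.testing.assert_allclose(out.signal,
                                   [[4.0, 1.0, 0.0, 0.0],
                                    [4.0, 1.0, 0.0, 0.0]])

    def test_window_mean_zero_postcondition(self, wl_grid):
        rng = np.random.default_rng(1)
        s = series_from(rng.normal(size=(3, wl_grid.size)), wl_grid)
        out = zero_high_wavelength(s)
        w = (wl_grid >= 250) & (wl_grid <= 260)
        np.testing.assert_allclose(out.signal[:, w].mean(axis=1), 0.0,
                                   atol=1e-14)

    def test_idempotent(self, wl_grid):
        rng = np.random.default_rng(2)
        s = series_from(rng.normal(size=(2, wl_grid.size)), wl_grid)
        once = zero_high_wavelength(s)
        twice = zero_high_wavelength(once)
        np.testing.assert_allclose(once.signal, twice.signal, atol=1e-14)

    def test_empty_window_rejected(self, wl_grid):
        s = series_from(np.ones((1, wl_grid.size)), wl_grid)
        with pytest.raises(ValidationError):
            zero_high_wavelength(s, (300.0, 310.0))


class TestSavitzkyGolay:
    def test_degree5_polynomial_reproduced_exactly(self, wl_grid):
        coef = [1e-8, -2e-6, 3e-5, -0.01, 0.5, -3.0]
        sig = np.polyval(coef, wl_grid - 225.0)[None, :]
        s = series_from(sig, wl_grid)
        out = savitzky_golay_smooth(s, 7, 5)
        np.testing.assert_allclose(out.signal, sig, rtol=1e-9, atol=1e-9)

    def test_constant_unchanged(self, wl_grid):
        s = series_from(np.full((2, wl_grid.size), -7.0), wl_grid)
        out = savitzky_golay_smooth(s)
        np.testing.assert_allclose(out.signal, -7.0)

    def test_interior_spike_matches_lsq_oracle(self, wl_grid):
        # brute-force oracle: LSQ fit of an order-5 polynomial on the
        # 7-point window centred at the spike, evaluated at the centre
        h = 10.0
        j = 30
        sig = np.zeros((1, wl_grid.size))
        sig[0, j] = h
        out = savitzky_golay_smooth(series_from(sig, wl_grid), 7, 5)
        x = np.arange(-3, 4, dtype=float)
        y = np.zeros(7)
        y[3] = h
        centre = np.polyval(np.polyfit(x, y, 5), 0.0)
        assert out.signal[0, j] == pytest.approx(centre, rel=1e-10)

    def test_window_larger_than_grid_rejected(self):
        wl = np.arange(215.0, 220.0)
        s = series_from(np.ones((1, 5)), wl)
        with pytest.raises(ValidationError):
            savitzky_golay_smooth(s, 7, 5)


class TestMre:
    def test_hand_computed_value(self, wl_grid):
        from cdmelt import SampleMeta
        meta = SampleMeta(protein_conc=100.0, pathlength=0.01,
                          molecular_weight=110000.0, n_residues=1001)
        s = series_from(np.full((1, wl_grid.size), -10.0), wl_grid, meta=meta)
        out = to_mre(s)
        # -10 mdeg * (110000/1000) / (10 * 0.01 * 100) = -110
        np.testing.assert_allclose(out.signal, -110.0)
        assert out.units == MRE

    def test_doubling_concentration_halves_mre(self, wl_grid, meta):
        import dataclasses
        s = series_from(np.full((1, wl_grid.size), -10.0), wl_grid, meta=meta)
        double = dataclasses.replace(meta, protein_conc=2 * meta.protein_conc)
        a = to_mre(s, meta)
        b = to_mre(s, double)
        np.testing.assert_allclose(b.signal, a.signal / 2)

    def test_zero_theta_zero_mre(self, wl_grid, meta):
        s = series_from(np.zeros((1, wl_grid.size)), wl_grid, meta=meta)
        np.testing.assert_array_equal(to_mre(s).signal, 0.0)

    def test_double_conversion_rejected(self, wl_grid, meta):
        s = series_from(np.ones((1, wl_grid.size)), wl_grid, units=MRE,
                        meta=meta)
        with pytest.raises(ValidationError, match="already"):
            to_mre(s)

    def test_linearity(self, wl_grid, meta):
        rng = np.random.default_rng(3)
        sig = rng.normal(size=(2, wl_grid.size))
        a = to_mre(series_from(sig, wl_grid, meta=meta))
        b = to_mre(series_from(3.0 * sig + 0.0, wl_grid, meta=meta))
        np.testing.assert_allclose(b.signal, 3.0 * a.signal, rtol=1e-12)


class TestPipeline:
    def test_bit_reproducible(self, wl_grid, meta):
        rng = np.random.default_rng(4)
        sig = rng.normal(size=(5, wl_grid.size))
        s = series_from(sig, wl_grid, meta=meta)
        cfg = PreprocessConfig()
        a = run_pipeline(s, cfg)
        b = run_pipeline(s, cfg)
        assert a.signal.tobytes() == b.signal.tobytes()
        assert a.units == MRE

    def test_config_invariants(self):
        with pytest.raises(ValidationError):
            PreprocessConfig(sg_window=6)
        with pytest.raises(ValidationError):
            PreprocessConfig(sg_window=5, sg_order=5)
        with pytest.raises(ValidationError):
            PreprocessConfig(zero_window=(260.0, 250.0))
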