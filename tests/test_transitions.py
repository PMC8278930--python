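import numpy as np
import pytest

from cdmelt import (BetaFractionCurve, detect_plateaus, fit_shape_models,
                    fit_sigmoid_chain, intersection_temperature,
                    onset_temperature, segment_curve)
from cdmelt.transitions import (BoltzmannSigmoid, LinearPlateau,
                                SegmentationError, boltzmann, rmse)


def curve(T, f):
    return BetaFractionCurve(np.asarray(T, float), np.asarray(f, float),
                             mode="two_state")


def make_sigmoid(A1, A2, T0, dT, rng=(25.0, 97.0)):
    return BoltzmannSigmoid(A1=A1, A2=A2, T0=T0, dT=dT, fit_T_range=rng,
                            rmse=0.0)


class TestDetectPlateaus:
    def test_flat_rise_flat_gives_two_plateaus(self):
        T = np.arange(25.0, 98.0)
        f = np.clip((T - 55.0) / 10.0, 0.0, 1.0)
        ps = detect_plateaus(curve(T, f))
        assert len(ps) == 2
        assert ps[0].T_range[0] == 25.0 and ps[-1].T_range[1] == 97.0
        assert abs(ps[0].slope) < 1e-12

    def test_single_sigmoid_yields_both_tails(self):
        T = np.arange(25.0, 98.0)
        f = boltzmann(T, 0.0, 1.0, 60.0, 3.0)
        ps = detect_plateaus(curve(T, f))
        assert len(ps) == 2
        assert ps[0].T_range[1] < 55.0 < 65.0 < ps[1].T_range[0]

    def test_straight_line_single_plateau(self):
        T = np.arange(25.0, 98.0)
        ps = detect_plateaus(curve(T, 0.1 + 0.003 * T))
        assert len(ps) == 1
        assert ps[0].n_points == T.size

    def test_too_few_points_rejected(self):
        with pytest.raises(SegmentationError):
            detect_plateaus(curve(np.arange(5.0), np.zeros(5)))


class TestSigmoidChain:
    def test_parameter_recovery_with_noise(self):
        T = np.arange(25.0, 98.0)
        f_true = boltzmann(T, 0.0, 1.0, 77.0, 1.5)
        rng = np.random.default_rng(42)
        f = f_true + rng.normal(0, 0.005, T.size)
        c = curve(T, f)
        sigs = fit_sigmoid_chain(c, detect_plateaus(c))
        assert len(sigs) == 1
        assert sigs[0].T0 == pytest.approx(77.0, abs=0.1)

    def test_midpoint_value_is_mean_of_asymptotes(self):
        s = make_sigmoid(0.2, 0.8, 60.0, 2.0)
        assert s(60.0) == pytest.approx(0.5)

    def test_three_transition_ordering(self):
        import warnings
        from cdmelt import preset, generate_cd_signal, MeltThermogramAnalyzer
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            an = MeltThermogramAnalyzer().fit(
                generate_cd_signal(preset("f1il-like", seed=5, noise_sd=0.01)))
        T0s = [s.T0 for s in an.segmentation_.sigmoids]
        assert len(T0s) == 3
        assert T0s == sorted(T0s)
        for got, want in zip(T0s, (52.4, 67.5, 86.8)):
            assert got == pytest.approx(want, abs=0.6)


class TestShapeModels:
    def test_symmetric_gaussian_breaks_tie_toward_fewer_params(self):
        T = np.arange(25.0, 98.0)
        f = 0.1 + 0.8 * np.exp(-((T - 60.0) ** 2) / (2 * 12.0 ** 2))
        m = fit_shape_models(curve(T, f))
        assert m.kind == "gaussian"
        assert m.rmse < 1e-8

    def test_asymmetric_data_selects_bigaussian(self):
        T = np.arange(25.0, 98.0)
        s = np.where(T <= 60.0, 5.0, 15.0)
        f = 0.1 + 0.8 * np.exp(-((T - 60.0) ** 2) / (2 * s ** 2))
        rng = np.random.default_rng(7)
        m = fit_shape_models(curve(T, f + rng.normal(0, 0.003, T.size)))
        assert m.kind == "bigaussian"
        assert m.all_rmse["bigaussian"] < m.all_rmse["gaussian"]

    def test_rmse_is_sqrt_rss_over_n(self):
        T = np.arange(25.0, 98.0)
        f = 0.1 + 0.8 * np.exp(-((T - 60.0) ** 2) / (2 * 10.0 ** 2))
        rng = np.random.default_rng(3)
        fn = f + rng.normal(0, 0.01, T.size)
        m = fit_shape_models(curve(T, fn))
        resid = fn - m(T)
        assert m.rmse == pytest.approx(np.sqrt(np.sum(resid ** 2) / T.size),
                                       rel=1e-9)


class TestIntersection:
    def test_mirror_symmetry_crosses_at_axis(self):
        s1 = make_sigmoid(0.0, 1.0, 65.0, 3.0)
        s2 = make_sigmoid(1.0, 0.0, 75.0, 3.0)  # mirror about T = 70
        assert intersection_temperature(s1, s2) == pytest.approx(70.0,
                                                                 abs=1e-8)

    def test_matches_high_precision_numeric_oracle(self):
        s1 = make_sigmoid(0.0, 0.9, 55.0, 2.5)
        s2 = make_sigmoid(1.2, 0.1, 75.0, 4.0)
        got = intersection_temperature(s1, s2)
        # oracle: dense scan + bisection at float precision
        from scipy.optimize import brentq
        oracle = brentq(lambda t: s1(t) - s2(t), 55.0, 75.0, xtol=1e-12)
        assert got == pytest.approx(oracle, abs=1e-8)

    def test_identical_sigmoids_rejected(self):
        s1 = make_sigmoid(0.0, 1.0, 60.0, 3.0)
        s2 = make_sigmoid(0.0, 1.0, 70.0, 3.0)
        # parallel-shifted identical shapes never cross and have no interior
        # closest approach
        with pytest.raises((SegmentationError, ValueError)):
            intersection_temperature(s1, make_sigmoid(0.0, 1.0, 60.0, 3.0))

    def test_chained_same_direction_uses_closest_approach(self):
        # two rising sigmoids sharing the 0.45 plateau level touch
        # asymptotically; the separator must lie between the midpoints
        s1 = make_sigmoid(0.0, 0.45, 52.4, 3.0)
        s2 = make_sigmoid(0.45, 1.0, 67.5, 1.3)
        ti = intersection_temperature(s1, s2)
        assert 52.4 < ti < 67.5


class TestOnset:
    def test_tangent_construction_closed_form(self):
        # flat plateau at 0 and Boltzmann(A1=0, A2=1, T0, dT):
        # tangent slope (A2-A1)/(4 dT) -> T_onset = T0 - 2 dT
        T0, dT = 70.0, 2.5
        s = make_sigmoid(0.0, 1.0, T0, dT)
        plateau = LinearPlateau((25.0, 50.0), 0.0, 0.0, 1.0, 26)
        T = np.arange(25.0, 98.0)
        c = curve(T, s(T))
        assert onset_temperature(c, s, plateau) == pytest.approx(T0 - 2 * dT)

    def test_parallel_tangent_rejected(self):
        s = make_sigmoid(0.0, 1.0, 70.0, 2.5)
        plateau = LinearPlateau((25.0, 50.0), s.midpoint_slope, 0.0, 1.0, 26)
        T = np.arange(25.0, 98.0)
        with pytest.raises(SegmentationError, match="parallel"):
            onset_temperature(curve(T, s(T)), s, plateau)

    def test_threshold_mode_interpolates(self):
        s = make_sigmoid(0.0, 1.0, 70.0, 2.5)
        plateau = LinearPlateau((25.0, 50.0), 0.0, 0.0, 1.0, 26)
        T = np.arange(25.0, 98.0)
        c = curve(T, s(T))
        t = onset_temperature(c, s, plateau, mode="threshold", threshold=0.05)
        # f crosses 0.05 at T0 - dT*ln(19) = 62.64
        assert t == pytest.approx(70.0 - 2.5 * np.log(19.0), abs=0.5)


class TestSegmentationInvariants:
    def test_noiseless_midpoints_and_interleaving(self):
        import warnings
        from cdmelt import preset, generate_cd_signal, MeltThermogramAnalyzer
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            an = MeltThermogramAnalyzer().fit(
                generate_cd_signal(preset("f1il-like", noise_sd=0.0)))
        for got, want in zip(an.T_m_, (52.4, 67.5, 86.8)):
            assert got == pytest.approx(want, abs=0.05)
        assert an.T_m_[0] < an.T_I_[0] < an.T_m_[1] < an.T_I_[1] < an.T_m_[2]

    def test_temperature_mirrored_curve_gives_mirrored_midpoints(self):
        T = np.arange(25.0, 98.0)
        f = boltzmann(T, 0.0, 1.0, 60.0, 3.0)
        seg = segment_curve(curve(T, f))
        seg_m = segment_curve(curve(T, f[::-1].copy()))
        # mirroring about the grid centre maps T0 -> Tmin + Tmax - T0
        assert seg_m.T_m[0] == pytest.approx(25.0 + 97.0 - seg.T_m[0],
                                             abs=0.2)

    def test_rmse_helper_matches_definition(self):
        r = np.array([1.0, -2.0, 2.0])
        assert rmse(r) == pytest.approx(np.sqrt(9.0 / 3.0))
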