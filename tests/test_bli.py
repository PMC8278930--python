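import numpy as np
import pytest
from scipy.integrate import solve_ivp

from cdmelt import (Kinetics1to1, Kinetics1to2, compute_KD, fit_sensorgram,
                    mass_to_molar, simulate_1to1, simulate_1to2)
from cdmelt.synthetic import generate_sensorgram

DUR = {"baseline": 60.0, "association": 120.0, "dissociation": 120.0}
C_IGG = mass_to_molar(0.96, 146000.0)


@pytest.fixture
def p11():
    return Kinetics1to1(kon=1e5, koff=1e-3, Rmax=1.0)


@pytest.fixture
def p12():
    return Kinetics1to2(kon1=2e5, koff1=5e-4, Rmax1=0.8,
                        kon2=1e4, koff2=5e-3, Rmax2=0.4)


class TestUnitConversions:
    def test_igg_loading_concentration(self):
        assert C_IGG == pytest.approx(6.58e-6, rel=1e-3)

    def test_simple_molar(self):
        assert mass_to_molar(1.0, 1000.0) == pytest.approx(1e-3)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            mass_to_molar(1.0, 0.0)

    @pytest.mark.parametrize("kon,koff,KD", [
        (1e5, 1e-3, 1e-8), (3.3e4, 6.6e-4, 2e-8),
    ])
    def test_KD(self, kon, koff, KD):
        assert compute_KD(kon, koff) == pytest.approx(KD)

    def test_KD_scales_with_koff(self):
        assert compute_KD(1e5, 2e-3) == pytest.approx(2 * compute_KD(1e5, 1e-3))


class TestSimulate1to1:
    def test_zero_concentration_flat(self, p11):
        sg = simulate_1to1(p11, 0.0, DUR)
        np.testing.assert_array_equal(sg.R, 0.0)

    def test_saturation_limit(self, p11):
        # C >> KD and long association: R -> Rmax
        sg = simulate_1to1(p11, 1e-3, {"association": 5000.0})
        assert sg.R.max() == pytest.approx(p11.Rmax, rel=1e-3)

    def test_closed_form_matches_ode_oracle(self, p11):
        sg = simulate_1to1(p11, C_IGG, DUR)

        def rhs(t, R, conc):
            return p11.kon * conc * (p11.Rmax - R) - p11.koff * R

        ta, Ra = sg.segment("association")
        sol = solve_ivp(rhs, (ta[0], ta[-1]), [0.0], t_eval=ta, args=(C_IGG,),
                        rtol=1e-12, atol=1e-14)
        assert np.max(np.abs(sol.y[0] - Ra)) < 1e-8
        td, Rd = sg.segment("dissociation")
        sol = solve_ivp(rhs, (td[0], td[-1]), [Ra[-1]], t_eval=td, args=(0.0,),
                        rtol=1e-12, atol=1e-14)
        assert np.max(np.abs(sol.y[0] - Rd)) < 1e-8

    def test_continuity_nonnegativity_monotone_dissociation(self, p11):
        dt = 0.1
        sg = simulate_1to1(p11, C_IGG, DUR, dt=dt)
        assert np.all(sg.R >= 0)
        # no discontinuities: per-step change bounded by the fastest
        # physical rate of change of the association phase
        kobs = p11.kon * C_IGG + p11.koff
        assert np.max(np.abs(np.diff(sg.R))) <= \
            p11.Rmax * (1 - np.exp(-kobs * dt)) * (1 + 1e-9)
        _, Rd = sg.segment("dissociation")
        assert np.all(np.diff(Rd) <= 1e-15)


class TestSimulate1to2:
    def test_reduces_to_1to1_in_both_forms(self, p11):
        for form in ("parallel_sites", "sequential_bivalent"):
            p = Kinetics1to2(kon1=p11.kon, koff1=p11.koff, Rmax1=p11.Rmax,
                             kon2=1e-12, koff2=1.0, Rmax2=0.0,
                             model_form=form)
            ref = simulate_1to1(p11, C_IGG, DUR)
            got = simulate_1to2(p, C_IGG, DUR)
            np.testing.assert_allclose(got.R, ref.R, atol=5e-7)

    def test_parallel_is_superposition(self, p12):
        got = simulate_1to2(p12, C_IGG, DUR)
        a = simulate_1to1(Kinetics1to1(p12.kon1, p12.koff1, p12.Rmax1),
                          C_IGG, DUR)
        b = simulate_1to1(Kinetics1to1(p12.kon2, p12.koff2, p12.Rmax2),
                          C_IGG, DUR)
        np.testing.assert_allclose(got.R, a.R + b.R, atol=1e-12)

    def test_sequential_mass_balance(self, p12):
        p = Kinetics1to2(**{**p12.__dict__, "model_form": "sequential_bivalent"})
        sg = simulate_1to2(p, C_IGG, DUR)
        s = sg.states
        balance = s["L"] + s["AL"] + 2 * s["AL2"]
        assert np.max(np.abs(balance - s["Ltot"])) < 1e-9

    def test_sequential_dissociation_non_increasing(self, p12):
        p = Kinetics1to2(**{**p12.__dict__, "model_form": "sequential_bivalent"})
        sg = simulate_1to2(p, C_IGG, DUR)
        _, Rd = sg.segment("dissociation")
        assert np.all(np.diff(Rd) <= 1e-12)


class TestFitSensorgram:
    def test_noiseless_parallel_recovery_within_1pct(self, p12):
        sg = simulate_1to2(p12, C_IGG, DUR)
        fit = fit_sensorgram(sg, "one_to_two")
        assert fit.converged
        k = fit.params
        for got, want in [(k.kon1, p12.kon1), (k.koff1, p12.koff1),
                          (k.Rmax1, p12.Rmax1), (k.kon2, p12.kon2),
                          (k.koff2, p12.koff2), (k.Rmax2, p12.Rmax2)]:
            assert got == pytest.approx(want, rel=0.01)
        assert fit.KD == pytest.approx(p12.koff1 / p12.kon1, rel=0.01)

    def test_1to1_fit_of_biphasic_trace_has_larger_rmse(self, p12):
        sg = simulate_1to2(p12, C_IGG, DUR)
        f2 = fit_sensorgram(sg, "one_to_two")
        f1 = fit_sensorgram(sg, "one_to_one")
        assert f1.rmse > f2.rmse

    def test_zero_concentration_simulation_has_phases_but_no_signal(self):
        sg = simulate_1to1(Kinetics1to1(1e5, 1e-3, 1.0), 0.0, DUR)
        assert "association" in sg.phases
        with pytest.raises(ValueError, match="concentration"):
            fit_sensorgram(sg, "one_to_one")

    def test_flat_trace_rejected(self):
        from cdmelt.bli import Sensorgram
        t = np.arange(0.0, 240.0, 0.5)
        sg = Sensorgram(t=t, R=np.zeros_like(t),
                        phases={"association": (0.0, 120.0),
                                "dissociation": (120.0, 240.0)}, C=C_IGG)
        with pytest.raises(ValueError, match="flat|signal"):
            fit_sensorgram(sg, "one_to_one")

    def test_missing_dissociation_rejected(self, p11):
        sg = simulate_1to1(p11, C_IGG, {"association": 120.0})
        with pytest.raises(ValueError, match="dissociation"):
            fit_sensorgram(sg)

    def test_noisy_recovery_within_10pct(self):
        # kinetics chosen so both dissociation rates are identifiable within
        # the 2-minute phases (slower first-phase koff values make the
        # bi-exponential separation ill-posed regardless of the fitter)
        p = Kinetics1to2(kon1=2e5, koff1=2e-3, Rmax1=0.8,
                         kon2=1e4, koff2=2e-2, Rmax2=0.4)
        hits = 0
        for seed in range(10):
            sg = generate_sensorgram(p, C_IGG, DUR,
                                     noise_sd=0.005 * 1.2, seed=seed)
            fit = fit_sensorgram(sg, "one_to_two")
            k = fit.params
            if (abs(k.kon1 - p.kon1) / p.kon1 < 0.1
                    and abs(k.koff1 - p.koff1) / p.koff1 < 0.1):
                hits += 1
        assert hits >= 9

    def test_rmse_definition(self, p12):
        sg = generate_sensorgram(p12, C_IGG, DUR, noise_sd=0.003, seed=1)
        fit = fit_sensorgram(sg, "one_to_two")
        n = sum(sg.segment(ph)[0].size for ph in ("association", "dissociation"))
        assert fit.rmse == pytest.approx(np.sqrt(fit.rss / n), rel=1e-9)


class TestValidation:
    def test_nonpositive_rates_rejected(self):
        with pytest.raises(ValueError):
            Kinetics1to1(kon=-1.0, koff=1e-3, Rmax=1.0)
        with pytest.raises(ValueError):
            Kinetics1to2(kon1=1e5, koff1=1e-3, Rmax1=1.0, kon2=1e4,
                         koff2=1e-3, Rmax2=0.5, model_form="bogus")
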