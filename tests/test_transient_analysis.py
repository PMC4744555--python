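"""Transient fit models: exponentials, binding, competition, lag phases."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dbp5kinetics as dk
from dbp5kinetics.transient_analysis import (
    binding_model, burst_lag_linear_model, competition_model,
    lag_hyperbola_model, lag_linear_model, multiexp_model)


class TestMultiExponential:
    def test_three_phase_recovery_noiseless(self):
        t = np.geomspace(1e-3, 400.0, 400)
        y = multiexp_model(t, 0.2, [1.0, 0.5, 0.3], [50.0, 2.0, 0.01])
        fit = dk.fit_multiexponential((t, y), 3)
        assert np.allclose(fit.rates, [50.0, 2.0, 0.01], rtol=0.01)
        assert np.allclose(fit.amplitudes, [1.0, 0.5, 0.3], rtol=0.01)
        assert fit.F0 == pytest.approx(0.2, abs=1e-3)

    def test_overfitting_two_phases_with_three_gives_null_third(self):
        t = np.geomspace(1e-3, 100.0, 300)
        y = multiexp_model(t, 0.0, [1.0, 0.4], [20.0, 0.1])
        fit = dk.fit_multiexponential((t, y), 3)
        main = sorted(np.abs(fit.amplitudes))[::-1]
        assert main[2] < 0.01 * main[0] or fit.n_phases_used < 3

    def test_constant_trace_yields_zero_amplitudes(self):
        t = np.linspace(0, 10, 50)
        fit = dk.fit_multiexponential((t, np.full_like(t, 3.3)), 2)
        assert np.all(fit.amplitudes == 0.0)
        assert fit.flag is not None

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            dk.fit_multiexponential((np.linspace(0, 1, 8),
                                     np.linspace(0, 1, 8)), 2)


class TestBindingNonPseudo:
    def test_pseudo_first_order_limit_is_sum_of_exponentials(self):
        t = np.linspace(0, 5, 100)
        y_bi = binding_model(t, 0.1, 1.0, 3.0, 0.0, [0.5], [0.2])
        y_exp = (0.1 + 1.0 * (1 - np.exp(-3.0 * t))
                 + 0.5 * (1 - np.exp(-0.2 * t)))
        assert np.allclose(y_bi, y_exp, rtol=1e-12)

    def test_round_trip_with_strong_deviation(self):
        t = np.geomspace(1e-3, 30.0, 500)
        y = binding_model(t, 0.05, 1.2, 4.0, 0.8, [0.3], [0.05])
        fit = dk.fit_binding_nonpseudo((t, y), n_extra_phases=1)
        assert fit.A0 == pytest.approx(1.2, rel=0.02)
        assert fit.k0_bi == pytest.approx(4.0, rel=0.02)
        assert fit.r == pytest.approx(0.8, abs=0.02)

    def test_equimolar_binding_is_not_pseudo_first_order(self):
        # analytic irreversible second-order progress at equal reactant
        # concentrations: [C](t) = a^2 k t / (1 + a k t)
        a, k = 0.5, 2.0  # uM, /uM/s
        t = np.geomspace(1e-2, 200.0, 400)
        y = a * a * k * t / (1 + a * k * t)
        fit = dk.fit_binding_nonpseudo((t, y), n_extra_phases=0)
        assert fit.r > 0.5
        assert fit.r > 5 * fit.se.get("r", np.inf) or fit.r > 0.5


class TestCompetition:
    def test_midpoint_identity(self):
        k = competition_model(np.array([6400.0]), k0=90.0, k_inf=10.0,
                              Kd=6400.0)
        assert k[0] == pytest.approx(50.0)

    @pytest.mark.parametrize("Kd", [6400.0, 360.0])
    def test_noiseless_recovery_of_reference_affinities(self, Kd):
        N = np.array([0.0, 100.0, 300.0, 1000.0, 2500.0, 5000.0, 11000.0])
        k = competition_model(N, k0=90.0, k_inf=8.0, Kd=Kd)
        fit = dk.fit_competition(N, k)
        assert fit.Kd == pytest.approx(Kd, rel=1e-6)
        assert fit.k0 == pytest.approx(90.0, rel=1e-8)
        assert fit.k_inf == pytest.approx(8.0, rel=1e-6)

    def test_requires_zero_competitor_point(self):
        with pytest.raises(ValueError):
            dk.fit_competition([10.0, 100.0, 1000.0, 5000.0],
                               [50.0, 40.0, 20.0, 10.0])

    def test_non_monotonic_data_flagged_not_rejected(self):
        N = np.array([0.0, 100.0, 300.0, 1000.0, 5000.0])
        k = np.array([90.0, 70.0, 80.0, 30.0, 10.0])
        fit = dk.fit_competition(N, k)
        assert fit.poor_fit


class TestLagLinear:
    def test_model_has_zero_initial_slope_and_beta_final_slope(self):
        eps = 1e-7
        s0 = (lag_linear_model(eps, 0.04, 2.0, 0.0)
              - lag_linear_model(0.0, 0.04, 2.0, 0.0)) / eps
        assert s0 == pytest.approx(0.0, abs=1e-6)
        t_late = np.array([1000.0, 1001.0])
        slope = np.diff(lag_linear_model(t_late, 0.04, 2.0, 0.0))[0]
        assert slope == pytest.approx(0.04, rel=1e-9)

    def test_noiseless_round_trip(self):
        t = np.linspace(0.05, 30, 300)
        y = lag_linear_model(t, 0.04, 2.0, 0.1)
        fit = dk.fit_lag_linear((t, y))
        assert fit.beta == pytest.approx(0.04, rel=1e-6)
        assert fit.lam == pytest.approx(2.0, rel=1e-6)
        assert fit.Pi0 == pytest.approx(0.1, abs=1e-6)
        assert not fit.lam_is_lower_bound

    def test_ode_trace_slope_matches_michaelis_menten(self, table1):
        t = np.linspace(0.1, 60, 300)
        tr = dk.simulate(dk.MixState(H=0.5, T=5000.0, PiBiP=50.0), table1,
                         t, "pibip_pi")
        fit = dk.fit_lag_linear(tr)
        kc = dk.kcat_closed_form(table1)
        km = dk.km_closed_form(table1)
        v = kc * 5000.0 / (5000.0 + km)
        assert fit.beta / 0.5 == pytest.approx(v, rel=0.10)

    def test_unresolved_lag_reported_as_lower_bound(self):
        t = np.linspace(0.5, 50, 100)  # 0.5 s sampling
        y = lag_linear_model(t, 0.04, 50.0, 0.0)  # lag over by 1st point
        fit = dk.fit_lag_linear((t, y))
        assert fit.lam_is_lower_bound


class TestLagHyperbola:
    def test_midpoint_identity(self):
        lam = lag_hyperbola_model(np.array([4000.0]), 2.0, 0.02, 4000.0)
        assert lam[0] == pytest.approx((2.0 + 0.02) / 2.0)

    def test_noiseless_recovery_atp_titration(self):
        conc = np.array([500.0, 1000.0, 2000.0, 5000.0, 10000.0, 20000.0])
        lam = lag_hyperbola_model(conc, 2.0, 0.02, 4000.0)
        fit = dk.fit_lag_hyperbola(np.column_stack([conc, lam]))
        assert fit.lam_inf == pytest.approx(2.0, rel=1e-6)
        assert fit.lam_0 == pytest.approx(0.02, rel=1e-4)
        assert fit.K_half == pytest.approx(4000.0, rel=1e-5)

    def test_noiseless_recovery_rna_titration(self):
        conc = np.array([450.0, 1250.0, 2000.0, 3000.0, 4500.0, 10000.0])
        lam = lag_hyperbola_model(conc, 5.5, 0.05, 3000.0)
        fit = dk.fit_lag_hyperbola(np.column_stack([conc, lam]))
        assert fit.lam_inf == pytest.approx(5.5, rel=1e-6)
        assert fit.K_half == pytest.approx(3000.0, rel=1e-5)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            dk.fit_lag_hyperbola([(100.0, 0.1), (1000.0, 0.5),
                                  (5000.0, 1.0)])


class TestDecomposeLag:
    def test_reference_decomposition(self):
        dec = dk.decompose_lag(2.0, 0.02, 0.01)
        assert dec.k_hyd == pytest.approx(1.98)
        assert dec.k_resyn == pytest.approx(0.0002)
        assert dec.k_rel_Pi == pytest.approx(0.0198)

    def test_zero_partition_puts_all_intercept_in_release(self):
        dec = dk.decompose_lag(2.0, 0.02, 0.0)
        assert dec.k_resyn == 0.0
        assert dec.k_rel_Pi == pytest.approx(0.02)

    @settings(max_examples=50, deadline=None)
    @given(lam_inf=st.floats(0.1, 100.0), frac=st.floats(1e-6, 0.99),
           Pc=st.floats(0.0, 0.99))
    def test_components_always_sum_to_lam_inf(self, lam_inf, frac, Pc):
        lam_0 = lam_inf * frac
        dec = dk.decompose_lag(lam_inf, lam_0, Pc)
        total = dec.k_hyd + dec.k_resyn + dec.k_rel_Pi
        assert total == pytest.approx(lam_inf, rel=1e-12)
        assert min(dec.k_hyd, dec.k_resyn, dec.k_rel_Pi) >= 0.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            dk.decompose_lag(2.0, 0.02, 1.0)
        with pytest.raises(ValueError):
            dk.decompose_lag(0.02, 2.0, 0.01)


class TestBurstLagLinear:
    def test_zero_burst_reduces_to_lag_linear(self):
        t = np.linspace(0.05, 30, 300)
        y = lag_linear_model(t, 0.04, 2.0, 0.0)
        burst = dk.fit_burst_lag_linear((t, y))
        plain = dk.fit_lag_linear((t, y))
        assert burst.beta == pytest.approx(plain.beta, rel=1e-3)
        assert burst.lam == pytest.approx(plain.lam, rel=1e-2)

    def test_synthetic_burst_round_trip(self):
        t = np.geomspace(1e-3, 30, 500)
        y = burst_lag_linear_model(t, 0.0, 1.0, 100.0, 0.0, 0.05, 2.0)
        fit = dk.fit_burst_lag_linear((t, y))
        assert fit.A0 == pytest.approx(1.0, rel=0.01)
        assert fit.k0_bi == pytest.approx(100.0, rel=0.05)
        assert fit.lam == pytest.approx(2.0, rel=0.01)
        assert fit.beta == pytest.approx(0.05, rel=0.01)

    def test_dual_mix_burst_amplitude_matches_aged_phosphate(self, table1):
        # explicit-sensor dual mix aged 25 s: the burst amplitude reports
        # the free phosphate accumulated during aging (independent
        # single-run oracle)
        t = np.geomspace(2e-4, 20.0, 500)
        dual = dk.simulate_dual_mix(
            dk.MixState(H=5.0, T=4000.0), 25.0,
            dk.MixState(PiBiP=5.0, pibip_explicit=True), table1, t,
            "pibip_pi")
        fit = dk.fit_burst_lag_linear(dual)
        full = dk.simulate(dk.MixState(H=5.0, T=4000.0), table1,
                           np.linspace(0.1, 25.0, 100), "species")
        aged_pi = full.species["Pi"].to_numpy()[-1] / 2.0
        assert fit.A0 == pytest.approx(aged_pi, rel=0.10)
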