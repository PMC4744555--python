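"""Closed-form steady-state theory, rate-curve fits and occupancies."""

import numpy as np
import pytest

import dbp5kinetics as dk

from conftest import ode_turnover


class TestClosedForms:
    def test_kcat_from_global_fit_constants(self, table2):
        # the four-state closed form with the global-fit constants gives
        # ~0.045 s^-1, printed as 0.04 to one significant figure
        kc = dk.kcat_closed_form(table2)
        assert kc == pytest.approx(0.0445, abs=0.0005)
        assert float(f"{kc:.1g}") == 0.04

    def test_km_from_global_fit_constants(self, table2):
        km = dk.km_closed_form(table2)  # uM
        assert km / 1000.0 == pytest.approx(1.12, abs=0.01)
        assert float(f"{km / 1000.0:.2g}") == 1.1

    def test_kcat_reduces_to_hydrolysis_when_release_steps_fast(self, table2):
        fast = table2.replace(k_rel_Pi=1e9, k_off_D=1e9)
        assert dk.kcat_closed_form(fast) == pytest.approx(table2.k_hyd,
                                                          rel=1e-6)

    def test_km_reduces_to_substrate_affinity_without_hydrolysis(self, table2):
        slow = table2.replace(k_hyd=0.0)
        assert dk.km_closed_form(slow) == pytest.approx(table2.K_T, rel=1e-9)

    def test_zero_denominator_raises(self):
        dead = dk.RateConstants(k_on_T=1.0, k_off_T=1.0, k_hyd=0.0,
                                k_resyn=0.0, k_rel_Pi=0.0, k_rebind_Pi=0.0,
                                k_off_D=0.0, k_rebind_D=0.0)
        with pytest.raises(ZeroDivisionError):
            dk.kcat_closed_form(dead)

    @pytest.mark.parametrize("i", range(8))
    def test_closed_forms_match_ode_flux(self, random_rates, i):
        # saturating flux and half-saturation against the independent
        # ODE oracle (catalytic enzyme, products regenerated)
        rates = random_rates(8, seed=7)[i]
        kc = dk.kcat_closed_form(rates)
        assert ode_turnover(rates, 1000.0) == pytest.approx(kc * 1000 / 1001,
                                                            rel=0.01)
        assert ode_turnover(rates, 1.0) == pytest.approx(kc / 2.0, rel=0.02)


class TestMichaelisFit:
    ATP_LADDER = np.array([250.0, 500.0, 1000.0, 2000.0, 8000.0, 20000.0])

    def test_noiseless_self_consistency(self):
        kcat, km = 0.043, 1700.0
        data = [dk.SteadyRateData(c, kcat * c / (c + km))
                for c in self.ATP_LADDER]
        fit = dk.fit_michaelis(data)
        assert fit.kcat == pytest.approx(kcat, rel=1e-6)
        assert fit.KM == pytest.approx(km, rel=1e-6)

    def test_noisy_recovery_within_three_se(self):
        rng = np.random.default_rng(3)
        kcat, km = 0.043, 1700.0
        v = kcat * self.ATP_LADDER / (self.ATP_LADDER + km)
        v_noisy = v * (1 + rng.normal(0, 0.05, size=v.shape))
        fit = dk.fit_michaelis(
            [dk.SteadyRateData(c, max(vi, 0))
             for c, vi in zip(self.ATP_LADDER, v_noisy)])
        assert abs(fit.kcat - kcat) <= 3 * fit.kcat_se
        assert abs(fit.KM - km) <= 3 * fit.KM_se

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            dk.fit_michaelis([dk.SteadyRateData(1000.0, 0.02)])

    def test_unsaturated_data_flagged(self):
        km = 1e6
        data = [dk.SteadyRateData(c, 0.04 * c / (c + km))
                for c in self.ATP_LADDER]
        with pytest.warns(UserWarning):
            fit = dk.fit_michaelis(data)
        assert fit.warning is not None


class TestRnaActivationFit:
    LADDER = np.array([0.0, 450.0, 1250.0, 2000.0, 3000.0, 4500.0, 7000.0])

    def test_zero_rna_gives_basal_rate(self):
        v = dk.steady_state.rna_activation_model(
            np.array([0.0]), kcat=0.92, k_basal=0.043, KM_RNA=3400.0,
            enzyme_total=0.1)
        assert v[0] == pytest.approx(0.043, rel=1e-12)

    def test_saturating_rna_approaches_kcat(self):
        v = dk.steady_state.rna_activation_model(
            np.array([1e10]), kcat=0.92, k_basal=0.043, KM_RNA=3400.0,
            enzyme_total=0.1)
        assert v[0] == pytest.approx(0.92, rel=1e-4)

    def test_noiseless_recovery_of_reference_parameters(self):
        kcat, k0, km, ht = 0.92, 0.043, 3400.0, 0.1
        v = dk.steady_state.rna_activation_model(self.LADDER, kcat, k0, km, ht)
        data = [dk.SteadyRateData(c, vi, ht)
                for c, vi in zip(self.LADDER, v)]
        fit = dk.fit_rna_activation(data, enzyme_total=ht)
        assert fit.kcat == pytest.approx(kcat, rel=1e-6)
        assert fit.k_basal == pytest.approx(k0, rel=1e-6)
        assert fit.KM_RNA == pytest.approx(km, rel=1e-5)

    def test_quadratic_reduces_to_hyperbola_for_catalytic_enzyme(self):
        v_quad = dk.steady_state.rna_activation_model(
            self.LADDER, 0.92, 0.043, 3400.0, enzyme_total=1e-6)
        v_hyp = (0.92 - 0.043) * self.LADDER / (self.LADDER + 3400.0) + 0.043
        assert np.allclose(v_quad, v_hyp, rtol=1e-5)


class TestPiRebindingBound:
    def test_reference_bound(self):
        # K_Pi >= 10 mM and k-Pi ~ 0.02 s^-1 bound rebinding at 2e-6
        assert dk.pi_rebinding_bound(10000.0, 0.02) == pytest.approx(2e-6)

    def test_zero_release_gives_zero_bound(self):
        assert dk.pi_rebinding_bound(10000.0, 0.0) == 0.0

    def test_inverse_proportionality(self):
        assert dk.pi_rebinding_bound(20000.0, 0.02) == pytest.approx(
            dk.pi_rebinding_bound(10000.0, 0.02) / 2.0)

    def test_nonpositive_affinity_rejected(self):
        with pytest.raises(ValueError):
            dk.pi_rebinding_bound(0.0, 0.02)


class TestOccupancies:
    def test_bottleneck_accumulates_all_enzyme(self, table2):
        rates = table2.replace(k_rel_Pi=1e-9, k_resyn=0.0)
        occ = dk.steady_state_occupancies(rates, T=1e6, D=0.0, Pi=0.0)
        assert occ["HDP"] == pytest.approx(1.0, abs=1e-3)

    def test_hdp_fraction_equals_flux_over_release_rate(self, table2):
        # flux identity: steady-state release flux k-Pi * [HDP] equals
        # the Michaelis-Menten turnover at the clamped [ATP]
        occ = dk.steady_state_occupancies(table2, T=20000.0, D=0.0, Pi=0.0)
        kc = dk.kcat_closed_form(table2)
        km = dk.km_closed_form(table2)
        v = kc * 20000.0 / (20000.0 + km)
        assert occ["HDP"] == pytest.approx(v / table2.k_rel_Pi, rel=1e-9)

    def test_occupancies_match_long_time_ode_populations(self, table2):
        occ = dk.steady_state_occupancies(table2, T=20000.0, D=0.0, Pi=0.0)
        t = np.linspace(1.0, 2000.0, 100)
        tr = dk.simulate(dk.MixState(H=0.5, T=20000.0, regen_rate=100.0),
                         table2, t, "species")
        sp = tr.species.iloc[-1]
        for state in ("H", "HT", "HDP", "HD"):
            assert occ[state] == pytest.approx(sp[state] / 0.5, abs=1e-3 if
                                               occ[state] < 1e-3 else None,
                                               rel=1e-3)

    def test_fractions_sum_to_one_and_increase_with_phosphate(self, table2):
        rates = table2.replace(k_rebind_Pi=1e-4)
        prev = -1.0
        for pi in (0.0, 1000.0, 5000.0, 20000.0):
            occ = dk.steady_state_occupancies(rates, T=20000.0, D=0.0, Pi=pi)
            assert sum(occ.fractions.values()) == pytest.approx(1.0, abs=1e-9)
            assert occ["HDP"] > prev
            prev = occ["HDP"]

    def test_all_zero_rates_rejected(self):
        dead = dk.RateConstants(k_on_T=0, k_off_T=0, k_hyd=0, k_resyn=0,
                                k_rel_Pi=0, k_rebind_Pi=0, k_off_D=0,
                                k_rebind_D=0)
        with pytest.raises(ValueError):
            dk.steady_state_occupancies(dead, T=1000.0, D=0.0, Pi=0.0)

    def test_in_vivo_conditions_disfavor_atp_state(self, table2, rna_default):
        # with weak millimolar ATP binding, physiological nucleotide
        # levels leave little enzyme in the pre-hydrolysis ATP state
        occ = dk.steady_state_occupancies(table2, T=2100.0, D=470.0,
                                          Pi=2500.0)
        assert occ["HT"] < 0.2
        assert occ["HDP"] > occ["HT"]  # the ADP-Pi state dominates
        occ_rna = dk.steady_state_occupancies(table2, T=2100.0, D=470.0,
                                              Pi=2500.0, rna=rna_default,
                                              RNA=8000.0)
        assert sum(occ_rna.fractions.values()) == pytest.approx(1.0, abs=1e-9)


class TestSteadyRateFromTrace:
    def test_slope_of_linear_tail(self):
        t = np.linspace(0, 100, 200)
        signal = 0.02 * t + 0.5 * (1 - np.exp(-0.5 * t))  # transient + line
        v = dk.steady_rate_from_trace(t, signal, enzyme_total=0.5)
        assert v == pytest.approx(0.04, rel=1e-3)
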