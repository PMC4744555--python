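import numpy as np
import pytest
from hypothesis import settings

import dbp5kinetics as dk

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def table1():
    """Experimentally determined intrinsic-cycle constants."""
    return dk.preset_rates("table1")


@pytest.fixture(scope="session")
def table2():
    """Global-fit constants (steady-state NADH dataset)."""
    return dk.preset_rates("table2_nadh")


@pytest.fixture(scope="session")
def rna_default():
    return dk.preset_rna()


@pytest.fixture(scope="session")
def random_rates():
    """Random positive rate-constant sets spanning realistic decades."""

    def make(n, seed=42, rebind_pi=False):
        rng = np.random.default_rng(seed)
        out = []
        for _ in range(n):
            out.append(dk.RateConstants(
                k_on_T=10 ** rng.uniform(-2, 0),
                k_off_T=10 ** rng.uniform(1, 3),
                k_hyd=10 ** rng.uniform(-1, 1),
                k_resyn=10 ** rng.uniform(-4, -1),
                k_rel_Pi=10 ** rng.uniform(-2, 0),
                k_rebind_Pi=10 ** rng.uniform(-6, -4) if rebind_pi else 0.0,
                k_off_D=10 ** rng.uniform(1, 2),
                k_rebind_D=10 ** rng.uniform(-2, 0),
            ))
        return out

    return make


def ode_turnover(rates, T_factor, n_points=200, duration_turnovers=20.0):
    """Independent ODE-derived turnover rate at T = T_factor * KM.

    Uses a catalytic enzyme concentration (H = KM/1000) and ATP
    regeneration so products stay near zero, matching the assumptions of
    the closed-form steady-state expressions.
    """
    km = dk.km_closed_form(rates)
    kc = dk.kcat_closed_form(rates)
    H = km / 1000.0
    t = np.linspace(0.0, duration_turnovers / kc, n_points)
    tr = dk.simulate(
        dk.MixState(H=H, T=T_factor * km, regen_rate=max(100.0, 100.0 * kc)),
        rates, t[1:], "species", rtol=1e-10, atol=1e-15)
    picum = tr.species["Pi_cum"].to_numpy()
    half = len(picum) // 2
    return float(np.polyfit(tr.time[half:], picum[half:], 1)[0] / H)
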