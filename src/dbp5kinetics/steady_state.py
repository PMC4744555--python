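"""Steady-state theory and fitting for the four-state ATPase cycle.

Provides the closed-form kcat and KM,ATP of the minimal cycle (no
assumption about the speed or reversibility of any transition),
Michaelis-Menten fitting of rate-vs-[ATP] data, the quadratic
(enzyme-depletion) Briggs-Haldane fit for RNA activation, the flux-based
upper bound on phosphate rebinding, and the steady-state occupancy
distribution of cycle intermediates at clamped ligand concentrations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .kinetic_scheme import MixState, RateConstants, RnaRateConstants

__all__ = [
    "SteadyRateData",
    "MichaelisFit",
    "RnaActivationFit",
    "OccupancyDistribution",
    "kcat_closed_form",
    "km_closed_form",
    "fit_michaelis",
    "fit_rna_activation",
    "pi_rebinding_bound",
    "steady_state_occupancies",
    "steady_rate_from_trace",
]


@dataclass(frozen=True)
class SteadyRateData:
    """One steady-state measurement: ligand concentration vs turnover."""

    ligand_conc: float  # uM ([ATP] or total RNA nucleotides)
    v0: float           # s^-1 per enzyme
    enzyme_total: float = 0.0  # uM

    def __post_init__(self) -> None:
        if self.ligand_conc < 0 or self.v0 < 0:
            raise ValueError("ligand_conc and v0 must be >= 0")


@dataclass
class MichaelisFit:
    kcat: float
    KM: float
    kcat_se: float = float("nan")
    KM_se: float = float("nan")
    residual_norm: float = float("nan")
    warning: str | None = None


@dataclass
class RnaActivationFit:
    kcat: float
    k_basal: float
    KM_RNA: float
    kcat_se: float = float("nan")
    k_basal_se: float = float("nan")
    KM_RNA_se: float = float("nan")
    residual_norm: float = float("nan")


@dataclass
class OccupancyDistribution:
    """Fractional steady-state populations of cycle intermediates."""

    fractions: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"occupancies must sum to 1, got {total}")
        if any(v < -1e-12 or v > 1 + 1e-12 for v in self.fractions.values()):
            raise ValueError("occupancies must lie in [0, 1]")

    def __getitem__(self, key: str) -> float:
        return self.fractions[key]


# ---------------------------------------------------------------------------
# closed forms


def _denominator(k: RateConstants, Pi_conc: float) -> float:
    return ((k.k_hyd + k.k_resyn) * (k.k_rebind_Pi * Pi_conc + k.k_off_D)
            + k.k_hyd * k.k_rel_Pi + k.k_rel_Pi * k.k_off_D)


def kcat_closed_form(rates: RateConstants, Pi_conc: float = 0.0) -> float:
    """Maximal steady-state turnover (s^-1) of the four-state cycle.

    kcat = k+H k-Pi k-D / [(k+H + k-H)(k+Pi[Pi] + k-D) + k+H k-Pi + k-Pi k-D]

    The grouping is validated against long-time ODE flux in the test
    suite (agreement to <1% over random parameter sets).
    """
    den = _denominator(rates, Pi_conc)
    if den == 0:
        raise ZeroDivisionError("all closed-form denominator terms are zero")
    return rates.k_hyd * rates.k_rel_Pi * rates.k_off_D / den


def km_closed_form(rates: RateConstants, Pi_conc: float = 0.0) -> float:
    """Michaelis constant for ATP (uM) of the four-state cycle.

    KM = [k-T (k-H (k+Pi[Pi] + k-D) + k-Pi k-D) + k+H k-Pi k-D]
         / {k+T [(k+H + k-H)(k+Pi[Pi] + k-D) + k+H k-Pi + k-Pi k-D]}
    """
    den = rates.k_on_T * _denominator(rates, Pi_conc)
    if den == 0:
        raise ZeroDivisionError("closed-form KM denominator is zero")
    num = (rates.k_off_T * (rates.k_resyn * (rates.k_rebind_Pi * Pi_conc
                                             + rates.k_off_D)
                            + rates.k_rel_Pi * rates.k_off_D)
           + rates.k_hyd * rates.k_rel_Pi * rates.k_off_D)
    return num / den


# ---------------------------------------------------------------------------
# fitting


def _fit_with_se(residual, p0, bounds, multi_starts=None):
    best = None
    starts = [p0] + (multi_starts or [])
    for start in starts:
        try:
            sol = least_squares(residual, start, bounds=bounds)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("least-squares fit failed from every start")
    n, p = len(best.fun), len(best.x)
    dof = max(n - p, 1)
    s2 = 2 * best.cost / dof
    try:
        cov = s2 * np.linalg.inv(best.jac.T @ best.jac)
        se = np.sqrt(np.maximum(np.diag(cov), 0))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    return best, se


def fit_michaelis(data: list[SteadyRateData]) -> MichaelisFit:
    """Least-squares Michaelis-Menten fit of v0 vs [ATP].

    Requires at least 4 concentrations; a warning flag is set when the
    data do not identify kcat (all concentrations far below KM).
    """
    if len(data) < 2:
        raise ValueError("need at least 2 data points for a Michaelis fit")
    conc = np.array([d.ligand_conc for d in data])
    v = np.array([d.v0 for d in data])
    if np.allclose(v, 0):
        raise ValueError("all rates are zero; nothing to fit")

    vmax0 = v.max()
    km0 = max(np.median(conc[conc > 0]), 1e-6)

    def residual(p):
        kcat, km = p
        return kcat * conc / (conc + km) - v

    # multi-start over log-spaced KM guesses to avoid local minima
    starts = [[vmax0, km0 * f] for f in (0.1, 10.0)]
    best, se = _fit_with_se(residual, [vmax0, km0],
                            ([0, 0], [np.inf, np.inf]), starts)
    kcat, km = best.x
    warning = None
    if km > 3 * conc.max():
        warning = ("KM exceeds the sampled concentration range; "
                   "kcat and KM are poorly identified")
        warnings.warn(warning)
    return MichaelisFit(kcat=kcat, KM=km, kcat_se=se[0], KM_se=se[1],
                        residual_norm=float(np.sqrt(2 * best.cost)),
                        warning=warning)


def rna_activation_model(R_T: np.ndarray, kcat: float, k_basal: float,
                         KM_RNA: float, enzyme_total: float) -> np.ndarray:
    """Quadratic Briggs-Haldane rate law with enzyme depletion.

    v = (kcat - k0)/(2 [H]T) * {([H]T + [R]T + KM) -
        sqrt(([H]T + [R]T + KM)^2 - 4 [H]T [R]T)} + k0
    """
    R_T = np.asarray(R_T, dtype=float)
    b = enzyme_total + R_T + KM_RNA
    disc = b * b - 4 * enzyme_total * R_T
    if np.any(disc < 0):
        raise ValueError("negative discriminant in quadratic rate law")
    bound = (b - np.sqrt(disc)) / (2 * enzyme_total)
    return (kcat - k_basal) * bound + k_basal


def fit_rna_activation(data: list[SteadyRateData],
                       enzyme_total: float) -> RnaActivationFit:
    """Fit RNA-activated turnover vs total RNA (nucleotides, uM).

    Uses the quadratic (tight-binding) Briggs-Haldane form, which reduces
    to a hyperbola when the enzyme concentration is far below KM_RNA.
    """
    if enzyme_total <= 0:
        raise ValueError("enzyme_total must be > 0")
    if len(data) < 3:
        raise ValueError("need at least 3 data points")
    R = np.array([d.ligand_conc for d in data])
    v = np.array([d.v0 for d in data])

    k0_guess = v[R == 0].mean() if np.any(R == 0) else v.min()
    km0 = max(np.median(R[R > 0]), 1.0)

    def residual(p):
        kcat, k_basal, km = p
        return rna_activation_model(R, kcat, k_basal, km, enzyme_total) - v

    starts = [[v.max(), k0_guess, km0 * f] for f in (0.1, 10.0)]
    best, se = _fit_with_se(residual, [v.max(), k0_guess, km0],
                            ([0, 0, 1e-9], [np.inf, np.inf, np.inf]), starts)
    return RnaActivationFit(
        kcat=best.x[0], k_basal=best.x[1], KM_RNA=best.x[2],
        kcat_se=se[0], k_basal_se=se[1], KM_RNA_se=se[2],
        residual_norm=float(np.sqrt(2 * best.cost)))


def pi_rebinding_bound(K_Pi_ss: float, k_rel_Pi: float) -> float:
    """Upper bound on the phosphate rebinding constant (uM^-1 s^-1).

    The equilibrium phosphate affinity is always weaker than the apparent
    steady-state affinity, so k+Pi <= k-Pi / K_Pi,SS.
    """
    if K_Pi_ss <= 0:
        raise ValueError("K_Pi_ss must be > 0")
    if k_rel_Pi < 0:
        raise ValueError("k_rel_Pi must be >= 0")
    return k_rel_Pi / K_Pi_ss


# ---------------------------------------------------------------------------
# steady-state occupancies


def steady_state_occupancies(rates: RateConstants, T: float, D: float,
                             Pi: float,
                             rna: RnaRateConstants | None = None,
                             RNA: float = 0.0) -> OccupancyDistribution:
    """Steady-state fractional populations of cycle intermediates.

    Ligand concentrations (uM) are clamped (treated as buffered); the
    linear balance over enzyme states is solved directly.  With the RNA
    branch active the state space extends to the RNA-bound intermediates.
    """
    states = ["H", "HT", "HDP", "HD"]
    use_rna = rna is not None and RNA > 0
    if use_rna:
        states += ["HTR", "HDPR", "HDR"]
    n = len(states)
    idx = {s: i for i, s in enumerate(states)}
    Q = np.zeros((n, n))  # Q[i, j] = rate i -> j

    def add(a, b, k):
        Q[idx[a], idx[b]] += k

    add("H", "HT", rates.k_on_T * T)
    add("HT", "H", rates.k_off_T)
    add("HT", "HDP", rates.k_hyd)
    add("HDP", "HT", rates.k_resyn)
    add("HDP", "HD", rates.k_rel_Pi)
    add("HD", "HDP", rates.k_rebind_Pi * Pi)
    add("HD", "H", rates.k_off_D)
    add("H", "HD", rates.k_rebind_D * D)
    if use_rna:
        add("HT", "HTR", rna.k_iso * RNA / (rna.Kd_RNA + RNA))
        add("HTR", "HDPR", rates.k_hyd * rna.hyd_scale)
        add("HDPR", "HTR", rates.k_resyn * rna.resyn_scale)
        add("HDPR", "HDR", rna.k_rel_Pi_RNA)
        add("HDR", "HDPR", rates.k_rebind_Pi * Pi)
        add("HDR", "H", rates.k_off_D)

    A = Q.T - np.diag(Q.sum(axis=1))  # generator; solve pi' A = 0
    if np.allclose(A, 0):
        raise ValueError("all transition rates are zero; singular system")
    # replace one balance equation by normalization
    M = np.vstack([A[:-1], np.ones(n)])
    b = np.zeros(n)
    b[-1] = 1.0
    frac, *_ = np.linalg.lstsq(M, b, rcond=None)
    if not np.all(np.isfinite(frac)):
        raise ValueError("singular steady-state system")
    frac = np.clip(frac, 0, None)
    frac = frac / frac.sum()
    return OccupancyDistribution(dict(zip(states, frac)))


# ---------------------------------------------------------------------------
# helpers


def steady_rate_from_trace(time, signal, enzyme_total: float,
                           tail_fraction: float = 0.5) -> float:
    """Turnover rate (s^-1 per enzyme) from the linear regime of a trace.

    Takes the least-squares slope of the final ``tail_fraction`` of the
    trace (default: last 50%), divided by total enzyme.
    """
    if enzyme_total <= 0:
        raise ValueError("enzyme_total must be > 0")
    time = np.asarray(time, dtype=float)
    signal = np.asarray(signal, dtype=float)
    n0 = int(len(time) * (1 - tail_fraction))
    t, s = time[n0:], signal[n0:]
    slope = np.polyfit(t, s, 1)[0]
    return float(slope) / enzyme_total
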