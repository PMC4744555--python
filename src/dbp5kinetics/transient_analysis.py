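"""Transient-kinetics fitting models for stopped-flow traces.

Covers the fit models used to analyse the ATPase cycle: sums of
exponentials for pseudo-first-order binding, a bimolecular binding term
for non-pseudo-first-order conditions, kinetic competition for unlabeled
nucleotide affinities, the lag-plus-linear model of pre-steady-state
phosphate release, its substrate-dependence hyperbola, the algebraic
decomposition of the lag limits into hydrolysis/resynthesis/release rate
constants, and the burst-plus-lag model for sequential-mix traces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .kinetic_scheme import KineticTrace

__all__ = [
    "MultiExpFit",
    "BindingTraceFit",
    "CompetitionFit",
    "LagLinearFit",
    "LagHyperbolaFit",
    "LagDecomposition",
    "fit_multiexponential",
    "fit_binding_nonpseudo",
    "fit_competition",
    "fit_lag_linear",
    "fit_lag_hyperbola",
    "decompose_lag",
    "fit_burst_lag_linear",
    "binding_model",
    "lag_linear_model",
    "lag_hyperbola_model",
    "competition_model",
    "burst_lag_linear_model",
]


# ---------------------------------------------------------------------------
# model functions


def multiexp_model(t, F0, amplitudes, rates):
    t = np.asarray(t, dtype=float)
    out = np.full_like(t, F0, dtype=float)
    for A, k in zip(amplitudes, rates):
        out += A * (1.0 - np.exp(-k * t))
    return out


def bimolecular_term(t, A0, k0, r):
    """Bimolecular binding progress: A0 (1 - e^{-k0 t}) / (1 - r e^{-k0 t}).

    r = 0 recovers a single exponential (pseudo-first-order limit);
    r -> 1 gives full second-order behaviour.
    """
    t = np.asarray(t, dtype=float)
    e = np.exp(-k0 * t)
    if r < 1e-6:  # continuity at the pseudo-first-order limit
        return A0 * (1.0 - e)
    return A0 * (1.0 - e) / (1.0 - r * e)


def binding_model(t, F0, A0, k0, r, amplitudes=(), rates=()):
    return F0 + bimolecular_term(t, A0, k0, r) + multiexp_model(
        t, 0.0, amplitudes, rates)


def competition_model(N, k0, k_inf, Kd):
    """Observed binding rate vs competitor: (k0 - kinf)/(1 + [N]/Kd) + kinf."""
    N = np.asarray(N, dtype=float)
    return (k0 - k_inf) / (1.0 + N / Kd) + k_inf


def lag_linear_model(t, beta, lam, Pi0):
    """Lag followed by a linear steady-state phase.

    [Pi](t) = beta ((e^{-lam t} - 1)/lam + t) + Pi0; the slope is 0 at
    t = 0 and beta as t -> inf.
    """
    t = np.asarray(t, dtype=float)
    return beta * ((np.exp(-lam * t) - 1.0) / lam + t) + Pi0


def lag_hyperbola_model(conc, lam_inf, lam_0, K_half):
    conc = np.asarray(conc, dtype=float)
    return (lam_inf - lam_0) * conc / (K_half + conc) + lam_0


def burst_lag_linear_model(t, F0, A0, k0, r, beta, lam):
    """Bimolecular burst plus lag/linear phase (sequential-mix traces)."""
    return (F0 + bimolecular_term(t, A0, k0, r)
            + beta * ((np.exp(-lam * np.asarray(t, float)) - 1.0) / lam
                      + np.asarray(t, float)))


# ---------------------------------------------------------------------------
# results


@dataclass
class MultiExpFit:
    F0: float
    amplitudes: np.ndarray  # ordered to match rates
    rates: np.ndarray       # decreasing
    residual_norm: float
    n_phases_requested: int
    n_phases_used: int
    flag: str | None = None

    def __call__(self, t):
        return multiexp_model(t, self.F0, self.amplitudes, self.rates)


@dataclass
class BindingTraceFit:
    F0: float
    A0: float
    k0_bi: float
    r: float
    amplitudes: np.ndarray
    rates: np.ndarray
    residual_norm: float
    se: dict = field(default_factory=dict)

    def __call__(self, t):
        return binding_model(t, self.F0, self.A0, self.k0_bi, self.r,
                             self.amplitudes, self.rates)


@dataclass
class CompetitionFit:
    k0: float
    k_inf: float
    Kd: float
    k0_se: float = float("nan")
    k_inf_se: float = float("nan")
    Kd_se: float = float("nan")
    residual_norm: float = float("nan")
    poor_fit: bool = False


@dataclass
class LagLinearFit:
    beta: float          # steady-state slope, uM Pi / s
    lam: float           # lag rate constant, s^-1
    Pi0: float           # offset, uM
    beta_se: float = float("nan")
    lam_se: float = float("nan")
    Pi0_se: float = float("nan")
    residual_norm: float = float("nan")
    lam_is_lower_bound: bool = False
    # burst parameters (set by fit_burst_lag_linear)
    A0: float = 0.0
    k0_bi: float = float("nan")
    r: float = 0.0

    def __call__(self, t):
        if self.A0:
            return burst_lag_linear_model(t, self.Pi0, self.A0, self.k0_bi,
                                          self.r, self.beta, self.lam)
        return lag_linear_model(t, self.beta, self.lam, self.Pi0)


@dataclass
class LagHyperbolaFit:
    lam_inf: float
    lam_0: float
    K_half: float
    lam_inf_se: float = float("nan")
    lam_0_se: float = float("nan")
    K_half_se: float = float("nan")
    residual_norm: float = float("nan")


@dataclass
class LagDecomposition:
    """Hydrolysis-cycle constants inferred from the lag-phase limits.

    k_hyd + k_resyn + k_rel_Pi equals lam_inf identically by construction.
    """

    k_hyd: float
    k_resyn: float
    k_rel_Pi: float


# ---------------------------------------------------------------------------
# fitting helpers


def _least_squares_se(sol):
    n, p = len(sol.fun), len(sol.x)
    dof = max(n - p, 1)
    s2 = 2 * sol.cost / dof
    try:
        cov = s2 * np.linalg.inv(sol.jac.T @ sol.jac)
        return np.sqrt(np.maximum(np.diag(cov), 0))
    except np.linalg.LinAlgError:
        return np.full(p, np.nan)


def _trace_arrays(trace):
    if isinstance(trace, KineticTrace):
        return trace.time, trace.signal
    t, s = trace
    return np.asarray(t, float), np.asarray(s, float)


def _varpro_residual(log_k, t, y):
    """Residual with amplitudes (and offset) projected out linearly."""
    k = np.exp(log_k)
    X = np.column_stack([np.ones_like(t)] + [1.0 - np.exp(-ki * t) for ki in k])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return X @ coef - y, coef


def fit_multiexponential(trace, n_phases: int) -> MultiExpFit:
    """Fit a trace to F0 + sum_i A_i (1 - e^{-k_i t}).

    Rates are initialized log-spaced over the sampled dynamic range and
    amplitudes solved linearly (variable projection).  A degenerate or
    non-convergent fit falls back to fewer phases with a flag.
    """
    if n_phases not in (1, 2, 3):
        raise ValueError("n_phases must be 1, 2 or 3")
    t, y = _trace_arrays(trace)
    if len(t) < 5 * n_phases:
        raise ValueError("trace too short for requested number of phases")
    if np.ptp(y) == 0:
        return MultiExpFit(F0=float(y[0]), amplitudes=np.zeros(n_phases),
                           rates=np.zeros(n_phases), residual_norm=0.0,
                           n_phases_requested=n_phases, n_phases_used=0,
                           flag="constant trace: zero amplitudes")

    tpos = t[t > 0]
    k_hi = 2.0 / tpos.min()
    k_lo = 0.5 / tpos.max()

    def solve(n):
        k0 = np.geomspace(k_lo, k_hi, n + 2)[1:-1] if n > 1 else \
            np.array([np.sqrt(k_lo * k_hi)])
        sol = least_squares(lambda p: _varpro_residual(p, t, y)[0],
                            np.log(k0[::-1]))
        _, coef = _varpro_residual(sol.x, t, y)
        return sol, coef

    flag = None
    n_used = n_phases
    sol, coef = solve(n_phases)
    k = np.exp(sol.x)
    # collapse of two phases onto the same rate -> fall back
    if n_phases > 1 and np.min(np.diff(np.sort(k))) < 1e-6 * k.max():
        flag = "degenerate phases: fell back to fewer phases"
        n_used = n_phases - 1
        sol, coef = solve(n_used)
        k = np.exp(sol.x)
    order = np.argsort(k)[::-1]
    rates = k[order]
    amps = coef[1:][order]
    if n_used < n_phases:  # pad so output length matches the request
        rates = np.concatenate([rates, np.zeros(n_phases - n_used)])
        amps = np.concatenate([amps, np.zeros(n_phases - n_used)])
    return MultiExpFit(F0=float(coef[0]), amplitudes=amps, rates=rates,
                       residual_norm=float(np.sqrt(2 * sol.cost)),
                       n_phases_requested=n_phases, n_phases_used=n_used,
                       flag=flag)


def fit_binding_nonpseudo(trace, n_extra_phases: int = 0) -> BindingTraceFit:
    """Fit the bimolecular binding model with optional extra phases.

    The deviation parameter r is bounded to [0, 1); r = 0 reduces the
    bimolecular term to a single exponential.
    """
    t, y = _trace_arrays(trace)
    pre = fit_multiexponential((t, y), min(n_extra_phases + 1, 3))
    k_init = pre.rates[pre.rates > 0]
    k0_init = k_init[0] if k_init.size else 1.0 / max(t[t > 0].min(), 1e-6)

    n = n_extra_phases
    # parameters: F0, A0, log k0, r, then (A_i, log k_i) per extra phase
    p0 = [y[0], np.ptp(y), np.log(k0_init), 0.5]
    lo = [-np.inf, 0.0, -np.inf, 0.0]
    hi = [np.inf, np.inf, np.inf, 1.0 - 1e-9]
    for i in range(n):
        ki = pre.rates[i + 1] if i + 1 < len(k_init) else k0_init / 10 ** (i + 1)
        p0 += [np.ptp(y) / 10, np.log(max(ki, 1e-9))]
        lo += [-np.inf, -np.inf]
        hi += [np.inf, np.inf]

    def unpack(p):
        F0, A0, logk0, r = p[:4]
        amps = p[4::2]
        ks = np.exp(p[5::2])
        return F0, A0, np.exp(logk0), r, amps, ks

    def residual(p):
        return binding_model(t, *unpack(p)) - y

    sol = least_squares(residual, p0, bounds=(lo, hi))
    se = _least_squares_se(sol)
    F0, A0, k0, r, amps, ks = unpack(sol.x)
    return BindingTraceFit(F0=F0, A0=A0, k0_bi=k0, r=r,
                           amplitudes=np.asarray(amps), rates=np.asarray(ks),
                           residual_norm=float(np.sqrt(2 * sol.cost)),
                           se={"F0": se[0], "A0": se[1], "r": se[3]})


def fit_competition(competitor_conc, k_obs) -> CompetitionFit:
    """Fit observed binding rates vs competitor concentration.

    Estimates the rate at zero competitor (k0), at saturation (k_inf) and
    the competitor dissociation constant Kd.  Requires >= 4 points
    including [N] = 0.  Non-monotonic data are fitted with a poor-fit
    flag rather than rejected.
    """
    N = np.asarray(competitor_conc, dtype=float)
    k = np.asarray(k_obs, dtype=float)
    if len(N) < 4:
        raise ValueError("need k_obs at >= 4 competitor concentrations")
    if not np.any(N == 0):
        raise ValueError("competition data must include [N] = 0")

    k0_init = k[N == 0].mean()
    kinf_init = k[np.argmax(N)]
    Kd_init = max(np.median(N[N > 0]), 1e-9)

    def residual(p):
        return competition_model(N, p[0], p[1], np.exp(p[2])) - k

    best = None
    for f in (0.1, 1.0, 10.0):
        sol = least_squares(residual, [k0_init, kinf_init,
                                       np.log(Kd_init * f)])
        if best is None or sol.cost < best.cost:
            best = sol
    se = _least_squares_se(best)
    Kd = float(np.exp(best.x[2]))
    resid_norm = float(np.sqrt(2 * best.cost))
    order = np.argsort(N)
    monotonic = np.all(np.diff(k[order]) <= 0) or np.all(np.diff(k[order]) >= 0)
    return CompetitionFit(k0=best.x[0], k_inf=best.x[1], Kd=Kd,
                          k0_se=se[0], k_inf_se=se[1], Kd_se=Kd * se[2],
                          residual_norm=resid_norm,
                          poor_fit=not monotonic)


def fit_lag_linear(trace) -> LagLinearFit:
    """Fit a phosphate-release trace to the lag-plus-linear model.

    When the fitted lag rate exceeds the sampling resolution
    (lam > 1/(2 median dt)) the lag is unresolved and lam is reported as
    a lower bound (``lam_is_lower_bound``).
    """
    t, y = _trace_arrays(trace)
    beta0 = max((y[-1] - y[len(y) // 2]) / (t[-1] - t[len(t) // 2]), 1e-12)
    # back-extrapolated x-intercept of the linear phase estimates 1/lam
    x_int = t[-1] - (y[-1] - y[0]) / beta0
    lam0 = 1.0 / max(x_int, (t[1] - t[0]))

    def residual(p):
        return lag_linear_model(t, p[0], np.exp(p[1]), p[2]) - y

    best = None
    for f in (0.3, 1.0, 3.0):
        sol = least_squares(residual, [beta0, np.log(lam0 * f), y[0]])
        if best is None or sol.cost < best.cost:
            best = sol
    se = _least_squares_se(best)
    lam = float(np.exp(best.x[1]))
    dt_med = float(np.median(np.diff(t)))
    return LagLinearFit(beta=float(best.x[0]), lam=lam, Pi0=float(best.x[2]),
                        beta_se=se[0], lam_se=lam * se[1], Pi0_se=se[2],
                        residual_norm=float(np.sqrt(2 * best.cost)),
                        lam_is_lower_bound=lam > 1.0 / (2.0 * dt_med))


def fit_lag_hyperbola(points) -> LagHyperbolaFit:
    """Fit (concentration, lag rate) pairs to a rectangular hyperbola.

    lam([T]) = (lam_inf - lam_0) [T]/(K_half + [T]) + lam_0, with lam_0
    bounded at zero.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 4:
        raise ValueError("need >= 4 (concentration, lambda) points")
    conc, lam = pts[:, 0], pts[:, 1]

    lam_inf0 = lam.max()
    lam_00 = max(lam.min(), 0.0)
    K0 = max(np.median(conc[conc > 0]), 1e-9)

    def residual(p):
        return lag_hyperbola_model(conc, p[0], p[1], np.exp(p[2])) - lam

    best = None
    for f in (0.1, 1.0, 10.0):
        sol = least_squares(residual, [lam_inf0, lam_00, np.log(K0 * f)],
                            bounds=([0, 0, -np.inf], [np.inf, np.inf, np.inf]))
        if best is None or sol.cost < best.cost:
            best = sol
    se = _least_squares_se(best)
    K_half = float(np.exp(best.x[2]))
    return LagHyperbolaFit(lam_inf=float(best.x[0]), lam_0=float(best.x[1]),
                           K_half=K_half, lam_inf_se=se[0], lam_0_se=se[1],
                           K_half_se=K_half * se[2],
                           residual_norm=float(np.sqrt(2 * best.cost)))


def decompose_lag(lam_inf: float, lam_0: float, Pc: float) -> LagDecomposition:
    """Resolve the lag limits into hydrolysis-cycle rate constants.

    With rapid-equilibrium substrate binding the saturating lag rate is
    the hydrolysis relaxation plus release (lam_inf = k+H + k-H + k-Pi)
    and the zero-substrate intercept is lam_0 = k-H + k-Pi; the isotope
    partition coefficient Pc = k-H/(k-H + k-Pi) splits the intercept.
    """
    if not 0 <= Pc < 1:
        raise ValueError("Pc must be in [0, 1)")
    if lam_inf <= lam_0:
        raise ValueError("lam_inf must exceed lam_0")
    if lam_0 < 0:
        raise ValueError("lam_0 must be >= 0")
    return LagDecomposition(k_hyd=lam_inf - lam_0,
                            k_resyn=Pc * lam_0,
                            k_rel_Pi=(1.0 - Pc) * lam_0)


def fit_burst_lag_linear(trace) -> LagLinearFit:
    """Fit a sequential-mix trace to burst (bimolecular) + lag/linear.

    If the burst amplitude is indistinguishable from zero the result
    reduces to the plain lag-plus-linear fit.
    """
    t, y = _trace_arrays(trace)
    base = fit_lag_linear(trace)

    A0_init = max(y[min(np.searchsorted(t, t[0] + 0.05 * (t[-1] - t[0])),
                        len(y) - 1)] - y[0], np.ptp(y) * 0.05)
    k0_init = 10.0 / max(t[t > 0].min() * 10, 1e-3)

    # parameters: F0, A0, log k0, r, beta, log lam
    p0 = [y[0], A0_init, np.log(k0_init), 0.1, base.beta,
          np.log(max(base.lam, 1e-6))]
    lo = [-np.inf, 0.0, -np.inf, 0.0, 0.0, -np.inf]
    hi = [np.inf, np.inf, np.inf, 1.0 - 1e-9, np.inf, np.inf]

    def residual(p):
        return burst_lag_linear_model(t, p[0], p[1], np.exp(p[2]), p[3],
                                      p[4], np.exp(p[5])) - y

    sol = least_squares(residual, p0, bounds=(lo, hi))
    se = _least_squares_se(sol)
    A0 = float(sol.x[1])
    if (np.sqrt(2 * sol.cost) >= base.residual_norm
            or A0 < 3 * (se[1] if np.isfinite(se[1]) else 0.0) and A0 < 1e-12):
        return base
    lam = float(np.exp(sol.x[5]))
    dt_med = float(np.median(np.diff(t)))
    return LagLinearFit(beta=float(sol.x[4]), lam=lam, Pi0=float(sol.x[0]),
                        beta_se=se[4], lam_se=lam * se[5], Pi0_se=se[0],
                        residual_norm=float(np.sqrt(2 * sol.cost)),
                        lam_is_lower_bound=lam > 1.0 / (2.0 * dt_med),
                        A0=A0, k0_bi=float(np.exp(sol.x[2])),
                        r=float(sol.x[3]))
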