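"""Mass-action model of the Dbp5 ATPase cycle.

The intrinsic cycle is the minimal four-state scheme

    H + T <=> HT --> HD.Pi <=> HD + Pi,   HD <=> H + D

where H is the enzyme (Dbp5), T is ATP, D is ADP and Pi is inorganic
phosphate.  Product release is sequential with phosphate preceding ADP.
An optional RNA-activated branch models rapid-equilibrium RNA binding to
the ATP-bound enzyme followed by a first-order isomerization, hydrolysis
and phosphate release on the RNA-bound pathway, and RNA release coupled
to ADP release.

Units: concentrations in uM, time in s, second-order rate constants in
uM^-1 s^-1.  All unit conversions happen at the I/O boundary.
"""

from __future__ import annotations

import importlib.resources
import json
import math
from dataclasses import dataclass, field, fields, replace

import numpy as np
import yaml
from scipy.integrate import solve_ivp

__all__ = [
    "RateConstants",
    "RnaRateConstants",
    "MixState",
    "KineticTrace",
    "SimulationError",
    "mass_action_rhs",
    "simulate",
    "simulate_dual_mix",
    "preset_rates",
    "SPECIES",
]

#: extinction coefficient of NADH at 340 nm (M^-1 cm^-1, 1 cm path)
EPS_NADH = 6220.0
#: default phosphate-sensor binding parameters (explicit-sensor mode)
PIBIP_KON = 300.0   # uM^-1 s^-1
PIBIP_KD = 0.1      # uM
#: default pseudo-first-order ATP regeneration rate for the NADH assay
DEFAULT_REGEN_RATE = 100.0  # s^-1

# species vector layout; bookkeeping entries (cumulative released Pi and
# cumulative regenerated ATP) ride along with the chemical species
SPECIES = (
    "H", "T", "HT", "HDP", "HD", "D", "Pi",
    "RNA", "HTR", "HDPR", "HDR",
    "PiBiP", "PiBiP_Pi",
    "Pi_cum", "regen_cum",
)
_IDX = {name: i for i, name in enumerate(SPECIES)}
_ENZYME = [_IDX[s] for s in ("H", "HT", "HDP", "HD", "HTR", "HDPR", "HDR")]
_RNA_SPECIES = [_IDX[s] for s in ("RNA", "HTR", "HDPR", "HDR")]
# phosphorus groups carried by each species (regeneration injects one
# phosphate per D->T event, so the balance includes regen_cum)
_PHOSPHORUS = np.zeros(len(SPECIES))
for _name, _n in [("T", 3), ("HT", 3), ("HDP", 3), ("D", 2), ("HD", 2),
                  ("Pi", 1), ("HTR", 3), ("HDPR", 3), ("HDR", 2),
                  ("PiBiP_Pi", 1), ("regen_cum", -1)]:
    _PHOSPHORUS[_IDX[_name]] = _n


class SimulationError(RuntimeError):
    """Raised when ODE integration fails or violates conservation."""


@dataclass(frozen=True)
class RateConstants:
    """Fundamental rate constants of the four-state ATPase cycle.

    Attributes
    ----------
    k_on_T, k_off_T :
        ATP binding (uM^-1 s^-1) and dissociation (s^-1).
    k_hyd, k_resyn :
        ATP hydrolysis and resynthesis (s^-1).
    k_rel_Pi, k_rebind_Pi :
        Phosphate release (s^-1) and rebinding (uM^-1 s^-1).
    k_off_D, k_rebind_D :
        ADP release (s^-1) and binding (uM^-1 s^-1).
    """

    k_on_T: float
    k_off_T: float
    k_hyd: float
    k_resyn: float
    k_rel_Pi: float
    k_rebind_Pi: float
    k_off_D: float
    k_rebind_D: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{f.name} must be finite and >= 0, got {v}")

    # derived equilibrium constants (dissociation / backward-over-forward);
    # infinite when the denominator vanishes
    @property
    def K_T(self) -> float:
        return self.k_off_T / self.k_on_T if self.k_on_T else math.inf

    @property
    def K_D(self) -> float:
        return self.k_off_D / self.k_rebind_D if self.k_rebind_D else math.inf

    @property
    def K_H(self) -> float:
        return self.k_resyn / self.k_hyd if self.k_hyd else math.inf

    @property
    def K_Pi(self) -> float:
        return self.k_rel_Pi / self.k_rebind_Pi if self.k_rebind_Pi else math.inf

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "RateConstants":
        names = {f.name for f in fields(cls)}
        return cls(**{k: float(v) for k, v in d.items() if k in names})

    def replace(self, **kw) -> "RateConstants":
        return replace(self, **kw)


@dataclass(frozen=True)
class RnaRateConstants:
    """RNA-branch parameters.

    RNA binds the ATP-bound enzyme in rapid equilibrium (``Kd_RNA``, uM
    nucleotide) followed by a first-order isomerization with maximal rate
    ``k_iso`` (s^-1); the composite gives the observed hyperbolic RNA
    dependence of the pre-steady-state lag.  On the RNA-bound branch
    hydrolysis and resynthesis are scaled by ``hyd_scale``/``resyn_scale``
    and phosphate release occurs at ``k_rel_Pi_RNA``.  RNA dissociates
    together with ADP, so every steady-state cycle re-engages RNA.
    """

    Kd_RNA: float = 3000.0       # uM nucleotide
    k_iso: float = 5.0           # s^-1
    k_rel_Pi_RNA: float = 5.0    # s^-1
    hyd_scale: float = 10.0
    resyn_scale: float = 80.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{f.name} must be finite and >= 0, got {v}")

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "RnaRateConstants":
        names = {f.name for f in fields(cls)}
        return cls(**{k: float(v) for k, v in d.items() if k in names})


@dataclass
class MixState:
    """Concentrations (uM) of every chemical species in a mix.

    ``regen_rate`` (s^-1) switches on the pseudo-first-order D -> T
    regeneration step used to model the NADH-coupled assay;
    ``pibip_explicit`` selects the explicit phosphate-sensor binding model
    instead of the default instantaneous-capture observable.
    """

    H: float = 0.0
    T: float = 0.0
    HT: float = 0.0
    HDP: float = 0.0
    HD: float = 0.0
    D: float = 0.0
    Pi: float = 0.0
    RNA: float = 0.0
    HTR: float = 0.0
    HDPR: float = 0.0
    HDR: float = 0.0
    PiBiP: float = 0.0
    PiBiP_Pi: float = 0.0
    Pi_cum: float = 0.0
    regen_cum: float = 0.0
    regen_rate: float = 0.0
    pibip_explicit: bool = False

    def to_vector(self) -> np.ndarray:
        return np.array([getattr(self, s) for s in SPECIES], dtype=float)

    @classmethod
    def from_vector(cls, y: np.ndarray, regen_rate: float = 0.0,
                    pibip_explicit: bool = False) -> "MixState":
        return cls(**dict(zip(SPECIES, map(float, y))),
                   regen_rate=regen_rate, pibip_explicit=pibip_explicit)

    def validate(self) -> None:
        for s in SPECIES:
            if getattr(self, s) < 0:
                raise ValueError(f"negative concentration for {s}")
        if self.regen_rate < 0:
            raise ValueError("regen_rate must be >= 0")

    def total_enzyme(self) -> float:
        return sum(self.to_vector()[_ENZYME])

    def uses_rna(self) -> bool:
        return any(self.to_vector()[_RNA_SPECIES] > 0)


@dataclass
class KineticTrace:
    """One observable time course with assay provenance.

    ``observable_kind`` is one of ``nadh_a340`` (A340 change of the
    NADH-coupled assay), ``pibip_pi`` (sensor-reported [Pi], uM),
    ``mant_fret`` (arbitrary fluorescence) or ``species``.
    ``meta`` carries the assay descriptor (mix composition, protocol,
    ground-truth parameters for synthetic data).
    """

    time: np.ndarray
    signal: np.ndarray
    observable_kind: str = "species"
    meta: dict = field(default_factory=dict)
    noise_sd: float = 0.0
    seed: int | None = None
    species: "object | None" = None  # pandas.DataFrame of populations

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time.shape != self.signal.shape:
            raise ValueError("time and signal must have the same shape")
        if self.time.size and self.time[0] < 0:
            raise ValueError("time must start at >= 0")
        if self.time.size > 1 and not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains non-finite values")

    def to_csv(self, path) -> None:
        """Write time_s,signal CSV with a JSON header comment block."""
        header = {
            "observable_kind": self.observable_kind,
            "noise_sd": self.noise_sd,
            "seed": self.seed,
            "meta": self.meta,
        }
        with open(path, "w") as fh:
            fh.write("# " + json.dumps(header, default=float) + "\n")
            fh.write("time_s,signal\n")
            for t, s in zip(self.time, self.signal):
                fh.write(f"{float(t)!r},{float(s)!r}\n")

    @classmethod
    def from_csv(cls, path) -> "KineticTrace":
        header: dict = {}
        times, signals = [], []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    header = json.loads(line[1:].strip())
                elif not line.startswith("time_s"):
                    t, s = line.split(",")
                    times.append(float(t))
                    signals.append(float(s))
        return cls(
            time=np.array(times), signal=np.array(signals),
            observable_kind=header.get("observable_kind", "species"),
            meta=header.get("meta", {}),
            noise_sd=header.get("noise_sd", 0.0),
            seed=header.get("seed"),
        )


# ---------------------------------------------------------------------------
# mass-action right-hand side


def _rhs(y: np.ndarray, k: RateConstants, rna: RnaRateConstants | None,
         regen_rate: float, pibip_explicit: bool,
         pibip_kon: float = PIBIP_KON, pibip_kd: float = PIBIP_KD) -> np.ndarray:
    (H, T, HT, HDP, HD, D, Pi, RNA, HTR, HDPR, HDR,
     B, BPi, _Pi_cum, _regen_cum) = y
    dy = np.zeros_like(y)

    bind_T = k.k_on_T * H * T
    unbind_T = k.k_off_T * HT
    hyd = k.k_hyd * HT
    resyn = k.k_resyn * HDP
    rel_Pi = k.k_rel_Pi * HDP
    rebind_Pi = k.k_rebind_Pi * Pi * HD
    rel_D = k.k_off_D * HD
    rebind_D = k.k_rebind_D * H * D

    dy[_IDX["H"]] = -bind_T + unbind_T + rel_D - rebind_D
    dy[_IDX["T"]] = -bind_T + unbind_T
    dy[_IDX["HT"]] = bind_T - unbind_T - hyd + resyn
    dy[_IDX["HDP"]] = hyd - resyn - rel_Pi + rebind_Pi
    dy[_IDX["HD"]] = rel_Pi - rebind_Pi - rel_D + rebind_D
    dy[_IDX["D"]] = rel_D - rebind_D
    dy[_IDX["Pi"]] = rel_Pi - rebind_Pi
    dy[_IDX["Pi_cum"]] = rel_Pi

    if rna is not None:
        # rapid-equilibrium RNA engagement of HT followed by isomerization,
        # folded into one saturable pseudo-first-order step
        engage = (rna.k_iso * RNA / (rna.Kd_RNA + RNA) * HT) if RNA > 0 else 0.0
        hyd_r = k.k_hyd * rna.hyd_scale * HTR
        resyn_r = k.k_resyn * rna.resyn_scale * HDPR
        rel_Pi_r = rna.k_rel_Pi_RNA * HDPR
        rebind_Pi_r = k.k_rebind_Pi * Pi * HDR
        rel_D_r = k.k_off_D * HDR  # releases ADP and RNA together

        dy[_IDX["HT"]] -= engage
        dy[_IDX["RNA"]] = -engage + rel_D_r
        dy[_IDX["HTR"]] = engage - hyd_r + resyn_r
        dy[_IDX["HDPR"]] = hyd_r - resyn_r - rel_Pi_r + rebind_Pi_r
        dy[_IDX["HDR"]] = rel_Pi_r - rebind_Pi_r - rel_D_r
        dy[_IDX["H"]] += rel_D_r
        dy[_IDX["D"]] += rel_D_r
        dy[_IDX["Pi"]] += rel_Pi_r - rebind_Pi_r
        dy[_IDX["Pi_cum"]] += rel_Pi_r

    if regen_rate > 0:
        regen = regen_rate * D
        dy[_IDX["D"]] -= regen
        dy[_IDX["T"]] += regen
        dy[_IDX["regen_cum"]] = regen

    if pibip_explicit:
        capture = pibip_kon * B * Pi - pibip_kon * pibip_kd * BPi
        dy[_IDX["PiBiP"]] = -capture
        dy[_IDX["PiBiP_Pi"]] = capture
        dy[_IDX["Pi"]] -= capture

    return dy


def mass_action_rhs(state: MixState, rates: RateConstants,
                    rna: RnaRateConstants | None = None) -> MixState:
    """Time derivatives (uM/s) of every species under mass action.

    Raises ``ValueError`` for negative concentrations or when RNA-branch
    species are populated without RNA parameters.
    """
    state.validate()
    if state.uses_rna() and rna is None:
        raise ValueError("RNA branch species present but no RnaRateConstants given")
    dy = _rhs(state.to_vector(), rates, rna, state.regen_rate,
              state.pibip_explicit)
    return MixState.from_vector(dy, regen_rate=state.regen_rate,
                                pibip_explicit=state.pibip_explicit)


# ---------------------------------------------------------------------------
# simulation


def _observable(ys: np.ndarray, kind: str, initial: MixState) -> np.ndarray:
    if kind == "nadh_a340":
        return -EPS_NADH * 1e-6 * ys[_IDX["regen_cum"]]
    if kind == "pibip_pi":
        if initial.pibip_explicit:
            return ys[_IDX["PiBiP_Pi"]]
        capacity = initial.PiBiP + initial.PiBiP_Pi
        # instantaneous, effectively irreversible capture: the sensor
        # reports all liberated phosphate up to its capacity
        return np.minimum(ys[_IDX["Pi"]], capacity)
    if kind == "species":
        return ys[_IDX["Pi"]]
    raise ValueError(f"unsupported observable_kind {kind!r} for this scheme")


def _integrate(y0: np.ndarray, rates: RateConstants,
               rna: RnaRateConstants | None, regen_rate: float,
               pibip_explicit: bool, t_grid: np.ndarray,
               rtol: float, atol: float, method: str) -> np.ndarray:
    t0 = 0.0
    sol = solve_ivp(
        lambda t, y: _rhs(y, rates, rna, regen_rate, pibip_explicit),
        (t0, float(t_grid[-1])), y0, t_eval=t_grid,
        method=method, rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise SimulationError(f"ODE integration failed: {sol.message}")
    if not np.all(np.isfinite(sol.y)):
        raise SimulationError("ODE integration produced non-finite values")
    e0 = y0[_ENZYME].sum()
    drift = np.abs(sol.y[_ENZYME].sum(axis=0) - e0).max()
    if drift > 10 * (rtol * max(e0, 1.0) + atol * len(_ENZYME)) + 1e-9:
        raise SimulationError(
            f"enzyme conservation violated: max drift {drift:.3e} uM")
    return sol.y


def simulate(initial: MixState, rates: RateConstants, t_grid,
             observable_kind: str = "species",
             rna: RnaRateConstants | None = None, *,
             rtol: float = 1e-8, atol: float = 1e-12,
             method: str = "LSODA") -> KineticTrace:
    """Integrate a single-mix protocol and return a noiseless trace.

    The full species time courses are attached to the returned trace as a
    ``pandas.DataFrame`` under ``trace.species``.
    """
    import pandas as pd

    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size < 2 or not np.all(np.diff(t_grid) > 0):
        raise ValueError("t_grid must be a 1-D strictly increasing array")
    if t_grid[0] < 0:
        raise ValueError("t_grid must start at >= 0")
    initial.validate()
    if (initial.uses_rna()) and rna is None:
        raise ValueError("RNA present but no RnaRateConstants given")

    y0 = initial.to_vector()
    if t_grid[0] > 0:
        t_eval = np.concatenate([[0.0], t_grid])
        ys = _integrate(y0, rates, rna, initial.regen_rate,
                        initial.pibip_explicit, t_eval, rtol, atol, method)[:, 1:]
    else:
        ys = _integrate(y0, rates, rna, initial.regen_rate,
                        initial.pibip_explicit, t_grid, rtol, atol, method)
    signal = _observable(ys, observable_kind, initial)
    trace = KineticTrace(
        time=t_grid, signal=signal, observable_kind=observable_kind,
        meta={"protocol": "single_mix", "initial": _state_meta(initial),
              "rates": rates.to_dict(),
              "rna": rna.to_dict() if rna else None},
    )
    trace.species = pd.DataFrame(ys.T, index=t_grid, columns=SPECIES)
    return trace


def _state_meta(state: MixState) -> dict:
    d = {s: getattr(state, s) for s in SPECIES if getattr(state, s) != 0}
    d["regen_rate"] = state.regen_rate
    d["pibip_explicit"] = state.pibip_explicit
    return d


def simulate_dual_mix(first_mix: MixState, age_time: float,
                      second_mix_additions: MixState, rates: RateConstants,
                      t_grid, observable_kind: str = "species",
                      rna: RnaRateConstants | None = None, *,
                      dilution: float = 2.0,
                      rtol: float = 1e-8, atol: float = 1e-12,
                      method: str = "LSODA") -> KineticTrace:
    """Sequential-mix protocol: age the first mix, dilute, add, re-integrate.

    ``age_time`` is the delay between mixes; ``dilution`` is the factor by
    which the aged solution is diluted in the second mix (2 for
    equal-volume mixing).  ``second_mix_additions`` holds the
    post-second-mix final concentrations of the added species.  Time zero
    of the returned trace is the second mix.
    """
    import pandas as pd

    if age_time < 0:
        raise ValueError("age_time must be >= 0")
    if dilution <= 0:
        raise ValueError("dilution must be > 0")
    first_mix.validate()
    second_mix_additions.validate()

    y_aged = first_mix.to_vector()
    if age_time > 0:
        t_age = np.array([0.0, age_time])
        y_aged = _integrate(y_aged, rates, rna, first_mix.regen_rate,
                            first_mix.pibip_explicit, t_age,
                            rtol, atol, method)[:, -1]
    y0 = y_aged / dilution + second_mix_additions.to_vector()

    regen_rate = max(first_mix.regen_rate, second_mix_additions.regen_rate)
    pibip_explicit = first_mix.pibip_explicit or second_mix_additions.pibip_explicit
    t_grid = np.asarray(t_grid, dtype=float)
    ys = _integrate(y0, rates, rna, regen_rate, pibip_explicit,
                    t_grid if t_grid[0] == 0 else np.concatenate([[0.0], t_grid]),
                    rtol, atol, method)
    if t_grid[0] > 0:
        ys = ys[:, 1:]
    start = MixState.from_vector(y0, regen_rate=regen_rate,
                                 pibip_explicit=pibip_explicit)
    signal = _observable(ys, observable_kind, start)
    trace = KineticTrace(
        time=t_grid, signal=signal, observable_kind=observable_kind,
        meta={"protocol": "dual_mix", "age_time": age_time,
              "dilution": dilution, "first_mix": _state_meta(first_mix),
              "additions": _state_meta(second_mix_additions),
              "rates": rates.to_dict(),
              "rna": rna.to_dict() if rna else None},
    )
    trace.species = pd.DataFrame(ys.T, index=t_grid, columns=SPECIES)
    return trace


# ---------------------------------------------------------------------------
# packaged parameter presets


def preset_rates(name: str) -> RateConstants:
    """Load a packaged rate-constant preset.

    ``table1`` – experimentally determined transient-kinetics constants;
    ``table2_nadh`` / ``table2_pibip`` – global-fit constants from the
    NADH-coupled and phosphate-sensor datasets.
    """
    ref = importlib.resources.files("dbp5kinetics") / "presets" / f"{name}.yaml"
    if not ref.is_file():
        raise FileNotFoundError(f"no preset named {name!r}")
    data = yaml.safe_load(ref.read_text())
    return RateConstants.from_dict(data["rates"])


def preset_rna(name: str = "rna_default") -> RnaRateConstants:
    """Load the packaged RNA-branch parameter preset."""
    ref = importlib.resources.files("dbp5kinetics") / "presets" / f"{name}.yaml"
    data = yaml.safe_load(ref.read_text())
    return RnaRateConstants.from_dict(data["rna"])
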