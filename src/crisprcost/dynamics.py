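"""Serial-transfer eco-evolutionary model of phage-challenged bacterial populations.

Three bacterial genotypes compete in daily 1:100 batch-transfer culture with
phage re-added every day:

* ``S`` -- phage-sensitive bacteria, lysed on infection;
* ``C`` -- CRISPR-immune bacteria, which clear infections but pay an *induced*
  cost: with probability ``tau_tox + p * q_self`` an infection kills the cell
  (toxicity of phage gene expression before clearance, plus lethal
  self-targeting spacer acquisition);
* ``M`` -- surface mutants that cannot be adsorbed at all and instead pay a
  small *constitutive* growth-rate cost ``c_sm``.

Within a day the populations follow Lotka-Volterra dynamics with shared
logistic resource limitation:

    dS/dt = r*S*(1 - N/K) - a*S*V
    dC/dt = r*C*(1 - N/K) - a*C*V*(tau_tox + p*q_self)
    dM/dt = r*(1 - c_sm)*M*(1 - N/K)
    dV/dt = b*a*S*V - a*(S + C)*V - d*V,         N = S + C + M

Every adsorption removes a phage particle; only infections of ``S`` burst.
At each transfer all densities are diluted 1:100 and fresh phage is added.

An optional escape-phage compartment ``W`` (off by default, enabled through
``ModelParams.escape_mu > 0``) models target-site escape mutants that arise at
rate ``escape_mu`` per burst particle and infect CRISPR-immune hosts with
reduced efficiency ``escape_infectivity`` (residual targeting by remaining
spacers). The escape class is what allows phage pressure to outlive the
collapse of the sensitive population, and with it the characteristic
trajectory of the 30-day evolution experiment: CRISPR immunity sweeps first,
surface mutants overtake later.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "PopulationState",
    "ModelParams",
    "TransferProtocol",
    "Trajectory",
    "within_day_derivative",
    "integrate_day",
    "apply_transfer",
    "run_serial_transfer",
    "run_scenarios",
    "classify_outcome",
    "baseline_params",
    "evolution_experiment_params",
    "SCENARIOS",
]


class DynamicsError(ValueError):
    """Invalid state or parameters for the population model."""


class IntegrationError(RuntimeError):
    """The ODE solver failed; carries the state at failure."""

    def __init__(self, message: str, state: "PopulationState | None" = None):
        super().__init__(message)
        self.state = state


@dataclass(frozen=True)
class PopulationState:
    """Densities (per mL) of the three bacterial genotypes and phage at time t (h).

    ``W`` is the escape-phage density; it stays 0 unless escape evolution is
    enabled in the parameters.
    """

    S: float
    C: float
    M: float
    V: float
    t: float = 0.0
    W: float = 0.0

    def __post_init__(self):
        for name in ("S", "C", "M", "V", "W"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise DynamicsError(f"non-finite density {name}={v!r}")
            if v < 0:
                raise DynamicsError(f"negative density {name}={v!r}")

    @property
    def total_bacteria(self) -> float:
        return self.S + self.C + self.M

    def frequencies(self) -> tuple[float, float, float]:
        """Genotype frequencies among bacteria; NaNs if the culture is empty."""
        n = self.total_bacteria
        if n <= 0:
            return (math.nan, math.nan, math.nan)
        return (self.S / n, self.C / n, self.M / n)

    def as_array(self) -> np.ndarray:
        return np.array([self.S, self.C, self.M, self.V, self.W], dtype=float)

    @classmethod
    def from_array(cls, y: Sequence[float], t: float = 0.0) -> "PopulationState":
        y = np.maximum(np.asarray(y, dtype=float), 0.0)
        return cls(S=y[0], C=y[1], M=y[2], V=y[3], t=t, W=y[4] if len(y) > 4 else 0.0)


@dataclass(frozen=True)
class ModelParams:
    """Rate constants of the within-day model.

    Parameters
    ----------
    r : maximal bacterial growth rate (per h).
    K : carrying capacity (CFU/mL).
    c_sm : constitutive growth-rate cost of surface mutation, in [0, 1).
    a : phage adsorption rate constant (mL/h).
    b : burst size (phage per lysis).
    d : free-phage decay rate (per h).
    tau_tox : probability that an infection of a CRISPR-immune cell kills it
        (the induced toxicity cost), in [0, 1].
    p : probability of spacer acquisition per surviving infection, in [0, 1].
    q_self : fraction of acquisitions that are self-targeting (lethal), in [0, 1].
    mu_sm : per-division rate of surface-mutant generation from S.
    mu_bim : per-infection rate at which infected S acquire immunity and join C.
    escape_mu : probability that a burst particle is a target-site escape
        mutant; 0 disables the escape compartment (the core model).
    escape_infectivity : relative efficiency with which escape phage adsorb to
        and lyse CRISPR-immune hosts, in [0, 1].
    """

    r: float = 1.0
    K: float = 1e9
    c_sm: float = 0.001
    a: float = 1e-9
    b: float = 50.0
    d: float = 0.1
    tau_tox: float = 0.05
    p: float = 0.01
    q_self: float = 0.0
    mu_sm: float = 0.0
    mu_bim: float = 0.0
    escape_mu: float = 0.0
    escape_infectivity: float = 0.015

    def __post_init__(self):
        for name in ("r", "K", "a", "b", "d", "mu_sm", "mu_bim"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise DynamicsError(f"parameter {name}={v!r} must be finite and >= 0")
        for name in ("tau_tox", "p", "q_self", "escape_mu", "escape_infectivity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise DynamicsError(f"parameter {name}={v!r} must lie in [0, 1]")
        if not 0.0 <= self.c_sm < 1.0:
            raise DynamicsError(f"c_sm={self.c_sm!r} must lie in [0, 1)")


@dataclass(frozen=True)
class TransferProtocol:
    """Daily serial-transfer regime: 1:100 dilution into 6 mL with 10^7 PFU
    of ancestral phage re-added each day for 30 days."""

    dilution: float = 0.01
    phage_added: float = 1e7
    culture_volume: float = 6.0
    n_days: int = 30
    day_length: float = 24.0
    S0: float = 1e6
    V0: float = 1e7
    initial_freqs: tuple[float, float, float] = (0.45, 0.45, 0.10)

    def __post_init__(self):
        if not 0.0 < self.dilution < 1.0:
            raise DynamicsError(f"dilution={self.dilution!r} must lie in (0, 1)")
        for name in ("phage_added", "culture_volume", "day_length", "S0", "V0"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise DynamicsError(f"{name}={v!r} must be finite and >= 0")
        if self.culture_volume <= 0:
            raise DynamicsError("culture_volume must be > 0")
        if self.n_days < 0:
            raise DynamicsError("n_days must be >= 0")
        f = self.initial_freqs
        if len(f) != 3 or any(x < 0 for x in f) or abs(sum(f) - 1.0) > 1e-9:
            raise DynamicsError(f"initial_freqs={f!r} must be 3 non-negative values summing to 1")

    def initial_state(self) -> PopulationState:
        """Inoculum densities per mL: total cells and PFU divided by culture volume."""
        n0 = self.S0 / self.culture_volume
        fs, fc, fm = self.initial_freqs
        return PopulationState(S=fs * n0, C=fc * n0, M=fm * n0,
                               V=self.V0 / self.culture_volume, t=0.0)


@dataclass
class Trajectory:
    """End-of-day population states over a serial-transfer experiment.

    ``states[0]`` is the initial (day-0) state; ``states[i]`` for i >= 1 is the
    state at the end of day i, before the transfer.
    """

    states: list[PopulationState] = field(default_factory=list)
    params: ModelParams | None = None
    protocol: TransferProtocol | None = None

    def __len__(self) -> int:
        return len(self.states)

    @property
    def days(self) -> np.ndarray:
        return np.arange(len(self.states))

    def frequencies(self) -> np.ndarray:
        """(n_days+1, 3) array of genotype frequencies (S, C, M)."""
        return np.array([s.frequencies() for s in self.states])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for day, s in enumerate(self.states):
            fs, fc, fm = s.frequencies()
            rows.append(dict(day=day, S=s.S, C=s.C, M=s.M, V=s.V, W=s.W,
                             freq_S=fs, freq_C=fc, freq_M=fm))
        return pd.DataFrame(rows)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


def within_day_derivative(state: PopulationState, params: ModelParams) -> tuple[float, ...]:
    """Time-derivatives (dS, dC, dM, dV[, dW]) of the within-day model.

    Returns a 4-tuple for the core model and a 5-tuple when the escape
    compartment is active (``escape_mu > 0`` or ``state.W > 0``).
    """
    d = _derivative(state.as_array(), params)
    if params.escape_mu > 0 or state.W > 0:
        return tuple(d)
    return tuple(d[:4])


def _derivative(y: np.ndarray, p: ModelParams) -> np.ndarray:
    S, C, M, V, W = np.maximum(y, 0.0)
    N = S + C + M
    g = 1.0 - N / p.K
    growth_S = p.r * S * g
    inf_S = p.a * S * V                      # ancestral phage adsorptions to S
    kill_C = p.a * C * V * (p.tau_tox + p.p * p.q_self)
    esc_inf_C = p.a * p.escape_infectivity * C * W   # escape phage lyse C
    dS = growth_S * (1.0 - p.mu_sm) - inf_S - p.a * S * W
    dC = p.r * C * g + p.mu_bim * inf_S - kill_C - esc_inf_C
    dM = p.r * (1.0 - p.c_sm) * M * g + p.mu_sm * growth_S
    dV = p.b * inf_S * (1.0 - p.escape_mu - p.mu_bim) - p.a * (S + C) * V - p.d * V
    dW = (p.b * inf_S * p.escape_mu + p.b * p.a * S * W + p.b * esc_inf_C
          - p.a * S * W - p.a * p.escape_infectivity * C * W - p.d * W)
    return np.array([dS, dC, dM, dV, dW])


def integrate_day(state: PopulationState, params: ModelParams,
                  day_length: float = 24.0, rtol: float = 1e-8,
                  atol: float = 1e-10) -> PopulationState:
    """Integrate the within-day ODEs over one growth period.

    Uses LSODA with adaptive step control (the system is stiff during phage
    blooms). Densities are clipped at zero on return.
    """
    if day_length <= 0:
        raise DynamicsError(f"day_length={day_length!r} must be > 0")
    y0 = state.as_array()
    if not y0.any():
        return PopulationState.from_array(y0, t=state.t + day_length)
    sol = solve_ivp(lambda t, y: _derivative(y, params), (0.0, day_length), y0,
                    method="LSODA", rtol=rtol, atol=atol)
    if not sol.success:
        raise IntegrationError(
            f"ODE integration failed: {sol.message}; state={state!r}", state)
    return PopulationState.from_array(sol.y[:, -1], t=state.t + day_length)


def apply_transfer(state: PopulationState, protocol: TransferProtocol) -> PopulationState:
    """1:100 (by default) dilution followed by re-addition of ancestral phage."""
    y = state.as_array() * protocol.dilution
    y[3] += protocol.phage_added / protocol.culture_volume
    return PopulationState.from_array(y, t=state.t)


def run_serial_transfer(params: ModelParams | None = None,
                        protocol: TransferProtocol | None = None) -> Trajectory:
    """Alternate within-day growth and daily transfer for ``protocol.n_days`` days.

    Deterministic; records the end-of-day state (pre-transfer) for each day
    plus the initial state at day 0.
    """
    params = params if params is not None else baseline_params()
    protocol = protocol if protocol is not None else TransferProtocol()
    state = protocol.initial_state()
    traj = Trajectory(states=[state], params=params, protocol=protocol)
    for day in range(protocol.n_days):
        try:
            grown = integrate_day(state, params, protocol.day_length)
        except IntegrationError as err:
            raise IntegrationError(f"day {day + 1}: {err}", err.state) from err
        traj.states.append(grown)
        state = apply_transfer(grown, protocol)
    return traj


def classify_outcome(trajectory: Trajectory,
                     tol: float = 1e-3,
                     culture_volume: float | None = None) -> str:
    """Classify the fate of the CRISPR genotype relative to the surface mutant.

    Returns ``"extinct"`` if the final C density corresponds to less than one
    cell per culture, ``"decline"`` if the final C:M frequency ratio fell below
    the initial ratio by more than the relative tolerance, else ``"no_decline"``.
    """
    if len(trajectory) < 2:
        raise DynamicsError("trajectory must contain at least 2 states")
    vol = culture_volume
    if vol is None:
        vol = trajectory.protocol.culture_volume if trajectory.protocol else 6.0
    first, last = trajectory.states[0], trajectory.states[-1]
    if last.C * vol < 1.0:
        return "extinct"
    f0, fT = first.frequencies(), last.frequencies()
    if f0[2] <= 0 or fT[2] <= 0:      # no surface mutant to compare against
        return "no_decline"
    r0, rT = f0[1] / f0[2], fT[1] / fT[2]
    return "decline" if rT < r0 * (1.0 - tol) else "no_decline"


def baseline_params() -> ModelParams:
    """Baseline parameterisation of the core (escape-free) model."""
    return ModelParams()


def evolution_experiment_params() -> ModelParams:
    """Baseline with the escape-phage extension enabled.

    Emulates the 30-day evolution experiment, where target-site escape phage
    arise during amplification on sensitive hosts and later erode the
    CRISPR-immune population, letting surface mutants take over.
    """
    return ModelParams(escape_mu=1e-5, escape_infectivity=0.015)


#: Scenario set contrasting the candidate mechanisms for the cost of CRISPR
#: immunity: an induced (infection-dependent) cost alone; no cost and no spacer
#: acquisition; no induced cost but frequent lethal self-targeting acquisition.
SCENARIOS: dict[str, dict[str, float]] = {
    "baseline": dict(tau_tox=0.05, p=0.01, q_self=0.0),
    "no_cost_no_acquisition": dict(tau_tox=0.0, p=0.0, q_self=0.0),
    "no_cost_high_self_targeting": dict(tau_tox=0.0, p=0.25, q_self=0.8),
}


def run_scenarios(protocol: TransferProtocol | None = None,
                  base: ModelParams | None = None) -> pd.DataFrame:
    """Run the named scenario set and classify each outcome.

    Returns a table with one row per scenario: parameter overrides, initial
    and final C:M frequency ratios, final frequencies and the classification.
    """
    protocol = protocol if protocol is not None else TransferProtocol()
    base = base if base is not None else baseline_params()
    rows = []
    for name, overrides in SCENARIOS.items():
        params = replace(base, **overrides)
        traj = run_serial_transfer(params, protocol)
        f0 = traj.states[0].frequencies()
        fT = traj.states[-1].frequencies()
        rows.append(dict(
            scenario=name,
            tau_tox=params.tau_tox, p=params.p, q_self=params.q_self,
            initial_CM_ratio=f0[1] / f0[2] if f0[2] > 0 else math.inf,
            final_CM_ratio=fT[1] / fT[2] if fT[2] > 0 else math.inf,
            final_freq_C=fT[1], final_freq_M=fT[2],
            outcome=classify_outcome(traj),
        ))
    return pd.DataFrame(rows)


def scenarios_to_json(table: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        json.dump(table.to_dict(orient="records"), fh, indent=2)
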