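"""Compartmental structure, parameters and vector field of the behavior-SEIR model.

The population of constant size N0 is split into two susceptible groups
S_{-1}, S_{+1} (differing in behavioral response profile), exposed E,
asymptomatic Ia, symptomatic Is, detected-and-isolated Id, and removed R.
Exposed individuals leave incubation at rate theta; a fraction pi is
detected early (E -> Id), the rest split sigma : (1-sigma) into symptomatic
and asymptomatic infectious, who are detected at rates gamma_s, gamma_a and
removed at rates rho_s, rho_a; detected cases are removed at rho_d.

Transmission uses quarantine-adjusted incidence: detected cases are
isolated, so the mixing denominator is N - Id, and each susceptible group's
effective contact rate is reduced by the factor (1 - kappa*m_i) where m_i
is its prophylactic proportion.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np

from .behavior import BehaviorProfile, RiskSignal, prophylactic_proportion

__all__ = [
    "DiseaseParams",
    "StateVector",
    "ReproductionSeries",
    "STATE_NAMES",
    "detected_incidence",
    "force_of_infection",
    "system_rhs",
    "behaviorless_reproduction_number",
    "basic_reproduction_number",
]

STATE_NAMES = ("S_m1", "S_p1", "E", "Ia", "Is", "Id", "R")


@dataclass(frozen=True)
class DiseaseParams:
    """Disease and information-flow constants (rates per day).

    Defaults are the reference parameterization used throughout: baseline
    contact rate beta0 = 1/day, certain transmission on contact
    (phi_a = phi_s = 1), prophylactic efficiency kappa = 9/10, mean
    incubation 1/theta = 4 days, early-detection probability pi = 1/2,
    symptomatic fraction sigma = 1/2, detection rates gamma_a = 2/70,
    gamma_s = 4/70, removal rates rho_a = 3/70, rho_s = 1/70, rho_d = 1/70,
    and information delay tau = 3 days.  Rate constants are entered as
    exact fractions to avoid decimal drift.
    """

    beta0: float = 1.0
    phi_a: float = 1.0
    phi_s: float = 1.0
    kappa: float = 0.9
    theta: float = 0.25
    pi: float = 0.5
    sigma: float = 0.5
    gamma_a: float = float(Fraction(2, 70))
    gamma_s: float = float(Fraction(4, 70))
    rho_a: float = float(Fraction(3, 70))
    rho_s: float = float(Fraction(1, 70))
    rho_d: float = float(Fraction(1, 70))
    tau: float = 3.0

    def __post_init__(self) -> None:
        rates = {
            "beta0": self.beta0, "theta": self.theta,
            "gamma_a": self.gamma_a, "gamma_s": self.gamma_s,
            "rho_a": self.rho_a, "rho_s": self.rho_s, "rho_d": self.rho_d,
        }
        for name, v in rates.items():
            if not np.isfinite(v) or v < 0.0:
                raise ValueError(f"{name} must be a finite non-negative rate, got {v}")
        probs = {"phi_a": self.phi_a, "phi_s": self.phi_s, "kappa": self.kappa,
                 "pi": self.pi, "sigma": self.sigma}
        for name, v in probs.items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.tau < 0.0:
            raise ValueError(f"tau must be >= 0, got {self.tau}")

    def replace(self, **changes) -> "DiseaseParams":
        return replace(self, **changes)

    def to_array(self) -> np.ndarray:
        """Packed parameter vector for the compiled solver core."""
        return np.array(
            [self.beta0, self.phi_a, self.phi_s, self.kappa, self.theta,
             self.pi, self.sigma, self.gamma_a, self.gamma_s,
             self.rho_a, self.rho_s, self.rho_d, self.tau],
            dtype=np.float64,
        )


@dataclass(frozen=True)
class StateVector:
    """Compartment counts at one time point (individuals, non-negative)."""

    S_m1: float = 49_998.0
    S_p1: float = 49_998.0
    E: float = 2.0
    Ia: float = 1.0
    Is: float = 1.0
    Id: float = 0.0
    R: float = 0.0

    @property
    def N0(self) -> float:
        return self.S_m1 + self.S_p1 + self.E + self.Ia + self.Is + self.Id + self.R

    @property
    def S(self) -> float:
        return self.S_m1 + self.S_p1

    @property
    def infected(self) -> float:
        """Infected-or-incubating individuals (E + Ia + Is + Id)."""
        return self.E + self.Ia + self.Is + self.Id

    def as_array(self) -> np.ndarray:
        return np.array([self.S_m1, self.S_p1, self.E, self.Ia, self.Is,
                         self.Id, self.R], dtype=np.float64)

    @classmethod
    def from_array(cls, y: np.ndarray) -> "StateVector":
        return cls(*map(float, y))


def detected_incidence(state, params: DiseaseParams) -> float:
    """New detected cases per day, C = pi*theta*E + gamma_a*Ia + gamma_s*Is."""
    y = state.as_array() if isinstance(state, StateVector) else np.asarray(state)
    return float(params.pi * params.theta * y[2]
                 + params.gamma_a * y[3] + params.gamma_s * y[4])


def force_of_infection(state, m: float, params: DiseaseParams) -> float:
    """Per-capita infection rate of a susceptible group with proportion m prophylactic.

    lambda = beta0*(1 - kappa*m) * (phi_a*Ia + phi_s*Is) / (N - Id)
    """
    y = state.as_array() if isinstance(state, StateVector) else np.asarray(state)
    N = float(np.sum(y))
    denom = N - y[5]
    if denom <= 0.0:
        raise ValueError("degenerate population: N - Id <= 0")
    return float(params.beta0 * (1.0 - params.kappa * m)
                 * (params.phi_a * y[3] + params.phi_s * y[4]) / denom)


def system_rhs(
    t: float,
    y: np.ndarray,
    signals: tuple[RiskSignal, RiskSignal],
    profiles: tuple[BehaviorProfile, BehaviorProfile],
    params: DiseaseParams,
) -> np.ndarray:
    """Vector field of the behavior-SEIR system given delayed risk signals.

    ``signals`` must already be evaluated at t - tau (zero before tau).
    The returned derivative conserves the population (components sum to 0).
    This reference implementation is plain Python; the delay solver uses a
    separately compiled equivalent.
    """
    y = np.asarray(y, dtype=float)
    S = y[:2]
    E, Ia, Is, Id = y[2], y[3], y[4], y[5]
    p = params
    N = float(np.sum(y))
    denom = N - Id
    if denom <= 0.0:
        raise ValueError("degenerate population: N - Id <= 0")
    infectious_pressure = (p.phi_a * Ia + p.phi_s * Is) / denom

    lam = np.empty(2)
    for i in (0, 1):
        m_i = prophylactic_proportion(signals[i].eta(profiles[i]), profiles[i])
        lam[i] = p.beta0 * (1.0 - p.kappa * m_i) * infectious_pressure

    inflow = lam[0] * S[0] + lam[1] * S[1]
    exit_E = p.theta * E
    dy = np.empty(7)
    dy[0] = -lam[0] * S[0]
    dy[1] = -lam[1] * S[1]
    dy[2] = inflow - exit_E
    dy[3] = (1.0 - p.sigma) * (1.0 - p.pi) * exit_E - (p.gamma_a + p.rho_a) * Ia
    dy[4] = p.sigma * (1.0 - p.pi) * exit_E - (p.gamma_s + p.rho_s) * Is
    dy[5] = p.pi * exit_E + p.gamma_a * Ia + p.gamma_s * Is - p.rho_d * Id
    dy[6] = p.rho_a * Ia + p.rho_s * Is + p.rho_d * Id
    return dy


def behaviorless_reproduction_number(params: DiseaseParams) -> float:
    """Reproductive number with no prophylactic behavior (m = 0 everywhere).

    R_o = beta0*(1-pi) * [phi_a*(1-sigma)/(gamma_a+rho_a) + phi_s*sigma/(gamma_s+rho_s)]
    """
    p = params
    return p.beta0 * (1.0 - p.pi) * (
        p.phi_a * (1.0 - p.sigma) / (p.gamma_a + p.rho_a)
        + p.phi_s * p.sigma / (p.gamma_s + p.rho_s)
    )


def basic_reproduction_number(
    initial: StateVector,
    profiles: tuple[BehaviorProfile, BehaviorProfile],
    params: DiseaseParams,
) -> float:
    """Basic reproductive number at outbreak, R(0) = R_o * sum_i S_i0/N0 * (1-kappa*m_i0)."""
    Ro = behaviorless_reproduction_number(params)
    N0 = initial.N0
    return Ro * (
        initial.S_m1 / N0 * (1.0 - params.kappa * profiles[0].m0)
        + initial.S_p1 / N0 * (1.0 - params.kappa * profiles[1].m0)
    )


@dataclass(frozen=True)
class ReproductionSeries:
    """Behavior-free, basic and effective reproductive numbers of a run.

    ``Rt`` is the susceptible-weighted average of the per-group series
    ``Rti`` (columns: group -1, group +1).
    """

    R_o: float
    R0: float
    t: np.ndarray = field(repr=False)
    Rt: np.ndarray = field(repr=False)
    Rti: np.ndarray = field(repr=False)
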