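"""Delay-system solver: method of steps with dense history interpolation.

The force of infection depends on risk information delayed by a single
constant tau — the detected prevalence P(t) = Id(t-tau)/N(t-tau) and the
relative incidence trend Q(t) = Cdot(t-tau)/C(t-tau), which involves the
derivative of the state history (a neutral delay term).  Integration
therefore proceeds so that no step crosses a multiple of tau: every
delayed lookup then falls in already-completed history, interpolated with
cubic Hermite polynomials.  Cdot is evaluated by central finite
differencing of the interpolated incidence series (half-step ``h``), which
avoids recursing into t - 2*tau and is second-order accurate.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np
import pandas as pd

from . import _core
from .behavior import BehaviorProfile, RiskSignal
from .epidemic import (
    STATE_NAMES,
    DiseaseParams,
    ReproductionSeries,
    StateVector,
    basic_reproduction_number,
    behaviorless_reproduction_number,
)

__all__ = ["SolverSettings", "HistoryBuffer", "Trajectory", "delayed_signal", "solve"]


@dataclass(frozen=True)
class SolverSettings:
    """Numerical knobs of the delay solver.

    rtol, atol
        Local error tolerances; ``atol=None`` resolves to 1e-10 * N0.
    max_step
        Hard cap on the step size (days); ``None`` resolves to the delay
        tau (or 0.5 day when tau = 0).
    output_dt
        Spacing of the sampled output grid in days.
    fd_half_step
        Half-step h (days) of the finite difference used for Cdot.
    q_floor
        Incidence level (cases/day) below which C is treated as zero and
        Q is set to 0, guarding floating-point underflow near extinction.
    """

    rtol: float = 1e-8
    atol: float | None = None
    max_step: float | None = None
    output_dt: float = 0.5
    fd_half_step: float = 1e-3
    q_floor: float = 1e-9
    max_knots: int = 200_000

    def __post_init__(self) -> None:
        if self.rtol <= 0 or (self.atol is not None and self.atol <= 0):
            raise ValueError("tolerances must be positive")
        if self.output_dt <= 0 or self.fd_half_step <= 0:
            raise ValueError("output_dt and fd_half_step must be positive")


class HistoryBuffer:
    """Dense solution history: knots (t, y, y') with cubic Hermite queries.

    Queries before t = 0 return the initial state.
    """

    def __init__(self, ts: np.ndarray, ys: np.ndarray, fs: np.ndarray,
                 params: DiseaseParams):
        self.ts = np.ascontiguousarray(ts, dtype=np.float64)
        self.ys = np.ascontiguousarray(ys, dtype=np.float64)
        self.fs = np.ascontiguousarray(fs, dtype=np.float64)
        self.params = params
        self._p = params.to_array()
        self.n = self.ts.shape[0]
        self.N0 = float(self.ys[0].sum())

    @classmethod
    def from_states(cls, ts: np.ndarray, ys: np.ndarray, params: DiseaseParams) -> "HistoryBuffer":
        """Build a buffer from sampled states, differencing for the knot slopes."""
        ts = np.asarray(ts, dtype=float)
        ys = np.asarray(ys, dtype=float)
        fs = np.gradient(ys, ts, axis=0)
        return cls(ts, ys, fs, params)

    @property
    def t_end(self) -> float:
        return float(self.ts[self.n - 1])

    def state(self, u: float) -> np.ndarray:
        """Interpolated compartment vector at time u (initial state for u < 0)."""
        return _core.sample_states(self.ts, self.ys, self.fs, self.n,
                                   np.array([float(u)]))[0]

    def incidence(self, u) -> np.ndarray | float:
        """Interpolated detected incidence C(u) = pi*theta*E + ga*Ia + gs*Is."""
        u_arr = np.atleast_1d(np.asarray(u, dtype=float))
        states = _core.sample_states(self.ts, self.ys, self.fs, self.n, u_arr)
        p = self.params
        C = p.pi * p.theta * states[:, 2] + p.gamma_a * states[:, 3] + p.gamma_s * states[:, 4]
        return float(C[0]) if np.isscalar(u) or np.ndim(u) == 0 else C

    def signal(self, t: float, tau: float | None = None,
               settings: SolverSettings | None = None) -> RiskSignal:
        settings = settings or SolverSettings()
        p = self._p.copy()
        if tau is not None:
            p[12] = tau
        if p[12] > 0 and t >= p[12] and t - p[12] > self.t_end:
            raise RuntimeError(
                f"delayed lookup at t-tau={t - p[12]:g} beyond history end {self.t_end:g}"
            )
        P, Q = _core.sample_signal(self.ts, self.ys, self.fs, self.n,
                                   np.array([float(t)]), p, self.N0,
                                   settings.fd_half_step, settings.q_floor)
        return RiskSignal(P=float(P[0]), Q=float(Q[0]))


def delayed_signal(history: HistoryBuffer, t: float, tau: float,
                   params: DiseaseParams | None = None,
                   settings: SolverSettings | None = None) -> RiskSignal:
    """Risk signal (P, Q) available at time t given the information delay tau.

    Zero up to and including t = tau; otherwise P = Id(t-tau)/N(t-tau) and
    Q = Cdot(t-tau)/C(t-tau) with Cdot from a finite difference of the
    interpolated incidence history.
    """
    return history.signal(t, tau=tau, settings=settings)


class Trajectory:
    """Dense solution of one behavior-SEIR run with derived series.

    Attributes
    ----------
    t : output-grid times (days)
    states : len(t) x 7 compartment matrix (columns ``STATE_NAMES``)
    C : new detected cases per day on the output grid
    m : len(t) x 2 prophylactic proportions (group -1, group +1)
    P, Q : delayed risk signal on the output grid
    """

    def __init__(self, history: HistoryBuffer,
                 profiles: tuple[BehaviorProfile, BehaviorProfile],
                 params: DiseaseParams, initial: StateVector,
                 settings: SolverSettings, stats: dict):
        self.history = history
        self.profiles = profiles
        self.params = params
        self.initial = initial
        self.settings = settings
        self.stats = stats
        self.N0 = initial.N0

        horizon = history.t_end
        n_out = int(round(horizon / settings.output_dt))
        self.t = np.linspace(0.0, horizon, n_out + 1)
        self.states = _core.sample_states(history.ts, history.ys, history.fs,
                                          history.n, self.t)
        p = params
        self.C = (p.pi * p.theta * self.states[:, 2]
                  + p.gamma_a * self.states[:, 3] + p.gamma_s * self.states[:, 4])
        self.P, self.Q = _core.sample_signal(
            history.ts, history.ys, history.fs, history.n, self.t,
            params.to_array(), self.N0, settings.fd_half_step, settings.q_floor)
        from .behavior import information_aggregate, prophylactic_proportion
        self.m = np.column_stack([
            prophylactic_proportion(
                information_aggregate(self.P, self.Q, prof), prof)
            for prof in profiles
        ])

    @property
    def horizon(self) -> float:
        return float(self.t[-1])

    @cached_property
    def reproduction(self) -> ReproductionSeries:
        """Behavior-free, basic and effective reproductive numbers."""
        p = self.params
        Ro = behaviorless_reproduction_number(p)
        R0 = basic_reproduction_number(self.initial, self.profiles, p)
        S = self.states[:, 0] + self.states[:, 1]
        denom = self.N0 - self.states[:, 5]
        Rti = Ro * (S / denom)[:, None] * (1.0 - p.kappa * self.m)
        with np.errstate(invalid="ignore", divide="ignore"):
            w = self.states[:, :2] / np.where(S > 0, S, np.nan)[:, None]
        Rt = np.nansum(w * Rti, axis=1)
        return ReproductionSeries(R_o=Ro, R0=R0, t=self.t, Rt=Rt, Rti=Rti)

    def daily_incidence(self) -> pd.Series:
        """C(t) sampled at integer days (the observable the wave rules use)."""
        days = np.arange(0, int(np.floor(self.horizon)) + 1)
        idx = np.searchsorted(self.t, days)
        return pd.Series(self.C[idx], index=days, name="C")

    @property
    def peak_incidence(self) -> float:
        """Maximum detected incidence on the output grid."""
        return float(self.C.max())

    @property
    def peak_time(self) -> float:
        return float(self.t[int(np.argmax(self.C))])

    def final_size(self, T: float | None = None) -> float:
        """F_T = 1 - S(T)/N0, the cumulative infected fraction by horizon T."""
        T = self.horizon if T is None else T
        i = int(np.searchsorted(self.t, T, side="right")) - 1
        S_T = self.states[i, 0] + self.states[i, 1]
        return float(1.0 - S_T / self.N0)

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: time, compartments, C, m_m1, m_p1, Rt."""
        df = pd.DataFrame(self.states, columns=list(STATE_NAMES))
        df.insert(0, "time", self.t)
        df["C"] = self.C
        df["m_m1"] = self.m[:, 0]
        df["m_p1"] = self.m[:, 1]
        df["Rt"] = self.reproduction.Rt
        return df

    def conservation_error(self) -> float:
        """max_t |sum of compartments - N0|."""
        return float(np.abs(self.states.sum(axis=1) - self.N0).max())


class SolverError(RuntimeError):
    """Raised when the step controller fails or invariants are violated."""


def solve(
    profiles: BehaviorProfile | tuple[BehaviorProfile, BehaviorProfile],
    params: DiseaseParams,
    initial: StateVector | None = None,
    horizon: float = 1000.0,
    settings: SolverSettings | None = None,
) -> Trajectory:
    """Solve the behavior-SEIR delay system on [0, horizon].

    A single profile is applied to both susceptible groups (homogeneous
    population); a pair assigns the first profile to S_{-1} and the second
    to S_{+1}.  For t <= tau the risk signal is zero, so behavior stays at
    its disease-free level m_i0.
    """
    if isinstance(profiles, BehaviorProfile):
        profiles = (profiles, profiles)
    if len(profiles) != 2:
        raise ValueError("profiles must be a single profile or a pair")
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    initial = initial or StateVector()
    settings = settings or SolverSettings()

    N0 = initial.N0
    atol = settings.atol if settings.atol is not None else 1e-10 * N0
    tau = params.tau
    max_step = settings.max_step
    if max_step is None:
        max_step = tau if tau > 0 else 0.5

    p = params.to_array()
    bp = np.vstack([prof.weights_array() for prof in profiles])
    y0 = initial.as_array()

    nmax = settings.max_knots
    for attempt in range(3):
        ts, ys, fs, n, status, n_acc, n_rej = _core.solve_core(
            p, bp, y0, float(horizon), settings.rtol, atol,
            settings.fd_half_step, settings.q_floor, float(max_step), nmax)
        if status != _core.STATUS_BUFFER_FULL:
            break
        nmax *= 4
    if status == _core.STATUS_STEP_UNDERFLOW:
        raise SolverError("step size underflow: tolerance cannot be met")
    if status == _core.STATUS_BUFFER_FULL:
        raise SolverError(f"history buffer exhausted at {nmax} knots")

    history = HistoryBuffer(ts[:n].copy(), ys[:n].copy(), fs[:n].copy(), params)
    stats = {"n_steps": n_acc, "n_rejected": n_rej, "n_knots": n}
    traj = Trajectory(history, tuple(profiles), params, initial, settings, stats)

    if traj.states.min() < -1e-6 * N0:
        raise SolverError(
            f"negative compartment beyond tolerance: min={traj.states.min():g}")
    if traj.conservation_error() > 1e-6 * N0:
        raise SolverError(
            f"population conservation violated: {traj.conservation_error():g}")
    return traj
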