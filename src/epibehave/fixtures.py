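"""Synthetic forcing curves for exercising the behavior pathway in isolation.

A prescribed single-pulse daily-incidence curve (a logistic-derivative
pulse peaking at N0/4) stands in for the epidemic side, so the perceived
prevalence P, trend signal Q, information aggregate and prophylactic
proportion can be computed and inspected without solving the delay system.
The forced pathway reuses exactly the operations of :mod:`.behavior`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_simpson

from .behavior import BehaviorProfile, information_aggregate, prophylactic_proportion

__all__ = ["FixtureCurve", "logistic_pulse", "detected_pool", "behavior_under_forcing"]


@dataclass(frozen=True)
class FixtureCurve:
    """Symmetric single-pulse incidence curve C(t) = N0 e^v / (1+e^v)^2.

    ``v = (t - center)/width``; the analytic maximum is N0/4 at t=center
    and the total pulse mass is N0 * width (times the unnormalized form).
    """

    N0: float
    center: float
    width: float
    t: np.ndarray = field(repr=False)
    C: np.ndarray = field(repr=False)

    def __call__(self, u):
        """Evaluate the analytic pulse at arbitrary times."""
        v = (np.asarray(u, dtype=float) - self.center) / self.width
        ev = np.exp(-np.abs(v))  # overflow-safe: e^v/(1+e^v)^2 is even in v
        return self.N0 * ev / (1.0 + ev) ** 2

    def derivative(self, u):
        """Analytic dC/dt of the pulse."""
        v = (np.asarray(u, dtype=float) - self.center) / self.width
        C = self(u)
        return -C * np.tanh(v / 2.0) / self.width


def logistic_pulse(N0: float = 100_000.0, center: float = 50.0,
                   width: float = 8.0, horizon: float = 150.0,
                   dt: float = 1.0) -> FixtureCurve:
    """Daily-sampled logistic incidence pulse used by the figure-style runs."""
    if width <= 0:
        raise ValueError("width must be positive")
    t = np.arange(0.0, horizon + 0.5 * dt, dt)
    curve = FixtureCurve(N0=N0, center=center, width=width, t=t, C=np.empty(0))
    object.__setattr__(curve, "t", t)
    object.__setattr__(curve, "C", curve(t))
    return curve


def detected_pool(curve: FixtureCurve, rho_d: float, t: np.ndarray | None = None,
                  Id0: float = 0.0) -> np.ndarray:
    """Detected-and-isolated pool driven by the pulse.

    Id(t) = exp(-rho_d t) [Id0 + int_0^t C(u) exp(rho_d u) du], evaluated
    by quadrature on the given grid.
    """
    t = curve.t if t is None else np.asarray(t, dtype=float)
    # Integrate exp(rho_d (u - t)) C(u) to avoid overflow at large rho_d*t.
    integrand = curve(t) * np.exp(rho_d * (t - t[-1]))
    inner = cumulative_simpson(integrand, x=t, initial=0.0) * np.exp(rho_d * (t[-1] - t))
    return np.exp(-rho_d * t) * Id0 + inner


def behavior_under_forcing(
    curve: FixtureCurve,
    profile: BehaviorProfile,
    rho_d: float = 1.0 / 14.0,
    tau: float = 3.0,
    dt: float = 0.1,
    horizon: float | None = None,
) -> dict[str, np.ndarray]:
    """Behavior pathway driven by a prescribed incidence pulse.

    Returns arrays on a ``dt`` grid: the delayed prevalence ``P``
    (= Id(t-tau)/N0, zero before tau), trend ``Q`` (= Cdot/C at t-tau),
    information aggregate ``eta`` and prophylactic proportion ``m``.
    """
    horizon = float(curve.t[-1]) if horizon is None else horizon
    t = np.arange(0.0, horizon + 0.5 * dt, dt)
    u = t - tau
    started = t >= tau

    Id_grid = detected_pool(curve, rho_d, t=t)
    P = np.where(started, np.interp(np.clip(u, 0.0, None), t, Id_grid) / curve.N0, 0.0)
    C_u = curve(u)
    with np.errstate(divide="ignore", invalid="ignore"):
        Q = np.where(started & (C_u > 1e-9), curve.derivative(u) / C_u, 0.0)
    eta = information_aggregate(P, Q, profile)
    m = prophylactic_proportion(eta, profile)
    return {"t": t, "P": P, "Q": Q, "eta": eta, "m": m, "Id": Id_grid}
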