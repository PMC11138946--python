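"""Risk-information aggregation and the prophylactic-proportion model.

A susceptible group observes two pieces of delayed risk information: the
perceived prevalence ``P`` (detected-and-isolated infectious fraction) and
the relative rate of change ``Q`` of new detected cases.  The group
combines them into a scalar information aggregate

    eta = a*P + b*P**2 + c*P*Q + d*Q**2 + e*Q

with non-negative weights, and the fraction of the group engaging in
prophylactic behavior (e.g. mask wearing) follows a generalized-logistic
(Richards) response

    m(eta) = (1 + exp(delta - eta)) ** (-1/alpha)

where ``alpha > 0`` tunes in-group pressure (alpha < 1: strong influence of
those already engaging; alpha > 1: strong drag from the non-engaging
majority) and ``delta`` anchors the disease-free level ``m0 = m(0)``.

An experimental fatigue extension lets sustained engagement erode the
response; it is off by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "BehaviorProfile",
    "RiskSignal",
    "FatigueState",
    "PROFILE_WEIGHTS",
    "preset_profile",
    "information_aggregate",
    "delta_from_m0",
    "prophylactic_proportion",
    "dm_dalpha",
    "fatigue_proportion_series",
]

# Exponent clamp before exponentiation; unreachable in realistic runs.
_EXP_CLAMP = 700.0


def delta_from_m0(m0: float, alpha: float) -> float:
    """Logistic offset ``delta = log(m0**(-alpha) - 1)`` anchoring m(0)=m0.

    Raises
    ------
    ValueError
        If ``m0`` is outside (0, 1) or ``alpha <= 0``.
    """
    if not (0.0 < m0 < 1.0):
        raise ValueError(f"m0 must lie in (0, 1), got {m0}")
    if alpha <= 0.0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    return math.log(m0 ** (-alpha) - 1.0)


@dataclass(frozen=True)
class BehaviorProfile:
    """Information weights and in-group response of one susceptible group.

    Parameters
    ----------
    a, b, c, d, e
        Non-negative weights of P, P^2, P*Q, Q^2 and Q in the information
        aggregate.
    alpha
        Positive in-group pressure parameter of the Richards response.
    m0
        Baseline prophylactic proportion in (0, 1) (disease-free level).
    """

    a: float = 0.0
    b: float = 0.0
    c: float = 0.0
    d: float = 0.0
    e: float = 0.0
    alpha: float = 1.0
    m0: float = 0.05
    delta: float = field(init=False, repr=False)

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d", "e"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0.0:
                raise ValueError(f"weight {name} must be finite and >= 0, got {v}")
        object.__setattr__(self, "delta", delta_from_m0(self.m0, self.alpha))

    def with_alpha(self, alpha: float) -> "BehaviorProfile":
        """Copy of this profile with a different in-group parameter."""
        return BehaviorProfile(self.a, self.b, self.c, self.d, self.e, alpha, self.m0)

    def weights_array(self) -> np.ndarray:
        """Packed [a, b, c, d, e, alpha, delta, m0] vector for the solver core."""
        return np.array(
            [self.a, self.b, self.c, self.d, self.e, self.alpha, self.delta, self.m0],
            dtype=np.float64,
        )


@dataclass(frozen=True)
class RiskSignal:
    """Delayed risk information available to susceptibles at one time point.

    ``P`` is the perceived prevalence Id/N in [0, 1]; ``Q`` the relative
    rate of change of new detected cases (per day).  Both are zero before
    outbreak information arrives (t < tau).
    """

    P: float = 0.0
    Q: float = 0.0

    def eta(self, profile: BehaviorProfile) -> float:
        return information_aggregate(self.P, self.Q, profile)


# Canonical response profiles: a reference population responsive to
# prevalence only (0) and four variants adding one weight each.  Profile B
# is quoted both with c=50 and c=150; the preset uses c=150, which is the
# value consistent with the reference grid summaries (pass ``c=50`` as an
# override for the lighter variant).
PROFILE_WEIGHTS: dict[str, dict[str, float]] = {
    "0": {"a": 20.0},
    "A": {"a": 20.0, "b": 50.0},
    "B": {"a": 20.0, "c": 150.0},
    "C": {"a": 20.0, "d": 50.0},
    "D": {"a": 20.0, "e": 10.0},
}


def preset_profile(name: str, alpha: float = 1.0, m0: float = 0.05, **overrides) -> BehaviorProfile:
    """Build one of the named response profiles 0, A, B, C, D.

    ``overrides`` may replace individual weights, e.g. ``c=150`` for the
    figure-style variant of profile B.
    """
    try:
        weights = dict(PROFILE_WEIGHTS[name])
    except KeyError:
        raise KeyError(
            f"unknown profile {name!r}; available: {sorted(PROFILE_WEIGHTS)}"
        ) from None
    weights.update(overrides)
    return BehaviorProfile(alpha=alpha, m0=m0, **weights)


def information_aggregate(P, Q, profile: BehaviorProfile):
    """Quadratic information aggregate eta(P, Q). Vectorized over P and Q."""
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if not (np.all(np.isfinite(P)) and np.all(np.isfinite(Q))):
        raise ValueError("P and Q must be finite")
    eta = (
        profile.a * P
        + profile.b * P * P
        + profile.c * P * Q
        + profile.d * Q * Q
        + profile.e * Q
    )
    return float(eta) if eta.ndim == 0 else eta


def prophylactic_proportion(eta, profile: BehaviorProfile):
    """Prophylactic proportion m(eta) = (1+exp(delta-eta))**(-1/alpha).

    Strictly increasing in eta with m(0) = m0.  Vectorized over eta.
    """
    eta = np.asarray(eta, dtype=float)
    if not np.all(np.isfinite(eta)):
        raise ValueError("eta must be finite")
    z = np.clip(profile.delta - eta, -_EXP_CLAMP, _EXP_CLAMP)
    m = (1.0 + np.exp(z)) ** (-1.0 / profile.alpha)
    return float(m) if m.ndim == 0 else m


def dm_dalpha(eta, profile: BehaviorProfile):
    """Sensitivity of the prophylactic proportion to the in-group parameter.

    dm/dalpha = -(m/alpha) * [log(m/m0) + m**alpha * (1 - e**(-eta)) * log(m0)]

    Negative for eta > 0 (larger alpha weakens the response above baseline),
    zero at eta = 0, positive for eta < 0.
    """
    eta = np.asarray(eta, dtype=float)
    m = np.asarray(prophylactic_proportion(eta, profile))
    alpha, m0 = profile.alpha, profile.m0
    out = -(m / alpha) * (
        np.log(m / m0) + m**alpha * (1.0 - np.exp(-eta)) * math.log(m0)
    )
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class FatigueState:
    """Parameters and state of the experimental fatigue extension.

    ``omega`` weighs indirectly perceived risk inferred from in-group
    behavior; ``epsilon`` is the fatigue rate turning accumulated effort
    ``M`` into a fatigue level ``f = 1 - exp(-epsilon*M)``.  ``zeta`` is the
    accumulated in-group/fatigue correction to the logistic argument and
    ``g`` the engagement indicator used by the gated variant.
    """

    omega: float = 0.0
    epsilon: float = 0.0
    M: float = 0.0
    zeta: float = 0.0
    g: int = 1

    def __post_init__(self) -> None:
        if self.omega < 0.0 or self.epsilon < 0.0:
            raise ValueError("omega and epsilon must be non-negative")

    @property
    def f(self) -> float:
        return 1.0 - math.exp(-self.epsilon * self.M)


def prophylactic_proportion_fatigue(eta: float, state: FatigueState, profile: BehaviorProfile) -> float:
    """Closed-form proportion m = (1+exp(delta - eta*(1-f) - zeta))**(-1/alpha)."""
    z = np.clip(profile.delta - eta * (1.0 - state.f) - state.zeta, -_EXP_CLAMP, _EXP_CLAMP)
    return float((1.0 + math.exp(z)) ** (-1.0 / profile.alpha))


def fatigue_proportion_series(
    times: np.ndarray,
    eta: np.ndarray,
    profile: BehaviorProfile,
    fatigue: FatigueState,
    gated: bool = False,
    rtol: float = 1e-9,
    atol: float = 1e-12,
) -> np.ndarray:
    """Prophylactic proportion along a prescribed eta(t) path with fatigue.

    Experimental.  Integrates the effort M and correction zeta from
    M(0)=zeta(0)=0 alongside the path:

        dM/dt    = eta*(1-f) + zeta          (f = 1 - exp(-epsilon*M))
        dzeta/dt = eta*(1-f) * (epsilon*dM/dt + omega)

    and evaluates the closed form m = (1+exp(delta - eta*(1-f) - zeta))**(-1/alpha).
    With ``gated=True`` fatigue only damps engagement (when d eta/dt >= 0),
    in which case m itself is integrated from its rate equation.  With
    omega = epsilon = 0 the result equals the memoryless model exactly.
    """
    times = np.asarray(times, dtype=float)
    eta = np.asarray(eta, dtype=float)
    if times.shape != eta.shape or times.ndim != 1:
        raise ValueError("times and eta must be 1-d arrays of equal length")
    omega, eps = fatigue.omega, fatigue.epsilon
    if omega == 0.0 and eps == 0.0 and not gated:
        return np.asarray(prophylactic_proportion(eta, profile))

    deta = np.gradient(eta, times)

    def eta_at(t):
        return np.interp(t, times, eta)

    def deta_at(t):
        return np.interp(t, times, deta)

    alpha, m0 = profile.alpha, profile.m0

    if not gated:
        def rhs(t, y):
            M, zeta = y
            f = 1.0 - math.exp(-eps * M)
            e_t = eta_at(t)
            dM = e_t * (1.0 - f) + zeta
            dz = e_t * (1.0 - f) * (eps * dM + omega)
            return (dM, dz)

        sol = solve_ivp(rhs, (times[0], times[-1]), (0.0, 0.0), t_eval=times,
                        rtol=rtol, atol=atol, method="LSODA")
        if not sol.success:  # pragma: no cover - defensive
            raise RuntimeError(f"fatigue path integration failed: {sol.message}")
        M, zeta = sol.y
        f = 1.0 - np.exp(-eps * M)
        z = np.clip(profile.delta - eta * (1.0 - f) - zeta, -_EXP_CLAMP, _EXP_CLAMP)
        return (1.0 + np.exp(z)) ** (-1.0 / alpha)

    # Gated variant: dm/dt = m(1-m^alpha)/alpha * (deta/dt + omega*eta) * (1 - f*g),
    # g = 1 iff deta/dt >= 0.  m is a genuine state here (no closed form).
    base = math.log(m0**alpha / (1.0 - m0**alpha))

    def rhs_gated(t, y):
        m, M = y
        m = min(max(m, 1e-12), 1.0 - 1e-12)
        f = 1.0 - math.exp(-eps * M)
        de = deta_at(t)
        g = 1.0 if de >= 0.0 else 0.0
        dm = m * (1.0 - m**alpha) / alpha * (de + omega * eta_at(t)) * (1.0 - f * g)
        dM = math.log(m**alpha / (1.0 - m**alpha)) - base
        return (dm, dM)

    sol = solve_ivp(rhs_gated, (times[0], times[-1]), (m0, 0.0), t_eval=times,
                    rtol=rtol, atol=atol, method="LSODA")
    if not sol.success:  # pragma: no cover - defensive
        raise RuntimeError(f"gated fatigue integration failed: {sol.message}")
    return sol.y[0]
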