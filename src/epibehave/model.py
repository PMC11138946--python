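"""High-level model facade tying the pieces together.

``BehaviorSEIR`` bundles a population (two behavior profiles), disease
parameters and initial state; ``solve()`` integrates the delay system and
returns a :class:`~epibehave.dde.Trajectory`, from which severity measures,
reproduction numbers and tidy tables are available.
"""

from __future__ import annotations

from dataclasses import dataclass

from .behavior import BehaviorProfile, preset_profile
from .dde import SolverSettings, Trajectory, solve
from .epidemic import DiseaseParams, StateVector, basic_reproduction_number
from .severity import SeveritySummary, severity_summary

__all__ = ["BehaviorSEIR"]


@dataclass(frozen=True)
class BehaviorSEIR:
    """A configured behavior-SEIR population.

    Examples
    --------
    >>> from epibehave import BehaviorSEIR
    >>> model = BehaviorSEIR.from_presets("0", "D", alpha=0.1)
    >>> traj = model.solve(horizon=1000)
    >>> round(traj.peak_incidence)  # doctest: +SKIP
    1377
    """

    profiles: tuple[BehaviorProfile, BehaviorProfile]
    params: DiseaseParams = DiseaseParams()
    initial: StateVector = StateVector()

    @classmethod
    def from_presets(cls, profile_m1: str, profile_p1: str | None = None,
                     alpha: float | tuple[float, float] = 1.0,
                     m0: float = 0.05,
                     params: DiseaseParams | None = None,
                     initial: StateVector | None = None) -> "BehaviorSEIR":
        """Build a population from named profiles (homogeneous if one name)."""
        if profile_p1 is None:
            profile_p1 = profile_m1
        a_m1, a_p1 = (alpha, alpha) if isinstance(alpha, (int, float)) else alpha
        return cls(
            profiles=(preset_profile(profile_m1, alpha=a_m1, m0=m0),
                      preset_profile(profile_p1, alpha=a_p1, m0=m0)),
            params=params or DiseaseParams(),
            initial=initial or StateVector(),
        )

    @property
    def R0(self) -> float:
        return basic_reproduction_number(self.initial, self.profiles, self.params)

    def solve(self, horizon: float = 1000.0,
              settings: SolverSettings | None = None) -> Trajectory:
        return solve(self.profiles, self.params, self.initial, horizon, settings)

    def severity(self, horizon: float = 1000.0,
                 settings: SolverSettings | None = None) -> SeveritySummary:
        return severity_summary(self.solve(horizon, settings))
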