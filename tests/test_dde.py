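"""Delay solver: delayed signal evaluation, oracles and invariants."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from epibehave.behavior import BehaviorProfile, RiskSignal, preset_profile
from epibehave.dde import HistoryBuffer, SolverSettings, delayed_signal, solve
from epibehave.epidemic import DiseaseParams, StateVector, system_rhs

FLAT = BehaviorProfile(m0=0.05)  # all information weights zero


def exponential_history(rate: float, params: DiseaseParams, t_end: float = 30.0):
    """History whose incidence C(u) grows like exp(rate*u) (via E(u)),
    with a constant detected pool of 1,000 in a population of 100,000."""
    ts = np.linspace(0.0, t_end, 1201)
    ys = np.zeros((ts.size, 7))
    fs = np.zeros_like(ys)
    ys[:, 2] = np.exp(rate * ts)          # E drives C = pi*theta*E
    fs[:, 2] = rate * ys[:, 2]
    ys[:, 5] = 1000.0                     # constant detected pool
    ys[:, 0] = 49_000.0
    ys[:, 1] = 50_000.0 - ys[:, 2]        # keeps the total at 100,000
    fs[:, 1] = -fs[:, 2]
    return HistoryBuffer(ts, ys, fs, params)


class TestDelayedSignal:
    def test_silent_before_information_arrives(self, default_params):
        hist = exponential_history(0.3, default_params)
        sig = delayed_signal(hist, t=2.0, tau=3.0)
        assert sig == RiskSignal(0.0, 0.0)

    def test_perceived_prevalence(self, default_params):
        hist = exponential_history(0.0, default_params)
        sig = delayed_signal(hist, t=10.0, tau=3.0)
        assert sig.P == pytest.approx(1000.0 / 100_000.0, rel=1e-9)

    @pytest.mark.parametrize("rate", [1.0, -0.5])
    def test_trend_is_log_derivative_of_incidence(self, rate, default_params):
        # C proportional to e^{rate*u} gives Q = rate exactly
        hist = exponential_history(rate, default_params, t_end=40.0)
        sig = delayed_signal(hist, t=23.0, tau=3.0)
        assert sig.Q == pytest.approx(rate, rel=1e-5)

    def test_trend_floored_at_extinct_incidence(self, default_params):
        ts = np.linspace(0, 20, 201)
        ys = np.zeros((ts.size, 7))
        ys[:, 0] = ys[:, 1] = 50_000.0
        hist = HistoryBuffer.from_states(ts, ys, default_params)
        assert delayed_signal(hist, t=10.0, tau=3.0).Q == 0.0

    def test_lookup_beyond_history_is_an_error(self, default_params):
        hist = exponential_history(0.1, default_params, t_end=5.0)
        with pytest.raises(RuntimeError, match="beyond history"):
            delayed_signal(hist, t=20.0, tau=3.0)


class TestSolveOracles:
    def test_weightless_population_matches_plain_ode(self, default_params):
        """With all information weights zero the delay structure is inert:
        an independent non-delayed integration must agree to 1e-6."""
        horizon = 400.0
        traj = solve(FLAT, default_params, horizon=horizon,
                     settings=SolverSettings(rtol=1e-10, atol=1e-10))
        sol = solve_ivp(
            lambda t, y: system_rhs(t, y, (RiskSignal(), RiskSignal()),
                                    (FLAT, FLAT), default_params),
            (0.0, horizon), StateVector().as_array(),
            t_eval=traj.t, rtol=1e-12, atol=1e-12, method="LSODA")
        scale = np.maximum(np.abs(sol.y.T), 1.0)
        assert np.max(np.abs(traj.states - sol.y.T) / scale) < 1e-6

    def test_no_transmission_keeps_susceptibles_constant(self):
        params = DiseaseParams(beta0=0.0)
        traj = solve(preset_profile("0", alpha=0.1), params, horizon=200.0)
        np.testing.assert_allclose(traj.states[:, 0], 49_998.0, rtol=1e-12)
        assert traj.peak_incidence < 1.0
        assert traj.final_size() == pytest.approx(4.0 / 100_000.0, rel=1e-6)

    def test_behavior_inert_before_information_delay(self, default_params):
        """Solutions on [0, tau] do not depend on the information weights."""
        tau = default_params.tau
        a = solve(preset_profile("0", alpha=0.1), default_params, horizon=2 * tau)
        b = solve(preset_profile("D", alpha=0.1), default_params, horizon=2 * tau)
        upto = a.t <= tau
        np.testing.assert_allclose(a.states[upto], b.states[upto],
                                   rtol=1e-9, atol=1e-6)
        # behavior sits at its disease-free level while the signal is silent
        before = a.t < tau
        np.testing.assert_allclose(a.m[before], 0.05, rtol=1e-12)
        np.testing.assert_allclose(b.m[before], 0.05, rtol=1e-12)


class TestSolveInvariants:
    @pytest.fixture(scope="class")
    def default_run(self, default_params):
        return solve(preset_profile("0", alpha=0.1), default_params, horizon=1000.0)

    def test_population_conserved(self, default_run):
        assert default_run.conservation_error() < 1e-6 * default_run.N0

    def test_compartments_nonnegative(self, default_run):
        assert default_run.states.min() > -1e-6 * default_run.N0

    def test_susceptibles_monotone_nonincreasing(self, default_run):
        S = default_run.states[:, 0] + default_run.states[:, 1]
        assert np.all(np.diff(S) <= 1e-9 * default_run.N0)

    def test_detected_pool_consistent_with_incidence(self, default_run):
        """The solved Id(t) equals exp(-rho_d t) [Id0 + int C e^{rho_d u} du]
        driven by the solved C(t) (quadrature cross-check)."""
        from scipy.integrate import cumulative_simpson
        t, C = default_run.t, default_run.C
        rho_d = default_run.params.rho_d
        inner = cumulative_simpson(C * np.exp(rho_d * (t - t[-1])), x=t, initial=0.0)
        Id_quad = inner * np.exp(rho_d * (t[-1] - t))
        scale = np.maximum(default_run.states[:, 5], 1.0)
        assert np.max(np.abs(Id_quad - default_run.states[:, 5]) / scale) < 1e-4

    def test_effective_reproduction_crosses_one_after_peak(self, default_params):
        # detected incidence lags infections through the E compartment, so
        # R(t) reaches 1 within a few days after the C peak
        traj = solve(preset_profile("0", alpha=2.0), default_params, horizon=1000.0)
        rep = traj.reproduction
        t_peak = traj.t[int(np.argmax(traj.C))]
        window = (traj.t >= t_peak) & (traj.t <= t_peak + 5.0)
        assert rep.Rt[window].min() <= 1.05

    def test_halved_tolerances_leave_peak_unchanged(self, default_params):
        base = solve(preset_profile("0", alpha=0.1), default_params, horizon=1000.0,
                     settings=SolverSettings(rtol=1e-8))
        tight = solve(preset_profile("0", alpha=0.1), default_params, horizon=1000.0,
                      settings=SolverSettings(rtol=5e-9, atol=0.5e-10 * 1e5))
        assert abs(base.peak_incidence - tight.peak_incidence) \
            < 1e-3 * base.peak_incidence

    def test_neutral_term_stable_under_fd_step(self, default_params):
        # profile 0 ignores Q, so the trajectory is shared and this probes
        # purely the finite-difference evaluation of Cdot on the history
        a = solve(preset_profile("0", alpha=1.0), default_params, horizon=300.0,
                  settings=SolverSettings(fd_half_step=1e-3))
        b = solve(preset_profile("0", alpha=1.0), default_params, horizon=300.0,
                  settings=SolverSettings(fd_half_step=5e-4))
        assert np.max(np.abs(a.Q - b.Q)) < 1e-4


class TestTrajectorySurface:
    def test_tidy_frame_columns(self, default_params):
        traj = solve(preset_profile("0"), default_params, horizon=20.0)
        df = traj.to_frame()
        assert list(df.columns) == ["time", "S_m1", "S_p1", "E", "Ia", "Is",
                                    "Id", "R", "C", "m_m1", "m_p1", "Rt"]
        assert len(df) == int(20.0 / traj.settings.output_dt) + 1

    def test_daily_incidence_on_integer_days(self, default_params):
        traj = solve(preset_profile("0"), default_params, horizon=30.0)
        daily = traj.daily_incidence()
        assert list(daily.index) == list(range(31))

    def test_zero_delay_allowed(self):
        params = DiseaseParams(tau=0.0)
        traj = solve(preset_profile("0", alpha=1.0), params, horizon=100.0)
        assert traj.conservation_error() < 1e-6 * traj.N0
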