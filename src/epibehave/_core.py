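"""Compiled numerical core of the delay solver.

The behavior-SEIR system is a neutral delay differential system: the force
of infection at time t depends on the state at t - tau (perceived
prevalence P) and on the derivative of the detected-incidence series at
t - tau (trend signal Q).  The solver integrates with an explicit
Dormand-Prince 5(4) pair whose steps never cross a multiple of the single
constant delay tau, so every delayed lookup falls inside completed history
(method of steps).  History is stored as knots (t, y, y') and queried with
cubic Hermite interpolation; the derivative of C is obtained by a central
finite difference of the interpolated C, falling back to one-sided
differences against the history boundaries.

Everything here operates on packed float64 arrays:

    p  = [beta0, phi_a, phi_s, kappa, theta, pi, sigma,
          gamma_a, gamma_s, rho_a, rho_s, rho_d, tau]
    bp = 2 x 8 rows [a, b, c, d, e, alpha, delta, m0] per susceptible group
    y  = [S_m1, S_p1, E, Ia, Is, Id, R]
"""

from __future__ import annotations

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_STEP_UNDERFLOW = 1
STATUS_BUFFER_FULL = 2

_EXP_CLAMP = 700.0


@njit(cache=True, fastmath=False)
def _interval(ts, n, u):
    """Largest k in [0, n-2] with ts[k] <= u (u assumed within [ts[0], ts[n-1]])."""
    lo, hi = 0, n - 1
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if ts[mid] <= u:
            lo = mid
        else:
            hi = mid
    return lo


@njit(cache=True, fastmath=False)
def _comp_at(ts, ys, fs, n, u, j):
    """Cubic-Hermite value of state component j at time u (clamped to history)."""
    if u <= ts[0]:
        return ys[0, j]
    if u >= ts[n - 1]:
        return ys[n - 1, j]
    k = _interval(ts, n, u)
    t0, t1 = ts[k], ts[k + 1]
    h = t1 - t0
    s = (u - t0) / h
    s2 = s * s
    omr = 1.0 - s
    h00 = (1.0 + 2.0 * s) * omr * omr
    h10 = s * omr * omr
    h01 = s2 * (3.0 - 2.0 * s)
    h11 = s2 * (s - 1.0)
    return (h00 * ys[k, j] + h10 * h * fs[k, j]
            + h01 * ys[k + 1, j] + h11 * h * fs[k + 1, j])


@njit(cache=True, fastmath=False)
def _C_at(ts, ys, fs, n, u, p):
    """Detected incidence C = pi*theta*E + gamma_a*Ia + gamma_s*Is at time u."""
    E = _comp_at(ts, ys, fs, n, u, 2)
    Ia = _comp_at(ts, ys, fs, n, u, 3)
    Is = _comp_at(ts, ys, fs, n, u, 4)
    return p[5] * p[4] * E + p[7] * Ia + p[8] * Is


@njit(cache=True, fastmath=False)
def _signal_PQ(ts, ys, fs, n, t, p, N0, h_fd, q_floor):
    """Delayed risk signal (P, Q) available at time t.

    P = Id(t-tau)/N, zero before t = tau; Q = Cdot(t-tau)/C(t-tau) with a
    floor on C guarding extinction-level incidence.
    """
    tau = p[12]
    if tau > 0.0:
        # information is silent up to and including tau, so the first
        # integration interval is exactly the disease-free behavior regime
        if t <= tau:
            return 0.0, 0.0
        u = t - tau
    else:
        # Instantaneous information (testing only): evaluate at the most
        # recent completed history point.
        u = min(t, ts[n - 1])
    P = _comp_at(ts, ys, fs, n, u, 5) / N0
    if P < 0.0:
        P = 0.0
    elif P > 1.0:
        P = 1.0
    C = _C_at(ts, ys, fs, n, u, p)
    if C <= q_floor:
        return P, 0.0
    t_end = ts[n - 1]
    if u - h_fd >= 0.0 and u + h_fd <= t_end:
        Cdot = (_C_at(ts, ys, fs, n, u + h_fd, p)
                - _C_at(ts, ys, fs, n, u - h_fd, p)) / (2.0 * h_fd)
    elif u - h_fd < 0.0:
        if u + h_fd > t_end:
            return P, 0.0
        Cdot = (_C_at(ts, ys, fs, n, u + h_fd, p) - C) / h_fd
    else:
        Cdot = (C - _C_at(ts, ys, fs, n, u - h_fd, p)) / h_fd
    return P, Cdot / C


@njit(cache=True, fastmath=False)
def _m_of(P, Q, bp, i):
    """Prophylactic proportion of group i given the risk signal."""
    a, b, c, d, e = bp[i, 0], bp[i, 1], bp[i, 2], bp[i, 3], bp[i, 4]
    alpha, delta = bp[i, 5], bp[i, 6]
    eta = a * P + b * P * P + c * P * Q + d * Q * Q + e * Q
    z = delta - eta
    if z > _EXP_CLAMP:
        z = _EXP_CLAMP
    elif z < -_EXP_CLAMP:
        z = -_EXP_CLAMP
    return (1.0 + np.exp(z)) ** (-1.0 / alpha)


@njit(cache=True, fastmath=False)
def _rhs(t, y, p, bp, ts, ys, fs, n, N0, h_fd, q_floor, dy):
    P, Q = _signal_PQ(ts, ys, fs, n, t, p, N0, h_fd, q_floor)
    N = y[0] + y[1] + y[2] + y[3] + y[4] + y[5] + y[6]
    denom = N - y[5]
    pressure = (p[1] * y[3] + p[2] * y[4]) / denom
    lam0 = p[0] * (1.0 - p[3] * _m_of(P, Q, bp, 0)) * pressure
    lam1 = p[0] * (1.0 - p[3] * _m_of(P, Q, bp, 1)) * pressure
    exit_E = p[4] * y[2]
    dy[0] = -lam0 * y[0]
    dy[1] = -lam1 * y[1]
    dy[2] = lam0 * y[0] + lam1 * y[1] - exit_E
    dy[3] = (1.0 - p[6]) * (1.0 - p[5]) * exit_E - (p[7] + p[9]) * y[3]
    dy[4] = p[6] * (1.0 - p[5]) * exit_E - (p[8] + p[10]) * y[4]
    dy[5] = p[5] * exit_E + p[7] * y[3] + p[8] * y[4] - p[11] * y[5]
    dy[6] = p[9] * y[3] + p[10] * y[4] + p[11] * y[5]


# Dormand-Prince 5(4) tableau.
_C2, _C3, _C4, _C5 = 1.0 / 5.0, 3.0 / 10.0, 4.0 / 5.0, 8.0 / 9.0
_A21 = 1.0 / 5.0
_A31, _A32 = 3.0 / 40.0, 9.0 / 40.0
_A41, _A42, _A43 = 44.0 / 45.0, -56.0 / 15.0, 32.0 / 9.0
_A51, _A52, _A53, _A54 = 19372.0 / 6561.0, -25360.0 / 2187.0, 64448.0 / 6561.0, -212.0 / 729.0
_A61, _A62, _A63, _A64, _A65 = (9017.0 / 3168.0, -355.0 / 33.0, 46732.0 / 5247.0,
                                49.0 / 176.0, -5103.0 / 18656.0)
_B1, _B3, _B4, _B5, _B6 = (35.0 / 384.0, 500.0 / 1113.0, 125.0 / 192.0,
                           -2187.0 / 6784.0, 11.0 / 84.0)
_E1, _E3, _E4, _E5, _E6, _E7 = (71.0 / 57600.0, -71.0 / 16695.0, 71.0 / 1920.0,
                                -17253.0 / 339200.0, 22.0 / 525.0, -1.0 / 40.0)


@njit(cache=True, fastmath=False)
def solve_core(p, bp, y0, horizon, rtol, atol, h_fd, q_floor, max_step, nmax):
    """Integrate the delay system on [0, horizon].

    Returns (ts, ys, fs, n, status, n_accepted, n_rejected); the first n
    entries of the knot arrays form the dense solution history.
    """
    tau = p[12]
    N0 = y0.sum()
    ts = np.empty(nmax)
    ys = np.empty((nmax, 7))
    fs = np.empty((nmax, 7))
    ts[0] = 0.0
    ys[0] = y0
    n = 1
    k1 = np.empty(7)
    k2 = np.empty(7)
    k3 = np.empty(7)
    k4 = np.empty(7)
    k5 = np.empty(7)
    k6 = np.empty(7)
    k7 = np.empty(7)
    ytmp = np.empty(7)
    ynew = np.empty(7)
    _rhs(0.0, y0, p, bp, ts, ys, fs, n, N0, h_fd, q_floor, k1)
    fs[0] = k1

    t = 0.0
    y = y0.copy()
    dt = 1e-2
    if dt > max_step:
        dt = max_step
    n_acc = 0
    n_rej = 0
    while t < horizon:
        if n >= nmax:
            return ts, ys, fs, n, STATUS_BUFFER_FULL, n_acc, n_rej
        dtmax = horizon - t
        if max_step < dtmax:
            dtmax = max_step
        hit_bound = -1.0
        if tau > 0.0:
            nb = (np.floor(t / tau) + 1.0) * tau
            if nb - t <= 1e-12 * (1.0 + abs(t)):
                nb += tau
            if nb - t <= dtmax:
                dtmax = nb - t
                hit_bound = nb
        if dt >= dtmax:
            dt = dtmax
            bound_step = hit_bound
        else:
            bound_step = -1.0
        if dt < 1e-12:
            return ts, ys, fs, n, STATUS_STEP_UNDERFLOW, n_acc, n_rej

        for j in range(7):
            ytmp[j] = y[j] + dt * _A21 * k1[j]
        _rhs(t + _C2 * dt, ytmp, p, bp, ts, ys, fs, n, N0, h_fd, q_floor, k2)
        for j in range(7):
            ytmp[j] = y[j] + dt * (_A31 * k1[j] + _A32 * k2[j])
        _rhs(t + _C3 * dt, ytmp, p, bp, ts, ys, fs, n, N0, h_fd, q_floor, k3)
        for j in range(7):
            ytmp[j] = y[j] + dt * (_A41 * k1[j] + _A42 * k2[j] + _A43 * k3[j])
        _rhs(t + _C4 * dt, ytmp, p, bp, ts, ys, fs, n, N0, h_fd, q_floor, k4)
        for j in range(7):
            ytmp[j] = y[j] + dt * (_A51 * k1[j] + _A52 * k2[j] + _A53 * k3[j] + _A54 * k4[j])
        _rhs(t + _C5 * dt, ytmp, p, bp, ts, ys, fs, n, N0, h_fd, q_floor, k5)
        for j in range(7):
            ytmp[j] = y[j] + dt * (_A61 * k1[j] + _A62 * k2[j] + _A63 * k3[j]
                                   + _A64 * k4[j] + _A65 * k5[j])
        _rhs(t + dt, ytmp, p, bp, ts, ys, fs, n, N0, h_fd, q_floor, k6)
        for j in range(7):
            ynew[j] = y[j] + dt * (_B1 * k1[j] + _B3 * k3[j] + _B4 * k4[j]
                                   + _B5 * k5[j] + _B6 * k6[j])
        _rhs(t + dt, ynew, p, bp, ts, ys, fs, n, N0, h_fd, q_floor, k7)

        err = 0.0
        for j in range(7):
            ej = dt * (_E1 * k1[j] + _E3 * k3[j] + _E4 * k4[j]
                       + _E5 * k5[j] + _E6 * k6[j] + _E7 * k7[j])
            ay = abs(y[j])
            ayn = abs(ynew[j])
            sc = atol + rtol * (ay if ay > ayn else ayn)
            r = ej / sc
            err += r * r
        err = np.sqrt(err / 7.0)

        if err <= 1.0:
            t = bound_step if bound_step > 0.0 else t + dt
            for j in range(7):
                y[j] = ynew[j]
                k1[j] = k7[j]
            ts[n] = t
            ys[n] = y
            fs[n] = k7
            n += 1
            n_acc += 1
            fac = 5.0 if err == 0.0 else 0.9 * err ** (-0.2)
            if fac > 5.0:
                fac = 5.0
            dt = dt * fac
        else:
            n_rej += 1
            fac = 0.9 * err ** (-0.2)
            if fac < 0.2:
                fac = 0.2
            dt = dt * fac
    return ts, ys, fs, n, STATUS_OK, n_acc, n_rej


@njit(cache=True, fastmath=False)
def sample_states(ts, ys, fs, n, tgrid):
    out = np.empty((tgrid.shape[0], 7))
    for i in range(tgrid.shape[0]):
        for j in range(7):
            out[i, j] = _comp_at(ts, ys, fs, n, tgrid[i], j)
    return out


@njit(cache=True, fastmath=False)
def sample_signal(ts, ys, fs, n, tgrid, p, N0, h_fd, q_floor):
    P = np.empty(tgrid.shape[0])
    Q = np.empty(tgrid.shape[0])
    for i in range(tgrid.shape[0]):
        P[i], Q[i] = _signal_PQ(ts, ys, fs, n, tgrid[i], p, N0, h_fd, q_floor)
    return P, Q
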