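"""Independent numerical oracles used only by the test suite.

The main oracle is a Crank-Nicolson finite-difference solver for the
dimensionless linearized sloping-aquifer equation

    eta_t = eta_xx + Hi eta_x + r(t),  x in (0,1),
    eta(0)=0,  eta_x(1) + Hi eta(1) = 0,

kept deliberately independent of the analytical series/transfer-function
implementation it cross-checks. Discharge is the outlet gradient
q*(t) = eta_x(0), so steady state gives q* = r exactly (mass balance).
"""

from __future__ import annotations

import math

import numpy as np
from scipy.linalg import solve_banded


def _operator(Hi: float, M: int):
    """Tridiagonal operator L (interior + divide node) on unknowns 1..M."""
    h = 1.0 / M
    n = M  # unknowns eta_1..eta_M; eta_0 = 0
    lower = np.zeros(n)
    diag = np.zeros(n)
    upper = np.zeros(n)
    for i in range(1, M):  # global node i, row i-1
        r = i - 1
        lower[r] = 1.0 / h**2 - Hi / (2 * h)   # coeff of eta_{i-1}
        diag[r] = -2.0 / h**2
        upper[r] = 1.0 / h**2 + Hi / (2 * h)   # coeff of eta_{i+1}
    # divide node M: ghost eta_{M+1} = eta_{M-1} - 2 h Hi eta_M
    r = M - 1
    lower[r] = 2.0 / h**2
    diag[r] = -(2.0 * (1.0 + h * Hi) / h**2 + Hi**2)
    upper[r] = 0.0
    return lower, diag, upper


def _banded(lower, diag, upper, scale_diag=0.0, scale_off=1.0):
    """Pack a*L (+ b*I) into solve_banded form."""
    n = len(diag)
    ab = np.zeros((3, n))
    ab[0, 1:] = scale_off * upper[:-1]
    ab[1, :] = scale_off * diag + scale_diag
    ab[2, :-1] = scale_off * lower[1:]
    return ab


def fd_steady(Hi: float, r: float, M: int = 50) -> np.ndarray:
    """Steady profile eta(x) on nodes x_i = i/M, i=0..M (unit recharge r)."""
    lower, diag, upper = _operator(Hi, M)
    ab = _banded(lower, diag, upper)
    rhs = -r * np.ones(M)
    eta = solve_banded((1, 1), ab, rhs)
    return np.concatenate([[0.0], eta])


def _outlet_flux(eta: np.ndarray, M: int) -> float:
    h = 1.0 / M
    return (4.0 * eta[1] - eta[2] - 3.0 * eta[0]) / (2.0 * h)


def fd_transient(Hi: float, eta_init: np.ndarray, r_fn, t_out: np.ndarray,
                 M: int = 50, dt: float | None = None):
    """Crank-Nicolson march; returns (eta at final time, q*(t) at t_out)."""
    t_out = np.asarray(t_out, dtype=float)
    t_end = float(t_out[-1])
    if dt is None:
        dt = t_end / 4000.0
    lower, diag, upper = _operator(Hi, M)
    A = _banded(lower, diag, upper, scale_diag=1.0, scale_off=-dt / 2.0)
    eta = eta_init[1:].copy()
    t = 0.0
    q_out = np.empty_like(t_out)
    next_i = 0
    full = np.concatenate([[0.0], eta])
    while next_i < len(t_out) and t_out[next_i] <= 1e-15:
        q_out[next_i] = _outlet_flux(full, M)
        next_i += 1
    max_steps = int(math.ceil(t_end / dt)) + 1
    for _ in range(max_steps):
        step = min(dt, t_end - t)
        if step <= 0:
            break
        if abs(step - dt) > 1e-15 * dt:
            A_step = _banded(lower, diag, upper, 1.0, -step / 2.0)
        else:
            A_step = A
        # rhs = (I + step/2 L) eta + step * (r(t) + r(t+step))/2
        Leta = np.empty(M)
        Leta[0] = diag[0] * eta[0] + upper[0] * eta[1]
        Leta[1:-1] = (lower[1:-1] * eta[:-2] + diag[1:-1] * eta[1:-1]
                      + upper[1:-1] * eta[2:])
        Leta[-1] = lower[-1] * eta[-2] + diag[-1] * eta[-1]
        rhs = eta + (step / 2.0) * Leta + step * 0.5 * (r_fn(t) + r_fn(t + step))
        eta = solve_banded((1, 1), A_step, rhs)
        t += step
        full = np.concatenate([[0.0], eta])
        while next_i < len(t_out) and t_out[next_i] <= t + 1e-12 * t_end:
            q_out[next_i] = _outlet_flux(full, M)
            next_i += 1
    return full, q_out


def fd_sudden_recession(Hi: float, t_star: np.ndarray, M: int = 50,
                        dt: float | None = None) -> np.ndarray:
    """Normalized recession g(t*) = q*(t*)/q*(0) from the steady profile."""
    eta0 = fd_steady(Hi, 1.0, M)
    q0 = _outlet_flux(eta0, M)
    _, q = fd_transient(Hi, eta0, lambda t: 0.0, np.asarray(t_star), M=M, dt=dt)
    return q / q0


def fd_periodic_response(Hi: float, omega_star: float, M: int = 50,
                         n_periods: int = 8, steps_per_period: int = 600):
    """Amplitude ratio and phase lag of the periodic outlet flux.

    Runs from the mean steady state through ``n_periods`` cycles and fits
    a + b sin + c cos over the final cycle. Returns (|G|, lag_radians, mean)
    for unit mean recharge and unit recharge amplitude.
    """
    P = 2.0 * math.pi / omega_star
    eta0 = fd_steady(Hi, 1.0, M)
    r_fn = lambda t: 1.0 + math.sin(omega_star * t)
    t_end = n_periods * P
    n_last = steps_per_period
    t_last = t_end - P + P * np.arange(1, n_last + 1) / n_last
    dt = P / steps_per_period
    _, q = fd_transient(Hi, eta0, r_fn, t_last, M=M, dt=dt)
    X = np.column_stack([np.ones_like(t_last),
                         np.sin(omega_star * t_last),
                         np.cos(omega_star * t_last)])
    a, b, cc = np.linalg.lstsq(X, q, rcond=None)[0]
    amp = math.hypot(b, cc)
    lag = (-math.atan2(cc, b)) % (2.0 * math.pi)
    return amp, lag, a


def union_find_components(n_nodes: int, edges) -> int:
    """Number of connected components by union-find (oracle for networkx)."""
    parent = list(range(n_nodes))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    comp = n_nodes
    for i, j in edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            comp -= 1
    return comp


def bisect_root(f, lo, hi, iters=200):
    """Plain bisection oracle (independent of scipy.brentq)."""
    flo = f(lo)
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        fm = f(mid)
        if flo * fm <= 0:
            hi = mid
        else:
            lo, flo = mid, fm
    return 0.5 * (lo + hi)
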