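import math

import numpy as np
import pytest
from scipy.integrate import quad

from conftest import random_catchments
from hydrorefugia.catchment import ClimateForcing, SpringCatchment
from hydrorefugia.boussinesq import (
    HI_SERIES_MAX,
    SuddenRecessionSeries,
    _g_talbot,
    _series_coefficients,
    max_head_position,
    periodic_discharge,
    periodic_flow_range,
    periodic_transfer,
    refine_recharge,
    steady_state_head,
    sudden_recession_discharge,
    tan_roots,
    unit_to_total_flow,
)
import oracles as oc


# -- eigenvalue roots ----------------------------------------------------------

def test_roots_tend_to_tan_poles_as_slope_vanishes():
    z_small = tan_roots(1e-9, 5)
    z_zero = tan_roots(0.0, 5)
    expected = (2 * np.arange(1, 6) - 1) * math.pi / 2
    assert np.allclose(z_zero, expected)
    assert np.allclose(z_small, expected, rtol=1e-6)


@pytest.mark.parametrize("Hi", [0.05, 0.5, 2.0, 10.0, 50.0])
def test_roots_satisfy_eigencondition_and_match_bisection(Hi):
    z = tan_roots(Hi, 12)
    assert np.all(np.diff(z) > 0)
    if Hi >= 2.0:
        # residual of the defining equation (for small Hi the roots sit next
        # to tan's poles, where this form is hopelessly ill-conditioned and
        # the pole-free characteristic below is the meaningful residual)
        assert np.max(np.abs(np.tan(z) + 2 * z / Hi)) < 1e-10
    char = z * np.cos(z) + 0.5 * Hi * np.sin(z)
    assert np.max(np.abs(char)) < 1e-11 * np.max(z)
    # independent bisection oracle on each branch of the pole-free form
    for k, zk in enumerate(z, start=1):
        f = lambda x: x * math.cos(x) + 0.5 * Hi * math.sin(x)
        ref = oc.bisect_root(f, (k - 0.5) * math.pi + 1e-12, k * math.pi)
        assert zk == pytest.approx(ref, abs=1e-10)


def test_roots_one_per_branch():
    z = tan_roots(3.0, 30)
    k = np.arange(1, 31)
    assert np.all(z > (k - 0.5) * math.pi)
    assert np.all(z < k * math.pi)


# -- series coefficients ------------------------------------------------------

@pytest.mark.parametrize("Hi", [0.0, 0.7, 3.0, 12.0])
def test_series_coefficients_match_quadrature_projection(Hi):
    """Closed-form eigenfunction projections of the steady profile equal a
    direct numerical quadrature of the projection integrals."""
    from hydrorefugia.boussinesq import _profile_shape

    z = tan_roots(Hi, 6)
    c_hat, _ = _series_coefficients(Hi, 6)
    b = Hi / 2.0
    for n in range(6):
        zn = z[n]
        num = quad(lambda x: _profile_shape(Hi, np.array(x))
                   * math.exp(b * x) * math.sin(zn * x), 0, 1, limit=200)[0]
        den = quad(lambda x: math.sin(zn * x) ** 2, 0, 1, limit=200)[0]
        assert c_hat[n] == pytest.approx(num / den * zn, rel=1e-8, abs=1e-12)


def test_series_mass_identity():
    # untruncated flux coefficients sum to 1 (steady mass balance)
    for Hi in (0.0, 1.0, 8.0):
        s = SuddenRecessionSeries.build(Hi)
        assert abs(1.0 - s.c_hat.sum()) < 2e-3
        assert np.all(np.diff(s.roots) > 0)


# -- sudden recession ----------------------------------------------------------

def test_recession_starts_at_steady_mass_balance(catchment):
    R0 = 0.05
    assert sudden_recession_discharge(catchment, R0, 0.0) == pytest.approx(
        R0 * catchment.Bx)


def test_recession_monotone_and_vanishes(catchment):
    t = np.logspace(-3, 4, 60)
    q = sudden_recession_discharge(catchment, 0.05, t)
    assert np.all(np.diff(q) <= 1e-12)
    assert q[-1] < 1e-6 * q[0]


def test_recession_floor_superposition(catchment):
    """A nonzero recharge floor adds exactly the floor steady state."""
    t = np.logspace(-2, 3, 20)
    q0 = sudden_recession_discharge(catchment, 0.04, t, R_floor=0.0)
    qf = sudden_recession_discharge(catchment, 0.05, t, R_floor=0.01)
    assert np.allclose(qf, q0 + 0.01 * catchment.Bx, rtol=1e-10)
    assert qf[-1] == pytest.approx(0.01 * catchment.Bx, rel=1e-4)


def test_recession_matches_finite_difference_oracle():
    """Analytical recession within 2% of an independent 50-node FD solve of
    the same linearized equation, on randomized catchments."""
    t_star = np.array([0.01, 0.03, 0.1, 0.3, 1.0])
    for c in random_catchments(6, seed=11):
        g_fd = oc.fd_sudden_recession(c.Hi, t_star, M=50, dt=2e-4)
        d_star = c.k0 * c.eta0 * math.cos(c.alpha) / c.n_e
        t = t_star * c.Bx ** 2 / d_star
        q = sudden_recession_discharge(c, 1.0, t)
        g_an = q / (1.0 * c.Bx)
        mask = g_fd > 1e-3
        assert np.max(np.abs(g_an[mask] - g_fd[mask]) / g_fd[mask]) < 0.02


def test_series_and_laplace_paths_agree():
    """The two evaluation routes of the same solution coincide below the
    switch-over slope number."""
    t_star = np.array([1e-3, 1e-2, 0.1, 0.5])
    for Hi in (0.0, 2.0, 15.0):
        assert Hi <= HI_SERIES_MAX
        g_series = SuddenRecessionSeries.build(Hi).g(t_star)
        g_lap = _g_talbot(Hi, t_star)
        assert np.allclose(g_series, g_lap, rtol=2e-3, atol=1e-6)


def test_recession_well_behaved_beyond_series_regime():
    # steep, long aquifer: ~3 km of relief along the flow path, Hi ~ 100
    c = SpringCatchment(B=4.5e4, alpha=math.atan(3000.0 / 4.5e4), A=4e9,
                        k0=3000.0, n_e=0.1)
    assert c.Hi > HI_SERIES_MAX
    t = np.logspace(-2, 5, 40)
    q = sudden_recession_discharge(c, 0.05, t)
    assert sudden_recession_discharge(c, 0.05, 0.0) == pytest.approx(
        0.05 * c.Bx)
    # monotone up to the Laplace-inversion noise floor at deep decay
    assert np.all(np.diff(q) <= 1e-6 * q[0])
    assert np.all(q >= 0)


def test_recession_rejects_unphysical_slope_numbers():
    c = SpringCatchment(B=8e4, alpha=0.2, A=1e10, k0=3000.0, n_e=0.1)
    assert c.Hi > 200.0
    with pytest.raises(ValueError, match="slope number"):
        sudden_recession_discharge(c, 0.05, 1.0)


# -- periodic forcing ----------------------------------------------------------

def test_periodic_constant_forcing_is_steady(catchment):
    f = ClimateForcing.periodic(R_max=0.05, R_min=0.05, P=100.0)
    t = np.linspace(0, 300, 7)
    q = periodic_discharge(catchment, f, t)
    assert np.allclose(q, 0.05 * catchment.Bx, rtol=1e-12)


def test_periodic_quasi_steady_limit(catchment):
    """P >> GRT: discharge tracks recharge, q(t) ~ R(t) Bx."""
    from hydrorefugia.catchment import grt

    P = 1e5 * grt(catchment)
    f = ClimateForcing.periodic(R_max=0.06, R_min=0.0, P=P)
    t = np.linspace(0, P, 9)
    q = periodic_discharge(catchment, f, t)
    assert np.allclose(q, f.recharge(t) * catchment.Bx, rtol=1e-3,
                       atol=1e-5 * f.R_av * catchment.Bx)


def test_periodic_mean_amplitude_and_lag_properties(catchment):
    f = ClimateForcing.periodic(R_max=0.06, R_min=0.001, P=50.0)
    t = np.linspace(0.0, 50.0, 4000, endpoint=False)
    q = periodic_discharge(catchment, f, t)
    # P-periodic and mean = R_av Bx
    assert periodic_discharge(catchment, f, 13.0) == pytest.approx(
        periodic_discharge(catchment, f, 13.0 + 50.0), rel=1e-12)
    assert q.mean() == pytest.approx(f.R_av * catchment.Bx, rel=1e-6)
    # attenuation: amplitude <= R_amp Bx, decreasing for shorter periods
    rng50 = periodic_flow_range(catchment, f)
    assert rng50["amplitude"] <= f.R_amp * catchment.Bx
    f5 = ClimateForcing.periodic(R_max=0.06, R_min=0.001, P=5.0)
    rng5 = periodic_flow_range(catchment, f5)
    assert rng5["amplitude"] < rng50["amplitude"]
    # lag in [0, P/4 +] and larger (as cycle fraction) when more attenuated
    assert 0 <= rng50["lag"] <= 50.0 / 4 * 1.2
    assert rng5["lag"] / 5.0 > rng50["lag"] / 50.0


def test_periodic_matches_finite_difference_oracle():
    """Amplitude and lag of the dynamically steady response within 2% of the
    FD solve run through several cycles."""
    for c in random_catchments(6, seed=23):
        d_star = c.k0 * c.eta0 * math.cos(c.alpha) / c.n_e
        grt_star = 1.0  # probe near the aquifer's own timescale
        omega_star = 2 * math.pi / grt_star
        P = 2 * math.pi / omega_star * c.Bx ** 2 / d_star
        amp_fd, lag_fd, _ = oc.fd_periodic_response(c.Hi, omega_star, M=50)
        G = periodic_transfer(c, P)
        assert abs(G) == pytest.approx(amp_fd, rel=0.02)
        lag_an = (-np.angle(G)) % (2 * math.pi)
        assert lag_an == pytest.approx(lag_fd, rel=0.02, abs=0.01)


def test_periodic_rejects_bad_period(catchment):
    with pytest.raises(ValueError):
        periodic_transfer(catchment, 0.0)


# -- steady state --------------------------------------------------------------

def test_zero_recharge_head_is_uniform(catchment):
    x = np.linspace(0, catchment.Bx, 11)
    eta = steady_state_head(catchment, 0.0, x)
    assert np.allclose(eta, 0.0)


def test_flat_aquifer_head_peaks_at_divide(flat_catchment):
    x = np.linspace(0, flat_catchment.Bx, 101)
    eta = steady_state_head(flat_catchment, 0.03, x)
    assert np.argmax(eta) == 100
    assert np.all(np.diff(eta) > 0)


def test_head_increases_with_recharge(catchment):
    x = np.linspace(1.0, catchment.Bx, 50)
    low = steady_state_head(catchment, 0.02, x)
    high = steady_state_head(catchment, 0.03, x)
    assert np.all(high > low)


def test_head_outside_domain_rejected(catchment):
    with pytest.raises(ValueError):
        steady_state_head(catchment, 0.02, -1.0)
    with pytest.raises(ValueError):
        steady_state_head(catchment, 0.02, catchment.Bx * 1.01)


def test_steady_head_matches_fd_oracle():
    for c in random_catchments(5, seed=7):
        eta_fd = oc.fd_steady(c.Hi, 1.0, M=200)
        x = np.linspace(0, c.Bx, 201)
        r = 1.0 * c.Bx ** 2 / (c.k0 * c.eta0 * math.cos(c.alpha))
        eta_an = steady_state_head(c, 1.0, x)
        assert np.max(np.abs(eta_an / r - eta_fd)) / np.max(eta_fd) < 0.01


def test_max_head_position_flat_is_divide(flat_catchment):
    res = max_head_position(flat_catchment, 0.02)
    assert res["x_star"] == pytest.approx(flat_catchment.Bx)


def test_max_head_agrees_with_grid_argmax(catchment):
    res = max_head_position(catchment, 0.02)
    x = np.linspace(0, catchment.Bx, 10_001)
    eta = steady_state_head(catchment, 0.02, x)
    i = int(np.argmax(eta))
    assert res["x_star"] == pytest.approx(x[i], abs=2 * catchment.Bx / 10_000)
    assert res["eta_star"] == pytest.approx(eta[i], rel=1e-6)
    assert res["eta_star"] >= eta.max() - 1e-9


def test_max_head_moves_downslope_with_steeper_aquifers():
    base = dict(B=2000.0, A=4e6, k0=300.0, n_e=0.1)
    xs = [max_head_position(SpringCatchment(alpha=a, **base), 0.02)["x_star"]
          / SpringCatchment(alpha=a, **base).Bx
          for a in (0.0, 0.02, 0.05, 0.1, 0.2)]
    assert np.all(np.diff(xs) < 0)


# -- recharge refinement -------------------------------------------------------

def test_refine_recharge_slack_constraint_passes_through(catchment):
    # tiny recharge: water table nowhere near the surface
    assert refine_recharge(catchment, 1e-5) == pytest.approx(1e-5)
    assert refine_recharge(catchment, 0.0) == 0.0


def test_refine_recharge_binding_cap_puts_table_at_surface(catchment):
    R_pot = 10.0  # absurdly wet: cap must bind
    R_ref = refine_recharge(catchment, R_pot)
    assert R_ref < R_pot
    eta_star = max_head_position(catchment, R_ref)["eta_star"]
    assert eta_star == pytest.approx(catchment.D, rel=1e-9)


def test_refine_recharge_matches_grid_search(catchment):
    """Closed-form cap equals the densest feasible recharge found by direct
    grid search within 0.1%."""
    R_grid = np.linspace(1e-6, 10.0, 20_001)
    ok = [R for R in R_grid
          if max_head_position(catchment, R)["eta_star"] <= catchment.D]
    R_ref = refine_recharge(catchment, 10.0)
    assert R_ref == pytest.approx(max(ok), rel=1e-3)


# -- flow rescaling ------------------------------------------------------------

def test_unit_to_total_flow_formula():
    c = SpringCatchment(B=1e3, alpha=0.0, A=1e6, k0=100.0, n_e=0.1)
    assert unit_to_total_flow(1.0, c) == pytest.approx(1e3)
    assert unit_to_total_flow(0.0, c) == 0.0
    with pytest.raises(ValueError):
        unit_to_total_flow(-1.0, c)


def test_steady_mass_balance_closes_over_random_catchments():
    """Steady total flow equals R A / cos(alpha) to better than 0.5%
    (exactly R A on flat aquifers)."""
    for c in random_catchments(10, seed=3):
        R = 0.02
        Q = unit_to_total_flow(
            sudden_recession_discharge(c, R, 0.0), c)
        assert Q == pytest.approx(R * c.A / math.cos(c.alpha), rel=5e-3)
    flat = SpringCatchment(B=1e3, alpha=0.0, A=1e6, k0=100.0, n_e=0.1)
    Q = unit_to_total_flow(sudden_recession_discharge(flat, 0.001, 0.0), flat)
    assert Q == pytest.approx(0.001 * 1e6, rel=1e-12)
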