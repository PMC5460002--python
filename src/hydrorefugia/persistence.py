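"""Spring-persistence metrics.

A spring counts as an active hydro-refugium while its total flow Q stays
above a potability threshold (default 1,000 m^3/y: drinking water for
hundreds of animals plus a small transpiring wetland). Two end-member
climate transitions are considered:

* sudden: recharge steps from the modern steady value down to a floor;
  persistence is the time ``tau`` until Q first falls below the threshold.
* gradual: recharge varies sinusoidally between a floor and the modern
  value; persistence is the longest period ``P_max`` for which Q never
  falls below the threshold at the driest part of the cycle. Long periods
  give the aquifer time to equilibrate to the dry phase, so the cycle
  minimum of Q is non-increasing in P and P_max is found by bisection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .catchment import ClimateForcing, SpringCatchment
from .boussinesq import (
    periodic_flow_range,
    sudden_recession_discharge,
    unit_to_total_flow,
)

DEFAULT_THRESHOLD_Q = 1000.0  # m^3/y
TAU_CAP = 1.0e6               # y; reported explicitly, never silently
P_RANGE_DEFAULT = (1.0, 23000.0)  # y, up to the precessional period


@dataclass(frozen=True)
class PersistenceResult:
    """Per-spring persistence metric with its producing scenario."""

    spring_id: object
    metric_name: str          # "tau_sudden" or "P_max_periodic"
    metric: float             # [y]
    threshold_Q: float        # [m^3/y]
    forcing: ClimateForcing
    active_at_target: bool
    capped: bool = False

    def __post_init__(self) -> None:
        if self.metric < 0:
            raise ValueError("persistence metric must be non-negative")
        if self.threshold_Q <= 0:
            raise ValueError("flow threshold must be positive")


def total_flow_sudden(c: SpringCatchment, R0: float, t,
                      R_floor: float = 0.0,
                      n_terms: int | None = None):
    """Total spring flow Q(t) [m^3/y] during a sudden-transition recession."""
    q = sudden_recession_discharge(c, R0, t, R_floor=R_floor, n_terms=n_terms)
    return unit_to_total_flow(q, c)


def min_cycle_flow(c: SpringCatchment, f: ClimateForcing) -> float:
    """Minimum of Q over one forcing cycle at dynamic equilibrium [m^3/y]."""
    rng = periodic_flow_range(c, f)
    return unit_to_total_flow(max(rng["q_min"], 0.0), c)


def persistence_sudden(c: SpringCatchment, R0: float,
                       threshold_Q: float = DEFAULT_THRESHOLD_Q,
                       R_floor: float = 0.0,
                       t_cap: float = TAU_CAP,
                       n_terms: int | None = None) -> float:
    """Time tau [y] for total flow to fall below ``threshold_Q`` after a step
    from steady recharge ``R0`` to ``R_floor`` [m/y].

    Returns 0 if the initial steady flow is already below the threshold and
    ``t_cap`` (default 1e6 y) if the flow never crosses it — in particular
    when the floor alone sustains the threshold.
    """
    if threshold_Q <= 0:
        raise ValueError("threshold must be positive")
    Q0 = unit_to_total_flow(R0 * c.Bx, c)
    if Q0 < threshold_Q:
        return 0.0
    Q_end = total_flow_sudden(c, R0, t_cap, R_floor=R_floor, n_terms=n_terms)
    if Q_end >= threshold_Q:
        return t_cap
    t_lo = 1e-12
    f = lambda u: total_flow_sudden(c, R0, math.exp(u), R_floor=R_floor,
                                    n_terms=n_terms) - threshold_Q
    if f(math.log(t_lo)) <= 0:
        return 0.0
    u = brentq(f, math.log(t_lo), math.log(t_cap), xtol=1e-12, rtol=8.9e-16)
    return math.exp(u)


def persistence_periodic(c: SpringCatchment, f_template: ClimateForcing,
                         threshold_Q: float = DEFAULT_THRESHOLD_Q,
                         P_range: tuple[float, float] = P_RANGE_DEFAULT) -> float:
    """Longest period P_max [y] of sinusoidal recharge variation (between the
    template's R_min and R_max) for which total flow stays at or above
    ``threshold_Q`` throughout the cycle.

    Returns 0 if the spring is inactive even at the shortest period, and the
    upper end of ``P_range`` (capped) if it survives even there.
    """
    if threshold_Q <= 0:
        raise ValueError("threshold must be positive")
    P_lo, P_hi = P_range
    if not 0 < P_lo < P_hi:
        raise ValueError("invalid period range")

    def margin(P: float) -> float:
        f = ClimateForcing.periodic(f_template.R_max, f_template.R_min, P)
        return min_cycle_flow(c, f) - threshold_Q

    if margin(P_lo) < 0:
        return 0.0
    if margin(P_hi) >= 0:
        return P_hi
    u = brentq(lambda lu: margin(math.exp(lu)),
               math.log(P_lo), math.log(P_hi), xtol=1e-12, rtol=8.9e-16)
    return math.exp(u)


def evaluate_persistence(c: SpringCatchment, forcing: ClimateForcing,
                         threshold_Q: float = DEFAULT_THRESHOLD_Q,
                         P_range: tuple[float, float] = P_RANGE_DEFAULT,
                         ) -> PersistenceResult:
    """Compute the persistence metric matching the forcing mode and wrap it
    with activity/cap flags."""
    if forcing.mode == "sudden":
        tau = persistence_sudden(c, forcing.R_steady, threshold_Q,
                                 R_floor=forcing.R_min)
        return PersistenceResult(
            spring_id=c.spring_id, metric_name="tau_sudden", metric=tau,
            threshold_Q=threshold_Q, forcing=forcing,
            active_at_target=tau > 0, capped=tau >= TAU_CAP)
    P_max = persistence_periodic(c, forcing, threshold_Q, P_range=P_range)
    return PersistenceResult(
        spring_id=c.spring_id, metric_name="P_max_periodic", metric=P_max,
        threshold_Q=threshold_Q, forcing=forcing,
        active_at_target=P_max >= P_range[1], capped=P_max >= P_range[1])
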