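"""Spring-catchment geometry and climate-forcing descriptions.

A spring is modelled as the outlet of a one-dimensional, homogeneous,
isotropic, sloping unconfined aquifer that extends from the spring (Dirichlet
head boundary at ``x = 0``) to the watershed divide (no-flow boundary at
``x = Bx = B / cos(alpha)``), receiving recharge uniformly over its surface.
The governing equation is the linearized Boussinesq equation, with the
water-table height linearized about ``eta0 = p * D``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace


class InvalidGeometryError(ValueError):
    """Raised when catchment geometry parameters are physically inadmissible."""


@dataclass(frozen=True)
class SpringCatchment:
    """Geometric and hydraulic description of one spring's aquifer.

    Parameters
    ----------
    B : float
        Horizontal distance from the spring to the watershed boundary [m].
    alpha : float
        Aquifer slope [radians], ``0 <= alpha < pi/2``.
    A : float
        Upstream contributing catchment area [m^2].
    k0 : float
        Hydraulic conductivity [m/y].
    n_e : float
        Drainable porosity (taken equal to specific yield) [-], in (0, 1).
    D : float
        Maximum saturated thickness [m]; default 100.
    p : float
        Linearization constant setting the mean saturated thickness
        ``eta0 = p * D``; default 0.3.
    """

    B: float
    alpha: float
    A: float
    k0: float
    n_e: float
    D: float = 100.0
    p: float = 0.3
    spring_id: str | int | None = None

    def __post_init__(self) -> None:
        if not self.B > 0:
            raise InvalidGeometryError(f"B must be positive, got {self.B}")
        if not self.A > 0:
            raise InvalidGeometryError(f"A must be positive, got {self.A}")
        if not self.k0 > 0:
            raise InvalidGeometryError(f"k0 must be positive, got {self.k0}")
        if not 0 < self.n_e < 1:
            raise InvalidGeometryError(f"n_e must be in (0,1), got {self.n_e}")
        if not 0 <= self.alpha < math.pi / 2:
            raise InvalidGeometryError(
                f"alpha must be in [0, pi/2), got {self.alpha}"
            )
        if not self.D > 0:
            raise InvalidGeometryError(f"D must be positive, got {self.D}")
        if not 0 < self.p <= 1:
            raise InvalidGeometryError(f"p must be in (0,1], got {self.p}")

    # -- derived geometry ---------------------------------------------------

    @property
    def Bx(self) -> float:
        """Aquifer length measured along the sloping base [m]."""
        return self.B / math.cos(self.alpha)

    @property
    def eta0(self) -> float:
        """Mean saturated thickness used by the linearization [m]."""
        return self.p * self.D

    @property
    def T(self) -> float:
        """Transmissivity ``k0 * eta0`` [m^2/y]."""
        return self.k0 * self.eta0

    @property
    def Hi(self) -> float:
        """Dimensionless slope (hillslope) number ``Bx * tan(alpha) / eta0``.

        Governs the relative strength of gravity-driven advection versus
        diffusion in the sloping-aquifer equation; the recession eigenvalues
        are the roots of ``tan(z) = -2 z / Hi``.
        """
        return self.Bx * math.tan(self.alpha) / self.eta0

    @property
    def diffusivity(self) -> float:
        """Hydraulic diffusivity for a sloping aquifer, ``T/(n_e cos alpha)``."""
        return self.T / (self.n_e * math.cos(self.alpha))

    def with_params(self, **kwargs) -> "SpringCatchment":
        return replace(self, **kwargs)


def effective_geometry(c: SpringCatchment) -> dict:
    """Derived geometry: aquifer length Bx [m], mean thickness eta0 [m],
    transmissivity T [m^2/y]."""
    return {"Bx": c.Bx, "eta0": c.eta0, "T": c.T}


def grt(c: SpringCatchment) -> float:
    """Groundwater response time, ``GRT = B^2 / D_h`` [y].

    ``D_h = T / (n_e cos(alpha))`` is the hydraulic diffusivity of the
    sloping aquifer. The GRT is the characteristic time the aquifer takes to
    equilibrate to changed boundary conditions: springs with large GRT are
    strongly buffered against climate variability.
    """
    if c.T <= 0:
        raise ValueError("transmissivity must be positive")
    return c.B ** 2 / c.diffusivity


@dataclass(frozen=True)
class ClimateForcing:
    """A sudden-cessation or periodic recharge scenario.

    ``mode='sudden'``: recharge drops as a step from the pre-change steady
    value ``R_max`` (alias ``R_steady``) to the floor ``R_min`` at t=0.

    ``mode='periodic'``: recharge varies sinusoidally,
    ``R(t) = R_av + R_amp sin(omega t)`` with ``R_av = (R_max+R_min)/2`` and
    ``R_amp = (R_max-R_min)/2``, so R(t) stays within [R_min, R_max].

    All rates in m/y; period P in years.
    """

    mode: str
    R_max: float
    R_min: float = 0.0
    P: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("sudden", "periodic"):
            raise ValueError(f"unknown forcing mode {self.mode!r}")
        if not (self.R_max >= self.R_min >= 0):
            raise ValueError("require R_max >= R_min >= 0")
        if self.mode == "periodic":
            if self.P is None or not self.P > 0:
                raise ValueError("periodic forcing requires a period P > 0")

    @classmethod
    def sudden(cls, R_steady: float, R_min: float = 0.0) -> "ClimateForcing":
        return cls(mode="sudden", R_max=R_steady, R_min=R_min)

    @classmethod
    def periodic(cls, R_max: float, R_min: float, P: float) -> "ClimateForcing":
        return cls(mode="periodic", R_max=R_max, R_min=R_min, P=P)

    @property
    def R_steady(self) -> float:
        return self.R_max

    @property
    def R_av(self) -> float:
        return 0.5 * (self.R_max + self.R_min)

    @property
    def R_amp(self) -> float:
        return 0.5 * (self.R_max - self.R_min)

    @property
    def omega(self) -> float:
        if self.P is None:
            raise ValueError("omega undefined without a period")
        return 2.0 * math.pi / self.P

    def recharge(self, t):
        """Recharge rate R(t) [m/y] at time t [y] (array-friendly)."""
        import numpy as np

        t = np.asarray(t, dtype=float)
        if self.mode == "sudden":
            return np.where(t < 0, self.R_max, self.R_min)
        return self.R_av + self.R_amp * np.sin(self.omega * t)
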