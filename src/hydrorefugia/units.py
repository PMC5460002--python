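"""Unit conventions.

All internal computation uses SI lengths in metres and time in years.
Recharge rates cross the package boundary in mm/y (the unit used in spring
tables and CLI flags) and are converted exactly once, here.
"""

SECONDS_PER_YEAR = 365.25 * 86400.0  # Julian year


def mm_per_y_to_m_per_y(rate_mm: float) -> float:
    return rate_mm / 1000.0


def m_per_y_to_mm_per_y(rate_m: float) -> float:
    return rate_m * 1000.0


def m_per_s_to_m_per_y(k_m_s: float) -> float:
    """Hydraulic conductivity from m/s (lab convention) to m/y (model unit)."""
    return k_m_s * SECONDS_PER_YEAR


def annual_volume_m3(area_m2: float, depth_mm_per_y: float) -> float:
    """Volume flux [m^3/y] of a depth rate [mm/y] applied over an area [m^2].

    Used e.g. to decompose a spring-flow threshold into a transpiring wetland
    area plus animal drinking demand.
    """
    return area_m2 * mm_per_y_to_m_per_y(depth_mm_per_y)
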