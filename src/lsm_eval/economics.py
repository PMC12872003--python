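"""Labor-cost margin and drone break-even model.

The cost model asks when the up-front purchase of a mapping drone is
repaid by labor savings alone. One larviciding operation over an area of
``S`` km2 saves

    M = R * S * (Ec - Ep)        [GHS per operation]

where ``R`` is the daily wage per worker (GHS/day), ``Ec`` the labor
intensity (person-days per km2, TPDUA) of conventional manual LSM and
``Ep`` that of the drone/AI-assisted method. The drone's cost ``C`` is
recovered after ``C / M`` operations.

The daily wage is derived from a surveyed public-sector net monthly
salary, compounded through annual adjustment fractions and divided by
the working days per month.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

__all__ = [
    "WageParams",
    "CostScenario",
    "derive_daily_wage",
    "worker_cost_margin",
    "break_even_operations",
    "margin_curve",
]


@dataclass(frozen=True)
class WageParams:
    """Wage derivation inputs (defaults: 2022 Ghana public-sector survey
    salary of GHS 2,594/month with +30% and +23% annual adjustments,
    20 working days per month)."""

    base_monthly_salary: float = 2594.0
    annual_adjustments: tuple[float, ...] = (0.30, 0.23)
    working_days_per_month: int = 20

    def __post_init__(self):
        if self.base_monthly_salary <= 0:
            raise ValueError("base_monthly_salary must be > 0")
        if self.working_days_per_month < 1:
            raise ValueError("working_days_per_month must be >= 1")
        if any(a <= -1 for a in self.annual_adjustments):
            raise ValueError("each adjustment must exceed -1")

    @property
    def adjusted_monthly_salary(self) -> float:
        out = self.base_monthly_salary
        for a in self.annual_adjustments:
            out *= 1.0 + a
        return out


@dataclass(frozen=True)
class CostScenario:
    """Inputs of the margin / break-even model (all strictly positive)."""

    daily_wage: float  # R, GHS/day
    operation_area_km2: float  # S
    tpdua_conventional: float  # Ec, person-days/km2
    tpdua_proposed: float  # Ep, person-days/km2
    drone_cost: float = 75_000.0  # GHS

    def __post_init__(self):
        for name in ("daily_wage", "operation_area_km2", "tpdua_conventional",
                     "tpdua_proposed", "drone_cost"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


def derive_daily_wage(p: WageParams) -> float:
    """Daily wage: compounded monthly salary / working days, full precision.

    With the defaults this is 2594 * 1.30 * 1.23 / 20 = 207.39 GHS/day
    (monthly 4147.8).
    """
    return p.adjusted_monthly_salary / p.working_days_per_month


def worker_cost_margin(s: CostScenario) -> float:
    """Labor saving per operation, M = R * S * (Ec - Ep) in GHS.

    Negative when the proposed method is the less efficient one.
    """
    return s.daily_wage * s.operation_area_km2 * (
        s.tpdua_conventional - s.tpdua_proposed
    )


def break_even_operations(s: CostScenario) -> tuple[float, int]:
    """Operations needed to recover the drone cost from labor savings.

    Returns ``(continuous, whole)``: the real-valued ``drone_cost / M``
    and the smallest integer n with ``n * M >= drone_cost``. Raises if
    the margin is non-positive (the investment is never recovered).
    """
    m = worker_cost_margin(s)
    if m <= 0:
        raise ValueError("margin is not positive: drone cost is never recovered")
    continuous = s.drone_cost / m
    whole = math.ceil(continuous)
    # guard against float fuzz at exact multiples
    if (whole - 1) * m >= s.drone_cost:
        whole -= 1
    return continuous, whole


def margin_curve(
    s: CostScenario, areas: Sequence[float]
) -> list[tuple[float, float]]:
    """Margin as a function of operation area, holding R, Ec, Ep fixed.

    Areas of zero are allowed here (margin 0); the curve is strictly
    increasing in area whenever Ec > Ep.
    """
    if len(areas) == 0:
        raise ValueError("areas must be non-empty")
    if any(a < 0 for a in areas):
        raise ValueError("areas must be >= 0")
    unit = s.daily_wage * (s.tpdua_conventional - s.tpdua_proposed)
    return [(float(a), unit * a) for a in areas]
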