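"""Health-economic conversion of pooled effects into events and costs.

A pooled effect in events per 100 registered patients per month is turned
into avoided monthly events for a registered population, annualised, and
multiplied by a per-admission unit cost.  The unit cost converts a
per-episode reference cost to a per-admission cost via the national ratio
of finished consultant episodes (FCE) to finished admission episodes (FAE),
since one admission can span several consultant episodes.

Rounding is half-up at the event and whole-currency level, and monthly
events are rounded before annualising (12 x the rounded monthly figure).
Sensitivity bounds repeat the computation at the 95% CI bounds of the
effect.  Admission and readmission savings are computed separately, never
summed, because avoided readmissions may be a subset of avoided admissions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .errors import ConfigError


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def unit_cost(reference_cost: float, fce: float, fae: float) -> int:
    """Per-admission unit cost: reference cost x FCE/FAE, to whole currency."""
    if reference_cost <= 0 or fce <= 0:
        raise ConfigError("reference_cost and fce must be positive")
    if fae <= 0:
        raise ConfigError("fae must be positive")
    return _round_half_up(reference_cost * fce / fae)


def annualize_events(effect: float, population: int) -> tuple[int, int]:
    """Avoided (monthly, annual) events for an effect per 100 patients/month.

    Monthly events are rounded half-up first; the annual figure is 12 times
    the rounded monthly count.
    """
    if population <= 0:
        raise ConfigError("population must be positive")
    monthly = _round_half_up(abs(effect) / 100.0 * population)
    return monthly, 12 * monthly


@dataclass
class CostResult:
    """Avoided events and annual savings for one pooled effect."""

    population: int
    effect: float
    monthly_events: int
    annual_events: int
    unit_cost: int
    savings: int
    savings_lo: int  # computed at ci95[0]
    savings_hi: int  # computed at ci95[1]
    reference_cost: Optional[float] = None
    fce: Optional[float] = None
    fae: Optional[float] = None


def savings(
    effect: float,
    ci95: tuple[float, float],
    population: int,
    unit_cost_value: int,
) -> CostResult:
    """Annual savings = annual avoided events x unit cost, with CI bounds.

    ``savings_lo``/``savings_hi`` repeat the event-and-cost arithmetic at
    the lower and upper CI bound of the effect (for a reduction, the lower
    bound gives the larger savings figure).
    """
    monthly, annual = annualize_events(effect, population)

    def bound(e: float) -> int:
        _, annual_b = annualize_events(e, population)
        return annual_b * unit_cost_value

    return CostResult(
        population=population,
        effect=float(effect),
        monthly_events=monthly,
        annual_events=annual,
        unit_cost=int(unit_cost_value),
        savings=annual * int(unit_cost_value),
        savings_lo=bound(ci95[0]),
        savings_hi=bound(ci95[1]),
    )


def estimate_savings(
    effect: float,
    ci95: tuple[float, float],
    population: int,
    reference_cost: float,
    fce: float,
    fae: float,
) -> CostResult:
    """Full chain: unit cost from reference inputs, then events and savings."""
    uc = unit_cost(reference_cost, fce, fae)
    result = savings(effect, ci95, population, uc)
    result.reference_cost = float(reference_cost)
    result.fce = float(fce)
    result.fae = float(fae)
    return result
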