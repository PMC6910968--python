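"""Techno-economics: capital scaling, NPV and the minimum selling price.

The minimum selling price (MSP) is the product price at which the project's
net present value over its lifespan is zero.  Capital costs are scaled
across plant capacities with a power-law exponent (default 0.836) and
across years with a cost index (CEPCI); the annual capital charge is the
annuity whose discounted sum repays the capital exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq

DEFAULT_SCALING_EXPONENT = 0.836


class TEAError(ValueError):
    pass


@dataclass(frozen=True)
class CapitalCostSpec:
    """Capital cost with capacity power-law and cost-index adjustments."""

    base_cost: float  # currency at base year
    base_capacity_kt: float
    target_capacity_kt: float
    scaling_exponent: float = DEFAULT_SCALING_EXPONENT
    index_base: float = 1.0
    index_target: float = 1.0

    def __post_init__(self) -> None:
        if self.base_capacity_kt <= 0 or self.target_capacity_kt <= 0:
            raise TEAError("capacities must be positive")
        if not 0.0 < self.scaling_exponent <= 1.0:
            raise TEAError("scaling exponent must be in (0, 1]")
        if self.index_base <= 0 or self.index_target <= 0:
            raise TEAError("cost indices must be positive")


def scale_capital(spec: CapitalCostSpec, fermenter_ratio: float = 1.0) -> float:
    """cost * (capacity ratio)^n * (index ratio), then (fermenter ratio)^n.

    The fermenter ratio carries plant-sizing differences between Monte Carlo
    draws (fermenter count relative to the base design) through the same
    power law.
    """
    if fermenter_ratio <= 0:
        raise TEAError("fermenter ratio must be positive")
    n = spec.scaling_exponent
    return (
        spec.base_cost
        * (spec.target_capacity_kt / spec.base_capacity_kt) ** n
        * (spec.index_target / spec.index_base)
        * fermenter_ratio ** n
    )


def npv(cashflows: Sequence[float], discount_rate: float) -> float:
    """End-of-year discounting; index 0 is the first (construction) year."""
    if len(cashflows) == 0:
        raise TEAError("need at least one cashflow")
    if discount_rate <= -1.0:
        raise TEAError("discount rate must exceed -100%")
    r = 1.0 + discount_rate
    return float(sum(cf / r**t for t, cf in enumerate(cashflows)))


def annualize_capital(capital: float, discount_rate: float, lifespan: int) -> float:
    """Annuity A with sum_{t=1..n} A/(1+r)^t = capital (capital charge)."""
    if lifespan < 1:
        raise TEAError("lifespan must be >= 1 year")
    r = discount_rate
    if abs(r) < 1e-12:
        return capital / lifespan
    return capital * r / (1.0 - (1.0 + r) ** (-lifespan))


@dataclass
class CashflowModel:
    """Cost structure of the plant over construction and production years.

    ``variable_opex`` is $/kg (optionally itemized in ``opex_breakdown``),
    ``fixed_opex`` $/yr, ``capital`` the installed cost already scaled to the
    target capacity and year.  Construction spends the capital over the
    profile years before production starts.
    """

    annual_output_kg: float
    variable_opex: float  # $ / kg
    fixed_opex: float  # $ / yr
    capital: float  # $
    lifespan: int  # production years
    discount_rate: float  # fraction / yr
    construction_profile: tuple[float, ...] = (0.5, 0.5)
    opex_breakdown: Mapping[str, float] = field(default_factory=dict)  # $ / kg items

    def __post_init__(self) -> None:
        if self.annual_output_kg <= 0:
            raise TEAError("annual output must be positive")
        if self.lifespan < 1:
            raise TEAError("lifespan must be >= 1")
        if self.capital < 0 or self.fixed_opex < 0:
            raise TEAError("costs must be non-negative")
        if self.construction_profile and abs(sum(self.construction_profile) - 1.0) > 1e-9:
            raise TEAError("construction profile fractions must sum to 1")

    def cashflows(self, price: float) -> np.ndarray:
        k = len(self.construction_profile)
        flows = np.empty(k + self.lifespan)
        for j, frac in enumerate(self.construction_profile):
            flows[j] = -frac * self.capital
        margin = (price - self.variable_opex) * self.annual_output_kg - self.fixed_opex
        flows[k:] = margin
        return flows

    def npv_at_price(self, price: float) -> float:
        return npv(self.cashflows(price), self.discount_rate)


@dataclass
class TEAResult:
    msp: float  # $ / kg
    npv_at_msp: float  # $, ~0 by construction
    cost_breakdown: dict[str, float]  # $ / kg contributions summing to msp


def minimum_selling_price(
    model: CashflowModel,
    bracket: tuple[float, float] = (0.0, 100.0),
    max_price: float = 1e6,
    xtol: float = 1e-10,
) -> TEAResult:
    """Root-find the price at which project NPV is zero.

    NPV is strictly increasing in price (revenue enters every production
    year with positive discounted weight), so the root is unique.  The
    bracket is widened geometrically up to ``max_price`` if needed.
    """
    lo, hi = bracket
    f_lo = model.npv_at_price(lo)
    if f_lo > 0:
        raise TEAError("NPV already positive at zero price; no MSP below bracket")
    f_hi = model.npv_at_price(hi)
    while f_hi < 0:
        hi *= 2.0
        if hi > max_price:
            raise TEAError(f"no NPV sign change below {max_price} $/kg")
        f_hi = model.npv_at_price(hi)
    msp = brentq(model.npv_at_price, lo, hi, xtol=xtol)

    # breakdown: discounted production-year weight maps capital to a per-kg charge
    r = 1.0 + model.discount_rate
    k = len(model.construction_profile)
    disc_prod = sum(r ** -(k + t) for t in range(model.lifespan))
    pv_capital = sum(frac * r**-j for j, frac in enumerate(model.construction_profile)) \
        * model.capital
    capital_per_kg = pv_capital / (model.annual_output_kg * disc_prod)
    fixed_per_kg = model.fixed_opex / model.annual_output_kg
    breakdown: dict[str, float] = {}
    if model.opex_breakdown:
        breakdown.update({k_: float(v) for k_, v in model.opex_breakdown.items()})
        itemized = sum(model.opex_breakdown.values())
        residual = model.variable_opex - itemized
        if abs(residual) > 1e-12:
            breakdown["other variable opex"] = residual
    else:
        breakdown["variable opex"] = model.variable_opex
    breakdown["fixed opex"] = fixed_per_kg
    breakdown["capital charge"] = capital_per_kg
    return TEAResult(msp=float(msp), npv_at_msp=model.npv_at_price(float(msp)),
                     cost_breakdown=breakdown)
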