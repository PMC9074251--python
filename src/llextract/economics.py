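"""Annualized recovery-cost arithmetic.

Capital is annualized straight-line over the payout time and added to the
annual utility bill; dividing by the annual product mass gives the unit
recovery cost:

    cost [$/kg] = (investment / payout_years + utility_per_year)
                  / (product_rate_kg_h * hours_per_year)

with investment and utilities in USD. An optional capital-recovery-factor
annualization with a discount rate is available but off by default, matching
the plain payout-time convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

__all__ = ["CostTable", "totals", "unit_recovery_cost"]


@dataclass(frozen=True)
class CostTable:
    """Investment line items (million USD) and annual utility line items
    (million USD/yr), with the annualization assumptions."""

    investment_items: Mapping[str, float]
    utility_items: Mapping[str, float]
    payout_years: float = 5.0
    hours_per_year: float = 8000.0

    def __post_init__(self) -> None:
        for name, items in (
            ("investment", self.investment_items),
            ("utility", self.utility_items),
        ):
            if any(v < 0 for v in items.values()):
                raise ValueError(f"negative {name} amount")
        if self.payout_years <= 0:
            raise ValueError("payout_years must be positive")
        if not 0 < self.hours_per_year <= 8784:
            raise ValueError("hours_per_year must be in (0, 8784]")


def totals(table: CostTable) -> tuple[float, float]:
    """(total investment M$, total utilities M$/yr) — exact line-item sums."""
    return (
        float(sum(table.investment_items.values())),
        float(sum(table.utility_items.values())),
    )


def unit_recovery_cost(
    table: CostTable,
    product_rate: float,
    discount_rate: float = 0.0,
) -> float:
    """USD per kg of product recovered.

    product_rate in kg/h. With ``discount_rate`` > 0 the capital charge uses
    the capital recovery factor r(1+r)^n / ((1+r)^n - 1) instead of 1/n.
    """
    if product_rate <= 0:
        raise ValueError("product_rate must be positive")
    inv, util = totals(table)
    if discount_rate > 0:
        r, n = discount_rate, table.payout_years
        crf = r * (1 + r) ** n / ((1 + r) ** n - 1)
        annual_capital = inv * crf
    else:
        annual_capital = inv / table.payout_years
    annual_usd = (annual_capital + util) * 1e6
    return annual_usd / (product_rate * table.hours_per_year)
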