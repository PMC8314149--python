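"""Cost aggregation and scenario comparison for EQA participation fees.

All money is integer euro cents; sums are exact and rounding (half-up)
happens only at the reporting edge.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

from .inventory import EQAScheme, InventoryError
from .scheduler import Plan

__all__ = [
    "CostScenario",
    "annual_cost",
    "scenario_from_plan",
    "compare_scenarios",
    "per_center_budget",
]


@dataclass(frozen=True)
class CostScenario:
    """A named annual-cost scenario, optionally backed by a composition."""

    name: str
    annual_cost_cents: int
    composition: tuple[tuple[int, tuple[tuple[str, int], ...]], ...] | None = None

    def __post_init__(self) -> None:
        if self.annual_cost_cents < 0:
            raise ValueError("annual_cost_cents must be >= 0")
        if self.composition is not None:
            yearly = [sum(fee for _sid, fee in items) for _year, items in self.composition]
            mean = _mean_cents(yearly)
            if mean != self.annual_cost_cents:
                raise ValueError(
                    f"scenario {self.name!r}: annual_cost {self.annual_cost_cents} does not "
                    f"match composition mean {mean}"
                )


def _mean_cents(yearly: list[int]) -> int:
    if not yearly:
        return 0
    mean = Decimal(sum(yearly)) / Decimal(len(yearly))
    return int(mean.quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def annual_cost(assignments: Plan, inventory: list[EQAScheme]) -> tuple[dict[int, int], int]:
    """Exact per-year fee sums of a plan and their mean (cents, half-up)."""
    idx = {s.scheme_id: s for s in inventory}
    per_year: dict[int, int] = {}
    for year in sorted(assignments.assignments):
        total = 0
        for sid in assignments.assignments[year]:
            if sid not in idx:
                raise InventoryError(f"plan references scheme {sid!r} with no known fee")
            total += idx[sid].annual_fee_cents
        per_year[year] = total
    return per_year, _mean_cents(list(per_year.values()))


def scenario_from_plan(
    assignments: Plan, inventory: list[EQAScheme], name: str = "guideline_plan"
) -> CostScenario:
    idx = {s.scheme_id: s for s in inventory}
    per_year, mean = annual_cost(assignments, inventory)
    composition = tuple(
        (
            year,
            tuple((sid, idx[sid].annual_fee_cents) for sid in assignments.assignments[year]),
        )
        for year in sorted(per_year)
    )
    return CostScenario(name=name, annual_cost_cents=mean, composition=composition)


def compare_scenarios(a: CostScenario, b: CostScenario) -> int:
    """Percent reduction of ``b`` relative to ``a``: 100·(a−b)/a, half-up."""
    if a.annual_cost_cents <= 0:
        raise ValueError("reference scenario must have a positive annual cost")
    frac = Decimal(100) * Decimal(a.annual_cost_cents - b.annual_cost_cents) / Decimal(
        a.annual_cost_cents
    )
    return int(frac.quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def per_center_budget(total_cents: int, n_centers: int, rounding_step_cents: int = 100_00) -> int:
    """Mean per-center budget, rounded to the nearest step (default €100)."""
    if n_centers < 1:
        raise ValueError("n_centers must be >= 1")
    if rounding_step_cents <= 0:
        raise ValueError("rounding_step_cents must be positive")
    share = Decimal(total_cents) / Decimal(n_centers) / Decimal(rounding_step_cents)
    steps = int(share.quantize(Decimal("1"), rounding=ROUND_HALF_UP))
    return steps * rounding_step_cents
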