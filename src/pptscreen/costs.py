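"""Euro costs of screening strategies and the fixed-size cohort projection.

Every analyte (TPOAb, TgAb, TSH, FT4/FT3) costs the same flat out-of-pocket
price (default Euro 10).  Gestational screening costs one price per assayed
antibody per screened woman; postpartum monitoring costs
visits x analytes-per-visit x price per monitored woman (default
4 x 2 x 10 = Euro 80).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .strategies import DecisionTable, StrategyDefinition

__all__ = ["CostParams", "CostBreakdown", "strategy_cost", "project_cost"]

REFERENCE_COHORT_SIZE = 412


@dataclass(frozen=True)
class CostParams:
    """Unit prices and the monitoring schedule."""

    analyte_cost: float = 10.0
    monitoring_visits: int = 4
    monitoring_analytes_per_visit: int = 2

    def __post_init__(self) -> None:
        if self.analyte_cost <= 0 or self.monitoring_visits <= 0 or (
            self.monitoring_analytes_per_visit <= 0
        ):
            raise ValueError("all cost parameters must be positive")

    @property
    def monitoring_cost_per_woman(self) -> float:
        return self.monitoring_visits * self.monitoring_analytes_per_visit * self.analyte_cost


@dataclass(frozen=True)
class CostBreakdown:
    """Euro totals; per-case fields are ``None`` when no case was caught."""

    gestational: float
    monitoring: float
    total: float
    per_ppt_caught: Optional[float]
    per_ph_caught: Optional[float]


def strategy_cost(
    decisions: DecisionTable,
    strategy: StrategyDefinition,
    params: CostParams = CostParams(),
) -> CostBreakdown:
    """Cost of one strategy given its per-woman decisions.

    Per-case costs are exact quotients (display rounding is left to
    reporting code).
    """
    gestational = decisions.n_screened * strategy.panel_size * params.analyte_cost
    monitoring = decisions.n_monitored * params.monitoring_cost_per_woman
    total = gestational + monitoring
    return CostBreakdown(
        gestational=gestational,
        monitoring=monitoring,
        total=total,
        per_ppt_caught=total / decisions.n_detected if decisions.n_detected else None,
        per_ph_caught=total / decisions.n_detected_ph if decisions.n_detected_ph else None,
    )


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def project_cost(
    strategy: StrategyDefinition,
    reference_counts: tuple[int, int],
    target_n: int,
    params: CostParams = CostParams(),
    reference_n: int = REFERENCE_COHORT_SIZE,
) -> float:
    """Total cost for a cohort of ``target_n`` women with the same structure.

    The screened and monitored populations are scaled by
    ``target_n / reference_n`` and rounded to the nearest whole woman (half
    away from zero) before costing, so the projection is an integer number
    of assays and visits.  ``target_n == reference_n`` returns the
    unprojected total.
    """
    if target_n <= 0:
        raise ValueError("target_n must be positive")
    n_screened, n_monitored = reference_counts
    scale = target_n / reference_n
    screened = _round_half_away(n_screened * scale)
    monitored = _round_half_away(n_monitored * scale)
    return (
        screened * strategy.panel_size * params.analyte_cost
        + monitored * params.monitoring_cost_per_woman
    )
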