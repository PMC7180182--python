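"""The eleven two-stage screening strategies and their application.

Each strategy combines a gestational screening stage (none, universal, or
selective on the intermediate risk tier) with a postpartum monitoring rule
(who gets TSH plus one free thyroid hormone at four visits in the first
year).  Strategies are labelled ``a`` through ``k``:

===  ====================  ==============  =========  ==================================
id   gestational scope     assay panel     threshold  postpartum monitoring
===  ====================  ==============  =========  ==================================
a    none                  --              --         everyone
b    none                  --              --         history categories II, III, IV
c    none                  --              --         very-high risk tier
d    universal             TPOAb           >100 U/ml  assay positives
e    universal             TPOAb           >60 U/ml   assay positives
f    universal             TPOAb + TgAb    >100 U/ml  assay positives
g    universal             TPOAb + TgAb    >60 U/ml   assay positives
h-k  intermediate tier     as d-g          as d-g     very-high tier + assay positives
===  ====================  ==============  =========  ==================================

Detection is monitoring plus disease: every monitored woman who develops PPT
is counted as caught (the four-visit schedule affects cost, never
sensitivity).
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import Category, RiskTier, WomanRecord

__all__ = [
    "GestationalScope",
    "AssayPanel",
    "Threshold",
    "MonitoringRule",
    "StrategyDefinition",
    "DecisionTable",
    "MissingAntibodyFlagsError",
    "canonical_strategies",
    "get_strategy",
    "apply_strategy",
    "strategies_to_json",
    "strategies_from_json",
]


class GestationalScope(enum.Enum):
    NONE = "none"
    UNIVERSAL = "universal"
    SELECTIVE_186TIER = "selective_186tier"


class AssayPanel(enum.Enum):
    NONE = "none"
    TPOAB = "tpoab"
    TPOAB_AND_TGAB = "tpoab_and_tgab"


class Threshold(enum.Enum):
    GT100 = "gt100"
    GT60 = "gt60"
    NOT_APPLICABLE = "not_applicable"


class MonitoringRule(enum.Enum):
    UNIVERSAL = "universal"
    TIERS_II_III_IV = "tiers_II_III_IV"
    VERY_HIGH_TIER = "very_high_tier"
    ASSAY_POSITIVE = "assay_positive"
    VERY_HIGH_TIER_PLUS_ASSAY_POSITIVE = "very_high_tier_plus_assay_positive"


# Flag attribute consulted for each (panel, threshold) pair.
_FLAG_ATTR = {
    (AssayPanel.TPOAB, Threshold.GT100): "tpoab_gt100",
    (AssayPanel.TPOAB, Threshold.GT60): "tpoab_gt60",
    (AssayPanel.TPOAB_AND_TGAB, Threshold.GT100): "anyab_gt100",
    (AssayPanel.TPOAB_AND_TGAB, Threshold.GT60): "anyab_gt60",
}


@dataclass(frozen=True)
class StrategyDefinition:
    """One screening/monitoring rule; see the module table."""

    id: str
    gestational_scope: GestationalScope
    assay_panel: AssayPanel
    threshold: Threshold
    monitoring_rule: MonitoringRule

    def __post_init__(self) -> None:
        no_assay = self.assay_panel is AssayPanel.NONE
        if no_assay != (self.threshold is Threshold.NOT_APPLICABLE):
            raise ValueError(f"strategy {self.id}: threshold must match assay panel")
        if no_assay != (self.gestational_scope is GestationalScope.NONE):
            raise ValueError(f"strategy {self.id}: scope must match assay panel")
        if self.gestational_scope is GestationalScope.SELECTIVE_186TIER and (
            self.monitoring_rule is not MonitoringRule.VERY_HIGH_TIER_PLUS_ASSAY_POSITIVE
        ):
            raise ValueError(
                f"strategy {self.id}: selective screening requires the combined monitoring rule"
            )

    @property
    def panel_size(self) -> int:
        """Assays per screened woman (0, 1 or 2)."""
        return {AssayPanel.NONE: 0, AssayPanel.TPOAB: 1, AssayPanel.TPOAB_AND_TGAB: 2}[
            self.assay_panel
        ]


def canonical_strategies() -> list[StrategyDefinition]:
    """The eleven published strategies [a]-[k]."""
    out = [
        StrategyDefinition(
            "a",
            GestationalScope.NONE,
            AssayPanel.NONE,
            Threshold.NOT_APPLICABLE,
            MonitoringRule.UNIVERSAL,
        ),
        StrategyDefinition(
            "b",
            GestationalScope.NONE,
            AssayPanel.NONE,
            Threshold.NOT_APPLICABLE,
            MonitoringRule.TIERS_II_III_IV,
        ),
        StrategyDefinition(
            "c",
            GestationalScope.NONE,
            AssayPanel.NONE,
            Threshold.NOT_APPLICABLE,
            MonitoringRule.VERY_HIGH_TIER,
        ),
    ]
    combos = [
        (AssayPanel.TPOAB, Threshold.GT100),
        (AssayPanel.TPOAB, Threshold.GT60),
        (AssayPanel.TPOAB_AND_TGAB, Threshold.GT100),
        (AssayPanel.TPOAB_AND_TGAB, Threshold.GT60),
    ]
    for label, (panel, thr) in zip("defg", combos):
        out.append(
            StrategyDefinition(
                label,
                GestationalScope.UNIVERSAL,
                panel,
                thr,
                MonitoringRule.ASSAY_POSITIVE,
            )
        )
    for label, (panel, thr) in zip("hijk", combos):
        out.append(
            StrategyDefinition(
                label,
                GestationalScope.SELECTIVE_186TIER,
                panel,
                thr,
                MonitoringRule.VERY_HIGH_TIER_PLUS_ASSAY_POSITIVE,
            )
        )
    return out


def get_strategy(label: str) -> StrategyDefinition:
    """Look up a canonical strategy by its letter a-k."""
    for s in canonical_strategies():
        if s.id == label:
            return s
    raise KeyError(f"unknown strategy {label!r}; expected one of a-k")


@dataclass(frozen=True)
class DecisionTable:
    """Per-woman screening and monitoring decisions for one strategy.

    ``detected`` is monitored AND developed PPT; ``detected_ph`` additionally
    requires progression to permanent hypothyroidism.
    """

    strategy_id: str
    ids: tuple[str, ...]
    screened: np.ndarray
    monitored: np.ndarray
    detected: np.ndarray
    detected_ph: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        for name in ("screened", "monitored", "detected", "detected_ph"):
            arr = getattr(self, name)
            if arr.shape != (n,) or arr.dtype != bool:
                raise ValueError(f"{name} must be a boolean array of length {n}")
        if (self.detected & ~self.monitored).any():
            raise ValueError("detected implies monitored")
        if (self.detected_ph & ~self.detected).any():
            raise ValueError("detected_ph implies detected")

    @property
    def n_screened(self) -> int:
        return int(self.screened.sum())

    @property
    def n_monitored(self) -> int:
        return int(self.monitored.sum())

    @property
    def n_detected(self) -> int:
        return int(self.detected.sum())

    @property
    def n_detected_ph(self) -> int:
        return int(self.detected_ph.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "screened": self.screened.astype(int),
                "monitored": self.monitored.astype(int),
                "detected": self.detected.astype(int),
                "detected_ph": self.detected_ph.astype(int),
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, lineterminator="\n")


class MissingAntibodyFlagsError(ValueError):
    """An assay-based strategy was applied to women without antibody flags."""

    def __init__(self, strategy_id: str, ids: Sequence[str]):
        self.ids = list(ids)
        shown = ", ".join(self.ids[:10]) + ("..." if len(self.ids) > 10 else "")
        super().__init__(
            f"strategy {strategy_id} requires antibody flags; missing for "
            f"{len(self.ids)} records: {shown}"
        )


def apply_strategy(
    strategy: StrategyDefinition, cohort: Sequence[WomanRecord]
) -> DecisionTable:
    """Per-woman decisions of one strategy on a cohort.

    Women in the screening scope must carry antibody flags when the strategy
    assays antibodies; otherwise flags are ignored.
    """
    n = len(cohort)
    tiers = np.array([rec.tier.value for rec in cohort])
    ppt = np.array([rec.ppt for rec in cohort], dtype=bool)
    ph = np.array([rec.ph for rec in cohort], dtype=bool)

    if strategy.gestational_scope is GestationalScope.NONE:
        screened = np.zeros(n, dtype=bool)
    elif strategy.gestational_scope is GestationalScope.UNIVERSAL:
        screened = np.ones(n, dtype=bool)
    else:
        screened = tiers == RiskTier.INTERMEDIATE.value

    if strategy.assay_panel is not AssayPanel.NONE:
        missing = [rec.id for rec, s in zip(cohort, screened) if s and rec.antibodies is None]
        if missing:
            raise MissingAntibodyFlagsError(strategy.id, missing)
        flag_attr = _FLAG_ATTR[(strategy.assay_panel, strategy.threshold)]
        positive = np.array(
            [
                bool(rec.antibodies is not None and getattr(rec.antibodies, flag_attr))
                for rec in cohort
            ],
            dtype=bool,
        )
    else:
        positive = np.zeros(n, dtype=bool)

    rule = strategy.monitoring_rule
    if rule is MonitoringRule.UNIVERSAL:
        monitored = np.ones(n, dtype=bool)
    elif rule is MonitoringRule.TIERS_II_III_IV:
        cats = np.array([rec.category for rec in cohort], dtype=object)
        monitored = np.isin(cats, [Category.II, Category.III, Category.IV])
    elif rule is MonitoringRule.VERY_HIGH_TIER:
        monitored = tiers == RiskTier.VERY_HIGH.value
    elif rule is MonitoringRule.ASSAY_POSITIVE:
        monitored = screened & positive
    else:  # very-high tier plus assay positives among the screened
        monitored = (tiers == RiskTier.VERY_HIGH.value) | (screened & positive)

    detected = monitored & ppt
    return DecisionTable(
        strategy_id=strategy.id,
        ids=tuple(rec.id for rec in cohort),
        screened=screened,
        monitored=monitored,
        detected=detected,
        detected_ph=detected & ph,
    )


# --- JSON round-trip --------------------------------------------------------


def strategies_to_json(strategies: Sequence[StrategyDefinition], path: str | Path) -> None:
    payload = [
        {
            "id": s.id,
            "gestational_scope": s.gestational_scope.value,
            "assay_panel": s.assay_panel.value,
            "threshold": s.threshold.value,
            "monitoring_rule": s.monitoring_rule.value,
        }
        for s in strategies
    ]
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def strategies_from_json(path: str | Path) -> list[StrategyDefinition]:
    payload = json.loads(Path(path).read_text())
    return [
        StrategyDefinition(
            id=item["id"],
            gestational_scope=GestationalScope(item["gestational_scope"]),
            assay_panel=AssayPanel(item["assay_panel"]),
            threshold=Threshold(item["threshold"]),
            monitoring_rule=MonitoringRule(item["monitoring_rule"]),
        )
        for item in payload
    ]
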