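"""Diagnostic-performance metrics under the study's denominator conventions.

"Positive" means selected for postpartum monitoring.  The study's false
positive rate is FP / monitored (= 1 - PPV) and its false negative rate is
FN / not-monitored (= 1 - NPV) -- these are complement-of-predictive-value
rates, not the epidemiological 1-specificity / 1-sensitivity.  Diagnostic
accuracy is (TP + TN) over the whole cohort.

For a strategy that monitors everyone, monitoring is surveillance rather
than a diagnostic claim, so the study books no false positives: FP is
defined as 0 and TN as the full non-PPT count.  :func:`confusion` applies
that convention when given a strategy with universal monitoring.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .cohort import WomanRecord
from .strategies import DecisionTable, MonitoringRule, StrategyDefinition

__all__ = ["ConfusionMatrix", "MetricSet", "confusion", "metrics"]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts with monitoring as the positive call: TP = monitored with PPT."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricSet:
    """Proportions in [0, 1]; ``None`` where the denominator is empty."""

    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]
    false_pos_rate: Optional[float]
    false_neg_rate: Optional[float]
    accuracy: Optional[float]
    ppt_missed: Optional[float]


def confusion(
    decisions: DecisionTable,
    cohort: Sequence[WomanRecord],
    strategy: Optional[StrategyDefinition] = None,
) -> ConfusionMatrix:
    """Cross-tabulate monitoring decisions against PPT outcomes.

    Pass the strategy to enable the universal-monitoring convention
    described in the module docstring.
    """
    ids = tuple(rec.id for rec in cohort)
    if ids != decisions.ids:
        raise ValueError("decision table and cohort cover different record ids")
    tp = fp = fn = tn = 0
    for rec, mon in zip(cohort, decisions.monitored):
        if mon and rec.ppt:
            tp += 1
        elif mon:
            fp += 1
        elif rec.ppt:
            fn += 1
        else:
            tn += 1
    if strategy is not None and strategy.monitoring_rule is MonitoringRule.UNIVERSAL:
        tn += fp
        fp = 0
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)


def _ratio(num: int, den: int) -> Optional[float]:
    return num / den if den > 0 else None


def metrics(cm: ConfusionMatrix) -> MetricSet:
    """All study metrics from a confusion matrix.

    Identities (whenever defined): PPV + false_pos_rate = 1,
    NPV + false_neg_rate = 1, ppt_missed = 1 - sensitivity, and
    accuracy = sensitivity * prevalence + specificity * (1 - prevalence).
    """
    sens = _ratio(cm.tp, cm.tp + cm.fn)
    return MetricSet(
        sensitivity=sens,
        specificity=_ratio(cm.tn, cm.tn + cm.fp),
        ppv=_ratio(cm.tp, cm.tp + cm.fp),
        npv=_ratio(cm.tn, cm.tn + cm.fn),
        false_pos_rate=_ratio(cm.fp, cm.tp + cm.fp),
        false_neg_rate=_ratio(cm.fn, cm.tn + cm.fn),
        accuracy=_ratio(cm.tp + cm.tn, cm.total),
        ppt_missed=None if sens is None else 1.0 - sens,
    )
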