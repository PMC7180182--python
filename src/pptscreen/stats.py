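"""2x2 contingency statistics: Pearson chi-square, Fisher's exact test,
Bonferroni correction and odds ratios.

The study compares PPT prevalence between all 28 pairs of the eight history
categories, using the uncorrected Pearson chi-square when expected cell
counts allow and Fisher's exact test otherwise, with Bonferroni adjustment
over the 28 comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd
from scipy import stats as sps

from .cohort import Category

__all__ = [
    "TwoByTwo",
    "pearson_chi2",
    "fisher_exact",
    "bonferroni",
    "odds_ratio",
    "choose_test",
    "run_test",
    "pairwise_ppt_tests",
    "batch_tests",
    "read_tables_csv",
]

#: Default Bonferroni multiplier: all pairwise comparisons among 8 categories.
PAIRWISE_COMPARISONS = 28


@dataclass(frozen=True)
class TwoByTwo:
    """Counts with rows = groups 1/2 and columns = outcome present/absent."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("all cell counts must be non-negative")
        if self.total == 0:
            raise ValueError("table total must be positive")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def margins(self) -> tuple[int, int, int, int]:
        """(row1, row2, col1, col2) totals."""
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)


def pearson_chi2(t: TwoByTwo) -> tuple[float, float]:
    """Uncorrected Pearson chi-square statistic and p-value (1 df).

    statistic = n (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)); no continuity
    correction.  Raises on a zero marginal total.
    """
    r1, r2, c1, c2 = t.margins
    if min(r1, r2, c1, c2) == 0:
        raise ValueError("chi-square undefined: a marginal total is zero")
    num = t.total * (t.a * t.d - t.b * t.c) ** 2
    stat = num / (r1 * r2 * c1 * c2)
    return stat, float(sps.chi2.sf(stat, df=1))


def fisher_exact(t: TwoByTwo) -> float:
    """Two-sided Fisher exact p: sum of hypergeometric probabilities no
    larger than the observed table's, with margins fixed."""
    _, p = sps.fisher_exact([[t.a, t.b], [t.c, t.d]], alternative="two-sided")
    return float(p)


def bonferroni(p_raw: float, m: int = PAIRWISE_COMPARISONS) -> float:
    """Bonferroni-adjusted p-value: min(1, m * p_raw)."""
    if m < 1:
        raise ValueError("number of comparisons must be >= 1")
    return min(1.0, m * p_raw)


def odds_ratio(t: TwoByTwo) -> Optional[float]:
    """Sample odds ratio ad/bc; ``None`` when a denominator cell is zero
    (no continuity adjustment is applied)."""
    if t.b * t.c == 0:
        return None
    return (t.a * t.d) / (t.b * t.c)


def choose_test(t: TwoByTwo) -> str:
    """'fisher' when any expected cell count is below 5, else 'chi2'."""
    r1, r2, c1, c2 = t.margins
    n = t.total
    expected = (r1 * c1 / n, r1 * c2 / n, r2 * c1 / n, r2 * c2 / n)
    return "fisher" if min(expected) < 5 else "chi2"


def run_test(
    t: TwoByTwo, m: int = PAIRWISE_COMPARISONS, rule: str = "auto"
) -> dict[str, object]:
    """Apply the appropriate test and Bonferroni-adjust the p-value.

    ``rule`` is ``auto`` (Fisher when an expected count is below 5),
    ``chi2`` or ``fisher`` to force one test.
    """
    if rule not in ("auto", "chi2", "fisher"):
        raise ValueError("rule must be auto, chi2 or fisher")
    test = choose_test(t) if rule == "auto" else rule
    if test == "chi2":
        stat, p_raw = pearson_chi2(t)
    else:
        stat, p_raw = float("nan"), fisher_exact(t)
    return {
        "test": test,
        "statistic": stat,
        "p_raw": p_raw,
        "p_adjusted": bonferroni(p_raw, m),
    }


def pairwise_ppt_tests(
    category_counts: Mapping[Category, tuple[int, int]],
    m: int = PAIRWISE_COMPARISONS,
    rule: str = "auto",
) -> pd.DataFrame:
    """All pairwise PPT-prevalence comparisons between history categories.

    ``category_counts`` maps each category to (n, n_ppt).  Returns one row
    per unordered pair with the chosen test, statistic (NaN for Fisher),
    raw and adjusted p, and the odds ratio when defined.  ``rule`` as in
    :func:`run_test`; note the published grid reports chi-square statistics
    even for pairs whose expected counts fall below 5.
    """
    cats = [c for c in Category if c in category_counts]
    rows = []
    for i, c1 in enumerate(cats):
        for c2 in cats[i + 1 :]:
            n1, k1 = category_counts[c1]
            n2, k2 = category_counts[c2]
            t = TwoByTwo(k1, n1 - k1, k2, n2 - k2)
            res = run_test(t, m, rule)
            orat = odds_ratio(t)
            rows.append(
                {
                    "category_1": c1.value,
                    "category_2": c2.value,
                    "test": res["test"],
                    "statistic": res["statistic"],
                    "p_raw": res["p_raw"],
                    "p_adjusted": res["p_adjusted"],
                    "odds_ratio": float("nan") if orat is None else orat,
                }
            )
    return pd.DataFrame(rows)


def read_tables_csv(path: str | Path) -> pd.DataFrame:
    """Read a batch of 2x2 tables (columns a,b,c,d; optional label)."""
    df = pd.read_csv(path)
    missing = [c for c in ("a", "b", "c", "d") if c not in df.columns]
    if missing:
        raise ValueError(f"tables CSV missing columns: {missing}")
    return df


def batch_tests(tables: pd.DataFrame, m: int = PAIRWISE_COMPARISONS) -> pd.DataFrame:
    """Run :func:`run_test` on each row of a table batch."""
    rows = []
    for row in tables.itertuples(index=False):
        t = TwoByTwo(int(row.a), int(row.b), int(row.c), int(row.d))
        res = run_test(t, m)
        out = {c: getattr(row, c) for c in tables.columns}
        out.update(res)
        orat = odds_ratio(t)
        out["odds_ratio"] = float("nan") if orat is None else orat
        rows.append(out)
    return pd.DataFrame(rows)
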