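"""Domain types and deterministic stratification rules for the pregnancy cohort.

A woman is characterised by three binary clinical histories (familial thyroid
disease, familial autoimmune non-thyroid disease, personal autoimmune
non-thyroid disease), a seafood-consumption group (A-E) and, once postpartum
follow-up is complete, two nested outcomes: postpartum thyroiditis (PPT)
within 12 months of delivery and permanent hypothyroidism (PH) at month 12.
The three histories define eight mutually exclusive categories I-VIII; the
category crossed with the fish group defines a three-level risk tier that
drives the two-stage screening strategies.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "FishGroup",
    "Category",
    "RiskTier",
    "HistoryProfile",
    "AntibodyFlags",
    "WomanRecord",
    "StratumCell",
    "StratumTable",
    "assign_category",
    "profile_for_category",
    "risk_tier",
    "stratum_table",
    "read_cohort_csv",
    "write_cohort_csv",
    "cohort_to_frame",
]


class FishGroup(enum.Enum):
    """Seafood-consumption group.

    A: selective/predominant swordfish; B: selective/predominant small oily
    fish; C: infrequent swordfish plus other fish; D: other fish only
    (no swordfish, no oily fish); E: no fish (meat eaters).
    """

    A = "A"
    B = "B"
    C = "C"
    D = "D"
    E = "E"


class Category(enum.Enum):
    """History category I-VIII, one per combination of the three histories."""

    I = "I"
    II = "II"
    III = "III"
    IV = "IV"
    V = "V"
    VI = "VI"
    VII = "VII"
    VIII = "VIII"


class RiskTier(enum.Enum):
    """Three-level risk partition of (category, fish group).

    very_high: postpartum monitoring mandatory, no gestational assay needed.
    low: neither gestational assay nor postpartum monitoring.
    intermediate: selective gestational antibody screening.
    """

    VERY_HIGH = "very_high"
    LOW = "low"
    INTERMEDIATE = "intermediate"


def _require_bool(value: object, name: str) -> None:
    if not isinstance(value, bool):
        raise TypeError(f"{name} must be a bool, got {value!r}")


@dataclass(frozen=True)
class HistoryProfile:
    """The three binary anamnestic items collected at enrolment.

    familial_td: thyroid disease in at least one consanguineous relative.
    familial_aintd: autoimmune non-thyroid disease in at least one
        consanguineous relative.
    personal_aintd: autoimmune non-thyroid disease in the woman herself.
    """

    familial_td: bool
    familial_aintd: bool
    personal_aintd: bool

    def __post_init__(self) -> None:
        _require_bool(self.familial_td, "familial_td")
        _require_bool(self.familial_aintd, "familial_aintd")
        _require_bool(self.personal_aintd, "personal_aintd")


# Category <-> history mapping (columns of the published stratification):
# fields ordered (familial_td, familial_aintd, personal_aintd).
_PROFILE_BY_CATEGORY: dict[Category, tuple[bool, bool, bool]] = {
    Category.I: (False, False, False),
    Category.II: (True, True, True),
    Category.III: (True, False, True),
    Category.IV: (False, True, True),
    Category.V: (False, False, True),
    Category.VI: (True, False, False),
    Category.VII: (False, True, False),
    Category.VIII: (True, True, False),
}
_CATEGORY_BY_PROFILE = {v: k for k, v in _PROFILE_BY_CATEGORY.items()}


def assign_category(profile: HistoryProfile) -> Category:
    """Map a history profile to its category I-VIII (a bijection on 2^3)."""
    key = (profile.familial_td, profile.familial_aintd, profile.personal_aintd)
    return _CATEGORY_BY_PROFILE[key]


def profile_for_category(category: Category) -> HistoryProfile:
    """Inverse of :func:`assign_category`."""
    return HistoryProfile(*_PROFILE_BY_CATEGORY[category])


# Risk-tier sets on Category x FishGroup.  The very-high tier is all of
# category II (any fish group), group A of category III, and category IV
# except group B.  The intermediate tier is the set selected for gestational
# antibody screening.  Pairs never observed in the reference cohort
# (II x B, III x {B,D,E}, VIII x E) are assigned by extending the same set
# rules, so the tier is total on all 40 pairs.
_VERY_HIGH_PAIRS = (
    {(Category.II, g) for g in FishGroup}
    | {(Category.III, FishGroup.A)}
    | {(Category.IV, g) for g in FishGroup if g is not FishGroup.B}
)
_INTERMEDIATE_PAIRS = (
    {(Category.I, FishGroup.A), (Category.I, FishGroup.D)}
    | {(Category.IV, FishGroup.B), (Category.V, FishGroup.B)}
    | {(Category.VI, g) for g in (FishGroup.A, FishGroup.B, FishGroup.C, FishGroup.D)}
    | {(Category.VII, g) for g in (FishGroup.A, FishGroup.C, FishGroup.E)}
    | {(Category.VIII, g) for g in (FishGroup.A, FishGroup.B, FishGroup.D)}
)


def risk_tier(
    category: Category,
    fish: FishGroup,
    overrides: Optional[Mapping[tuple[Category, FishGroup], RiskTier]] = None,
) -> RiskTier:
    """Risk tier of a (category, fish group) stratum.

    ``overrides`` may remap individual strata, e.g. to explore alternative
    tier assignments for the pairs absent from the reference cohort.
    """
    pair = (category, fish)
    if overrides is not None and pair in overrides:
        return overrides[pair]
    if pair in _VERY_HIGH_PAIRS:
        return RiskTier.VERY_HIGH
    if pair in _INTERMEDIATE_PAIRS:
        return RiskTier.INTERMEDIATE
    return RiskTier.LOW


@dataclass(frozen=True)
class AntibodyFlags:
    """Nested gestational antibody-positivity flags.

    tpoab_gt100: TPOAb above 100 U/ml (upper limit of the reference range).
    tpoab_gt60: TPOAb above 60 U/ml (upper part of the reference range).
    anyab_gt100 / anyab_gt60: TPOAb and/or TgAb above the same thresholds.

    Nesting invariants: a titre above 100 is above 60, and a positive TPOAb
    makes the any-antibody flag positive at the same threshold.
    """

    tpoab_gt100: bool
    tpoab_gt60: bool
    anyab_gt100: bool
    anyab_gt60: bool

    def __post_init__(self) -> None:
        for name in ("tpoab_gt100", "tpoab_gt60", "anyab_gt100", "anyab_gt60"):
            _require_bool(getattr(self, name), name)
        if self.tpoab_gt100 and not self.tpoab_gt60:
            raise ValueError("tpoab_gt100 implies tpoab_gt60")
        if self.tpoab_gt100 and not self.anyab_gt100:
            raise ValueError("tpoab_gt100 implies anyab_gt100")
        if self.tpoab_gt60 and not self.anyab_gt60:
            raise ValueError("tpoab_gt60 implies anyab_gt60")
        if self.anyab_gt100 and not self.anyab_gt60:
            raise ValueError("anyab_gt100 implies anyab_gt60")


@dataclass(frozen=True)
class WomanRecord:
    """One study participant.

    ``antibodies`` is ``None`` until gestational assays are (really or
    synthetically) performed.  ``ph`` (permanent hypothyroidism at month 12)
    is nested within ``ppt``.
    """

    id: str
    history: HistoryProfile
    fish: FishGroup
    antibodies: Optional[AntibodyFlags]
    ppt: bool
    ph: bool

    def __post_init__(self) -> None:
        _require_bool(self.ppt, "ppt")
        _require_bool(self.ph, "ph")
        if self.ph and not self.ppt:
            raise ValueError(f"record {self.id!r}: ph without ppt is invalid")

    @property
    def category(self) -> Category:
        return assign_category(self.history)

    @property
    def tier(self) -> RiskTier:
        return risk_tier(self.category, self.fish)


@dataclass(frozen=True)
class StratumCell:
    """Counts in one (category, fish group) cell: size, PPT cases, PH cases."""

    n: int
    n_ppt: int
    n_ph: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_ph <= self.n_ppt <= self.n):
            raise ValueError(
                f"invalid cell counts n={self.n}, n_ppt={self.n_ppt}, n_ph={self.n_ph}"
            )


@dataclass(frozen=True)
class StratumTable:
    """Counts of N / PPT / PH per (category, fish group) cell."""

    cells: Mapping[tuple[Category, FishGroup], StratumCell]

    def cell(self, category: Category, fish: FishGroup) -> StratumCell:
        return self.cells.get((category, fish), StratumCell(0, 0, 0))

    def category_totals(self, category: Category) -> StratumCell:
        n = ppt = ph = 0
        for g in FishGroup:
            c = self.cell(category, g)
            n, ppt, ph = n + c.n, ppt + c.n_ppt, ph + c.n_ph
        return StratumCell(n, ppt, ph)

    def totals(self) -> StratumCell:
        n = ppt = ph = 0
        for c in self.cells.values():
            n, ppt, ph = n + c.n, ppt + c.n_ppt, ph + c.n_ph
        return StratumCell(n, ppt, ph)

    def tier_totals(self, tier: RiskTier) -> StratumCell:
        n = ppt = ph = 0
        for (cat, g), c in self.cells.items():
            if risk_tier(cat, g) is tier:
                n, ppt, ph = n + c.n, ppt + c.n_ppt, ph + c.n_ph
        return StratumCell(n, ppt, ph)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "category": cat.value,
                "fish_group": g.value,
                "n": c.n,
                "n_ppt": c.n_ppt,
                "n_ph": c.n_ph,
            }
            for (cat, g), c in sorted(
                self.cells.items(), key=lambda kv: (kv[0][0].value, kv[0][1].value)
            )
        ]
        return pd.DataFrame(rows, columns=["category", "fish_group", "n", "n_ppt", "n_ph"])


def stratum_table(cohort: Iterable[WomanRecord]) -> StratumTable:
    """Cross-tabulate a cohort into (category, fish group) cells.

    Rejects records whose outcomes violate the PH-within-PPT nesting,
    naming the offending record id.
    """
    counts: dict[tuple[Category, FishGroup], list[int]] = {}
    for rec in cohort:
        if rec.ph and not rec.ppt:  # unreachable for validated records
            raise ValueError(f"record {rec.id!r}: ph without ppt is invalid")
        key = (rec.category, rec.fish)
        cell = counts.setdefault(key, [0, 0, 0])
        cell[0] += 1
        cell[1] += int(rec.ppt)
        cell[2] += int(rec.ph)
    return StratumTable({k: StratumCell(*v) for k, v in counts.items()})


# --- Cohort CSV dialect -----------------------------------------------------
# Columns: id,familial_td,familial_aintd,personal_aintd,fish_group,
#          tpoab_gt100,tpoab_gt60,anyab_gt100,anyab_gt60,ppt,ph
# Booleans are 0/1; fish_group a single letter A-E; antibody columns are
# empty when flags have not been allocated; header mandatory; UTF-8.

_CSV_COLUMNS = [
    "id",
    "familial_td",
    "familial_aintd",
    "personal_aintd",
    "fish_group",
    "tpoab_gt100",
    "tpoab_gt60",
    "anyab_gt100",
    "anyab_gt60",
    "ppt",
    "ph",
]
_AB_COLUMNS = ["tpoab_gt100", "tpoab_gt60", "anyab_gt100", "anyab_gt60"]


def cohort_to_frame(cohort: Sequence[WomanRecord]) -> pd.DataFrame:
    """Cohort as a DataFrame in the cohort-CSV column layout."""
    rows = []
    for rec in cohort:
        row: dict[str, object] = {
            "id": rec.id,
            "familial_td": int(rec.history.familial_td),
            "familial_aintd": int(rec.history.familial_aintd),
            "personal_aintd": int(rec.history.personal_aintd),
            "fish_group": rec.fish.value,
            "ppt": int(rec.ppt),
            "ph": int(rec.ph),
        }
        for col in _AB_COLUMNS:
            row[col] = "" if rec.antibodies is None else int(getattr(rec.antibodies, col))
        rows.append(row)
    return pd.DataFrame(rows, columns=_CSV_COLUMNS)


def write_cohort_csv(cohort: Sequence[WomanRecord], path: str | Path) -> None:
    cohort_to_frame(cohort).to_csv(path, index=False, lineterminator="\n")


def read_cohort_csv(path: str | Path) -> list[WomanRecord]:
    df = pd.read_csv(path, dtype={"id": str, "fish_group": str})
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV missing columns: {missing}")
    records: list[WomanRecord] = []
    for row in df.itertuples(index=False):
        flags: Optional[AntibodyFlags]
        ab_vals = [getattr(row, c) for c in _AB_COLUMNS]
        if all(pd.isna(v) or v == "" for v in ab_vals):
            flags = None
        else:
            flags = AntibodyFlags(*(bool(int(v)) for v in ab_vals))
        records.append(
            WomanRecord(
                id=str(row.id),
                history=HistoryProfile(
                    bool(int(row.familial_td)),
                    bool(int(row.familial_aintd)),
                    bool(int(row.personal_aintd)),
                ),
                fish=FishGroup(row.fish_group),
                antibodies=flags,
                ppt=bool(int(row.ppt)),
                ph=bool(int(row.ph)),
            )
        )
    return records
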