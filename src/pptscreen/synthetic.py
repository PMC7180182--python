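"""Synthetic reconstruction and simulation of the reference cohort.

The published study prints its full stratified counts: cohort size, PPT and
PH cases per (category, fish group) cell, and the aggregate antibody-screening
results (positives and true positives at each of four threshold levels,
overall and within the intermediate screening tier, plus PH among the cases
each strategy detects).  No per-woman data are deposited.  This module
rebuilds a woman-level cohort that is exactly consistent with every printed
aggregate:

* :func:`reconstruct_reference_cohort` — deterministic expansion of the
  stratified cell counts into 412 records (antibody flags unset);
* :func:`allocate_antibody_flags` — deterministic greedy allocation of the
  four nested positivity flags so that all screening aggregates are met;
* :func:`sample_cohort` — a seeded sampler for new cohorts with the same
  (or perturbed) stratum structure, for robustness experiments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import (
    AntibodyFlags,
    Category,
    FishGroup,
    HistoryProfile,
    RiskTier,
    StratumCell,
    StratumTable,
    WomanRecord,
    profile_for_category,
    risk_tier,
)

__all__ = [
    "AllocationConstraints",
    "AllocationInfeasibleError",
    "SamplerParams",
    "reference_constraints",
    "reconstruct_reference_cohort",
    "allocate_antibody_flags",
    "sample_cohort",
    "draw_antibody_titres",
    "load_table2",
    "PH_CORRECTIONS",
]

# The printed PH cells of the stratification table sum to 35, while the
# category totals, the overall 34-PH count and the tier-level PH aggregates
# all require 34, with category VI contributing 1 (not 2).  Both VI cells
# with a printed PH of 1 (groups B and C) lie in the intermediate tier, so
# either one may be zeroed without disturbing any printed aggregate; the
# reconstruction fixes VI x B to 0 and keeps VI x C at 1.
PH_CORRECTIONS: dict[tuple[Category, FishGroup], int] = {
    (Category.VI, FishGroup.B): 0,
}


def _data_path(name: str):
    return resources.files("pptscreen.data").joinpath(name)


def load_table2(path: str | Path | None = None) -> StratumTable:
    """Load the checked-in transcription of the published stratum table.

    The PH correction above is applied after loading, so the returned table
    totals 412 women, 63 PPT and 34 PH.
    """
    if path is None:
        with resources.as_file(_data_path("table2.csv")) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    cells: dict[tuple[Category, FishGroup], StratumCell] = {}
    for row in df.itertuples(index=False):
        key = (Category(row.category), FishGroup(row.fish_group))
        n_ph = PH_CORRECTIONS.get(key, int(row.n_ph))
        cells[key] = StratumCell(int(row.n), int(row.n_ppt), n_ph)
    return StratumTable(cells)


def reconstruct_reference_cohort(
    table2_path: str | Path | None = None,
) -> list[WomanRecord]:
    """Expand the stratified counts into an ordered woman-level cohort.

    Within each (category, fish group) cell, PPT cases with PH come first,
    then PPT cases without PH, then unaffected women; ids are sequential
    ``W0001``..``W0412``.  Antibody flags are left unset.
    """
    table = load_table2(table2_path)
    records: list[WomanRecord] = []
    idx = 0
    for cat in Category:
        profile = profile_for_category(cat)
        for g in FishGroup:
            cell = table.cell(cat, g)
            for j in range(cell.n):
                ppt = j < cell.n_ppt
                ph = j < cell.n_ph
                idx += 1
                records.append(
                    WomanRecord(
                        id=f"W{idx:04d}",
                        history=profile,
                        fish=g,
                        antibodies=None,
                        ppt=ppt,
                        ph=ph,
                    )
                )
    return records


# --- Antibody-flag allocation ----------------------------------------------


class AllocationInfeasibleError(ValueError):
    """Raised when the screening aggregates cannot be realised on a cohort.

    The message names the first violated constraint.
    """


@dataclass(frozen=True)
class AllocationConstraints:
    """Aggregate antibody-screening counts the allocation must reproduce.

    Keys are strategy labels: ``d``-``g`` are the whole-cohort positives at
    the four threshold levels (TPOAb>100, TPOAb>60, any-Ab>100, any-Ab>60);
    ``h``-``k`` are the same levels restricted to the intermediate screening
    tier.  ``true_positives`` count PPT cases among the positives.
    ``ph_among_detected`` gives, per strategy, the PH cases among the PPT
    cases that strategy detects (for ``a``-``c`` this is implied by the
    cohort itself and is used as a cross-check only).
    """

    overall_positives: Mapping[str, int]
    overall_true_positives: Mapping[str, int]
    within186_positives: Mapping[str, int]
    within186_true_positives: Mapping[str, int]
    ph_among_detected: Mapping[str, int]


def reference_constraints(path: str | Path | None = None) -> AllocationConstraints:
    """Load the published screening aggregates used for calibration."""
    if path is None:
        with resources.as_file(_data_path("table3_constraints.json")) as p:
            raw = json.loads(Path(p).read_text())
    else:
        raw = json.loads(Path(path).read_text())
    return AllocationConstraints(
        overall_positives=dict(raw["overall_positives"]),
        overall_true_positives=dict(raw["overall_true_positives"]),
        within186_positives=dict(raw["within186_positives"]),
        within186_true_positives=dict(raw["within186_true_positives"]),
        ph_among_detected=dict(raw["ph_among_detected"]),
    )


# Flag classes, tightest first.  Each woman falls in exactly one class; the
# class determines all four nested flags.  The class with TPOAb in (60,100]
# AND TgAb>100 is deliberately left empty: the printed aggregates do not
# require it, and leaving it empty makes the decomposition unique.
_CLASSES = ("T100", "T60", "G100", "G60", "NEG")
_FLAGS_BY_CLASS: dict[str, AntibodyFlags] = {
    "T100": AntibodyFlags(True, True, True, True),
    "T60": AntibodyFlags(False, True, False, True),
    "G100": AntibodyFlags(False, False, True, True),
    "G60": AntibodyFlags(False, False, False, True),
    "NEG": AntibodyFlags(False, False, False, False),
}


def _class_decomposition(
    counts: Mapping[str, int], keys: tuple[str, str, str, str], label: str
) -> dict[str, int]:
    """Decompose nested level counts (at keys d<e, d<f, e,f<g) into classes."""
    k1, k2, k3, k4 = keys
    out = {
        "T100": counts[k1],
        "T60": counts[k2] - counts[k1],
        "G100": counts[k3] - counts[k1],
        "G60": counts[k4] - counts[k2] - counts[k3] + counts[k1],
    }
    for cls, v in out.items():
        if v < 0:
            raise AllocationInfeasibleError(
                f"{label} violate threshold nesting at class {cls} (count {v})"
            )
    return out


@dataclass
class _Quota:
    pos: int
    tp: int
    ph: int

    def __post_init__(self) -> None:
        self.nonppt = self.pos - self.tp
        self.tp_nonph = self.tp - self.ph


def _derive_quotas(
    constraints: AllocationConstraints, vh_ph_detected: int
) -> dict[str, dict[str, _Quota]]:
    """Per-region (within/outside the intermediate tier), per-class quotas."""
    ov_pos = _class_decomposition(
        constraints.overall_positives, ("d", "e", "f", "g"), "overall_positives"
    )
    ov_tp = _class_decomposition(
        constraints.overall_true_positives, ("d", "e", "f", "g"), "overall_true_positives"
    )
    wi_pos = _class_decomposition(
        constraints.within186_positives, ("h", "i", "j", "k"), "within186_positives"
    )
    wi_tp = _class_decomposition(
        constraints.within186_true_positives,
        ("h", "i", "j", "k"),
        "within186_true_positives",
    )
    ph = constraints.ph_among_detected
    # PH among assay-detected within the screening tier: the selective
    # strategies also detect the very-high tier's PH cases, which must be
    # subtracted before decomposition.
    wi_ph_counts = {s: ph[s] - vh_ph_detected for s in ("h", "i", "j", "k")}
    for s, v in wi_ph_counts.items():
        if v < 0:
            raise AllocationInfeasibleError(
                f"ph_among_detected[{s}]={ph[s]} below the very-high tier's "
                f"{vh_ph_detected} PH cases"
            )
    wi_ph = _class_decomposition(
        {"h": wi_ph_counts["h"], "i": wi_ph_counts["i"], "j": wi_ph_counts["j"], "k": wi_ph_counts["k"]},
        ("h", "i", "j", "k"),
        "ph_among_detected[h..k]",
    )
    ov_ph = _class_decomposition(
        {"d": ph["d"], "e": ph["e"], "f": ph["f"], "g": ph["g"]},
        ("d", "e", "f", "g"),
        "ph_among_detected[d..g]",
    )

    quotas: dict[str, dict[str, _Quota]] = {"within": {}, "outside": {}}
    for cls in _CLASSES[:-1]:
        for name, pos, tp, phc in (
            ("within", wi_pos[cls], wi_tp[cls], wi_ph[cls]),
            ("outside", ov_pos[cls] - wi_pos[cls], ov_tp[cls] - wi_tp[cls], ov_ph[cls] - wi_ph[cls]),
        ):
            if pos < 0 or tp < 0 or phc < 0:
                raise AllocationInfeasibleError(
                    f"within-tier counts exceed overall counts at class {cls} ({name})"
                )
            if tp > pos:
                raise AllocationInfeasibleError(
                    f"true positives exceed positives at class {cls} ({name}): {tp} > {pos}"
                )
            if phc > tp:
                raise AllocationInfeasibleError(
                    f"PH cases exceed true positives at class {cls} ({name}): {phc} > {tp}"
                )
            quotas[name][cls] = _Quota(pos, tp, phc)
    return quotas


def allocate_antibody_flags(
    cohort: Sequence[WomanRecord], constraints: AllocationConstraints
) -> list[WomanRecord]:
    """Assign nested antibody flags so all screening aggregates hold exactly.

    Deterministic greedy procedure: the cohort is split into the intermediate
    screening tier ("within") and its complement ("outside"); in each region,
    flag classes are filled tightest first (TPOAb>100, then TPOAb in
    (60,100], then TgAb>100, then TgAb in (60,100]), taking PH-positive PPT
    cases first, then PH-negative PPT cases, then unaffected women, in the
    cohort's own deterministic order.  Raises
    :class:`AllocationInfeasibleError` naming the first violated constraint.
    """
    tiers = [risk_tier(rec.category, rec.fish) for rec in cohort]
    vh_ph = sum(
        1 for rec, t in zip(cohort, tiers) if t is RiskTier.VERY_HIGH and rec.ppt and rec.ph
    )
    quotas = _derive_quotas(constraints, vh_ph)

    regions = {
        "within": [i for i, t in enumerate(tiers) if t is RiskTier.INTERMEDIATE],
        "outside": [i for i, t in enumerate(tiers) if t is not RiskTier.INTERMEDIATE],
    }
    assigned: dict[int, str] = {}
    for region, idxs in regions.items():
        pools = {
            "ph": [i for i in idxs if cohort[i].ppt and cohort[i].ph],
            "tp_nonph": [i for i in idxs if cohort[i].ppt and not cohort[i].ph],
            "nonppt": [i for i in idxs if not cohort[i].ppt],
        }
        need_ph = sum(q.ph for q in quotas[region].values())
        need_tp_nonph = sum(q.tp_nonph for q in quotas[region].values())
        need_nonppt = sum(q.nonppt for q in quotas[region].values())
        for pool_name, need, field_name in (
            ("ph", need_ph, "ph_among_detected"),
            ("tp_nonph", need_tp_nonph, "true_positives"),
            ("nonppt", need_nonppt, "positives"),
        ):
            if need > len(pools[pool_name]):
                raise AllocationInfeasibleError(
                    f"{field_name} demand {need} exceeds the {len(pools[pool_name])} "
                    f"available {pool_name.replace('_', ' ')} women in the "
                    f"{region} region"
                )
        cursors = {k: 0 for k in pools}

        def take(pool: str, count: int) -> list[int]:
            start = cursors[pool]
            cursors[pool] = start + count
            return pools[pool][start : start + count]

        for cls in _CLASSES[:-1]:
            q = quotas[region][cls]
            for i in take("ph", q.ph) + take("tp_nonph", q.tp_nonph) + take("nonppt", q.nonppt):
                assigned[i] = cls

    out = [
        replace(rec, antibodies=_FLAGS_BY_CLASS[assigned.get(i, "NEG")])
        for i, rec in enumerate(cohort)
    ]
    _audit_allocation(out, constraints)
    return out


def _audit_allocation(
    cohort: Sequence[WomanRecord], constraints: AllocationConstraints
) -> None:
    """Defensive recount of every constrained aggregate after allocation."""
    level_by_strategy = {
        "d": "tpoab_gt100",
        "e": "tpoab_gt60",
        "f": "anyab_gt100",
        "g": "anyab_gt60",
        "h": "tpoab_gt100",
        "i": "tpoab_gt60",
        "j": "anyab_gt100",
        "k": "anyab_gt60",
    }
    inter = [r for r in cohort if risk_tier(r.category, r.fish) is RiskTier.INTERMEDIATE]
    vh_ph = sum(
        1 for r in cohort if risk_tier(r.category, r.fish) is RiskTier.VERY_HIGH and r.ph
    )
    for s in ("d", "e", "f", "g"):
        flag = level_by_strategy[s]
        pos = [r for r in cohort if getattr(r.antibodies, flag)]
        checks = [
            (constraints.overall_positives[s], len(pos), f"overall_positives[{s}]"),
            (
                constraints.overall_true_positives[s],
                sum(r.ppt for r in pos),
                f"overall_true_positives[{s}]",
            ),
            (
                constraints.ph_among_detected[s],
                sum(r.ph for r in pos),
                f"ph_among_detected[{s}]",
            ),
        ]
        for expected, actual, name in checks:
            if expected != actual:
                raise RuntimeError(f"allocation audit failed: {name} {actual} != {expected}")
    for s in ("h", "i", "j", "k"):
        flag = level_by_strategy[s]
        pos = [r for r in inter if getattr(r.antibodies, flag)]
        checks = [
            (constraints.within186_positives[s], len(pos), f"within186_positives[{s}]"),
            (
                constraints.within186_true_positives[s],
                sum(r.ppt for r in pos),
                f"within186_true_positives[{s}]",
            ),
            (
                constraints.ph_among_detected[s],
                vh_ph + sum(r.ph for r in pos),
                f"ph_among_detected[{s}]",
            ),
        ]
        for expected, actual, name in checks:
            if expected != actual:
                raise RuntimeError(f"allocation audit failed: {name} {actual} != {expected}")


# --- Stochastic cohort sampler ----------------------------------------------


@dataclass(frozen=True)
class SamplerParams:
    """Parameters for drawing i.i.d. synthetic cohorts.

    ``strata`` lists the (category, fish group) pairs; ``stratum_probs``,
    ``ppt_rate`` and ``ph_given_ppt`` are aligned with it.
    ``flag_class_probs`` gives, per (risk tier, PPT status), a length-5
    probability vector over the antibody flag classes
    (TPOAb>100, TPOAb 60-100, TgAb>100, TgAb 60-100, negative), so sampled
    flags respect the nesting invariants by construction.
    """

    n: int
    strata: tuple[tuple[Category, FishGroup], ...]
    stratum_probs: tuple[float, ...]
    ppt_rate: tuple[float, ...]
    ph_given_ppt: tuple[float, ...]
    flag_class_probs: Mapping[tuple[RiskTier, bool], tuple[float, ...]]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be non-negative")
        k = len(self.strata)
        if not (len(self.stratum_probs) == len(self.ppt_rate) == len(self.ph_given_ppt) == k):
            raise ValueError("stratum-aligned arrays must share the strata length")
        probs = np.asarray(self.stratum_probs, dtype=float)
        if (probs < 0).any() or not np.isclose(probs.sum(), 1.0):
            raise ValueError("stratum_probs must be non-negative and sum to 1")
        for name in ("ppt_rate", "ph_given_ppt"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if ((arr < 0) | (arr > 1)).any():
                raise ValueError(f"{name} entries must lie in [0, 1]")
        for key, vec in self.flag_class_probs.items():
            v = np.asarray(vec, dtype=float)
            if len(v) != 5 or (v < 0).any() or not np.isclose(v.sum(), 1.0):
                raise ValueError(f"flag_class_probs[{key}] must be a length-5 simplex vector")

    @classmethod
    def from_reference(cls, n: int = 412, seed: int = 0) -> "SamplerParams":
        """Calibrate all rates to the reconstructed reference cohort."""
        cohort = allocate_antibody_flags(
            reconstruct_reference_cohort(), reference_constraints()
        )
        return cls.from_cohort(cohort, n=n, seed=seed)

    @classmethod
    def from_cohort(
        cls, cohort: Sequence[WomanRecord], n: int, seed: int = 0
    ) -> "SamplerParams":
        """Empirical rates from any cohort carrying antibody flags."""
        keys = sorted(
            {(r.category, r.fish) for r in cohort}, key=lambda k: (k[0].value, k[1].value)
        )
        total = len(cohort)
        probs, ppt_rates, ph_rates = [], [], []
        for key in keys:
            members = [r for r in cohort if (r.category, r.fish) == key]
            n_ppt = sum(r.ppt for r in members)
            probs.append(len(members) / total)
            ppt_rates.append(n_ppt / len(members))
            ph_rates.append(sum(r.ph for r in members) / n_ppt if n_ppt else 0.0)
        class_probs: dict[tuple[RiskTier, bool], tuple[float, ...]] = {}
        for tier in RiskTier:
            for ppt in (False, True):
                members = [
                    r
                    for r in cohort
                    if risk_tier(r.category, r.fish) is tier and r.ppt == ppt
                ]
                if not members:
                    class_probs[(tier, ppt)] = (0.0, 0.0, 0.0, 0.0, 1.0)
                    continue
                counts = np.zeros(5)
                for r in members:
                    counts[_CLASSES.index(_class_of(r.antibodies))] += 1
                class_probs[(tier, ppt)] = tuple(counts / counts.sum())
        return cls(
            n=n,
            strata=tuple(keys),
            stratum_probs=tuple(probs),
            ppt_rate=tuple(ppt_rates),
            ph_given_ppt=tuple(ph_rates),
            flag_class_probs=class_probs,
            seed=seed,
        )


def _class_of(flags: Optional[AntibodyFlags]) -> str:
    if flags is None:
        return "NEG"
    if flags.tpoab_gt100:
        return "T100"
    if flags.tpoab_gt60:
        return "T60"
    if flags.anyab_gt100:
        return "G100"
    if flags.anyab_gt60:
        return "G60"
    return "NEG"


def sample_cohort(params: SamplerParams) -> list[WomanRecord]:
    """Draw ``params.n`` independent synthetic women (seeded, reproducible)."""
    rng = np.random.default_rng(params.seed)
    k = len(params.strata)
    stratum_idx = rng.choice(k, size=params.n, p=np.asarray(params.stratum_probs))
    u_ppt = rng.random(params.n)
    u_ph = rng.random(params.n)
    u_cls = rng.random(params.n)
    records: list[WomanRecord] = []
    ppt_rate = np.asarray(params.ppt_rate)
    ph_rate = np.asarray(params.ph_given_ppt)
    for i in range(params.n):
        cat, g = params.strata[stratum_idx[i]]
        ppt = bool(u_ppt[i] < ppt_rate[stratum_idx[i]])
        ph = bool(ppt and u_ph[i] < ph_rate[stratum_idx[i]])
        tier = risk_tier(cat, g)
        cum = np.cumsum(params.flag_class_probs[(tier, ppt)])
        cls = _CLASSES[int(np.searchsorted(cum, u_cls[i], side="right"))]
        records.append(
            WomanRecord(
                id=f"S{i + 1:06d}",
                history=profile_for_category(cat),
                fish=g,
                antibodies=_FLAGS_BY_CLASS[cls],
                ppt=ppt,
                ph=ph,
            )
        )
    return records


def draw_antibody_titres(
    cohort: Sequence[WomanRecord], seed: int = 0
) -> pd.DataFrame:
    """Optional continuous titres (U/ml) consistent with each woman's flags.

    TPOAb is drawn uniformly in (100, 300] / (60, 100] / [0, 60] according to
    its band; a TgAb titre above 60 is drawn only when an any-antibody flag
    is not already explained by TPOAb.  The study prints no per-woman titres,
    so these are convenience values for downstream tooling, not data.
    """
    rng = np.random.default_rng(seed)

    def band(low: float, high: float) -> float:
        return float(low + (high - low) * rng.random())

    rows = []
    for rec in cohort:
        f = rec.antibodies
        if f is None:
            rows.append({"id": rec.id, "tpoab": np.nan, "tgab": np.nan})
            continue
        if f.tpoab_gt100:
            tpo = band(100.0, 300.0)
        elif f.tpoab_gt60:
            tpo = band(60.0, 100.0)
        else:
            tpo = band(0.0, 60.0)
        if f.anyab_gt100 and not f.tpoab_gt100:
            tga = band(100.0, 300.0)
        elif f.anyab_gt60 and not f.tpoab_gt60 and not f.anyab_gt100:
            tga = band(60.0, 100.0)
        else:
            tga = band(0.0, 60.0)
        rows.append({"id": rec.id, "tpoab": tpo, "tgab": tga})
    return pd.DataFrame(rows, columns=["id", "tpoab", "tgab"])
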