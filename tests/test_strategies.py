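"""Strategy definitions and their application to cohorts."""

import dataclasses

import pytest

from pptscreen import (
    AssayPanel,
    GestationalScope,
    MissingAntibodyFlagsError,
    MonitoringRule,
    RiskTier,
    SamplerParams,
    StrategyDefinition,
    Threshold,
    apply_strategy,
    canonical_strategies,
    get_strategy,
    risk_tier,
    sample_cohort,
)
from pptscreen.strategies import strategies_from_json, strategies_to_json

from expected_values import DETECTED_PH, CONFUSION, N_ASSAYED, N_MONITORED


def test_canonical_strategies_are_the_eleven_published_rules():
    strategies = canonical_strategies()
    assert [s.id for s in strategies] == list("abcdefghijk")
    a = get_strategy("a")
    assert a.monitoring_rule is MonitoringRule.UNIVERSAL
    assert a.assay_panel is AssayPanel.NONE
    for label in "hijk":
        s = get_strategy(label)
        assert s.gestational_scope is GestationalScope.SELECTIVE_186TIER
        assert s.monitoring_rule is MonitoringRule.VERY_HIGH_TIER_PLUS_ASSAY_POSITIVE
    with pytest.raises(KeyError):
        get_strategy("z")


def test_invalid_strategy_combinations_rejected():
    with pytest.raises(ValueError):
        StrategyDefinition(
            "x", GestationalScope.NONE, AssayPanel.TPOAB, Threshold.GT60,
            MonitoringRule.ASSAY_POSITIVE,
        )
    with pytest.raises(ValueError):
        StrategyDefinition(
            "x", GestationalScope.SELECTIVE_186TIER, AssayPanel.TPOAB, Threshold.GT60,
            MonitoringRule.ASSAY_POSITIVE,
        )


@pytest.mark.parametrize("label", list("abcdefghijk"))
def test_population_rows_on_reference_cohort(label, flagged_cohort):
    """Assayed, monitored, detected and PH-detected counts match the
    published strategy table for every strategy."""
    dec = apply_strategy(get_strategy(label), flagged_cohort)
    assert dec.n_screened == N_ASSAYED[label]
    assert dec.n_monitored == N_MONITORED[label]
    tp = CONFUSION[label][0]
    assert dec.n_detected == tp
    assert dec.n_detected_ph == DETECTED_PH[label]


def test_universal_monitoring_detects_every_ppt_case(flagged_cohort):
    dec = apply_strategy(get_strategy("a"), flagged_cohort)
    assert dec.n_screened == 0
    assert dec.n_detected == sum(r.ppt for r in flagged_cohort) == 63


def test_history_only_strategies_need_no_flags(reference_cohort):
    # b and c never assay, so they run on a cohort without antibody flags
    assert apply_strategy(get_strategy("b"), reference_cohort).n_monitored == 31
    assert apply_strategy(get_strategy("c"), reference_cohort).n_monitored == 26


def test_assay_strategy_without_flags_raises_listing_ids(reference_cohort):
    with pytest.raises(MissingAntibodyFlagsError) as exc:
        apply_strategy(get_strategy("d"), reference_cohort)
    assert "W0001" in str(exc.value)


@pytest.mark.parametrize("chain", [("d", "e", "g"), ("d", "f", "g"), ("h", "i", "k"), ("h", "j", "k")])
@pytest.mark.parametrize("seed", [0, 1, 2])
def test_threshold_nesting_of_monitored_sets(chain, seed, flagged_cohort):
    """Widening the assay threshold or panel only ever adds monitored women."""
    cohort = (
        flagged_cohort
        if seed == 0
        else sample_cohort(SamplerParams.from_reference(n=412, seed=seed))
    )
    decs = [apply_strategy(get_strategy(label), cohort) for label in chain]
    for narrow, wide in zip(decs, decs[1:]):
        assert not (narrow.monitored & ~wide.monitored).any()


@pytest.mark.parametrize("label", list("hijk"))
def test_selective_strategies_screen_exactly_the_intermediate_tier(label, flagged_cohort):
    dec = apply_strategy(get_strategy(label), flagged_cohort)
    for rec, screened, monitored in zip(flagged_cohort, dec.screened, dec.monitored):
        tier = risk_tier(rec.category, rec.fish)
        assert screened == (tier is RiskTier.INTERMEDIATE)
        if tier is RiskTier.LOW:
            assert not monitored
        if tier is RiskTier.VERY_HIGH:
            assert monitored


def test_no_positives_means_nothing_monitored(reference_cohort):
    from pptscreen import AntibodyFlags

    negative = [
        dataclasses.replace(r, antibodies=AntibodyFlags(False, False, False, False))
        for r in reference_cohort
    ]
    dec = apply_strategy(get_strategy("d"), negative)
    assert dec.n_screened == 412
    assert dec.n_monitored == 0
    assert dec.n_detected == 0


def test_detected_never_exceeds_ppt_total(flagged_cohort):
    total_ppt = sum(r.ppt for r in flagged_cohort)
    for strat in canonical_strategies():
        assert apply_strategy(strat, flagged_cohort).n_detected <= total_ppt


def test_strategy_json_roundtrip(tmp_path):
    path = tmp_path / "strategies.json"
    strategies_to_json(canonical_strategies(), path)
    assert strategies_from_json(path) == canonical_strategies()


def test_decision_table_csv(tmp_path, flagged_cohort):
    dec = apply_strategy(get_strategy("k"), flagged_cohort)
    path = tmp_path / "decisions.csv"
    dec.to_csv(path)
    header = path.read_text().splitlines()[0]
    assert header == "id,screened,monitored,detected,detected_ph"
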