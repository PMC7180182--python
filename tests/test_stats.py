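"""2x2 contingency statistics against printed values and brute-force oracles."""

from math import comb

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pptscreen import (
    Category,
    TwoByTwo,
    bonferroni,
    choose_test,
    fisher_exact,
    odds_ratio,
    pairwise_ppt_tests,
    pearson_chi2,
    stratum_table,
)
from pptscreen.stats import batch_tests, run_test

from expected_values import CHI2_GRID, ODDS_RATIOS


def _category_ppt_counts(cohort):
    table = stratum_table(cohort)
    return {
        c: (table.category_totals(c).n, table.category_totals(c).n_ppt) for c in Category
    }


@pytest.mark.parametrize("pair, printed", sorted(CHI2_GRID.items()))
def test_printed_chi_square_grid(pair, printed, reference_cohort):
    """Each printed pairwise chi-square statistic is reproduced from the
    category PPT counts to the printed precision (within half a unit in the
    first decimal; two of the ten are printed rounded down)."""
    counts = _category_ppt_counts(reference_cohort)
    (n1, k1), (n2, k2) = (counts[Category(pair[0])], counts[Category(pair[1])])
    stat, p = pearson_chi2(TwoByTwo(k1, n1 - k1, k2, n2 - k2))
    assert stat == pytest.approx(printed, abs=0.06)
    assert 0 < p < 1e-4


def test_chi_square_examples_from_printed_counts():
    stat, _ = pearson_chi2(TwoByTwo(9, 84, 12, 0))  # categories I vs II
    assert round(stat, 1) == 54.2
    stat, _ = pearson_chi2(TwoByTwo(12, 0, 3, 75))  # categories II vs V
    assert round(stat, 1) == 69.2
    stat, p = pearson_chi2(TwoByTwo(5, 5, 5, 5))
    assert stat == 0.0 and p == 1.0


def test_adjusted_p_for_categories_i_vs_iv(reference_cohort):
    """chi2 = 40.8 at 1 df, Bonferroni x28, gives the printed 4.8e-9."""
    counts = _category_ppt_counts(reference_cohort)
    (n1, k1), (n2, k2) = counts[Category.I], counts[Category.IV]
    _, p_raw = pearson_chi2(TwoByTwo(k1, n1 - k1, k2, n2 - k2))
    assert bonferroni(p_raw, 28) == pytest.approx(4.8e-9, rel=0.05)


def test_chi_square_zero_margin_rejected():
    with pytest.raises(ValueError, match="marginal"):
        pearson_chi2(TwoByTwo(0, 0, 5, 5))


@given(
    a=st.integers(0, 40), b=st.integers(0, 40), c=st.integers(0, 40), d=st.integers(0, 40)
)
@settings(max_examples=200, deadline=None, derandomize=True)
def test_chi_square_invariant_under_table_symmetries(a, b, c, d):
    t = TwoByTwo(a + 1, b + 1, c + 1, d + 1)  # keep margins positive
    stat, _ = pearson_chi2(t)
    transposed, _ = pearson_chi2(TwoByTwo(t.a, t.c, t.b, t.d))
    row_swap, _ = pearson_chi2(TwoByTwo(t.c, t.d, t.a, t.b))
    col_swap, _ = pearson_chi2(TwoByTwo(t.b, t.a, t.d, t.c))
    assert stat == pytest.approx(transposed)
    assert stat == pytest.approx(row_swap)
    assert stat == pytest.approx(col_swap)


def _fisher_enumeration_oracle(t: TwoByTwo) -> float:
    """Two-sided Fisher p by exhaustive enumeration over all tables with the
    observed margins: sum hypergeometric probabilities <= the observed one."""
    r1, r2, c1 = t.a + t.b, t.c + t.d, t.a + t.c
    n = r1 + r2

    def pmf(x: int) -> float:
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    p_obs = pmf(t.a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return min(1.0, sum(pmf(x) for x in range(lo, hi + 1) if pmf(x) <= p_obs * (1 + 1e-7)))


def test_fisher_examples():
    # categories III vs IV: small counts, non-significant
    assert fisher_exact(TwoByTwo(2, 2, 12, 3)) > 0.05
    # no outcome variation
    assert fisher_exact(TwoByTwo(0, 7, 0, 9)) == pytest.approx(1.0)


@given(
    a=st.integers(0, 30), b=st.integers(0, 30), c=st.integers(0, 30), d=st.integers(0, 30)
)
@settings(max_examples=300, deadline=None, derandomize=True)
def test_fisher_matches_enumeration_oracle_on_small_tables(a, b, c, d):
    if a + b + c + d == 0 or a + b + c + d > 30:
        return
    t = TwoByTwo(a, b, c, d)
    assert fisher_exact(t) == pytest.approx(_fisher_enumeration_oracle(t), rel=1e-6)


def test_bonferroni_cap_identity_and_scaling():
    assert bonferroni(0.2, 28) == 1.0
    assert bonferroni(0.01, 1) == 0.01
    assert bonferroni(1.7e-10, 28) == pytest.approx(4.76e-9, rel=1e-2)
    with pytest.raises(ValueError):
        bonferroni(0.1, 0)


@pytest.mark.parametrize("cells, expected", ODDS_RATIOS)
def test_history_odds_ratios(cells, expected):
    """The three history-item odds ratios from the printed 2x2 counts."""
    assert round(odds_ratio(TwoByTwo(*cells)), 2) == expected


def test_odds_ratio_degenerate_cases():
    assert round(odds_ratio(TwoByTwo(7, 7, 7, 7)), 2) == 1.00
    assert odds_ratio(TwoByTwo(5, 0, 3, 2)) is None


def test_choose_test_uses_expected_counts():
    assert choose_test(TwoByTwo(9, 84, 12, 0)) == "fisher"  # expected 2.4 < 5
    assert choose_test(TwoByTwo(50, 50, 50, 50)) == "chi2"
    forced = run_test(TwoByTwo(9, 84, 12, 0), rule="chi2")
    assert forced["test"] == "chi2"
    assert forced["statistic"] == pytest.approx(54.2, abs=0.05)


def test_pairwise_grid_shape_and_significance(reference_cohort):
    counts = _category_ppt_counts(reference_cohort)
    df = pairwise_ppt_tests(counts)
    assert len(df) == 28
    sig = df[df.p_adjusted < 0.05]
    # the ten significant pairs all involve the high-risk categories II or IV
    assert set(map(tuple, sig[["category_1", "category_2"]].values)) == set(CHI2_GRID)


def test_batch_tests(tmp_path):
    import pandas as pd

    from pptscreen.stats import read_tables_csv

    path = tmp_path / "tables.csv"
    pd.DataFrame(
        [{"label": "x", "a": 50, "b": 50, "c": 50, "d": 50},
         {"label": "y", "a": 2, "b": 2, "c": 12, "d": 3}]
    ).to_csv(path, index=False)
    out = batch_tests(read_tables_csv(path), m=2)
    assert list(out.test) == ["chi2", "fisher"]
    assert (out.p_adjusted <= 1.0).all()
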