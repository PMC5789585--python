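"""Discrimination, calibration and rate estimation."""

import numpy as np
import pytest
from scipy import stats

from opmort import (
    auc_ci,
    calibration_table,
    hosmer_lemeshow,
    load_model,
    mortality_rate,
    recalibrate,
    roc_auc,
    validate_model,
)
from opmort.scoring import complete_case_filter, predict_frame
from opmort.validation import UndefinedStatisticError, bivariate_screen


def brute_force_auc(p, y):
    """All-pairs concordance oracle: concordant + half ties over
    events x non-events."""
    p, y = np.asarray(p, float), np.asarray(y, bool)
    events, nonevents = p[y], p[~y]
    total = conc = ties = 0
    for a in events:
        for b in nonevents:
            total += 1
            if a > b:
                conc += 1
            elif a == b:
                ties += 1
    return (conc + 0.5 * ties) / total


@pytest.mark.parametrize(
    "p,y,expected",
    [
        ([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0], 1.0),  # perfect separation
        ([0.3, 0.3, 0.3, 0.3], [1, 0, 1, 0], 0.5),  # all tied
        ([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1], 0.75),  # 3 concordant of 4 pairs
    ],
)
def test_auc_fixed_examples(p, y, expected):
    assert roc_auc(p, y) == pytest.approx(expected)


def test_auc_undefined_without_both_classes():
    with pytest.raises(UndefinedStatisticError):
        roc_auc([0.1, 0.2], [1, 1])
    with pytest.raises(UndefinedStatisticError):
        roc_auc([0.1, 0.2], [0, 0])


def test_auc_equals_all_pairs_oracle_on_random_instances():
    """Rank-statistic AUC == exhaustive pairwise oracle, including ties."""
    rng = np.random.default_rng(1)
    for _ in range(60):
        n = rng.integers(4, 200)
        p = rng.choice(np.round(rng.uniform(0, 1, 10), 2), size=n)
        y = rng.uniform(size=n) < 0.3
        if 0 < y.sum() < n:
            assert roc_auc(p, y) == pytest.approx(brute_force_auc(p, y), abs=1e-12)


def test_auc_rank_statistic_properties():
    """Complement symmetry for tie-free predictions; invariance under any
    strictly monotone transform of the predictions."""
    rng = np.random.default_rng(2)
    p = rng.permutation(np.linspace(0.01, 0.99, 80))
    y = rng.uniform(size=80) < 0.25
    a = roc_auc(p, y)
    assert a + roc_auc(p, ~y) == pytest.approx(1.0)
    assert roc_auc(1 / (1 + np.exp(-(5 * p - 1))), y) == pytest.approx(a)
    assert roc_auc(np.log(p), y) == pytest.approx(a)


def test_auc_ci_width_shrinks_and_clips():
    rng = np.random.default_rng(3)

    def sample(n):
        y = rng.uniform(size=n) < 0.2
        p = np.where(y, rng.normal(0.6, 0.2, n), rng.normal(0.4, 0.2, n))
        return np.clip(p, 0, 1), y

    p_small, y_small = sample(300)
    p_big, y_big = sample(6000)
    lo_s, hi_s = auc_ci(p_small, y_small)
    lo_b, hi_b = auc_ci(p_big, y_big)
    assert hi_b - lo_b < hi_s - lo_s
    for lo, hi, p, y in [(lo_s, hi_s, p_small, y_small)]:
        assert lo <= roc_auc(p, y) <= hi

    # degenerate perfect separation clips at 1.0
    _, hi = auc_ci([0.9, 0.9, 0.1, 0.1], [1, 1, 0, 0])
    assert hi == 1.0

    lo, hi = auc_ci(p_small, y_small, method="bootstrap", n_boot=200, seed=0)
    assert 0.0 <= lo < hi <= 1.0


def test_hosmer_lemeshow_perfect_fit_is_zero():
    """Observed deaths equal expected in every group: statistic 0, p = 1."""
    p = np.full(40, 0.5)
    y = np.tile([True, False], 20)
    result = hosmer_lemeshow(p, y, groups=10)
    stat, df, pval = result
    assert stat == pytest.approx(0.0)
    assert pval == pytest.approx(1.0)


def test_hosmer_lemeshow_two_group_hand_oracle():
    """Two risk groups checked against the four-cell chi-square by hand."""
    p = np.array([0.1] * 10 + [0.3] * 10)
    y = np.array([True, True] + [False] * 8 + [True] * 3 + [False] * 7)
    result = hosmer_lemeshow(p, y, groups=2)
    # group A: n=10, expected 1.0, observed 2; group B: n=10, expected 3.0, observed 3
    expected_stat = (2 - 1) ** 2 / 1 + (8 - 9) ** 2 / 9 + 0.0 + 0.0
    assert result.statistic == pytest.approx(expected_stat)
    assert result.df == 1  # floor of groups-2 at 1
    assert result.p_value == pytest.approx(stats.chi2.sf(expected_stat, 1))


def test_hosmer_lemeshow_invariances():
    """Row order cannot matter when predictions are distinct (the grouping
    depends only on ranks); merging a zero-expected group conserves totals."""
    rng = np.random.default_rng(4)
    p = rng.uniform(0.01, 0.3, 500)  # distinct almost surely
    y = rng.uniform(size=500) < p
    base = hosmer_lemeshow(p, y)
    order = rng.permutation(500)
    shuffled = hosmer_lemeshow(p[order], y[order])
    assert shuffled.statistic == pytest.approx(base.statistic)
    assert shuffled.df == base.df

    # a block of zero predictions forces a zero-expected group merge
    p2 = np.concatenate([np.zeros(60), p])
    y2 = np.concatenate([np.zeros(60, bool), y])
    merged = hosmer_lemeshow(p2, y2)
    assert merged.n_merged >= 1
    assert merged.table["n"].sum() == len(p2)
    assert merged.table["observed"].sum() == y2.sum()


def test_calibration_table_conservation_and_empty_bands():
    p = np.array([0.05, 0.1, 0.2, 0.4])
    y = np.array([0, 0, 1, 1], bool)
    single = calibration_table(p, y, bands=[0.0, 1.0])
    assert single.table.loc[0, "expected"] == pytest.approx(p.sum())
    assert single.table.loc[0, "observed"] == 2
    assert single.oe_ratio == pytest.approx(2 / p.sum())

    banded = calibration_table(p, y, bands=[0.0, 0.5, 0.9, 1.0])
    assert banded.table.loc[2, "n"] == 0  # empty top band emitted
    assert banded.table["n"].sum() == 4


def test_recalibrated_oe_is_one_on_fitting_cohort(complete_cohort, cr_possum):
    """Logistic MLE equates mean predicted risk with the event rate."""
    result = recalibrate(complete_cohort, cr_possum)
    assert result.post_report.calibration.oe_ratio == pytest.approx(1.0, abs=1e-6)


@pytest.mark.parametrize(
    "events,n,rate,lo,hi",
    [
        (41, 2749, 1.5, 1.0, 1.9),
        (47, 2749, 1.7, 1.2, 2.2),
        (0, 100, 0.0, 0.0, 0.0),
    ],
)
def test_mortality_rate_normal_ci(events, n, rate, lo, hi):
    """Crude rates and CIs agree with the normal approximation to one
    decimal on the percent scale."""
    est = mortality_rate(events, n)
    assert round(est.rate_pct, 1) == rate
    assert round(est.ci_pct[0], 1) == lo
    assert round(est.ci_pct[1], 1) == hi
    assert 0 <= est.ci_pct[0] <= est.rate_pct <= est.ci_pct[1] <= 100


def test_mortality_rate_errors_and_exact_method():
    with pytest.raises(UndefinedStatisticError):
        mortality_rate(0, 0)
    exact = mortality_rate(2, 1000, method="exact")
    assert exact.ci_pct[0] > 0.0 and exact.ci_pct[1] < 1.0 * 100


def test_validation_report_invariants(default_cohort, cr_possum):
    """Calibration totals reconcile with the analyzed N and included deaths;
    the CI brackets the AUC."""
    report = validate_model(default_cohort, cr_possum)
    assert report.auc_ci[0] <= report.auc <= report.auc_ci[1]
    assert report.calibration.table["n"].sum() == report.n_analyzed
    assert report.calibration.table["observed"].sum() == report.deaths_included
    assert 0 <= report.hl_p <= 1
    assert report.exclusion_log.n_retained == report.n_analyzed


def test_afc_validation_is_na_but_counts_are_real(default_cohort):
    afc = load_model("AFC")
    report = validate_model(default_cohort, afc)
    assert report.auc is None and report.hl_p is None
    assert report.n_analyzed > 0
    retained, _ = complete_case_filter(default_cohort, afc)
    assert report.n_analyzed == len(retained)


def test_bivariate_screen_switches_tests(default_cohort):
    table = bivariate_screen(
        default_cohort, ["urgency", "weight_loss_gt10pct", "dukes_stage"]
    )
    assert set(table["variable"]) == {"urgency", "weight_loss_gt10pct", "dukes_stage"}
    ok = table[table["test"] != "NA"]
    assert ((ok["p_value"] >= 0) & (ok["p_value"] <= 1)).all()
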