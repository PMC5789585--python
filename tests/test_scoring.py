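"""Score models: category weights, score sums, logistic predictions."""

import math

import numpy as np
import pandas as pd
import pytest

from opmort import (
    assign_weights,
    complete_case_filter,
    compute_scores,
    frame_to_cohort,
    load_model,
    predict_frame,
    predict_risk,
    score_frame,
)
from opmort.registry import (
    load_coefficients,
    load_definition,
    save_coefficients,
    save_definition,
)
from opmort.scoring import (
    ConfigurationError,
    MissingVariableError,
    ScoreComponents,
)

from conftest import make_reference_record


@pytest.mark.parametrize(
    "field,value,variable,expected_weight",
    [
        ("urgency", "scheduled", "urgency", 1),
        ("urgency", "urgent", "urgency", 3),
        ("urgency", "emergency", "urgency", 8),
        ("peritoneal_contamination", "none_or_serous", "peritoneal_contamination", 1),
        ("peritoneal_contamination", "local_pus", "peritoneal_contamination", 2),
        ("peritoneal_contamination", "free_pus_faeces_blood", "peritoneal_contamination", 3),
        ("heart_failure", "severe", "heart_failure", 3),
        ("age", 81, "age", 8),
        ("operative_severity", "moderate", "operative_severity", 3),
    ],
)
def test_cr_possum_category_weights(cr_possum, field, value, variable, expected_weight):
    """Each CR-POSSUM category carries its published integer weight."""
    record = make_reference_record(**{field: value})
    assert assign_weights(record, cr_possum)[variable] == expected_weight


def test_minimum_scores(cr_possum):
    """A patient in the lowest bin of every variable scores PS=6, OS=4
    (six physiological and four operative variables, minimum weight 1)."""
    record = make_reference_record(operative_severity="minor")
    scores = compute_scores(record, cr_possum)
    assert scores.physiological_score == 6
    assert scores.operative_score == 4


def test_hand_summed_score_oracle(cr_possum):
    """PS/OS of a fixed high-risk record equal an independently summed
    oracle over its per-variable weights."""
    record = make_reference_record(
        age=75, heart_failure="moderate", sbp=95, heart_rate=110,
        urea=12.0, haemoglobin=9.0, operative_severity="complex_major",
        peritoneal_contamination="local_pus", urgency="urgent", dukes_stage="C",
    )
    # frozen independent weight table for this record's categories
    expected_ps = 4 + 2 + 2 + 2 + 2 + 3  # age, HF, SBP, HR, urea, Hb
    expected_os = 8 + 2 + 3 + 2  # severity, contamination, urgency, stage
    scores = compute_scores(record, cr_possum)
    assert scores.physiological_score == expected_ps
    assert scores.operative_score == expected_os


def test_missing_variable_error_names_variable(cr_possum):
    record = make_reference_record(urea=None)
    with pytest.raises(MissingVariableError) as err:
        assign_weights(record, cr_possum)
    assert "urea" in str(err.value)
    assert "CR_POSSUM" in str(err.value)


def test_predict_risk_logit_identities(cr_possum):
    """lp=0 maps to probability 0.5; a +1 PS step strictly raises risk; a
    fixed (PS, OS) pair matches a hand-evaluated inverse logit."""
    coef = cr_possum.coefficient_set
    zero = predict_risk(ScoreComponents(0, 0), coef.__class__(
        model_id="toy", intercept=0.0, terms={"physiological_score": 0.0, "operative_score": 0.0}))
    assert zero.probability == 0.5

    lo = predict_risk(ScoreComponents(10, 9), coef)
    hi = predict_risk(ScoreComponents(11, 9), coef)
    assert hi.probability > lo.probability

    lp = -9.167 + 0.338 * 15 + 0.308 * 15
    expected = 1.0 / (1.0 + math.exp(-lp))
    got = predict_risk(ScoreComponents(15, 15), coef)
    assert got.probability == pytest.approx(expected, rel=1e-12)
    assert got.linear_predictor == pytest.approx(lp, rel=1e-12)


def test_predict_risk_missing_coefficient_is_config_error(cr_possum):
    broken = cr_possum.coefficient_set.__class__(
        model_id="CR_POSSUM", intercept=-9.167, terms={"physiological_score": 0.338})
    with pytest.raises(ConfigurationError):
        predict_risk(ScoreComponents(10, 9), broken)


def test_possum_and_p_possum_share_components(complete_cohort):
    """POSSUM and P-POSSUM bin identically; only coefficients differ."""
    possum, p_possum = load_model("POSSUM"), load_model("P_POSSUM")
    sample = complete_cohort.head(500)
    a = score_frame(sample, possum)
    b = score_frame(sample, p_possum)
    pd.testing.assert_frame_equal(a, b)
    assert possum.coefficient_set.terms != p_possum.coefficient_set.terms


@pytest.mark.parametrize("model_id", ["POSSUM", "P_POSSUM", "CR_POSSUM", "AFC", "IRCS"])
def test_record_loop_matches_vectorized_and_never_errors(model_id, complete_cohort):
    """Fuzz over realistic in-range records: every record gets a weight for
    every variable (bin completeness), score sums equal the brute-force sum
    of per-variable weights, and the vectorized path agrees exactly."""
    definition = load_model(model_id)
    sample = complete_cohort.sample(n=300, random_state=42).reset_index(drop=True)
    scored = score_frame(sample, definition)
    for idx, record in enumerate(frame_to_cohort(sample)):
        weights = assign_weights(record, definition)  # must not raise
        for name, w in weights.items():
            assert scored.loc[idx, f"w_{name}"] == w
        if definition.family == "score_link":
            scores = compute_scores(record, definition)
            assert scores.physiological_score == sum(
                weights[v] for v in definition.groups["physiological"])
            assert scores.operative_score == sum(
                weights[v] for v in definition.groups["operative"])
            assert scored.loc[idx, "physiological_score"] == scores.physiological_score
            assert scored.loc[idx, "operative_score"] == scores.operative_score


@pytest.mark.parametrize("model_id", ["CR_POSSUM", "IRCS"])
def test_monotone_in_every_weight(model_id):
    """Raising any single variable to a heavier category never lowers the
    predicted probability (positive weights, positive coefficients)."""
    definition = load_model(model_id)
    base = make_reference_record()
    base_p = predict_risk(base, definition.coefficient_set, definition).probability
    bumps = dict(
        age=85, heart_failure="severe", sbp=85, heart_rate=130, urea=20.0,
        haemoglobin=8.0, operative_severity="complex_major",
        peritoneal_contamination="free_pus_faeces_blood", urgency="emergency",
        dukes_stage="D", respiratory_status="dyspnoea_at_rest",
    )
    for field, value in bumps.items():
        if field not in {v.field for v in definition.variables.values()}:
            continue
        bumped = make_reference_record(**{field: value})
        p = predict_risk(bumped, definition.coefficient_set, definition).probability
        assert p >= base_p


def test_registry_roundtrip_bitwise(tmp_path, cr_possum, complete_cohort):
    """Serialize + reload a definition and coefficient set: predictions on a
    fixture cohort are reproduced bit for bit."""
    dpath, cpath = tmp_path / "def.json", tmp_path / "coef.json"
    save_definition(cr_possum, str(dpath))
    save_coefficients(cr_possum.coefficient_set, str(cpath))
    reloaded = load_definition(str(dpath)).with_coefficients(load_coefficients(str(cpath)))
    sample = complete_cohort.head(200)
    before = predict_frame(sample, cr_possum)["probability"].to_numpy()
    after = predict_frame(sample, reloaded)["probability"].to_numpy()
    assert np.array_equal(before, after)


def test_complete_case_filter_accounting(cr_possum):
    records = [
        make_reference_record(patient_id="a"),
        make_reference_record(patient_id="b", urea=None),
        make_reference_record(patient_id="c"),
    ]
    retained, log = complete_case_filter(records, cr_possum)
    assert [r.patient_id for r in retained] == ["a", "c"]
    assert log.n_input == 3 and log.n_retained == 2 and log.n_excluded == 1
    assert log.by_variable["urea"] == 1
    assert log.n_retained + log.n_excluded == log.n_input

    all_clean, log2 = complete_case_filter(records[:1] * 3, cr_possum)
    assert len(all_clean) == 3 and log2.n_excluded == 0

    empty, log3 = complete_case_filter([], cr_possum)
    assert empty == [] and log3.n_input == 0


def test_complete_case_rate_matches_independence_product(cr_possum):
    """Under MCAR with the published per-variable missingness, the retained
    fraction matches the product of per-variable availabilities."""
    from opmort import CohortConfig, generate_cohort
    from opmort.synthetic import DEFAULT_MISSINGNESS

    n = 30000
    cohort = generate_cohort(CohortConfig(n_patients=n, seed=23))
    _, log = complete_case_filter(cohort, cr_possum)
    expected = 1.0
    for field in cr_possum.required_fields:
        expected *= 1.0 - DEFAULT_MISSINGNESS.get(field, 0.0)
    se = math.sqrt(expected * (1 - expected) / n)
    assert abs(log.n_retained / n - expected) < 3 * se
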