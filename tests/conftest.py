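import pandas as pd
import pytest

from opmort import CohortConfig, PatientRecord, generate_cohort, load_model


def make_reference_record(**overrides) -> PatientRecord:
    """A fully specified, clinically unremarkable elective colon-cancer
    patient; tests perturb single fields from this baseline."""
    base = dict(
        patient_id="ref-001",
        age=55,
        sex="male",
        tumor_site="colon",
        heart_failure="none_or_mild",
        respiratory_status="no_dyspnoea",
        sbp=120.0,
        heart_rate=70.0,
        glasgow_coma_score=15,
        urea=5.0,
        haemoglobin=14.0,
        leucocytes=7.0,
        sodium=140.0,
        potassium=4.2,
        ecg="normal",
        weight_loss_gt10pct=False,
        neuro_comorbidity=False,
        urgency="scheduled",
        operative_severity="major",
        n_procedures=1,
        blood_loss=150.0,
        peritoneal_contamination="none_or_serous",
        dukes_stage="A_B",
        death_inhospital=False,
        death_30day=False,
    )
    base.update(overrides)
    return PatientRecord(**base)


@pytest.fixture(scope="session")
def reference_record() -> PatientRecord:
    return make_reference_record()


@pytest.fixture(scope="session")
def default_cohort() -> pd.DataFrame:
    """Study-sized cohort under the default conditions (with missingness)."""
    return generate_cohort(CohortConfig(n_patients=3000, seed=11))


@pytest.fixture(scope="session")
def complete_cohort() -> pd.DataFrame:
    """Mid-sized cohort with no missingness, for fitting/statistics tests."""
    return generate_cohort(CohortConfig(n_patients=20000, seed=5, missingness={}))


@pytest.fixture(scope="session")
def cr_possum():
    return load_model("CR_POSSUM")


@pytest.fixture(scope="session")
def all_models():
    return {m: load_model(m) for m in ("POSSUM", "P_POSSUM", "CR_POSSUM", "AFC", "IRCS")}
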