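"""Risk-score computation: clinical variables -> weights -> scores -> risk.

Two model families are supported.  The POSSUM family (POSSUM, P-POSSUM,
CR-POSSUM) sums integer category weights into a physiological score (PS) and
an operative severity score (OS) and pushes ``intercept + b_PS*PS + b_OS*OS``
through the logistic link.  The category family (AFC, IRCS) enters one
coefficient per non-reference category of each variable directly into the
linear predictor.

The record-level operations (:func:`assign_weights`, :func:`compute_scores`,
:func:`predict_risk`) define the semantics; :func:`score_frame` and
:func:`predict_frame` are the vectorized cohort path used by the validation
and recalibration engines and are tested for exact agreement with the
record-level loop.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd

from .records import PatientRecord, as_frame, cohort_to_frame, frame_to_cohort
from .registry import Bin, CoefficientSet, RegistryError, ScoreDefinition, VariableDef

PS_TERM = "physiological_score"
OS_TERM = "operative_score"


class MissingVariableError(ValueError):
    """A model variable required for scoring is missing on the record."""

    def __init__(self, variable: str, model_id: str, patient_id: str = ""):
        self.variable = variable
        self.model_id = model_id
        self.patient_id = patient_id
        who = f" (patient {patient_id})" if patient_id else ""
        super().__init__(
            f"variable {variable!r} required by {model_id} is missing{who}"
        )


class DomainError(ValueError):
    """A value falls outside every bin of its variable."""


class ConfigurationError(ValueError):
    """A coefficient required for prediction is absent."""


@dataclass(frozen=True)
class ScoreComponents:
    """Physiological and operative severity scores of one patient."""

    physiological_score: int
    operative_score: int


@dataclass(frozen=True)
class RiskPrediction:
    model_id: str
    linear_predictor: float
    probability: float


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and np.isnan(value):
        return True
    return value is pd.NA


def assign_weights(
    record: PatientRecord, definition: ScoreDefinition
) -> dict[str, int]:
    """Map each model variable of ``record`` to its integer category weight.

    Raises :class:`MissingVariableError` (naming the variable and model) when
    a required field is absent, and :class:`DomainError` when a present value
    falls outside every bin.
    """
    weights: dict[str, int] = {}
    for var in definition.variables.values():
        value = getattr(record, var.field)
        if _is_missing(value):
            raise MissingVariableError(var.field, definition.model_id, record.patient_id)
        try:
            weights[var.name] = var.bin_for(value).weight
        except RegistryError as exc:
            raise DomainError(f"{definition.model_id}: {exc}") from exc
    return weights


def assign_labels(
    record: PatientRecord, definition: ScoreDefinition
) -> dict[str, str]:
    """Category label of each model variable (the terms of category models)."""
    labels: dict[str, str] = {}
    for var in definition.variables.values():
        value = getattr(record, var.field)
        if _is_missing(value):
            raise MissingVariableError(var.field, definition.model_id, record.patient_id)
        try:
            labels[var.name] = var.bin_for(value).label
        except RegistryError as exc:
            raise DomainError(f"{definition.model_id}: {exc}") from exc
    return labels


def compute_scores(
    record: PatientRecord, definition: ScoreDefinition
) -> ScoreComponents:
    """Sum the per-variable weights into (PS, OS).  POSSUM family only."""
    if definition.family != "score_link":
        raise ConfigurationError(
            f"{definition.model_id} has no physiological/operative score split"
        )
    weights = assign_weights(record, definition)
    ps = sum(weights[name] for name in definition.groups["physiological"])
    os_ = sum(weights[name] for name in definition.groups["operative"])
    return ScoreComponents(physiological_score=ps, operative_score=os_)


def _inverse_logit(lp: float) -> float:
    # stable for large |lp|
    if lp >= 0:
        return 1.0 / (1.0 + np.exp(-lp))
    e = np.exp(lp)
    return float(e / (1.0 + e))


def predict_risk(
    scores_or_record: Union[ScoreComponents, PatientRecord],
    coefficient_set: CoefficientSet,
    definition: Optional[ScoreDefinition] = None,
) -> RiskPrediction:
    """Evaluate the logistic link for one patient.

    POSSUM-family callers pass :class:`ScoreComponents`; category-model
    callers pass the :class:`PatientRecord` together with the model's
    :class:`ScoreDefinition` so categories can be resolved.
    """
    if isinstance(scores_or_record, ScoreComponents):
        terms = coefficient_set.terms
        for needed in (PS_TERM, OS_TERM):
            if needed not in terms:
                raise ConfigurationError(
                    f"{coefficient_set.model_id}: coefficient {needed!r} absent"
                )
        lp = (
            coefficient_set.intercept
            + terms[PS_TERM] * scores_or_record.physiological_score
            + terms[OS_TERM] * scores_or_record.operative_score
        )
    else:
        if definition is None:
            raise ConfigurationError(
                "a ScoreDefinition is required to predict from a raw record"
            )
        if definition.family == "score_link":
            return predict_risk(
                compute_scores(scores_or_record, definition), coefficient_set
            )
        labels = assign_labels(scores_or_record, definition)
        lp = coefficient_set.intercept
        for var in definition.variables.values():
            label = labels[var.name]
            if label == var.bins[0].label:
                continue  # reference category
            term = f"{var.name}:{label}"
            if term not in coefficient_set.terms:
                raise ConfigurationError(
                    f"{coefficient_set.model_id}: coefficient {term!r} absent"
                )
            lp += coefficient_set.terms[term]
    return RiskPrediction(
        model_id=coefficient_set.model_id,
        linear_predictor=float(lp),
        probability=_inverse_logit(float(lp)),
    )


@dataclass
class ExclusionLog:
    """Complete-case accounting: who was dropped and which variable did it."""

    model_id: str
    n_input: int
    n_retained: int
    n_excluded: int
    by_variable: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "n_excluded": self.n_excluded,
            "by_variable": dict(self.by_variable),
        }


def complete_case_filter(
    cohort: Union[pd.DataFrame, Iterable[PatientRecord]],
    definition: ScoreDefinition,
):
    """Drop every patient missing any variable the model requires.

    Returns ``(retained, log)`` where ``retained`` has the same type as the
    input (DataFrame in, DataFrame out) and the log attributes each excluded
    patient to every one of their missing model variables.
    """
    as_records = not isinstance(cohort, pd.DataFrame)
    frame = cohort_to_frame(cohort) if as_records else cohort
    fields = definition.required_fields
    if len(frame) == 0:
        log = ExclusionLog(definition.model_id, 0, 0, 0, {f: 0 for f in fields})
        return ([] if as_records else frame), log

    missing = frame[list(fields)].isna()
    keep = ~missing.any(axis=1)
    by_variable = {f: int(missing.loc[~keep, f].sum()) for f in fields}
    retained_frame = frame.loc[keep]
    log = ExclusionLog(
        model_id=definition.model_id,
        n_input=int(len(frame)),
        n_retained=int(keep.sum()),
        n_excluded=int((~keep).sum()),
        by_variable=by_variable,
    )
    if as_records:
        return frame_to_cohort(retained_frame), log
    return retained_frame.reset_index(drop=True), log


# ---------------------------------------------------------------------------
# vectorized cohort path


def _variable_weights_and_labels(var: VariableDef, values: pd.Series):
    n = len(values)
    weights = np.full(n, np.nan)
    labels = np.full(n, None, dtype=object)
    arr = values.to_numpy(dtype=object, copy=True)
    present = ~pd.isna(values).to_numpy()
    arr[~present] = None  # pd.NA breaks elementwise comparison in np.isin
    assigned = np.zeros(n, dtype=bool)
    for b in var.bins:
        if b.values:
            mask = np.isin(arr, np.array(list(b.values), dtype=object)) & present
        else:
            vals = pd.to_numeric(values, errors="coerce").to_numpy(dtype=float)
            mask = present.copy()
            in_any = np.zeros(n, dtype=bool)
            for lo, hi, lo_incl, hi_incl in b.intervals:
                ok = np.ones(n, dtype=bool)
                if lo is not None:
                    ok &= vals >= lo if lo_incl else vals > lo
                if hi is not None:
                    ok &= vals <= hi if hi_incl else vals < hi
                in_any |= ok & present
            mask &= in_any
        mask &= ~assigned
        weights[mask] = b.weight
        labels[mask] = b.label
        assigned |= mask
    if (present & ~assigned).any():
        bad = arr[present & ~assigned][:3]
        raise DomainError(
            f"values {list(bad)!r} of {var.name} fall outside every bin"
        )
    return weights, labels


def score_frame(
    cohort: Union[pd.DataFrame, Iterable[PatientRecord]],
    definition: ScoreDefinition,
) -> pd.DataFrame:
    """Vectorized scoring of a (complete-case) cohort table.

    Returns a DataFrame indexed like the input with one ``w_<variable>``
    weight column and one ``cat_<variable>`` label column per model variable,
    plus ``physiological_score``/``operative_score`` for the POSSUM family.
    Patients with a missing model variable get NaN scores (callers are
    expected to have applied :func:`complete_case_filter`).
    """
    # only the model's own fields are needed here, so outcome-less tables are fine
    frame = cohort if isinstance(cohort, pd.DataFrame) else cohort_to_frame(cohort)
    absent = [v.field for v in definition.variables.values() if v.field not in frame.columns]
    if absent:
        raise MissingVariableError(absent[0], definition.model_id)
    out = pd.DataFrame(index=frame.index)
    for group_name, variables in definition.groups.items():
        for var in variables.values():
            w, lab = _variable_weights_and_labels(var, frame[var.field])
            out[f"w_{var.name}"] = w
            out[f"cat_{var.name}"] = lab
    if definition.family == "score_link":
        for score_col, group_name in (
            (PS_TERM, "physiological"),
            (OS_TERM, "operative"),
        ):
            cols = [f"w_{name}" for name in definition.groups[group_name]]
            out[score_col] = out[cols].sum(axis=1, skipna=False)
    return out


def predict_frame(
    cohort: Union[pd.DataFrame, Iterable[PatientRecord]],
    definition: ScoreDefinition,
    coefficient_set: Optional[CoefficientSet] = None,
) -> pd.DataFrame:
    """Per-patient linear predictor and death probability for a cohort.

    Uses the definition's own coefficient set unless an explicit one (e.g. a
    recalibrated fit) is supplied.  Raises :class:`ConfigurationError` when
    no coefficient set exists (AFC original validation).
    """
    coef = coefficient_set or definition.coefficient_set
    if coef is None:
        raise ConfigurationError(
            f"{definition.model_id}: no coefficient set available for prediction"
        )
    scored = score_frame(cohort, definition)
    if definition.family == "score_link":
        for needed in (PS_TERM, OS_TERM):
            if needed not in coef.terms:
                raise ConfigurationError(
                    f"{coef.model_id}: coefficient {needed!r} absent"
                )
        lp = (
            coef.intercept
            + coef.terms[PS_TERM] * scored[PS_TERM]
            + coef.terms[OS_TERM] * scored[OS_TERM]
        )
    else:
        lp = pd.Series(float(coef.intercept), index=scored.index)
        for var in definition.variables.values():
            labels = scored[f"cat_{var.name}"]
            ref = var.bins[0].label
            for b in var.bins[1:]:
                term = f"{var.name}:{b.label}"
                if term not in coef.terms:
                    raise ConfigurationError(
                        f"{coef.model_id}: coefficient {term!r} absent"
                    )
                lp = lp + np.where(labels == b.label, coef.terms[term], 0.0)
            lp = lp.where(~labels.isna(), np.nan)
    scored["linear_predictor"] = lp
    with np.errstate(over="ignore"):
        scored["probability"] = 1.0 / (1.0 + np.exp(-lp.astype(float)))
    return scored
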