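"""Refitting published risk equations on a new cohort.

Recalibration keeps a model's score structure and refits its logistic
coefficients by maximum likelihood on the target cohort: a new intercept and
new per-score betas for the POSSUM family (POSSUM and P-POSSUM share one
score pair, so their recalibrated equations coincide), or one coefficient per
non-reference category for the indicator models (AFC, IRCS).  Fitting is
Newton-Raphson (iteratively reweighted least squares) via statsmodels with a
1e-8 score tolerance and a 50-iteration cap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .records import PatientRecord, as_frame
from .registry import CoefficientSet, ScoreDefinition
from .scoring import OS_TERM, PS_TERM, complete_case_filter, score_frame
from .validation import OUTCOME_COLUMNS, ValidationReport, validate_model

#: a fitted logit coefficient beyond this magnitude flags (quasi-)separation
SEPARATION_COEF_LIMIT = 15.0
DEFAULT_TOL = 1e-8
DEFAULT_MAXITER = 50


class SeparationError(RuntimeError):
    """Perfect or quasi-perfect separation during the logistic refit."""

    def __init__(self, model_id: str, term: str):
        self.model_id = model_id
        self.term = term
        super().__init__(
            f"{model_id}: (quasi-)separation detected on term {term!r}; "
            "too few events support this category"
        )


@dataclass
class RecalibrationResult:
    model_id: str
    coefficient_set: CoefficientSet
    n_fit: int
    events_fit: int
    converged: bool
    n_iterations: int
    log_likelihood: float
    post_report: ValidationReport
    outcome: str = "inhospital"

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "outcome": self.outcome,
            "coefficients": self.coefficient_set.to_dict(),
            "n_fit": self.n_fit,
            "events_fit": self.events_fit,
            "converged": self.converged,
            "n_iterations": self.n_iterations,
            "log_likelihood": self.log_likelihood,
            "post_report": self.post_report.to_dict(),
        }


def _ridge_logit(
    X: np.ndarray, y: np.ndarray, alpha: float = 1e-3, iters: int = 50
) -> np.ndarray:
    """Ridge-penalized logistic fit used only to name the separating term."""
    from scipy.special import expit

    beta = np.zeros(X.shape[1])
    eye = alpha * np.eye(X.shape[1])
    for _ in range(iters):
        p = expit(X @ beta)
        w = np.clip(p * (1 - p), 1e-10, None)
        grad = X.T @ (y - p) - alpha * beta
        hess = (X * w[:, None]).T @ X + eye
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-8:
            break
    return beta


def design_matrix(
    frame: pd.DataFrame, definition: ScoreDefinition
) -> pd.DataFrame:
    """Regression design for a complete-case cohort: (PS, OS) columns for the
    POSSUM family, 0/1 category indicators (reference = lowest-risk category)
    for AFC/IRCS.  A constant column is prepended."""
    scored = score_frame(frame, definition)
    if definition.family == "score_link":
        X = scored[[PS_TERM, OS_TERM]].copy()
    else:
        cols = {}
        for var in definition.variables.values():
            labels = scored[f"cat_{var.name}"]
            for b in var.bins[1:]:
                cols[f"{var.name}:{b.label}"] = (labels == b.label).astype(float)
        X = pd.DataFrame(cols, index=frame.index)
    return sm.add_constant(X, has_constant="add")


def log_likelihood(
    frame: pd.DataFrame,
    definition: ScoreDefinition,
    coefficient_set: CoefficientSet,
    outcome: str = "inhospital",
) -> float:
    """Bernoulli log-likelihood of an arbitrary coefficient set on a
    complete-case cohort (used to compare original vs recalibrated fits)."""
    from .scoring import predict_frame

    y = frame[OUTCOME_COLUMNS[outcome]].astype(float).to_numpy()
    p = predict_frame(frame, definition, coefficient_set)["probability"].to_numpy()
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(np.sum(y * np.log(p) + (1 - y) * np.log1p(-p)))


def recalibrate(
    cohort: Union[pd.DataFrame, Iterable[PatientRecord]],
    definition: ScoreDefinition,
    outcome: str = "inhospital",
    tol: float = DEFAULT_TOL,
    maxiter: int = DEFAULT_MAXITER,
    hl_groups: int = 10,
) -> RecalibrationResult:
    """Maximum-likelihood refit of a model's logistic coefficients.

    Applies the complete-case rule, fits the outcome on the model's design
    by Newton-Raphson, and attaches a post-fit :class:`ValidationReport`
    evaluated on the same (fitting) cohort.  Raises :class:`SeparationError`
    naming the worst term when the fit separates; a fit that merely hits the
    iteration cap is returned with ``converged=False``.
    """
    frame = as_frame(cohort)
    retained, _log = complete_case_filter(frame, definition)
    y = retained[OUTCOME_COLUMNS[outcome]].astype(float).to_numpy()
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError(
            f"{definition.model_id}: need at least one event and one non-event"
        )
    X = design_matrix(retained, definition)
    model = sm.Logit(y, X)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # convergence warnings handled below
            res = model.fit(method="newton", maxiter=maxiter, tol=tol, disp=0)
        params = res.params
        converged = bool(res.mle_retvals.get("converged", False))
        n_iter = int(res.mle_retvals.get("iterations", maxiter))
        llf = float(res.llf)
        bse = res.bse
    except (PerfectSeparationError, np.linalg.LinAlgError):
        # identify the culprit with a lightly ridge-penalized refit, which
        # stays solvable even under perfect separation
        beta = _ridge_logit(X.to_numpy(dtype=float), y)
        names = list(X.columns)
        mags = {
            name: abs(b)
            for name, b in zip(names, beta)
            if name != "const"
        }
        worst = max(mags, key=mags.get)
        raise SeparationError(definition.model_id, worst) from None

    non_const = params.drop(labels=["const"], errors="ignore")
    if len(non_const) and non_const.abs().max() > SEPARATION_COEF_LIMIT:
        raise SeparationError(definition.model_id, str(non_const.abs().idxmax()))

    coef = CoefficientSet(
        model_id=definition.model_id,
        intercept=float(params["const"]),
        terms={k: float(v) for k, v in params.items() if k != "const"},
        provenance="recalibrated",
        source_label=f"MLE refit on cohort (n={len(y)}, outcome={outcome})",
        fit_info={
            "converged": converged,
            "n_iterations": n_iter,
            "log_likelihood": llf,
            "standard_errors": {k: float(v) for k, v in bse.items()},
            "tol": tol,
            "maxiter": maxiter,
        },
    )
    post = validate_model(
        retained,
        definition,
        outcome=outcome,
        coefficient_set=coef,
        hl_groups=hl_groups,
        stage="recalibration",
    )
    return RecalibrationResult(
        model_id=definition.model_id,
        coefficient_set=coef,
        n_fit=int(len(y)),
        events_fit=int(y.sum()),
        converged=converged,
        n_iterations=n_iter,
        log_likelihood=llf,
        post_report=post,
        outcome=outcome,
    )


def compare_models(
    results: Iterable[Union[ValidationReport, RecalibrationResult]],
) -> pd.DataFrame:
    """Arrange validation/recalibration reports as one row per
    model x outcome x stage (the layout of a classic comparison table)."""
    rows = []
    for item in results:
        report = item.post_report if isinstance(item, RecalibrationResult) else item
        rows.append(
            {
                "model_id": report.model_id,
                "outcome": report.outcome,
                "stage": report.stage,
                "n": report.n_analyzed,
                "deaths_included": report.deaths_included,
                "auc": report.auc,
                "auc_ci_low": report.auc_ci[0] if report.auc_ci else None,
                "auc_ci_high": report.auc_ci[1] if report.auc_ci else None,
                "hl_p": report.hl_p,
            }
        )
    if not rows:
        raise ValueError("need at least one report")
    return pd.DataFrame(rows)
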