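"""External-validation statistics for mortality risk models.

Discrimination is summarized by the area under the ROC curve, computed as the
Mann-Whitney concordance (ties count one half) with a DeLong variance for the
confidence interval; calibration by the Hosmer-Lemeshow chi-square over
near-equal groups of predicted risk and by observed/expected (O/E) tables;
crude event rates carry normal-approximation confidence intervals, which is
what clinical registries conventionally print for percentages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .records import PatientRecord
from .registry import CoefficientSet, ScoreDefinition
from .scoring import ExclusionLog, complete_case_filter, predict_frame


class UndefinedStatisticError(ValueError):
    """The requested statistic is undefined for this input (e.g. AUC with no
    events, a rate with n = 0)."""


def _as_arrays(predictions, outcomes):
    p = np.asarray(list(predictions), dtype=float)
    y = np.asarray(list(outcomes)).astype(bool)
    if p.shape != y.shape:
        raise ValueError("predictions and outcomes differ in length")
    return p, y


def roc_auc(predictions: Iterable[float], outcomes: Iterable[bool]) -> float:
    """Mann-Whitney AUC: P(score of a death > score of a survivor) + half ties.

    Raises :class:`UndefinedStatisticError` when the outcome is constant.
    """
    p, y = _as_arrays(predictions, outcomes)
    n1 = int(y.sum())
    n0 = int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise UndefinedStatisticError(
            "AUC undefined: need at least one event and one non-event"
        )
    ranks = stats.rankdata(p)  # midranks handle ties
    auc = (ranks[y].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    return float(auc)


def _delong_variance(p: np.ndarray, y: np.ndarray) -> float:
    """DeLong's variance of the AUC via midrank structural components."""
    x = p[y]  # events
    z = p[~y]  # non-events
    m, n = len(x), len(z)
    all_r = stats.rankdata(np.concatenate([x, z]))
    rx = stats.rankdata(x)
    rz = stats.rankdata(z)
    # V10[i]: placement of event i among non-events; V01[j]: of non-event j.
    v10 = (all_r[:m] - rx) / n
    v01 = 1.0 - (all_r[m:] - rz) / m
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def auc_ci(
    predictions: Iterable[float],
    outcomes: Iterable[bool],
    level: float = 0.95,
    method: str = "delong",
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[float, float]:
    """Confidence interval for the AUC, clipped to [0, 1].

    ``method='delong'`` (default) uses DeLong's analytic variance;
    ``method='bootstrap'`` stratified-resamples events and non-events
    ``n_boot`` times (seeded), the percentile interval being the more robust
    choice when only a handful of deaths are available.
    """
    p, y = _as_arrays(predictions, outcomes)
    auc = roc_auc(p, y)
    if method == "delong":
        se = float(np.sqrt(_delong_variance(p, y)))
        zq = stats.norm.ppf(0.5 + level / 2.0)
        lo, hi = auc - zq * se, auc + zq * se
    elif method == "bootstrap":
        rng = np.random.default_rng(seed)
        ev, nev = np.where(y)[0], np.where(~y)[0]
        reps = np.empty(n_boot)
        for b in range(n_boot):
            idx = np.concatenate(
                [rng.choice(ev, len(ev)), rng.choice(nev, len(nev))]
            )
            reps[b] = roc_auc(p[idx], y[idx])
        alpha = (1.0 - level) / 2.0
        lo, hi = np.quantile(reps, [alpha, 1.0 - alpha])
    else:
        raise ValueError(f"unknown AUC CI method {method!r}")
    return (float(max(0.0, lo)), float(min(1.0, hi)))


@dataclass
class HosmerLemeshowResult:
    statistic: float
    df: int
    p_value: float
    table: pd.DataFrame  # per group: n, observed, expected, mean_predicted
    n_merged: int = 0

    def __iter__(self):
        return iter((self.statistic, self.df, self.p_value))


def hosmer_lemeshow(
    predictions: Iterable[float],
    outcomes: Iterable[bool],
    groups: int = 10,
) -> HosmerLemeshowResult:
    """Hosmer-Lemeshow goodness-of-fit chi-square over groups of risk.

    Patients are stably sorted by predicted risk and split into ``groups``
    near-equal deciles-of-risk; the statistic sums (O-E)^2/E over both outcome
    classes in every group and is referred to chi-square with ``groups - 2``
    degrees of freedom (the convention printed in every report).  Groups whose
    expected death count is zero are merged into their neighbour (counted in
    ``n_merged``); the degrees of freedom follow the merged group count.
    """
    p, y = _as_arrays(predictions, outcomes)
    n = len(p)
    if n < groups:
        raise UndefinedStatisticError(f"need at least {groups} observations")
    if y.sum() == 0:
        raise UndefinedStatisticError("need at least one event")
    order = np.argsort(p, kind="stable")
    chunks = np.array_split(order, groups)
    rows = [
        {
            "n": len(idx),
            "observed": float(y[idx].sum()),
            "expected": float(p[idx].sum()),
            "mean_predicted": float(p[idx].mean()) if len(idx) else np.nan,
        }
        for idx in chunks
        if len(idx)
    ]
    # merge groups with zero expected deaths into the nearest neighbour
    merged = 0
    i = 0
    while i < len(rows):
        if rows[i]["expected"] == 0.0 and len(rows) > 1:
            j = i + 1 if i + 1 < len(rows) else i - 1
            rows[j]["n"] += rows[i]["n"]
            rows[j]["observed"] += rows[i]["observed"]
            rows[j]["expected"] += rows[i]["expected"]
            del rows[i]
            merged += 1
        else:
            i += 1
    stat = 0.0
    for row in rows:
        e1 = row["expected"]
        e0 = row["n"] - e1
        o1 = row["observed"]
        o0 = row["n"] - o1
        if e1 > 0:
            stat += (o1 - e1) ** 2 / e1
        if e0 > 0:
            stat += (o0 - e0) ** 2 / e0
    df = max(len(rows) - 2, 1)
    p_value = float(stats.chi2.sf(stat, df))
    table = pd.DataFrame(rows)
    return HosmerLemeshowResult(float(stat), int(df), p_value, table, merged)


@dataclass
class CalibrationTable:
    """Observed vs expected deaths per band of predicted risk."""

    table: pd.DataFrame  # band, n, observed, expected
    oe_ratio: float

    def to_dict(self) -> dict:
        return {
            "bands": self.table.to_dict(orient="records"),
            "oe_ratio": self.oe_ratio,
        }


def calibration_table(
    predictions: Iterable[float],
    outcomes: Iterable[bool],
    bands: Union[int, Sequence[float]] = 10,
) -> CalibrationTable:
    """Tabulate observed and model-expected deaths by band of predicted risk.

    ``bands`` is either a number of equal-frequency (quantile) bands or an
    explicit increasing sequence of probability cut points spanning [0, 1].
    Empty bands are kept with n = 0.  The overall O/E ratio (total observed /
    total expected) is attached; O/E < 1 means the model overestimates risk.
    """
    p, y = _as_arrays(predictions, outcomes)
    if isinstance(bands, int):
        qs = np.quantile(p, np.linspace(0, 1, bands + 1)) if len(p) else np.linspace(0, 1, bands + 1)
        edges = np.unique(qs)
        edges[0], edges[-1] = 0.0, 1.0
    else:
        edges = np.asarray(list(bands), dtype=float)
        if edges[0] != 0.0 or edges[-1] != 1.0 or np.any(np.diff(edges) <= 0):
            raise ValueError("bands must increase from 0.0 to 1.0")
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        last = hi == edges[-1]
        mask = (p >= lo) & ((p <= hi) if last else (p < hi))
        rows.append(
            {
                "band": f"[{lo:.6g},{hi:.6g}{']' if last else ')'}",
                "n": int(mask.sum()),
                "observed": float(y[mask].sum()),
                "expected": float(p[mask].sum()),
            }
        )
    total_expected = float(p.sum())
    oe = float(y.sum()) / total_expected if total_expected > 0 else np.nan
    return CalibrationTable(pd.DataFrame(rows), oe)


@dataclass(frozen=True)
class RateEstimate:
    """A crude event rate with its confidence interval, on the percent scale."""

    events: int
    n: int
    rate_pct: float
    ci_pct: tuple[float, float]
    level: float = 0.95

    def formatted(self, decimals: int = 1) -> str:
        lo, hi = self.ci_pct
        return (
            f"{self.rate_pct:.{decimals}f}% "
            f"[{100*self.level:.0f}% CI: {lo:.{decimals}f}-{hi:.{decimals}f}]"
        )


def mortality_rate(
    events: int, n: int, level: float = 0.95, method: str = "normal"
) -> RateEstimate:
    """Crude mortality rate with CI (normal approximation by default,
    Clopper-Pearson exact behind ``method='exact'``); lower bound truncated
    at zero, reported on the percent scale."""
    if n <= 0:
        raise UndefinedStatisticError("rate undefined for n = 0")
    if not 0 <= events <= n:
        raise ValueError("events must lie in [0, n]")
    phat = events / n
    if method == "normal":
        zq = stats.norm.ppf(0.5 + level / 2.0)
        half = zq * np.sqrt(phat * (1 - phat) / n)
        lo, hi = phat - half, phat + half
    elif method == "exact":
        alpha = 1.0 - level
        lo = stats.beta.ppf(alpha / 2, events, n - events + 1) if events > 0 else 0.0
        hi = (
            stats.beta.ppf(1 - alpha / 2, events + 1, n - events)
            if events < n
            else 1.0
        )
    else:
        raise ValueError(f"unknown rate CI method {method!r}")
    lo = max(0.0, float(lo))
    hi = min(1.0, float(hi))
    return RateEstimate(
        events=int(events),
        n=int(n),
        rate_pct=100.0 * phat,
        ci_pct=(100.0 * lo, 100.0 * hi),
        level=level,
    )


@dataclass
class ValidationReport:
    """Everything Table-3-shaped reports need for one model x outcome."""

    model_id: str
    outcome: str  # inhospital | day30
    n_analyzed: int
    deaths_included: int
    auc: Optional[float]
    auc_ci: Optional[tuple[float, float]]
    hl_statistic: Optional[float]
    hl_df: Optional[int]
    hl_p: Optional[float]
    calibration: Optional[CalibrationTable]
    coefficient_provenance: Optional[str] = None
    exclusion_log: Optional[ExclusionLog] = None
    stage: str = "validation"  # validation | recalibration
    notes: list[str] = field(default_factory=list)

    @property
    def available(self) -> bool:
        return self.auc is not None

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "outcome": self.outcome,
            "stage": self.stage,
            "n_analyzed": self.n_analyzed,
            "deaths_included": self.deaths_included,
            "auc": self.auc,
            "auc_ci": list(self.auc_ci) if self.auc_ci else None,
            "hl_statistic": self.hl_statistic,
            "hl_df": self.hl_df,
            "hl_p": self.hl_p,
            "calibration": self.calibration.to_dict() if self.calibration else None,
            "coefficient_provenance": self.coefficient_provenance,
            "exclusion_log": self.exclusion_log.to_dict() if self.exclusion_log else None,
            "notes": list(self.notes),
        }


OUTCOME_COLUMNS = {"inhospital": "death_inhospital", "day30": "death_30day"}


def validate_model(
    cohort: Union[pd.DataFrame, Iterable[PatientRecord]],
    definition: ScoreDefinition,
    outcome: str = "inhospital",
    coefficient_set: Optional[CoefficientSet] = None,
    hl_groups: int = 10,
    bands: Union[int, Sequence[float]] = 10,
    stage: str = "validation",
) -> ValidationReport:
    """Run the full external-validation battery for one model.

    Applies the complete-case rule, predicts with the model's (or the given)
    coefficient set and computes AUC with its 95% CI, the Hosmer-Lemeshow
    test, and a calibration table.  A model with no coefficient set (AFC
    original equation) yields a report whose statistics are all ``None`` --
    rendered "NA" downstream -- but whose complete-case accounting is real.
    """
    if outcome not in OUTCOME_COLUMNS:
        raise ValueError(f"outcome must be one of {tuple(OUTCOME_COLUMNS)}")
    from .records import as_frame

    frame = as_frame(cohort)
    retained, log = complete_case_filter(frame, definition)
    ycol = OUTCOME_COLUMNS[outcome]
    y = retained[ycol].astype(bool).to_numpy()
    coef = coefficient_set or definition.coefficient_set
    if coef is None:
        return ValidationReport(
            model_id=definition.model_id,
            outcome=outcome,
            n_analyzed=len(retained),
            deaths_included=int(y.sum()),
            auc=None,
            auc_ci=None,
            hl_statistic=None,
            hl_df=None,
            hl_p=None,
            calibration=None,
            coefficient_provenance=None,
            exclusion_log=log,
            stage=stage,
            notes=["no original coefficient set in registry; statistics NA"],
        )
    predicted = predict_frame(retained, definition, coef)
    p = predicted["probability"].to_numpy(dtype=float)
    auc = roc_auc(p, y)
    ci = auc_ci(p, y)
    hl = hosmer_lemeshow(p, y, groups=hl_groups)
    cal = calibration_table(p, y, bands=bands)
    return ValidationReport(
        model_id=definition.model_id,
        outcome=outcome,
        n_analyzed=len(retained),
        deaths_included=int(y.sum()),
        auc=auc,
        auc_ci=ci,
        hl_statistic=hl.statistic,
        hl_df=hl.df,
        hl_p=hl.p_value,
        calibration=cal,
        coefficient_provenance=coef.provenance,
        exclusion_log=log,
        stage=stage,
    )


def bivariate_screen(
    cohort: pd.DataFrame,
    variables: Sequence[str],
    outcome: str = "inhospital",
) -> pd.DataFrame:
    """Per-factor association screen against an outcome.

    Chi-square test of the factor x outcome table, switching to Fisher's
    exact test when the table is 2x2 and any expected cell is below 5
    (larger sparse tables keep the chi-square and are flagged).
    """
    ycol = OUTCOME_COLUMNS[outcome]
    rows = []
    for var in variables:
        sub = cohort[[var, ycol]].dropna()
        tab = pd.crosstab(sub[var], sub[ycol].astype(bool))
        if tab.shape[1] < 2 or tab.shape[0] < 2:
            rows.append({"variable": var, "test": "NA", "p_value": np.nan})
            continue
        expected = stats.contingency.expected_freq(tab.to_numpy())
        sparse = (expected < 5).any()
        if sparse and tab.shape == (2, 2):
            _, pval = stats.fisher_exact(tab.to_numpy())
            test = "fisher_exact"
        else:
            _, pval, _, _ = stats.chi2_contingency(tab.to_numpy())
            test = "chi_square" + ("_sparse" if sparse else "")
        rows.append({"variable": var, "test": test, "p_value": float(pval)})
    return pd.DataFrame(rows)
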