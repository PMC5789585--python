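"""Seeded synthetic cohorts of colorectal cancer surgery patients.

The generator emulates the statistical structure of a prospective surgical
registry: per-variable categorical marginals (the CR-POSSUM factor
distribution of a low-mortality elective-dominated cohort), continuous
values drawn uniformly within the sampled category's interval, in-hospital
death simulated from a configurable true logistic risk model whose intercept
can be tuned to a target event rate (~1.5% by default), 30-day death layered
on top (~1.7%), and missing-completely-at-random gaps mirroring the
availability of each variable in routine clinical practice.

Only category membership affects any downstream score, so the within-bin
distribution of continuous values is deliberately simple (uniform, truncated
at documented physiologic limits).  Variables are independent by default;
a one-factor Gaussian copula can couple them.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import norm

from .registry import CoefficientSet, ScoreDefinition, load_model
from .scoring import predict_frame

# ---------------------------------------------------------------------------
# default study conditions

#: Categorical marginals.  The CR-POSSUM factors reproduce the published
#: cohort's column percentages; the remaining variables use realistic
#: registry values (see docs/methods.md).  Probabilities are normalized at
#: sampling time to absorb rounding in printed percentages.
DEFAULT_MARGINALS: dict[str, dict[str, float]] = {
    "age_band": {"le60": 0.233, "61-70": 0.302, "71-80": 0.329, "ge81": 0.136},
    "sex": {"male": 0.636, "female": 0.364},
    "tumor_site": {"colon": 0.72, "rectum": 0.28},
    "heart_failure": {"none_or_mild": 0.929, "moderate": 0.054, "severe": 0.017},
    "respiratory_status": {
        "no_dyspnoea": 0.85,
        "dyspnoea_on_exertion": 0.10,
        "limiting_dyspnoea": 0.04,
        "dyspnoea_at_rest": 0.01,
    },
    "sbp_band": {"100-170": 0.931, "gt170_or_90s": 0.061, "lt90": 0.008},
    "heart_rate_band": {"40-100": 0.966, "101-120": 0.029, "extreme": 0.005},
    "gcs_band": {"15": 0.99, "12-14": 0.008, "9-11": 0.0015, "lt9": 0.0005},
    "urea_band": {"le10": 0.311, "10.1-15": 0.408, "gt15": 0.281},
    "haemoglobin_band": {"13-16": 0.391, "mid": 0.479, "extreme": 0.130},
    "leucocytes_band": {"4-10": 0.78, "out_mild": 0.19, "out_severe": 0.03},
    "sodium_band": {"ge136": 0.90, "131-135": 0.08, "126-130": 0.017, "lt126": 0.003},
    "potassium_band": {"3.5-5": 0.92, "mild": 0.06, "moderate": 0.017, "severe": 0.003},
    "ecg": {"normal": 0.90, "atrial_fibrillation": 0.06, "other_abnormal": 0.04},
    "weight_loss_gt10pct": {"no": 0.85, "yes": 0.15},
    "neuro_comorbidity": {"no": 0.92, "yes": 0.08},
    "urgency": {"scheduled": 0.964, "urgent": 0.034, "emergency": 0.003},
    "operative_severity": {
        "minor": 0.0,
        "moderate": 0.022,
        "major": 0.554,
        "complex_major": 0.424,
    },
    "n_procedures_band": {"1": 0.80, "2": 0.17, "gt2": 0.03},
    "blood_loss_band": {"le100": 0.35, "101-500": 0.45, "501-999": 0.15, "ge1000": 0.05},
    "peritoneal_contamination": {
        "none_or_serous": 0.980,
        "local_pus": 0.003,
        "free_pus_faeces_blood": 0.017,
    },
    "dukes_stage": {"A_B": 0.579, "C": 0.327, "D": 0.094},
}

#: Per-field MCAR missingness.  The five CR-POSSUM factors carry the
#: published availability gaps; the variables only the 18-parameter models
#: use get small plausible gaps so per-model complete-case Ns differ the way
#: they do in real registries, and weight loss (an anamnestic item) is the
#: hardest to collect.
DEFAULT_MISSINGNESS: dict[str, float] = {
    "urea": 0.103,
    "sbp": 0.042,
    "heart_rate": 0.052,
    "heart_failure": 0.027,
    "haemoglobin": 0.020,
    "age": 0.001,
    "operative_severity": 0.002,
    "peritoneal_contamination": 0.004,
    "dukes_stage": 0.006,
    "respiratory_status": 0.010,
    "glasgow_coma_score": 0.010,
    "leucocytes": 0.030,
    "sodium": 0.025,
    "potassium": 0.025,
    "ecg": 0.010,
    "blood_loss": 0.030,
    "weight_loss_gt10pct": 0.45,
    "neuro_comorbidity": 0.05,
}

# band label -> weighted union of value intervals (lo, hi, share);
# continuous values are drawn uniformly inside a share-weighted interval.
_CONTINUOUS_BANDS: dict[str, dict[str, list[tuple[float, float, float]]]] = {
    "age_band": {
        "le60": [(24, 60, 1.0)],
        "61-70": [(61, 70, 1.0)],
        "71-80": [(71, 80, 1.0)],
        "ge81": [(81, 97, 1.0)],
    },
    "sbp_band": {
        "100-170": [(100, 170, 1.0)],
        "gt170_or_90s": [(171, 210, 0.6), (90, 99, 0.4)],
        "lt90": [(60, 89, 1.0)],
    },
    "heart_rate_band": {
        "40-100": [(40, 100, 1.0)],
        "101-120": [(101, 120, 1.0)],
        "extreme": [(121, 180, 0.7), (30, 39, 0.3)],
    },
    "gcs_band": {
        "15": [(15, 15, 1.0)],
        "12-14": [(12, 14, 1.0)],
        "9-11": [(9, 11, 1.0)],
        "lt9": [(3, 8, 1.0)],
    },
    "urea_band": {
        "le10": [(1.5, 10.0, 1.0)],
        "10.1-15": [(10.1, 15.0, 1.0)],
        "gt15": [(15.1, 45.0, 1.0)],
    },
    "haemoglobin_band": {
        "13-16": [(13.0, 16.0, 1.0)],
        "mid": [(10.0, 12.9, 0.8), (16.1, 18.0, 0.2)],
        "extreme": [(6.0, 9.9, 0.9), (18.1, 20.0, 0.1)],
    },
    "leucocytes_band": {
        "4-10": [(4.0, 10.0, 1.0)],
        "out_mild": [(10.1, 20.0, 0.9), (3.0, 3.9, 0.1)],
        "out_severe": [(20.1, 35.0, 0.8), (1.0, 2.9, 0.2)],
    },
    "sodium_band": {
        "ge136": [(136, 148, 1.0)],
        "131-135": [(131, 135, 1.0)],
        "126-130": [(126, 130, 1.0)],
        "lt126": [(115, 125, 1.0)],
    },
    "potassium_band": {
        "3.5-5": [(3.5, 5.0, 1.0)],
        "mild": [(3.2, 3.4, 0.5), (5.1, 5.3, 0.5)],
        "moderate": [(2.9, 3.1, 0.5), (5.4, 5.9, 0.5)],
        "severe": [(2.2, 2.8, 0.5), (6.0, 6.8, 0.5)],
    },
    "n_procedures_band": {
        "1": [(1, 1, 1.0)],
        "2": [(2, 2, 1.0)],
        "gt2": [(3, 5, 1.0)],
    },
    "blood_loss_band": {
        "le100": [(0, 100, 1.0)],
        "101-500": [(101, 500, 1.0)],
        "501-999": [(501, 999, 1.0)],
        "ge1000": [(1000, 2500, 1.0)],
    },
}

_INTEGER_FIELDS = {"age", "glasgow_coma_score", "n_procedures", "sbp",
                   "heart_rate", "sodium", "blood_loss"}

# band variable -> cohort-table field it fills (categoricals map 1:1)
_BAND_FIELD = {
    "age_band": "age",
    "sbp_band": "sbp",
    "heart_rate_band": "heart_rate",
    "gcs_band": "glasgow_coma_score",
    "urea_band": "urea",
    "haemoglobin_band": "haemoglobin",
    "leucocytes_band": "leucocytes",
    "sodium_band": "sodium",
    "potassium_band": "potassium",
    "n_procedures_band": "n_procedures",
    "blood_loss_band": "blood_loss",
}

_BOOLEAN_VARS = {"weight_loss_gt10pct", "neuro_comorbidity"}


class ConfigError(ValueError):
    """Invalid cohort configuration."""


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort.

    ``target_rate`` / ``target_rate_day30`` are percentages; the true-model
    intercept is tuned on the generated cohort so the mean true risk hits
    ``target_rate`` exactly (set it to ``None`` to use the coefficient set's
    own intercept).  ``dependence`` maps band-variable names to loadings in
    [0, 1) on a single latent Gaussian factor.
    """

    n_patients: int = 2749
    seed: int = 0
    marginals: dict[str, dict[str, float]] = dc_field(
        default_factory=lambda: copy.deepcopy(DEFAULT_MARGINALS)
    )
    missingness: dict[str, float] = dc_field(
        default_factory=lambda: dict(DEFAULT_MISSINGNESS)
    )
    true_model_id: str = "CR_POSSUM"
    true_coefficients: Optional[CoefficientSet] = None
    target_rate: Optional[float] = 1.5
    target_rate_day30: Optional[float] = 1.7
    dependence: Optional[dict[str, float]] = None

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ConfigError("n_patients must be positive")
        for var, probs in self.marginals.items():
            total = sum(probs.values())
            if not np.isclose(total, 1.0, atol=0.02):
                raise ConfigError(f"marginal for {var} sums to {total:.3f}, not 1")
            if any(p < 0 for p in probs.values()):
                raise ConfigError(f"negative probability in marginal {var}")
        for var, p in self.missingness.items():
            if not 0 <= p < 1:
                raise ConfigError(f"missingness for {var} must lie in [0, 1)")
        for rate, name in (
            (self.target_rate, "target_rate"),
            (self.target_rate_day30, "target_rate_day30"),
        ):
            if rate is not None and not 0 < rate < 100:
                raise ConfigError(f"{name} must lie in (0, 100) percent")
        if self.dependence:
            for var, loading in self.dependence.items():
                if not 0 <= loading < 1:
                    raise ConfigError(f"dependence loading for {var} not in [0,1)")


def tune_intercept(
    linear_predictor: np.ndarray, target_rate_pct: float
) -> float:
    """Additive intercept shift making mean(expit(lp + delta)) hit the target.

    The mean predicted risk is strictly increasing in the shift, so the root
    is unique; raises :class:`ConfigError` when the target is unreachable
    within +/-30 logit units.
    """
    target = target_rate_pct / 100.0
    lp = np.asarray(linear_predictor, dtype=float)

    def gap(delta: float) -> float:
        return float(np.mean(expit(lp + delta)) - target)

    lo, hi = -30.0, 30.0
    if gap(lo) > 0 or gap(hi) < 0:
        raise ConfigError(f"target rate {target_rate_pct}% unattainable")
    return float(brentq(gap, lo, hi, xtol=1e-12))


def _sample_categories(
    rng: np.random.Generator,
    probs: dict[str, float],
    n: int,
    latent: Optional[np.ndarray] = None,
    loading: float = 0.0,
) -> np.ndarray:
    labels = list(probs)
    p = np.array([probs[k] for k in labels], dtype=float)
    p = p / p.sum()
    if latent is None or loading == 0.0:
        return rng.choice(labels, size=n, p=p)
    # Gaussian copula: common factor + idiosyncratic noise -> uniform -> category
    z = loading * latent + np.sqrt(1 - loading**2) * rng.standard_normal(n)
    u = norm.cdf(z)
    cum = np.cumsum(p)
    idx = np.searchsorted(cum, u, side="right").clip(max=len(labels) - 1)
    return np.array(labels, dtype=object)[idx]


def _fill_continuous(
    rng: np.random.Generator,
    band_var: str,
    bands: np.ndarray,
    field_name: str,
) -> np.ndarray:
    spec = _CONTINUOUS_BANDS[band_var]
    n = len(bands)
    out = np.empty(n, dtype=float)
    for label, pieces in spec.items():
        mask = bands == label
        k = int(mask.sum())
        if k == 0:
            continue
        shares = np.array([w for _, _, w in pieces], dtype=float)
        shares /= shares.sum()
        which = rng.choice(len(pieces), size=k, p=shares)
        los = np.array([lo for lo, _, _ in pieces])[which]
        his = np.array([hi for _, hi, _ in pieces])[which]
        vals = rng.uniform(los, his + (1.0 if field_name in _INTEGER_FIELDS else 0.0))
        if field_name in _INTEGER_FIELDS:
            vals = np.floor(vals).clip(los, his)
        out[mask] = vals
    return out


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Generate one synthetic cohort table (missingness already injected when
    the config carries a missingness map).

    Identical configs (including seed) produce identical tables.  Metadata —
    the per-stage child seeds, the tuned intercept, and the realized event
    rates before missingness — is attached as ``frame.attrs['meta']``.
    """
    config.validate()
    n = config.n_patients
    master = np.random.SeedSequence(config.seed)
    seeds = master.spawn(5)
    rng_cat = np.random.default_rng(seeds[0])
    rng_cont = np.random.default_rng(seeds[1])
    rng_out = np.random.default_rng(seeds[2])
    rng_d30 = np.random.default_rng(seeds[3])

    latent = rng_cat.standard_normal(n) if config.dependence else None
    frame = pd.DataFrame({"patient_id": [f"S{idx:06d}" for idx in range(n)]})
    for band_var, probs in config.marginals.items():
        loading = (config.dependence or {}).get(band_var, 0.0)
        bands = _sample_categories(rng_cat, probs, n, latent, loading)
        if band_var in _CONTINUOUS_BANDS:
            field_name = _BAND_FIELD[band_var]
            frame[field_name] = _fill_continuous(rng_cont, band_var, bands, field_name)
        elif band_var in _BOOLEAN_VARS:
            frame[band_var] = bands == "yes"
        else:
            frame[band_var] = bands

    # outcomes from the true logistic model on the complete cohort
    definition = load_model(config.true_model_id)
    coef = config.true_coefficients or definition.coefficient_set
    if coef is None:
        raise ConfigError(f"true model {config.true_model_id} has no coefficients")
    lp = predict_frame(frame, definition, coef)["linear_predictor"].to_numpy()
    if config.target_rate is not None:
        delta = tune_intercept(lp, config.target_rate)
    else:
        delta = 0.0
    p_true = expit(lp + delta)
    death_ih = rng_out.uniform(size=n) < p_true
    frame["death_inhospital"] = death_ih

    # 30-day mortality: every simulated in-hospital death occurs within 30
    # days; survivors add post-discharge deaths proportional to the same risk
    death_30 = death_ih.copy()
    if config.target_rate_day30 is not None:
        extra = (config.target_rate_day30 - (config.target_rate or 100 * p_true.mean())) / 100.0
        if extra > 0:
            surv = ~death_ih
            scale = (extra * n) / max(p_true[surv].sum(), 1e-12)
            q = np.clip(scale * p_true, 0.0, 1.0)
            death_30[surv] |= rng_d30.uniform(size=int(surv.sum())) < q[surv]
    frame["death_30day"] = death_30

    meta = {
        "seed": config.seed,
        "child_spawn_keys": [list(s.spawn_key) for s in seeds],
        "n_patients": n,
        "true_model": config.true_model_id,
        "intercept_shift": delta,
        "tuned_intercept": float(coef.intercept + delta),
        "mean_true_risk": float(p_true.mean()),
        "realized_inhospital_rate_pct": 100.0 * float(death_ih.mean()),
        "realized_day30_rate_pct": 100.0 * float(death_30.mean()),
    }

    from .records import COLUMN_ORDER

    if config.missingness:
        frame = inject_missingness(
            frame, config.missingness, seed=np.random.default_rng(seeds[4])
        )
    frame = frame.reindex(columns=list(COLUMN_ORDER))
    frame.attrs["meta"] = meta
    return frame


def inject_missingness(
    cohort: pd.DataFrame,
    missingness: dict[str, float],
    seed=0,
) -> pd.DataFrame:
    """Blank each clinical value independently with its field's probability
    (missing completely at random).  Outcome flags are never blanked."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = cohort.copy()
    n = len(out)
    for field_name, prob in missingness.items():
        if not 0 <= prob < 1:
            raise ConfigError(f"missingness for {field_name} must lie in [0, 1)")
        if field_name.startswith("death_"):
            raise ConfigError("outcomes are never blanked")
        if field_name not in out.columns or prob == 0.0:
            continue
        mask = rng.uniform(size=n) < prob
        col = out[field_name]
        if col.dtype.kind == "f":
            out[field_name] = col.where(~mask, other=np.nan)
        else:
            out[field_name] = col.astype(object).where(~mask, other=pd.NA)
    return out
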