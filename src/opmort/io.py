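"""Cohort CSV input/output, report rendering, and run manifests.

The cohort exchange format is delimited UTF-8 text with a header row and one
row per patient (columns of :data:`opmort.records.COLUMN_ORDER`); missing
clinical values are empty cells.  Two dialects are supported: ``standard``
(period decimal, comma separator) and ``european`` (comma decimal, semicolon
separator — common in Spanish clinical exports).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd

from . import __version__
from .records import (
    BOOLEAN_FIELDS,
    CATEGORICAL_LEVELS,
    COLUMN_ORDER,
    NUMERIC_FIELDS,
    OUTCOME_FIELDS,
    UNIT_PLAUSIBILITY,
)
from .recalibration import RecalibrationResult
from .validation import ValidationReport

logger = logging.getLogger("opmort")

_DIALECTS = {"standard": (",", "."), "european": (";", ",")}

_TRUE = {"true", "1", "yes", "y"}
_FALSE = {"false", "0", "no", "n"}


class SchemaError(ValueError):
    """The cohort file does not carry the expected columns."""


@dataclass
class ParseReport:
    n_rows: int
    n_columns: int
    unparseable_cells: int = 0
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_rows": self.n_rows,
            "n_columns": self.n_columns,
            "unparseable_cells": self.unparseable_cells,
            "warnings": list(self.warnings),
        }


def read_cohort(
    path: str, dialect: str = "standard"
) -> tuple[pd.DataFrame, ParseReport]:
    """Read a cohort table; unparseable cells become missing with a warning.

    Raises :class:`SchemaError` listing the expected columns when any is
    absent from the header.
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; use standard|european")
    sep, decimal = _DIALECTS[dialect]
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing_cols = [c for c in COLUMN_ORDER if c not in raw.columns]
    if missing_cols:
        raise SchemaError(
            f"cohort file lacks columns {missing_cols}; "
            f"expected exactly: {list(COLUMN_ORDER)}"
        )
    report = ParseReport(n_rows=len(raw), n_columns=len(raw.columns))
    out = pd.DataFrame(index=raw.index)
    out["patient_id"] = raw["patient_id"].astype(str)

    def _exact_float(text: str) -> float:
        # float() round-trips repr() exactly; pandas' fast parser may be
        # off by one ulp, which would break bit-for-bit cohort round-trips
        try:
            return float(text)
        except ValueError:
            return np.nan

    for name in NUMERIC_FIELDS:
        col = raw[name].str.strip()
        if decimal != ".":
            col = col.str.replace(decimal, ".", regex=False)
        values = col.map(lambda s: np.nan if s == "" else _exact_float(s))
        bad = values.isna() & (col != "") & col.notna()
        if bad.any():
            report.unparseable_cells += int(bad.sum())
            report.warnings.append(
                f"{name}: {int(bad.sum())} unparseable numeric cell(s) set missing"
            )
        out[name] = values.astype(float)
        limit = UNIT_PLAUSIBILITY.get(name)
        if limit is not None and (values > limit[0]).any():
            report.warnings.append(
                f"{name}: {int((values > limit[0]).sum())} value(s) above "
                f"{limit[0]} — {limit[1]} (no conversion applied)"
            )

    for name, levels in CATEGORICAL_LEVELS.items():
        col = raw[name].str.strip()
        valid = col.isin(levels)
        bad = ~valid & (col != "")
        if bad.any():
            report.unparseable_cells += int(bad.sum())
            report.warnings.append(
                f"{name}: {int(bad.sum())} value(s) outside {levels} set missing"
            )
        out[name] = col.where(valid, other=pd.NA).astype(object)

    for name in BOOLEAN_FIELDS + OUTCOME_FIELDS:
        col = raw[name].str.strip().str.lower()
        parsed = pd.Series(pd.NA, index=raw.index, dtype=object)
        parsed[col.isin(_TRUE)] = True
        parsed[col.isin(_FALSE)] = False
        bad = parsed.isna() & (col != "")
        if bad.any():
            report.unparseable_cells += int(bad.sum())
            report.warnings.append(
                f"{name}: {int(bad.sum())} unparseable boolean cell(s) set missing"
            )
        if name in OUTCOME_FIELDS:
            out[name] = np.where(parsed.isna(), False, parsed.to_numpy(object)).astype(bool)
        else:
            out[name] = parsed

    out = out.reindex(columns=list(COLUMN_ORDER))
    for message in report.warnings:
        logger.warning("read_cohort: %s", message)
    logger.info(
        "read_cohort: %d rows, %d columns from %s", report.n_rows, report.n_columns, path
    )
    return out, report


def write_cohort(frame: pd.DataFrame, path: str, dialect: str = "standard") -> None:
    """Write a cohort table; missing values become empty cells and booleans
    the literals ``true``/``false`` so a read round-trips exactly."""
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; use standard|european")
    sep, decimal = _DIALECTS[dialect]
    out = frame.copy()

    def fmt(value) -> str:
        if value is None or value is pd.NA:
            return ""
        if isinstance(value, float) and np.isnan(value):
            return ""
        if isinstance(value, (bool, np.bool_)):
            return "true" if value else "false"
        if isinstance(value, (float, np.floating)):
            text = repr(float(value))
            return text.replace(".", decimal) if decimal != "." else text
        return str(value)

    for col in out.columns:
        out[col] = out[col].map(fmt)
    out.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# report rendering


def _fmt_pct(value: Optional[float], decimals: int = 1) -> str:
    return "NA" if value is None else f"{100.0 * value:.{decimals}f}"


def _fmt_auc_cell(auc: Optional[float], ci: Optional[tuple]) -> str:
    if auc is None:
        return "NA"
    cell = _fmt_pct(auc)
    if ci is not None:
        cell += f" ({_fmt_pct(ci[0])}–{_fmt_pct(ci[1])})"
    return cell


def _fmt_p(p: Optional[float]) -> str:
    if p is None:
        return "NA"
    return "< 0.001" if p < 0.001 else f"{p:.3f}"


def render_report(
    reports: Iterable[Union[ValidationReport, RecalibrationResult]],
) -> tuple[str, dict]:
    """Render reports as a comparison-table text block plus a JSON twin.

    AUCs are printed on the percent scale to one decimal with their CI, e.g.
    ``75.5 (67.3–83.7)``; unavailable statistics render ``NA``.  The JSON twin
    carries the full-precision values.
    """
    items = list(reports)
    if not items:
        raise ValueError("need at least one report")
    flat: list[ValidationReport] = []
    json_reports = []
    for item in items:
        report = item.post_report if isinstance(item, RecalibrationResult) else item
        flat.append(report)
        json_reports.append(
            item.to_dict() if isinstance(item, RecalibrationResult) else report.to_dict()
        )
    header = f"{'Model':<10}{'Outcome':<11}{'Stage':<15}{'N':>6}{'Deaths':>8}  {'AUC (95% CI)':<22}{'H-L p':>9}"
    lines = [header, "-" * len(header)]
    for rep in flat:
        lines.append(
            f"{rep.model_id:<10}{rep.outcome:<11}{rep.stage:<15}"
            f"{rep.n_analyzed:>6}{rep.deaths_included:>8}  "
            f"{_fmt_auc_cell(rep.auc, rep.auc_ci):<22}{_fmt_p(rep.hl_p):>9}"
        )
    return "\n".join(lines), {"reports": json_reports}


# ---------------------------------------------------------------------------
# run manifests


def file_checksum(path: str) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


@dataclass
class RunManifest:
    """Provenance of one CLI run: what was run, on what, with which seeds."""

    command: str
    seeds: dict
    config_hash: str = ""
    input_checksums: dict = field(default_factory=dict)
    registry_citations: dict = field(default_factory=dict)
    package_version: str = __version__
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )

    def to_dict(self) -> dict:
        return {
            "command": self.command,
            "seeds": self.seeds,
            "config_hash": self.config_hash,
            "input_checksums": self.input_checksums,
            "registry_citations": self.registry_citations,
            "package_version": self.package_version,
            "timestamp": self.timestamp,
        }

    def write(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")
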