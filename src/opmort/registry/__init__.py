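"""Model registry: immutable literature constants kept as data, not code.

Each of the five risk models ships as one human-readable JSON file under
``registry/data/`` holding its variable bins, integer category weights,
logistic coefficients and citation.  The loader turns those files into
:class:`ScoreDefinition` objects; recalibrated coefficient sets are written
back in the same format so provenance stays auditable.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Any, Optional

MODEL_IDS = ("POSSUM", "P_POSSUM", "CR_POSSUM", "AFC", "IRCS")

_DATA_FILES = {
    "POSSUM": "possum.json",
    "P_POSSUM": "p_possum.json",
    "CR_POSSUM": "cr_possum.json",
    "AFC": "afc.json",
    "IRCS": "ircs_synthetic.json",
}


class RegistryError(ValueError):
    """Malformed or inconsistent registry content."""


@dataclass(frozen=True)
class Bin:
    """One category of a model variable: a label, an integer weight, and
    either a list of closed/open numeric intervals or a set of values."""

    label: str
    weight: int
    intervals: tuple[tuple[Optional[float], Optional[float], bool, bool], ...] = ()
    values: tuple[Any, ...] = ()

    def contains(self, value: Any) -> bool:
        if self.values:
            return value in self.values
        for lo, hi, lo_incl, hi_incl in self.intervals:
            ok_lo = lo is None or (value >= lo if lo_incl else value > lo)
            ok_hi = hi is None or (value <= hi if hi_incl else value < hi)
            if ok_lo and ok_hi:
                return True
        return False


@dataclass(frozen=True)
class VariableDef:
    name: str
    field: str
    kind: str  # numeric | categorical | boolean
    bins: tuple[Bin, ...]

    def bin_for(self, value: Any) -> Bin:
        for b in self.bins:
            if b.contains(value):
                return b
        raise RegistryError(
            f"value {value!r} of {self.name} falls outside every bin"
        )


@dataclass(frozen=True)
class CoefficientSet:
    """Intercept + per-term logistic coefficients with provenance.

    Terms are ``physiological_score``/``operative_score`` for the POSSUM
    family and ``variable:category`` indicators for the category models
    (reference categories carry an implicit 0).
    """

    model_id: str
    intercept: float
    terms: dict[str, float]
    provenance: str = "original_publication"
    source_label: str = ""
    fit_info: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        out: dict[str, Any] = {
            "model_id": self.model_id,
            "provenance": self.provenance,
            "source_label": self.source_label,
            "intercept": self.intercept,
            "terms": dict(self.terms),
        }
        if self.fit_info:
            out["fit_info"] = dict(self.fit_info)
        return out

    @classmethod
    def from_dict(cls, model_id: str, data: dict[str, Any]) -> "CoefficientSet":
        return cls(
            model_id=data.get("model_id", model_id),
            intercept=float(data["intercept"]),
            terms={k: float(v) for k, v in data["terms"].items()},
            provenance=data.get("provenance", "original_publication"),
            source_label=data.get("source_label", ""),
            fit_info=data.get("fit_info", {}),
        )


@dataclass(frozen=True)
class ScoreDefinition:
    """A risk model's full structural definition.

    ``family`` is ``score_link`` (POSSUM/P-POSSUM/CR-POSSUM: weights sum to a
    physiological and an operative score that enter the logit) or
    ``category`` (AFC/IRCS: category indicators enter the logit directly).
    """

    model_id: str
    family: str
    name: str
    citation: str
    groups: dict[str, dict[str, VariableDef]]
    coefficient_set: Optional[CoefficientSet]
    metadata: dict[str, Any] = field(default_factory=dict)

    @property
    def variables(self) -> dict[str, VariableDef]:
        merged: dict[str, VariableDef] = {}
        for group in self.groups.values():
            merged.update(group)
        return merged

    @property
    def required_fields(self) -> tuple[str, ...]:
        seen: list[str] = []
        for var in self.variables.values():
            if var.field not in seen:
                seen.append(var.field)
        return tuple(seen)

    def with_coefficients(self, coef: CoefficientSet) -> "ScoreDefinition":
        return ScoreDefinition(
            model_id=self.model_id,
            family=self.family,
            name=self.name,
            citation=self.citation,
            groups=self.groups,
            coefficient_set=coef,
            metadata=self.metadata,
        )


def _parse_bin(data: dict[str, Any]) -> Bin:
    weight = data["weight"]
    if not (isinstance(weight, int) and weight > 0):
        raise RegistryError(f"bin weight must be a positive integer: {data}")
    intervals = tuple(
        (
            None if lo is None else float(lo),
            None if hi is None else float(hi),
            bool(lo_incl),
            bool(hi_incl),
        )
        for lo, hi, lo_incl, hi_incl in data.get("intervals", [])
    )
    return Bin(
        label=data["label"],
        weight=weight,
        intervals=intervals,
        values=tuple(data.get("values", [])),
    )


def _parse_groups(data: dict[str, Any]) -> dict[str, dict[str, VariableDef]]:
    groups: dict[str, dict[str, VariableDef]] = {}
    for group_name, variables in data.items():
        groups[group_name] = {
            var_name: VariableDef(
                name=var_name,
                field=var_data["field"],
                kind=var_data["kind"],
                bins=tuple(_parse_bin(b) for b in var_data["bins"]),
            )
            for var_name, var_data in variables.items()
        }
    return groups


def definition_from_dict(data: dict[str, Any]) -> ScoreDefinition:
    model_id = data["model_id"]
    coef = data.get("coefficients")
    return ScoreDefinition(
        model_id=model_id,
        family=data["family"],
        name=data.get("name", model_id),
        citation=data.get("citation", ""),
        groups=_parse_groups(data["groups"]),
        coefficient_set=None if coef is None else CoefficientSet.from_dict(model_id, coef),
        metadata=data.get("metadata", {}),
    )


def definition_to_dict(definition: ScoreDefinition) -> dict[str, Any]:
    groups: dict[str, Any] = {}
    for group_name, variables in definition.groups.items():
        groups[group_name] = {
            name: {
                "field": var.field,
                "kind": var.kind,
                "bins": [
                    {
                        "label": b.label,
                        "weight": b.weight,
                        **({"intervals": [list(iv) for iv in b.intervals]} if b.intervals else {}),
                        **({"values": list(b.values)} if b.values else {}),
                    }
                    for b in var.bins
                ],
            }
            for name, var in variables.items()
        }
    coef = definition.coefficient_set
    return {
        "model_id": definition.model_id,
        "family": definition.family,
        "name": definition.name,
        "citation": definition.citation,
        "metadata": definition.metadata,
        "groups": groups,
        "coefficients": None if coef is None else coef.to_dict(),
    }


def _read_data_file(model_id: str) -> dict[str, Any]:
    fname = _DATA_FILES[model_id]
    text = resources.files("opmort.registry").joinpath("data", fname).read_text()
    return json.loads(text)


def load_model(model_id: str) -> ScoreDefinition:
    """Load a model definition from the shipped registry.

    ``model_id`` is case-insensitive and accepts ``-`` for ``_``
    (``cr-possum`` == ``CR_POSSUM``).
    """
    key = model_id.upper().replace("-", "_")
    if key not in _DATA_FILES:
        raise RegistryError(f"unknown model {model_id!r}; known: {MODEL_IDS}")
    raw = _read_data_file(key)
    if "bins_from" in raw:
        parent = _read_data_file(raw["bins_from"].upper().replace("-", "_"))
        raw = {**raw, "groups": parent["groups"]}
        raw.pop("bins_from")
    return definition_from_dict(raw)


def available_models() -> tuple[str, ...]:
    return MODEL_IDS


def save_definition(definition: ScoreDefinition, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(definition_to_dict(definition), fh, indent=2)
        fh.write("\n")


def load_definition(path: str) -> ScoreDefinition:
    with open(path, encoding="utf-8") as fh:
        return definition_from_dict(json.load(fh))


def save_coefficients(coef: CoefficientSet, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(coef.to_dict(), fh, indent=2)
        fh.write("\n")


def load_coefficients(path: str) -> CoefficientSet:
    with open(path, encoding="utf-8") as fh:
        data = json.load(fh)
    return CoefficientSet.from_dict(data.get("model_id", "unknown"), data)
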