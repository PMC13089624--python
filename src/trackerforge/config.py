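"""Canonical schema, synonym map, sentinel policy and validation rules.

Tracker workbooks arrive with column headers that differ by hospital and by
era of the template. All harmonization is driven by one YAML configuration:
a list of canonical variables (with dtypes, bounds, allowed values), a
synonym map from normalized raw headers to canonical names, the sentinel
policy, and cross-cutting validation thresholds. The configuration is fully
validated at load time; any inconsistency raises :class:`ConfigError` naming
the offending key.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from datetime import date
from importlib import resources
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, model_validator

__all__ = [
    "ConfigError", "CanonicalVariable", "Bounds", "SynonymMap",
    "SentinelPolicy", "ValidationRuleSet", "Config",
    "normalize_header", "load_config", "load_default_config",
    "default_config_path",
]

Entity = Literal["patient", "product"]
Dtype = Literal["number", "date", "text", "category", "hba1c",
                "blood_pressure", "height"]

#: dtypes whose variables must declare numeric bounds.
BOUNDED_DTYPES = ("number", "hba1c", "height")


class ConfigError(ValueError):
    """Raised when a configuration file violates the schema contract."""


_WS_RUN = re.compile(r"\s+")


def normalize_header(raw: str) -> str:
    """Normalize a raw column header for synonym lookup.

    Case-folds, converts non-breaking spaces to ordinary spaces, strips
    leading/trailing whitespace and collapses internal whitespace runs to a
    single space. Total and idempotent.
    """
    s = str(raw).replace("\u00a0", " ")
    return _WS_RUN.sub(" ", s).strip().casefold()


class Bounds(BaseModel):
    model_config = ConfigDict(frozen=True)
    min: float
    max: float

    @model_validator(mode="after")
    def _ordered(self) -> "Bounds":
        if not self.min < self.max:
            raise ValueError(f"bounds min {self.min} must be < max {self.max}")
        return self

    def contains(self, value: float) -> bool:
        # closed interval: boundary values pass
        return self.min <= value <= self.max


class CanonicalVariable(BaseModel):
    """One standardized variable of the patient or product schema."""

    model_config = ConfigDict(frozen=True)
    name: str
    entity: Entity
    dtype: Dtype
    required: bool = False
    bounds: Optional[Bounds] = None
    allowed_values: Optional[tuple[str, ...]] = None

    @model_validator(mode="after")
    def _consistent(self) -> "CanonicalVariable":
        if (self.bounds is not None) != (self.dtype in BOUNDED_DTYPES):
            raise ValueError(
                f"variable {self.name!r}: bounds must be present exactly when "
                f"dtype is one of {BOUNDED_DTYPES}, got dtype={self.dtype!r}")
        if (self.allowed_values is not None) != (self.dtype == "category"):
            raise ValueError(
                f"variable {self.name!r}: allowed_values required exactly "
                f"when dtype is 'category'")
        if self.allowed_values is not None and len(self.allowed_values) == 0:
            raise ValueError(f"variable {self.name!r}: allowed_values empty")
        return self


@dataclass(frozen=True)
class SynonymMap:
    """Mapping from normalized raw header to canonical variable name."""

    entries: dict[str, str]
    patient_variable_count: int
    product_variable_count: int

    def lookup(self, raw_header: str) -> Optional[str]:
        return self.entries.get(normalize_header(raw_header))

    def variants_of(self, canonical: str) -> list[str]:
        """All normalized header variants mapping to one canonical name."""
        return sorted(k for k, v in self.entries.items() if v == canonical)


class SentinelPolicy(BaseModel):
    """Conspicuous placeholders substituted for unconvertible values."""

    model_config = ConfigDict(frozen=True)
    numeric_sentinel: float = 999999
    date_sentinel: date = date(9999, 12, 31)


class ValidationRuleSet(BaseModel):
    """Cross-cutting cleaning thresholds, on top of per-variable bounds."""

    model_config = ConfigDict(frozen=True)
    height_cm_threshold: float = 50
    hba1c_bounds: Bounds = Bounds(min=0, max=25)
    age_bounds: Bounds = Bounds(min=0, max=100)
    bp_systolic_bounds: Bounds = Bounds(min=50, max=250)
    bp_diastolic_bounds: Bounds = Bounds(min=30, max=150)

    @model_validator(mode="after")
    def _positive(self) -> "ValidationRuleSet":
        if self.height_cm_threshold <= 0:
            raise ValueError("height_cm_threshold must be strictly positive")
        return self


@dataclass(frozen=True)
class Config:
    """A fully validated configuration bundle."""

    variables: tuple[CanonicalVariable, ...]
    synonyms: SynonymMap
    sentinels: SentinelPolicy
    rules: ValidationRuleSet

    def variable(self, name: str, entity: Optional[str] = None) -> CanonicalVariable:
        for v in self.variables:
            if v.name == name and (entity is None or v.entity == entity):
                return v
        raise KeyError(name)

    def entity_variables(self, entity: str) -> tuple[CanonicalVariable, ...]:
        return tuple(v for v in self.variables if v.entity == entity)

    def has_variable(self, name: str, entity: str) -> bool:
        return any(v.name == name and v.entity == entity for v in self.variables)


def _err(key: str, msg: str) -> ConfigError:
    return ConfigError(f"{key}: {msg}")


def _parse_variables(raw_vars: object) -> tuple[CanonicalVariable, ...]:
    if not isinstance(raw_vars, list) or not raw_vars:
        raise _err("variables", "must be a non-empty list")
    out: list[CanonicalVariable] = []
    seen: set[tuple[str, str]] = set()
    for item in raw_vars:
        try:
            var = CanonicalVariable(**item)
        except Exception as exc:
            name = item.get("name", "<unnamed>") if isinstance(item, dict) else "<bad>"
            raise _err(f"variables.{name}", str(exc)) from exc
        key = (var.entity, var.name)
        if key in seen:
            raise _err(f"variables.{var.name}",
                       f"duplicate name within entity {var.entity!r}")
        seen.add(key)
        out.append(var)
    return tuple(out)


def _parse_synonyms(raw_syn: object,
                    variables: tuple[CanonicalVariable, ...]) -> SynonymMap:
    if not isinstance(raw_syn, dict) or not raw_syn:
        raise _err("synonyms", "must be a non-empty mapping")
    declared = {v.name for v in variables}
    entries: dict[str, str] = {}
    for raw_key, target in raw_syn.items():
        norm = normalize_header(raw_key)
        if norm in entries:
            raise _err(f"synonyms.{raw_key}",
                       f"duplicate normalized header {norm!r}")
        if target not in declared:
            raise _err(f"synonyms.{raw_key}",
                       f"targets undeclared variable {target!r}")
        entries[norm] = target
    targeted = set(entries.values())
    patient_names = {v.name for v in variables if v.entity == "patient"}
    product_names = {v.name for v in variables if v.entity == "product"}
    return SynonymMap(
        entries=entries,
        patient_variable_count=len(targeted & patient_names),
        product_variable_count=len(targeted & product_names),
    )


def _check_sentinels(sentinels: SentinelPolicy,
                     variables: tuple[CanonicalVariable, ...]) -> None:
    for v in variables:
        if v.bounds is not None and v.bounds.contains(sentinels.numeric_sentinel):
            raise _err(f"sentinels.numeric",
                       f"sentinel {sentinels.numeric_sentinel} lies inside the "
                       f"bounds of variable {v.name!r}")
    if sentinels.date_sentinel.year < 9000:
        raise _err("sentinels.date",
                   "date sentinel must be far beyond any plausible clinical date")


def load_config(path: Path | str) -> Config:
    """Load and fully validate a YAML configuration file.

    Returns a :class:`Config` bundling the canonical variables, synonym map,
    sentinel policy and validation rules. Any contract violation raises
    :class:`ConfigError` naming the offending key.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        doc = yaml.safe_load(path.read_text(encoding="utf-8"))
    except yaml.YAMLError as exc:
        raise ConfigError(f"malformed YAML in {path}: {exc}") from exc
    if not isinstance(doc, dict):
        raise ConfigError(f"config root must be a mapping, got {type(doc).__name__}")

    variables = _parse_variables(doc.get("variables"))
    synonyms = _parse_synonyms(doc.get("synonyms"), variables)

    try:
        sentinels = SentinelPolicy(
            numeric_sentinel=doc.get("sentinels", {}).get("numeric", 999999),
            date_sentinel=doc.get("sentinels", {}).get("date", date(9999, 12, 31)),
        )
    except Exception as exc:
        raise _err("sentinels", str(exc)) from exc
    _check_sentinels(sentinels, variables)

    try:
        rules = ValidationRuleSet(**(doc.get("validation") or {}))
    except Exception as exc:
        raise _err("validation", str(exc)) from exc

    return Config(variables=variables, synonyms=synonyms,
                  sentinels=sentinels, rules=rules)


def default_config_path() -> Path:
    """Path of the shipped default configuration."""
    return Path(resources.files("trackerforge").joinpath("data/default_config.yaml"))


def load_default_config() -> Config:
    return load_config(default_config_path())
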