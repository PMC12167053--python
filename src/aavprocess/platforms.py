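"""Scenario data model: platforms, schedules, facilities and cost catalogs.

A *scenario* bundles everything the cost engine needs: the production
platforms under comparison, the day-indexed process schedule for each, the
facility constraints (area, microbial safety cabinets, staffing rules) and a
currency-free cost catalog. Scenarios are read from YAML (or an equivalent
JSON mapping) with a versioned ``schema_version`` key and validate on load;
validation failures are reported with field paths.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Any, Literal, Mapping

import yaml
from pydantic import (
    BaseModel,
    ConfigDict,
    Field,
    ValidationError,
    model_validator,
)

SCHEMA_VERSION = 1

__all__ = [
    "SCHEMA_VERSION",
    "ScenarioError",
    "Finding",
    "MaterialUse",
    "ProcessStep",
    "ProcessDefinition",
    "PlatformSpec",
    "FacilityConfig",
    "CatalogItem",
    "CostCatalog",
    "Scenario",
    "load_scenario",
    "save_scenario",
    "serialize_scenario",
    "validate_schedule",
]


class ScenarioError(ValueError):
    """A scenario file failed schema or referential-integrity validation."""


@dataclass(frozen=True)
class Finding:
    """One schedule-validation problem, located by a field path."""

    path: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.path}: {self.message}"


class MaterialUse(BaseModel):
    """One catalog item consumed by a step.

    ``basis`` states whether ``quantity`` scales with the number of vessel
    units in a production (``per_unit``) or is incurred once per production
    (``per_batch``).
    """

    model_config = ConfigDict(extra="forbid")

    item: str
    quantity: float = Field(ge=0)
    basis: Literal["per_unit", "per_batch"] = "per_unit"


class ProcessStep(BaseModel):
    """A single scheduled activity on a given process day."""

    model_config = ConfigDict(extra="forbid")

    name: str
    day: int = Field(ge=0)
    duration_hours: float = Field(default=0.0, ge=0)
    operators: int = Field(default=1, ge=0)
    msc_sessions: int = Field(default=0, ge=0)
    open_manipulations_per_unit: int = Field(default=0, ge=0)
    open_manipulations_per_batch: int = Field(default=0, ge=0)
    materials: list[MaterialUse] = Field(default_factory=list)
    qc_samples: int = Field(default=0, ge=0)


class ProcessDefinition(BaseModel):
    """Day-indexed schedule of steps for one platform.

    Steps are kept sorted by day; insertion order is preserved within a day
    (stable sort) so reports are reproducible.
    """

    model_config = ConfigDict(extra="forbid")

    platform: str
    steps: list[ProcessStep] = Field(min_length=1)

    @model_validator(mode="after")
    def _sort_steps(self) -> "ProcessDefinition":
        self.steps.sort(key=lambda s: s.day)  # stable within a day
        return self

    @property
    def batch_duration_days(self) -> int:
        return max(s.day for s in self.steps) + 1


class PlatformSpec(BaseModel):
    """A production vessel or system type.

    ``units_per_msc_session = 0`` means the platform is not throughput-limited
    by the safety cabinet (closed system; a single MSC is still occupied for
    sterile preparation). ``units_per_incubator = 0`` marks a self-contained
    system needing no incubator. ``systems_per_operator_pair > 0`` switches
    staffing from the per-MSC rule to a crew rule (two operators per that many
    systems).
    """

    model_config = ConfigDict(extra="forbid")

    name: str
    surface_area_cm2: float = Field(gt=0)
    working_volume_mL: float = Field(gt=0)
    yield_vg_per_unit: float = Field(ge=0)
    yield_vp_per_unit: float | None = Field(default=None, ge=0)
    footprint_m2: float = Field(ge=0)
    units_per_msc_session: int = Field(default=0, ge=0)
    units_per_incubator: int = Field(default=0, ge=0)
    systems_per_operator_pair: int = Field(default=0, ge=0)
    is_closed: bool = False


class FacilityConfig(BaseModel):
    """Cleanroom constraints and currency-free operating rates."""

    model_config = ConfigDict(extra="forbid")

    area_m2: float = Field(default=60.0, gt=0)
    operator_space_m2: float = Field(default=2.0, ge=0)
    msc_footprint_m2: float = Field(default=2.5, ge=0)
    incubator_footprint_m2: float = Field(default=0.7, ge=0)
    operator_cost_per_hour: float = Field(default=0.0, ge=0)
    facility_cost_per_day: float = Field(default=0.0, ge=0)
    max_mscs: int = Field(default=3, ge=1)
    operators_per_msc: int = Field(default=2, ge=1)


class CatalogItem(BaseModel):
    model_config = ConfigDict(extra="forbid")

    unit_cost: float = Field(ge=0)
    unit: str = ""


class CostCatalog(BaseModel):
    """Item prices plus the QC plate-sharing rule.

    QC costs are charged per full analytical plate: samples are pooled across
    a batch and the batch pays ``ceil(samples / qc_samples_per_plate)`` plates.
    """

    model_config = ConfigDict(extra="forbid")

    items: dict[str, CatalogItem] = Field(default_factory=dict)
    qc_cost_per_plate: float = Field(default=0.0, ge=0)
    qc_samples_per_plate: int = Field(default=96, ge=1)


class Scenario(BaseModel):
    """A full, cross-reference-checked scenario configuration."""

    model_config = ConfigDict(extra="forbid")

    schema_version: int = SCHEMA_VERSION
    platforms: list[PlatformSpec] = Field(min_length=1)
    facility: FacilityConfig = Field(default_factory=FacilityConfig)
    catalog: CostCatalog = Field(default_factory=CostCatalog)
    processes: list[ProcessDefinition] = Field(default_factory=list)

    @model_validator(mode="after")
    def _check_references(self) -> "Scenario":
        names = [p.name for p in self.platforms]
        if len(set(names)) != len(names):
            raise ValueError("platform names must be unique")
        known = set(names)
        for i, proc in enumerate(self.processes):
            if proc.platform not in known:
                raise ValueError(
                    f"processes[{i}].platform: unknown platform "
                    f"{proc.platform!r}"
                )
            for j, step in enumerate(proc.steps):
                for k, mat in enumerate(step.materials):
                    if mat.item not in self.catalog.items:
                        raise ValueError(
                            f"processes[{i}].steps[{j}].materials[{k}]: "
                            f"material id {mat.item!r} not in catalog"
                        )
        return self

    def platform(self, name: str) -> PlatformSpec:
        for p in self.platforms:
            if p.name == name:
                return p
        raise KeyError(f"no platform named {name!r}")

    def process_for(self, platform_name: str) -> ProcessDefinition:
        for proc in self.processes:
            if proc.platform == platform_name:
                return proc
        raise KeyError(f"no process defined for platform {platform_name!r}")


def _format_validation_error(err: ValidationError) -> str:
    lines = []
    for e in err.errors():
        loc = ".".join(str(p) for p in e["loc"]) or "<root>"
        lines.append(f"{loc}: {e['msg']}")
    return "; ".join(lines)


def load_scenario(path: str | Path) -> Scenario:
    """Read and validate a YAML/JSON scenario file.

    Raises :class:`ScenarioError` naming the offending field on schema
    violations or dangling material references; ``FileNotFoundError`` if the
    file is absent.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"scenario file not found: {path}")
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, Mapping):
        raise ScenarioError(f"{path}: top level must be a mapping")
    try:
        return Scenario.model_validate(dict(raw))
    except ValidationError as err:
        raise ScenarioError(_format_validation_error(err)) from err


def serialize_scenario(scenario: Scenario) -> dict[str, Any]:
    """Normalized plain-dict form of a scenario (defaults filled in)."""
    return scenario.model_dump(mode="json")


def save_scenario(scenario: Scenario, path: str | Path) -> Path:
    """Write a scenario back to YAML. Deterministic: key order is the model's
    declared field order, not alphabetical."""
    path = Path(path)
    path.write_text(
        yaml.safe_dump(serialize_scenario(scenario), sort_keys=False)
    )
    return path


def validate_schedule(
    pd: ProcessDefinition | Mapping[str, Any],
) -> list[Finding]:
    """Check schedule invariants, returning findings rather than raising.

    Accepts either a parsed :class:`ProcessDefinition` (already guaranteed
    valid, so this returns ``[]``) or a raw mapping, for which every invariant
    is checked and one finding per violation is returned. Duplicate step names
    on the same day are allowed (stable order disambiguates them).
    """
    if isinstance(pd, ProcessDefinition):
        data: Mapping[str, Any] = pd.model_dump()
    else:
        data = pd

    findings: list[Finding] = []
    steps = data.get("steps")
    if not isinstance(steps, list) or not steps:
        findings.append(Finding("steps", "steps list must be non-empty"))
        return findings

    count_fields = (
        "operators",
        "msc_sessions",
        "open_manipulations_per_unit",
        "open_manipulations_per_batch",
        "qc_samples",
    )
    for j, step in enumerate(steps):
        if not isinstance(step, Mapping):
            findings.append(Finding(f"steps[{j}]", "step must be a mapping"))
            continue
        day = step.get("day")
        if not isinstance(day, int) or day < 0:
            findings.append(
                Finding(f"steps[{j}].day", f"day must be an integer >= 0, got {day!r}")
            )
        dur = step.get("duration_hours", 0.0)
        if not isinstance(dur, (int, float)) or dur < 0:
            findings.append(
                Finding(f"steps[{j}].duration_hours", f"must be >= 0, got {dur!r}")
            )
        for field in count_fields:
            val = step.get(field, 0)
            if not isinstance(val, int) or val < 0:
                findings.append(
                    Finding(f"steps[{j}].{field}", f"must be an integer >= 0, got {val!r}")
                )
        for k, mat in enumerate(step.get("materials", []) or []):
            if isinstance(mat, Mapping):
                qty = mat.get("quantity", 0)
                if not isinstance(qty, (int, float)) or qty < 0:
                    findings.append(
                        Finding(
                            f"steps[{j}].materials[{k}].quantity",
                            f"must be >= 0, got {qty!r}",
                        )
                    )
    return findings
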