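"""Cost-of-goods engine: unit sizing, batch packing, costing, comparison.

The model is deliberately deterministic and spreadsheet-like. For a requested
post-downstream output it computes the number of vessel units needed (given
per-unit crude yield and an end-to-end downstream recovery), packs those
units into sequential productions under the facility's area, safety-cabinet
and staffing constraints (greedy: each production takes the largest feasible
unit count), and prices the batch from the process schedule and catalog.
Platforms are compared as fold changes against a reference platform across a
sweep of target outputs, which makes the comparison invariant to the
(currency-free) price scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .platforms import (
    CostCatalog,
    FacilityConfig,
    PlatformSpec,
    ProcessDefinition,
    Scenario,
    ScenarioError,
)

__all__ = [
    "CapacityError",
    "Production",
    "BatchPlan",
    "CoGReport",
    "ComparisonTable",
    "required_units",
    "plan_batches",
    "cost_of_batch",
    "doses_from_batch",
    "run_target",
    "compare",
    "METRICS",
]

METRICS = ("total_cost", "open_steps", "production_days")


class CapacityError(RuntimeError):
    """The facility cannot host even a single unit of a production."""

    def __init__(self, message: str, binding_constraint: str):
        super().__init__(message)
        self.binding_constraint = binding_constraint


@dataclass(frozen=True)
class Production:
    index: int
    units: int
    days: int


@dataclass(frozen=True)
class BatchPlan:
    """How one batch is split into sequential productions."""

    platform: str
    target_vg: float
    units_required: int
    productions: tuple[Production, ...]
    total_days: int
    operators_assigned: int
    mscs_used: int
    incubators_used: int
    area_used_m2: float


@dataclass(frozen=True)
class CoGReport:
    """Cost and risk breakdown for one batch plan."""

    plan: BatchPlan
    materials_cost: float
    labor_cost: float
    facility_cost: float
    qc_cost: float
    total_cost: float
    open_steps: int
    production_days: int
    operator_hours: float

    def as_dict(self) -> dict:
        return {
            "platform": self.plan.platform,
            "target_vg": self.plan.target_vg,
            "units_required": self.plan.units_required,
            "productions": [
                {"index": p.index, "units": p.units, "days": p.days}
                for p in self.plan.productions
            ],
            "materials_cost": self.materials_cost,
            "labor_cost": self.labor_cost,
            "facility_cost": self.facility_cost,
            "qc_cost": self.qc_cost,
            "total_cost": self.total_cost,
            "open_steps": self.open_steps,
            "production_days": self.production_days,
            "operator_hours": self.operator_hours,
            "area_used_m2": self.plan.area_used_m2,
            "mscs_used": self.plan.mscs_used,
            "operators_assigned": self.plan.operators_assigned,
        }


def required_units(
    target_vg: float, per_unit_yield_vg: float, dsp_recovery: float
) -> int:
    """Smallest unit count whose post-downstream output meets the target.

    ``n * per_unit_yield_vg * dsp_recovery >= target_vg`` with n minimal.
    """
    if per_unit_yield_vg <= 0:
        raise ValueError("per_unit_yield_vg must be > 0")
    if not (0 < dsp_recovery <= 1):
        raise ValueError("dsp_recovery must be in (0, 1]")
    if target_vg < 0:
        raise ValueError("target_vg must be >= 0")
    if target_vg == 0:
        return 0
    per_unit_out = per_unit_yield_vg * dsp_recovery
    n = math.ceil(target_vg / per_unit_out)
    # guard against float round-up on exactly-divisible targets
    if n >= 1 and (n - 1) * per_unit_out >= target_vg * (1.0 - 1e-12):
        n -= 1
    return n


def _mscs_needed(platform: PlatformSpec, units: int) -> int:
    if units == 0:
        return 0
    if platform.units_per_msc_session > 0:
        return math.ceil(units / platform.units_per_msc_session)
    return 1  # closed system: one cabinet for sterile prep regardless of count


def _operators_needed(
    platform: PlatformSpec, facility: FacilityConfig, units: int
) -> int:
    if units == 0:
        return 0
    if platform.systems_per_operator_pair > 0:
        return 2 * math.ceil(units / platform.systems_per_operator_pair)
    return facility.operators_per_msc * _mscs_needed(platform, units)


def _incubators_needed(platform: PlatformSpec, units: int) -> int:
    if units == 0 or platform.units_per_incubator == 0:
        return 0
    return math.ceil(units / platform.units_per_incubator)


def _area_used(
    platform: PlatformSpec, facility: FacilityConfig, units: int
) -> float:
    return (
        units * platform.footprint_m2
        + _mscs_needed(platform, units) * facility.msc_footprint_m2
        + _incubators_needed(platform, units) * facility.incubator_footprint_m2
        + _operators_needed(platform, facility, units) * facility.operator_space_m2
    )


def _infeasibility(
    platform: PlatformSpec, facility: FacilityConfig, units: int
) -> str | None:
    """Name the first violated constraint for a production of ``units``."""
    if _mscs_needed(platform, units) > facility.max_mscs:
        return "msc_capacity"
    if _area_used(platform, facility, units) > facility.area_m2 + 1e-9:
        return "facility_area"
    return None


def max_units_per_production(
    platform: PlatformSpec, facility: FacilityConfig, cap: int | None = None
) -> int:
    """Largest feasible production size (0 if even one unit does not fit).

    Feasibility is monotone in the unit count (every resource requirement is
    non-decreasing), so a downward scan from any upper bound is exact.
    """
    if cap is None:
        # area gives a hard upper bound even with zero equipment footprint
        if platform.footprint_m2 > 0:
            cap = int(facility.area_m2 / platform.footprint_m2) + 1
        else:
            cap = 10_000
        if platform.units_per_msc_session > 0:
            cap = min(cap, platform.units_per_msc_session * facility.max_mscs)
    for n in range(cap, 0, -1):
        if _infeasibility(platform, facility, n) is None:
            return n
    return 0


def plan_batches(
    units: int,
    platform: PlatformSpec,
    process: ProcessDefinition,
    facility: FacilityConfig,
    target_vg: float = 0.0,
) -> BatchPlan:
    """Split ``units`` into sequential productions (greedy largest-first).

    Each production takes the maximum unit count that simultaneously
    satisfies the facility area budget (equipment + MSC + incubator
    footprints + reserved operator space), the MSC cap and the staffing rule.
    Productions run back-to-back, so calendar days multiply.
    """
    if units < 0:
        raise ValueError("units must be >= 0")
    if units == 0:
        return BatchPlan(
            platform=platform.name,
            target_vg=target_vg,
            units_required=0,
            productions=(),
            total_days=0,
            operators_assigned=0,
            mscs_used=0,
            incubators_used=0,
            area_used_m2=0.0,
        )

    duration = process.batch_duration_days
    cap = max_units_per_production(platform, facility)
    if cap == 0:
        binding = _infeasibility(platform, facility, 1) or "facility_area"
        raise CapacityError(
            f"facility cannot host one {platform.name} unit "
            f"(binding constraint: {binding})",
            binding,
        )

    productions: list[Production] = []
    remaining = units
    idx = 0
    while remaining > 0:
        take = min(remaining, cap)
        productions.append(Production(index=idx, units=take, days=duration))
        remaining -= take
        idx += 1

    peak_units = max(p.units for p in productions)
    return BatchPlan(
        platform=platform.name,
        target_vg=target_vg,
        units_required=units,
        productions=tuple(productions),
        total_days=duration * len(productions),
        operators_assigned=_operators_needed(platform, facility, peak_units),
        mscs_used=_mscs_needed(platform, peak_units),
        incubators_used=_incubators_needed(platform, peak_units),
        area_used_m2=_area_used(platform, facility, peak_units),
    )


def cost_of_batch(
    plan: BatchPlan,
    process: ProcessDefinition,
    catalog: CostCatalog,
    facility: FacilityConfig,
) -> CoGReport:
    """Price a batch plan from the schedule and catalog.

    materials: per-unit items scale with the total unit count, per-batch
    items are incurred once per production; labor bills step duration x
    operators x rate per production; facility bills calendar days; QC pools
    samples batch-wide and pays whole plates. A zero-unit plan still pays its
    per-batch material and open-step terms once (batch-level setup exists
    even before any vessel is committed).
    """
    n_prods = max(1, len(plan.productions))
    total_units = plan.units_required

    materials = 0.0
    labor_hours = 0.0
    qc_samples = 0
    open_steps = 0

    for step in process.steps:
        for mat in step.materials:
            try:
                unit_cost = catalog.items[mat.item].unit_cost
            except KeyError:
                raise ScenarioError(
                    f"material id {mat.item!r} not in catalog "
                    f"(step {step.name!r})"
                ) from None
            if mat.basis == "per_unit":
                materials += mat.quantity * unit_cost * total_units
            else:
                materials += mat.quantity * unit_cost * n_prods
        labor_hours += step.duration_hours * step.operators * len(plan.productions)
        qc_samples += step.qc_samples * n_prods
        open_steps += step.open_manipulations_per_batch * n_prods

    for prod in plan.productions:
        for step in process.steps:
            open_steps += step.open_manipulations_per_unit * prod.units
    if not plan.productions:
        # zero-unit batch: per-batch open terms only (counted once above)
        pass

    labor = labor_hours * facility.operator_cost_per_hour
    facility_cost = plan.total_days * facility.facility_cost_per_day
    qc_plates = math.ceil(qc_samples / catalog.qc_samples_per_plate)
    qc_cost = qc_plates * catalog.qc_cost_per_plate
    total = materials + labor + facility_cost + qc_cost

    return CoGReport(
        plan=plan,
        materials_cost=materials,
        labor_cost=labor,
        facility_cost=facility_cost,
        qc_cost=qc_cost,
        total_cost=total,
        open_steps=open_steps,
        production_days=plan.total_days,
        operator_hours=labor_hours,
    )


def doses_from_batch(
    total_vg: float, dsp_recovery: float, dose_vg: float
) -> int:
    """Whole doses obtainable from a crude batch after downstream losses."""
    if dose_vg <= 0:
        raise ValueError("dose_vg must be > 0")
    if total_vg < 0 or not (0 < dsp_recovery <= 1):
        raise ValueError("total_vg >= 0 and dsp_recovery in (0, 1] required")
    return math.floor(total_vg * dsp_recovery / dose_vg)


def run_target(
    scenario: Scenario,
    platform_name: str,
    target_vg: float,
    dsp_recovery: float = 0.30,
) -> CoGReport:
    """Size, pack and price one platform for one target output."""
    platform = scenario.platform(platform_name)
    process = scenario.process_for(platform_name)
    units = required_units(target_vg, platform.yield_vg_per_unit, dsp_recovery)
    plan = plan_batches(
        units, platform, process, scenario.facility, target_vg=target_vg
    )
    return cost_of_batch(plan, process, scenario.catalog, scenario.facility)


@dataclass
class ComparisonTable:
    """Per-platform cost reports and fold changes across an output sweep."""

    reference: str
    sweep: tuple[float, ...]
    reports: dict[tuple[str, float], CoGReport] = field(default_factory=dict)

    def fold_change(self, platform: str, target_vg: float, metric: str) -> float:
        ref = getattr(self.reports[(self.reference, target_vg)], metric)
        val = getattr(self.reports[(platform, target_vg)], metric)
        return val / ref if ref else float("nan")

    def platforms(self) -> list[str]:
        return sorted({p for (p, _) in self.reports})

    def to_frame(self) -> pd.DataFrame:
        """Wide table: one row per sweep point, platform x metric folds."""
        rows = []
        for target in self.sweep:
            row: dict[str, float] = {"target_vg": target}
            for plat in self.platforms():
                for metric in METRICS:
                    row[f"{plat}_{metric}_fold"] = self.fold_change(
                        plat, target, metric
                    )
            rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6g")


def compare(
    scenario: Scenario,
    reference: str,
    sweep: Sequence[float],
    dsp_recovery: float = 0.30,
    platforms: Iterable[str] | None = None,
) -> ComparisonTable:
    """Run the full pipeline per platform per sweep point; fold vs reference.

    Capacity errors are re-raised annotated with the platform and target.
    """
    if not sweep:
        raise ValueError("sweep must be non-empty")
    if any(t <= 0 for t in sweep):
        raise ValueError("sweep targets must be positive")
    names = list(platforms) if platforms else [p.name for p in scenario.platforms]
    if reference not in names:
        raise ValueError(f"reference platform {reference!r} not in scenario")

    table = ComparisonTable(reference=reference, sweep=tuple(sweep))
    for target in sweep:
        for name in names:
            try:
                table.reports[(name, target)] = run_target(
                    scenario, name, target, dsp_recovery
                )
            except CapacityError as err:
                raise CapacityError(
                    f"{name} @ {target:g} vg: {err}", err.binding_constraint
                ) from err
    return table
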