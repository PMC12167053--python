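"""Seeded generators for every input the pipeline consumes.

Provides the shipped three-platform reference scenario (process schedules,
facility rules and a FIXTURE cost catalog), synthetic lysis-DoE datasets
with a known truth surface, and synthetic perfusion growth runs. Every
generator is a pure function of its arguments and seed.

The catalog prices are invented round numbers in currency-free "cost units"
— the study publishes no prices — and are labelled FIXTURE in the emitted
file so cost magnitudes are never mistaken for published data. Structural
and operational assumptions (yields, facility area, staffing, MSC rules)
follow the published model assumptions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import constants as k
from .doe import CCDDesign, FactorDef, ccd_face_centered, model_matrix
from .growth import MetaboliteSeries, logistic_curve, simulate_metabolites
from .platforms import (
    CatalogItem,
    CostCatalog,
    FacilityConfig,
    MaterialUse,
    PlatformSpec,
    ProcessDefinition,
    ProcessStep,
    Scenario,
    serialize_scenario,
)

__all__ = [
    "GeneratorConfig",
    "gen_reference_scenario",
    "write_reference_scenario",
    "default_lysis_factors",
    "default_lysis_truth",
    "DoEDataset",
    "gen_doe_dataset",
    "GrowthRun",
    "gen_growth_run",
    "default_perfusion_schedule",
]


class GeneratorConfig(BaseModel):
    """Knobs for the stochastic generators (CLI-facing)."""

    model_config = ConfigDict(extra="forbid")

    seed: int
    archetype: Literal["quantum-like", "flask-like"] = "quantum-like"
    noise_sd: float = Field(default=0.0, ge=0)
    plateau_cells: float = Field(default=k.GROWTH_PLATEAU_CELLS, gt=0)
    growth_rate: float = Field(default=1.2, gt=0)
    seed_cells: float = Field(default=4.0e7, gt=0)
    days: int = Field(default=8, ge=2)


# ---------------------------------------------------------------------------
# reference scenario
# ---------------------------------------------------------------------------

def _fixture_catalog() -> CostCatalog:
    items = {
        "quantum_kit": (300.0, "set"),
        "fibronectin_5mg": (30.0, "vial"),
        "cryovial": (16.0, "vial"),
        "media_expansion_L": (6.0, "L"),
        "media_production_L": (7.0, "L"),
        "plasmid_mg": (160.0, "mg"),
        "peipro_mL": (8.0, "mL"),
        "triton_mL": (0.4, "mL"),
        "benzonase_kU": (12.0, "kU"),
        "tryple_L": (18.0, "L"),
        "bag_set": (24.0, "set"),
        "cs10_flask": (50.0, "flask"),
        "hs36_flask": (180.0, "flask"),
    }
    return CostCatalog(
        items={
            name: CatalogItem(unit_cost=cost, unit=unit)
            for name, (cost, unit) in items.items()
        },
        qc_cost_per_plate=2000.0,
        qc_samples_per_plate=96,
    )


def _quantum_process() -> ProcessDefinition:
    m = MaterialUse
    steps = [
        ProcessStep(
            name="coat, condition and seed", day=0, duration_hours=4,
            operators=2, msc_sessions=1, open_manipulations_per_unit=2,
            qc_samples=1,
            materials=[
                m(item="quantum_kit", quantity=1),
                m(item="fibronectin_5mg", quantity=1),
                m(item="cryovial", quantity=1),
                m(item="media_expansion_L", quantity=4),
            ],
        ),
        ProcessStep(
            name="attachment check and feed", day=1, duration_hours=1,
            operators=2,
            materials=[m(item="media_expansion_L", quantity=6)],
        ),
        ProcessStep(
            name="expansion feed", day=2, duration_hours=1, operators=2,
            qc_samples=1,
            materials=[m(item="media_expansion_L", quantity=8)],
        ),
        ProcessStep(
            name="expansion feed", day=3, duration_hours=1, operators=2,
            materials=[m(item="media_expansion_L", quantity=10)],
        ),
        ProcessStep(
            name="triple transfection", day=4, duration_hours=3, operators=2,
            msc_sessions=1, open_manipulations_per_unit=1, qc_samples=1,
            materials=[
                m(item="plasmid_mg", quantity=2.6),
                m(item="peipro_mL", quantity=5.2),
                m(item="media_production_L", quantity=6),
            ],
        ),
        ProcessStep(
            name="production feed", day=5, duration_hours=1, operators=2,
            materials=[m(item="media_production_L", quantity=8)],
        ),
        ProcessStep(
            name="production feed", day=6, duration_hours=1, operators=2,
            materials=[m(item="media_production_L", quantity=10)],
        ),
        ProcessStep(
            name="harvest and in situ lysis", day=7, duration_hours=4,
            operators=2, msc_sessions=1, open_manipulations_per_unit=2,
            open_manipulations_per_batch=2, qc_samples=3,
            materials=[
                m(item="triton_mL", quantity=20),
                m(item="benzonase_kU", quantity=0.67),
                m(item="tryple_L", quantity=0.5),
                m(item="bag_set", quantity=1),
            ],
        ),
    ]
    return ProcessDefinition(platform="Quantum", steps=steps)


def _flask_process(
    platform: str,
    flask_item: str,
    fill_L: float,
    plasmid_mg: float,
    pei_mL: float,
    triton_mL: float,
    benzonase_kU: float,
    tryple_L: float,
) -> ProcessDefinition:
    m = MaterialUse

    def per_batch(item: str, qty: float) -> MaterialUse:
        return m(item=item, quantity=qty, basis="per_batch")

    steps = [
        ProcessStep(
            name="thaw and seed expansion train", day=0, duration_hours=4,
            operators=2, msc_sessions=1, open_manipulations_per_batch=4,
            qc_samples=1,
            materials=[
                per_batch("cryovial", 1),
                per_batch("media_expansion_L", 2),
            ],
        ),
        ProcessStep(
            name="passage expansion train", day=2, duration_hours=4,
            operators=3, msc_sessions=1, open_manipulations_per_batch=6,
            materials=[
                per_batch("media_expansion_L", 4),
                per_batch("tryple_L", 0.1),
            ],
        ),
        ProcessStep(
            name="passage expansion train", day=4, duration_hours=4,
            operators=3, msc_sessions=1, open_manipulations_per_batch=8,
            materials=[
                per_batch("media_expansion_L", 8),
                per_batch("tryple_L", 0.2),
            ],
        ),
        ProcessStep(
            name="seed stacks", day=6, duration_hours=6, operators=6,
            msc_sessions=3, open_manipulations_per_unit=4, qc_samples=1,
            materials=[
                m(item=flask_item, quantity=1),
                m(item="media_expansion_L", quantity=fill_L),
                m(item="tryple_L", quantity=0.1),
            ],
        ),
        ProcessStep(
            name="media exchange", day=7, duration_hours=6, operators=6,
            msc_sessions=3, open_manipulations_per_unit=2,
            materials=[m(item="media_expansion_L", quantity=fill_L)],
        ),
        ProcessStep(
            name="culture check", day=8, duration_hours=2, operators=2,
            qc_samples=1,
        ),
        ProcessStep(
            name="media exchange", day=9, duration_hours=6, operators=6,
            msc_sessions=3, open_manipulations_per_unit=2,
            materials=[m(item="media_expansion_L", quantity=fill_L)],
        ),
        ProcessStep(
            name="triple transfection", day=10, duration_hours=6, operators=6,
            msc_sessions=3, open_manipulations_per_unit=3, qc_samples=1,
            materials=[
                m(item="plasmid_mg", quantity=plasmid_mg),
                m(item="peipro_mL", quantity=pei_mL),
                m(item="media_production_L", quantity=fill_L),
            ],
        ),
        ProcessStep(
            name="post-transfection media change", day=11, duration_hours=6,
            operators=6, msc_sessions=3, open_manipulations_per_unit=2,
            materials=[m(item="media_production_L", quantity=fill_L)],
        ),
        ProcessStep(
            name="harvest and lysis", day=13, duration_hours=8, operators=6,
            msc_sessions=3, open_manipulations_per_unit=4, qc_samples=3,
            materials=[
                m(item="tryple_L", quantity=tryple_L),
                m(item="triton_mL", quantity=triton_mL),
                m(item="benzonase_kU", quantity=benzonase_kU),
                m(item="bag_set", quantity=1),
            ],
        ),
    ]
    return ProcessDefinition(platform=platform, steps=steps)


def gen_reference_scenario() -> Scenario:
    """The shipped three-platform comparison scenario (deterministic).

    Yields, facility area, operator space, MSC and incubator rules follow
    the published model assumptions; catalog prices and step-level material
    quantities are FIXTURE values.
    """
    platforms = [
        PlatformSpec(
            name="Quantum",
            surface_area_cm2=k.QUANTUM_SURFACE_AREA_CM2,
            working_volume_mL=k.QUANTUM_HARVEST_VOLUME_ML,
            yield_vg_per_unit=k.QUANTUM_YIELD_VG_PER_UNIT,
            yield_vp_per_unit=k.QUANTUM_YIELD_VP_PER_UNIT,
            footprint_m2=0.6,  # 6.0 m^2 of bench for 10 systems
            units_per_msc_session=0,  # closed system: one MSC for prep
            units_per_incubator=0,  # self-contained
            systems_per_operator_pair=k.QUANTUM_SYSTEMS_PER_OPERATOR_PAIR,
            is_closed=True,
        ),
        PlatformSpec(
            name="HYPERStack36",
            surface_area_cm2=k.HYPERSTACK36_SURFACE_AREA_CM2,
            working_volume_mL=5600.0,
            yield_vg_per_unit=k.HYPERSTACK36_YIELD_VG_PER_UNIT,
            footprint_m2=0.3,
            units_per_msc_session=k.FLASK_UNITS_PER_MSC,
            units_per_incubator=1,  # one unit per 168 L incubator
            systems_per_operator_pair=0,
            is_closed=False,
        ),
        PlatformSpec(
            name="CS10",
            surface_area_cm2=k.CS10_SURFACE_AREA_CM2,
            working_volume_mL=2000.0,
            yield_vg_per_unit=k.CS10_YIELD_VG_PER_UNIT,
            footprint_m2=0.2,
            units_per_msc_session=k.FLASK_UNITS_PER_MSC,
            units_per_incubator=1,
            systems_per_operator_pair=0,
            is_closed=False,
        ),
    ]
    facility = FacilityConfig(
        area_m2=k.FACILITY_AREA_M2,
        operator_space_m2=k.OPERATOR_SPACE_M2,
        msc_footprint_m2=2.5,
        incubator_footprint_m2=0.7,
        operator_cost_per_hour=150.0,
        facility_cost_per_day=800.0,
        max_mscs=k.MAX_MSCS,
        operators_per_msc=k.OPERATORS_PER_MSC,
    )
    processes = [
        _quantum_process(),
        _flask_process(
            "HYPERStack36", "hs36_flask", fill_L=5.6, plasmid_mg=2.57,
            pei_mL=5.1, triton_mL=28, benzonase_kU=0.67, tryple_L=0.5,
        ),
        _flask_process(
            "CS10", "cs10_flask", fill_L=2.0, plasmid_mg=0.91,
            pei_mL=1.8, triton_mL=10, benzonase_kU=0.24, tryple_L=0.2,
        ),
    ]
    return Scenario(
        schema_version=1,
        platforms=platforms,
        facility=facility,
        catalog=_fixture_catalog(),
        processes=processes,
    )


_SCENARIO_HEADER = """\
# Three-platform AAV production comparison scenario.
# Platform yields, facility constraints and staffing rules follow the
# published model assumptions. All catalog prices and step-level material
# quantities are FIXTURE values (invented round numbers in currency-free
# cost units) -- NOT published data. Fold-change comparisons are invariant
# to the price scale.
"""


def write_reference_scenario(path: str | Path) -> Path:
    """Emit the reference scenario as YAML (byte-identical across calls)."""
    path = Path(path)
    body = yaml.safe_dump(
        serialize_scenario(gen_reference_scenario()), sort_keys=False
    )
    path.write_text(_SCENARIO_HEADER + body)
    return path


# ---------------------------------------------------------------------------
# DoE datasets
# ---------------------------------------------------------------------------

def default_lysis_factors() -> list[FactorDef]:
    """The three in situ lysis factors with their studied ranges."""
    return [
        FactorDef("contact_time_min", *k.LYSIS_CONTACT_TIME_MIN),
        FactorDef("cell_density_per_mL", *k.LYSIS_CELL_DENSITY_PER_ML),
        FactorDef("triton_pct", *k.LYSIS_TRITON_PCT),
    ]


def default_lysis_truth() -> np.ndarray:
    """Synthetic truth surface (coded units, vg/mL scale).

    Chosen so the surface maximum sits at low detergent (0.2% face) and low
    cell density with a mildly interior contact-time optimum — the
    qualitative geometry reported for the lysis study. Coefficient order:
    intercept, 3 linear, 3 square, 3 interaction terms.
    """
    return np.array(
        [6.0e10, 3.0e9, -1.2e10, -9.0e9,
         -9.0e9, -3.0e9, 1.2e9,
         1.0e9, -5.0e8, 0.0]
    )


@dataclass(frozen=True)
class DoEDataset:
    design: CCDDesign
    responses: np.ndarray
    truth: np.ndarray
    noise_sd: float
    seed: int | None

    def to_frames(self):
        design = self.design.to_frame()
        responses = design[["label"]].copy()
        responses["response"] = self.responses
        return design, responses


def gen_doe_dataset(
    truth: Sequence[float] | None = None,
    factors: Sequence[FactorDef] | None = None,
    n_center: int = 3,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> DoEDataset:
    """CCD design plus responses = truth(design) + Gaussian noise."""
    factors = list(factors) if factors is not None else default_lysis_factors()
    truth_vec = (
        np.asarray(truth, dtype=float)
        if truth is not None
        else default_lysis_truth()
    )
    design = ccd_face_centered(factors, n_center=n_center)
    X = model_matrix(design.coded)
    if truth_vec.shape[0] != X.shape[1]:
        raise ValueError(
            f"truth has {truth_vec.shape[0]} coefficients, "
            f"model needs {X.shape[1]}"
        )
    responses = X @ truth_vec
    if noise_sd > 0:
        if seed is None:
            raise ValueError("a seed is required when noise_sd > 0")
        rng = np.random.default_rng(seed)
        responses = responses + rng.normal(0.0, noise_sd, size=len(responses))
    return DoEDataset(
        design=design,
        responses=responses,
        truth=truth_vec,
        noise_sd=noise_sd,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# growth runs
# ---------------------------------------------------------------------------

def default_perfusion_schedule(times: Sequence[float]) -> np.ndarray:
    """Daily media feed ramp (mL/day), saturating mid-run.

    Emulates operator practice of stepping up perfusion as the culture
    expands, then holding a maximum rate.
    """
    t = np.asarray(times, dtype=float)
    return np.minimum(300.0 + 150.0 * t, 1200.0)


@dataclass(frozen=True)
class GrowthRun:
    times: np.ndarray
    cells: np.ndarray
    series: MetaboliteSeries


def gen_growth_run(
    plateau_cells: float = k.GROWTH_PLATEAU_CELLS,
    days: int = 8,
    seed: int | None = None,
    noise_sd: float = 0.0,
    growth_rate: float = 1.2,
    seed_cells: float = 4.0e7,
    volume_mL: float = k.DEFAULT_SYSTEM_VOLUME_ML,
) -> GrowthRun:
    """Logistic growth to a plateau plus the matching metabolite series.

    Defaults emulate the engineering runs: 4e7 seeded cells growing to a
    ~5e9-cell plateau over 8 days with the inflection near day 4, daily
    sampling, perfusion ramping to a held maximum.
    """
    if plateau_cells <= 0:
        raise ValueError("plateau_cells must be > 0")
    times = np.arange(days + 1, dtype=float)
    cells = logistic_curve(times, plateau_cells, n0=seed_cells, rate=growth_rate)
    series = simulate_metabolites(
        times,
        cells,
        perfusion_rate=default_perfusion_schedule(times),
        volume_mL=volume_mL,
        noise_sd=noise_sd,
        seed=seed,
    )
    return GrowthRun(times=times, cells=cells, series=series)
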