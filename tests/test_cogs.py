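"""Cost engine: unit sizing, batch packing, costing, fold-change comparison."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from aavprocess.cogs import (
    CapacityError,
    compare,
    cost_of_batch,
    doses_from_batch,
    max_units_per_production,
    plan_batches,
    required_units,
    run_target,
)
from aavprocess.platforms import (
    CatalogItem,
    CostCatalog,
    FacilityConfig,
    MaterialUse,
    PlatformSpec,
    ProcessDefinition,
    ProcessStep,
)


def make_platform(**overrides) -> PlatformSpec:
    base = dict(
        name="toy",
        surface_area_cm2=1000.0,
        working_volume_mL=500.0,
        yield_vg_per_unit=1e13,
        footprint_m2=0.5,
        units_per_msc_session=6,
        units_per_incubator=1,
    )
    base.update(overrides)
    return PlatformSpec(**base)


def single_step_process(platform="toy", **step_overrides) -> ProcessDefinition:
    step = dict(name="only", day=0, duration_hours=2.0, operators=1)
    step.update(step_overrides)
    return ProcessDefinition(platform=platform, steps=[ProcessStep(**step)])


class TestRequiredUnits:
    @pytest.mark.parametrize(
        "target,per_unit,recovery,expected",
        [
            (1e14, 2.45e13, 0.30, 14),  # ceil(13.6) flask units for 1e14 vg
            (0.0, 2.45e13, 0.30, 0),
            (6.81e13 * 0.30, 6.81e13, 0.30, 1),  # one unit exactly suffices
            (1e14, 1.26e14, 0.30, 3),
            (1e14, 6.81e13, 0.30, 5),
        ],
    )
    def test_examples(self, target, per_unit, recovery, expected):
        assert required_units(target, per_unit, recovery) == expected

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            required_units(1e14, 0.0, 0.3)
        with pytest.raises(ValueError):
            required_units(1e14, 1e13, 0.0)
        with pytest.raises(ValueError):
            required_units(1e14, 1e13, 1.5)

    @given(
        n=st.integers(min_value=0, max_value=500),
        y=st.floats(min_value=1e10, max_value=1e15),
        r=st.floats(min_value=0.01, max_value=1.0),
    )
    def test_exact_multiples_recover_n(self, n, y, r):
        assert required_units(n * y * r, y, r) == n

    @given(
        t1=st.floats(min_value=0, max_value=1e16),
        t2=st.floats(min_value=0, max_value=1e16),
        y=st.floats(min_value=1e10, max_value=1e15),
        r=st.floats(min_value=0.01, max_value=1.0),
    )
    def test_monotone_in_target(self, t1, t2, y, r):
        lo, hi = sorted((t1, t2))
        assert required_units(lo, y, r) <= required_units(hi, y, r)

    @given(
        t=st.floats(min_value=1e12, max_value=1e16),
        y1=st.floats(min_value=1e10, max_value=1e15),
        y2=st.floats(min_value=1e10, max_value=1e15),
        r=st.floats(min_value=0.01, max_value=1.0),
    )
    def test_non_increasing_in_yield(self, t, y1, y2, r):
        lo, hi = sorted((y1, y2))
        assert required_units(t, hi, r) <= required_units(t, lo, r)


class TestPlanBatches:
    def test_ten_quantum_systems_fit_one_production(self, scenario):
        plat = scenario.platform("Quantum")
        proc = scenario.process_for("Quantum")
        plan = plan_batches(10, plat, proc, scenario.facility)
        assert len(plan.productions) == 1
        assert plan.mscs_used == 1
        assert plan.operators_assigned == 2
        # 10 systems occupy 6.0 m^2 of bench
        assert 10 * plat.footprint_m2 == pytest.approx(6.0)
        assert plan.area_used_m2 <= scenario.facility.area_m2

    def test_zero_units_empty_plan(self, scenario):
        plat = scenario.platform("Quantum")
        proc = scenario.process_for("Quantum")
        plan = plan_batches(0, plat, proc, scenario.facility)
        assert plan.productions == ()
        assert plan.total_days == 0
        assert plan.operators_assigned == 0
        assert plan.area_used_m2 == 0.0

    def test_twelve_units_with_cap_six_gives_two_productions(self):
        plat = make_platform(units_per_msc_session=6, units_per_incubator=0,
                             footprint_m2=0.1)
        fac = FacilityConfig(max_mscs=1)
        proc = single_step_process()
        plan = plan_batches(12, plat, proc, fac)
        assert [p.units for p in plan.productions] == [6, 6]
        assert plan.total_days == 2 * proc.batch_duration_days

    def test_conservation_of_units(self, scenario):
        plat = scenario.platform("CS10")
        proc = scenario.process_for("CS10")
        for units in (0, 1, 17, 18, 19, 55):
            plan = plan_batches(units, plat, proc, scenario.facility)
            assert sum(p.units for p in plan.productions) == units

    def test_capacity_error_names_binding_constraint(self):
        plat = make_platform(footprint_m2=100.0)  # wider than the cleanroom
        fac = FacilityConfig(area_m2=60.0)
        with pytest.raises(CapacityError, match="facility_area"):
            plan_batches(1, plat, single_step_process(), fac)

    def test_greedy_matches_bruteforce_minimum_small_instances(self):
        """Exhaustive packing oracle on small capacity-bound scenarios."""
        facilities = [
            FacilityConfig(area_m2=20.0, max_mscs=1),
            FacilityConfig(area_m2=30.0, max_mscs=2),
            FacilityConfig(area_m2=60.0, max_mscs=3),
        ]
        platforms = [
            make_platform(units_per_msc_session=3, footprint_m2=0.4),
            make_platform(units_per_msc_session=6, footprint_m2=1.5),
            make_platform(units_per_msc_session=0, footprint_m2=2.0,
                          units_per_incubator=0,
                          systems_per_operator_pair=4),
        ]
        proc = single_step_process()
        for fac in facilities:
            for plat in platforms:
                cap = max_units_per_production(plat, fac)
                for units in range(0, 31):
                    # brute force: DP over unit counts, any feasible split
                    INF = 10**9
                    best = [0] + [INF] * units
                    for u in range(1, units + 1):
                        for take in range(1, min(u, cap) + 1):
                            best[u] = min(best[u], 1 + best[u - take])
                    if cap == 0 and units > 0:
                        with pytest.raises(CapacityError):
                            plan_batches(units, plat, proc, fac)
                        continue
                    plan = plan_batches(units, plat, proc, fac)
                    assert len(plan.productions) == best[units]


class TestCostOfBatch:
    @pytest.fixture()
    def toy_setup(self):
        plat = make_platform(units_per_msc_session=6, footprint_m2=0.1)
        proc = ProcessDefinition(
            platform="toy",
            steps=[
                ProcessStep(
                    name="only", day=0, duration_hours=2.0, operators=1,
                    materials=[MaterialUse(item="reagent", quantity=2)],
                )
            ],
        )
        catalog = CostCatalog(
            items={"reagent": CatalogItem(unit_cost=5.0)},
            qc_cost_per_plate=960.0,
            qc_samples_per_plate=96,
        )
        fac = FacilityConfig(
            operator_cost_per_hour=10.0, facility_cost_per_day=100.0
        )
        return plat, proc, catalog, fac

    def test_hand_arithmetic_single_step(self, toy_setup):
        plat, proc, catalog, fac = toy_setup
        plan = plan_batches(1, plat, proc, fac)
        report = cost_of_batch(plan, proc, catalog, fac)
        assert report.materials_cost == 10.0  # 2 x 5
        assert report.labor_cost == 20.0  # 2 h x 1 op x 10
        assert report.facility_cost == 100.0  # 1 day x 100
        assert report.qc_cost == 0.0
        assert report.total_cost == 130.0

    def test_total_is_sum_of_components(self, scenario):
        report = run_target(scenario, "HYPERStack36", 3e14)
        assert report.total_cost == pytest.approx(
            report.materials_cost + report.labor_cost
            + report.facility_cost + report.qc_cost
        )

    def test_qc_plate_sharing_partial_plate_costs_one_plate(self, toy_setup):
        plat, _, catalog, fac = toy_setup
        proc = ProcessDefinition(
            platform="toy",
            steps=[ProcessStep(name="qc", day=0, qc_samples=7)],
        )
        plan = plan_batches(1, plat, proc, fac)
        report = cost_of_batch(plan, proc, catalog, fac)
        assert report.qc_cost == 960.0  # 7 samples still pay one full plate

    def test_zero_unit_plan_charges_per_batch_terms_only(self, toy_setup):
        plat, _, catalog, fac = toy_setup
        proc = ProcessDefinition(
            platform="toy",
            steps=[
                ProcessStep(
                    name="setup", day=0,
                    open_manipulations_per_unit=5,
                    open_manipulations_per_batch=2,
                    materials=[
                        MaterialUse(item="reagent", quantity=3,
                                    basis="per_batch"),
                        MaterialUse(item="reagent", quantity=7,
                                    basis="per_unit"),
                    ],
                )
            ],
        )
        plan = plan_batches(0, plat, proc, fac)
        report = cost_of_batch(plan, proc, catalog, fac)
        assert report.materials_cost == 15.0  # per-batch 3 x 5 only
        assert report.open_steps == 2  # per-batch opens only

    def test_open_steps_affine_in_units_within_one_production(self, scenario):
        plat = scenario.platform("Quantum")
        proc = scenario.process_for("Quantum")
        per_unit_slope = sum(s.open_manipulations_per_unit for s in proc.steps)
        opens = []
        for units in (1, 2, 3, 4):
            plan = plan_batches(units, plat, proc, scenario.facility)
            opens.append(
                cost_of_batch(plan, proc, scenario.catalog,
                              scenario.facility).open_steps
            )
        diffs = np.diff(opens)
        assert np.all(diffs == per_unit_slope)


class TestDoses:
    @pytest.mark.parametrize(
        "total,recovery,dose,expected",
        [
            (6.81e13, 0.30, 1.5e11, 136),  # one Quantum batch, retinal dosing
            (1.0e11, 0.5, 1.5e11, 0),
            (1.5e11, 1.0, 1.5e11, 1),
        ],
    )
    def test_examples(self, total, recovery, dose, expected):
        assert doses_from_batch(total, recovery, dose) == expected

    def test_non_positive_dose_rejected(self):
        with pytest.raises(ValueError):
            doses_from_batch(1e13, 0.3, 0.0)


class TestCompare:
    def test_reference_fold_changes_are_exactly_one(self, scenario):
        table = compare(scenario, "Quantum", [1e14, 5e14, 1e15])
        for t in table.sweep:
            for metric in ("total_cost", "open_steps", "production_days"):
                assert table.fold_change("Quantum", t, metric) == 1.0

    def test_fold_changes_invariant_under_price_rescaling(self, scenario):
        table = compare(scenario, "Quantum", [2e14])
        scaled = scenario.model_copy(deep=True)
        for item in scaled.catalog.items.values():
            item.unit_cost *= 2.0
        scaled.facility.operator_cost_per_hour *= 2.0
        scaled.facility.facility_cost_per_day *= 2.0
        scaled.catalog.qc_cost_per_plate *= 2.0
        table2 = compare(scaled, "Quantum", [2e14])
        for plat in ("CS10", "HYPERStack36"):
            assert table2.fold_change(plat, 2e14, "total_cost") == pytest.approx(
                table.fold_change(plat, 2e14, "total_cost")
            )

    def test_flask_platforms_cost_more_than_quantum_across_sweep(self, scenario):
        sweep = list(np.linspace(1e14, 1e15, 5))
        table = compare(scenario, "Quantum", sweep)
        for t in sweep:
            cs10 = table.fold_change("CS10", t, "total_cost")
            hs36 = table.fold_change("HYPERStack36", t, "total_cost")
            assert cs10 >= hs36 > 1.0

    def test_cost_and_days_monotone_in_target(self, scenario):
        sweep = list(np.linspace(1e14, 1e15, 7))
        for name in ("Quantum", "HYPERStack36", "CS10"):
            reports = [run_target(scenario, name, t) for t in sweep]
            costs = [r.total_cost for r in reports]
            days = [r.production_days for r in reports]
            assert all(a <= b for a, b in zip(costs, costs[1:]))
            assert all(a <= b for a, b in zip(days, days[1:]))

    def test_empty_sweep_rejected(self, scenario):
        with pytest.raises(ValueError):
            compare(scenario, "Quantum", [])
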