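"""Surrogate growth model and the management rule engine."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from catchex import (
    ClimateParams,
    ConfigurationError,
    GrowthParams,
    ManagementRules,
    UsageError,
    apply_thinning,
    check_ccf_harvest,
    check_dnm,
    check_fertilization,
    check_final_felling,
    grow_stand,
    step_period,
)
from catchex.dynamics import apply_ccf_plan
from catchex.types import EventType, Fertility, LandClass, Management, Origin, Species


def _quiet_growth(**kw):
    """Growth params without ingrowth/mortality for controlled experiments."""
    defaults = dict(mortality_per_yr=0.0, ingrowth_stems_yr=0.0)
    defaults.update(kw)
    return GrowthParams(**defaults)


class TestGrowth:
    def test_planted_and_seeded_increment_multipliers(self, make_compartment, climate):
        params = _quiet_growth()
        base = {}
        for origin in Origin:
            comp = make_compartment(diam=(15.0,), stems=(800.0,), origin=origin)
            grown = grow_stand(comp, 1, climate, params)
            base[origin] = grown.diam_cm[0] - 15.0
        assert base[Origin.PLANTED] / base[Origin.NATURAL] == pytest.approx(1.10)
        assert base[Origin.SEEDED] / base[Origin.NATURAL] == pytest.approx(1.05)

    def test_zero_increment_leaves_structure_unchanged(self, make_compartment, climate):
        params = _quiet_growth(
            base_increment_cm_yr={f: 0.0 for f in Fertility}
        )
        comp = make_compartment()
        grown = grow_stand(comp, 10, climate, params)
        np.testing.assert_array_equal(grown.diam_cm, comp.diam_cm)
        np.testing.assert_array_equal(grown.stems_ha, comp.stems_ha)
        assert grown.age_years == comp.age_years + 10

    def test_class_table_agrees_with_ode_integration(self, make_compartment, climate):
        """Single-cohort growth vs. direct numerical integration of the rate law."""
        params = _quiet_growth()
        n = 600.0
        comp = make_compartment(
            diam=(18.0,), stems=(n,), fertility=Fertility.MESIC, species=Species.SPRUCE
        )
        grown = grow_stand(comp, 10, climate, params)

        def rate(_t, d):
            ba = n * math.pi * (d[0] / 200.0) ** 2
            return [0.40 * d[0] / (d[0] + 5.0) * math.exp(-0.03 * ba)]

        sol = solve_ivp(rate, (0, 10), [18.0], rtol=1e-10, atol=1e-12)
        v_oracle = n * params.volume_fn(sol.y[0, -1])
        assert grown.volume_m3_ha == pytest.approx(float(v_oracle), rel=0.01)

    def test_growth_declines_with_stand_density(self, make_compartment, climate):
        params = _quiet_growth()
        sparse = make_compartment(diam=(15.0,), stems=(300.0,))
        dense = make_compartment(diam=(15.0,), stems=(2000.0,))
        inc_sparse = grow_stand(sparse, 1, climate, params).diam_cm[0] - 15
        inc_dense = grow_stand(dense, 1, climate, params).diam_cm[0] - 15
        assert inc_sparse > inc_dense

    def test_invalid_usage(self, make_compartment, climate):
        with pytest.raises(ConfigurationError):
            grow_stand(make_compartment(), 0, climate)
        nf = make_compartment(diam=(), stems=(), land_class=LandClass.NONFOREST)
        with pytest.raises(UsageError):
            grow_stand(nf, 5, climate)


class TestFinalFelling:
    def _stand(self, make_compartment, d):
        return make_compartment(
            diam=(d,), stems=(500.0,), fertility=Fertility.XERIC, species=Species.PINE
        )

    def test_threshold_comparisons(self, make_compartment, rules):
        # xeric default threshold 24 cm; ERP threshold 24 * 1.10 = 26.4 cm
        stand = self._stand(make_compartment, 25.0)
        assert check_final_felling(stand, rules, Management.RF)
        assert not check_final_felling(stand, rules, Management.ERP)
        assert check_final_felling(self._stand(make_compartment, 26.5), rules, Management.ERP)

    def test_strictly_exceeded_at_boundary(self, make_compartment, rules):
        assert not check_final_felling(self._stand(make_compartment, 24.0), rules, Management.RF)

    def test_undefined_for_ccf(self, make_compartment, rules):
        with pytest.raises(UsageError):
            check_final_felling(self._stand(make_compartment, 30.0), rules, Management.CCF)


class TestThinning:
    @pytest.fixture
    def two_cohort_stand(self, make_compartment):
        return make_compartment(
            diam=(10.0, 30.0), stems=(1000.0, 300.0), fertility=Fertility.MESIC
        )

    def test_below_removal_plan_hand_computed(self, two_cohort_stand, rules):
        # independent arithmetic for the removal plan
        ba10, ba30 = 1000 * math.pi * 0.05**2, 300 * math.pi * 0.15**2
        ba = ba10 + ba30
        target = rules.post_thinning_m2_ha[Fertility.MESIC]  # 16
        removal = ba - target
        frac_u = removal / 2 / ba
        # uniform half
        s10 = 1000 * (1 - frac_u)
        s30 = 300 * (1 - frac_u)
        # remainder from the smallest class, spilling into the next
        need = removal / 2
        take10 = min(s10 * math.pi * 0.05**2, need)
        s10 -= take10 / (math.pi * 0.05**2)
        need -= take10
        s30 -= need / (math.pi * 0.15**2)

        thinned, removed_vol = apply_thinning(two_cohort_stand, "below", rules)
        assert thinned.basal_area_m2_ha == pytest.approx(target, abs=1e-9)
        got = {round(d): n for d, n in zip(thinned.diam_cm, thinned.stems_ha)}
        assert got.get(10, 0.0) == pytest.approx(s10, abs=1e-9)
        assert got[30] == pytest.approx(s30, abs=1e-9)
        assert removed_vol > 0

    def test_above_removal_takes_largest(self, two_cohort_stand, rules):
        ba10, ba30 = 1000 * math.pi * 0.05**2, 300 * math.pi * 0.15**2
        ba = ba10 + ba30
        removal = ba - 16.0
        frac_u = removal / 2 / ba
        s10 = 1000 * (1 - frac_u)
        s30 = 300 * (1 - frac_u) - (removal / 2) / (math.pi * 0.15**2)
        thinned, _ = apply_thinning(two_cohort_stand, "above", rules)
        got = {round(d): n for d, n in zip(thinned.diam_cm, thinned.stems_ha)}
        assert got[10] == pytest.approx(s10, abs=1e-9)
        assert got[30] == pytest.approx(s30, abs=1e-9)

    def test_no_op_below_thinning_limit(self, make_compartment, rules):
        light = make_compartment(diam=(15.0,), stems=(500.0,))  # BA ~8.8
        thinned, removed = apply_thinning(light, "below", rules)
        assert removed == 0.0
        np.testing.assert_array_equal(thinned.stems_ha, light.stems_ha)

    def test_invalid_mode(self, two_cohort_stand, rules):
        with pytest.raises(UsageError):
            apply_thinning(two_cohort_stand, "sideways", rules)

    def test_stems_stay_nonnegative(self, two_cohort_stand, rules):
        thinned, _ = apply_thinning(two_cohort_stand, "below", rules)
        assert (thinned.stems_ha >= 0).all()


class TestCcfHarvest:
    @pytest.fixture
    def layered_stand(self, make_compartment):
        # BA ~26 m2/ha spread over five cohorts, mean d ~20 cm
        return make_compartment(
            diam=(10.0, 15.0, 20.0, 25.0, 30.0),
            stems=(400.0, 300.0, 250.0, 150.0, 80.0),
            fertility=Fertility.MESIC,
        )

    def test_no_cut_below_threshold(self, make_compartment, rules, climate):
        light = make_compartment(diam=(15.0,), stems=(400.0,))  # BA ~7
        cut, plan = check_ccf_harvest(light, rules, climate)
        assert not cut and plan is None

    def test_intensity_monotone_in_diameter(self, layered_stand, rules, climate):
        cut, plan = check_ccf_harvest(layered_stand, rules, climate)
        assert cut
        assert np.all(np.diff(plan.remove_fraction) >= 0)

    def test_removal_reaches_post_cut_target(self, layered_stand, rules, climate):
        ba0 = layered_stand.basal_area_m2_ha
        cut, plan = check_ccf_harvest(layered_stand, rules, climate)
        thr = rules.ccf.threshold_basal_area(
            layered_stand.mean_diameter_cm,
            layered_stand.fertility,
            climate.temperature_sum_dd,
        )
        assert plan.removed_basal_area == pytest.approx(
            ba0 - rules.ccf.post_cut_fraction * thr, rel=1e-9
        )
        after = apply_ccf_plan(layered_stand, plan)
        assert ba0 - after.basal_area_m2_ha == pytest.approx(plan.removed_basal_area, abs=1e-6)


class TestFertilizationWindows:
    def test_peat_interval_strictly_more_than_50(self, make_compartment, rules):
        base = dict(
            diam=(15.0,), stems=(1000.0,), land_class=LandClass.DRAINED_PEAT
        )
        eligible = make_compartment(**base, years_since_fertilization=51.0)
        assert check_fertilization(eligible, rules, Management.RF)
        assert check_fertilization(eligible, rules, Management.CCF)
        boundary = make_compartment(**base, years_since_fertilization=50.0)
        assert not check_fertilization(boundary, rules, Management.RF)

    def test_mineral_only_in_even_aged_systems(self, make_compartment, rules):
        comp = make_compartment(
            diam=(28.0,),
            stems=(320.0,),  # BA ~19.7
            fertility=Fertility.XERIC,
            species=Species.PINE,
            years_since_fertilization=11.0,
        )
        assert check_fertilization(comp, rules, Management.RF)
        assert check_fertilization(comp, rules, Management.ERP)
        assert not check_fertilization(comp, rules, Management.CCF)

    def test_mineral_diameter_window_lower_bound(self, make_compartment, rules):
        comp = make_compartment(
            diam=(20.0,),
            stems=(640.0,),
            fertility=Fertility.MESIC,
            species=Species.SPRUCE,
            years_since_fertilization=30.0,
        )
        assert not check_fertilization(comp, rules, Management.RF)

    def test_mineral_site_species_restriction(self, make_compartment, rules):
        comp = make_compartment(
            diam=(28.0,),
            stems=(320.0,),
            fertility=Fertility.MESIC,
            species=Species.PINE,  # mesic pine is not an eligible pair
            years_since_fertilization=20.0,
        )
        assert not check_fertilization(comp, rules, Management.RF)


class TestDnm:
    def _peat(self, make_compartment, **kw):
        defaults = dict(
            diam=(15.0,), stems=(900.0,), land_class=LandClass.DRAINED_PEAT,
            years_since_dnm=40.0,
        )
        defaults.update(kw)
        return make_compartment(**defaults)

    def test_blocked_by_large_growing_stock(self, make_compartment, rules):
        # ~160 m3/ha: evapotranspiration keeps the water table down already
        dense = self._peat(make_compartment, diam=(20.0,), stems=(1250.0,))
        assert dense.volume_m3_ha > 150
        assert not check_dnm(dense, rules)

    def test_blocked_before_30_years_elapsed(self, make_compartment, rules):
        recent = self._peat(make_compartment, years_since_dnm=29.0)
        assert not check_dnm(recent, rules)

    def test_allowed_right_after_final_felling(self, make_compartment, rules):
        felled = self._peat(
            make_compartment, diam=(0.5,), stems=(2000.0,), years_since_dnm=35.0
        )
        assert felled.volume_m3_ha < 20
        assert check_dnm(felled, rules, after_final_felling=True)
        # the same young stand is outside the window without the felling trigger
        assert not check_dnm(felled, rules, after_final_felling=False)

    def test_usage_error_on_mineral(self, make_compartment, rules):
        with pytest.raises(UsageError):
            check_dnm(make_compartment(), rules)


class TestStepPeriod:
    def test_no_management_emits_no_events(self, make_compartment, rules, climate):
        rng = np.random.default_rng(0)
        comp = make_compartment()
        for p in range(5):
            comp, events, vols = step_period(comp, Management.NONE, rules, climate, p, rng)
            assert events == []
            assert len(vols) == 10

    def test_peat_fertilized_at_most_once_in_50_years(self, make_compartment, rules, climate):
        rng = np.random.default_rng(0)
        comp = make_compartment(
            diam=(12.0,), stems=(1200.0,), land_class=LandClass.DRAINED_PEAT,
            species=Species.PINE, fertility=Fertility.SUB_XERIC,
        )
        all_events = []
        for p in range(5):
            comp, events, _ = step_period(comp, Management.CCF, rules, climate, p, rng)
            all_events.extend(events)
        ferts = [e for e in all_events if e.event_type is EventType.FERTILIZATION_PEAT_ASH]
        assert len(ferts) <= 1

    def test_rf_clearcut_triggers_immediate_regeneration(self, make_compartment, rules, climate):
        rng = np.random.default_rng(1)
        comp = make_compartment(
            diam=(26.5,), stems=(350.0,), fertility=Fertility.MESIC, species=Species.SPRUCE
        )
        comp, events, _ = step_period(comp, Management.RF, rules, climate, 0, rng)
        types = [e.event_type for e in events]
        assert EventType.CLEAR_CUT in types
        assert EventType.SITE_PREPARATION in types
        assert EventType.PLANTING in types or EventType.SEEDING in types
        cut = next(e for e in events if e.event_type is EventType.CLEAR_CUT)
        regen = next(e for e in events if e.event_type is EventType.SITE_PREPARATION)
        assert cut.year == regen.year == 5
        assert comp.age_years < 10 and comp.tending_due

    def test_tending_follows_in_next_period(self, make_compartment, rules, climate):
        rng = np.random.default_rng(1)
        comp = make_compartment(
            diam=(26.5,), stems=(350.0,), fertility=Fertility.MESIC, species=Species.SPRUCE
        )
        comp, _, _ = step_period(comp, Management.RF, rules, climate, 0, rng)
        comp, events, _ = step_period(comp, Management.RF, rules, climate, 1, rng)
        assert EventType.TENDING in [e.event_type for e in events]

    def test_event_years_at_mid_period(self, make_compartment, rules, climate):
        rng = np.random.default_rng(3)
        comp = make_compartment(
            diam=(20.0, 26.0), stems=(400.0, 250.0), land_class=LandClass.DRAINED_PEAT,
            fertility=Fertility.MESIC, species=Species.PINE,
        )
        for p in range(5):
            comp, events, _ = step_period(comp, Management.RF, rules, climate, p, rng)
            for e in events:
                assert e.year % 10 == 5

    def test_ccf_never_emits_final_fellings(self, make_compartment, rules, climate):
        rng = np.random.default_rng(4)
        comp = make_compartment(
            diam=(10.0, 20.0, 30.0), stems=(500.0, 300.0, 150.0),
            land_class=LandClass.DRAINED_PEAT, fertility=Fertility.MESIC,
        )
        all_events = []
        for p in range(5):
            comp, events, _ = step_period(comp, Management.CCF, rules, climate, p, rng)
            all_events.extend(events)
            assert (comp.stems_ha >= 0).all()
        assert all(
            e.event_type not in (EventType.CLEAR_CUT, EventType.SEED_TREE_FELLING)
            for e in all_events
        )

    def test_erp_fells_no_earlier_than_rf(self, make_compartment, rules, climate):
        def first_felling_period(system):
            rng = np.random.default_rng(5)
            comp = make_compartment(
                diam=(24.0,), stems=(380.0,), fertility=Fertility.MESIC, species=Species.SPRUCE
            )
            for p in range(5):
                comp, events, _ = step_period(comp, system, rules, climate, p, rng)
                if any(e.event_type is EventType.CLEAR_CUT for e in events):
                    return p
            return 99

        assert first_felling_period(Management.ERP) >= first_felling_period(Management.RF)
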