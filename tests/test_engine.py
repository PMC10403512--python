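"""The growth/stress engine: indices, bucket hydrology, EI, classification."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ecoclim.climate_grid import MONTH_LENGTHS, MONTH_MID, WeeklySeries, monthly_to_weekly
from ecoclim.engine import (
    HIGH,
    SUITABLE,
    UNSUITABLE,
    annual_growth_index,
    classify,
    ecoclimatic_index,
    moisture_index,
    potential_evapotranspiration,
    run_cell,
    run_grid,
    soil_moisture_series,
    stress_index,
    temperature_index,
)
from ecoclim.synthetic import fixture_cell, fixture_weekly
from ecoclim.climate_grid import ClimateGrid, GridCell, MonthlyNormals

from conftest import random_normals


class TestGrowthIndices:
    @pytest.mark.parametrize(
        "tavg,expected",
        [(15.0, 1.0), (5.0, 0.0), (27.0, 0.0), (7.5, 0.5), (10.0, 1.0), (23.0, 1.0), (25.0, 0.5)],
    )
    def test_temperature_index_values(self, params, tavg, expected):
        assert temperature_index(tavg, params) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "sm,expected",
        [(0.5, 1.0), (0.1, 0.0), (2.5, 0.0), (0.15, 0.5), (0.2, 1.0), (0.8, 1.0)],
    )
    def test_moisture_index_values(self, params, sm, expected):
        assert moisture_index(sm, params) == pytest.approx(expected)

    def test_trapezoid_shape_by_dense_scan(self, params):
        """0 outside the limits, 1 on the optimum plateau, continuous overall."""
        x = np.linspace(params.dv0 - 10, params.dv3 + 10, 20001)
        y = temperature_index(x, params)
        assert np.all((y >= 0) & (y <= 1))
        assert np.all(y[x <= params.dv0] == 0)
        assert np.all(y[x >= params.dv3] == 0)
        plateau = (x >= params.dv1) & (x <= params.dv2)
        assert np.all(y[plateau] == 1.0)
        # continuity: max jump between dense neighbours is bounded by the slope
        max_slope = max(1 / (params.dv1 - params.dv0), 1 / (params.dv3 - params.dv2))
        assert np.max(np.abs(np.diff(y))) <= max_slope * (x[1] - x[0]) + 1e-12

    def test_annual_growth_index_matches_weekly_loop(self, params):
        rng = np.random.default_rng(11)
        tavg = rng.uniform(-5, 30, 52)
        weeks = WeeklySeries(tavg=tavg, tmin=tavg - 2, tmax=tavg + 2, precip=np.full(52, 20.0))
        sm = rng.uniform(0, 3, 52)
        expected = sum(
            temperature_index(t, params) * moisture_index(s, params)
            for t, s in zip(tavg, sm)
        ) / 52
        assert annual_growth_index(weeks, sm, params) == pytest.approx(expected, abs=1e-12)

    def test_growth_index_normalization(self, params):
        tavg = np.full(52, 16.0)
        tavg[26:] = -30.0  # TI=0 for half the year
        weeks = WeeklySeries(tavg=tavg, tmin=tavg - 2, tmax=tavg + 2, precip=np.zeros(52))
        sm = np.full(52, 0.5)  # MI=1 always
        assert annual_growth_index(weeks, sm, params) == pytest.approx(0.5)


class TestHydrology:
    @pytest.mark.parametrize("tavg,expected", [(20.0, 17.33), (-30.0, 0.0)])
    def test_pet_values(self, params, tavg, expected):
        assert potential_evapotranspiration(tavg, params) == pytest.approx(expected, abs=0.01)

    def test_pet_scaling_to_zero(self, params):
        p0 = params.replace(pet_coeff=0.0)
        for t in (-10, 0, 20, 40):
            assert potential_evapotranspiration(t, p0) == 0.0

    def test_balanced_bucket_is_fixed_point(self, params):
        weeks = fixture_weekly("optimal", params)  # precip == PET every week
        sm = soil_moisture_series(weeks, params)
        np.testing.assert_allclose(sm, 0.5, atol=1e-9)

    def test_constant_surplus_settles_just_above_field_capacity(self, params):
        # +10 mm/week surplus: the bucket fills by 0.1/week (0.5 -> 0.6 -> ...),
        # and once full every week reads 1.1 (runoff resets carryover to 1)
        pet = potential_evapotranspiration(16.0, params)
        weeks = WeeklySeries(
            tavg=np.full(52, 16.0), tmin=np.full(52, 10.0), tmax=np.full(52, 22.0),
            precip=np.full(52, pet + 10.0),
        )
        sm = soil_moisture_series(weeks, params)
        np.testing.assert_allclose(sm, 1.1, atol=1e-9)

    def test_dry_year_converges_to_zero(self, params):
        weeks = fixture_weekly("dry", params)
        sm = soil_moisture_series(weeks, params)
        np.testing.assert_allclose(sm, 0.0, atol=1e-6)

    def test_spinup_independent_of_initial_state(self, params):
        """Two different initial bucket states converge to the same cycle."""
        rng = np.random.default_rng(5)
        for _ in range(10):
            tmin, tmax, precip = random_normals(rng)
            weeks = monthly_to_weekly(MonthlyNormals(tmin=tmin, tmax=tmax, precip=precip))
            sm_a = soil_moisture_series(weeks, params.replace(sm_init=0.0))
            sm_b = soil_moisture_series(weeks, params.replace(sm_init=1.0))
            assert np.max(np.abs(sm_a - sm_b)) < 1e-5



class TestStress:
    def test_no_exceedance_no_stress(self, params):
        assert stress_index(np.zeros(52), params.thcs) == 0.0

    def test_cold_stress_worked_example(self, params):
        # 10 weeks at tmin = -19 with TTCS = 1: exceedance 20 each
        ex = np.zeros(52)
        ex[:10] = 20.0
        assert stress_index(ex, -0.00009) == pytest.approx(0.936)

    def test_saturation_at_one(self, params):
        ex = np.full(52, 100.0)
        assert stress_index(ex, params.thhs) == 1.0

    def test_negative_exceedance_is_caller_bug(self, params):
        with pytest.raises(ValueError):
            stress_index(np.array([-0.1] + [0.0] * 51), params.thhs)

    @given(
        scale=st.floats(min_value=0.0, max_value=5.0),
        rate=st.floats(min_value=1e-6, max_value=0.01),
    )
    def test_stress_monotone_in_exceedance(self, scale, rate):
        base = np.linspace(0, 2, 52)
        assert stress_index(base * scale, rate) <= stress_index(base * (scale + 0.5), rate)


class TestEiAndClass:
    def test_ideal_conditions_give_100(self):
        assert ecoclimatic_index(1.0, 0, 0, 0, 0) == 100.0

    def test_product_form(self):
        assert ecoclimatic_index(0.6, 0.5, 0, 0, 0) == pytest.approx(30.0)

    def test_any_full_stress_annihilates(self):
        for pos in range(4):
            stresses = [0.0] * 4
            stresses[pos] = 1.0
            assert ecoclimatic_index(0.9, *stresses) == 0.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ecoclimatic_index(1.5, 0, 0, 0, 0)

    @pytest.mark.parametrize(
        "ei,expected",
        [(0.0, UNSUITABLE), (1e-12, UNSUITABLE), (1e-6, SUITABLE), (15.0, SUITABLE),
         (29.999, SUITABLE), (30.0, HIGH), (100.0, HIGH)],
    )
    def test_classification_scheme(self, ei, expected):
        assert classify(ei) == expected

    @given(
        gi=st.floats(min_value=0, max_value=1),
        cs=st.floats(min_value=0, max_value=1),
        hs=st.floats(min_value=0, max_value=1),
        ds=st.floats(min_value=0, max_value=1),
        ws=st.floats(min_value=0, max_value=1),
    )
    def test_ei_bounds_property(self, gi, cs, hs, ds, ws):
        ei = ecoclimatic_index(gi, cs, hs, ds, ws)
        assert 0.0 <= ei <= 100.0
        if ei == 100.0:
            assert gi == 1.0 and cs == hs == ds == ws == 0.0


def brute_force_run_cell(cell, p):
    """Straight-line single-loop re-implementation of the whole cell pipeline."""
    # daily interpolation
    anchors = list(MONTH_MID)

    def interp(day, values):
        vals = list(values)
        pts = [(anchors[-1] - 365.0, vals[-1])] + list(zip(anchors, vals)) + [
            (anchors[0] + 365.0, vals[0])
        ]
        for (x0, y0), (x1, y1) in zip(pts, pts[1:]):
            if x0 <= day <= x1:
                return y0 + (y1 - y0) * (day - x0) / (x1 - x0)

    n = cell.normals
    rates = [n.precip[m] / MONTH_LENGTHS[m] for m in range(12)]
    tmin_w, tmax_w, tavg_w, prec_w = [], [], [], []
    for w in range(52):
        days = list(range(7 * w, 7 * w + 7)) if w < 51 else list(range(357, 365))
        lo = sum(interp(d + 0.5, n.tmin) for d in days) / len(days)
        hi = sum(interp(d + 0.5, n.tmax) for d in days) / len(days)
        tmin_w.append(lo)
        tmax_w.append(hi)
        tavg_w.append((lo + hi) / 2)
        prec_w.append(max(sum(interp(d + 0.5, rates) for d in days), 0.0))

    def trap(x, a, b, c, d):
        if x <= a or x >= d:
            return 0.0
        if x < b:
            return (x - a) / (b - a)
        if x <= c:
            return 1.0
        return (d - x) / (d - c)

    pet = [p.pet_coeff * max(0.0, 0.46 * t + 8.13) for t in tavg_w]
    state = p.sm_init
    sm = [0.0] * 52
    prev = None
    for _ in range(100):
        for w in range(52):
            val = min(max(state + (prec_w[w] - pet[w]) / p.soil_capacity, 0.0), p.sm_cap)
            sm[w] = val
            state = min(val, 1.0)
        if prev is not None and max(abs(a - b) for a, b in zip(sm, prev)) < 1e-6:
            break
        prev = list(sm)

    gi = sum(trap(tavg_w[w], p.dv0, p.dv1, p.dv2, p.dv3) * trap(sm[w], p.sm0, p.sm1, p.sm2, p.sm3) for w in range(52)) / 52
    cs = min(1.0, 52 * abs(p.thcs) * sum(max(0.0, p.ttcs - tmin_w[w]) for w in range(52)))
    hs = min(1.0, 52 * abs(p.thhs) * sum(max(0.0, tmax_w[w] - p.tths) for w in range(52)))
    ds = min(1.0, 52 * abs(p.hds) * sum(max(0.0, p.smds - sm[w]) for w in range(52)))
    ws = min(1.0, 52 * abs(p.hws) * sum(max(0.0, sm[w] - p.smws) for w in range(52)))
    return 100.0 * gi * (1 - cs) * (1 - hs) * (1 - ds) * (1 - ws)


class TestCellPipeline:
    def test_optimal_fixture_reaches_ei_100(self, params):
        r = run_cell(fixture_cell("optimal"), params)
        assert r.ei == pytest.approx(100.0, abs=1e-9)
        assert r.suitability == HIGH

    def test_deep_frost_fixture_cold_killed(self, params):
        r = run_cell(fixture_cell("cold"), params)
        assert r.cs == 1.0
        assert r.ei == 0.0
        assert r.suitability == UNSUITABLE

    def test_cold_weekly_fixture_stress_arithmetic(self, params):
        """12 weeks at tmin=-20 with TTCS=1: CS = min(1, 52*12*0.00009*21) = 1."""
        weeks = fixture_weekly("cold", params)
        ex = np.maximum(0.0, params.ttcs - weeks.tmin)
        assert stress_index(ex, params.thcs) == 1.0

    def test_dry_fixture_stressed(self, params):
        weeks = fixture_weekly("dry", params)
        sm = soil_moisture_series(weeks, params)
        assert np.max(sm) < 1e-6
        ds = stress_index(np.maximum(0.0, params.smds - sm), params.hds)
        assert ds > 0

    def test_repeated_invocation_bit_identical(self, params):
        cell = fixture_cell("optimal")
        a, b = run_cell(cell, params), run_cell(cell, params)
        assert a == b

    def test_matches_brute_force_oracle_on_random_cells(self, params):
        rng = np.random.default_rng(100)
        for i in range(100):
            tmin, tmax, precip = random_normals(rng)
            cell = GridCell(
                cell_id=f"r{i}", lat=float(rng.uniform(-60, 60)), lon=0.0,
                normals=MonthlyNormals(tmin=tmin, tmax=tmax, precip=precip),
            )
            expected = brute_force_run_cell(cell, params)
            assert run_cell(cell, params).ei == pytest.approx(expected, abs=1e-9)


class TestRunGrid:
    def test_one_result_per_cell_sorted(self, small_grid, params):
        results = run_grid(small_grid, params)
        assert [r.cell_id for r in results] == small_grid.cell_ids

    def test_permutation_invariance(self, small_grid, params):
        shuffled = ClimateGrid(list(reversed(small_grid.cells)))
        assert run_grid(shuffled, params) == run_grid(small_grid, params)

    def test_empty_grid_rejected(self, params):
        with pytest.raises(ValueError):
            run_grid(ClimateGrid([]), params)

    def test_identical_cells_identical_ei(self, params):
        base = fixture_cell("optimal")
        cells = [GridCell(f"id{i}", base.lat, base.lon, base.normals) for i in range(3)]
        results = run_grid(ClimateGrid(cells), params)
        assert len({r.ei for r in results}) == 1

    def test_ei_in_range_and_internally_consistent(self, small_results):
        for r in small_results:
            assert 0.0 <= r.ei <= 100.0
            recomputed = 100.0 * r.gi_a * (1 - r.cs) * (1 - r.hs) * (1 - r.ds) * (1 - r.ws)
            assert r.ei == pytest.approx(recomputed, abs=1e-9)
            assert r.suitability == classify(r.ei)
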