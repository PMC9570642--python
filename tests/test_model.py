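"""Core growth-model operations: uptake, critical N, NNI, balance steps,
biomass increments and the forward simulation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nfertdss import (
    CropParams,
    DoseSchedule,
    FieldParams,
    LeakageNetwork,
    Scenario,
    ScenarioSeries,
    biomass_increment,
    critical_n,
    nitrogen_uptake,
    nni,
    potential_increment,
    simulate,
    step_soil_n_multi,
    step_soil_n_single,
)


class TestElementaryOps:
    @pytest.mark.parametrize(
        "lai, avail, expected",
        [
            (1.0, 100.0, 35.7),
            (1.0, 0.0, 0.0),
            (2.0, 100.0, 35.7 * math.exp(0.63 * math.log(2.0))),
        ],
    )
    def test_nitrogen_uptake(self, lai, avail, expected):
        assert nitrogen_uptake(lai, avail) == pytest.approx(expected, rel=1e-12)

    def test_uptake_never_exceeds_stock(self):
        assert nitrogen_uptake(5.0, 2.0) == 2.0

    def test_uptake_rejects_nonpositive_lai(self):
        with pytest.raises(ValueError):
            nitrogen_uptake(0.0, 1.0)
        with pytest.raises(ValueError):
            nitrogen_uptake(-1.0, 1.0)

    @pytest.mark.parametrize(
        "lai, expected",
        [
            (1.0, 3.7),
            (2.0, 3.7 * math.exp(-0.35 * math.log(2.0))),  # 2.9028
            (4.0, 3.7 * math.exp(-0.35 * math.log(4.0))),  # 2.2777
        ],
    )
    def test_critical_n(self, lai, expected):
        assert critical_n(lai) == pytest.approx(expected, rel=1e-12)

    def test_critical_n_decreasing_in_lai(self):
        lai = np.linspace(0.2, 8.0, 50)
        vals = critical_n(lai)
        assert np.all(np.diff(vals) < 0)

    def test_nni_definitional(self):
        assert nni(critical_n(2.3), 2.3) == pytest.approx(1.0)
        assert nni(0.0, 1.7) == 0.0
        assert nni(5.0, 1.0) == pytest.approx(5.0 / 3.7)

    @pytest.mark.parametrize(
        "n, dose, eta, uptake, expected",
        [
            (5.0, 0.0, 1.0, 0.0, 5.0),
            (5.0, 10.0, 0.8, 2.0, 10.0),
            (1.0, 0.0, 0.5, 5.0, 0.0),  # clamped at zero
        ],
    )
    def test_step_soil_n_single(self, n, dose, eta, uptake, expected):
        assert step_soil_n_single(n, dose, eta, uptake) == pytest.approx(expected)


class TestMultiFieldStep:
    def test_two_field_leakage_hand_evaluated(self):
        fields = (
            FieldParams(field_id=1, eta=1.0, gamma=0.015),
            FieldParams(field_id=2, eta=1.0, gamma=0.015),
        )
        leak = LeakageNetwork.chain([0.01])  # field1 -> field2
        out = step_soil_n_multi([10.0, 10.0], [0.0, 0.0], fields, leak, [0.0, 0.0])
        assert out[0] == pytest.approx(10.0 - 0.15)
        assert out[1] == pytest.approx(10.0 - 0.15 - 0.10)

    def test_zero_coupling_reduces_to_single_step_bitwise(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = rng.uniform(0, 20, size=3)
            u = rng.uniform(0, 25, size=3)
            nu = rng.uniform(0, 5, size=3)
            eta = rng.uniform(0, 1, size=3)
            fields = tuple(
                FieldParams(field_id=i + 1, eta=eta[i], gamma=0.0) for i in range(3)
            )
            multi = step_soil_n_multi(n, u, fields, LeakageNetwork.none(3), nu)
            single = np.array(
                [step_soil_n_single(n[i], u[i], eta[i], nu[i]) for i in range(3)]
            )
            assert np.array_equal(multi, single)

    def test_mismatched_field_sets_raise(self):
        fields = (FieldParams(field_id=1),)
        with pytest.raises(ValueError):
            step_soil_n_multi([1.0, 2.0], [0.0, 0.0], fields, LeakageNetwork.none(2), [0.0, 0.0])


class TestBiomassIncrement:
    CROP = CropParams(lue=3.0, k=0.6, eps=0.5)

    def test_worked_value(self):
        # 30*(1-exp(-1.8))*exp(-0.1)
        got = biomass_increment(self.CROP, 20.0, 3.0, 0.8)
        assert got == pytest.approx(30 * (1 - math.exp(-1.8)) * math.exp(-0.1), rel=1e-12)
        assert got == pytest.approx(22.658, abs=5e-4)

    def test_potential_worked_value(self):
        assert potential_increment(self.CROP, 20.0, 3.0) == pytest.approx(25.041, abs=5e-4)

    def test_no_stress_at_full_nutrition(self):
        pot = potential_increment(self.CROP, 20.0, 3.0)
        assert biomass_increment(self.CROP, 20.0, 3.0, 1.0) == pytest.approx(pot)
        # surplus N does not amplify growth beyond potential
        assert biomass_increment(self.CROP, 20.0, 3.0, 1.7) == pytest.approx(pot)

    def test_eps_zero_removes_stress(self):
        crop = CropParams(lue=3.0, k=0.6, eps=0.0)
        pot = potential_increment(crop, 20.0, 3.0)
        for nni_val in (0.0, 0.3, 0.9):
            assert biomass_increment(crop, 20.0, 3.0, nni_val) == pytest.approx(pot)

    def test_potential_limits(self):
        assert potential_increment(self.CROP, 0.0, 3.0) == 0.0
        assert potential_increment(self.CROP, 20.0, 500.0) == pytest.approx(30.0, rel=1e-6)

    @settings(deadline=None, max_examples=200)
    @given(
        dtr=st.floats(0.0, 40.0),
        lai=st.floats(0.05, 10.0),
        n1=st.floats(0.0, 1.0),
        n2=st.floats(0.0, 1.0),
    )
    def test_monotone_in_nutrition_and_bounded_by_potential(self, dtr, lai, n1, n2):
        lo, hi = sorted((n1, n2))
        g_lo = biomass_increment(self.CROP, dtr, lai, lo)
        g_hi = biomass_increment(self.CROP, dtr, lai, hi)
        pot = potential_increment(self.CROP, dtr, lai)
        assert g_lo <= g_hi + 1e-12
        assert g_hi <= pot + 1e-12

    @settings(deadline=None, max_examples=100)
    @given(
        d1=st.floats(0.0, 40.0), d2=st.floats(0.0, 40.0),
        l1=st.floats(0.05, 10.0), l2=st.floats(0.05, 10.0),
        nv=st.floats(0.0, 1.5),
    )
    def test_monotone_in_radiation_and_canopy(self, d1, d2, l1, l2, nv):
        dlo, dhi = sorted((d1, d2))
        llo, lhi = sorted((l1, l2))
        assert biomass_increment(self.CROP, dlo, llo, nv) <= (
            biomass_increment(self.CROP, dhi, lhi, nv) + 1e-12
        )


class TestSimulate:
    def test_matches_hand_unrolled_recursion(self, tiny_scenario):
        sched = DoseSchedule.from_events(1, 5, {1: {1: 12.0, 4: 10.0}})
        sim = simulate(tiny_scenario, sched)

        # independent scalar unroll of the same recursion
        crop = tiny_scenario.crop
        eta = tiny_scenario.fields[0].eta
        n = 5.0
        for d in range(5):
            lai = tiny_scenario.series.lai[0, d]
            dtr = tiny_scenario.series.dtr[0, d]
            u = sched.u[0, d]
            a = n + u
            ncr = 3.7 * lai ** -0.35
            expected_nni = a / ncr
            pot = 0.5 * crop.lue * dtr * (1 - math.exp(-crop.k * lai))
            expected_growth = pot * math.exp(-crop.eps * (1 - min(expected_nni, 1.0)))
            cap = crop.uptake_scale * 35.7 * lai ** 0.63
            nu = min(a, cap)
            assert sim.soil_n[0, d] == pytest.approx(n, rel=1e-12)
            assert sim.nni[0, d] == pytest.approx(expected_nni, rel=1e-12)
            assert sim.growth[0, d] == pytest.approx(expected_growth, rel=1e-12)
            assert sim.uptake[0, d] == pytest.approx(nu, rel=1e-12)
            n = max(0.0, a * eta - nu)
        assert sim.final_n[0] == pytest.approx(n, rel=1e-12)

    def test_depleted_soil_floor_behaviour(self):
        crop = CropParams(lue=3.0, k=0.6, eps=0.5, uptake_scale=0.01)
        series = ScenarioSeries(dtr=np.full((1, 10), 20.0), lai=np.full((1, 10), 2.0))
        scen = Scenario(
            crop=crop, fields=(FieldParams(n0=0.0),), series=series
        )
        sim = simulate(scen, DoseSchedule.zeros(1, 10))
        assert np.all(sim.nni == 0.0)
        expected = sim.potential_growth * math.exp(-crop.eps)
        np.testing.assert_allclose(sim.growth, expected, rtol=1e-12)

    def test_nitrogen_rich_soil_attains_potential(self, tiny_scenario):
        scen = Scenario(
            crop=tiny_scenario.crop,
            fields=(FieldParams(field_id=1, eta=0.9, n0=1e6),),
            series=tiny_scenario.series,
        )
        sim = simulate(scen, DoseSchedule.zeros(1, 5))
        np.testing.assert_allclose(sim.growth, sim.potential_growth, rtol=1e-12)

    def test_growth_never_exceeds_potential_and_soil_nonnegative(self):
        rng = np.random.default_rng(42)
        for trial in range(10):
            nd = 15
            crop = CropParams(
                lue=rng.uniform(2, 4), k=0.6, eps=rng.uniform(0, 1),
                uptake_scale=rng.uniform(0.001, 1.0),
            )
            series = ScenarioSeries(
                dtr=rng.uniform(5, 30, (2, nd)), lai=rng.uniform(0.1, 6, (2, nd))
            )
            scen = Scenario(
                crop=crop,
                fields=(
                    FieldParams(field_id=1, eta=rng.uniform(0.5, 1), n0=rng.uniform(0, 10)),
                    FieldParams(field_id=2, eta=rng.uniform(0.5, 1), gamma=0.02, n0=5.0),
                ),
                series=series,
                leakage=LeakageNetwork.chain([0.01]),
            )
            u = rng.uniform(0, 25, (2, nd)) * (rng.random((2, nd)) < 0.2)
            sim = simulate(scen, DoseSchedule(b=(u > 0).astype(int), u=u))
            assert np.all(sim.growth <= sim.potential_growth + 1e-12)
            assert np.all(sim.soil_n >= 0.0)

    def test_deterministic(self, tiny_scenario):
        sched = DoseSchedule.from_events(1, 5, {1: {1: 12.0}})
        a = simulate(tiny_scenario, sched)
        b = simulate(tiny_scenario, sched)
        assert np.array_equal(a.soil_n, b.soil_n)
        assert np.array_equal(a.growth, b.growth)

    def test_dimension_mismatch_raises(self, tiny_scenario):
        with pytest.raises(ValueError):
            simulate(tiny_scenario, DoseSchedule.zeros(1, 7))
        with pytest.raises(ValueError):
            simulate(tiny_scenario, DoseSchedule.zeros(2, 5))
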