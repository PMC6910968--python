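"""Process model: yield frontier, batch balances, distillation, flowsheet closure."""

import math

import numpy as np
import pytest

from bioassess.bioprocess import (
    MW,
    N_FRACTION,
    BatchOutcome,
    DistillationSpec,
    FermentationParams,
    ModelError,
    build_flowsheet,
    distillation_heat,
    simulate_batch,
    size_plant,
    yield_tradeoff,
)
from bioassess.synthetic_data import (
    distributions_from_table,
    generate_fixture_bundle,
    generate_toy_network,
    scenario_space,
)
from bioassess.uncertainty import ParameterDraw, draw_parameters


class TestYieldTradeoff:
    def test_zero_growth_gives_analytic_maximum(self, toy_network):
        # all substrate to product: one diamine per glucose
        _, py = yield_tradeoff(toy_network, 0.0)
        assert py == pytest.approx(MW["putrescine"] / MW["glucose"], rel=1e-9)

    def test_full_growth_commitment_zeroes_product(self, toy_network):
        by, py = yield_tradeoff(toy_network, 1.0)
        assert py == pytest.approx(0.0, abs=1e-9)
        assert by == pytest.approx(5 * MW["biomass_c1"] / MW["glucose"], rel=1e-9)

    def test_product_yield_non_increasing_in_growth(self, toy_network):
        yields = [yield_tradeoff(toy_network, f)[1] for f in np.linspace(0, 1, 5)]
        assert all(a >= b - 1e-12 for a, b in zip(yields, yields[1:]))

    def test_carbon_closure_along_frontier(self, toy_network):
        # glucose 6 C; biomass 1 C per unit; putrescine 4 C; CO2 1 C
        carbon = {"glc": 6, "bio": 1, "prod": 4, "co2": 1}
        for f in (0.0, 0.3, 0.7, 1.0):
            v = toy_network._solve(
                toy_network.objective,
                fixed={"biomass_export": f * 50.0 * toy_network.bounds["uptake"][1] / 10.0},
            )
            names = toy_network.reaction_names
            c_in = 6 * v[names.index("uptake")]
            c_out = (1 * v[names.index("biomass_export")]
                     + 4 * v[names.index("product_export")]
                     + 1 * v[names.index("co2_export")])
            assert c_in == pytest.approx(c_out, abs=1e-6)

    def test_cadaverine_network_maximum(self):
        net = generate_toy_network("cadaverine")
        _, py = yield_tradeoff(net, 0.0)
        assert py == pytest.approx(MW["cadaverine"] / MW["glucose"], rel=1e-9)


class TestSimulateBatch:
    BASE = dict(substrate_uptake_rate=3.0, biomass_yield_growth=0.4,
                product_yield=0.35, switch_time=8.0, batch_time=48.0,
                turnaround_time=12.0, working_volume=200_000.0)

    def test_no_production_phase_means_zero_titre(self):
        out = simulate_batch(FermentationParams(**{**self.BASE, "switch_time": 48.0}))
        assert out.titre == 0.0 and out.biomass_produced > 0

    def test_pure_production_titre_closed_form(self):
        # titre = uptake * yield * time when the whole batch makes product
        p = FermentationParams(**{**self.BASE, "switch_time": 0.0})
        out = simulate_batch(p)
        assert out.titre == pytest.approx(3.0 * 0.35 * 48.0, rel=1e-12)

    def test_overall_yield_diluted_by_growth_sugar(self):
        out = simulate_batch(FermentationParams(**self.BASE))
        assert out.overall_yield <= out.params.product_yield
        # growth phase is 1/6 of the batch
        assert out.overall_yield == pytest.approx(0.35 * 40 / 48, rel=1e-12)

    def test_productivity_includes_turnaround(self):
        out = simulate_batch(FermentationParams(**self.BASE))
        assert out.productivity == pytest.approx(out.titre / 60.0, rel=1e-12)

    def test_nitrogen_from_elemental_composition(self):
        out = simulate_batch(FermentationParams(**self.BASE))
        expected = (out.biomass_produced * N_FRACTION["biomass"]
                    + out.product_produced * N_FRACTION["putrescine"])
        assert out.nitrogen_required == pytest.approx(expected, rel=1e-12)

    def test_switch_after_batch_end_rejected(self):
        with pytest.raises(ModelError):
            FermentationParams(**{**self.BASE, "switch_time": 49.0})


class TestDistillation:
    def test_water_like_hand_case(self):
        spec = DistillationSpec(4.18, 75.0, 2257.0, 0.5)
        assert distillation_heat(spec) == pytest.approx((313.5 + 2257) / 0.5, rel=1e-12)
        assert distillation_heat(spec) == pytest.approx(5141.0, rel=1e-9)

    def test_zero_sensible_perfect_efficiency_is_dhvap(self):
        assert distillation_heat(DistillationSpec(4.18, 0.0, 2257.0, 1.0)) == 2257.0

    def test_halving_efficiency_doubles_duty(self):
        full = distillation_heat(DistillationSpec(2.9, 130.0, 560.0, 0.8))
        half = distillation_heat(DistillationSpec(2.9, 130.0, 560.0, 0.4))
        assert half == pytest.approx(2 * full, rel=1e-12)

    def test_invalid_efficiency_rejected(self):
        with pytest.raises(ModelError):
            DistillationSpec(2.9, 130.0, 560.0, 0.0)


class TestSizePlant:
    def _outcome(self, titre_g_l: float) -> BatchOutcome:
        p = FermentationParams(substrate_uptake_rate=1, biomass_yield_growth=0,
                               product_yield=1, switch_time=0, batch_time=10,
                               turnaround_time=0, working_volume=1000.0)
        product_kg = titre_g_l * 1000.0 / 1000.0
        return BatchOutcome(titre=titre_g_l, productivity=titre_g_l / 10,
                            overall_yield=1, biomass_produced=0,
                            product_produced=product_kg, sugar_fed=product_kg,
                            nitrogen_required=0, params=p)

    def test_exactly_one_fermenter_when_demand_met(self):
        # 800 batches/yr * 50 kg/batch = 40,000 kg/yr = 0.04 kt/yr
        out = self._outcome(50.0)
        assert size_plant(out, annual_output_kt=0.04, operating_hours=8000) == 1

    def test_ceiling_monotone_in_output(self):
        out = self._outcome(50.0)
        n1 = size_plant(out, 0.05, 8000)
        n2 = size_plant(out, 0.10, 8000)
        assert n1 <= n2 <= 2 * n1

    def test_zero_titre_rejected(self):
        with pytest.raises(ModelError):
            size_plant(self._outcome(0.0), 100.0)


@pytest.fixture(scope="module")
def flowsheet_inputs():
    bundle = generate_fixture_bundle(0, "smoke")
    return distributions_from_table(bundle.parameter_table), scenario_space()


def _flowsheet_for(dists, space, seed, i, waste=None):
    draw = draw_parameters(dists, space, seed, i)
    if waste is not None:
        draw = ParameterDraw(values=draw.values,
                             scenario={**draw.scenario, "waste_handling": waste},
                             iteration_index=i)
    params = FermentationParams(
        substrate_uptake_rate=draw["sugar_uptake_rate"],
        biomass_yield_growth=draw["biomass_yield_growth"],
        product_yield=draw["product_yield"],
        switch_time=draw["switch_time"],
        batch_time=draw["batch_time"],
        turnaround_time=draw["turnaround_time"],
        working_volume=draw["working_volume"],
    )
    return build_flowsheet(simulate_batch(params), draw), draw


class TestFlowsheet:
    def test_mass_closure_over_random_draws(self, flowsheet_inputs):
        dists, space = flowsheet_inputs
        for i in range(1000):
            fs, _ = _flowsheet_for(dists, space, seed=11, i=i)
            for stage in fs.stages:
                assert stage.mass_imbalance() < 1e-6, stage.name

    def test_integrated_steam_never_exceeds_non_integrated(self, flowsheet_inputs):
        dists, space = flowsheet_inputs
        for i in range(1000):
            fs_int, _ = _flowsheet_for(dists, space, 13, i, waste="integrated")
            fs_non, _ = _flowsheet_for(dists, space, 13, i, waste="non-integrated")
            assert fs_int.net_steam_mj <= fs_non.net_steam_mj + 1e-12

    def test_non_integrated_has_zero_steam_credit(self, flowsheet_inputs):
        dists, space = flowsheet_inputs
        fs, _ = _flowsheet_for(dists, space, 17, 0, waste="non-integrated")
        assert fs.steam_credit_mj == 0.0

    def test_evaporation_reaches_sixty_percent_water(self, flowsheet_inputs):
        # cake at 80% water, solids m: water 4m -> target 1.5m, remove 2.5m
        # (the 10 kg cake worked case: 2 kg solids, remove 5 kg water)
        dists, space = flowsheet_inputs
        fs, draw = _flowsheet_for(dists, space, 19, 0)
        evap = fs.stage("evaporation")
        dried = evap.outputs["dried-cake"]
        wet = evap.inputs["wet-cake"]
        solids = wet / (1 + draw["cake_water_initial"] / (1 - draw["cake_water_initial"]))
        assert dried == pytest.approx(solids / 0.4, rel=1e-9)  # 60% water
        assert evap.outputs["emission/water-vapour"] == pytest.approx(
            wet - dried, rel=1e-9)
        assert wet / solids == pytest.approx(5.0, rel=1e-9)  # 80% water cake
        assert (wet - dried) / solids == pytest.approx(2.5, rel=1e-9)

    def test_unresolved_scenario_axis_rejected(self, flowsheet_inputs):
        dists, space = flowsheet_inputs
        draw = draw_parameters(dists, space, 23, 0)
        bare = ParameterDraw(values=draw.values, scenario={}, iteration_index=0)
        params = FermentationParams(
            substrate_uptake_rate=3, biomass_yield_growth=0.4, product_yield=0.35,
            switch_time=8, batch_time=48, turnaround_time=12, working_volume=2e5)
        with pytest.raises(ModelError):
            build_flowsheet(simulate_batch(params), bare)

    def test_waste_cake_routed_to_exactly_one_branch(self, flowsheet_inputs):
        dists, space = flowsheet_inputs
        for waste, route in (("integrated", "waste-cake-to-combustor"),
                             ("non-integrated", "waste-cake-to-incineration")):
            fs, _ = _flowsheet_for(dists, space, 29, 0, waste=waste)
            outs = fs.stage("waste handling").outputs
            assert set(outs) == {route}
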