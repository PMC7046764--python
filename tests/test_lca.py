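"""Per-MJ LCA assembly: elementary operations and system contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from palmghg import (
    LUCParams,
    ProcessParams,
    allocation_factor,
    assemble_lca,
    biogenic_combustion,
    energy_chain,
    foregone_sequestration,
    luc_annualized,
    pome_emissions,
    scenario,
    yield_trajectory,
)
from palmghg.scenarios import AnnualTrajectory


class TestLUC:
    def test_default_stocks_amortized_over_25_years(self):
        _, mg_ha_yr = luc_annualized(LUCParams(t_years=25.0))
        assert mg_ha_yr == pytest.approx(25.44, abs=0.01)

    def test_equal_stocks_no_emission(self):
        _, mg = luc_annualized(LUCParams(cs_r=100.0, cs_a=100.0, t_years=25.0))
        assert mg == 0.0

    def test_forty_year_amortization(self):
        _, mg = luc_annualized(LUCParams(t_years=40.0))
        assert mg == pytest.approx(15.90, abs=0.01)

    def test_nonpositive_period_rejected(self):
        with pytest.raises(ValueError):
            LUCParams(t_years=0.0)

    def test_unit_consistency(self):
        g_m2, mg_ha = luc_annualized(LUCParams(t_years=30.0))
        assert g_m2 == pytest.approx(mg_ha * 1e6 / 1e4)


class TestForegoneSequestration:
    def test_forest_sink_becomes_positive_charge(self):
        assert foregone_sequestration(-124.0) == pytest.approx(454.3, abs=0.1)

    def test_zero_and_source_sign_logic(self):
        assert foregone_sequestration(0.0) == 0.0
        assert foregone_sequestration(50.0) < 0.0


class TestEnergyChain:
    def test_one_kg_cpo_needs_5_18_kg_ffb(self):
        traj = AnnualTrajectory(values=[5.18e-3], unit="Mg ha-1 yr-1")
        chain = energy_chain(traj, ProcessParams())
        assert chain["cpo_kg"].iloc[0] == pytest.approx(1.0)

    def test_simulated_mean_yield_chain(self):
        traj = AnnualTrajectory(values=[21.925], unit="Mg ha-1 yr-1")
        chain = energy_chain(traj, ProcessParams())
        assert chain["cpo_kg"].iloc[0] == pytest.approx(4232.6, abs=0.5)
        assert chain["biodiesel_kg"].iloc[0] == pytest.approx(4021.0, abs=0.5)
        assert chain["biodiesel_mj"].iloc[0] == pytest.approx(150788.0, rel=1e-3)

    def test_zero_yield_zero_products(self):
        chain = energy_chain(AnnualTrajectory(values=[0.0, 0.0], unit=""), ProcessParams())
        assert (chain[["cpo_kg", "biodiesel_kg", "glycerol_kg", "biodiesel_mj"]] == 0).all().all()

    def test_mass_conservation_at_split(self):
        chain = energy_chain(AnnualTrajectory(values=[26.5], unit=""), ProcessParams())
        assert chain["biodiesel_kg"].iloc[0] + chain["glycerol_kg"].iloc[0] == pytest.approx(
            chain["cpo_kg"].iloc[0]
        )


class TestAllocation:
    def test_energy_allocation_biodiesel_vs_glycerol(self):
        f = allocation_factor("energy", {"biodiesel": 150788.0, "glycerol": 3386.0})
        assert f["biodiesel"] == pytest.approx(0.978, abs=1e-3)

    def test_single_product_gets_everything(self):
        assert allocation_factor("energy", {"only": 10.0}) == {"only": 1.0}

    def test_equal_energies_split_evenly(self):
        f = allocation_factor("energy", {"a": 5.0, "b": 5.0})
        assert f["a"] == f["b"] == 0.5

    def test_economic_requires_prices(self):
        with pytest.raises(ValueError):
            allocation_factor("economic", {"a": 1.0})

    @settings(derandomize=True)
    @given(
        st.dictionaries(
            st.sampled_from(["a", "b", "c", "d"]),
            st.floats(min_value=0.01, max_value=1e6),
            min_size=1,
        )
    )
    def test_factors_sum_to_one_energy_and_economic(self, outputs):
        for method, prices in [("energy", None), ("economic", {k: 2.0 for k in outputs})]:
            f = allocation_factor(method, outputs, prices)
            assert sum(f.values()) == pytest.approx(1.0)


class TestBiogenicCombustion:
    def test_biodiesel_per_mj(self):
        g = biogenic_combustion(1.0, 0.7635)
        assert g == pytest.approx(2797.0, rel=1e-3)
        assert g / 37.5 == pytest.approx(74.6, abs=0.1)

    def test_fibre_with_water_content(self):
        assert biogenic_combustion(1.0, 0.472, water_content=0.40) == pytest.approx(
            1037.6, abs=0.5
        )

    def test_zero_carbon_content(self):
        assert biogenic_combustion(5.0, 0.0) == 0.0


class TestPOME:
    def test_open_to_closed_ratio_is_ninefold(self):
        ratio = pome_emissions("open", 1.0) / pome_emissions("closed", 1.0)
        assert ratio == pytest.approx(25.0 / (44.0 / 16.0))
        assert round(ratio) == 9

    def test_calibrated_closed_emission(self, paper_inventory):
        ch4 = paper_inventory.background["pome_ch4_per_mj"]
        assert pome_emissions("closed", ch4) == pytest.approx(1.8)
        assert pome_emissions("open", ch4) == pytest.approx(16.36, abs=0.01)

    def test_zero_inventory_and_bad_mode(self):
        assert pome_emissions("closed", 0.0) == 0.0
        assert pome_emissions("open", 0.0) == 0.0
        with pytest.raises(ValueError):
            pome_emissions("lagoon-ish", 1.0)


class TestAssembly:
    def test_net_is_sum_of_components(self, paper_inventory):
        res = assemble_lca(scenario("BAU"), paper_inventory, mode="enhanced")
        assert res.net == pytest.approx(sum(res.components.values()), abs=1e-9)

    def test_mode_contract_traditional_vs_enhanced(self, paper_inventory):
        trad = assemble_lca(scenario("BAU"), paper_inventory, mode="traditional")
        enh = assemble_lca(scenario("BAU"), paper_inventory, mode="enhanced")
        assert trad.components["ecosystem_sink"] == 0.0
        assert trad.components["biogenic_use"] == 0.0
        assert enh.components["ecosystem_sink"] < 0.0
        assert enh.components["biogenic_use"] > 0.0
        for shared in ("cultivation", "milling", "biodiesel_production", "pome", "luc"):
            assert trad.components[shared] == pytest.approx(enh.components[shared])

    def test_second_rotation_drops_land_use_change(self, paper_inventory, decay_curve):
        res = assemble_lca(
            scenario("BAU", rotation="second"),
            paper_inventory,
            mode="enhanced",
            decay_curve=decay_curve,
        )
        assert res.components["luc"] == 0.0
        assert res.components["foregone_sequestration"] == 0.0

    def test_second_rotation_net_below_first(self, paper_inventory, decay_curve):
        first = assemble_lca(scenario("BAU"), paper_inventory, mode="enhanced")
        second = assemble_lca(
            scenario("BAU", rotation="second"),
            paper_inventory,
            mode="enhanced",
            decay_curve=decay_curve,
        )
        assert second.net < first.net

    def test_zero_background_zero_luc_zero_fluxes_nets_zero(self, zero_inventory):
        from dataclasses import replace

        spec = replace(scenario("BAU"), nee_young=0.0, nee_mature=0.0)
        res = assemble_lca(
            spec,
            zero_inventory,
            mode="traditional",
            luc=LUCParams(cs_r=0.0, cs_a=0.0, t_years=25.0, forest_nee=0.0),
            soil_ch4_annual=0.0,
            soil_n2o_annual=0.0,
        )
        assert res.net == pytest.approx(0.0, abs=1e-12)

    def test_luc_per_mj_decreases_with_longer_rotation(self, paper_inventory):
        vals = []
        for name in ("BAU", "A", "B"):
            spec = scenario(name)
            res = assemble_lca(
                spec,
                paper_inventory,
                mode="enhanced",
                luc=LUCParams(t_years=float(spec.cycle_length)),
            )
            vals.append(res.components["luc"])
        assert vals[0] > vals[1] > vals[2]

    def test_scenario_net_ordering_first_rotation(self, paper_inventory):
        nets = {}
        for name in ("BAU", "A", "B"):
            spec = scenario(name)
            nets[name] = assemble_lca(
                spec,
                paper_inventory,
                mode="enhanced",
                luc=LUCParams(t_years=float(spec.cycle_length)),
            ).net
        assert nets["BAU"] >= nets["A"] >= nets["B"]

    def test_incomplete_inventory_names_missing_factor(self, paper_inventory):
        from palmghg import ForegroundInventory

        broken = ForegroundInventory(
            process=paper_inventory.process,
            background={
                k: v
                for k, v in paper_inventory.background.items()
                if k != "ef_mill"
            },
        )
        with pytest.raises(KeyError, match="ef_mill"):
            assemble_lca(scenario("BAU"), broken)

    def test_savings_definition(self, paper_inventory):
        res = assemble_lca(scenario("BAU"), paper_inventory, mode="enhanced")
        assert res.savings_vs_fossil == pytest.approx(
            1.0 - res.net / paper_inventory.fossil_reference
        )

    def test_allocation_factor_applied_is_energy_share(self, paper_inventory):
        res = assemble_lca(scenario("BAU"), paper_inventory)
        p = paper_inventory.process
        expected = (0.95 * p.hv_biodiesel) / (0.95 * p.hv_biodiesel + 0.05 * p.hv_glycerol)
        assert res.allocation_factor == pytest.approx(expected)
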