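"""Cropland N2O: nitrogen budget components, direct and indirect
pathways, unit conversions."""

import numpy as np
import pandas as pd
import pytest

from cropghg.aggregate_gwp import to_co2eq
from cropghg.cropland_n2o import (NitrogenBudget, cropland_n2o_emissions,
                                  direct_n2o, indirect_n2o, manure_nitrogen,
                                  nitrogen_budget, residue_nitrogen)
from cropghg.synthetic_data import generate_panel

from conftest import make_panel, set_values
from oracles import cropland_n2o_oracle


class TestResidueNitrogen:
    def test_hand_evaluated_example(self, ps):
        # Prod 1000 kg, f_dry .85, f_harv .5, f_rb .1, f_rbrate .01,
        # f_retu .14: NRoot 1.7, NStra 8.5, residue N 2.89 kg
        tuned = set_values(ps, f_dry={"wheat": 0.85}, f_harv={"wheat": 0.5},
                           f_rb={"wheat": 0.1}, f_rbrate={"wheat": 0.01},
                           f_retu=0.14)
        panel = make_panel(crop_production={("beijing", 1980, "wheat"): 1000.0})
        res = residue_nitrogen(panel, tuned)
        assert res.loc[("beijing", 1980)] == pytest.approx(2.89, rel=1e-9)

    def test_harvest_index_one_leaves_no_straw(self, ps):
        tuned = set_values(ps, f_dry={"wheat": 0.85}, f_harv={"wheat": 1.0},
                           f_rb={"wheat": 0.1}, f_rbrate={"wheat": 0.01})
        panel = make_panel(crop_production={("beijing", 1980, "wheat"): 1000.0})
        res = residue_nitrogen(panel, tuned)
        # only the root pool remains
        assert res.loc[("beijing", 1980)] == pytest.approx(
            1000 * 0.85 * 0.1 * 0.01, rel=1e-9)

    def test_zero_production_zero_nitrogen(self, ps):
        assert (residue_nitrogen(make_panel(), ps) == 0).all()

    def test_zero_harvest_index_rejected(self, ps):
        tuned = set_values(ps, f_harv={"wheat": 0.0})
        panel = make_panel(crop_production={("beijing", 1980, "wheat"): 1.0})
        with pytest.raises(ZeroDivisionError):
            residue_nitrogen(panel, tuned)

    def test_excluded_crops_contribute_nothing(self, ps):
        panel = make_panel(crop_production={("beijing", 1980, "tobacco"): 1e6,
                                            ("beijing", 1980, "fiber"): 1e6})
        assert (residue_nitrogen(panel, ps) == 0).all()


class TestManureNitrogen:
    def test_hand_evaluated_example(self, ps):
        # 100 head x 40 kg N x (0.2+0.2+0.2) x (1-0.2) = 1920 kg N
        tuned = set_values(ps, f_excr={"cattle": 40.0}, f_mana={"cattle": 0.2},
                           f_liq={"cattle": 0.2}, f_sol={"cattle": 0.2},
                           f_enn=0.2)
        panel = make_panel(populations={("beijing", 1980, "cattle"): 100.0})
        man = manure_nitrogen(panel, tuned)
        assert man.loc[("beijing", 1980)] == pytest.approx(1920.0, rel=1e-9)

    def test_full_gaseous_loss_zeroes_manure(self, ps):
        tuned = set_values(ps, f_enn=1.0)
        panel = make_panel(populations={("beijing", 1980, "cattle"): 100.0})
        assert (manure_nitrogen(panel, tuned) == 0).all()

    def test_partition_fractions_above_one_rejected(self, ps):
        tuned = set_values(ps, f_mana={"cattle": 0.5}, f_liq={"cattle": 0.4},
                           f_sol={"cattle": 0.4})
        panel = make_panel(populations={("beijing", 1980, "cattle"): 1.0})
        with pytest.raises(ValueError, match="partition"):
            manure_nitrogen(panel, tuned)


def _budget(nfert_kg: float, ps, province="beijing", year=1980):
    panel = make_panel(provinces=(province,), years=(year, year),
                       n_fertilizer={(province, year): nfert_kg})
    return nitrogen_budget(panel, ps)


class TestDirectIndirect:
    def test_direct_hand_value_and_unit_conversion(self, ps):
        # 100 t N x 0.01 = 1 t N2O-N = 44/28 t N2O; x265 -> 416.43 t CO2-eq
        tuned = set_values(ps, ef_crla_d={"beijing": 0.01})
        budget = _budget(100_000.0, tuned)
        out = direct_n2o(budget, tuned)
        n2o = out.loc[("beijing", 1980), "n2o"]
        assert n2o == pytest.approx(1000.0 * 44 / 28, rel=1e-9)
        eq = to_co2eq(out, tuned.gwp()).loc[("beijing", 1980)]
        assert eq == pytest.approx(1000.0 * 44 / 28 * 265, rel=1e-9)
        assert eq / 1000 == pytest.approx(416.43, rel=1e-4)

    def test_indirect_hand_value(self, ps):
        # NFert 100 t: Atmos = 100x0.1x0.01 = 0.1 t N2O-N,
        # Leach = 100x0.3x0.0075 = 0.225 t; total 0.325 t N2O-N
        budget = _budget(100_000.0, ps)
        out = indirect_n2o(budget, ps)
        n2o = out.loc[("beijing", 1980), "n2o"]
        assert n2o * 28 / 44 == pytest.approx(325.0, rel=1e-9)
        eq = to_co2eq(out, ps.gwp()).loc[("beijing", 1980)]
        assert eq / 1000 == pytest.approx(135.34, rel=1e-4)

    def test_indirect_to_direct_ratio_with_fertilizer_only(self, ps):
        tuned = set_values(ps, ef_crla_d={"beijing": 0.01})
        budget = _budget(50_000.0, tuned)
        d = direct_n2o(budget, tuned).loc[("beijing", 1980), "n2o"]
        i = indirect_n2o(budget, tuned).loc[("beijing", 1980), "n2o"]
        assert i / d == pytest.approx(0.325, rel=1e-9)

    def test_zero_budget_zero_emissions(self, ps):
        budget = _budget(0.0, ps)
        assert (direct_n2o(budget, ps).to_numpy() == 0).all()
        assert (indirect_n2o(budget, ps).to_numpy() == 0).all()


class TestBudgetAndTotals:
    def test_budget_additivity_invariant(self, ps):
        panel = generate_panel(seed=23, provinces=3, years=(1990, 1995))
        b = nitrogen_budget(panel, ps)
        np.testing.assert_allclose(
            b.total.to_numpy(),
            (b.n_fert + b.manure + b.residue).to_numpy(), rtol=1e-12)

    def test_negative_component_rejected(self):
        idx = pd.MultiIndex.from_tuples([("beijing", 1980)],
                                        names=["province", "year"])
        with pytest.raises(ValueError):
            NitrogenBudget(n_fert=pd.Series([-1.0], index=idx),
                           manure=pd.Series([0.0], index=idx),
                           residue=pd.Series([0.0], index=idx))

    def test_matches_loop_oracle(self, ps):
        panel = generate_panel(seed=29, provinces=4, years=(2000, 2006))
        fast = cropland_n2o_emissions(panel, ps)
        slow = cropland_n2o_oracle(panel, ps, fast)
        np.testing.assert_allclose(fast.to_numpy(), slow.to_numpy(),
                                   rtol=1e-9, atol=1e-9)

    def test_jointly_linear_in_all_inputs(self, ps):
        panel = generate_panel(seed=31, provinces=2, years=(1995, 1998))
        scaled = panel.copy()
        for name in ("n_fertilizer", "populations", "crop_production"):
            getattr(scaled, name)["value"] *= 2.0
        a = cropland_n2o_emissions(panel, ps)["n2o"]
        b = cropland_n2o_emissions(scaled, ps)["n2o"]
        np.testing.assert_allclose(b.to_numpy(), 2 * a.to_numpy(), rtol=1e-9)
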