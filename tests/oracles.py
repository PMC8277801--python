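"""Naive per-row reference implementations of the seven sub-models.

These loop over long-format panel rows with scalar parameter lookups —
no vectorization, no shared code with the array engines — and exist
solely to cross-check the production implementations.
"""

from collections import defaultdict

import pandas as pd

from cropghg import dimensions as dims
from cropghg.cropland_change import (CarbonPoolTable, annualize_transitions,
                                     landchange_ef)
from cropghg.input_production import (PESTICIDE_START_YEAR,
                                      effective_component_regression)


def _frame(cells: dict, like: pd.DataFrame) -> pd.DataFrame:
    out = pd.DataFrame(0.0, index=like.index, columns=dims.GAS_COLUMNS)
    for (prov, year, col), val in cells.items():
        out.loc[(prov, year), col] += val
    return out


def residue_burning_oracle(panel, ps, like):
    cells: dict = defaultdict(float)
    for r in panel.crop_production.itertuples():
        burned = (r.value * ps.get("f_str", {"crop": r.crop})
                  * ps.get("f_open", {"province": r.province})
                  * ps.get("f_burn"))
        cells[(r.province, r.year, "ch4")] += burned * ps.get("ef_crop_ch4") / 1000
        cells[(r.province, r.year, "n2o")] += burned * ps.get("ef_crop_n2o") / 1000
    return _frame(cells, like)


def rice_oracle(panel, ps, like):
    weights = ps.series("f_regime_weight")
    cells: dict = defaultdict(float)
    for r in panel.rice_area.itertuples():
        ef = sum(weights.loc[w] * ps.get("ef_rice", {
            "province": r.province, "rice_type": r.rice_type, "regime": w})
            for w in dims.RICE_REGIMES)
        length = ps.get("f_length", {"province": r.province,
                                     "rice_type": r.rice_type})
        cells[(r.province, r.year, "ch4")] += r.value * length * ef
    return _frame(cells, like)


def cropland_change_oracle(panel, ps, like):
    pools = CarbonPoolTable.from_params(ps, years=panel.year_range())
    annual = annualize_transitions(panel.land_transitions,
                                   years=panel.year_range())
    cells: dict = defaultdict(float)
    for r in annual.itertuples():
        ef = landchange_ef(r.change_type, r.year, pools)  # t C/ha
        cells[(r.province, r.year, "co2")] += r.value * ef * 1000 * 44 / 12
    return _frame(cells, like)


def cropland_n2o_oracle(panel, ps, like):
    nfert: dict = defaultdict(float)
    manure: dict = defaultdict(float)
    residue: dict = defaultdict(float)
    for r in panel.n_fertilizer.itertuples():
        nfert[(r.province, r.year)] += r.value
    for r in panel.populations.itertuples():
        k = {"creature": r.creature}
        manure[(r.province, r.year)] += (
            (1 - ps.get("f_enn")) * r.value * ps.get("f_excr", k)
            * (ps.get("f_mana", k) + ps.get("f_liq", k) + ps.get("f_sol", k)))
    for r in panel.crop_production.itertuples():
        if r.crop not in dims.RESIDUE_CROPS:
            continue
        k = {"crop": r.crop}
        dry = r.value * ps.get("f_dry", k)
        nroot = dry * ps.get("f_rb", k) / ps.get("f_harv", k) \
            * ps.get("f_rbrate", k)
        nstra = dry * (1 / ps.get("f_harv", k) - 1) * ps.get("f_rbrate", k)
        residue[(r.province, r.year)] += nroot + nstra * ps.get("f_retu")
    cells: dict = defaultdict(float)
    for key in set(nfert) | set(manure) | set(residue):
        prov, year = key
        nf, ma, re = nfert[key], manure[key], residue[key]
        nitr = nf + ma + re
        direct = nitr * ps.get("ef_crla_d", {"province": prov})
        atmos = (nf * ps.get("f_fvolat") + ma * ps.get("f_ovolat")) \
            * ps.get("ef_crla_atm")
        leach = nitr * ps.get("f_leach") * ps.get("ef_crla_leach")
        cells[(prov, year, "n2o")] += (direct + atmos + leach) * 44 / 28
    return _frame(cells, like)


def machinery_oracle(panel, ps, like):
    ratio = panel.gdp_ratio.set_index(["province", "year"])["value"]
    cells: dict = defaultdict(float)
    for r in panel.energy_use.itertuples():
        share = r.value * ratio.loc[(r.province, r.year)]
        lcv = ps.get("f_lcv", {"energy": r.energy})
        if r.energy == "electricity":
            ef = ps.get("ef_elec", {"year": r.year})
        else:
            k = {"energy": r.energy}
            ef = ps.get("f_carb", k) * ps.get("f_oxid", k) * 44 / 12
        cells[(r.province, r.year, "co2")] += share * lcv * ef
    return _frame(cells, like)


def fertilizer_oracle(panel, ps, like):
    cells: dict = defaultdict(float)
    for r in panel.n_fertilizer.itertuples():
        cells[(r.province, r.year, "co2")] += r.value * ps.get("ef_fert_co2")
        cells[(r.province, r.year, "ch4")] += r.value * ps.get("ef_fert_ch4")
        cells[(r.province, r.year, "n2o")] += r.value * ps.get("ef_fert_n2o")
    return _frame(cells, like)


def pesticide_oracle(panel, ps, like):
    props = effective_component_regression(
        ps.series("f_plpest_anchor"), panel.year_range())
    scale = ps.get("f_plpest_scale")
    cells: dict = defaultdict(float)
    for r in panel.pesticide_use.itertuples():
        if r.year < PESTICIDE_START_YEAR:
            continue
        cells[(r.province, r.year, "co2eq_direct")] += (
            r.value * props.loc[r.year] * scale * ps.get("ef_pest"))
    return _frame(cells, like)


ORACLES = {
    "residue_burning": residue_burning_oracle,
    "rice": rice_oracle,
    "cropland_change": cropland_change_oracle,
    "cropland_n2o": cropland_n2o_oracle,
    "machinery": machinery_oracle,
    "fertilizer_production": fertilizer_oracle,
    "pesticide_production": pesticide_oracle,
}
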