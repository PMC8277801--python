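"""CO2 from energy use by crop-farming machinery.

Generalized-agriculture energy consumption is scaled to crop farming by
the GDP ratio of cropping to generalized agriculture, then converted to
CO2 per carrier:

    CO2 = sum_e EC_e * f_pGDP * f_LCV_e * EF_e               [kg]
    EF_e = f_carb_e * f_oxid_e * 44/12                       [kg CO2/GJ]

for the eight primary carriers (physical quantity x low calorific value
-> GJ).  Electricity bypasses the carbon-content route: its factor is a
year-indexed grid emission factor per kWh (its LCV slot is a unit
passthrough).  Only CO2 is computed; the CH4/N2O columns stay zero.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import dimensions as dims
from .arrays import PanelArrays, ParamView, emission_frame

__all__ = ["crop_energy_share", "energy_ef", "machinery_emissions"]

_ELEC_I = dims.ENERGY_CARRIERS.index("electricity")
_PRIMARY_I = [dims.ENERGY_CARRIERS.index(e) for e in dims.PRIMARY_ENERGY]


def crop_energy_share(panel) -> pd.DataFrame:
    """Energy consumption attributed to crop farming: the elementwise
    product of generalized-agriculture consumption and the GDP ratio."""
    ratio = panel.gdp_ratio.set_index(["province", "year"])["value"]
    if ((ratio.dropna() < 0) | (ratio.dropna() > 1)).any():
        raise ValueError("gdp_ratio outside [0, 1]")
    df = panel.energy_use.copy()
    keys = pd.MultiIndex.from_frame(df[["province", "year"]])
    df["value"] = df["value"].to_numpy() * ratio.reindex(keys).to_numpy()
    return df


def energy_ef(carrier: str, year: int, ps) -> float:
    """Emission factor per energy unit: kg CO2/GJ for primary carriers
    (f_carb * f_oxid * 44/12), kg CO2/kWh for electricity (year table)."""
    if carrier == "electricity":
        return ps.get("ef_elec", {"year": int(year)})
    if carrier not in dims.PRIMARY_ENERGY:
        raise KeyError(f"unknown energy carrier {carrier!r}")
    key = {"energy": carrier}
    return (ps.get("f_carb", key) * ps.get("f_oxid", key)
            * dims.MOLAR_CO2_PER_C)


def _kernel(energy: np.ndarray, gdp: np.ndarray, f_lcv: np.ndarray,
            f_carb: np.ndarray, f_oxid: np.ndarray,
            ef_elec: np.ndarray) -> np.ndarray:
    """energy (P,Y,E), gdp (P,Y) -> CO2 (P,Y) kg."""
    share = energy * gdp[..., None]
    ef_unit = np.zeros((gdp.shape[1], energy.shape[2]))  # (Y, E) kg CO2/unit
    ef_unit[:, _PRIMARY_I] = f_lcv[_PRIMARY_I] * f_carb * f_oxid \
        * dims.MOLAR_CO2_PER_C
    ef_unit[:, _ELEC_I] = f_lcv[_ELEC_I] * ef_elec
    return np.einsum("pye,ye->py", share, ef_unit)


def machinery_emissions(panel, ps) -> pd.DataFrame:
    """Province x year CO2 (kg) from machinery energy use."""
    arr = PanelArrays.from_panel(panel)
    if ((arr.gdp < 0) | (arr.gdp > 1)).any():
        raise ValueError("gdp_ratio outside [0, 1]")
    v = ParamView(ps, arr, ("f_lcv", "f_carb", "f_oxid", "ef_elec")).values()
    co2 = _kernel(arr.energy, arr.gdp, v["f_lcv"], v["f_carb"], v["f_oxid"],
                  v["ef_elec"])
    return emission_frame(arr, co2=co2)
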