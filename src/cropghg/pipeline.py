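"""End-to-end point-estimate pipeline: seven sub-models -> tensor.

``compute_tensor`` evaluates every activity on a complete panel and
stacks the (province, year, activity) x gas frame the aggregation and
uncertainty layers consume.  ``national_co2eq_kernel`` is the fast
arrays-only variant reused by the Monte-Carlo engine: it maps one
realization of all parameters to national annual CO2-eq per activity.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import dimensions as dims
from . import (cropland_change, cropland_n2o, input_production,
               machinery_energy, residue_burning, rice_cultivation)
from .aggregate_gwp import EmissionTensor
from .arrays import PanelArrays, ParamView

__all__ = ["compute_tensor", "activity_functions", "national_co2eq_kernel"]

_RESIDUE_IDX = [dims.CROPS.index(c) for c in dims.RESIDUE_CROPS]


def activity_functions() -> dict:
    """activity name -> (panel, ps) -> province x year gas frame."""
    return {
        "residue_burning": residue_burning.residue_burning_emissions,
        "rice": rice_cultivation.rice_emissions,
        "cropland_change": cropland_change.cropland_change_emissions,
        "cropland_n2o": cropland_n2o.cropland_n2o_emissions,
        "machinery": machinery_energy.machinery_emissions,
        "fertilizer_production":
            input_production.fertilizer_production_emissions,
        "pesticide_production":
            input_production.pesticide_production_emissions,
    }


def compute_tensor(panel, ps, seed: int | None = None) -> EmissionTensor:
    """Run all seven sub-models on a complete (interpolated, folded)
    panel and stack the results into an :class:`EmissionTensor`."""
    frames = []
    for activity, fn in activity_functions().items():
        frame = fn(panel, ps)
        frame = frame.copy()
        frame["activity"] = activity
        frames.append(frame.set_index("activity", append=True))
    data = pd.concat(frames).sort_index()
    meta = {
        "gwp": ps.gwp(),
        "param_digest": ps.digest(),
        "seed": seed,
        "pesticide_zero_filled_before": input_production.PESTICIDE_START_YEAR,
    }
    return EmissionTensor(data=data, metadata=meta)


def national_co2eq_kernel(arr: PanelArrays, v: dict,
                          proportions: np.ndarray) -> np.ndarray:
    """One parameter realization -> national CO2-eq (Y, 7) in kg.

    ``v`` maps parameter names to aligned arrays/scalars (a
    :meth:`ParamView.values` or :meth:`ParamView.sample` result);
    ``proportions`` is the regressed pesticide effective-component
    proportion per panel year (before the uncertainty scale).
    """
    gwp_ch4, gwp_n2o = v["gwp_ch4"], v["gwp_n2o"]
    out = np.empty((len(arr.years), len(dims.ACTIVITIES)))

    ch4, n2o = residue_burning._kernel(
        arr.prod, v["f_str"], v["f_open"], v["f_burn"],
        v["ef_crop_ch4"], v["ef_crop_n2o"])
    out[:, 0] = (gwp_ch4 * ch4 + gwp_n2o * n2o).sum(axis=0)

    ch4 = rice_cultivation._kernel(arr.rice, v["f_length"], v["ef_rice"],
                                   v["f_regime_weight"])
    out[:, 1] = gwp_ch4 * ch4.sum(axis=0)

    co2 = cropland_change._kernel(arr.dca, arr.years, v["f_bio"], v["f_soil"],
                                  v["soc_cropland_1980"],
                                  v["soc_change_rate"])
    out[:, 2] = co2.sum(axis=0)

    manu = cropland_n2o._manure_kernel(arr.pop, v["f_enn"], v["f_excr"],
                                       v["f_mana"], v["f_liq"], v["f_sol"])
    rcrop = cropland_n2o._residue_kernel(
        arr.prod[:, :, _RESIDUE_IDX], v["f_dry"], v["f_rb"], v["f_harv"],
        v["f_rbrate"], v["f_retu"])
    nitr = arr.nfert + manu + rcrop
    n2o = cropland_n2o._direct_kernel(nitr, v["ef_crla_d"]) \
        + cropland_n2o._indirect_kernel(arr.nfert, manu, nitr, v["f_fvolat"],
                                        v["f_ovolat"], v["ef_crla_atm"],
                                        v["f_leach"], v["ef_crla_leach"])
    out[:, 3] = gwp_n2o * n2o.sum(axis=0)

    co2 = machinery_energy._kernel(arr.energy, arr.gdp, v["f_lcv"],
                                   v["f_carb"], v["f_oxid"], v["ef_elec"])
    out[:, 4] = co2.sum(axis=0)

    fert_eq = arr.nfert * (v["ef_fert_co2"] + gwp_ch4 * v["ef_fert_ch4"]
                           + gwp_n2o * v["ef_fert_n2o"])
    out[:, 5] = fert_eq.sum(axis=0)

    mask = arr.years >= input_production.PESTICIDE_START_YEAR
    pest = arr.pest * (proportions * mask) * v["ef_pest"] * v["f_plpest_scale"]
    out[:, 6] = pest.sum(axis=0)
    return out
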