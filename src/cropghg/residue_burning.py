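"""CH4 and N2O from crop residue open burning.

Per province and year the burned dry residue mass is

    B = (sum_s Prod_s * f_str_s) * f_open * f_burn          [kg]

with Prod the production of the 13 crop types, f_str the straw-to-grain
ratio, f_open the provincial open-burning ratio and f_burn the burning
efficiency.  CH4 = B * EF_CROP(CH4), N2O = B * EF_CROP(N2O) (emission
factors published in g/kg burned, converted to kg here).  CO2 is booked
as zero: carbon released in the fire was fixed from the atmosphere by
the same crop, so the burn is CO2-neutral.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .arrays import PanelArrays, ParamView, emission_frame

__all__ = ["residue_burning_emissions"]

_PARAMS = ("f_str", "f_open", "f_burn", "ef_crop_ch4", "ef_crop_n2o")

_G_PER_KG = 1e-3  # EF_CROP is published per-gram of gas


def _kernel(prod: np.ndarray, f_str: np.ndarray, f_open: np.ndarray,
            f_burn: float, ef_ch4: float, ef_n2o: float):
    """prod (P,Y,S) kg -> (ch4, n2o) each (P,Y) kg."""
    burned = (prod @ f_str) * np.asarray(f_open)[..., None] * f_burn
    return burned * ef_ch4 * _G_PER_KG, burned * ef_n2o * _G_PER_KG


def residue_burning_emissions(panel, ps) -> pd.DataFrame:
    """Province x year gas emissions (kg) from open residue burning.

    Requires a complete (post-interpolation) crop-production panel;
    crops absent from a province contribute zero.
    """
    arr = PanelArrays.from_panel(panel)
    v = ParamView(ps, arr, _PARAMS).values()
    ch4, n2o = _kernel(arr.prod, v["f_str"], v["f_open"], v["f_burn"],
                       v["ef_crop_ch4"], v["ef_crop_n2o"])
    return emission_frame(arr, ch4=ch4, n2o=n2o)
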