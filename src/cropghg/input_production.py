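"""Secondary emissions embodied in producing nitrogen fertilizer and
pesticides.

Fertilizer production emits all three gases per kg of effective-
component N applied (CO2 6.08, CH4 0.02, N2O 0.0009 kg/kg N by
default).  Pesticide production is denominated directly in CO2-eq per
kg of effective component:

    E_PEST = Pest * f_plPest(year) * EF_PEST                 [kg CO2-eq]

where the effective-component proportion f_plPest is observed for
2010-2014 and extended to other years by an ordinary-least-squares
regression of the proportion on calendar year (predictions clamped to
[0, 1]; the anchor years also take the fitted values).  Pesticide-use
statistics begin in 1990, so no pesticide-production emissions are
booked before 1990.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .arrays import PanelArrays, ParamView, emission_frame

__all__ = [
    "fertilizer_production_emissions",
    "effective_component_regression",
    "pesticide_proportions",
    "pesticide_production_emissions",
    "PESTICIDE_START_YEAR",
]

PESTICIDE_START_YEAR = 1990


def fertilizer_production_emissions(panel, ps) -> pd.DataFrame:
    """Province x year (CO2, CH4, N2O) in kg from N-fertilizer production."""
    arr = PanelArrays.from_panel(panel)
    v = ParamView(ps, arr, ("ef_fert_co2", "ef_fert_ch4",
                            "ef_fert_n2o")).values()
    return emission_frame(arr,
                          co2=arr.nfert * v["ef_fert_co2"],
                          ch4=arr.nfert * v["ef_fert_ch4"],
                          n2o=arr.nfert * v["ef_fert_n2o"])


def effective_component_regression(points: Mapping[int, float] | pd.Series,
                                   target_years) -> pd.Series:
    """OLS of the effective-component proportion on calendar year.

    Returns fitted/predicted proportions for ``target_years``, clamped
    to [0, 1]; anchor years get fitted (not raw) values.  Needs at least
    two anchor points at distinct years.
    """
    s = pd.Series(dict(points)) if not isinstance(points, pd.Series) else points
    years = s.index.to_numpy(dtype=float)
    props = s.to_numpy(dtype=float)
    if len(s) < 2:
        raise ValueError("regression needs at least 2 anchor points")
    if len(np.unique(years)) < 2:
        raise ValueError("anchor years must be distinct")
    center = years.mean()  # center the covariate for conditioning
    slope, intercept = np.polyfit(years - center, props, 1)
    target_years = [int(y) for y in target_years]
    pred = slope * (np.asarray(target_years, dtype=float) - center) + intercept
    return pd.Series(np.clip(pred, 0.0, 1.0), index=target_years,
                     name="f_plpest")


def pesticide_proportions(ps, years) -> pd.Series:
    """Regressed effective-component proportion for the given years,
    scaled by the (normally unity) f_plpest_scale uncertainty knob."""
    anchors = ps.series("f_plpest_anchor")
    scale = ps.get("f_plpest_scale")
    return effective_component_regression(anchors, years) * scale


def pesticide_production_emissions(panel, ps,
                                   proportions: pd.Series | None = None,
                                   pre_start: str = "zero") -> pd.DataFrame:
    """Province x year pesticide-production emissions (kg CO2-eq).

    The factor is already CO2-eq-denominated, so the result lives in the
    ``co2eq_direct`` column with no gas split.  Years before 1990 are
    zero-filled when ``pre_start="zero"`` (flagged in the frame's attrs)
    or rejected when ``pre_start="error"``.
    """
    arr = PanelArrays.from_panel(panel)
    years = [int(y) for y in arr.years]
    if proportions is None:
        proportions = pesticide_proportions(ps, years)
    prop = proportions.reindex(years)
    if prop.isna().any():
        raise ValueError("proportions do not cover all panel years")
    ef = ParamView(ps, arr, ("ef_pest",)).value("ef_pest")
    mask = np.asarray(years) >= PESTICIDE_START_YEAR
    if pre_start == "error" and not mask.all():
        raise ValueError(
            f"pesticide emissions are only defined from {PESTICIDE_START_YEAR}")
    co2eq = arr.pest * prop.to_numpy() * ef * mask
    out = emission_frame(arr, co2eq_direct=co2eq)
    out.attrs["pesticide_zero_filled_before"] = PESTICIDE_START_YEAR
    return out
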