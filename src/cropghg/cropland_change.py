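"""CO2 source/sink from land conversion to and from cropland.

Snapshot land-use maps give conversion areas per interval; these are
annualized as the interval mean (10- or 5-year), with 1978-1979 carrying
the 1980 rate and 2015-2016 carrying the 2014 rate.  Each conversion is
booked in full in its year (committed-emissions convention):

    CO2 = sum_l dCA_l * EF_LAND(l, year) * 1000 * 44/12      [kg]
    EF_LAND(old->new, y) = C_old(y) - C_new(y)               [t C/ha]

where C is biomass + soil carbon of the land class.  Cropland soil
carbon follows an annually updated trajectory anchored at the 1980
density with published annual change rates for 1980-2009 (edge years
held at the nearest rate); all other pools are constant in time.
Positive EF means net carbon release; cropland gaining carbon-dense
classes (e.g. conversion to forest) yields negative emissions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import dimensions as dims
from .arrays import PanelArrays, ParamView, emission_frame

__all__ = [
    "CarbonPoolTable",
    "soc_trajectory",
    "annualize_transitions",
    "landchange_ef",
    "landchange_emissions",
    "cropland_change_emissions",
]

_KG_PER_T = 1000.0


def soc_trajectory(soc_1980: float, rates: pd.Series,
                   years=None) -> pd.Series:
    """Cropland soil-organic-carbon density per year (t C/ha).

    ``rates`` maps year -> annual change (t C/ha/yr) covering 1980-2009;
    1978-1979 reuse the 1980 rate and years past the last rate reuse the
    final one.  SOC(y) = SOC(y-1) + rate(y), anchored at SOC(1980).
    """
    if years is None:
        years = dims.YEARS
    years = [int(y) for y in years]
    rates = rates.astype(float).sort_index()
    first_rate_year, last_rate_year = int(rates.index[0]), int(rates.index[-1])
    out = {1980: float(soc_1980)}

    def rate(y: int) -> float:
        y = min(max(y, first_rate_year), last_rate_year)
        return float(rates.loc[y])

    for y in range(1981, max(max(years), 1980) + 1):
        out[y] = out[y - 1] + rate(y)
    for y in range(1979, min(min(years), 1980) - 1, -1):
        out[y] = out[y + 1] - rate(y)
    return pd.Series({y: out[y] for y in years}, name="soc_cropland")


def annualize_transitions(transitions: pd.DataFrame, years=None) -> pd.DataFrame:
    """Interval conversion areas -> annual areas (ha/yr), long format.

    Each interval's area is divided by its length and assigned to years
    (start, end]; years before the first interval take the first rate
    and years after the last take the last (so 2015-2016 equal the 2014
    value).  Overlapping intervals for one (province, change_type) are
    an error.
    """
    if years is None:
        years = dims.YEARS
    years = np.asarray(sorted(int(y) for y in years))
    cols = ["province", "interval_start", "interval_end", "change_type"]
    out = []
    for (prov, ctype), sub in transitions.groupby(["province", "change_type"],
                                                  observed=True, sort=False):
        sub = sub.sort_values("interval_start")
        starts = sub["interval_start"].to_numpy(dtype=int)
        ends = sub["interval_end"].to_numpy(dtype=int)
        if (ends <= starts).any():
            raise ValueError(f"{prov}/{ctype}: empty or inverted interval")
        if (starts[1:] < ends[:-1]).any():
            raise ValueError(f"{prov}/{ctype}: overlapping intervals")
        rates = sub["value"].to_numpy(dtype=float) / (ends - starts)
        # year y takes the rate of the interval with start < y <= end;
        # outside the covered span the nearest rate is held constant.
        pos = np.searchsorted(ends, years, side="left")
        pos = np.clip(pos, 0, len(rates) - 1)
        annual = rates[pos]
        out.append(pd.DataFrame({
            "province": prov, "year": years, "change_type": ctype,
            "value": annual,
        }))
    if not out:
        return pd.DataFrame(columns=["province", "year", "change_type", "value"])
    return pd.concat(out, ignore_index=True)


@dataclass
class CarbonPoolTable:
    """Biomass and soil carbon densities (t C/ha) per land class, with
    cropland soil as a year-indexed series."""

    biomass: pd.Series  # land_class -> t C/ha
    soil: pd.Series  # land_class -> t C/ha (cropland entry unused)
    cropland_soc: pd.Series  # year -> t C/ha

    @classmethod
    def from_params(cls, ps, years=None) -> "CarbonPoolTable":
        soc = soc_trajectory(ps.get("soc_cropland_1980"),
                             ps.series("soc_change_rate"), years=years)
        return cls(biomass=ps.series("f_bio"), soil=ps.series("f_soil"),
                   cropland_soc=soc)

    def total(self, land_class: str, year: int) -> float:
        if land_class not in self.biomass.index:
            raise KeyError(f"unknown land class {land_class!r}")
        bio = float(self.biomass.loc[land_class])
        if land_class == "cropland":
            return bio + float(self.cropland_soc.loc[int(year)])
        return bio + float(self.soil.loc[land_class])


def _split_change_type(change_type: str) -> tuple[str, str]:
    for old in dims.LAND_CLASSES:
        prefix = old + "_to_"
        if change_type.startswith(prefix):
            return old, change_type[len(prefix):]
    raise KeyError(f"unknown change type {change_type!r}")


def landchange_ef(change_type: str, year: int,
                  pools: CarbonPoolTable) -> float:
    """Carbon flux density of one conversion (t C/ha, positive = release):
    carbon stock of the old class minus the new class in that year."""
    old, new = _split_change_type(change_type)
    return pools.total(old, year) - pools.total(new, year)


def _ef_matrix(years: np.ndarray, f_bio: np.ndarray, f_soil: np.ndarray,
               soc: np.ndarray) -> np.ndarray:
    """(Y, L) EF in t C/ha from aligned pool arrays; ``soc`` is the
    cropland SOC trajectory over ``years``."""
    classes = dims.LAND_CLASSES
    crop_i = classes.index("cropland")
    totals = np.broadcast_to(f_bio + f_soil, (len(years), len(classes))).copy()
    totals[:, crop_i] = f_bio[crop_i] + soc
    ef = np.empty((len(years), len(dims.CHANGE_TYPES)))
    for l, ctype in enumerate(dims.CHANGE_TYPES):
        old, new = _split_change_type(ctype)
        ef[:, l] = totals[:, classes.index(old)] - totals[:, classes.index(new)]
    return ef


def _soc_offsets(years: np.ndarray, soc_rates: np.ndarray) -> np.ndarray:
    """Cumulative SOC change relative to the 1980 anchor, per year."""
    years = np.asarray(years, dtype=int)
    n = len(soc_rates)
    lo = min(int(years.min()), 1980)
    hi = max(int(years.max()), 1980)
    span = np.arange(lo, hi + 1)
    r = soc_rates[np.clip(span - 1980, 0, n - 1)]
    cum = np.concatenate([[0.0], np.cumsum(r[1:])])
    return cum[years - lo] - cum[1980 - lo]


# +1 where cropland is the source class of the conversion, -1 where it
# is the destination; the counterpart class index per change type.
_SIGN = np.array([1.0 if ct.startswith("cropland_to_") else -1.0
                  for ct in dims.CHANGE_TYPES])
_OTHER_IDX = np.array([
    dims.LAND_CLASSES.index(
        ct.removeprefix("cropland_to_") if ct.startswith("cropland_to_")
        else ct[: -len("_to_cropland")])
    for ct in dims.CHANGE_TYPES])
_CROP_I = dims.LAND_CLASSES.index("cropland")


def _kernel(dca: np.ndarray, years: np.ndarray, f_bio: np.ndarray,
            f_soil: np.ndarray, soc_1980, soc_rates: np.ndarray) -> np.ndarray:
    """dca (P,Y,L) ha/yr -> CO2 (P,Y) kg (sign carries source/sink).

    Every change type pairs cropland with one counterpart class, so the
    flux splits into a cropland-stock term (year-dependent through the
    SOC trajectory; ``soc_1980`` may be a per-province array) and a
    constant counterpart-stock term.
    """
    crop_total = f_bio[_CROP_I] + soc_1980 + _soc_offsets(years, soc_rates)
    c_other = f_bio[_OTHER_IDX] + f_soil[_OTHER_IDX]
    term_crop = (dca * _SIGN).sum(axis=-1) * crop_total
    term_other = dca @ (_SIGN * c_other)
    return (term_crop - term_other) * _KG_PER_T * dims.MOLAR_CO2_PER_C


def landchange_emissions(annual_areas: pd.DataFrame,
                         pools: CarbonPoolTable) -> pd.DataFrame:
    """Annualized areas (province, year, change_type, value in ha/yr) ->
    (province, year) frame of CO2 (kg); CH4 = N2O = 0."""
    df = annual_areas.copy()
    efs = {(ct, y): landchange_ef(ct, y, pools)
           for ct in df["change_type"].unique()
           for y in df["year"].unique()}
    df["co2"] = [
        v * efs[(ct, y)] * _KG_PER_T * dims.MOLAR_CO2_PER_C
        for v, ct, y in zip(df["value"], df["change_type"], df["year"])
    ]
    out = df.groupby(["province", "year"], observed=True)["co2"].sum()
    out.index.names = ["province", "year"]
    frame = pd.DataFrame(0.0, index=out.index, columns=dims.GAS_COLUMNS)
    frame["co2"] = out
    return frame


def cropland_change_emissions(panel, ps) -> pd.DataFrame:
    """Province x year CO2 (kg) from cropland change on a full panel."""
    arr = PanelArrays.from_panel(panel)
    v = ParamView(ps, arr, ("f_bio", "f_soil", "soc_cropland_1980",
                            "soc_change_rate")).values()
    co2 = _kernel(arr.dca, arr.years, v["f_bio"], v["f_soil"],
                  v["soc_cropland_1980"], v["soc_change_rate"])
    return emission_frame(arr, co2=co2)
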