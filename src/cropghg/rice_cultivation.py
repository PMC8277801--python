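"""CH4 from rice paddies.

    CH4 = sum_r RA_r * f_length_r * EF_RICE_r                [kg]

RA is the cultivated area of the three rice types (early, pooled
middle & single-late, double-late), f_length the growing-period length
in days, and EF_RICE (kg CH4/ha/day) a weighted mean over four
water/organic-input regimes: half the area is assumed to receive
organic input, one third to be continuously flooded and two thirds
intermittently irrigated, giving weights 1/6, 1/3, 1/6, 1/3 on the
(F&CI, F&SI, NF&CI, NF&SI) emission-factor quadruple.

Source EF tables distinguish middle from single-late rice; agro-
ecological-zone substitution rules map them onto the three model types
(zone 6A provinces take the mean of middle and single-late; zone 6B
provinces reuse the middle-rice factors for early and double-late).
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd

from . import dimensions as dims
from .arrays import PanelArrays, ParamView, emission_frame

__all__ = [
    "RiceEFQuad",
    "combine_rice_ef",
    "build_rice_ef_table",
    "rice_emissions",
]

# (organic-input share, flooding share) -> regime weights; sums to 1.
REGIME_WEIGHTS: dict[str, float] = {
    "f_ci": 0.5 * (1 / 3),
    "f_si": 0.5 * (2 / 3),
    "nf_ci": 0.5 * (1 / 3),
    "nf_si": 0.5 * (2 / 3),
}


class RiceEFQuad(NamedTuple):
    """Paddy CH4 emission rates (per area per day) for the four
    water/organic-input regimes."""

    ef_f_ci: float
    ef_f_si: float
    ef_nf_ci: float
    ef_nf_si: float


def combine_rice_ef(q: RiceEFQuad) -> float:
    """Regime-weighted mean: 1/2 (1/3 q.F&CI + 2/3 q.F&SI + 1/3 q.NF&CI
    + 2/3 q.NF&SI)."""
    if any(v < 0 for v in q):
        raise ValueError("rice EF quadruple must be non-negative")
    return 0.5 * ((1 / 3) * q.ef_f_ci + (2 / 3) * q.ef_f_si
                  + (1 / 3) * q.ef_nf_ci + (2 / 3) * q.ef_nf_si)


def build_rice_ef_table(base: pd.Series) -> pd.Series:
    """Map source EF quads (province, source_type, regime) onto the model
    rice types, applying the AEZ substitution rules.

    * default: early <- early, middle_single_late <- middle,
      double_late <- double_late;
    * zone 6A provinces: middle_single_late <- mean(middle, single_late);
    * zone 6B provinces: early and double_late <- middle.

    Provinces in neither zone pass through unchanged.
    """
    if base.index.nlevels != 3:
        raise ValueError("base table must be keyed (province, source_type, regime)")
    out: dict[tuple, float] = {}
    provinces = base.index.get_level_values(0).unique()
    for p in provinces:
        sub = base.xs(p, level=0)

        def src(stype: str, regime: str) -> float:
            try:
                return float(sub.loc[(stype, regime)])
            except KeyError as exc:
                raise KeyError(
                    f"rice EF table: province {p!r} missing source entry "
                    f"({stype}, {regime})") from exc

        for w in dims.RICE_REGIMES:
            early = src("early", w)
            mid = src("middle", w)
            late = src("double_late", w)
            pooled = mid
            if p in dims.AEZ_6A_PROVINCES:
                pooled = 0.5 * (mid + src("single_late", w))
            if p in dims.AEZ_6B_PROVINCES:
                early = mid
                late = mid
            out[(p, "early", w)] = early
            out[(p, "middle_single_late", w)] = pooled
            out[(p, "double_late", w)] = late
    idx = pd.MultiIndex.from_tuples(out, names=["province", "rice_type", "regime"])
    return pd.Series(out.values(), index=idx, name="ef_rice", dtype=float)


def _kernel(rice: np.ndarray, f_length: np.ndarray, ef_rice: np.ndarray,
            weights: np.ndarray) -> np.ndarray:
    """rice (P,Y,R) ha -> CH4 (P,Y) kg."""
    ef = ef_rice @ weights  # (P, R)
    return np.einsum("pyr,pr->py", rice, f_length * ef)


def rice_emissions(panel, ps) -> pd.DataFrame:
    """Province x year CH4 (kg) from rice cultivation; CO2 = N2O = 0."""
    arr = PanelArrays.from_panel(panel)
    pv = ParamView(ps, arr, ("f_length", "ef_rice", "f_regime_weight"))
    v = pv.values()
    area_pr = arr.rice.sum(axis=1)  # (P, R)
    for name in ("f_length", "ef_rice"):
        miss = pv.missing_mask(name)
        if miss is None or not miss.any():
            continue
        while miss.ndim > 2:  # collapse the regime axis of ef_rice
            miss = miss.any(axis=-1)
        bad = miss & (area_pr > 0)
        if bad.any():
            p_i, r_i = np.argwhere(bad)[0]
            raise KeyError(
                f"missing {name} for province {arr.provinces[p_i]!r}, "
                f"rice type {dims.RICE_TYPES[r_i]!r} with nonzero area")
    ch4 = _kernel(arr.rice, v["f_length"], v["ef_rice"], v["f_regime_weight"])
    return emission_frame(arr, ch4=ch4)
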