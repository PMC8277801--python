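"""Direct and indirect N2O from cropland (regional nitrogen-budget
accounting in the IAP-N tradition plus IPCC Tier-1 indirect pathways).

The provincial nitrogen input is

    Nitr = NFert + Manu + RCrop                              [kg N]

with synthetic-fertilizer N taken from statistics, manure N from the
six excreta-producing classes,

    Manu = (1 - f_enn) * sum_a Amou_a * f_excr_a
                         * (f_mana_a + f_liq_a + f_sol_a),

and residue N from the 11 residue-relevant crops,

    NRoot_s = Prod_s * f_dry_s * (f_rb_s / f_harv_s) * f_rbrate_s
    NStra_s = Prod_s * f_dry_s * (1 / f_harv_s - 1) * f_rbrate_s
    RCrop   = sum_s (NRoot_s + NStra_s * f_retu).

Direct emission: N2O = Nitr * EF_CRLA,d * 44/28 with a provincial
direct emission factor.  Indirect emission combines redeposition of
volatilized N (fertilizer fraction f_Fvolat, organic fraction f_Ovolat,
factor EF_CRLA,atm) and leaching/runoff (fraction f_leach, factor
EF_CRLA,leach); both pathways are in N2O-N and converted by 44/28.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import dimensions as dims
from .arrays import PanelArrays, ParamView

__all__ = [
    "NitrogenBudget",
    "residue_nitrogen",
    "manure_nitrogen",
    "nitrogen_budget",
    "direct_n2o",
    "indirect_n2o",
    "cropland_n2o_emissions",
]

_RESIDUE_IDX = [dims.CROPS.index(c) for c in dims.RESIDUE_CROPS]


@dataclass
class NitrogenBudget:
    """Province x year nitrogen inputs to cropland (kg N)."""

    n_fert: pd.Series
    manure: pd.Series
    residue: pd.Series

    def __post_init__(self) -> None:
        for name in ("n_fert", "manure", "residue"):
            s = getattr(self, name)
            if (s.dropna() < 0).any():
                raise ValueError(f"nitrogen budget: negative {name} component")

    @property
    def total(self) -> pd.Series:
        return (self.n_fert + self.manure + self.residue).rename("nitr")


def _residue_kernel(prod11: np.ndarray, f_dry, f_rb, f_harv, f_rbrate,
                    f_retu) -> np.ndarray:
    """prod11 (P,Y,11) kg -> residue N (P,Y) kg."""
    if np.any(f_harv == 0):
        raise ZeroDivisionError("harvest index f_harv must be nonzero")
    nroot = f_dry * (f_rb / f_harv) * f_rbrate
    nstra = f_dry * (1.0 / f_harv - 1.0) * f_rbrate
    coef = nroot + nstra * f_retu
    if coef.ndim == 1:
        return prod11 @ coef
    # per-province f_retu draws broadcast the coefficients to (P, crops)
    return np.einsum("pys,ps->py", prod11, coef)


def _manure_kernel(pop: np.ndarray, f_enn, f_excr, f_mana, f_liq,
                   f_sol) -> np.ndarray:
    """pop (P,Y,A) head -> manure N applied to cropland (P,Y) kg."""
    part = f_mana + f_liq + f_sol
    if np.any(part > 1.0 + 1e-12):
        raise ValueError("manure partition fractions sum above 1 for a class")
    return (1.0 - f_enn) * (pop @ (f_excr * part))


def _direct_kernel(nitr: np.ndarray, ef_d: np.ndarray) -> np.ndarray:
    return nitr * np.asarray(ef_d)[..., None] * dims.MOLAR_N2O_PER_N


def _indirect_kernel(nfert, manu, nitr, f_fvolat, f_ovolat, ef_atm,
                     f_leach, ef_leach) -> np.ndarray:
    atmos = (nfert * f_fvolat + manu * f_ovolat) * ef_atm
    leach = nitr * f_leach * ef_leach
    return (atmos + leach) * dims.MOLAR_N2O_PER_N


_RES_PARAMS = ("f_dry", "f_rb", "f_harv", "f_rbrate", "f_retu")
_MAN_PARAMS = ("f_enn", "f_excr", "f_mana", "f_liq", "f_sol")
_IND_PARAMS = ("f_fvolat", "f_ovolat", "ef_crla_atm", "f_leach",
               "ef_crla_leach")


def residue_nitrogen(panel, ps, crops=None) -> pd.Series:
    """Province x year crop-residue N returned to cropland (kg N).

    ``crops`` defaults to the 13 burning crops minus fiber and tobacco.
    """
    arr = PanelArrays.from_panel(panel)
    v = ParamView(ps, arr, _RES_PARAMS).values()
    idx = (_RESIDUE_IDX if crops is None
           else [dims.CROPS.index(c) for c in crops])
    if crops is not None:
        sel = [dims.RESIDUE_CROPS.index(c) for c in crops]
        v = {**v, **{k: v[k][sel] for k in ("f_dry", "f_rb", "f_harv",
                                            "f_rbrate")}}
    res = _residue_kernel(arr.prod[:, :, idx], v["f_dry"], v["f_rb"],
                          v["f_harv"], v["f_rbrate"], v["f_retu"])
    return pd.Series(res.reshape(-1), index=arr.index, name="residue_n")


def manure_nitrogen(panel, ps) -> pd.Series:
    """Province x year manure N applied to cropland (kg N)."""
    arr = PanelArrays.from_panel(panel)
    v = ParamView(ps, arr, _MAN_PARAMS).values()
    man = _manure_kernel(arr.pop, v["f_enn"], v["f_excr"], v["f_mana"],
                         v["f_liq"], v["f_sol"])
    return pd.Series(man.reshape(-1), index=arr.index, name="manure_n")


def nitrogen_budget(panel, ps) -> NitrogenBudget:
    arr = PanelArrays.from_panel(panel)
    nfert = pd.Series(arr.nfert.reshape(-1), index=arr.index, name="n_fert")
    return NitrogenBudget(n_fert=nfert, manure=manure_nitrogen(panel, ps),
                          residue=residue_nitrogen(panel, ps))


def _budget_frame(budget: NitrogenBudget) -> pd.DataFrame:
    df = pd.concat([budget.n_fert.rename("n_fert"),
                    budget.manure.rename("manure"),
                    budget.residue.rename("residue")], axis=1)
    if df.isna().any().any():
        raise ValueError("nitrogen budget components are misaligned")
    return df


def direct_n2o(budget: NitrogenBudget, ps) -> pd.DataFrame:
    """Direct cropland N2O (kg) from the total N input, provincial EF."""
    df = _budget_frame(budget)
    nitr = df.sum(axis=1)
    provinces = nitr.index.get_level_values("province")
    ef = ps.series("ef_crla_d").reindex(provinces)
    if ef.isna().any():
        missing = sorted(set(provinces[ef.isna().to_numpy()]))
        raise KeyError(f"missing ef_crla_d for provinces {missing}")
    n2o = nitr.to_numpy() * ef.to_numpy() * dims.MOLAR_N2O_PER_N
    out = pd.DataFrame(0.0, index=nitr.index, columns=dims.GAS_COLUMNS)
    out["n2o"] = n2o
    return out


def indirect_n2o(budget: NitrogenBudget, ps) -> pd.DataFrame:
    """Indirect cropland N2O (kg): volatilization redeposition + leaching."""
    df = _budget_frame(budget)
    v = {n: ps.get(n) for n in _IND_PARAMS}
    n2o = _indirect_kernel(df["n_fert"].to_numpy(), df["manure"].to_numpy(),
                           df.sum(axis=1).to_numpy(), v["f_fvolat"],
                           v["f_ovolat"], v["ef_crla_atm"], v["f_leach"],
                           v["ef_crla_leach"])
    out = pd.DataFrame(0.0, index=df.index, columns=dims.GAS_COLUMNS)
    out["n2o"] = n2o
    return out


def cropland_n2o_emissions(panel, ps) -> pd.DataFrame:
    """Province x year direct + indirect cropland N2O (kg)."""
    budget = nitrogen_budget(panel, ps)
    return direct_n2o(budget, ps) + indirect_n2o(budget, ps)
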