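"""Dense-array views of panels and parameters.

The seven sub-models are linear bookkeeping over province x year grids,
so both the point-estimate path and the 50,000-draw Monte-Carlo loop run
on plain numpy arrays.  :class:`PanelArrays` pivots a complete activity
panel once; :class:`ParamView` aligns every parameter table to those
axes once (integer position maps), after which a fresh joint draw of all
parameters costs microseconds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import dimensions as dims

__all__ = ["PanelArrays", "ParamView", "emission_frame", "ALIGNMENTS"]

_SOC_YEARS = list(range(1980, 2010))

# parameter name -> dimension names its aligned array is laid out over.
# () = scalar; "self" = keep the spec's own index order.
ALIGNMENTS: dict[str, tuple[str, ...]] = {
    "f_str": ("crop",), "f_open": ("province",), "f_burn": (),
    "ef_crop_ch4": (), "ef_crop_n2o": (),
    "f_length": ("province", "rice_type"),
    "ef_rice": ("province", "rice_type", "regime"),
    "f_regime_weight": ("regime",),
    "f_bio": ("land_class",), "f_soil": ("land_class",),
    "soc_cropland_1980": (), "soc_change_rate": ("soc_year",),
    "f_enn": (), "f_excr": ("creature",), "f_mana": ("creature",),
    "f_liq": ("creature",), "f_sol": ("creature",),
    "f_retu": (), "f_dry": ("residue_crop",), "f_rb": ("residue_crop",),
    "f_harv": ("residue_crop",), "f_rbrate": ("residue_crop",),
    "ef_crla_d": ("province",), "f_fvolat": (), "f_ovolat": (),
    "ef_crla_atm": (), "f_leach": (), "ef_crla_leach": (),
    "f_lcv": ("energy",), "f_carb": ("primary_energy",),
    "f_oxid": ("primary_energy",), "ef_elec": ("year",),
    "ef_fert_co2": (), "ef_fert_ch4": (), "ef_fert_n2o": (),
    "f_plpest_anchor": ("self",), "f_plpest_scale": (), "ef_pest": (),
    "gwp_ch4": (), "gwp_n2o": (),
}


@dataclass
class PanelArrays:
    """Complete panel pivoted to dense arrays with shared axis order."""

    provinces: list[str]
    years: np.ndarray  # (Y,) ints
    prod: np.ndarray  # (P, Y, n_crops) kg
    rice: np.ndarray  # (P, Y, n_rice_types) ha
    dca: np.ndarray  # (P, Y, n_change_types) ha/yr, annualized
    pop: np.ndarray  # (P, Y, n_creatures) head
    nfert: np.ndarray  # (P, Y) kg N
    pest: np.ndarray  # (P, Y) kg
    energy: np.ndarray  # (P, Y, n_carriers) physical units
    gdp: np.ndarray  # (P, Y) fraction

    @property
    def index(self) -> pd.MultiIndex:
        return pd.MultiIndex.from_product(
            [self.provinces, self.years], names=["province", "year"])

    @classmethod
    def from_panel(cls, panel) -> "PanelArrays":
        provinces = panel.provinces()
        years = np.asarray(panel.year_range(), dtype=int)
        p_idx = {p: i for i, p in enumerate(provinces)}
        y_idx = {int(y): i for i, y in enumerate(years)}

        def grid(df: pd.DataFrame, key: str | None,
                 labels: Sequence[str] | None, name: str) -> np.ndarray:
            if df["value"].isna().any():
                raise ValueError(
                    f"{name}: panel has missing cells; run interpolate_gaps first")
            shape = (len(provinces), len(years)) + ((len(labels),) if key else ())
            out = np.zeros(shape)
            pi = df["province"].map(p_idx).to_numpy()
            yi = df["year"].map(y_idx).to_numpy()
            if np.isnan(pi.astype(float)).any() or np.isnan(yi.astype(float)).any():
                raise ValueError(f"{name}: province/year outside the panel grid")
            if key:
                k_idx = {k: i for i, k in enumerate(labels)}
                ki = df[key].map(k_idx).to_numpy()
                out[pi, yi, ki] = df["value"].to_numpy(dtype=float)
            else:
                out[pi, yi] = df["value"].to_numpy(dtype=float)
            return out

        from .cropland_change import annualize_transitions

        annual = annualize_transitions(panel.land_transitions, years=years)
        return cls(
            provinces=provinces,
            years=years,
            prod=grid(panel.crop_production, "crop", dims.CROPS, "crop_production"),
            rice=grid(panel.rice_area, "rice_type", dims.RICE_TYPES, "rice_area"),
            dca=grid(annual, "change_type", dims.CHANGE_TYPES, "land_transitions"),
            pop=grid(panel.populations, "creature", dims.CREATURES, "populations"),
            nfert=grid(panel.n_fertilizer, None, None, "n_fertilizer"),
            pest=grid(panel.pesticide_use, None, None, "pesticide_use"),
            energy=grid(panel.energy_use, "energy", dims.ENERGY_CARRIERS,
                        "energy_use"),
            gdp=grid(panel.gdp_ratio, None, None, "gdp_ratio"),
        )

    def dim_labels(self, dim: str) -> list:
        return {
            "province": list(self.provinces),
            "year": [int(y) for y in self.years],
            "crop": dims.CROPS,
            "residue_crop": dims.RESIDUE_CROPS,
            "rice_type": dims.RICE_TYPES,
            "regime": dims.RICE_REGIMES,
            "creature": dims.CREATURES,
            "energy": dims.ENERGY_CARRIERS,
            "primary_energy": dims.PRIMARY_ENERGY,
            "land_class": dims.LAND_CLASSES,
            "soc_year": _SOC_YEARS,
        }[dim]


class _Aligned:
    """One parameter pre-aligned to panel axes, ready for fast draws."""

    __slots__ = ("name", "base", "pos", "shape", "dist", "cv", "a", "b",
                 "missing")

    def __init__(self, spec, arr: PanelArrays,
                 fill_missing: float | None) -> None:
        self.name = spec.name
        self.dist, self.cv, self.a, self.b = spec.dist, spec.cv, spec.a, spec.b
        align = ALIGNMENTS[spec.name]
        self.base = spec.values_array()
        if not align:  # scalar
            self.pos, self.shape, self.missing = None, (), None
            return
        if align == ("self",):
            self.pos = np.arange(len(self.base))
            self.shape = (len(self.base),)
            self.missing = np.zeros(len(self.base), dtype=bool)
            return
        labels = [arr.dim_labels(d) for d in align]
        if len(labels) == 1:
            target = pd.Index(labels[0])
        else:
            target = pd.MultiIndex.from_product(labels)
        pos = spec.value.index.get_indexer(target)
        self.missing = pos < 0
        if self.missing.any():
            if fill_missing is None:
                missing_at = target[self.missing][:5].tolist()
                raise KeyError(
                    f"parameter {spec.name} has no entry for {missing_at}")
            # route missing entries to a sentinel slot holding the fill
            self.base = np.append(self.base, fill_missing)
            pos = np.where(self.missing, len(self.base) - 1, pos)
        self.pos = pos
        self.shape = tuple(len(l) for l in labels)

    def _align(self, entries: np.ndarray):
        if self.pos is None:
            return float(entries[0])
        return entries[self.pos].reshape(self.shape)

    def value(self):
        return self._align(self.base)

    def sample(self, rng: np.random.Generator, *, floor: bool,
               n_province: int | None = None):
        """One joint draw.  ``n_province`` draws scalar parameters
        independently per province (shape (P, 1)) instead of shared."""
        if self.dist == "fixed":
            return self.value()
        size = None
        if self.pos is None and n_province is not None:
            size = (n_province, 1)
        if self.dist == "normal":
            draw = rng.normal(self.base, np.abs(self.base) * self.cv, size=size)
        else:
            draw = rng.triangular(self.a, self.base, self.b, size=size)
        if floor:
            draw = np.maximum(draw, 0.0)
        if size is not None:
            return draw
        return self._align(draw)


class ParamView:
    """All parameters of a ParamSet aligned to one panel's axes."""

    #: tables where an absent entry is tolerated as 0 provided the
    #: matching activity is zero (checked by the sub-model wrappers)
    _FILL_ZERO = {"f_length": 0.0, "ef_rice": 0.0}

    def __init__(self, ps, arr: PanelArrays,
                 names: Iterable[str] | None = None) -> None:
        self.arr = arr
        self.floor = bool(getattr(ps, "floor_at_zero", False))
        names = list(names) if names is not None else list(ALIGNMENTS)
        self.aligned: dict[str, _Aligned] = {
            n: _Aligned(ps.spec(n), arr, self._FILL_ZERO.get(n)) for n in names
        }

    def value(self, name: str):
        return self.aligned[name].value()

    def values(self) -> dict[str, np.ndarray | float]:
        return {n: a.value() for n, a in self.aligned.items()}

    def missing_mask(self, name: str) -> np.ndarray | None:
        a = self.aligned[name]
        if a.missing is None or a.pos is None:
            return None
        return a.missing.reshape(a.shape)

    def sample(self, rng: np.random.Generator,
               *, scalars_by_province: bool = False
               ) -> dict[str, np.ndarray | float]:
        n_p = len(self.arr.provinces) if scalars_by_province else None
        return {n: a.sample(rng, floor=self.floor, n_province=n_p)
                for n, a in self.aligned.items()}


def emission_frame(arr: PanelArrays, *, co2=None, ch4=None, n2o=None,
                   co2eq_direct=None) -> pd.DataFrame:
    """(province, year)-indexed frame with the four gas columns (kg)."""
    n = len(arr.provinces) * len(arr.years)
    data = {}
    for col, val in zip(dims.GAS_COLUMNS, (co2, ch4, n2o, co2eq_direct)):
        data[col] = (np.zeros(n) if val is None
                     else np.asarray(val, dtype=float).reshape(n))
    return pd.DataFrame(data, index=arr.index)
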