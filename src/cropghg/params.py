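"""Typed registry of every constant in the inventory model.

Each parameter is a :class:`ParamSpec`: a scalar or a keyed table, its
published units, the dimension names it is indexed by, and its
uncertainty distribution (fixed, normal with a coefficient of variation,
or triangular with bounds ``a <= mode <= b``).  Values are stored in the
units they are published in; sub-models apply explicit conversions.

Main-text constants (burning efficiency, residue emission factors,
volatilization/leaching fractions, fertilizer/pesticide production
factors, GWPs, land carbon pools) are pre-filled verbatim.  Per-province
supplementary tables are not published in full; they ship as documented
placeholder defaults (``source="placeholder"``) that users replace via a
config file or keyed CSV tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Iterator, Mapping

import numpy as np
import pandas as pd
import yaml

from . import dimensions as dims

__all__ = [
    "ParamSpec",
    "ParamSet",
    "load_params",
    "get_value",
    "sample_param",
    "default_params",
    "export_param_tables",
    "REQUIRED_NAMES",
    "GWP_SETS",
]

_DISTS = ("fixed", "normal", "triangular")

# GWP weighting sets (mass CO2 per mass gas).  The 100-year horizon is
# the reporting default; the 20-year set is an alternative config.
GWP_SETS: dict[str, dict[str, float]] = {
    "100": {"ch4": 28.0, "n2o": 265.0},
    "20": {"ch4": 84.0, "n2o": 264.0},
}


@dataclass(frozen=True)
class ParamSpec:
    """One named constant: a scalar or a keyed table plus distribution."""

    name: str
    value: float | pd.Series
    units: str
    keys: tuple[str, ...] = ()
    dist: str = "fixed"
    cv: float = 0.0
    a: float | None = None
    b: float | None = None
    source: str = "main-text"

    def __post_init__(self) -> None:
        if not self.units:
            raise ValueError(f"{self.name}: units must be non-empty")
        if self.dist not in _DISTS:
            raise ValueError(f"{self.name}: unknown dist {self.dist!r}")
        if self.cv < 0:
            raise ValueError(f"{self.name}: cv must be >= 0")
        vals = self.values_array()
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"{self.name}: non-finite value")
        if self.keys and not isinstance(self.value, pd.Series):
            raise ValueError(f"{self.name}: keyed spec needs a Series value")
        if self.dist == "triangular":
            if self.a is None or self.b is None:
                raise ValueError(f"{self.name}: triangular needs a and b")
            if not np.all((self.a <= vals) & (vals <= self.b)):
                raise ValueError(f"{self.name}: requires a <= mode <= b")

    def values_array(self) -> np.ndarray:
        """Values as a flat float array (singleton for scalars)."""
        if isinstance(self.value, pd.Series):
            return self.value.to_numpy(dtype=float)
        return np.asarray([self.value], dtype=float)

    @property
    def is_keyed(self) -> bool:
        return bool(self.keys)

    def lookup(self, key_values: Mapping[str, Any] | None = None) -> float:
        """Resolve a scalar; keyed specs require exactly their keys."""
        key_values = dict(key_values or {})
        if not self.keys:
            if key_values:
                raise KeyError(f"{self.name} takes no keys, got {sorted(key_values)}")
            return float(self.value)
        if set(key_values) != set(self.keys):
            raise KeyError(
                f"{self.name} requires keys {self.keys}, got {tuple(sorted(key_values))}"
            )
        idx = tuple(key_values[k] for k in self.keys)
        if len(idx) == 1:
            idx = idx[0]
        try:
            return float(self.value.loc[idx])
        except KeyError as exc:
            raise KeyError(f"{self.name}: no entry for {idx!r}") from exc

    def sample(self, rng: np.random.Generator, *, floor_at_zero: bool = False):
        """One draw of the whole spec (scalar or full keyed table).

        fixed -> value; normal -> mean=value, sd=cv*value; triangular ->
        (a, mode=value, b).  Keyed entries are drawn independently.
        Negative normal draws are kept unless ``floor_at_zero``.
        """
        base = self.values_array()
        if self.dist == "fixed":
            draw = base.copy()
        elif self.dist == "normal":
            draw = rng.normal(base, np.abs(base) * self.cv)
        else:
            draw = rng.triangular(self.a, base, self.b)
        if floor_at_zero:
            draw = np.maximum(draw, 0.0)
        if isinstance(self.value, pd.Series):
            return pd.Series(draw, index=self.value.index, name=self.name)
        return float(draw[0])


# Every name the seven sub-models resolve from the registry.
REQUIRED_NAMES: tuple[str, ...] = (
    # residue open burning
    "f_str", "f_open", "f_burn", "ef_crop_ch4", "ef_crop_n2o",
    # rice cultivation
    "f_length", "ef_rice", "f_regime_weight",
    # cropland change
    "f_bio", "f_soil", "soc_cropland_1980", "soc_change_rate",
    # cropland N2O (direct + indirect)
    "f_enn", "f_excr", "f_mana", "f_liq", "f_sol",
    "f_retu", "f_dry", "f_rb", "f_harv", "f_rbrate",
    "ef_crla_d", "f_fvolat", "f_ovolat", "ef_crla_atm",
    "f_leach", "ef_crla_leach",
    # machinery energy
    "f_lcv", "f_carb", "f_oxid", "ef_elec",
    # input production
    "ef_fert_co2", "ef_fert_ch4", "ef_fert_n2o",
    "f_plpest_anchor", "f_plpest_scale", "ef_pest",
    # aggregation
    "gwp_ch4", "gwp_n2o",
)


class ParamSet:
    """Mapping name -> ParamSpec with validation and draw helpers."""

    def __init__(
        self,
        specs: Mapping[str, ParamSpec],
        metadata: Mapping[str, Any] | None = None,
        *,
        floor_at_zero: bool = False,
    ) -> None:
        self.specs: dict[str, ParamSpec] = dict(specs)
        self.metadata: dict[str, Any] = dict(metadata or {})
        self.floor_at_zero = bool(floor_at_zero)
        missing = [n for n in REQUIRED_NAMES if n not in self.specs]
        if missing:
            raise ValueError(f"missing required parameters: {missing}")

    def __contains__(self, name: str) -> bool:
        return name in self.specs

    def __iter__(self) -> Iterator[str]:
        return iter(self.specs)

    def spec(self, name: str) -> ParamSpec:
        try:
            return self.specs[name]
        except KeyError as exc:
            raise KeyError(f"unknown parameter {name!r}") from exc

    def get(self, name: str, key_values: Mapping[str, Any] | None = None) -> float:
        return self.spec(name).lookup(key_values)

    def series(self, name: str) -> pd.Series:
        """Full keyed table of a parameter (scalars come back length-1)."""
        spec = self.spec(name)
        if isinstance(spec.value, pd.Series):
            return spec.value
        return pd.Series([spec.value], index=[name])

    def sample(self, name: str, rng: np.random.Generator):
        return self.spec(name).sample(rng, floor_at_zero=self.floor_at_zero)

    def sample_all(self, rng: np.random.Generator) -> "ParamSet":
        """One joint draw: every spec replaced by a fixed-dist realization."""
        drawn = {
            n: replace(s, value=s.sample(rng, floor_at_zero=self.floor_at_zero),
                       dist="fixed", cv=0.0, a=None, b=None)
            for n, s in self.specs.items()
        }
        return ParamSet(drawn, {**self.metadata, "realized": True})

    def with_overrides(self, overrides: Mapping[str, ParamSpec]) -> "ParamSet":
        unknown = sorted(set(overrides) - set(self.specs))
        if unknown:
            raise KeyError(f"unknown parameter names in overrides: {unknown}")
        merged = {**self.specs, **overrides}
        return ParamSet(merged, self.metadata, floor_at_zero=self.floor_at_zero)

    def with_gwp(self, horizon: str) -> "ParamSet":
        """Swap the CH4/N2O CO2-eq weighting (horizon '100' or '20')."""
        gwp = GWP_SETS[str(horizon)]
        return self.with_overrides({
            "gwp_ch4": replace(self.specs["gwp_ch4"], value=gwp["ch4"]),
            "gwp_n2o": replace(self.specs["gwp_n2o"], value=gwp["n2o"]),
        })

    def gwp(self) -> dict[str, float]:
        return {"ch4": self.get("gwp_ch4"), "n2o": self.get("gwp_n2o")}

    def digest(self) -> str:
        """Stable hash of all values, for output provenance metadata."""
        import hashlib

        h = hashlib.sha256()
        for name in sorted(self.specs):
            h.update(name.encode())
            h.update(self.specs[name].values_array().tobytes())
        return h.hexdigest()[:16]


# ---------------------------------------------------------------------------
# Default registry


def _keyed(name, mapping, units, keys, **kw) -> ParamSpec:
    if len(keys) == 1:
        idx = pd.Index(list(mapping), name=keys[0])
        vals = list(mapping.values())
    else:
        idx = pd.MultiIndex.from_tuples(list(mapping), names=list(keys))
        vals = list(mapping.values())
    s = pd.Series(vals, index=idx, name=name, dtype=float)
    return ParamSpec(name=name, value=s, units=units, keys=tuple(keys), **kw)


def _uniform_by(name, labels, value, units, keys, **kw) -> ParamSpec:
    return _keyed(name, {lab: value for lab in labels}, units, keys, **kw)


# Straw-to-grain ratios: multi-study Chinese means are unpublished in the
# main text; magnitudes below are field-typical placeholders.
_F_STR = {
    "rice": 1.0, "wheat": 1.1, "corn": 1.2, "millet": 1.4, "jowar": 1.6,
    "other_cereal": 1.3, "beans": 1.5, "tubers": 0.5, "cotton": 3.0,
    "oil_bearing": 2.0, "fiber": 1.7, "sugar": 0.1, "tobacco": 1.0,
}
_F_DRY = {c: 0.85 for c in dims.RESIDUE_CROPS}
_F_HARV = {
    "rice": 0.49, "wheat": 0.43, "corn": 0.44, "millet": 0.40, "jowar": 0.40,
    "other_cereal": 0.42, "beans": 0.38, "tubers": 0.65, "cotton": 0.12,
    "oil_bearing": 0.27, "sugar": 0.75,
}
_F_RB = {c: 0.1 for c in dims.RESIDUE_CROPS}
_F_RBRATE = {
    "rice": 0.0091, "wheat": 0.0065, "corn": 0.0092, "millet": 0.0070,
    "jowar": 0.0070, "other_cereal": 0.0070, "beans": 0.0181,
    "tubers": 0.0110, "cotton": 0.0074, "oil_bearing": 0.0110,
    "sugar": 0.0040,
}
# kg N per head per year and manure-management partition fractions.
_F_EXCR = {
    "rural_population": 4.0, "cattle": 40.0, "pigs": 16.0,
    "sheep_goats": 12.0, "poultry": 0.6, "other_livestock": 40.0,
}
_F_MANA = {
    "rural_population": 0.0, "cattle": 0.10, "pigs": 0.20,
    "sheep_goats": 0.00, "poultry": 0.10, "other_livestock": 0.00,
}
_F_LIQ = {
    "rural_population": 0.30, "cattle": 0.20, "pigs": 0.30,
    "sheep_goats": 0.00, "poultry": 0.10, "other_livestock": 0.10,
}
_F_SOL = {
    "rural_population": 0.30, "cattle": 0.40, "pigs": 0.30,
    "sheep_goats": 0.50, "poultry": 0.50, "other_livestock": 0.50,
}
# Rice paddy EF quad by pooled-source type (kg CH4/ha/day); flooding >=
# intermittent within each organic-input arm.
_RICE_EF_BASE = {
    "early": {"f_ci": 2.0, "f_si": 1.2, "nf_ci": 1.4, "nf_si": 0.8},
    "middle": {"f_ci": 3.0, "f_si": 1.8, "nf_ci": 2.1, "nf_si": 1.2},
    "single_late": {"f_ci": 2.8, "f_si": 1.7, "nf_ci": 2.0, "nf_si": 1.1},
    "double_late": {"f_ci": 2.4, "f_si": 1.5, "nf_ci": 1.7, "nf_si": 1.0},
}
_RICE_LENGTH = {"early": 95.0, "middle_single_late": 130.0, "double_late": 110.0}
# Standard low calorific values (GJ per physical unit) and carbon
# content / oxidation factors for primary carriers.
_F_LCV = {
    "coal": 20.908, "coke": 28.435, "gasoline": 43.070, "kerosene": 43.070,
    "diesel": 42.652, "fuel_oil": 41.816, "lpg": 50.179,
    "natural_gas": 38.931, "electricity": 1.0,
}
_F_CARB = {
    "coal": 26.37, "coke": 29.5, "gasoline": 18.9, "kerosene": 19.6,
    "diesel": 20.2, "fuel_oil": 21.1, "lpg": 17.2, "natural_gas": 15.3,
}
_F_OXID = {
    "coal": 0.94, "coke": 0.93, "gasoline": 0.98, "kerosene": 0.98,
    "diesel": 0.98, "fuel_oil": 0.98, "lpg": 0.99, "natural_gas": 0.99,
}
# Biomass / soil carbon pools (t C/ha).  Cropland soil comes from the
# year-indexed SOC trajectory, not from f_soil.
_F_BIO = {
    "cropland": 10.075, "wood": 116.2, "grassland": 3.7,
    "water_residential": 0.0, "others": 11.5,
}
_F_SOIL = {
    "cropland": 0.0, "wood": 97.6, "grassland": 58.0,
    "water_residential": 0.0, "others": 14.5,
}


def _province_codes() -> list[str]:
    from .panel_io import PROVINCES

    return [p.code for p in PROVINCES]


def default_params() -> ParamSet:
    """Build the default registry (main-text constants + placeholders)."""
    from .rice_cultivation import build_rice_ef_table

    provs = _province_codes()
    specs: dict[str, ParamSpec] = {}

    def add(spec: ParamSpec) -> None:
        specs[spec.name] = spec

    ph = {"source": "placeholder"}

    # --- residue open burning
    add(_keyed("f_str", _F_STR, "kg straw/kg grain", ("crop",),
               dist="normal", cv=0.2, **ph))
    add(_uniform_by("f_open", provs, 0.25, "fraction", ("province",),
                    dist="normal", cv=0.3, **ph))
    add(ParamSpec("f_burn", 0.90, "fraction"))
    add(ParamSpec("ef_crop_ch4", 3.23, "g CH4/kg burned", dist="normal", cv=0.17))
    add(ParamSpec("ef_crop_n2o", 0.008, "g N2O/kg burned", dist="normal", cv=0.23))

    # --- rice cultivation
    add(_keyed("f_length",
               {(p, r): _RICE_LENGTH[r] for p in provs for r in dims.RICE_TYPES},
               "day", ("province", "rice_type"), **ph))
    source_quads = pd.Series(
        {(p, t, w): _RICE_EF_BASE[t][w]
         for p in provs for t in dims.RICE_SOURCE_TYPES for w in dims.RICE_REGIMES},
        name="ef_rice_source", dtype=float,
    )
    source_quads.index = pd.MultiIndex.from_tuples(
        source_quads.index, names=["province", "source_type", "regime"])
    model_quads = build_rice_ef_table(source_quads)
    add(ParamSpec("ef_rice", model_quads, "kg CH4/ha/day",
                  keys=("province", "rice_type", "regime"),
                  dist="normal", cv=0.3, source="placeholder"))
    # Organic-input share 1/2 crossed with continuous-flooding 1/3 vs
    # intermittent 2/3; the four weights sum to exactly 1.
    add(_keyed("f_regime_weight",
               {"f_ci": 0.5 * (1 / 3), "f_si": 0.5 * (2 / 3),
                "nf_ci": 0.5 * (1 / 3), "nf_si": 0.5 * (2 / 3)},
               "fraction", ("regime",)))

    # --- cropland change
    add(_keyed("f_bio", _F_BIO, "t C/ha", ("land_class",),
               dist="normal", cv=0.25, source="mixed: main-text + placeholder"))
    add(_keyed("f_soil", _F_SOIL, "t C/ha", ("land_class",),
               dist="normal", cv=0.25, source="mixed: main-text + placeholder"))
    add(ParamSpec("soc_cropland_1980", 33.0, "t C/ha", dist="normal", cv=0.25,
                  source="placeholder"))
    add(_keyed("soc_change_rate",
               {y: 0.08 for y in range(1980, 2010)},
               "t C/ha/yr", ("year",), **ph))

    # --- cropland N2O
    add(ParamSpec("f_enn", 0.20, "fraction"))
    add(_keyed("f_excr", _F_EXCR, "kg N/head/yr", ("creature",),
               dist="normal", cv=0.2, **ph))
    add(_keyed("f_mana", _F_MANA, "fraction", ("creature",), **ph))
    add(_keyed("f_liq", _F_LIQ, "fraction", ("creature",), **ph))
    add(_keyed("f_sol", _F_SOL, "fraction", ("creature",), **ph))
    add(ParamSpec("f_retu", 0.14, "kg N/kg N", dist="normal", cv=0.11))
    add(_keyed("f_dry", _F_DRY, "kg dry/kg fresh", ("crop",), **ph))
    add(_keyed("f_rb", _F_RB, "kg root/kg shoot", ("crop",), **ph))
    add(_keyed("f_harv", _F_HARV, "kg grain/kg aboveground", ("crop",), **ph))
    add(_keyed("f_rbrate", _F_RBRATE, "kg N/kg biomass", ("crop",), **ph))
    add(_uniform_by("ef_crla_d", provs, 0.01, "kg N2O-N/kg N", ("province",),
                    dist="normal", cv=0.3, **ph))
    add(ParamSpec("f_fvolat", 0.1, "kg NH3-N and NOx-N/kg N applied",
                  dist="triangular", a=0.03, b=0.3))
    add(ParamSpec("f_ovolat", 0.2, "kg NH3-N and NOx-N/kg N applied",
                  dist="triangular", a=0.05, b=0.5))
    add(ParamSpec("ef_crla_atm", 0.01, "kg N2O-N/kg N volatilized",
                  dist="triangular", a=0.002, b=0.05))
    add(ParamSpec("f_leach", 0.3, "kg N/kg N", dist="triangular", a=0.1, b=0.8))
    add(ParamSpec("ef_crla_leach", 0.0075, "kg N2O-N/kg N leached",
                  dist="triangular", a=0.0005, b=0.025))

    # --- machinery energy
    add(_keyed("f_lcv", _F_LCV, "GJ/physical unit", ("energy",), **ph))
    add(_keyed("f_carb", _F_CARB, "kg C/GJ", ("energy",),
               dist="normal", cv=0.1, **ph))
    add(_keyed("f_oxid", _F_OXID, "fraction", ("energy",), **ph))
    # Grid EF declines with generation-mix improvement; 50% CV assumed.
    add(_keyed("ef_elec",
               {y: 0.90 - 0.0065 * (y - dims.FIRST_YEAR) for y in dims.YEARS},
               "kg CO2/kWh", ("year",), dist="normal", cv=0.5, **ph))

    # --- input production
    add(ParamSpec("ef_fert_co2", 6.08, "kg CO2/kg N", dist="normal", cv=0.5))
    add(ParamSpec("ef_fert_ch4", 0.02, "kg CH4/kg N", dist="normal", cv=0.5))
    add(ParamSpec("ef_fert_n2o", 0.0009, "kg N2O/kg N", dist="normal", cv=0.5))
    add(_keyed("f_plpest_anchor",
               {2010: 0.30, 2011: 0.31, 2012: 0.32, 2013: 0.33, 2014: 0.34},
               "fraction", ("year",), **ph))
    # Multiplicative uncertainty on the regressed effective-component
    # proportion (50% CV on f_plPest).
    add(ParamSpec("f_plpest_scale", 1.0, "dimensionless", dist="normal", cv=0.5))
    add(ParamSpec("ef_pest", 16.35, "kg CO2-eq/kg effective component",
                  dist="normal", cv=0.5))

    # --- aggregation
    add(ParamSpec("gwp_ch4", GWP_SETS["100"]["ch4"], "kg CO2-eq/kg CH4"))
    add(ParamSpec("gwp_n2o", GWP_SETS["100"]["n2o"], "kg CO2-eq/kg N2O"))

    return ParamSet(specs, {"source": "cropghg defaults", "version": "0.1.0"})


# ---------------------------------------------------------------------------
# Config loading / export

_TABLE_META_COLS = ("value", "units", "dist", "cv", "a", "b")


def _spec_from_table(name: str, base: ParamSpec, df: pd.DataFrame) -> ParamSpec:
    """Rebuild a keyed spec from a long CSV table ``dim...,value[,units,...]``."""
    keys = list(base.keys)
    missing = [k for k in keys if k not in df.columns]
    if missing or "value" not in df.columns:
        raise ValueError(f"{name}: table must have columns {keys + ['value']}")
    df = df.copy()
    if len(keys) == 1:
        idx = pd.Index(df[keys[0]], name=keys[0])
    else:
        idx = pd.MultiIndex.from_frame(df[keys])
    series = pd.Series(df["value"].to_numpy(dtype=float), index=idx, name=name)

    def col(c, default):
        if c in df.columns and df[c].notna().any():
            vals = df[c].dropna().unique()
            if len(vals) > 1:
                raise ValueError(f"{name}: column {c} must be constant per table")
            return vals[0]
        return default

    return ParamSpec(
        name=name, value=series, units=str(col("units", base.units)),
        keys=base.keys, dist=str(col("dist", base.dist)),
        cv=float(col("cv", base.cv)),
        a=None if col("a", base.a) is None else float(col("a", base.a)),
        b=None if col("b", base.b) is None else float(col("b", base.b)),
        source="config",
    )


def _spec_from_config(name: str, base: ParamSpec, entry: Any,
                      root: Path) -> ParamSpec:
    if isinstance(entry, (int, float)):
        return replace(base, value=float(entry), source="config")
    if not isinstance(entry, Mapping):
        raise ValueError(f"{name}: malformed override {entry!r}")
    if "file" in entry:
        df = pd.read_csv(root / str(entry["file"]))
        return _spec_from_table(name, base, df)
    if "table" in entry:
        return _spec_from_table(name, base, pd.DataFrame(entry["table"]))
    kw: dict[str, Any] = {}
    if "value" in entry:
        if base.is_keyed and isinstance(entry["value"], Mapping):
            s = base.value.copy()
            for k, v in entry["value"].items():
                key = tuple(k) if isinstance(k, (list, tuple)) else k
                if key not in s.index:
                    raise KeyError(f"{name}: unknown table key {key!r}")
                s.loc[key] = float(v)
            kw["value"] = s
        else:
            kw["value"] = float(entry["value"])
    for fld in ("units", "dist", "cv", "a", "b"):
        if fld in entry:
            kw[fld] = entry[fld]
    if not kw:
        raise ValueError(f"{name}: empty override block")
    return replace(base, source="config", **kw)


def load_params(config_path: str | Path | None = None) -> ParamSet:
    """Defaults merged with a YAML override file.

    Config layout::

        floor_negative_samples: false
        params:
          f_burn: 1.0
          ef_pest: {value: 17.0, dist: normal, cv: 0.4}
          f_open: {file: f_open.csv}     # long keyed CSV

    Unknown parameter names are rejected; every spec is re-validated.
    """
    ps = default_params()
    if config_path is None:
        return ps
    config_path = Path(config_path)
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, Mapping):
        raise ValueError("config root must be a mapping")
    overrides = {}
    for name, entry in (cfg.get("params") or {}).items():
        if name not in ps.specs:
            raise KeyError(f"unknown parameter {name!r} in {config_path}")
        overrides[name] = _spec_from_config(name, ps.specs[name], entry,
                                            config_path.parent)
    out = ps.with_overrides(overrides)
    out.floor_at_zero = bool(cfg.get("floor_negative_samples", False))
    if "gwp" in cfg:
        out = out.with_gwp(str(cfg["gwp"]))
    out.metadata["config"] = str(config_path)
    return out


def export_param_tables(ps: ParamSet, out_dir: str | Path) -> list[Path]:
    """Write every keyed parameter as an editable long CSV table."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, spec in sorted(ps.specs.items()):
        if not spec.is_keyed:
            continue
        df = spec.value.rename("value").reset_index()
        df["units"] = spec.units
        df["dist"] = spec.dist
        df["cv"] = spec.cv
        df["a"] = spec.a
        df["b"] = spec.b
        path = out_dir / f"{name}.csv"
        df.to_csv(path, index=False)
        written.append(path)
    return written


# --- thin functional surface over ParamSet ---------------------------------

def get_value(ps: ParamSet, name: str,
              key_values: Mapping[str, Any] | None = None) -> float:
    """Deterministic scalar lookup; keys must match the spec exactly."""
    return ps.get(name, key_values)


def sample_param(ps: ParamSet, name: str, rng: np.random.Generator):
    """One random realization of a parameter under its distribution."""
    return ps.sample(name, rng)
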