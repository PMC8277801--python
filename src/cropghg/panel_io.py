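"""Activity-panel data model, CSV readers/writers, gap interpolation,
and province-founding normalization.

Panels are long-format tables (one row = province, year, optional key,
value) covering 1978-2016.  Missing cells are explicit (absent rows or
NaN values), never silent zeros.  Hainan's pre-founding rows fold into
Guangdong and Chongqing's into Sichuan so the 31-province registry is
consistent across the whole period.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import dimensions as dims

__all__ = [
    "Province",
    "PROVINCES",
    "province_codes",
    "ActivityPanel",
    "read_panel",
    "write_panel",
    "interpolate_gaps",
    "fold_provinces",
    "PANEL_SCHEMAS",
]


@dataclass(frozen=True)
class Province:
    """Registry entry; ``parent_before`` = (parent code, first year the
    province reports independently)."""

    code: str
    name: str
    parent_before: tuple[str, int] | None = None


# 31 mainland provinces.  Hainan was carved out of Guangdong (first
# independent year 1988, i.e. folded through 1987) and Chongqing out of
# Sichuan (first independent year 1997).
PROVINCES: tuple[Province, ...] = tuple(
    Province(code, name, parent)
    for code, name, parent in [
        ("beijing", "Beijing", None),
        ("tianjin", "Tianjin", None),
        ("hebei", "Hebei", None),
        ("shanxi", "Shanxi", None),
        ("inner_mongolia", "Inner Mongolia", None),
        ("liaoning", "Liaoning", None),
        ("jilin", "Jilin", None),
        ("heilongjiang", "Heilongjiang", None),
        ("shanghai", "Shanghai", None),
        ("jiangsu", "Jiangsu", None),
        ("zhejiang", "Zhejiang", None),
        ("anhui", "Anhui", None),
        ("fujian", "Fujian", None),
        ("jiangxi", "Jiangxi", None),
        ("shandong", "Shandong", None),
        ("henan", "Henan", None),
        ("hubei", "Hubei", None),
        ("hunan", "Hunan", None),
        ("guangdong", "Guangdong", None),
        ("guangxi", "Guangxi", None),
        ("hainan", "Hainan", ("guangdong", 1988)),
        ("chongqing", "Chongqing", ("sichuan", 1997)),
        ("sichuan", "Sichuan", None),
        ("guizhou", "Guizhou", None),
        ("yunnan", "Yunnan", None),
        ("tibet", "Tibet", None),
        ("shaanxi", "Shaanxi", None),
        ("gansu", "Gansu", None),
        ("qinghai", "Qinghai", None),
        ("ningxia", "Ningxia", None),
        ("xinjiang", "Xinjiang", None),
    ]
)

_PROVINCE_BY_CODE = {p.code: p for p in PROVINCES}


def province_codes() -> list[str]:
    return [p.code for p in PROVINCES]


# variable -> (csv filename, key column or None, value column, scale to
# internal units).  Internal units: kg (mass), ha (area), head, physical
# energy units, dimensionless ratio.
PANEL_SCHEMAS: dict[str, tuple[str, str | None, str, float]] = {
    "crop_production": ("crop_production.csv", "crop", "production_t", 1000.0),
    "rice_area": ("rice_area.csv", "rice_type", "area_ha", 1.0),
    "populations": ("populations.csv", "creature", "head", 1.0),
    "n_fertilizer": ("n_fertilizer.csv", None, "n_fert_tN", 1000.0),
    "pesticide_use": ("pesticide_use.csv", None, "pesticide_t", 1000.0),
    "energy_use": ("energy_use.csv", "energy", "quantity", 1.0),
    "gdp_ratio": ("gdp_ratio.csv", None, "gdp_ratio", 1.0),
}
_TRANSITIONS_FILE = "land_transitions.csv"

_KEY_DOMAINS = {
    "crop": set(dims.CROPS),
    "rice_type": set(dims.RICE_TYPES),
    "creature": set(dims.CREATURES),
    "energy": set(dims.ENERGY_CARRIERS),
    "change_type": set(dims.CHANGE_TYPES),
}


@dataclass
class ActivityPanel:
    """Long-format province x year activity tables.

    Year-indexed tables have columns ``province, year[, key], value``
    (value in internal units); ``land_transitions`` has
    ``province, interval_start, interval_end, change_type, value`` (ha
    per snapshot interval, annualized downstream).
    """

    crop_production: pd.DataFrame
    rice_area: pd.DataFrame
    land_transitions: pd.DataFrame
    populations: pd.DataFrame
    n_fertilizer: pd.DataFrame
    pesticide_use: pd.DataFrame
    energy_use: pd.DataFrame
    gdp_ratio: pd.DataFrame
    years: tuple[int, int] = (dims.FIRST_YEAR, dims.LAST_YEAR)

    def tables(self) -> dict[str, pd.DataFrame]:
        return {f.name: getattr(self, f.name) for f in fields(self)
                if f.name != "years"}

    def provinces(self) -> list[str]:
        seen: list[str] = []
        for df in self.tables().values():
            for p in df["province"].unique():
                if p not in seen:
                    seen.append(p)
        return [p.code for p in PROVINCES if p.code in seen] or seen

    def year_range(self) -> list[int]:
        return list(range(self.years[0], self.years[1] + 1))

    def copy(self) -> "ActivityPanel":
        return replace(self, **{k: v.copy() for k, v in self.tables().items()})

    def validate(self) -> "ActivityPanel":
        for name, df in self.tables().items():
            key = "change_type" if name == "land_transitions" else \
                PANEL_SCHEMAS.get(name, (None, None, None, None))[1]
            self._validate_table(name, df, key)
        return self

    def _validate_table(self, name: str, df: pd.DataFrame,
                        key: str | None) -> None:
        unknown = set(df["province"]) - set(_PROVINCE_BY_CODE)
        if unknown:
            raise ValueError(f"{name}: unknown province labels {sorted(unknown)}")
        if key is not None:
            bad = set(df[key]) - _KEY_DOMAINS[key]
            if bad:
                raise ValueError(f"{name}: unknown {key} labels {sorted(bad)}")
        observed = df["value"].dropna()
        if (observed < 0).any():
            row = df.loc[observed[observed < 0].index[0]]
            raise ValueError(f"{name}: negative activity value in row "
                             f"{row.to_dict()}")
        if name == "gdp_ratio" and (observed > 1).any():
            raise ValueError("gdp_ratio: fraction outside [0, 1]")
        if name == "land_transitions":
            id_cols = ["province", "interval_start", "interval_end", "change_type"]
        else:
            id_cols = ["province", "year"] + ([key] if key else [])
            yrs = df["year"]
            if ((yrs < self.years[0]) | (yrs > self.years[1])).any():
                raise ValueError(f"{name}: year outside {self.years}")
        dup = df.duplicated(id_cols)
        if dup.any():
            row = df.loc[dup.idxmax(), id_cols].to_dict()
            raise ValueError(f"{name}: duplicate key row {row}")

    def is_complete(self) -> bool:
        """True when every year-indexed series covers every model year."""
        n_years = len(self.year_range())
        for name, df in self.tables().items():
            if name == "land_transitions":
                continue
            if df["value"].isna().any():
                return False
            key = PANEL_SCHEMAS[name][1]
            group_cols = ["province"] + ([key] if key else [])
            if (df.groupby(group_cols, observed=True)["year"].count() < n_years).any():
                return False
        return True


# ---------------------------------------------------------------------------
# Readers / writers


def read_panel(paths: Mapping[str, str | Path] | str | Path,
               years: tuple[int, int] = (dims.FIRST_YEAR, dims.LAST_YEAR),
               ) -> ActivityPanel:
    """Read a panel from a directory or an explicit variable->path map.

    CSV schemas (UTF-8, header row required)::

        crop_production:  province,year,crop,production_t
        rice_area:        province,year,rice_type,area_ha
        land_transitions: province,interval_start,interval_end,change_type,area_ha
        populations:      province,year,creature,head
        n_fertilizer:     province,year,n_fert_tN
        pesticide_use:    province,year,pesticide_t
        energy_use:       province,year,energy,quantity
        gdp_ratio:        province,year,gdp_ratio

    Masses are converted to kg internally.
    """
    if not isinstance(paths, Mapping):
        root = Path(paths)
        paths = {v: root / fname for v, (fname, *_rest) in PANEL_SCHEMAS.items()}
        paths["land_transitions"] = root / _TRANSITIONS_FILE

    tables: dict[str, pd.DataFrame] = {}
    for var, (fname, key, value_col, scale) in PANEL_SCHEMAS.items():
        df = pd.read_csv(paths[var])
        want = ["province", "year"] + ([key] if key else []) + [value_col]
        missing = [c for c in want if c not in df.columns]
        if missing:
            raise ValueError(f"{var}: missing columns {missing}")
        df = df[want].rename(columns={value_col: "value"})
        df["value"] = df["value"].astype(float) * scale
        tables[var] = df
    tdf = pd.read_csv(paths["land_transitions"])
    want = ["province", "interval_start", "interval_end", "change_type", "area_ha"]
    missing = [c for c in want if c not in tdf.columns]
    if missing:
        raise ValueError(f"land_transitions: missing columns {missing}")
    tables["land_transitions"] = tdf[want].rename(columns={"area_ha": "value"})

    return ActivityPanel(years=years, **tables).validate()


def write_panel(panel: ActivityPanel, out_dir: str | Path) -> list[Path]:
    """Write a panel back to the long CSV schemas (inverse of read_panel)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for var, (fname, key, value_col, scale) in PANEL_SCHEMAS.items():
        df = getattr(panel, var).copy()
        df[value_col] = df.pop("value") / scale
        path = out_dir / fname
        df.to_csv(path, index=False)
        written.append(path)
    tdf = panel.land_transitions.rename(columns={"value": "area_ha"})
    path = out_dir / _TRANSITIONS_FILE
    tdf.to_csv(path, index=False)
    written.append(path)
    return written


# ---------------------------------------------------------------------------
# Gap interpolation


def _fill_series(values: pd.Series, years: list[int]) -> pd.Series:
    s = values.reindex(years).astype(float)
    if s.notna().sum() == 0:
        raise ValueError("fully-empty series cannot be interpolated")
    # interior gaps: linear between nearest flanking observations;
    # one-sided edge gaps: held constant at the nearest observation.
    return s.interpolate(method="index", limit_area="inside").ffill().bfill()


def interpolate_gaps(panel: ActivityPanel) -> ActivityPanel:
    """Fill every missing year of every (province, series) independently.

    Interior gaps are linearly interpolated between the closest observed
    years; years outside the observed range take the closest observed
    value.  Observed cells are returned unchanged.  Land transitions are
    interval-based and pass through untouched (annualization handles
    their year coverage).

    Years before a child province's first independent year (Hainan 1988,
    Chongqing 1997) are structurally absent — the activity is booked
    under the parent — so absent pre-founding cells become zero rather
    than back-extrapolated values; observed pre-founding cells pass
    through for :func:`fold_provinces` to absorb.
    """
    years = panel.year_range()
    founding = {p.code: p.parent_before[1] for p in PROVINCES
                if p.parent_before}
    out: dict[str, pd.DataFrame] = {"land_transitions": panel.land_transitions.copy()}
    for var, (fname, key, _vc, _s) in PANEL_SCHEMAS.items():
        df = getattr(panel, var)
        group_cols = ["province"] + ([key] if key else [])
        pieces = []
        for g, sub in df.groupby(group_cols, observed=True, sort=False):
            g = g if isinstance(g, tuple) else (g,)
            observed = sub.set_index("year")["value"]
            first_year = founding.get(g[0])
            if first_year is not None:
                active = [y for y in years if y >= first_year]
                filled = _fill_series(observed[observed.index >= first_year],
                                      active)
                pre = observed[observed.index < first_year].reindex(
                    [y for y in years if y < first_year], fill_value=0.0)
                filled = pd.concat([pre, filled]).sort_index()
            else:
                filled = _fill_series(observed, years)
            piece = pd.DataFrame({"year": years, "value": filled.to_numpy()})
            for col, val in zip(group_cols, g):
                piece[col] = val
            pieces.append(piece[group_cols + ["year", "value"]])
        out[var] = pd.concat(pieces, ignore_index=True)
    return replace(panel, **out)


# ---------------------------------------------------------------------------
# Province folding


def fold_provinces(panel: ActivityPanel,
                   registry: tuple[Province, ...] = PROVINCES) -> ActivityPanel:
    """Sum child-province rows into their parent before the founding year.

    Hainan rows before 1988 are added to Guangdong, Chongqing rows
    before 1997 to Sichuan; national totals are conserved.  Transition
    intervals are folded when they end before the child's first
    independent year.
    """
    folds = {p.code: p.parent_before for p in registry if p.parent_before}

    out: dict[str, pd.DataFrame] = {}
    for name, df in panel.tables().items():
        df = df.copy()
        year_col = "interval_end" if name == "land_transitions" else "year"
        for child, (parent, first_year) in folds.items():
            pre = (df["province"] == child) & (df[year_col] < first_year)
            df.loc[pre, "province"] = parent
        id_cols = [c for c in df.columns if c != "value"]
        out[name] = (df.groupby(id_cols, observed=True, sort=False, dropna=False)
                       ["value"].sum(min_count=1).reset_index())
    return replace(panel, **out)
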