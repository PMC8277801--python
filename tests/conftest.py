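"""Shared fixtures: the default parameter registry and a tiny-panel
builder used to exercise single sub-models on hand-checkable inputs."""

from __future__ import annotations

from dataclasses import replace

import pandas as pd
import pytest

from cropghg import dimensions as dims
from cropghg.panel_io import PANEL_SCHEMAS, ActivityPanel
from cropghg.params import ParamSet, load_params

_DEFAULT_KEY = {
    "crop_production": "rice",
    "rice_area": "early",
    "populations": "cattle",
    "energy_use": "diesel",
}


def make_panel(provinces=("beijing",), years=(1980, 1980), **cells
               ) -> ActivityPanel:
    """Zero-filled panel with selected cells set.

    ``cells`` maps a variable name to ``{(province, year[, key]): value}``
    (internal units: kg, ha, head, physical energy units);
    ``land_transitions`` uses
    ``{(province, start, end, change_type): area_ha}``.
    """
    yrs = list(range(years[0], years[1] + 1))
    tables = {}
    for var, (_f, key, _vc, _sc) in PANEL_SCHEMAS.items():
        base = {}
        for p in provinces:
            for y in yrs:
                k = (p, y, _DEFAULT_KEY[var]) if key else (p, y)
                base[k] = 0.0
        base.update(cells.get(var, {}))
        rows = []
        for k, v in base.items():
            row = {"province": k[0], "year": k[1], "value": v}
            if key:
                row[key] = k[2]
            rows.append(row)
        tables[var] = pd.DataFrame(rows)
    lt = cells.get("land_transitions", {})
    tables["land_transitions"] = pd.DataFrame(
        [{"province": p, "interval_start": s, "interval_end": e,
          "change_type": ct, "value": v}
         for (p, s, e, ct), v in lt.items()],
        columns=["province", "interval_start", "interval_end",
                 "change_type", "value"])
    return ActivityPanel(years=tuple(years), **tables).validate()


def set_values(ps: ParamSet, **updates) -> ParamSet:
    """Override parameter values; keyed entries via {key: value} dicts."""
    overrides = {}
    for name, val in updates.items():
        spec = ps.spec(name)
        if isinstance(val, dict):
            series = spec.value.copy()
            for k, v in val.items():
                series.loc[k] = v
            overrides[name] = replace(spec, value=series)
        else:
            overrides[name] = replace(spec, value=float(val))
    return ps.with_overrides(overrides)


def fix_all_dists(ps: ParamSet) -> ParamSet:
    """Degenerate copy: every distribution collapsed to fixed."""
    specs = {n: replace(s, dist="fixed", cv=0.0, a=None, b=None)
             for n, s in ps.specs.items()}
    return ParamSet(specs, ps.metadata)


@pytest.fixture(scope="session")
def ps() -> ParamSet:
    return load_params()
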