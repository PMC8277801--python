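"""CO2-equivalent aggregation and output-matrix assembly.

Gas masses convert to CO2-eq with 100-year global-warming potentials
(CH4 = 28, N2O = 265 by default; a 20-year set is a config swap) plus
any directly CO2-eq-denominated component.  Outputs mirror the
deposited data-record layout: one national year x activity matrix with
a total column, one provincial year x province total matrix, and one
provincial matrix per activity, all in Mt CO2-eq.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, NamedTuple

import pandas as pd

from . import dimensions as dims

__all__ = [
    "GasEmission",
    "EmissionTensor",
    "to_co2eq",
    "assemble_outputs",
    "write_outputs",
    "read_outputs",
]

_KG_PER_MT = 1e9


class GasEmission(NamedTuple):
    """A (CO2, CH4, N2O) mass triple plus an optional directly
    CO2-eq-denominated component."""

    co2: float
    ch4: float
    n2o: float
    co2eq_direct: float = 0.0


@dataclass
class EmissionTensor:
    """Point estimates over (province, year, activity) x gas columns (kg).

    ``data`` is indexed by a (province, year, activity) MultiIndex with
    the four gas columns; metadata records the GWP set, parameter digest
    and seed used to produce it.
    """

    data: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad_act = set(self.data.index.get_level_values("activity")) \
            - set(dims.ACTIVITIES)
        if bad_act:
            raise ValueError(f"unknown activities {sorted(bad_act)}")
        missing = [c for c in dims.GAS_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"tensor missing gas columns {missing}")
        non_lcc = self.data.drop("cropland_change", level="activity",
                                 errors="ignore")
        if (non_lcc[dims.GAS_COLUMNS].to_numpy() < 0).any():
            raise ValueError(
                "negative emission outside the cropland_change activity")

    def co2eq(self, gwp: Mapping[str, float]) -> pd.Series:
        return to_co2eq(self.data, gwp)


def to_co2eq(g, gwp: Mapping[str, float]):
    """CO2-eq mass: co2 + gwp_ch4 * ch4 + gwp_n2o * n2o (+ direct part).

    Accepts a :class:`GasEmission` (returns a float) or any frame with
    the gas columns (returns a Series).
    """
    if gwp["ch4"] <= 0 or gwp["n2o"] <= 0:
        raise ValueError("GWP values must be positive")
    if isinstance(g, GasEmission):
        return (g.co2 + gwp["ch4"] * g.ch4 + gwp["n2o"] * g.n2o
                + g.co2eq_direct)
    return (g["co2"] + gwp["ch4"] * g["ch4"] + gwp["n2o"] * g["n2o"]
            + g["co2eq_direct"]).rename("co2eq")


def assemble_outputs(t: EmissionTensor,
                     gwp: Mapping[str, float] | None = None,
                     ) -> dict[str, pd.DataFrame]:
    """National and provincial CO2-eq matrices (Mt) from a tensor.

    Returns ``national_by_activity`` (year x activities + total),
    ``provincial_total`` (year x province) and one
    ``provincial_<activity>`` matrix per activity.  National values are
    province sums; the total column is the activity sum.
    """
    if gwp is None:
        gwp = t.metadata.get("gwp", {"ch4": 28.0, "n2o": 265.0})
    eq = t.co2eq(gwp) / _KG_PER_MT

    activities = [a for a in dims.ACTIVITIES
                  if a in eq.index.get_level_values("activity")]
    national = (eq.groupby(["year", "activity"], observed=True).sum()
                  .unstack("activity").reindex(columns=activities))
    national["total"] = national.sum(axis=1)

    by_province = (eq.groupby(["year", "province", "activity"], observed=True)
                     .sum().unstack("province"))
    out: dict[str, pd.DataFrame] = {"national_by_activity": national}
    out["provincial_total"] = by_province.groupby("year", observed=True).sum()
    for act in activities:
        out[f"provincial_{act}"] = by_province.xs(act, level="activity")
    return out


def write_outputs(outputs: Mapping[str, pd.DataFrame], out_dir: str | Path,
                  metadata: Mapping | None = None, decimals: int = 2,
                  ) -> list[Path]:
    """Write the output matrices as CSV (values rounded to ``decimals``,
    matching the Mt-scale reporting precision) plus a metadata sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in outputs.items():
        path = out_dir / f"{name}.csv"
        df.round(decimals).to_csv(path, float_format=f"%.{decimals}f")
        written.append(path)
    if metadata is not None:
        path = out_dir / "metadata.json"
        path.write_text(json.dumps(dict(metadata), indent=2, sort_keys=True,
                                   default=str))
        written.append(path)
    return written


def read_outputs(out_dir: str | Path) -> dict[str, pd.DataFrame]:
    """Read back matrices written by :func:`write_outputs`."""
    out: dict[str, pd.DataFrame] = {}
    for path in sorted(Path(out_dir).glob("*.csv")):
        out[path.stem] = pd.read_csv(path, index_col=0)
    return out
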