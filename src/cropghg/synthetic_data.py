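"""Synthetic activity panels and parameter tables.

The generator emulates the structure of the provincial statistics the
inventory consumes — multi-decade exponential trends (fertilizer,
pesticide and machinery inputs growing steadily from 1978, rural
population declining), strictly non-negative values, land-use
transitions observed only at snapshot intervals, and pesticide-use
statistics starting in 1990 — without imitating the real provincial
heterogeneity of China.  Each series is

    value(t) = share_p * national(1978) * exp(g * (t - 1978) + e_t),

with e_t a mean-reverting AR(1) log-noise process and province shares
drawn from a symmetric Dirichlet.  National base levels are set so
synthetic inventory totals land in the hundreds-of-Mt CO2-eq range of
the historical record (readable demos, not a calibration target).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import dimensions as dims
from .panel_io import ActivityPanel, PROVINCES

__all__ = ["SynthConfig", "generate_panel", "generate_param_tables"]

# national 1978 level, annual exponential growth rate
_CROP_BASE = {  # kg production
    "rice": (1.4e11, 0.010), "wheat": (5.5e10, 0.018), "corn": (5.6e10, 0.025),
    "millet": (7.0e9, -0.010), "jowar": (6.0e9, -0.015),
    "other_cereal": (8.0e9, 0.000), "beans": (1.5e10, 0.010),
    "tubers": (3.0e10, 0.004), "cotton": (2.2e9, 0.015),
    "oil_bearing": (5.2e9, 0.030), "fiber": (1.2e9, -0.005),
    "sugar": (2.4e10, 0.020), "tobacco": (1.2e9, 0.010),
}
_RICE_AREA_BASE = {  # ha
    "early": (8.5e6, -0.008), "middle_single_late": (1.7e7, 0.002),
    "double_late": (8.5e6, -0.008),
}
_POP_BASE = {  # head
    "rural_population": (7.9e8, -0.004), "cattle": (7.0e7, 0.012),
    "pigs": (3.0e8, 0.012), "sheep_goats": (1.7e8, 0.018),
    "poultry": (1.5e9, 0.030), "other_livestock": (1.1e7, -0.010),
}
_ENERGY_BASE = {  # physical units: t fuels, 1e3 m3 gas, kWh electricity
    "coal": (3.0e7, 0.002), "coke": (5.0e5, 0.005), "gasoline": (2.0e6, 0.020),
    "kerosene": (3.0e5, 0.000), "diesel": (7.0e6, 0.030),
    "fuel_oil": (1.0e6, 0.000), "lpg": (2.0e5, 0.040),
    "natural_gas": (2.0e5, 0.050), "electricity": (2.5e10, 0.060),
}
_NFERT_BASE = (8.8e9, 0.034)  # kg N
_PEST_BASE = (5.0e8, 0.035)  # kg
# per-interval national conversion area (ha) for each change type
_TRANSITION_BASE = 1.5e6


@dataclass(frozen=True)
class SynthConfig:
    """Growth/noise settings of the generator.

    ``noise_sd`` is the innovation s.d. of the AR(1) log-noise
    (``rho`` its autocorrelation); ``growth_shift`` adds a uniform
    offset to every growth rate; ``drop_before`` removes observations
    of a variable before a year (default: pesticide statistics start in
    1990); ``missing_years`` knocks out listed years of a variable so
    interpolation has work to do.
    """

    noise_sd: float = 0.08
    rho: float = 0.7
    growth_shift: float = 0.0
    growth_override: float | None = None
    drop_before: dict = field(
        default_factory=lambda: {"pesticide_use": 1990})
    missing_years: dict = field(default_factory=dict)
    snapshot_years: tuple = dims.SNAPSHOT_YEARS

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or not -1.0 < self.rho < 1.0:
            raise ValueError("invalid noise configuration")


def _ar1(rng, n_years: int, shape: tuple, sd: float, rho: float) -> np.ndarray:
    out = np.zeros(shape + (n_years,))
    if sd == 0:
        return out
    innov_sd = sd * np.sqrt(1.0 - rho**2)
    out[..., 0] = rng.normal(0.0, sd, shape)
    for t in range(1, n_years):
        out[..., t] = rho * out[..., t - 1] \
            + rng.normal(0.0, innov_sd, shape)
    return out


def generate_panel(seed: int, provinces: int = 31,
                   years: tuple[int, int] = (dims.FIRST_YEAR, dims.LAST_YEAR),
                   config: SynthConfig | None = None) -> ActivityPanel:
    """Deterministic synthetic activity panel.

    ``provinces`` takes the first N codes of the registry; ``years``
    must lie within 1978-2016.  The same seed reproduces the panel
    bit-identically.
    """
    cfg = config or SynthConfig()
    if provinces < 1 or provinces > len(PROVINCES):
        raise ValueError("provinces must be in 1..31")
    y0, y1 = years
    if y0 < dims.FIRST_YEAR or y1 > dims.LAST_YEAR or y1 < y0:
        raise ValueError(f"years must lie within "
                         f"{dims.FIRST_YEAR}-{dims.LAST_YEAR}")
    rng = np.random.default_rng(seed)
    codes = [p.code for p in PROVINCES[:provinces]]
    yrs = np.arange(y0, y1 + 1)
    n_y = len(yrs)

    def series_block(var: str, key: str | None, base_map) -> pd.DataFrame:
        keys = list(base_map) if key else [None]
        shares = rng.dirichlet(np.full(len(codes), 5.0), size=len(keys))
        noise = _ar1(rng, n_y, (len(keys), len(codes)), cfg.noise_sd, cfg.rho)
        rows = []
        for k_i, k in enumerate(keys):
            base, growth = base_map[k] if key else base_map
            if cfg.growth_override is not None:
                growth = cfg.growth_override
            growth += cfg.growth_shift
            trend = base * np.exp(growth * (yrs - dims.FIRST_YEAR))
            vals = shares[k_i][:, None] * trend[None, :] \
                * np.exp(noise[k_i])
            df = pd.DataFrame({
                "province": np.repeat(codes, n_y),
                "year": np.tile(yrs, len(codes)),
                "value": vals.reshape(-1),
            })
            if key:
                df.insert(2, key, k)
            rows.append(df)
        out = pd.concat(rows, ignore_index=True)
        drop = cfg.drop_before.get(var)
        if drop is not None:
            out = out[out["year"] >= drop].reset_index(drop=True)
        gone = cfg.missing_years.get(var)
        if gone:
            out = out[~out["year"].isin(list(gone))].reset_index(drop=True)
        return out

    crop_production = series_block("crop_production", "crop", _CROP_BASE)
    rice_area = series_block("rice_area", "rice_type", _RICE_AREA_BASE)
    populations = series_block("populations", "creature", _POP_BASE)
    energy_use = series_block("energy_use", "energy", _ENERGY_BASE)
    n_fertilizer = series_block("n_fertilizer", None, _NFERT_BASE)
    pesticide_use = series_block("pesticide_use", None, _PEST_BASE)

    # GDP ratio of cropping to generalized agriculture: slow decline,
    # clipped to [0, 1].
    ratio_noise = _ar1(rng, n_y, (len(codes),), cfg.noise_sd / 2, cfg.rho)
    ratio = np.clip(0.80 - 0.005 * (yrs - dims.FIRST_YEAR)[None, :]
                    + ratio_noise, 0.0, 1.0)
    gdp_ratio = pd.DataFrame({
        "province": np.repeat(codes, n_y),
        "year": np.tile(yrs, len(codes)),
        "value": ratio.reshape(-1),
    })
    drop = cfg.drop_before.get("gdp_ratio")
    if drop is not None:
        gdp_ratio = gdp_ratio[gdp_ratio["year"] >= drop].reset_index(drop=True)

    # land transitions observed only at snapshot intervals
    snaps = sorted(cfg.snapshot_years)
    intervals = list(zip(snaps[:-1], snaps[1:]))
    shares = rng.dirichlet(np.full(len(codes), 5.0))
    rows = []
    for start, end in intervals:
        for ct in dims.CHANGE_TYPES:
            areas = shares * _TRANSITION_BASE \
                * rng.lognormal(0.0, cfg.noise_sd * 2, len(codes))
            rows.append(pd.DataFrame({
                "province": codes, "interval_start": start,
                "interval_end": end, "change_type": ct, "value": areas,
            }))
    land_transitions = pd.concat(rows, ignore_index=True)

    # child provinces (Hainan, Chongqing) report nothing before their
    # first independent year: their extensive pre-founding activity is
    # merged into the parent (keeping national trends continuous) and
    # their intensive GDP-ratio rows are simply absent.
    founding = {p.code: p.parent_before[1] for p in PROVINCES
                if p.parent_before}
    keep = np.ones(len(gdp_ratio), dtype=bool)
    for child, first in founding.items():
        keep &= ~((gdp_ratio["province"] == child)
                  & (gdp_ratio["year"] < first))
    gdp_ratio = gdp_ratio[keep].reset_index(drop=True)

    panel = ActivityPanel(
        crop_production=crop_production, rice_area=rice_area,
        land_transitions=land_transitions, populations=populations,
        n_fertilizer=n_fertilizer, pesticide_use=pesticide_use,
        energy_use=energy_use, gdp_ratio=gdp_ratio, years=(y0, y1),
    )
    from .panel_io import fold_provinces

    return fold_provinces(panel).validate()


def generate_param_tables(seed: int) -> dict[str, pd.DataFrame]:
    """Randomized but plausible per-province factor tables.

    Values stay inside published ranges (open-burning ratios in [0, 1],
    paddy EF quadruples with flooded >= intermittently irrigated within
    each organic-input arm, direct N2O factors within the IPCC span);
    the same seed reproduces identical tables.  Output frames use the
    keyed-CSV layout ``dimension...,value,units,dist,cv,a,b`` accepted
    by the parameter-config loader.
    """
    rng = np.random.default_rng(seed)
    codes = [p.code for p in PROVINCES]

    def table(rows: list[dict], units: str, dist="fixed", cv=0.0) -> pd.DataFrame:
        df = pd.DataFrame(rows)
        df["units"] = units
        df["dist"] = dist
        df["cv"] = cv
        df["a"] = np.nan
        df["b"] = np.nan
        return df

    f_open = table(
        [{"province": p, "value": rng.uniform(0.10, 0.40)} for p in codes],
        "fraction", dist="normal", cv=0.3)

    rice_rows = []
    for p in codes:
        for r in dims.RICE_TYPES:
            nf_si = rng.uniform(0.6, 1.4)
            nf_ci = nf_si * rng.uniform(1.0, 1.8)
            f_si = nf_si * rng.uniform(1.2, 2.0)
            f_ci = max(f_si * rng.uniform(1.0, 1.8), nf_ci)
            quad = {"f_ci": f_ci, "f_si": f_si, "nf_ci": nf_ci,
                    "nf_si": nf_si}
            for w in dims.RICE_REGIMES:
                rice_rows.append({"province": p, "rice_type": r,
                                  "regime": w, "value": quad[w]})
    ef_rice = table(rice_rows, "kg CH4/ha/day", dist="normal", cv=0.3)

    f_length = table(
        [{"province": p, "rice_type": r,
          "value": float(np.round(rng.normal({"early": 95, "middle_single_late": 130,
                                              "double_late": 110}[r], 6.0)))}
         for p in codes for r in dims.RICE_TYPES],
        "day")

    ef_crla_d = table(
        [{"province": p, "value": rng.uniform(0.003, 0.02)} for p in codes],
        "kg N2O-N/kg N", dist="normal", cv=0.3)

    f_str = table(
        [{"crop": c, "value": rng.uniform(0.5, 2.5) if c != "sugar"
          else rng.uniform(0.05, 0.2)} for c in dims.CROPS],
        "kg straw/kg grain", dist="normal", cv=0.2)

    return {"f_open": f_open, "ef_rice": ef_rice, "f_length": f_length,
            "ef_crla_d": ef_crla_d, "f_str": f_str}
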