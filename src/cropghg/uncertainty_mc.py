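"""Monte-Carlo propagation of parameter uncertainty.

Activity data are treated as certain (official statistics); every
uncertain parameter is redrawn once per sample under its registered
distribution (normal with the published coefficient of variation, or
triangular over the published range).  Within a draw a scalar parameter
is shared across all provinces and years — the most conservative
correlation assumption, yielding the widest intervals; an
independent-per-province alternative sits behind a flag.  Keyed-table
entries (per-province, per-crop factors) are drawn independently.

Each draw re-evaluates all seven sub-models nationally; the 2.5th and
97.5th percentiles of the resulting annual CO2-eq totals (empirical
order statistics, linear interpolation between ranks) form the 95%
confidence band, reported absolutely and relative to the point
estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import dimensions as dims
from .arrays import PanelArrays, ParamView
from .input_production import effective_component_regression
from .pipeline import national_co2eq_kernel

__all__ = ["MCResult", "run_mc", "relative_bounds"]

_COLUMNS = dims.ACTIVITIES + ["total"]


@dataclass
class MCResult:
    """Percentile summary of national annual CO2-eq per activity (kg).

    ``point``, ``lower`` and ``upper`` are year x (activity + total)
    frames; lower/upper are the 2.5th/97.5th percentiles over draws.
    """

    point: pd.DataFrame
    lower: pd.DataFrame
    upper: pd.DataFrame
    n_samples: int
    seed: int

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")

    def to_frame(self) -> pd.DataFrame:
        """Long summary: year, activity, point, p2.5, p97.5, rel bounds."""
        lo_pct, hi_pct = relative_bounds(self)
        rows = []
        for frame, name in [(self.point, "point"), (self.lower, "p2.5"),
                            (self.upper, "p97.5"), (lo_pct, "rel_lo_pct"),
                            (hi_pct, "rel_hi_pct")]:
            rows.append(frame.stack().rename(name))
        out = pd.concat(rows, axis=1).reset_index()
        out.columns = ["year", "activity"] + [r.name for r in rows]
        return out


def run_mc(panel, ps, n_samples: int = 50_000, seed: int = 0,
           scalars_by_province: bool = False) -> MCResult:
    """Monte-Carlo 95% intervals for national emissions per activity.

    The panel must be complete (post-interpolation).  Reproducible: the
    same seed yields identical percentiles.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    arr = PanelArrays.from_panel(panel)
    view = ParamView(ps, arr)
    years = [int(y) for y in arr.years]
    # pesticide effective-component proportions are regression output;
    # their uncertainty enters through the sampled f_plpest_scale
    proportions = effective_component_regression(
        ps.series("f_plpest_anchor"), years).to_numpy()

    point_arr = national_co2eq_kernel(arr, view.values(), proportions)
    rng = np.random.default_rng(seed)
    draws = np.empty((n_samples, len(years), len(dims.ACTIVITIES)))
    for i in range(n_samples):
        v = view.sample(rng, scalars_by_province=scalars_by_province)
        draws[i] = national_co2eq_kernel(arr, v, proportions)

    def with_total(a: np.ndarray) -> np.ndarray:
        return np.concatenate([a, a.sum(axis=-1, keepdims=True)], axis=-1)

    point = with_total(point_arr)
    draws = with_total(draws)
    lower = np.quantile(draws, 0.025, axis=0, method="linear")
    upper = np.quantile(draws, 0.975, axis=0, method="linear")

    def frame(a: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame(a, index=pd.Index(years, name="year"),
                            columns=_COLUMNS)

    return MCResult(point=frame(point), lower=frame(lower),
                    upper=frame(upper), n_samples=n_samples, seed=seed)


def relative_bounds(r: MCResult) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Interval bounds relative to the point estimate, in percent:
    (p2.5/point - 1, p97.5/point - 1) x 100.  Zero point estimates give
    NaN (flagged as undefined rather than infinite)."""
    point = r.point.replace(0.0, np.nan)
    lo = (r.lower / point - 1.0) * 100.0
    hi = (r.upper / point - 1.0) * 100.0
    return lo, hi
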