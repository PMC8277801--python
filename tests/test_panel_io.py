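"""Panel I/O: interpolation rules, province folding, CSV round-trips
and input validation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cropghg.panel_io import (PROVINCES, fold_provinces, interpolate_gaps,
                              read_panel, write_panel)
from cropghg.synthetic_data import SynthConfig, generate_panel

from conftest import make_panel


def _nfert_series(panel, province):
    df = panel.n_fertilizer
    return df[df["province"] == province].set_index("year")["value"].sort_index()


class TestInterpolation:
    def test_interior_gap_is_linear(self):
        panel = make_panel(years=(1980, 1990), n_fertilizer={
            ("beijing", y): np.nan for y in range(1981, 1990)
        } | {("beijing", 1980): 10.0, ("beijing", 1990): 20.0})
        out = interpolate_gaps(panel)
        s = _nfert_series(out, "beijing")
        assert s.loc[1985] == pytest.approx(15.0)
        assert s.loc[1983] == pytest.approx(13.0)
        assert s.loc[1980] == 10.0 and s.loc[1990] == 20.0

    def test_one_sided_gap_held_constant(self):
        panel = make_panel(years=(1978, 1982), n_fertilizer={
            ("beijing", 1978): np.nan, ("beijing", 1979): np.nan,
            ("beijing", 1980): 10.0,
            ("beijing", 1981): np.nan, ("beijing", 1982): np.nan,
        })
        s = _nfert_series(interpolate_gaps(panel), "beijing")
        assert (s == 10.0).all()

    def test_fully_observed_series_unchanged(self):
        vals = {("beijing", y): float(y) for y in range(1980, 1986)}
        panel = make_panel(years=(1980, 1985), n_fertilizer=vals)
        out = interpolate_gaps(panel)
        pd.testing.assert_series_equal(
            _nfert_series(out, "beijing"), _nfert_series(panel, "beijing"))

    def test_fully_empty_series_rejected(self):
        panel = make_panel(years=(1980, 1982), n_fertilizer={
            ("beijing", y): np.nan for y in range(1980, 1983)})
        with pytest.raises(ValueError, match="empty"):
            interpolate_gaps(panel)

    def test_idempotent(self):
        panel = make_panel(years=(1980, 1990), n_fertilizer={
            ("beijing", 1980): 3.0, ("beijing", 1990): 33.0
        } | {("beijing", y): np.nan for y in range(1981, 1990)})
        once = interpolate_gaps(panel)
        twice = interpolate_gaps(once)
        pd.testing.assert_frame_equal(once.n_fertilizer, twice.n_fertilizer)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(intercept=st.floats(0.0, 100.0),
           slope=st.floats(0.0, 5.0),
           observed=st.sets(st.integers(1980, 1990), min_size=2))
    def test_exact_on_linear_series(self, intercept, slope, observed):
        observed = sorted(observed | {1980, 1990})
        cells = {("beijing", y): intercept + slope * (y - 1980)
                 for y in observed}
        cells |= {("beijing", y): np.nan
                  for y in range(1980, 1991) if y not in observed}
        panel = make_panel(years=(1980, 1990), n_fertilizer=cells)
        s = _nfert_series(interpolate_gaps(panel), "beijing")
        expect = intercept + slope * (np.arange(1980, 1991) - 1980)
        np.testing.assert_allclose(s.to_numpy(), expect, rtol=1e-12,
                                   atol=1e-9)

    def test_prefounding_child_years_become_zero(self):
        panel = make_panel(provinces=("chongqing",), years=(1995, 1999),
                           n_fertilizer={("chongqing", 1997): 7.0,
                                         ("chongqing", 1998): np.nan,
                                         ("chongqing", 1999): 9.0})
        s = _nfert_series(interpolate_gaps(panel), "chongqing")
        assert s.loc[1995] == 0.0 and s.loc[1996] == 0.0
        assert s.loc[1998] == pytest.approx(8.0)


class TestFolding:
    def test_prefounding_child_rows_summed_into_parent(self):
        panel = make_panel(provinces=("chongqing", "sichuan"),
                           years=(1996, 1998), n_fertilizer={
                               ("chongqing", 1996): 5.0,
                               ("sichuan", 1996): 7.0,
                               ("chongqing", 1997): 2.0,
                               ("sichuan", 1997): 3.0,
                           })
        out = fold_provinces(panel)
        sichuan = _nfert_series(out, "sichuan")
        assert sichuan.loc[1996] == 12.0
        chongqing = _nfert_series(out, "chongqing")
        assert 1996 not in chongqing.index  # folded away
        assert chongqing.loc[1997] == 2.0  # post-founding untouched
        assert sichuan.loc[1997] == 3.0

    def test_national_totals_conserved(self):
        rng = np.random.default_rng(0)
        provinces = ("guangdong", "hainan", "sichuan", "chongqing")
        years = (1985, 1998)
        cells = {
            "n_fertilizer": {(p, y): float(rng.uniform(0, 10))
                             for p in provinces
                             for y in range(years[0], years[1] + 1)},
            "crop_production": {(p, y, "wheat"): float(rng.uniform(0, 10))
                                for p in provinces
                                for y in range(years[0], years[1] + 1)},
        }
        panel = make_panel(provinces=provinces, years=years, **cells)
        out = fold_provinces(panel)
        for name in ("n_fertilizer", "crop_production"):
            before = getattr(panel, name).groupby("year")["value"].sum()
            after = getattr(out, name).groupby("year")["value"].sum()
            np.testing.assert_allclose(after.to_numpy(), before.to_numpy(),
                                       rtol=1e-9)

    def test_transition_intervals_fold_when_wholly_prefounding(self):
        panel = make_panel(provinces=("sichuan", "chongqing"),
                           years=(1980, 2000), land_transitions={
                               ("chongqing", 1980, 1990, "cropland_to_wood"): 10.0,
                               ("sichuan", 1980, 1990, "cropland_to_wood"): 5.0,
                               ("chongqing", 1990, 2000, "cropland_to_wood"): 4.0,
                           })
        out = fold_provinces(panel)
        lt = out.land_transitions.set_index(
            ["province", "interval_start", "change_type"])["value"]
        assert lt.loc[("sichuan", 1980, "cropland_to_wood")] == 15.0
        assert lt.loc[("chongqing", 1990, "cropland_to_wood")] == 4.0


class TestReadWrite:
    def test_roundtrip_preserves_values(self, tmp_path):
        panel = generate_panel(seed=5, provinces=3, years=(1990, 1995))
        write_panel(panel, tmp_path)
        back = read_panel(tmp_path, years=(1990, 1995))
        for name, df in panel.tables().items():
            other = getattr(back, name)
            sort_cols = [c for c in df.columns if c != "value"]
            a = df.sort_values(sort_cols).reset_index(drop=True)
            b = other.sort_values(sort_cols).reset_index(drop=True)
            np.testing.assert_allclose(a["value"], b["value"], rtol=1e-12)

    def test_minimal_single_cell_panel(self, tmp_path):
        panel = make_panel(provinces=("tibet",), years=(2000, 2000),
                           crop_production={("tibet", 2000, "wheat"): 1.0})
        write_panel(panel, tmp_path)
        back = read_panel(tmp_path, years=(2000, 2000))
        assert back.provinces() == ["tibet"]

    def test_duplicate_key_row_rejected(self, tmp_path):
        panel = make_panel()
        write_panel(panel, tmp_path)
        path = tmp_path / "n_fertilizer.csv"
        df = pd.read_csv(path)
        pd.concat([df, df.iloc[[0]]]).to_csv(path, index=False)
        with pytest.raises(ValueError, match="duplicate"):
            read_panel(tmp_path)

    def test_negative_activity_rejected(self, tmp_path):
        panel = make_panel()
        write_panel(panel, tmp_path)
        path = tmp_path / "crop_production.csv"
        df = pd.read_csv(path)
        df.loc[0, "production_t"] = -1.0
        df.to_csv(path, index=False)
        with pytest.raises(ValueError, match="negative activity"):
            read_panel(tmp_path)

    def test_unknown_labels_rejected(self, tmp_path):
        panel = make_panel()
        write_panel(panel, tmp_path)
        path = tmp_path / "crop_production.csv"
        df = pd.read_csv(path)
        df.loc[0, "province"] = "atlantis"
        df.to_csv(path, index=False)
        with pytest.raises(ValueError, match="province"):
            read_panel(tmp_path)


def test_registry_has_31_provinces_with_expected_folds():
    assert len(PROVINCES) == 31
    folds = {p.code: p.parent_before for p in PROVINCES if p.parent_before}
    assert folds == {"hainan": ("guangdong", 1988),
                     "chongqing": ("sichuan", 1997)}
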