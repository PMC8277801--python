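"""Parameter registry: published constants, distribution metadata,
config overrides and sampling behaviour."""

import numpy as np
import pandas as pd
import pytest

from cropghg.params import (REQUIRED_NAMES, ParamSpec, default_params,
                            get_value, load_params, sample_param)

from conftest import set_values


class TestRegistry:
    def test_every_model_parameter_resolves(self, ps):
        for name in REQUIRED_NAMES:
            assert name in ps
            spec = ps.spec(name)
            assert spec.units
            assert np.isfinite(spec.values_array()).all()

    @pytest.mark.parametrize("name,key,expected", [
        ("f_burn", None, 0.90),
        ("ef_crop_ch4", None, 3.23),
        ("ef_crop_n2o", None, 0.008),
        ("f_enn", None, 0.20),
        ("f_retu", None, 0.14),
        ("f_fvolat", None, 0.1),
        ("f_ovolat", None, 0.2),
        ("ef_crla_atm", None, 0.01),
        ("f_leach", None, 0.3),
        ("ef_crla_leach", None, 0.0075),
        ("ef_fert_co2", None, 6.08),
        ("ef_fert_ch4", None, 0.02),
        ("ef_fert_n2o", None, 0.0009),
        ("ef_pest", None, 16.35),
        ("gwp_ch4", None, 28.0),
        ("gwp_n2o", None, 265.0),
        ("f_bio", {"land_class": "cropland"}, 10.075),
        ("f_bio", {"land_class": "wood"}, 116.2),
        ("f_soil", {"land_class": "wood"}, 97.6),
        ("f_bio", {"land_class": "others"}, 11.5),
        ("f_soil", {"land_class": "others"}, 14.5),
        ("f_bio", {"land_class": "water_residential"}, 0.0),
        ("f_soil", {"land_class": "water_residential"}, 0.0),
    ])
    def test_published_constants(self, ps, name, key, expected):
        assert get_value(ps, name, key) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("name,dist,cv,a,b", [
        ("ef_fert_co2", "normal", 0.5, None, None),
        ("ef_crop_ch4", "normal", 0.17, None, None),
        ("ef_crop_n2o", "normal", 0.23, None, None),
        ("f_retu", "normal", 0.11, None, None),
        ("f_fvolat", "triangular", 0.0, 0.03, 0.3),
        ("f_ovolat", "triangular", 0.0, 0.05, 0.5),
        ("ef_crla_atm", "triangular", 0.0, 0.002, 0.05),
        ("f_leach", "triangular", 0.0, 0.1, 0.8),
        ("ef_crla_leach", "triangular", 0.0, 0.0005, 0.025),
        ("f_burn", "fixed", 0.0, None, None),
        ("f_enn", "fixed", 0.0, None, None),
    ])
    def test_distribution_metadata(self, ps, name, dist, cv, a, b):
        spec = ps.spec(name)
        assert spec.dist == dist
        assert spec.cv == pytest.approx(cv)
        assert spec.a == a and spec.b == b

    def test_rice_regime_weights_sum_to_one_exactly(self, ps):
        w = ps.series("f_regime_weight")
        assert w.sum() == 1.0
        assert w.loc["f_si"] == 2 * w.loc["f_ci"]

    def test_keyed_lookup_requires_exact_keys(self, ps):
        with pytest.raises(KeyError):
            get_value(ps, "f_leach", {"province": "beijing"})
        with pytest.raises(KeyError):
            get_value(ps, "f_open", None)
        with pytest.raises(KeyError):
            get_value(ps, "f_open", {"crop": "rice"})
        with pytest.raises(KeyError):
            get_value(ps, "no_such_parameter")

    def test_spec_validation_rejects_bad_blocks(self):
        with pytest.raises(ValueError):
            ParamSpec("x", 1.0, units="")
        with pytest.raises(ValueError):
            ParamSpec("x", 1.0, units="u", dist="lognormal")
        with pytest.raises(ValueError):
            ParamSpec("x", 1.0, units="u", dist="normal", cv=-0.1)
        with pytest.raises(ValueError):
            ParamSpec("x", 1.0, units="u", dist="triangular", a=2.0, b=3.0)


class TestConfigOverrides:
    def test_scalar_override_leaves_rest_unchanged(self, tmp_path, ps):
        cfg = tmp_path / "cfg.yaml"
        cfg.write_text("params:\n  f_burn: 1.0\n")
        out = load_params(cfg)
        assert get_value(out, "f_burn") == 1.0
        assert get_value(out, "ef_crop_ch4") == get_value(ps, "ef_crop_ch4")
        assert get_value(out, "f_open", {"province": "hebei"}) == \
            get_value(ps, "f_open", {"province": "hebei"})

    def test_unknown_name_rejected(self, tmp_path):
        cfg = tmp_path / "cfg.yaml"
        cfg.write_text("params:\n  not_a_parameter: 1.0\n")
        with pytest.raises(KeyError, match="not_a_parameter"):
            load_params(cfg)

    def test_keyed_csv_override(self, tmp_path):
        table = pd.DataFrame({
            "province": ["beijing", "tianjin"],
            "value": [0.5, 0.6],
            "units": "fraction", "dist": "fixed", "cv": 0.0,
        })
        table.to_csv(tmp_path / "f_open.csv", index=False)
        cfg = tmp_path / "cfg.yaml"
        cfg.write_text("params:\n  f_open: {file: f_open.csv}\n")
        out = load_params(cfg)
        assert get_value(out, "f_open", {"province": "beijing"}) == 0.5
        assert out.spec("f_open").dist == "fixed"

    def test_malformed_distribution_block_rejected(self, tmp_path):
        cfg = tmp_path / "cfg.yaml"
        cfg.write_text("params:\n  f_fvolat: {dist: triangular, a: 0.5}\n")
        with pytest.raises(ValueError):
            load_params(cfg)

    def test_gwp_swap_changes_only_weights(self, ps):
        alt = ps.with_gwp("20")
        assert get_value(alt, "gwp_ch4") == 84.0
        assert get_value(alt, "gwp_n2o") == 264.0
        assert get_value(alt, "ef_fert_co2") == get_value(ps, "ef_fert_co2")


class TestSampling:
    def test_fixed_dist_is_bit_identical_to_lookup(self, ps):
        rng = np.random.default_rng(0)
        for _ in range(5):
            assert sample_param(ps, "f_burn", rng) == get_value(ps, "f_burn")

    def test_triangular_mean_matches_closed_form(self, ps):
        # mean of triangular(a, mode, b) is (a + mode + b) / 3
        rng = np.random.default_rng(42)
        draws = np.array([sample_param(ps, "f_fvolat", rng)
                          for _ in range(50_000)])
        a, b, mode = 0.03, 0.3, 0.1
        expected = (a + b + mode) / 3
        var = (a**2 + b**2 + mode**2 - a*b - a*mode - b*mode) / 18
        se = np.sqrt(var / draws.size)
        assert abs(draws.mean() - expected) < 3 * se
        assert draws.min() >= a and draws.max() <= b

    def test_normal_percentiles_match_quantile_formula(self, ps):
        rng = np.random.default_rng(7)
        spec = ps.spec("ef_fert_co2")
        draws = rng.normal(spec.value, spec.value * spec.cv, 50_000)
        lo, hi = np.percentile(draws, [2.5, 97.5])
        assert lo == pytest.approx(6.08 * (1 - 1.96 * 0.5), abs=0.2)
        assert hi == pytest.approx(6.08 * (1 + 1.96 * 0.5), abs=0.2)
        # the sampler itself follows the same law
        many = np.array([sample_param(ps, "ef_fert_co2", rng)
                         for _ in range(50_000)])
        assert np.percentile(many, 2.5) == pytest.approx(lo, abs=0.25)
        assert np.percentile(many, 97.5) == pytest.approx(hi, abs=0.25)

    def test_keyed_sampling_preserves_index(self, ps):
        rng = np.random.default_rng(3)
        draw = sample_param(ps, "f_open", rng)
        assert isinstance(draw, pd.Series)
        assert draw.index.equals(ps.series("f_open").index)

    def test_negative_draws_not_truncated_by_default(self, ps):
        rng = np.random.default_rng(11)
        draws = np.array([sample_param(ps, "ef_fert_n2o", rng)
                          for _ in range(2_000)])
        assert (draws < 0).any()  # cv=0.5 normal leaves ~2.3% below zero
        floored = set_values(ps)  # copy via no-op override
        floored.floor_at_zero = True
        rng = np.random.default_rng(11)
        fdraws = np.array([sample_param(floored, "ef_fert_n2o", rng)
                           for _ in range(2_000)])
        assert (fdraws >= 0).all()

    def test_sample_all_realizes_every_spec(self, ps):
        realized = ps.sample_all(np.random.default_rng(5))
        assert realized.spec("ef_fert_co2").dist == "fixed"
        rng = np.random.default_rng(0)
        assert sample_param(realized, "ef_fert_co2", rng) == \
            realized.get("ef_fert_co2")
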