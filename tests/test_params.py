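"""Parameter registry: config I/O, validation, distribution fitting, PSA draws."""

import dataclasses
import math

import numpy as np
import pytest
import scipy.stats
import yaml

from dkdcea import params
from dkdcea.params import (REGISTRY, ConfigError, ScenarioError, base_inputs,
                           dump_inputs, fit_distribution, load_inputs,
                           sample_psa, scenario)


class TestLoadInputs:
    def test_packaged_defaults_carry_published_values(self, base):
        assert base["aikd_sensitivity"] == 0.51
        assert base["aikd_specificity"] == 0.93
        assert base["soc_sensitivity"] == 0.28
        assert base["soc_specificity"] == 0.88
        assert base["cost_test"] == 1050
        assert base["discount_rate"] == 0.03
        assert base["time_horizon"] == 5
        assert base["utility_constant"] == 0.944

    def test_packaged_defaults_match_in_code_registry(self, base):
        assert base.values == {n: s.base for n, s in REGISTRY.items()}

    def test_missing_parameter_is_named_in_error(self, base, tmp_path):
        doc = yaml.safe_load(dump_inputs(base))
        del doc["parameters"]["general"]["discount_rate"]
        p = tmp_path / "broken.yaml"
        p.write_text(yaml.safe_dump(doc))
        with pytest.raises(ConfigError, match="discount_rate"):
            load_inputs(p)

    def test_unknown_parameter_rejected(self, base, tmp_path):
        doc = yaml.safe_load(dump_inputs(base))
        doc["parameters"]["cost"]["cost_of_unicorns"] = {"base": 1.0}
        p = tmp_path / "broken.yaml"
        p.write_text(yaml.safe_dump(doc))
        with pytest.raises(ConfigError, match="cost_of_unicorns"):
            load_inputs(p)

    def test_out_of_domain_value_names_parameter(self, base, tmp_path):
        doc = yaml.safe_load(dump_inputs(base))
        doc["parameters"]["test_performance"]["aikd_sensitivity"]["base"] = 1.7
        p = tmp_path / "broken.yaml"
        p.write_text(yaml.safe_dump(doc))
        with pytest.raises(ConfigError, match="aikd_sensitivity"):
            load_inputs(p)

    def test_round_trip_is_lossless(self, base, tmp_path):
        p = tmp_path / "roundtrip.yaml"
        dump_inputs(base, p)
        reloaded = load_inputs(p)
        assert reloaded.values == base.values
        assert reloaded.settings == base.settings
        assert reloaded.scenario == base.scenario


class TestFitDistribution:
    def test_beta_moment_match_worked_example(self):
        # sensitivity-style parameter: mean 0.51, 95% range 0.41-0.61
        spec = REGISTRY["aikd_sensitivity"]
        h = fit_distribution(spec)
        assert h["family"] == "beta"
        assert h["alpha"] == pytest.approx(48.45, rel=1e-3)
        assert h["beta"] == pytest.approx(46.55, rel=1e-3)

    def test_normal_sd_is_range_over_3_92(self):
        spec = REGISTRY["hr_comp_fp"]
        h = fit_distribution(spec)
        assert h["family"] == "normal"
        assert h["mean"] == 0.95
        assert h["sd"] == pytest.approx(0.1 / 3.92)

    def test_uniform_uses_printed_endpoints(self):
        h = fit_distribution(REGISTRY["cost_education"])
        assert h == {"family": "uniform", "low": 108, "high": 179}

    @pytest.mark.parametrize(
        "name", [n for n, s in REGISTRY.items() if s.distribution != "fixed"]
    )
    def test_fitted_moments_agree_with_scipy(self, name):
        """Independent check: scipy's analytic moments of the fitted law
        reproduce mean=base and sd=(high-low)/3.92 (uniform: endpoints)."""
        spec = REGISTRY[name]
        h = fit_distribution(spec)
        if h["family"] == "uniform":
            dist = scipy.stats.uniform(h["low"], h["high"] - h["low"])
            assert dist.mean() == pytest.approx((spec.low + spec.high) / 2)
            return
        if h["family"] == "beta":
            dist = scipy.stats.beta(h["alpha"], h["beta"])
        elif h["family"] == "gamma":
            dist = scipy.stats.gamma(h["shape"], scale=h["scale"])
        else:
            dist = scipy.stats.norm(h["mean"], h["sd"])
        assert dist.mean() == pytest.approx(spec.base, abs=1e-9)
        assert dist.std() == pytest.approx((spec.high - spec.low) / 3.92,
                                           abs=1e-9)

    def test_infeasible_beta_falls_back_to_fixed(self):
        spec = dataclasses.replace(REGISTRY["aikd_sensitivity"],
                                   base=0.01, low=0.0, high=1.0)
        assert fit_distribution(spec)["family"] == "fixed"

    def test_fixed_parameters_have_no_distribution(self):
        with pytest.raises(ConfigError):
            fit_distribution(REGISTRY["discount_rate"])


class TestSamplePSA:
    def test_reproducible_under_seed(self, base):
        a = sample_psa(base, 50, seed=123)
        b = sample_psa(base, 50, seed=123)
        assert all(x.values == y.values for x, y in zip(a, b))

    def test_all_fixed_degenerates_to_base(self, base, monkeypatch):
        fixed = {n: dataclasses.replace(s, distribution="fixed")
                 for n, s in REGISTRY.items()}
        monkeypatch.setattr(params, "REGISTRY", fixed)
        draws = sample_psa(base, 5, seed=1)
        assert all(d.values == base.values for d in draws)

    def test_sample_means_converge_to_base(self, base):
        draws = sample_psa(base, 10_000, seed=2024)
        for name in ("aikd_sensitivity", "cost_g3a", "utility_constant",
                     "rr_pdkf_g2", "cost_education"):
            spec = REGISTRY[name]
            vals = np.array([d[name] for d in draws])
            if spec.distribution == "uniform":
                expected = (spec.low + spec.high) / 2
                sd = (spec.high - spec.low) / math.sqrt(12)
            else:
                expected = spec.base
                sd = (spec.high - spec.low) / 3.92
            se = sd / math.sqrt(len(vals))
            assert abs(vals.mean() - expected) < 4 * se, name

    def test_draws_respect_parameter_domains(self, base):
        draws = sample_psa(base, 2_000, seed=5)
        for d in draws:
            assert d["rr_pdkf_g1"] >= 1.0       # truncated normal
            assert 0.0 < d["hr_comp_fp"] <= 1.0
            assert 0.0 <= d["aikd_specificity"] <= 1.0
            assert d["cost_g5"] > 0.0

    def test_stage_shares_remain_a_distribution(self, base):
        draws = sample_psa(base, 200, seed=6)
        for d in draws:
            total = sum(d[f"stage_share_{s}"] for s in params.EARLY_STAGES)
            assert total == pytest.approx(1.0, abs=1e-12)


class TestScenario:
    def test_high_risk_sets_half_prevalence_everywhere(self, base):
        hr = scenario(base, "high_risk")
        for s in params.EARLY_STAGES:
            assert hr[f"pdkf_prevalence_{s}"] == 0.50
        assert hr["pdkf_prevalence_overall"] == 0.50
        # everything else untouched
        same = {k: v for k, v in hr.values.items()
                if not k.startswith("pdkf_prevalence")}
        assert same == {k: v for k, v in base.values.items()
                        if not k.startswith("pdkf_prevalence")}

    def test_base_case_is_identity(self, base):
        assert scenario(base, "base_case").values == base.values

    def test_liberal_without_overrides_errors(self, base):
        with pytest.raises(ScenarioError, match="scenario inputs required"):
            scenario(base, "liberal")

    def test_liberal_applies_overrides(self, base):
        lib = scenario(base, "liberal",
                       {"aikd_sensitivity": 0.70, "aikd_specificity": 0.80})
        assert lib["aikd_sensitivity"] == 0.70
        assert lib["aikd_specificity"] == 0.80
        assert lib.scenario == "liberal"

    def test_liberal_rejects_non_test_overrides(self, base):
        with pytest.raises(ScenarioError):
            scenario(base, "liberal", {"cost_test": 0.0})
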