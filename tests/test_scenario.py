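"""Scenario engine: pipeline stages, determinism, variance inflation."""

import numpy as np
import pytest

from ptabias import metrics
from ptabias.distributions import ScalarSpec, UniformSpec, lognormal_from_mean_cv
from ptabias.scenario import (
    IndexSample,
    ScenarioConfig,
    back_scale,
    run_scenario,
    simulate_reference,
    to_total,
)


def make_config(**kw):
    base = dict(
        dose=10.0,
        mic=1.0,
        cl_spec=lognormal_from_mean_cv(7, 0.10),
        fu_generate=lognormal_from_mean_cv(0.5, 0.15),
        fu_scale=ScalarSpec(0.5),
        n=5000,
        seed=7,
    )
    base.update(kw)
    return ScenarioConfig(**base)


class TestReference:
    def test_degenerate_clearance_gives_constant_index(self):
        cfg = make_config(cl_spec=ScalarSpec(7.0), n=10)
        ref = simulate_reference(cfg)
        assert np.allclose(ref.values, 10 / 7)

    def test_reference_q10_near_its_analytic_value(self):
        # closed form: (dose/mic) * exp(-(mu_cl + z_0.90 * sigma_cl)) ~ 1.2635
        ref = simulate_reference(make_config())
        assert metrics.quantile(ref, 0.10) == pytest.approx(1.2635, abs=0.03)

    def test_deterministic_given_seed(self):
        a = simulate_reference(make_config())
        b = simulate_reference(make_config())
        assert np.array_equal(a.values, b.values)

    def test_mic_divides_the_index(self):
        lo = simulate_reference(make_config(mic=1.0))
        hi = simulate_reference(make_config(mic=2.0))
        assert np.allclose(hi.values, lo.values / 2)


class TestTotal:
    def test_scalar_fu_rescales_exactly(self):
        cfg = make_config(fu_generate=ScalarSpec(0.5))
        ref = simulate_reference(cfg)
        tot = to_total(ref, cfg)
        assert np.allclose(tot.values, 2 * ref.values)

    def test_uniform_fu_bounds_totals_elementwise(self):
        cfg = make_config(fu_generate=UniformSpec(0.05, 0.15))
        ref = simulate_reference(cfg)
        tot = to_total(ref, cfg)
        assert np.all(tot.values >= ref.values / 0.15 - 1e-12)
        assert np.all(tot.values <= ref.values / 0.05 + 1e-12)

    def test_log_variance_adds_for_independent_lognormals(self):
        # Var ln(total) = sigma_cl^2 + sigma_fu^2 at large n
        cfg = make_config(n=10**6)
        tot = to_total(simulate_reference(cfg), cfg)
        expected = 0.09975**2 + 0.149166**2
        observed = np.var(np.log(tot.values))
        # SE of a normal-sample variance: sigma^2 * sqrt(2/(n-1))
        assert abs(observed - expected) < 3 * expected * np.sqrt(2 / (10**6 - 1))

    def test_variance_inflation_whenever_fu_varies(self):
        for gen in (lognormal_from_mean_cv(0.5, 0.15), UniformSpec(0.05, 0.15)):
            cfg = make_config(fu_generate=gen)
            ref = simulate_reference(cfg)
            tot = to_total(ref, cfg)
            assert np.var(np.log(tot.values)) > np.var(np.log(ref.values))


class TestBackScale:
    def test_scalar_scaling_inverts_degenerate_generation(self):
        cfg = make_config(fu_generate=ScalarSpec(0.5), fu_scale=ScalarSpec(0.5))
        ref = simulate_reference(cfg)
        back = back_scale(to_total(ref, cfg), cfg)
        assert np.allclose(back.values, ref.values)

    def test_distribution_scaling_draws_are_independent_of_generation(self):
        # scaling by the same law that generated fu must NOT reproduce the
        # reference: the analyst's draws are a fresh independent stream
        cfg = make_config(fu_generate=UniformSpec(0.05, 0.15),
                          fu_scale=UniformSpec(0.05, 0.15))
        ref = simulate_reference(cfg)
        back = back_scale(to_total(ref, cfg), cfg)
        assert not np.allclose(back.values, ref.values)
        assert np.var(np.log(back.values)) > np.var(np.log(ref.values))

    def test_all_paper_scenarios_have_negative_q10_bias(self, paper_scenarios):
        for cfg in paper_scenarios:
            res = run_scenario(cfg)
            assert res.bias[0.10].bias_percent < 0, cfg.label

    def test_median_bias_much_smaller_than_q10_bias(self, paper_scenarios):
        for cfg in paper_scenarios:
            res = run_scenario(cfg)
            assert abs(res.bias[0.50].bias_percent) < abs(res.bias[0.10].bias_percent)


class TestRunScenario:
    def test_all_degenerate_specs_give_zero_bias_exactly(self):
        cfg = make_config(cl_spec=ScalarSpec(7.0), fu_generate=ScalarSpec(0.5),
                          fu_scale=ScalarSpec(0.5), n=100)
        res = run_scenario(cfg)
        assert np.array_equal(res.back.values, res.reference.values)
        assert res.bias[0.10].bias_percent == 0.0
        assert res.dose_exact.dose == pytest.approx(cfg.dose)

    def test_dose_linearity_is_exact(self):
        r1 = run_scenario(make_config(dose=10.0))
        r2 = run_scenario(make_config(dose=23.0))
        k = 2.3
        for a, b in [(r1.reference, r2.reference), (r1.total, r2.total),
                     (r1.back, r2.back)]:
            assert np.allclose(b.values, k * a.values, rtol=1e-14)

    def test_scaling_by_distribution_biases_more_than_its_central_scalar(self):
        pairs = [
            (ScalarSpec(0.5), UniformSpec(0.40, 0.60), lognormal_from_mean_cv(0.5, 0.15)),
            (ScalarSpec(0.1), UniformSpec(0.05, 0.15), UniformSpec(0.05, 0.15)),
        ]
        for scalar, dist, gen in pairs:
            b_scalar = run_scenario(make_config(fu_generate=gen, fu_scale=scalar))
            b_dist = run_scenario(make_config(fu_generate=gen, fu_scale=dist))
            assert b_dist.bias[0.10].bias_percent < b_scalar.bias[0.10].bias_percent

    def test_result_bundles_consistent_metrics(self):
        res = run_scenario(make_config())
        assert res.target == pytest.approx(metrics.quantile(res.reference, 0.10))
        assert res.pct_achieving == pytest.approx(
            metrics.percent_achieving(res.back, res.target))
        assert res.ref_quantiles[0.10] < res.ref_quantiles[0.50] < res.ref_quantiles[0.90]


class TestValidationAndExport:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            make_config(dose=0.0)
        with pytest.raises(ValueError):
            make_config(n=1)
        with pytest.raises(TypeError):
            make_config(cl_spec=7.0)

    def test_index_sample_rejects_bad_labels_and_values(self):
        with pytest.raises(ValueError):
            IndexSample(values=np.array([1.0]), label="bogus")
        with pytest.raises(ValueError):
            IndexSample(values=np.array([1.0, -2.0]), label="total")

    def test_single_column_csv_export(self, tmp_path):
        ref = simulate_reference(make_config(n=5))
        path = tmp_path / "ref.csv"
        ref.to_csv(path)
        lines = path.read_text().strip().splitlines()
        assert lines[0] == "reference_free_auc_mic_days"
        assert len(lines) == 6
        assert np.allclose([float(v) for v in lines[1:]], ref.values)
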