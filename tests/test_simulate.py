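"""Synthetic-population generator: additivity, moments, thinning, correlations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from flowdecon import (
    DualReporterParams,
    NoiseModel,
    PopulationSpec,
    ScenarioConfig,
    SignalParams,
    SurvivalModel,
    apply_survival_thinning,
    default_autofluorescence,
    sample_signal,
    synthesize_dual_reporter,
    synthesize_population,
    synthesize_scenario,
)


class TestSampleSignal:
    def test_empty_draw(self):
        assert sample_signal(SignalParams(1, 1), n=0, seed=0).size == 0

    def test_mean_within_standard_error_bound(self):
        # Gamma(0.5, 100): mean 50, SE of the mean sqrt(k theta^2 / n)
        draws = sample_signal(SignalParams(0.5, 100.0), n=100_000, seed=7)
        assert abs(draws.mean() - 50.0) < 3 * np.sqrt(0.5 * 100.0**2 / 100_000)
        assert np.all(draws > 0)

    def test_seed_determinism(self):
        a = sample_signal(SignalParams(2, 3), n=100, seed=11)
        b = sample_signal(SignalParams(2, 3), n=100, seed=11)
        np.testing.assert_array_equal(a, b)

    @pytest.mark.parametrize("shape,scale", [(0, 1), (-1, 1), (1, 0), (1, -2)])
    def test_invalid_parameters_rejected(self, shape, scale):
        with pytest.raises(ValueError):
            SignalParams(shape, scale)


class TestSynthesizePopulation:
    def test_additivity_is_exact_with_constant_noise(self):
        noise = NoiseModel.parametric(mean=5.0, variance=0.0)
        table = synthesize_population(SignalParams(1, 10), noise, n=4, seed=0)
        np.testing.assert_array_equal(
            table["yfp"].to_numpy(), table["latent_signal"].to_numpy() + 5.0
        )

    def test_additivity_identity_holds_eventwise(self):
        table = synthesize_population(
            SignalParams(0.5, 20), default_autofluorescence(), n=5_000, seed=3
        )
        # R is stored as the float sum S + N, so recomputing the sum matches bitwise
        np.testing.assert_array_equal(
            table["yfp"].to_numpy(),
            table["latent_signal"].to_numpy() + table["latent_noise"].to_numpy(),
        )

    def test_variance_additivity_at_scale(self):
        # Var(R) = Var(S) + Var(N) within sampling error
        noise = NoiseModel.parametric(mean=4.0, variance=2.0)
        table = synthesize_population(SignalParams(1, 10), noise, n=30_000, seed=5)
        expected = 1 * 10.0**2 + 2.0
        assert table["yfp"].var(ddof=1) == pytest.approx(expected, rel=0.05)

    def test_empty_population(self):
        table = synthesize_population(
            SignalParams(1, 1), default_autofluorescence(), n=0, seed=0
        )
        assert len(table) == 0

    def test_empty_empirical_pool_rejected(self):
        with pytest.raises(ValueError):
            NoiseModel.empirical([])


class TestSurvivalThinning:
    def test_identity_survival_retains_everything(self):
        table = synthesize_population(
            SignalParams(2, 1), default_autofluorescence(), n=1_000, seed=1
        )
        out = apply_survival_thinning(table, SurvivalModel(p0=1.0, beta=0.0), seed=2)
        assert len(out) == len(table)
        assert (out["condition"] == "post").all()

    def test_near_total_killing_empties_table(self):
        table = synthesize_population(
            SignalParams(2, 1), default_autofluorescence(), n=500, seed=1
        )
        out = apply_survival_thinning(table, SurvivalModel(p0=1e-300, beta=0.0), seed=2)
        assert len(out) == 0

    def test_requires_latent_signal(self):
        table = pd.DataFrame({"yfp": [1.0, 2.0]})
        with pytest.raises(ValueError, match="latent_signal"):
            apply_survival_thinning(table, SurvivalModel(p0=0.5, beta=0.0), seed=0)

    def test_nonnormalizable_tilt_warns(self):
        table = synthesize_population(
            SignalParams(2, 3), default_autofluorescence(), n=100, seed=1
        )
        with pytest.warns(RuntimeWarning, match="not normalizable"):
            apply_survival_thinning(
                table,
                SurvivalModel(p0=0.01, beta=0.5),
                seed=2,
                signal=SignalParams(2, 3),
            )

    def test_exponential_tilting_law(self):
        # survivors of p(s) = p0 e^{beta s} thinning of Gamma(k, theta) follow
        # Gamma(k, theta / (1 - beta theta)); checked two ways at n ~ 1e4:
        # against the closed form and against direct rejection sampling
        k, theta, beta, p0 = 2.0, 1.0, 0.5, 3e-4
        table = synthesize_population(
            SignalParams(k, theta),
            NoiseModel.parametric(mean=1.0, variance=0.0),
            n=4_000_000,
            seed=9,
        )
        out = apply_survival_thinning(table, SurvivalModel(p0=p0, beta=beta), seed=10)
        survivors = out["latent_signal"].to_numpy()
        assert survivors.size > 3_000
        tilted_scale = theta / (1 - beta * theta)
        p_closed = stats.kstest(
            survivors, stats.gamma(a=k, scale=tilted_scale).cdf
        ).pvalue
        assert p_closed > 0.01

        # independent oracle: rejection sampling with the same survival rule
        rng = np.random.default_rng(11)
        pool = rng.gamma(k, theta, size=4_000_000)
        oracle = pool[rng.random(pool.size) < np.minimum(1, p0 * np.exp(beta * pool))]
        p_two_sample = stats.ks_2samp(survivors, oracle).pvalue
        assert p_two_sample > 0.01


class TestDualReporter:
    def test_pure_extrinsic_limit_is_perfectly_correlated(self):
        params = DualReporterParams(extrinsic_cv=0.5, intrinsic_cv=0.0, n=2_000)
        table = synthesize_dual_reporter(params, seed=0)
        r = np.corrcoef(table["yfp"], table["mcherry"])[0, 1]
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_independence_limit_is_uncorrelated(self):
        params = DualReporterParams(extrinsic_cv=0.0, intrinsic_cv=0.5, n=10_000)
        table = synthesize_dual_reporter(params, seed=1)
        r = np.corrcoef(table["yfp"], table["mcherry"])[0, 1]
        assert abs(r) < 0.05

    def test_correlation_matches_product_variable_formula(self):
        ce, ci = 0.5, 0.3
        expected = ce**2 / (ce**2 + ci**2 + ce**2 * ci**2)
        rs = []
        for seed in range(5):
            table = synthesize_dual_reporter(
                DualReporterParams(extrinsic_cv=ce, intrinsic_cv=ci, n=100_000),
                seed=seed,
            )
            rs.append(np.corrcoef(table["yfp"], table["mcherry"])[0, 1])
        assert np.mean(rs) == pytest.approx(expected, abs=0.015)


class TestScenario:
    def _config(self, survival=None):
        spec = PopulationSpec(
            signal=SignalParams(1.0, 10.0),
            noise=default_autofluorescence(),
            survival=survival,
            n=2_000,
        )
        return spec

    def test_seed_streams_are_label_stable(self):
        config = ScenarioConfig(
            populations={"a": self._config(), "b": self._config()}
        )
        tables = synthesize_scenario(config, seed=42)
        assert not np.array_equal(tables["a"]["yfp"], tables["b"]["yfp"])
        # same parameters, different streams: summary moments agree loosely
        assert tables["a"]["yfp"].mean() == pytest.approx(
            tables["b"]["yfp"].mean(), rel=0.1
        )
        # adding a population never perturbs existing streams
        bigger = ScenarioConfig(
            populations={"a": self._config(), "b": self._config(), "c": self._config()}
        )
        again = synthesize_scenario(bigger, seed=42)
        np.testing.assert_array_equal(tables["a"]["yfp"], again["a"]["yfp"])

    def test_panel_cardinality(self):
        config = ScenarioConfig(
            populations={f"g{i}": self._config() for i in range(4)}
        )
        tables = synthesize_scenario(config, seed=0)
        assert len(tables) == 4
        assert all(len(t) == 2_000 for t in tables.values())

    def test_survival_label_emits_paired_conditions(self):
        config = ScenarioConfig(
            populations={"treated": self._config(SurvivalModel(p0=0.5, beta=0.0))}
        )
        table = synthesize_scenario(config, seed=0)["treated"]
        conditions = set(table["condition"].unique())
        assert conditions == {"pre", "post"}

    def test_reproducibility_is_bytewise(self):
        config = ScenarioConfig(populations={"a": self._config()})
        t1 = synthesize_scenario(config, seed=5)["a"]
        t2 = synthesize_scenario(config, seed=5)["a"]
        pd.testing.assert_frame_equal(t1, t2)

    def test_invalid_dual_reporter_params_rejected(self):
        with pytest.raises(ValueError):
            DualReporterParams(extrinsic_cv=-1, intrinsic_cv=0)
        with pytest.raises(ValueError):
            DualReporterParams(extrinsic_cv=0.1, intrinsic_cv=0.1, n=0)


@given(
    shape=st.floats(0.1, 10, allow_nan=False),
    scale=st.floats(0.1, 1e3, allow_nan=False),
)
def test_signal_params_moments_roundtrip(shape, scale):
    params = SignalParams(shape, scale)
    rebuilt = SignalParams.from_moments(params.mean, params.variance)
    assert rebuilt.shape == pytest.approx(shape, rel=1e-9)
    assert rebuilt.scale == pytest.approx(scale, rel=1e-9)
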