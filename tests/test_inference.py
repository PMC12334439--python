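"""HPD computation, variable selection and sampler contracts."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, strategies as st

from gxetwin.inference import (
    MCMCConfig,
    PosteriorSummary,
    fit,
    fit_sum_scores,
    hpd,
    select_variables,
)
from gxetwin.model_core import ModelConfig
from gxetwin.synthetic import (
    generate_dataset,
    hyperactivity_scenario,
    null_moderation_scenario,
)
from _oracles import brute_force_hpd


class TestHPD:
    def test_uniform_grid_tie_break(self):
        # symmetric grid: every 95%-window ties; smallest lower bound wins
        draws = np.arange(21.0)
        assert hpd(draws, 0.95) == (0.0, 19.0)

    def test_skewed_sample_shorter_than_equal_tails(self, rng):
        d = rng.exponential(size=2000)
        lo, hi = hpd(d, 0.95)
        eq = np.quantile(d, [0.025, 0.975])
        assert (hi - lo) < (eq[1] - eq[0])
        assert lo < np.quantile(d, 0.01)  # mass hugs zero

    @given(
        data=st.lists(st.floats(-50, 50), min_size=25, max_size=120),
        mass=st.sampled_from([0.5, 0.8, 0.95]),
    )
    def test_matches_brute_force_scan(self, data, mass):
        lo, hi = hpd(np.array(data), mass)
        blo, bhi = brute_force_hpd(data, mass)
        assert (hi - lo) == pytest.approx(bhi - blo, abs=0.0)

    def test_too_few_draws(self):
        with pytest.raises(ValueError, match="draws"):
            hpd(np.arange(10), 0.95)
        with pytest.raises(ValueError, match="mass"):
            hpd(np.arange(100), 1.2)


def _summary(slopes: dict[str, np.ndarray], decomposition="AE"):
    """Posterior stub with the given per-variable slope draws."""
    moderators = tuple(slopes)
    config = ModelConfig(
        decomposition=decomposition,
        moderators=moderators,
        means_covariates=moderators,
    )
    draws = {f"beta1_A:{v}": d.reshape(1, -1) for v, d in slopes.items()}
    return PosteriorSummary(
        draws, structural=tuple(draws), config=config, n_families=100
    )


class TestSelectVariables:
    def test_hpd_exclusion_rule(self, rng):
        # centre/width chosen to reproduce published category-model HPDs
        def slope(lo, hi):
            return rng.uniform(lo, hi, 4000)  # uniform: HPD ~ [lo, hi]

        fits = {
            "personality": _summary({"conscientiousness": slope(0.10, 0.33)}),
            "school": _summary({"satisfaction_school": slope(-0.02, 0.49)}),
            "callous": _summary({"callousness": slope(-1.0, 1.0)}),
        }
        config, decisions = select_variables(fits)
        assert config.moderators == ("conscientiousness",)
        assert config.means_covariates == config.moderators
        by_var = {d.variable: d for d in decisions}
        assert by_var["conscientiousness"].included
        assert not by_var["satisfaction_school"].included  # straddles zero
        assert not by_var["callousness"].included

    def test_all_null_yields_empty_valid_config(self, rng):
        fits = {"only": _summary({"x": rng.normal(0, 1, 2000)})}
        config, _ = select_variables(fits)
        assert config.moderators == ()

    def test_idempotent_and_order_invariant(self, rng):
        a = _summary({"x": rng.normal(0.5, 0.05, 2000)})
        b = _summary({"y": rng.normal(0.0, 1.0, 2000)})
        c1, _ = select_variables({"a": a, "b": b})
        c2, _ = select_variables({"b": b, "a": a})
        assert c1 == c2
        refit = {"final": _summary({v: rng.normal(0.5, 0.05, 2000)
                                    for v in c1.moderators})}
        c3, _ = select_variables(refit)
        assert c3.moderators == c1.moderators

    def test_duplicate_variable_rejected(self, rng):
        d = rng.normal(size=2000)
        with pytest.raises(ValueError, match="appears in"):
            select_variables({"a": _summary({"x": d}), "b": _summary({"x": d})})


@pytest.fixture(scope="module")
def small_dataset():
    scenario = null_moderation_scenario(20, 30)
    return scenario, generate_dataset(scenario, seed=42)


class TestFitContracts:
    def test_single_chain_fixed_seed_is_deterministic(self, small_dataset):
        scenario, records = small_dataset
        mcmc = MCMCConfig(chains=1, warmup=50, draws=50, seed=9)
        s1 = fit(records, scenario.model_config(), mcmc)
        s2 = fit(records, scenario.model_config(), mcmc)
        for name in s1.draws:
            assert np.array_equal(s1.draws[name], s2.draws[name])
        assert any("single-chain" in w for w in s1.warnings)

    def test_requires_both_zygosity_groups(self, small_dataset):
        scenario, records = small_dataset
        mz_only = [r for r in records if r.zygosity == "MZ"] * 2
        with pytest.raises(ValueError, match="MZ and 2 DZ"):
            fit(mz_only, scenario.model_config(), MCMCConfig(warmup=5, draws=5))

    def test_degenerate_responses_rejected(self, small_dataset):
        scenario, records = small_dataset
        flat = [
            dataclasses.replace(
                r,
                items_twin1=np.full(9, 4.0),
                items_twin2=np.full(9, 4.0),
            )
            for r in records
        ]
        with pytest.raises(ValueError, match="degenerate"):
            fit(flat, scenario.model_config(), MCMCConfig(warmup=5, draws=5))

    def test_missing_moderator_column_is_structured_error(self, small_dataset):
        scenario, records = small_dataset
        config = ModelConfig(
            decomposition="AE", moderators=("chaos",), means_covariates=("chaos",)
        )
        with pytest.raises(KeyError, match="chaos"):
            fit(records, config, MCMCConfig(warmup=5, draws=5))

    def test_posterior_summary_table_columns(self, small_dataset):
        scenario, records = small_dataset
        summary = fit(
            records, scenario.model_config(),
            MCMCConfig(chains=2, warmup=60, draws=60, seed=1),
        )
        table = summary.table()
        assert list(table.columns) == [
            "parameter", "mean", "median", "hpd_low", "hpd_high", "rhat", "ess",
        ]
        assert (table.hpd_low < table.hpd_high).all()
        # item parameters are sampled alongside the structural ones
        assert "disc:item1" in summary.draws
        assert summary.point("beta0_A", "median") == pytest.approx(
            np.median(summary.flat("beta0_A"))
        )


class TestSumScoreModel:
    def test_recovers_a_and_e_from_continuous_scores(self):
        # large AE scenario, no moderation: the sum-score twin model should
        # put the MZ/DZ covariance contrast into A (scores standardised, so
        # compare proportions rather than raw variances)
        scenario = hyperactivity_scenario(600, 900)
        scenario = dataclasses.replace(
            scenario,
            components=dataclasses.replace(
                scenario.components, beta1_A=np.zeros(3)
            ),
        )
        records = generate_dataset(scenario, seed=17)
        summary = fit_sum_scores(
            records, scenario.model_config(),
            MCMCConfig(chains=1, warmup=400, draws=400, seed=2),
        )
        va = np.exp(summary.point("beta0_A"))
        ve = np.exp(summary.point("beta0_E"))
        h2 = va / (va + ve)
        # attenuated toward E by item-level measurement error, but the
        # genetic share should remain substantial and below the latent 0.425
        assert 0.15 < h2 < 0.55

    def test_hpd_width_shrinks_with_sample_size(self):
        widths = {}
        for n in (250, 1000):
            scenario = null_moderation_scenario().scaled(n)
            records = generate_dataset(scenario, seed=5)
            summary = fit_sum_scores(
                records, scenario.model_config(),
                MCMCConfig(chains=1, warmup=400, draws=500, seed=3),
            )
            lo, hi = summary.hpd_interval("beta1_A:environment")
            widths[n] = hi - lo
        assert widths[1000] < widths[250]
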