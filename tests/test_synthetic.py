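"""Statistical structure of the synthetic twin-study generator."""

import dataclasses

import numpy as np
import pytest

from gxetwin.model_core import MeansModel, VarianceComponents
from gxetwin.synthetic import (
    GeneratorScenario,
    default_items,
    generate_dataset,
    generate_environments,
    generate_latent_traits,
    hyperactivity_scenario,
    inattentiveness_scenario,
    null_moderation_scenario,
    skewed_items,
    skewed_null_scenario,
)
from gxetwin.irt import sum_score
from gxetwin import io as gio


def _cov_se(v1, v2, c, n):
    """Standard error of an empirical covariance of a bivariate normal."""
    return np.sqrt((v1 * v2 + c**2) / (n - 1))


class TestEnvironments:
    @pytest.mark.parametrize("rho", [0.0, 0.4, 0.99])
    def test_within_pair_correlation(self, rho):
        sc = dataclasses.replace(
            null_moderation_scenario(1000, 1000), env_within_pair_corr=rho
        )
        env = generate_environments(sc, np.random.default_rng(3))["environment"]
        r = np.corrcoef(env[:, 0], env[:, 1])[0, 1]
        tol = 0.05 if rho > 0 else 3 / np.sqrt(2000)
        assert abs(r - rho) < tol
        # standardised marginals
        assert abs(env.mean()) < 0.05 and abs(env.std() - 1) < 0.05

    def test_invalid_correlation_rejected(self):
        with pytest.raises(ValueError, match="within-pair correlation"):
            dataclasses.replace(
                null_moderation_scenario(), env_within_pair_corr=1.0
            )


class TestLatentTraits:
    def test_cross_twin_covariances_match_components(self):
        # AE at the hyperactivity point estimates, no moderation
        base = hyperactivity_scenario(5000, 5000)
        sc = dataclasses.replace(
            base,
            components=VarianceComponents(
                beta0_A=np.log(0.17), beta0_E=np.log(0.23),
                beta1_A=[0.0, 0.0, 0.0],
            ),
            # zero the means structure so the cross-twin covariance is purely
            # the biometric part (environment effects add their own share)
            means=dataclasses.replace(
                base.means,
                beta_m_mz=np.zeros(3), beta_mc_mz=np.zeros(3),
                beta_m_dz=np.zeros(3), beta_mc_dz=np.zeros(3),
            ),
        )
        rng = np.random.default_rng(7)
        theta = generate_latent_traits(sc, generate_environments(sc, rng), rng)
        mz, dz = theta[:5000], theta[5000:]
        cov_mz = np.cov(mz.T)[0, 1]
        cov_dz = np.cov(dz.T)[0, 1]
        se = _cov_se(0.45, 0.45, 0.17, 5000)
        assert abs(cov_mz - 0.17) < 3 * se + 0.01
        assert abs(cov_dz - 0.085) < 3 * se + 0.01

    def test_ace_covariances(self):
        comp = VarianceComponents(
            beta0_A=np.log(0.09), beta0_C=np.log(0.07), beta0_E=np.log(0.38)
        )
        sc = GeneratorScenario(
            n_mz_pairs=5000, n_dz_pairs=5000, components=comp,
            means=MeansModel(), items=default_items(),
        )
        rng = np.random.default_rng(11)
        theta = generate_latent_traits(sc, generate_environments(sc, rng), rng)
        se = _cov_se(0.54, 0.54, 0.16, 5000)
        assert abs(np.cov(theta[:5000].T)[0, 1] - 0.16) < 3 * se
        assert abs(np.cov(theta[5000:].T)[0, 1] - 0.115) < 3 * se

    def test_no_genetic_no_shared_means_uncorrelated(self):
        comp = VarianceComponents(beta0_A=-30.0, beta0_E=0.0)
        sc = GeneratorScenario(
            n_mz_pairs=3000, n_dz_pairs=10, components=comp,
            means=MeansModel(), items=default_items(),
        )
        rng = np.random.default_rng(5)
        theta = generate_latent_traits(sc, generate_environments(sc, rng), rng)
        assert abs(np.corrcoef(theta[:3000, 0], theta[:3000, 1])[0, 1]) < 0.06

    def test_moderation_raises_variance_in_high_environment_decile(self):
        comp = VarianceComponents(
            beta0_A=np.log(0.17), beta0_E=np.log(0.23), beta1_A=[0.4]
        )
        base = null_moderation_scenario(2500, 2500)
        sc = dataclasses.replace(base, components=comp)
        contrasts = []
        for seed in range(8):
            rng = np.random.default_rng(seed)
            envs = generate_environments(sc, rng)
            theta = generate_latent_traits(sc, envs, rng)
            e = envs["environment"].ravel()
            t = theta.ravel()
            top = t[e > np.quantile(e, 0.9)]
            bottom = t[e < np.quantile(e, 0.1)]
            contrasts.append(top.var() - bottom.var())
        assert all(c > 0 for c in contrasts)


class TestDataset:
    def test_study_scale_composition(self):
        recs = generate_dataset(hyperactivity_scenario(), seed=0)
        assert len(recs) == 1085
        assert sum(r.zygosity == "MZ" for r in recs) == 419
        assert sum(r.zygosity == "DZ" for r in recs) == 666

    def test_no_missingness_profile(self):
        sc = dataclasses.replace(
            hyperactivity_scenario(50, 50), missingness=(1.0, 0.0, 0.0, 0.0)
        )
        recs = generate_dataset(sc, seed=1)
        for r in recs:
            assert not np.any(np.isnan(r.items_twin1))
            assert not np.any(np.isnan(r.items_twin2))

    def test_missingness_profile_in_expectation(self):
        recs = generate_dataset(hyperactivity_scenario(2000, 2000), seed=2)
        n_missing = np.array(
            [
                np.isnan(r.items_twin1).sum() + np.isnan(r.items_twin2).sum()
                for r in recs
            ]
        )
        frac_complete = np.mean(n_missing == 0)
        frac_one = np.mean(n_missing == 1)
        frac_nine = np.mean(n_missing == 9)
        assert abs(frac_complete - 0.95) < 0.02
        assert abs(frac_one - 0.02) < 0.01
        assert abs(frac_nine - 0.02) < 0.01

    def test_bit_reproducible_csv(self, tmp_path):
        sc = hyperactivity_scenario(30, 40)
        a, b = tmp_path / "a.csv", tmp_path / "b.csv"
        gio.write_dataset(generate_dataset(sc, seed=9), a)
        gio.write_dataset(generate_dataset(sc, seed=9), b)
        assert a.read_bytes() == b.read_bytes()

    def test_skewed_items_skew_sum_scores(self):
        recs = generate_dataset(skewed_null_scenario(500, 500), seed=3)
        scores = np.array(
            [sum_score(r.items_twin1) for r in recs]
            + [sum_score(r.items_twin2) for r in recs]
        )
        from scipy.stats import skew

        assert skew(scores) < -0.5  # ceiling profile: left-skewed

    def test_scenario_validation(self):
        with pytest.raises(ValueError, match="missingness"):
            dataclasses.replace(
                hyperactivity_scenario(), missingness=(0.9, 0.2, 0.0, 0.0)
            )
        with pytest.raises(ValueError, match="slope"):
            dataclasses.replace(
                hyperactivity_scenario(), moderators=("conscientiousness",)
            )

    def test_scaled_preserves_zygosity_mix(self):
        sc = hyperactivity_scenario().scaled(150)
        assert sc.n_pairs == 150
        assert abs(sc.n_mz_pairs / sc.n_pairs - 419 / 1085) < 0.01

    def test_rge_hook_tilts_environment_toward_genetic_factor(self):
        sc = dataclasses.replace(
            inattentiveness_scenario(1000, 1000),
            rge_loading={"callousness": 0.6},
        )
        rng = np.random.default_rng(21)
        envs = generate_environments(sc, rng)
        theta = generate_latent_traits(sc, envs, rng)
        r = np.corrcoef(envs["callousness"].ravel(), theta.ravel())[0, 1]
        sc0 = dataclasses.replace(sc, rge_loading={})
        rng = np.random.default_rng(21)
        envs0 = generate_environments(sc0, rng)
        theta0 = generate_latent_traits(sc0, envs0, rng)
        r0 = np.corrcoef(envs0["callousness"].ravel(), theta0.ravel())[0, 1]
        assert r > r0 + 0.05
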