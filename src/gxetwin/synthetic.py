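"""Generator of twin datasets with the full structure the analysis assumes.

The restricted study data (1085 16-year-old twin pairs, 419 MZ + 666 DZ,
9-item 7-category subscale scores plus self-reported environmental scales)
cannot be redistributed, so this module generates datasets with the same
statistical anatomy:

* environment scores that are standard-normal marginally and correlated
  within a pair (the condition under which naive moderation analyses are
  biased),
* latent traits built from additive-genetic factors with cross-twin
  correlation 1 (MZ) / 0.5 (DZ), each twin's factor scaled by
  ``exp((beta0_A + beta1_A . E_ij)/2)`` so its variance follows the
  log-linear moderation model exactly, plus shared-C and unique-E noise and
  the own/co-twin means structure,
* 7-category item responses from the graded response model, and
* family-level missingness matching the reported pattern (about 95% of
  families complete, small fractions missing one, up to eight, or nine item
  answers).

Environments are exogenous here; their correlation with the trait arises
through the means model, mirroring how the analysis regresses it out.  An
optional hook adds direct correlation between a twin's genetic factor and an
environment variable for robustness probes; it is off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .irt import ItemParameters, simulate_responses
from .model_core import (
    DZ,
    GENETIC_CORRELATION,
    MZ,
    MeansModel,
    ModelConfig,
    TwinPairRecord,
    VarianceComponents,
)

__all__ = [
    "GeneratorScenario",
    "default_items",
    "skewed_items",
    "hyperactivity_scenario",
    "inattentiveness_scenario",
    "null_moderation_scenario",
    "skewed_null_scenario",
    "generate_environments",
    "generate_latent_traits",
    "generate_dataset",
]


@dataclass(frozen=True)
class GeneratorScenario:
    """Generating values for one synthetic twin study.

    ``missingness`` gives family-level fractions of (no missing item, exactly
    one missing item, two-to-eight missing items, nine missing items i.e. one
    twin's whole subscale); any remainder is treated as complete.
    ``rge_loading`` optionally maps an environment name to a loading that
    tilts that environment toward the twin's genetic factor (a controlled
    dose of gene-environment correlation for robustness checks).
    """

    n_mz_pairs: int
    n_dz_pairs: int
    components: VarianceComponents
    means: MeansModel
    moderators: tuple[str, ...] = ()
    env_within_pair_corr: float = 0.4
    items: tuple[ItemParameters, ...] = ()
    missingness: tuple[float, float, float, float] = (1.0, 0.0, 0.0, 0.0)
    rge_loading: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not -1 < self.env_within_pair_corr < 1:
            raise ValueError("within-pair correlation must lie in (-1, 1)")
        if sum(self.missingness) > 1 + 1e-9:
            raise ValueError("missingness fractions must sum to at most 1")
        unknown = set(self.moderators) - set(self.means.covariates)
        if unknown:
            raise ValueError(
                f"moderators {sorted(unknown)} missing from means covariates"
            )
        if len(self.moderators) != self.components.n_moderators:
            raise ValueError(
                f"{len(self.moderators)} moderator name(s) but "
                f"{self.components.n_moderators} slope(s) in beta1_A"
            )

    @property
    def n_pairs(self) -> int:
        return self.n_mz_pairs + self.n_dz_pairs

    @property
    def zygosities(self) -> np.ndarray:
        return np.array([MZ] * self.n_mz_pairs + [DZ] * self.n_dz_pairs)

    def model_config(self) -> ModelConfig:
        return ModelConfig(
            decomposition="ACE" if self.components.has_c else "AE",
            moderators=self.moderators,
            means_covariates=self.means.covariates,
        )

    def scaled(self, n_pairs: int) -> "GeneratorScenario":
        """Same scenario at a different total size, zygosity mix preserved."""
        n_mz = max(2, round(n_pairs * self.n_mz_pairs / self.n_pairs))
        return replace(self, n_mz_pairs=n_mz, n_dz_pairs=max(2, n_pairs - n_mz))


def default_items(n_items: int = 9, n_categories: int = 7) -> tuple[ItemParameters, ...]:
    """A calibrated 9-item, 7-category set: discriminations spread around 1
    with product anchored to 1, thresholds spanning the realistic trait range
    with per-item shifts whose grand mean is 0."""
    disc = np.array([0.8, 1.25, 1.1, 0.9, 1.3, 0.7, 1.2, 1.0, 1.0])[:n_items]
    disc[-1] = 1.0 / np.prod(disc[:-1])
    base = np.linspace(-1.1, 1.1, n_categories - 1)
    shifts = np.linspace(-0.3, 0.3, n_items)
    return tuple(
        ItemParameters(discrimination=a, thresholds=base + s)
        for a, s in zip(disc, shifts)
    )


def skewed_items(
    severity: float = 1.5, n_items: int = 9, n_categories: int = 7
) -> tuple[ItemParameters, ...]:
    """Items whose thresholds bunch in the lower tail of the trait range.

    Most respondents then sit above every threshold and pile into the top
    category, so sum scores hit a ceiling and are skewed — the measurement
    artefact that manufactures spurious moderation in sum-score analyses.
    ``severity`` is the downward threshold shift in latent-trait units.
    """
    items = default_items(n_items, n_categories)
    return tuple(
        ItemParameters(it.discrimination, 0.6 * it.thresholds - severity)
        for it in items
    )


def _study_means(covariates: tuple[str, ...]) -> MeansModel:
    n = len(covariates)
    return MeansModel(
        intercept=0.0,
        covariates=covariates,
        beta_m_mz=np.full(n, 0.10),
        beta_mc_mz=np.full(n, 0.05),
        beta_m_dz=np.full(n, 0.10),
        beta_mc_dz=np.full(n, 0.05),
    )


#: family-level missingness pattern of the hyperactivity-impulsivity subscale
STUDY_MISSINGNESS = (0.95, 0.02, 0.01, 0.02)


def hyperactivity_scenario(
    n_mz_pairs: int = 419, n_dz_pairs: int = 666
) -> GeneratorScenario:
    """The hyperactivity-impulsivity study at its published point estimates:
    AE decomposition (A variance 0.17, E variance 0.23 at the average
    environment) with three moderated environments (academic self-concept
    0.15, classroom environment 0.24, conscientiousness 0.22)."""
    mods = ("academic_self_concept", "classroom_environment", "conscientiousness")
    return GeneratorScenario(
        n_mz_pairs=n_mz_pairs,
        n_dz_pairs=n_dz_pairs,
        components=VarianceComponents(
            beta0_A=np.log(0.17),
            beta0_E=np.log(0.23),
            beta1_A=np.array([0.15, 0.24, 0.22]),
        ),
        means=_study_means(mods),
        moderators=mods,
        items=default_items(),
        missingness=STUDY_MISSINGNESS,
    )


def inattentiveness_scenario(
    n_mz_pairs: int = 419, n_dz_pairs: int = 666
) -> GeneratorScenario:
    """The inattentiveness study at its published point estimates: ACE
    decomposition (A 0.09, C 0.07, E 0.38) with five moderated environments
    (satisfaction with school 0.24, satisfaction with oneself 0.34,
    callousness -0.58, conscientiousness 0.40, academic self-concept 0.27)."""
    mods = (
        "satisfaction_school",
        "satisfaction_oneself",
        "callousness",
        "conscientiousness",
        "academic_self_concept",
    )
    return GeneratorScenario(
        n_mz_pairs=n_mz_pairs,
        n_dz_pairs=n_dz_pairs,
        components=VarianceComponents(
            beta0_A=np.log(0.09),
            beta0_E=np.log(0.38),
            beta0_C=np.log(0.07),
            beta1_A=np.array([0.24, 0.34, -0.58, 0.40, 0.27]),
        ),
        means=_study_means(mods),
        moderators=mods,
        missingness=(0.94, 0.03, 0.01, 0.02),
        items=default_items(),
    )


def null_moderation_scenario(
    n_mz_pairs: int = 58, n_dz_pairs: int = 92
) -> GeneratorScenario:
    """AE scenario with a single candidate moderator whose true slope is 0."""
    mods = ("environment",)
    return GeneratorScenario(
        n_mz_pairs=n_mz_pairs,
        n_dz_pairs=n_dz_pairs,
        components=VarianceComponents(
            beta0_A=np.log(0.17), beta0_E=np.log(0.23), beta1_A=np.array([0.0])
        ),
        means=_study_means(mods),
        moderators=mods,
        items=default_items(),
    )


def skewed_null_scenario(
    n_mz_pairs: int = 77,
    n_dz_pairs: int = 123,
    skew_severity: float = 1.5,
) -> GeneratorScenario:
    """No true moderation, but a strong trait-environment main effect and a
    ceiling-profile item set: the configuration under which sum-score
    analyses manufacture spurious gene-environment interaction."""
    mods = ("environment",)
    n = len(mods)
    means = MeansModel(
        covariates=mods,
        beta_m_mz=np.full(n, 0.40),
        beta_mc_mz=np.full(n, 0.10),
        beta_m_dz=np.full(n, 0.40),
        beta_mc_dz=np.full(n, 0.10),
    )
    return GeneratorScenario(
        n_mz_pairs=n_mz_pairs,
        n_dz_pairs=n_dz_pairs,
        components=VarianceComponents(
            beta0_A=np.log(0.17), beta0_E=np.log(0.23), beta1_A=np.array([0.0])
        ),
        means=means,
        moderators=mods,
        items=skewed_items(skew_severity),
    )


def generate_environments(
    scenario: GeneratorScenario, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Per-variable (n_pairs, 2) environment scores.

    Each variable is bivariate standard normal within a pair with the
    scenario's within-pair correlation; variables are mutually independent.
    """
    rho = scenario.env_within_pair_corr
    chol = np.linalg.cholesky(np.array([[1.0, rho], [rho, 1.0]]))
    return {
        name: rng.standard_normal((scenario.n_pairs, 2)) @ chol.T
        for name in scenario.means.covariates
    }


def _genetic_factors(
    scenario: GeneratorScenario, rng: np.random.Generator
) -> np.ndarray:
    """Standard-normal additive-genetic factors with twin correlation 1/0.5."""
    r = np.array([GENETIC_CORRELATION[z] for z in scenario.zygosities])
    shared = rng.standard_normal(scenario.n_pairs)
    unique = rng.standard_normal((scenario.n_pairs, 2))
    return np.sqrt(r)[:, None] * shared[:, None] + np.sqrt(1 - r)[:, None] * unique


def generate_latent_traits(
    scenario: GeneratorScenario,
    environments: dict[str, np.ndarray],
    rng: np.random.Generator,
) -> np.ndarray:
    """(n_pairs, 2) latent trait values under the full generative model."""
    comp, means = scenario.components, scenario.means
    a = _genetic_factors(scenario, rng)

    for name, lam in scenario.rge_loading.items():
        # optional direct gene-environment correlation: tilt the environment
        # toward the genetic factor, re-standardising the marginal
        e = environments[name]
        environments[name] = (e + lam * a) / np.sqrt(1 + lam**2)

    env_mod = np.stack(
        [environments[m] for m in scenario.moderators], axis=-1
    ) if scenario.moderators else np.zeros((scenario.n_pairs, 2, 0))
    scale = np.exp(0.5 * (comp.beta0_A + env_mod @ comp.beta1_A))

    theta = scale * a
    if comp.has_c:
        theta = theta + np.sqrt(comp.sigma2_C) * rng.standard_normal(
            (scenario.n_pairs, 1)
        )
    theta = theta + np.sqrt(comp.sigma2_E) * rng.standard_normal(
        (scenario.n_pairs, 2)
    )

    theta = theta + means.intercept
    if means.covariates:
        env_cov = np.stack([environments[c] for c in means.covariates], axis=-1)
        is_mz = scenario.zygosities == MZ
        for group, (bm, bmc) in (
            (is_mz, (means.beta_m_mz, means.beta_mc_mz)),
            (~is_mz, (means.beta_m_dz, means.beta_mc_dz)),
        ):
            theta[group] += env_cov[group] @ bm + env_cov[group][:, ::-1, :] @ bmc
    return theta


def _inject_missingness(
    responses: np.ndarray, scenario: GeneratorScenario, rng: np.random.Generator
) -> None:
    """Blank item cells in place, family by family, per the scenario profile."""
    n_pairs, _, n_items = responses.shape
    probs = np.array(scenario.missingness)
    probs = np.append(probs, max(0.0, 1.0 - probs.sum()))  # remainder: complete
    categories = rng.choice(5, size=n_pairs, p=probs / probs.sum())
    for i in np.flatnonzero(categories == 1):
        flat = rng.integers(2 * n_items)
        responses[i, flat // n_items, flat % n_items] = np.nan
    for i in np.flatnonzero(categories == 2):
        k = int(rng.integers(2, min(8, 2 * n_items - 1) + 1))
        flat = rng.choice(2 * n_items, size=k, replace=False)
        responses[i, flat // n_items, flat % n_items] = np.nan
    for i in np.flatnonzero(categories == 3):
        responses[i, int(rng.integers(2)), :] = np.nan


def generate_dataset(
    scenario: GeneratorScenario, seed: int
) -> list[TwinPairRecord]:
    """Complete pipeline-ready dataset; bit-reproducible given the seed."""
    rng = np.random.default_rng(seed)
    environments = generate_environments(scenario, rng)
    theta = generate_latent_traits(scenario, environments, rng)
    flat = simulate_responses(theta.ravel(), list(scenario.items), rng)
    responses = flat.reshape(scenario.n_pairs, 2, len(scenario.items))
    _inject_missingness(responses, scenario, rng)

    names = scenario.means.covariates
    records = []
    for i, zyg in enumerate(scenario.zygosities):
        records.append(
            TwinPairRecord(
                family_id=f"fam{i + 1:05d}",
                zygosity=str(zyg),
                items_twin1=responses[i, 0],
                items_twin2=responses[i, 1],
                env_twin1={n: float(environments[n][i, 0]) for n in names},
                env_twin2={n: float(environments[n][i, 1]) for n in names},
            )
        )
    return records
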