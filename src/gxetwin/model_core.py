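"""Biometric twin model with log-linear moderation of additive genetic variance.

The classical ACE decomposition splits the phenotypic variance of a trait into
additive-genetic (A), common-environment (C) and unique-environment (E)
components,

    sigma2_P = sigma2_A + sigma2_C + sigma2_E,

identified by contrasting monozygotic (MZ) twins, whose additive genetic
values correlate 1, with dizygotic (DZ) twins, whose additive genetic values
correlate 0.5 on average.  Gene-environment interaction is parameterised by
letting a measured, within-pair-varying environmental variable moderate the
*log* of the additive-genetic variance of twin j in family i:

    sigma2_A(i,j) = exp(beta0_A + beta1_A . E_ij)

so the A variance at the average environment (standardised E = 0) is
exp(beta0_A) and each moderation slope acts multiplicatively.  The means part
of the model regresses a twin's latent trait on their own environment scores
(beta_m) and the co-twin's scores (beta_mc), with coefficients estimated
separately per zygosity group; this "own + co-twin, per zygosity" correction
removes trait-environment covariance (including any gene-environment
correlation) that would otherwise masquerade as moderation when environments
correlate within pairs.

Everything in this module is pure model arithmetic; it is consumed by the
inference and synthetic-data layers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "MZ",
    "DZ",
    "VarianceComponents",
    "MeansModel",
    "TwinPairRecord",
    "ModelConfig",
    "moderated_a_variance",
    "twin_pair_latent_covariance",
    "expected_latent_mean",
    "heritability",
]

MZ = "MZ"
DZ = "DZ"

#: additive-genetic cross-twin correlation by zygosity
GENETIC_CORRELATION = {MZ: 1.0, DZ: 0.5}


def _check_zygosity(zygosity: str) -> str:
    if zygosity not in GENETIC_CORRELATION:
        raise ValueError(
            f"unknown zygosity label {zygosity!r}; expected {MZ!r} or {DZ!r}"
        )
    return zygosity


@dataclass(frozen=True)
class VarianceComponents:
    """Variance-component intercepts on the log scale plus moderation slopes.

    ``beta0_A``, ``beta0_C`` and ``beta0_E`` are log-variances; the implied
    variance components are ``exp(beta0_X)`` (evaluated at environment 0 for
    A).  ``beta0_C is None`` encodes an AE model.  ``beta1_A`` holds one
    log-linear moderation slope per moderator variable, in units of
    log-variance per standard deviation of the (standardised) moderator.
    """

    beta0_A: float
    beta0_E: float
    beta0_C: float | None = None
    beta1_A: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "beta1_A", np.atleast_1d(np.asarray(self.beta1_A, dtype=float))
        )

    @property
    def has_c(self) -> bool:
        return self.beta0_C is not None

    @property
    def sigma2_A(self) -> float:
        """Additive-genetic variance at the average environment (E = 0)."""
        return float(np.exp(self.beta0_A))

    @property
    def sigma2_C(self) -> float:
        return float(np.exp(self.beta0_C)) if self.has_c else 0.0

    @property
    def sigma2_E(self) -> float:
        return float(np.exp(self.beta0_E))

    @property
    def n_moderators(self) -> int:
        return int(self.beta1_A.size)


@dataclass(frozen=True)
class MeansModel:
    """Zygosity-specific regression of the latent trait on environment scores.

    For each environmental covariate there are four coefficients: the effect
    of a twin's own score (``beta_m``) and of the co-twin's score
    (``beta_mc``), estimated separately for MZ and DZ families.
    """

    intercept: float = 0.0
    covariates: tuple[str, ...] = ()
    beta_m_mz: np.ndarray = field(default_factory=lambda: np.zeros(0))
    beta_mc_mz: np.ndarray = field(default_factory=lambda: np.zeros(0))
    beta_m_dz: np.ndarray = field(default_factory=lambda: np.zeros(0))
    beta_mc_dz: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        n = len(self.covariates)
        for name in ("beta_m_mz", "beta_mc_mz", "beta_m_dz", "beta_mc_dz"):
            vec = np.atleast_1d(np.asarray(getattr(self, name), dtype=float))
            if vec.size != n:
                raise ValueError(
                    f"{name} has length {vec.size}, expected one coefficient per "
                    f"covariate ({n})"
                )
            object.__setattr__(self, name, vec)

    def coefficients(self, zygosity: str) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(beta_m, beta_mc)`` for the requested zygosity group."""
        _check_zygosity(zygosity)
        if zygosity == MZ:
            return self.beta_m_mz, self.beta_mc_mz
        return self.beta_m_dz, self.beta_mc_dz


@dataclass(frozen=True)
class TwinPairRecord:
    """One family: zygosity, per-twin item responses and environment scores.

    Item responses are stored as float arrays with ``nan`` marking a missing
    answer; observed entries must be integers in ``1..n_categories``.
    Environment scores are keyed by variable name and assumed standardised
    (mean 0, SD 1 over individuals).
    """

    family_id: str
    zygosity: str
    items_twin1: np.ndarray
    items_twin2: np.ndarray
    env_twin1: dict[str, float]
    env_twin2: dict[str, float]

    def __post_init__(self) -> None:
        _check_zygosity(self.zygosity)
        for attr in ("items_twin1", "items_twin2"):
            arr = np.asarray(getattr(self, attr), dtype=float)
            object.__setattr__(self, attr, arr)

    def validate_responses(self, n_categories: int) -> None:
        for twin, arr in ((1, self.items_twin1), (2, self.items_twin2)):
            obs = arr[~np.isnan(arr)]
            bad = (obs != np.round(obs)) | (obs < 1) | (obs > n_categories)
            if np.any(bad):
                item = int(np.flatnonzero(~np.isnan(arr))[np.flatnonzero(bad)[0]])
                raise ValueError(
                    f"family {self.family_id!r}, twin {twin}, item {item + 1}: "
                    f"response outside 1..{n_categories}"
                )

    def environments(self, names: Sequence[str], twin: int) -> np.ndarray:
        env = self.env_twin1 if twin == 1 else self.env_twin2
        try:
            return np.array([env[n] for n in names], dtype=float)
        except KeyError as exc:
            raise KeyError(
                f"family {self.family_id!r} twin {twin} lacks environment "
                f"variable {exc.args[0]!r}"
            ) from None


@dataclass(frozen=True)
class ModelConfig:
    """Which decomposition to fit and which variables enter where.

    Every moderator's main effect is always carried in the means part, so the
    moderator set must be a subset of the means covariates.
    """

    decomposition: str = "AE"
    moderators: tuple[str, ...] = ()
    means_covariates: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.decomposition not in ("AE", "ACE"):
            raise ValueError(
                f"decomposition must be 'AE' or 'ACE', got {self.decomposition!r}"
            )
        object.__setattr__(self, "moderators", tuple(self.moderators))
        object.__setattr__(self, "means_covariates", tuple(self.means_covariates))
        missing = set(self.moderators) - set(self.means_covariates)
        if missing:
            raise ValueError(
                "moderators must be a subset of means_covariates; missing main "
                f"effects for {sorted(missing)}"
            )


def moderated_a_variance(
    beta0_A: float, beta1_A: np.ndarray, env: np.ndarray
) -> float:
    """Additive-genetic variance ``exp(beta0_A + beta1_A . env)``.

    ``env`` holds the moderator values for one twin; the result is strictly
    positive and log-linear in every coordinate.
    """
    beta1_A = np.atleast_1d(np.asarray(beta1_A, dtype=float))
    env = np.atleast_1d(np.asarray(env, dtype=float))
    if env.shape != beta1_A.shape:
        raise ValueError(
            f"moderator mismatch: {beta1_A.size} slope(s) but {env.size} "
            "environment value(s)"
        )
    return float(np.exp(beta0_A + beta1_A @ env))


def twin_pair_latent_covariance(
    components: VarianceComponents,
    env_twin1: np.ndarray,
    env_twin2: np.ndarray,
    zygosity: str,
) -> np.ndarray:
    """2x2 covariance of a pair's latent traits under moderation.

    Each twin's additive-genetic factor is a standard normal scaled by
    ``exp((beta0_A + beta1_A . E_ij)/2)``, with cross-twin correlation 1 (MZ)
    or 0.5 (DZ); C is perfectly shared and E independent.  Diagonal entries
    are ``sigma2_A(E_j) + sigma2_C + sigma2_E``; the off-diagonal is
    ``r * sqrt(sigma2_A(E_1) * sigma2_A(E_2)) + sigma2_C``.
    """
    r = GENETIC_CORRELATION[_check_zygosity(zygosity)]
    va1 = moderated_a_variance(components.beta0_A, components.beta1_A, env_twin1)
    va2 = moderated_a_variance(components.beta0_A, components.beta1_A, env_twin2)
    vc = components.sigma2_C
    ve = components.sigma2_E
    off = r * np.sqrt(va1 * va2) + vc
    return np.array([[va1 + vc + ve, off], [off, va2 + vc + ve]])


def expected_latent_mean(
    means: MeansModel,
    env_self: np.ndarray,
    env_cotwin: np.ndarray,
    zygosity: str,
) -> float:
    """Expected latent trait of one twin under the means model."""
    beta_m, beta_mc = means.coefficients(zygosity)
    env_self = np.atleast_1d(np.asarray(env_self, dtype=float))
    env_cotwin = np.atleast_1d(np.asarray(env_cotwin, dtype=float))
    if env_self.shape != beta_m.shape or env_cotwin.shape != beta_mc.shape:
        raise ValueError(
            f"covariate mismatch: means model has {beta_m.size} covariate(s) but "
            f"got {env_self.size} self / {env_cotwin.size} co-twin value(s)"
        )
    return float(means.intercept + beta_m @ env_self + beta_mc @ env_cotwin)


def heritability(components: VarianceComponents) -> float:
    """Narrow-sense heritability h2 = sigma2_A / sigma2_P at environment 0."""
    va, vc, ve = components.sigma2_A, components.sigma2_C, components.sigma2_E
    total = va + vc + ve
    if total <= 0:
        raise ValueError("total phenotypic variance must be positive")
    return va / total
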