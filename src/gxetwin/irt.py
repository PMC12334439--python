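"""Graded-response measurement model for ordinal questionnaire items.

Links a latent trait theta to K ordered response categories through a
logistic graded response model (Samejima type): the probability of responding
in category k or above is

    P(X >= k | theta) = logistic(a * (theta - b_{k-1})),   k = 2..K,

with per-item discrimination a > 0 and strictly increasing category
thresholds b_1 < ... < b_{K-1}.  Category masses are adjacent differences of
these boundary curves.  This is the standard measurement model for 7-point
polytomous items such as the SWAN ADHD subscales (9 items per subscale,
scored so that a higher response reflects fewer symptoms).

The module also provides the raw sum score used by the skewness benchmark
(composite scores inherit heterogeneous measurement error and become skewed
when item thresholds bunch in one tail), and single-factor scores used as
proxies for environmental scales.

Missing responses are encoded as ``nan`` and treated as ignorably missing
given theta.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

__all__ = [
    "ItemParameters",
    "category_probabilities",
    "response_loglik",
    "simulate_responses",
    "sum_score",
    "one_factor_scores",
]


@dataclass(frozen=True)
class ItemParameters:
    """One item's discrimination and ordered category thresholds."""

    discrimination: float
    thresholds: np.ndarray

    def __post_init__(self) -> None:
        if not self.discrimination > 0:
            raise ValueError(
                f"discrimination must be positive, got {self.discrimination}"
            )
        thr = np.asarray(self.thresholds, dtype=float)
        if thr.ndim != 1 or thr.size < 1:
            raise ValueError("thresholds must be a non-empty 1-d vector")
        if np.any(np.diff(thr) <= 0):
            raise ValueError(f"thresholds must be strictly increasing, got {thr}")
        object.__setattr__(self, "thresholds", thr)

    @property
    def n_categories(self) -> int:
        return self.thresholds.size + 1


def category_probabilities(theta, item: ItemParameters) -> np.ndarray:
    """Probability of each of the K categories at latent value(s) theta.

    Returns an array of shape ``(*theta.shape, K)`` lying on the probability
    simplex for every finite theta.
    """
    theta = np.asarray(theta, dtype=float)
    # boundary curves P(X >= k), padded with 1 and 0
    upper = expit(item.discrimination * (theta[..., None] - item.thresholds))
    ones = np.ones(theta.shape + (1,))
    cum = np.concatenate([ones, upper, np.zeros_like(ones)], axis=-1)
    return -np.diff(cum, axis=-1)


def response_loglik(
    responses: np.ndarray, theta: float, items: list[ItemParameters]
) -> float:
    """Log-likelihood of one person's responses given theta.

    Missing (nan) responses contribute zero.  Responses outside the item's
    category range raise with the offending item index.
    """
    responses = np.asarray(responses, dtype=float)
    if responses.size != len(items):
        raise ValueError(
            f"{responses.size} responses but {len(items)} items"
        )
    total = 0.0
    for j, (resp, item) in enumerate(zip(responses, items)):
        if np.isnan(resp):
            continue
        k = int(resp)
        if resp != k or not 1 <= k <= item.n_categories:
            raise ValueError(
                f"item {j + 1}: response {resp} outside 1..{item.n_categories}"
            )
        p = category_probabilities(theta, item)[k - 1]
        total += np.log(max(p, 1e-300))
    return float(total)


def simulate_responses(
    theta: np.ndarray, items: list[ItemParameters], rng: np.random.Generator
) -> np.ndarray:
    """Draw a persons x items response matrix from the graded response model."""
    theta = np.asarray(theta, dtype=float)
    out = np.empty((theta.size, len(items)))
    for j, item in enumerate(items):
        cum = np.cumsum(category_probabilities(theta, item), axis=-1)
        u = rng.random(theta.size)
        out[:, j] = 1 + np.sum(u[:, None] > cum[:, :-1], axis=1)
    return out


def sum_score(responses: np.ndarray) -> float:
    """Sum of non-missing responses; nan when every item is missing."""
    responses = np.asarray(responses, dtype=float)
    if responses.size == 0 or np.all(np.isnan(responses)):
        return float("nan")
    return float(np.nansum(responses))


def one_factor_scores(score_matrix: np.ndarray, names=None) -> np.ndarray:
    """Standardised single-factor scores from a matrix of scale indicators.

    Fits a one-factor linear model by maximum likelihood and returns
    regression-method factor scores, standardised to mean 0 and SD 1.  The
    sign is anchored so that the indicator with the largest absolute loading
    loads positively.  Missing cells are mean-imputed per indicator.
    """
    from sklearn.decomposition import FactorAnalysis

    x = np.asarray(score_matrix, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2 or x.shape[0] < 3:
        raise ValueError("need at least 3 persons and 2 indicators")
    names = list(names) if names is not None else [str(j) for j in range(x.shape[1])]
    col_means = np.nanmean(x, axis=0)
    x = np.where(np.isnan(x), col_means, x)
    sd = x.std(axis=0)
    if np.any(sd == 0):
        bad = names[int(np.flatnonzero(sd == 0)[0])]
        raise ValueError(f"indicator {bad!r} has zero variance")
    fa = FactorAnalysis(n_components=1, random_state=0)
    scores = fa.fit_transform((x - x.mean(axis=0)) / sd).ravel()
    loadings = fa.components_.ravel()
    if loadings[np.argmax(np.abs(loadings))] < 0:
        scores = -scores
    return (scores - scores.mean()) / scores.std()
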