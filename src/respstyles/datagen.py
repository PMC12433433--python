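"""Synthetic Likert data under the three response-style regimes.

One :class:`GenCondition` is a cell of the simulation design: a model kind
(``null``, ``ers_mrs`` or ``ers_plus_mrs``), a sample size N, a test length J,
the number of substantive dimensions D, and — where applicable — the
response-style trait standard deviation, the correlation between the ERS and
MRS traits, and the correlation between the ERS and MRS item slopes.

Generation follows a fixed recipe: substantive traits are independent standard
normal; response-style traits are normal with mean zero and SD ``sigma_rs``
(bivariate with correlation ``r_rs`` for the two-dimensional kind), drawn
independently of the substantive traits; item slopes are log-normal with
log-mean 0 and log-SD 0.3; category intercepts are the fixed symmetric vector
(-2, -1, 0, -1, -2), which makes the answer distribution mirror-symmetric
around the midpoint.  Responses are drawn categorically from the model's
category probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import (
    MISSING,
    ItemParameters,
    ModelSpec,
    ScoringMatrix,
)

__all__ = [
    "GenCondition",
    "ResponseMatrix",
    "LatentTraits",
    "GENERATING_INTERCEPTS",
    "draw_item_parameters",
    "draw_latent_traits",
    "simulate_responses",
    "generate_dataset",
]

#: Fixed generating intercepts for K = 5; symmetric so that the category
#: distribution mirrors when the substantive trait changes sign.
GENERATING_INTERCEPTS = np.array([-2.0, -1.0, 0.0, -1.0, -2.0])

#: log-SD of the log-normal slope distribution (log-mean is 0).
DEFAULT_SLOPE_SIGMA = 0.3


@dataclass(frozen=True)
class GenCondition:
    """One cell of the simulation design.

    ``sigma_rs`` applies to both response-style kinds; ``r_rs`` (trait
    correlation) and ``slope_corr`` (0 = independent ERS and MRS slopes,
    1 = identical slopes) apply only to ``ers_plus_mrs``.
    """

    kind: str
    n_persons: int
    n_items: int
    n_substantive: int = 1
    sigma_rs: float | None = None
    r_rs: float | None = None
    slope_corr: float | None = None
    seed: int = 0
    n_categories: int = 5

    def __post_init__(self) -> None:
        if self.kind == "null":
            if self.sigma_rs is not None or self.r_rs is not None or self.slope_corr is not None:
                raise ValueError("null condition takes no response-style fields")
        elif self.kind == "ers_mrs":
            if self.sigma_rs is None:
                raise ValueError("ers_mrs condition requires sigma_rs")
            if self.r_rs is not None or self.slope_corr is not None:
                raise ValueError("ers_mrs condition takes no r_rs / slope_corr")
        elif self.kind == "ers_plus_mrs":
            if self.sigma_rs is None or self.r_rs is None or self.slope_corr is None:
                raise ValueError("ers_plus_mrs condition requires sigma_rs, r_rs and slope_corr")
            if self.slope_corr not in (0, 1):
                raise ValueError("slope_corr must be 0 (independent) or 1 (identical)")
            if not -1 < self.r_rs < 1:
                raise ValueError("r_rs must be in (-1, 1)")
        else:
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.n_persons < 0 or self.n_items < 1:
            raise ValueError("invalid sample size or test length")

    def model_spec(self) -> ModelSpec:
        return ModelSpec.create(self.kind, self.n_items, self.n_substantive,
                                self.n_categories)

    def latent_sds(self) -> np.ndarray:
        """Generating SD of each latent column (substantive first, then RS)."""
        spec = self.model_spec()
        sds = np.ones(spec.n_dims)
        if spec.n_rs_dims:
            sds[spec.n_substantive:] = self.sigma_rs
        return sds


@dataclass
class ResponseMatrix:
    """N x J integer responses, 0..K-1 internally, -1 for missing."""

    responses: np.ndarray
    n_categories: int = 5
    item_labels: tuple[str, ...] = ()
    person_ids: tuple = ()

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses, dtype=np.int64)
        if self.responses.ndim != 2:
            raise ValueError("responses must be a 2-d matrix")
        valid = (self.responses == MISSING) | (
            (self.responses >= 0) & (self.responses < self.n_categories))
        if not np.all(valid):
            raise ValueError("responses outside 0..K-1 (or -1 for missing)")
        if not self.item_labels:
            self.item_labels = tuple(
                f"item{j + 1}" for j in range(self.responses.shape[1]))
        if not self.person_ids:
            self.person_ids = tuple(range(self.responses.shape[0]))

    @property
    def n_persons(self) -> int:
        return self.responses.shape[0]

    @property
    def n_items(self) -> int:
        return self.responses.shape[1]

    @property
    def n_missing(self) -> int:
        return int(np.sum(self.responses == MISSING))

    def category_counts(self) -> np.ndarray:
        """(J, K) matrix of observed category counts, missing excluded."""
        J, K = self.n_items, self.n_categories
        counts = np.zeros((J, K), dtype=np.int64)
        for k in range(K):
            counts[:, k] = np.sum(self.responses == k, axis=0)
        return counts


@dataclass
class LatentTraits:
    """N x T latent scores; column order matches the scoring-matrix rows."""

    theta: np.ndarray

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        if self.theta.ndim != 2:
            raise ValueError("theta must be a 2-d matrix")


def draw_item_parameters(condition: GenCondition, rng: np.random.Generator,
                         slope_sigma: float = DEFAULT_SLOPE_SIGMA) -> list[ItemParameters]:
    """Draw item slopes and set the fixed generating intercepts.

    Every loaded slope (substantive and response-style alike) is i.i.d.
    log-normal(0, ``slope_sigma``).  For ``ers_plus_mrs`` with
    ``slope_corr = 1`` each item's MRS slope is copied from its ERS slope;
    with ``slope_corr = 0`` the two are drawn independently.
    """
    spec = condition.model_spec()
    if condition.n_categories != 5:
        raise ValueError("the generating intercepts are defined for K = 5")
    T = spec.n_dims
    items = []
    for j in range(spec.n_items):
        slopes = np.zeros(T)
        slopes[spec.item_assignment[j]] = rng.lognormal(0.0, slope_sigma)
        if condition.kind == "ers_mrs":
            slopes[spec.n_substantive] = rng.lognormal(0.0, slope_sigma)
        elif condition.kind == "ers_plus_mrs":
            ers = rng.lognormal(0.0, slope_sigma)
            mrs = ers if condition.slope_corr == 1 else rng.lognormal(0.0, slope_sigma)
            slopes[spec.n_substantive] = ers
            slopes[spec.n_substantive + 1] = mrs
        items.append(ItemParameters(slopes, GENERATING_INTERCEPTS.copy()))
    return items


def draw_latent_traits(condition: GenCondition,
                       rng: np.random.Generator) -> LatentTraits:
    """Draw latent trait scores for every person.

    Substantive columns are independent standard normal.  Response-style
    columns have SD ``sigma_rs``; for ``ers_plus_mrs`` the ERS and MRS columns
    are bivariate normal with correlation ``r_rs``.  Response styles are
    always independent of the substantive traits.
    """
    spec = condition.model_spec()
    N, D = condition.n_persons, spec.n_substantive
    theta = np.empty((N, spec.n_dims))
    theta[:, :D] = rng.standard_normal((N, D))
    if condition.kind == "ers_mrs":
        theta[:, D] = rng.normal(0.0, condition.sigma_rs, size=N)
    elif condition.kind == "ers_plus_mrs":
        s, r = condition.sigma_rs, condition.r_rs
        cov = s * s * np.array([[1.0, r], [r, 1.0]])
        theta[:, D:] = rng.multivariate_normal(
            np.zeros(2), cov, size=N, method="cholesky")
    return LatentTraits(theta)


def simulate_responses(items: list[ItemParameters], traits: LatentTraits,
                       scoring: ScoringMatrix,
                       rng: np.random.Generator) -> ResponseMatrix:
    """Draw one categorical response per person and item from the model."""
    theta = traits.theta
    N = theta.shape[0]
    J = len(items)
    K = scoring.n_categories
    if theta.shape[1] != scoring.n_dims:
        raise ValueError("traits and scoring matrix disagree on dimensions")
    responses = np.empty((N, J), dtype=np.int64)
    u = rng.random((N, J))
    for j, item in enumerate(items):
        # (N, K) logits: sum_d a_d s[d, k] theta_d + c_k, vectorized over persons
        z = (theta * item.slopes) @ scoring.values + item.intercepts
        z -= z.max(axis=1, keepdims=True)
        p = np.exp(z)
        cdf = np.cumsum(p, axis=1)
        cdf /= cdf[:, -1:]
        responses[:, j] = np.sum(u[:, j:j + 1] > cdf[:, :-1], axis=1)
    return ResponseMatrix(responses, n_categories=K)


def generate_dataset(condition: GenCondition, slope_sigma: float = DEFAULT_SLOPE_SIGMA,
                     max_redraws: int = 100):
    """Generate one full dataset for a design cell.

    Deterministic given the condition (including its seed).  If any item has a
    category that nobody endorsed, the whole dataset is redrawn with an
    incremented sub-seed so that every fitted model sees all K categories; the
    number of redraws is returned for reporting.

    Returns ``(responses, items, traits, n_redraws)``.
    """
    scoring = condition.model_spec().scoring_matrix()
    for attempt in range(max_redraws + 1):
        seq = np.random.SeedSequence((condition.seed, attempt))
        rng = np.random.default_rng(seq)
        items = draw_item_parameters(condition, rng, slope_sigma)
        traits = draw_latent_traits(condition, rng)
        responses = simulate_responses(items, traits, scoring, rng)
        if condition.n_persons == 0 or np.all(responses.category_counts() > 0):
            return responses, items, traits, attempt
    raise RuntimeError(
        f"no full-coverage dataset after {max_redraws} redraws for {condition}; "
        "the cell is degenerate (some category is effectively never endorsed)")
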