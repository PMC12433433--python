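"""Adapted multidimensional nominal response model (MNRM) with scoring matrices.

The model gives the probability that a respondent with latent vector ``theta``
endorses category ``k`` of item ``i`` as a softmax over categories,

    P(Y_i = k | theta) ∝ exp([a_i ⊙ s_k]' theta + c_ik),

where ``a_i`` is a vector of item slopes (one per latent dimension), ``s_k`` is
the k-th column of a fixed scoring matrix ``s`` (one row per latent dimension,
one column per category), ``⊙`` is the element-wise (Hadamard) product, and
``c_ik`` are category intercepts.  The scoring matrix is what distinguishes the
competing response-style conceptualizations:

* ``null`` — a single linear scoring row ``(0, 1, ..., K-1)`` per substantive
  dimension; the model reduces to the generalized partial credit model.
* ``ers_mrs`` — one additional bipolar response-style row ``(2, 1, 0, 1, 2)``:
  extreme and midpoint response styles as opposite poles of one dimension.
* ``ers_plus_mrs`` — two additional rows ``(1, 0, 0, 0, 1)`` (extreme response
  style, ERS) and ``(0, 0, 1, 0, 0)`` (midpoint response style, MRS) as
  separate dimensions.

This module is pure computation: scoring-matrix construction, category
probabilities, probability curves, and free-parameter counting.  Everything
else in the package builds on it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "KINDS",
    "N_RESPONSE_STYLE_DIMS",
    "ScoringMatrix",
    "ModelSpec",
    "ItemParameters",
    "LatentDistribution",
    "build_scoring_matrix",
    "category_probabilities",
    "probability_curves",
    "count_free_parameters",
    "default_item_assignment",
]

#: The three model kinds, ordered from most parsimonious to most complex.
KINDS = ("null", "ers_mrs", "ers_plus_mrs")

#: Number of response-style dimensions each kind adds to the substantive ones.
N_RESPONSE_STYLE_DIMS = {"null": 0, "ers_mrs": 1, "ers_plus_mrs": 2}

#: Internal category codes are 0-based (0..K-1); file I/O uses 1..K.
MISSING = -1


@dataclass(frozen=True)
class ScoringMatrix:
    """Fixed per-dimension category scoring functions.

    ``values`` has one row per latent dimension (substantive dimensions first,
    then response-style dimensions) and one column per response category.
    """

    values: np.ndarray
    dim_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("scoring matrix must be 2-dimensional")
        if values.shape[1] < 2:
            raise ValueError("scoring matrix needs at least 2 categories")
        if values.shape[0] != len(self.dim_labels):
            raise ValueError("one label per scoring row is required")
        object.__setattr__(self, "values", values)

    @property
    def n_dims(self) -> int:
        return self.values.shape[0]

    @property
    def n_categories(self) -> int:
        return self.values.shape[1]


def default_item_assignment(n_items: int, n_substantive: int) -> tuple[int, ...]:
    """Assign items to substantive dimensions in equal consecutive blocks.

    With two substantive dimensions the test is split in half: the first
    ``n_items / 2`` items measure dimension 0, the rest dimension 1.
    """
    if n_items % n_substantive:
        raise ValueError(
            f"cannot split {n_items} items evenly over {n_substantive} dimensions"
        )
    per_dim = n_items // n_substantive
    return tuple(i // per_dim for i in range(n_items))


def build_scoring_matrix(kind: str, n_categories: int = 5, n_substantive: int = 1) -> ScoringMatrix:
    """Build the scoring matrix for one of the three model kinds.

    Substantive rows are always the linear scores ``(0, 1, ..., K-1)``; which
    row applies to an item is decided by the item-to-dimension assignment.
    For K = 5 the response-style rows are exactly the bipolar ``(2,1,0,1,2)``
    and the separate ERS ``(1,0,0,0,1)`` / MRS ``(0,0,1,0,0)`` rows.  For other
    K the ERS row is the indicator of the two end categories, the MRS row the
    indicator of the single midpoint, and the bipolar row is the distance
    ``|k - (K-1)/2|`` from the midpoint; kinds that involve a midpoint
    therefore require an odd number of categories.
    """
    if kind not in KINDS:
        raise ValueError(f"unknown model kind {kind!r}; expected one of {KINDS}")
    K = int(n_categories)
    if K < 2:
        raise ValueError("need at least 2 response categories")
    if kind != "null" and K % 2 == 0:
        raise ValueError(
            f"kind {kind!r} models a midpoint response style, which requires an odd "
            f"number of categories (got K={K}: no single midpoint exists)"
        )
    if n_substantive not in (1, 2):
        raise ValueError("n_substantive must be 1 or 2")

    linear = np.arange(K, dtype=float)
    rows = [linear for _ in range(n_substantive)]
    labels = [f"substantive_{d}" for d in range(n_substantive)]
    if kind == "ers_mrs":
        rows.append(np.abs(linear - (K - 1) / 2.0))
        labels.append("ers_mrs")
    elif kind == "ers_plus_mrs":
        ers = np.zeros(K)
        ers[[0, K - 1]] = 1.0
        mrs = np.zeros(K)
        mrs[(K - 1) // 2] = 1.0
        rows.append(ers)
        rows.append(mrs)
        labels += ["ers", "mrs"]
    return ScoringMatrix(np.vstack(rows), tuple(labels))


@dataclass(frozen=True)
class ModelSpec:
    """Which model is generated or fitted.

    ``item_assignment`` maps each item to the single substantive dimension it
    measures (between-item multidimensionality); response-style dimensions
    apply to every item.
    """

    kind: str
    n_substantive: int = 1
    n_categories: int = 5
    item_assignment: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.n_substantive not in (1, 2):
            raise ValueError("n_substantive must be 1 or 2")
        if not self.item_assignment:
            raise ValueError("item_assignment must be non-empty")
        if any(d not in range(self.n_substantive) for d in self.item_assignment):
            raise ValueError("item_assignment indices out of range")

    @classmethod
    def create(cls, kind: str, n_items: int, n_substantive: int = 1,
               n_categories: int = 5) -> "ModelSpec":
        return cls(kind, n_substantive, n_categories,
                   default_item_assignment(n_items, n_substantive))

    @property
    def n_items(self) -> int:
        return len(self.item_assignment)

    @property
    def n_rs_dims(self) -> int:
        return N_RESPONSE_STYLE_DIMS[self.kind]

    @property
    def n_dims(self) -> int:
        """Total latent dimensions T = substantive + response-style."""
        return self.n_substantive + self.n_rs_dims

    def scoring_matrix(self) -> ScoringMatrix:
        return build_scoring_matrix(self.kind, self.n_categories, self.n_substantive)

    def slope_mask(self) -> np.ndarray:
        """Boolean (J, T) mask of which slopes each item has.

        True for the item's assigned substantive dimension and for every
        response-style dimension.
        """
        J, T = self.n_items, self.n_dims
        mask = np.zeros((J, T), dtype=bool)
        mask[np.arange(J), np.asarray(self.item_assignment)] = True
        mask[:, self.n_substantive:] = True
        return mask


@dataclass
class ItemParameters:
    """Slopes (length T, zeros on unloaded substantive dimensions) and
    category intercepts (length K) of one item, on the logit scale."""

    slopes: np.ndarray
    intercepts: np.ndarray

    def __post_init__(self) -> None:
        self.slopes = np.asarray(self.slopes, dtype=float)
        self.intercepts = np.asarray(self.intercepts, dtype=float)
        if self.slopes.ndim != 1 or self.intercepts.ndim != 1:
            raise ValueError("slopes and intercepts must be vectors")
        if not (np.all(np.isfinite(self.slopes)) and np.all(np.isfinite(self.intercepts))):
            raise ValueError("item parameters must be finite")


@dataclass
class LatentDistribution:
    """Multivariate normal latent distribution with zero means and unit
    variances; only the correlations are free (the identification used when
    fitting)."""

    correlation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.correlation, dtype=float)
        if R.ndim != 2 or R.shape[0] != R.shape[1]:
            raise ValueError("correlation matrix must be square")
        if not np.allclose(np.diag(R), 1.0):
            raise ValueError("correlation matrix must have unit diagonal")
        if not np.allclose(R, R.T):
            raise ValueError("correlation matrix must be symmetric")
        if np.linalg.eigvalsh(R).min() <= 0:
            raise ValueError("correlation matrix must be positive definite")
        object.__setattr__(self, "correlation", R)

    @classmethod
    def identity(cls, n_dims: int) -> "LatentDistribution":
        return cls(np.eye(n_dims))

    @property
    def n_dims(self) -> int:
        return self.correlation.shape[0]


def _logits(theta: np.ndarray, slopes: np.ndarray, intercepts: np.ndarray,
            scoring: np.ndarray) -> np.ndarray:
    # z_k = sum_d slopes_d * s[d, k] * theta_d + c_k
    return (slopes * theta) @ scoring + intercepts


def category_probabilities(theta: np.ndarray, item: ItemParameters,
                           scoring: ScoringMatrix) -> np.ndarray:
    """Category probabilities for one respondent and one item.

    Softmax of ``[a ⊙ s_k]' theta + c_k`` over the K categories.
    """
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (scoring.n_dims,):
        raise ValueError(
            f"theta has shape {theta.shape}, expected ({scoring.n_dims},)")
    if item.slopes.shape != (scoring.n_dims,):
        raise ValueError("item slopes do not match the scoring matrix rows")
    if item.intercepts.shape != (scoring.n_categories,):
        raise ValueError("item intercepts do not match the category count")
    if not np.all(np.isfinite(theta)):
        raise ValueError("theta must be finite")
    z = _logits(theta, item.slopes, item.intercepts, scoring.values)
    z -= z.max()
    p = np.exp(z)
    return p / p.sum()


def probability_curves(item: ItemParameters, scoring: ScoringMatrix,
                       grid: np.ndarray, varied_dim: int = 0) -> np.ndarray:
    """Category response probabilities along one latent dimension.

    Returns a ``K x len(grid)`` matrix whose column ``g`` is the category
    probability vector at ``theta[varied_dim] = grid[g]`` with all other
    dimensions held at zero.  These are the category response curves usually
    plotted to judge how a response style reshapes the answer distribution.
    """
    grid = np.atleast_1d(np.asarray(grid, dtype=float))
    if grid.size == 0:
        raise ValueError("grid must contain at least one latent value")
    if not 0 <= varied_dim < scoring.n_dims:
        raise ValueError(f"varied_dim {varied_dim} out of range")
    out = np.empty((scoring.n_categories, grid.size))
    theta = np.zeros(scoring.n_dims)
    for g, value in enumerate(grid):
        theta[varied_dim] = value
        out[:, g] = category_probabilities(theta, item, scoring)
    return out


def count_free_parameters(spec: ModelSpec, n_items: int | None = None) -> int:
    """Free parameters of a fitted model.

    Per item: one substantive slope, one slope per response-style dimension,
    and K - 1 free intercepts (the first category's intercept is fixed at zero
    for identification).  All latent correlations are freely estimated, adding
    T(T-1)/2.
    """
    J = spec.n_items if n_items is None else int(n_items)
    if J < 1:
        raise ValueError("need at least one item")
    K, T = spec.n_categories, spec.n_dims
    return J * (1 + spec.n_rs_dims + (K - 1)) + T * (T - 1) // 2
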