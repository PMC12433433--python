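"""Marginal maximum likelihood estimation of the adapted MNRM.

The latent traits are integrated out over a multivariate normal with zero
means, unit variances and free correlations (the identification used
throughout), approximated on a tensor Gauss–Hermite grid rotated by the
Cholesky factor of the current correlation matrix.  Estimation is a
Bock–Aitkin EM:

* E-step — posterior weights of the quadrature nodes per person, computed
  with one dense matrix product between the one-hot response matrix and the
  per-node item log-probabilities (fast enough for thousands of fits).
* M-step — each item's slopes and free intercepts solve a weighted
  multinomial-logit problem (concave, Newton with backtracking, batched over
  items); the latent correlation matrix is updated from the posterior second
  moments, rescaled to unit diagonal.

The first category's intercept is fixed at zero for identification; the
generating intercepts (-2,-1,0,-1,-2) are therefore recovered in the
location-shifted form (0,1,2,1,0), which describes exactly the same model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .datagen import ResponseMatrix
from .model import (
    MISSING,
    ItemParameters,
    LatentDistribution,
    ModelSpec,
    count_free_parameters,
)

__all__ = ["FitOptions", "FitResult", "marginal_loglik", "fit_mnrm",
           "fitted_model_battery"]

#: Default EM quadrature points per dimension, by total latent
#: dimensionality; tensor grids are pruned to nodes carrying non-negligible
#: prior mass, which keeps the largest models desk-tractable.
DEFAULT_QUAD_POINTS = {1: 21, 2: 15, 3: 13, 4: 9}

#: Denser per-dimension grids used once per fit to evaluate the reported
#: marginal log-likelihood at the final estimates (rotated by the Cholesky
#: factor of the estimated correlation matrix, which stays accurate for
#: strong correlations where an axis-aligned grid degrades).
EVAL_QUAD_POINTS = {1: 61, 2: 31, 3: 21, 4: 13}


@dataclass(frozen=True)
class FitOptions:
    """Estimator settings.

    ``quad_points`` of ``None`` picks the per-dimension default for the
    model's dimensionality.  Convergence is declared when either the marginal
    log-likelihood change or the largest parameter change falls below its
    tolerance; optionally also when the total log-likelihood gain over the
    last ``stall_window`` cycles drops below ``stall_tol`` (a coarser rule
    for Monte-Carlo runs, where a weakly identified direction can otherwise
    crawl for hundreds of cycles without affecting model selection).
    """

    quad_points: int | None = None
    tol_loglik: float = 1e-6
    tol_param: float = 1e-4
    stall_window: int | None = None
    stall_tol: float = 0.0
    max_cycles: int = 500
    newton_steps: int = 1
    start_slope: float = 1.0
    slope_min: float = 1e-3
    slope_max: float = 20.0
    intercept_bound: float = 15.0
    corr_bound: float = 0.85
    prune_mass: float = 1e-8
    accelerate: bool = True
    fallback: bool = False

    def __post_init__(self) -> None:
        if self.quad_points is not None and self.quad_points < 3:
            raise ValueError("need at least 3 quadrature points per dimension")
        if self.tol_loglik <= 0 or self.tol_param <= 0:
            raise ValueError("tolerances must be positive")
        if not 0 < self.corr_bound < 1:
            raise ValueError("corr_bound must be in (0, 1)")

    def points_for(self, n_dims: int) -> int:
        if self.quad_points is not None:
            return self.quad_points
        return DEFAULT_QUAD_POINTS.get(n_dims, 7)

    def eval_points_for(self, n_dims: int) -> int:
        return EVAL_QUAD_POINTS.get(n_dims, 11)


@dataclass
class FitResult:
    """Outcome of one marginal-maximum-likelihood fit."""

    spec: ModelSpec
    slopes: np.ndarray            # (J, T), zeros on unloaded dimensions
    intercepts: np.ndarray        # (J, K), first column fixed at 0
    correlation: np.ndarray       # (T, T)
    loglik: float
    n_params: int
    n_persons: int
    converged: bool
    n_cycles: int
    loglik_trace: list[float] = field(default_factory=list)
    at_bound: bool = False
    used_fallback: bool = False

    @property
    def items(self) -> list[ItemParameters]:
        return [ItemParameters(a, c) for a, c in zip(self.slopes, self.intercepts)]

    def to_dict(self) -> dict:
        return {
            "kind": self.spec.kind,
            "n_substantive": self.spec.n_substantive,
            "n_categories": self.spec.n_categories,
            "item_assignment": list(self.spec.item_assignment),
            "slopes": self.slopes.tolist(),
            "intercepts": self.intercepts.tolist(),
            "correlation": self.correlation.tolist(),
            "loglik": self.loglik,
            "n_params": self.n_params,
            "n_persons": self.n_persons,
            "converged": self.converged,
            "n_cycles": self.n_cycles,
            "at_bound": self.at_bound,
            "used_fallback": self.used_fallback,
            "loglik_trace": self.loglik_trace,
        }


def _gauss_hermite_grid(n_dims: int, n_points: int):
    """Tensor Gauss–Hermite grid for a standard normal: nodes (Q, T) and
    log-weights (Q,)."""
    x, w = np.polynomial.hermite.hermgauss(n_points)
    x = x * np.sqrt(2.0)               # probabilists' scaling
    logw = np.log(w) - 0.5 * np.log(np.pi)
    grids = np.meshgrid(*([x] * n_dims), indexing="ij")
    nodes = np.column_stack([g.ravel() for g in grids])
    logws = np.zeros(nodes.shape[0])
    wgrids = np.meshgrid(*([logw] * n_dims), indexing="ij")
    for g in wgrids:
        logws += g.ravel()
    return nodes, logws


def _reweight_for_correlation(Z: np.ndarray, logw: np.ndarray,
                              R: np.ndarray) -> np.ndarray:
    """Fold a correlated normal prior into fixed-grid node weights.

    The axis-aligned Gauss–Hermite grid integrates against the independent
    standard normal; multiplying each node weight by the density ratio
    φ_R(z)/φ_I(z) makes the same grid integrate against the correlated
    prior without moving any node.
    """
    T = Z.shape[1]
    if T == 1 or np.allclose(R, np.eye(T)):
        return logw
    _, logdet = np.linalg.slogdet(R)
    M = np.linalg.inv(R) - np.eye(T)
    quad_form = np.einsum("qi,ij,qj->q", Z, M, Z, optimize=True)
    return logw - 0.5 * (quad_form + logdet)


def _one_hot(data: ResponseMatrix) -> np.ndarray:
    """(N, J*K) one-hot encoding; missing responses give an all-zero block,
    so they contribute no likelihood factor."""
    N, J = data.responses.shape
    K = data.n_categories
    C = np.zeros((N, J * K))
    rows, cols = np.nonzero(data.responses != MISSING)
    C[rows, cols * K + data.responses[rows, cols]] = 1.0
    return C


def _log_softmax(z: np.ndarray) -> np.ndarray:
    """Log-softmax over the last axis, in place (max-shifted for stability)."""
    z -= z.max(axis=-1, keepdims=True)
    z -= np.log(np.exp(z).sum(axis=-1, keepdims=True))
    return z


def _row_logsumexp(a: np.ndarray):
    """Per-row log-sum-exp and normalized exponentials of a 2-d array."""
    m = a.max(axis=1)
    E = np.exp(a - m[:, None])
    s = E.sum(axis=1)
    E /= s[:, None]
    return m + np.log(s), E


def _item_log_probs(slopes: np.ndarray, intercepts: np.ndarray,
                    scoring: np.ndarray, nodes: np.ndarray) -> np.ndarray:
    """(J, Q, K) log category probabilities at every quadrature node."""
    z = np.einsum("jd,dk,qd->jqk", slopes, scoring, nodes, optimize=True)
    z += intercepts[:, None, :]
    return _log_softmax(z)


def _person_log_liks(C: np.ndarray, log_probs: np.ndarray) -> np.ndarray:
    """(N, Q) joint response log-likelihood per person and node."""
    J, Q, K = log_probs.shape
    flat = log_probs.transpose(0, 2, 1).reshape(J * K, Q)
    return C @ flat


def marginal_loglik(data: ResponseMatrix, items: list[ItemParameters],
                    spec: ModelSpec, latent: LatentDistribution | None = None,
                    options: FitOptions = FitOptions()) -> float:
    """Marginal log-likelihood of fixed parameters under quadrature.

    Sum over persons of ``log ∫ Π_j P(y_j | θ) φ(θ; 0, R) dθ``; missing
    responses are skipped (ignorable missingness).
    """
    T = spec.n_dims
    if latent is None:
        latent = LatentDistribution.identity(T)
    if latent.n_dims != T:
        raise ValueError("latent distribution dimension does not match the model")
    if np.any((data.responses < MISSING) | (data.responses >= spec.n_categories)):
        raise ValueError("response codes outside 0..K-1")
    slopes = np.vstack([it.slopes for it in items])
    intercepts = np.vstack([it.intercepts for it in items])
    scoring = spec.scoring_matrix().values
    return _loglik_at(_one_hot(data), slopes, intercepts, scoring,
                      latent.correlation, options.points_for(T))


def _loglik_at(C: np.ndarray, slopes: np.ndarray, intercepts: np.ndarray,
               scoring: np.ndarray, R: np.ndarray, n_points: int) -> float:
    """Quadrature marginal log-likelihood on a correlation-rotated grid."""
    T = R.shape[0]
    Z, logw = _gauss_hermite_grid(T, n_points)
    X = Z @ np.linalg.cholesky(R).T
    log_probs = _item_log_probs(slopes, intercepts, scoring, X)
    person_ll, _ = _row_logsumexp(_person_log_liks(C, log_probs) + logw)
    return float(person_ll.sum())


def _expected_item_logliks(a_red, c, r, S_eff, X_eff):
    """Per-item expected complete-data log-likelihood and probabilities."""
    z = np.einsum("jp,pk,jqp->jqk", a_red, S_eff, X_eff, optimize=True)
    z += c[:, None, :]
    logP = _log_softmax(z)
    ell = np.einsum("jqk,jqk->j", r, logP, optimize=True)
    return ell, np.exp(logP)


def _newton_mstep(a_red, c, r, S_eff, X_eff, F, options: FitOptions):
    """Batched Newton updates of each item's slopes and free intercepts.

    The objective per item is the expected multinomial-logit log-likelihood
    with quadrature-node design — concave, so Newton with backtracking is
    globally safe.  Returns updated ``(a_red, c)``.
    """
    J, n_a = a_red.shape
    K = c.shape[1]
    n_par = n_a + K - 1
    Nq = r.sum(axis=2)
    params = np.concatenate([a_red, c[:, 1:]], axis=1)  # (J, n_par)

    for _ in range(options.newton_steps):
        ell, P = _expected_item_logliks(params[:, :n_a], _with_zero_first(params[:, n_a:]),
                                        r, S_eff, X_eff)
        resid = r - Nq[:, :, None] * P
        grad = np.einsum("jqk,jqkp->jp", resid, F, optimize=True)
        mbar = np.einsum("jqk,jqkp->jqp", P, F, optimize=True)
        H = np.einsum("jq,jqk,jqkp,jqkr->jpr", Nq, P, F, F, optimize=True)
        H -= np.einsum("jq,jqp,jqr->jpr", Nq, mbar, mbar, optimize=True)
        H += 1e-9 * np.eye(n_par)
        try:
            step = np.linalg.solve(H, grad[..., None])[..., 0]
        except np.linalg.LinAlgError:
            step = grad / np.maximum(np.einsum("jpp->j", H), 1e-9)[:, None]

        # backtracking line search, vectorized over items
        t = np.ones(J)
        accepted = np.zeros(J, dtype=bool)
        new_params = params.copy()
        for _ in range(12):
            trial = params + t[:, None] * step
            ell_new, _ = _expected_item_logliks(
                trial[:, :n_a], _with_zero_first(trial[:, n_a:]), r, S_eff, X_eff)
            improved = ~accepted & (ell_new >= ell - 1e-10)
            new_params[improved] = trial[improved]
            accepted |= improved
            if accepted.all():
                break
            t[~accepted] *= 0.5
        params = new_params

    a_new = np.clip(params[:, :n_a], options.slope_min, options.slope_max)
    c_new = _with_zero_first(np.clip(params[:, n_a:], -options.intercept_bound,
                                     options.intercept_bound))
    at_bound = bool(np.any(params[:, :n_a] != a_new) or
                    np.any(params[:, n_a:] != c_new[:, 1:]))
    return a_new, c_new, at_bound


def _with_zero_first(c_free: np.ndarray) -> np.ndarray:
    """Prepend the fixed zero first-category intercept."""
    J = c_free.shape[0]
    return np.concatenate([np.zeros((J, 1)), c_free], axis=1)


def _rescale_to_correlation(S: np.ndarray, eigen_floor: float = 0.05) -> np.ndarray:
    """Unit-diagonal rescaling with an eigenvalue floor.

    The floor keeps the latent distribution away from singularity (pairwise
    correlations effectively bounded near ±(1 - floor)); a singular latent
    covariance is both unidentifiable and numerically hostile to the
    quadrature rotation, and without the floor the EM can crawl toward ±1
    for hundreds of cycles when a two-dimensional response-style model is
    fitted to data whose styles are perfectly anti-correlated.
    """
    S = 0.5 * (S + S.T)
    scale = np.sqrt(np.clip(np.diag(S), 1e-12, None))
    R = S / np.outer(scale, scale)
    w, V = np.linalg.eigh(R)
    if w.min() < eigen_floor:
        w = np.clip(w, eigen_floor, None)
        R = (V * w) @ V.T
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)
    R = 0.5 * (R + R.T)
    np.fill_diagonal(R, 1.0)
    return R


def _angles_to_cholesky(phi: np.ndarray, T: int) -> np.ndarray:
    """Hyperspherical Cholesky factor: unit-norm rows built from angles, so
    ``L @ L.T`` is always a valid correlation matrix."""
    L = np.eye(T)
    idx = 0
    for i in range(1, T):
        tail = 1.0
        for j in range(i):
            L[i, j] = np.cos(phi[idx]) * tail
            tail *= np.sin(phi[idx])
            idx += 1
        L[i, i] = tail
    return L


def _cholesky_to_angles(R: np.ndarray) -> np.ndarray:
    T = R.shape[0]
    L = np.linalg.cholesky(R)
    phi = []
    for i in range(1, T):
        tail = 1.0
        for j in range(i):
            ratio = np.clip(L[i, j] / max(tail, 1e-12), -1.0, 1.0)
            phi.append(np.arccos(ratio))
            tail *= np.sin(phi[-1])
    return np.array(phi)


def _shrink_to_bound(R: np.ndarray, bound: float) -> np.ndarray:
    """Shrink a correlation matrix toward the identity until every pairwise
    correlation is within ±bound (a convex combination, so positive
    definiteness is preserved)."""
    off = np.tril_indices(R.shape[0], -1)
    worst = np.abs(R[off]).max() if off[0].size else 0.0
    if worst <= bound:
        return R
    t = bound / worst
    out = t * R + (1.0 - t) * np.eye(R.shape[0])
    np.fill_diagonal(out, 1.0)
    return out


def _update_correlation(S_post: np.ndarray, R_current: np.ndarray,
                        corr_bound: float) -> np.ndarray:
    """Exact constrained M-step for the latent correlation matrix.

    Maximizes the expected Gaussian log-density, i.e. minimizes
    ``log det R + tr(R^{-1} S)`` over unit-diagonal positive-definite R,
    through the hyperspherical-Cholesky angles (at most T(T-1)/2 = 6 of
    them).  Pairwise correlations are kept inside ±``corr_bound`` by a
    smooth penalty: a near-singular latent covariance is weakly identified
    and degrades the fixed quadrature grid, and without the bound the EM
    can crawl toward ±1 for hundreds of cycles when a two-dimensional
    response-style model is fitted to data whose styles are perfectly
    anti-correlated.  The update never loses (penalized) objective relative
    to the current R, preserving EM monotonicity; plain unit-diagonal
    rescaling of ``S_post`` does not have this property and can walk the
    marginal likelihood downhill.
    """
    from scipy.optimize import minimize

    T = R_current.shape[0]
    S = 0.5 * (S_post + S_post.T)
    off = np.tril_indices(T, -1)

    def objective(phi):
        L = _angles_to_cholesky(phi, T)
        R = L @ L.T
        sign, logdet = np.linalg.slogdet(R)
        if sign <= 0:
            return np.inf
        excess = np.clip(np.abs(R[off]) - corr_bound, 0.0, None)
        return (logdet + np.trace(np.linalg.solve(R, S))
                + 1e4 * float(excess @ excess))

    def gaussian_objective(R):
        sign, logdet = np.linalg.slogdet(R)
        if sign <= 0:
            return np.inf
        return logdet + np.trace(np.linalg.solve(R, S))

    R_start = _shrink_to_bound(R_current, corr_bound)
    phi0 = _cholesky_to_angles(R_start)
    eps = 1e-3          # keep the Cholesky factor non-degenerate
    phi0 = np.clip(phi0, eps, np.pi - eps)
    res = minimize(objective, phi0, method="L-BFGS-B",
                   bounds=[(eps, np.pi - eps)] * phi0.size,
                   options={"maxiter": 40})
    L = _angles_to_cholesky(res.x, T)
    R = _shrink_to_bound(L @ L.T, corr_bound)
    R = 0.5 * (R + R.T)
    np.fill_diagonal(R, 1.0)
    # both candidates are inside the bound, so comparing the plain Gaussian
    # objective guarantees the M-step never loses expected log-density
    if gaussian_objective(R) > gaussian_objective(R_start):
        return R_start
    return R


def fit_mnrm(data: ResponseMatrix, spec: ModelSpec,
             options: FitOptions = FitOptions(),
             start: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None
             ) -> FitResult:
    """Fit the adapted MNRM by marginal maximum likelihood (EM).

    Starts from unit slopes, zero intercepts and uncorrelated traits, or
    from an explicit ``start = (slopes (J, T), intercepts (J, K),
    correlation (T, T))`` triple (used by the model battery to warm-start
    the larger models from the smaller ones).  Returns a
    :class:`FitResult`; if the EM does not converge within ``max_cycles``
    the result is returned with ``converged=False`` (and, when
    ``options.fallback`` is set, after a quasi-Newton polish of the
    marginal likelihood from the EM solution).
    """
    if data.n_items != spec.n_items:
        raise ValueError("data and model disagree on the number of items")
    observed = data.responses[data.responses != MISSING]
    if observed.size and (observed.min() < 0 or observed.max() >= spec.n_categories):
        raise ValueError("response codes outside 0..K-1")
    for j in range(data.n_items):
        col = data.responses[:, j]
        if np.unique(col[col != MISSING]).size < 2:
            raise ValueError(f"item {j} shows fewer than 2 observed categories")

    J, K, T, D = spec.n_items, spec.n_categories, spec.n_dims, spec.n_substantive
    n_rs = spec.n_rs_dims
    n_a = 1 + n_rs
    assign = np.asarray(spec.item_assignment)
    scoring = spec.scoring_matrix().values
    # Reduced scoring: each item loads one substantive row (identical linear
    # scores) plus every response-style row.
    S_eff = np.vstack([scoring[0], scoring[D:]]) if n_rs else scoring[:1]

    Z, logw = _gauss_hermite_grid(T, options.points_for(T))
    if T > 1 and options.prune_mass > 0:
        # drop tensor-grid corners carrying negligible prior mass
        keep = logw > logw.max() + np.log(options.prune_mass)
        Z, logw = Z[keep], logw[keep]
    Q = Z.shape[0]
    C = _one_hot(data)
    N = data.n_persons

    a_red = np.full((J, n_a), options.start_slope)
    c = np.zeros((J, K))
    R = np.eye(T)
    if start is not None:
        slopes0, intercepts0, R0 = start
        a_red[:, 0] = slopes0[np.arange(J), assign]
        if n_rs:
            a_red[:, 1:] = slopes0[:, D:]
        a_red = np.clip(a_red, options.slope_min, options.slope_max)
        c = np.asarray(intercepts0, dtype=float).copy()
        c[:, 0] = 0.0
        R = np.asarray(R0, dtype=float).copy()

    # The quadrature grid is FIXED (axis-aligned standard-normal tensor grid);
    # a non-identity latent correlation enters through the prior node weights
    # as the density ratio φ_R/φ_I at each node.  Keeping the nodes fixed
    # makes the E- and M-steps coherent (a true EM with a non-decreasing
    # marginal likelihood) and lets the per-node design features be built once.
    n_par = n_a + K - 1
    F = np.zeros((J, Q, K, n_par))
    for k in range(1, K):
        F[:, :, k, n_a + k - 1] = 1.0
    X_eff = np.empty((J, Q, n_a))
    X_eff[:, :, 0] = Z[:, assign].T
    for rdim in range(n_rs):
        X_eff[:, :, 1 + rdim] = Z[:, D + rdim]
    F[:, :, :, :n_a] = np.einsum("pk,jqp->jqkp", S_eff, X_eff, optimize=True)

    def prior_log_weights(Rmat):
        return _reweight_for_correlation(Z, logw, Rmat)

    def full_slopes(a):
        out = np.zeros((J, T))
        out[np.arange(J), assign] = a[:, 0]
        if n_rs:
            out[:, D:] = a[:, 1:]
        return out

    # flat parameter vector: reduced slopes, free intercepts, correlations
    tril = np.tril_indices(T, -1)

    def pack(a, cmat, Rmat):
        return np.concatenate([a.ravel(), cmat[:, 1:].ravel(), Rmat[tril]])

    def unpack(vec):
        a = vec[:J * n_a].reshape(J, n_a)
        cmat = _with_zero_first(vec[J * n_a:J * (n_a + K - 1)].reshape(J, K - 1))
        Rmat = np.eye(T)
        if tril[0].size:
            Rmat[tril] = vec[J * (n_a + K - 1):]
            Rmat.T[tril] = Rmat[tril]
        return a, cmat, Rmat

    def project(vec):
        """Pull an extrapolated point back into the feasible region
        (slope/intercept bounds, positive-definite correlations inside the
        pairwise bound)."""
        a, cmat, Rmat = unpack(vec)
        a = np.clip(a, options.slope_min, options.slope_max)
        cfree = np.clip(cmat[:, 1:], -options.intercept_bound,
                        options.intercept_bound)
        Rmat = _shrink_to_bound(_rescale_to_correlation(Rmat),
                                options.corr_bound)
        return pack(a, _with_zero_first(cfree), Rmat)

    state = {"at_bound": False}

    def em_update(vec):
        """One EM cycle; returns the new point and the log-likelihood at the
        *input* point (a by-product of the E-step)."""
        a, cmat, Rmat = unpack(vec)
        log_probs = _item_log_probs(full_slopes(a), cmat, scoring, Z)
        person_ll, post = _row_logsumexp(
            _person_log_liks(C, log_probs) + prior_log_weights(Rmat))
        loglik = float(person_ll.sum())
        r = (C.T @ post).reshape(J, K, Q).transpose(0, 2, 1)
        a_new, c_new, hit = _newton_mstep(a, cmat, r, S_eff, X_eff, F, options)
        state["at_bound"] |= hit
        if T > 1:
            node_mass = post.sum(axis=0)
            R_new = _update_correlation((Z.T * node_mass) @ Z / N, Rmat,
                                        options.corr_bound)
        else:
            R_new = Rmat
        return pack(a_new, c_new, R_new), loglik

    theta = pack(a_red, c, R)
    trace: list[float] = []
    converged = False
    n_cycles = 0
    prev_ll = -np.inf

    def stalled():
        w = options.stall_window
        return (w is not None and len(trace) > w
                and trace[-1] - trace[-1 - w] < options.stall_tol)

    # EM with optional SQUAREM-style extrapolation: two plain cycles give a
    # secant direction, the extrapolated point is projected back into the
    # feasible region, and a stabilizing EM cycle follows.  The jump is kept
    # only if it does not lose likelihood, so the accepted trace stays
    # non-decreasing like plain EM.
    while n_cycles < options.max_cycles and not converged:
        theta1, ll0 = em_update(theta)
        n_cycles += 1
        trace.append(ll0)
        if (abs(ll0 - prev_ll) < options.tol_loglik
                or np.abs(theta1 - theta).max() < options.tol_param
                or stalled()):
            theta, prev_ll, converged = theta1, ll0, True
            break
        prev_ll = ll0
        if not options.accelerate or n_cycles + 2 > options.max_cycles:
            theta = theta1
            continue

        theta2, ll1 = em_update(theta1)
        n_cycles += 1
        trace.append(ll1)
        if (abs(ll1 - ll0) < options.tol_loglik
                or np.abs(theta2 - theta1).max() < options.tol_param
                or stalled()):
            theta, prev_ll, converged = theta2, ll1, True
            break
        prev_ll = ll1

        r_vec = theta1 - theta
        v_vec = theta2 - 2.0 * theta1 + theta
        v_norm = np.linalg.norm(v_vec)
        if v_norm < 1e-12:
            theta = theta2
            continue
        alpha = -max(1.0, np.linalg.norm(r_vec) / v_norm)
        candidate = project(theta - 2.0 * alpha * r_vec + alpha * alpha * v_vec)
        theta3, ll_ex = em_update(candidate)
        n_cycles += 1
        if ll_ex >= ll1:
            trace.append(ll_ex)
            theta, prev_ll = theta3, ll_ex
        else:  # reject the jump, keep the plain EM point
            theta = theta2

    a_red, c, R = unpack(theta)

    # The reported marginal log-likelihood is recomputed once on a denser
    # grid rotated by the Cholesky factor of the estimated correlation
    # matrix.  The rotated evaluation stays accurate for strong correlations
    # and, being shared by all model kinds, removes the small grid-dependent
    # bias from AIC/BIC comparisons; the EM trace keeps the working-grid
    # values it actually monotonically improved.
    final_ll = _loglik_at(C, full_slopes(a_red), c, scoring, R,
                          options.eval_points_for(T))

    result = FitResult(
        spec=spec, slopes=full_slopes(a_red), intercepts=c, correlation=R,
        loglik=final_ll, n_params=count_free_parameters(spec),
        n_persons=N, converged=converged, n_cycles=n_cycles,
        loglik_trace=trace, at_bound=state["at_bound"])

    if not converged:
        warnings.warn(
            f"EM did not converge in {options.max_cycles} cycles for kind "
            f"{spec.kind!r}", RuntimeWarning, stacklevel=2)
        if options.fallback:
            result = _direct_maximize(data, result, options)
    return result


def _direct_maximize(data: ResponseMatrix, start: FitResult,
                     options: FitOptions) -> FitResult:
    """Quasi-Newton polish of the marginal likelihood from an EM solution.

    Packs item parameters and the free correlations (through a normalized
    Cholesky factor) into one vector and runs bounded L-BFGS with numerical
    gradients.  Intended as a fallback for non-converged EM runs on small
    problems, not as the primary estimator.
    """
    from scipy.optimize import minimize

    spec = start.spec
    J, K, T, D = spec.n_items, spec.n_categories, spec.n_dims, spec.n_substantive
    n_rs = spec.n_rs_dims
    assign = np.asarray(spec.item_assignment)
    scoring = spec.scoring_matrix().values
    Z, logw = _gauss_hermite_grid(T, options.points_for(T))
    C = _one_hot(data)
    n_corr = T * (T - 1) // 2
    tril = np.tril_indices(T, -1)

    def unpack(x):
        a_sub = x[:J]
        a_rs = x[J:J + J * n_rs].reshape(J, n_rs)
        c_free = x[J + J * n_rs:J + J * n_rs + J * (K - 1)].reshape(J, K - 1)
        slopes = np.zeros((J, T))
        slopes[np.arange(J), assign] = a_sub
        if n_rs:
            slopes[:, D:] = a_rs
        c = _with_zero_first(c_free)
        Lraw = np.eye(T)
        if n_corr:
            Lraw[tril] = x[-n_corr:]
            Lraw /= np.sqrt((Lraw ** 2).sum(axis=1, keepdims=True))
        R = Lraw @ Lraw.T
        return slopes, c, _rescale_to_correlation(R)

    def negloglik(x):
        slopes, c, R = unpack(x)
        log_probs = _item_log_probs(slopes, c, scoring, Z)
        person_ll, _ = _row_logsumexp(
            _person_log_liks(C, log_probs) + _reweight_for_correlation(Z, logw, R))
        return -float(person_ll.sum())

    x0 = np.concatenate([
        start.slopes[np.arange(J), assign],
        start.slopes[:, D:].ravel(),
        start.intercepts[:, 1:].ravel(),
        np.linalg.cholesky(start.correlation)[tril] if n_corr else np.empty(0),
    ])
    bounds = ([(options.slope_min, options.slope_max)] * (J * (1 + n_rs))
              + [(-options.intercept_bound, options.intercept_bound)] * (J * (K - 1))
              + [(-5.0, 5.0)] * n_corr)
    res = minimize(negloglik, x0, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": 50})
    slopes, c, R = unpack(res.x)
    # report on the same dense rotated grid as the EM path for comparability
    final_ll = _loglik_at(C, slopes, c, scoring, R, options.eval_points_for(T))
    if final_ll <= start.loglik:
        return start
    return replace(start, slopes=slopes, intercepts=c, correlation=R,
                   loglik=final_ll, converged=bool(res.success),
                   used_fallback=True)


def _battery_start(prev: FitResult, spec: ModelSpec):
    """Map a smaller model's estimates onto a larger model's start values.

    Substantive slopes and intercepts carry over directly.  Going from the
    bipolar model to separate ERS and MRS dimensions, both response-style
    slopes start at the bipolar slope (the models coincide at an ERS-MRS
    correlation of -1, since the bipolar scoring row is the ERS row minus
    the MRS row up to a constant); the starting correlation is left at a
    feasible interior value.
    """
    J, T, D = spec.n_items, spec.n_dims, spec.n_substantive
    T_prev = prev.spec.n_dims
    slopes = np.zeros((J, T))
    slopes[:, :D] = prev.slopes[:, :D]
    if prev.spec.kind == "null":
        slopes[:, D:] = 1.0
    elif prev.spec.kind == "ers_mrs":
        slopes[:, D] = prev.slopes[:, D]
        slopes[:, D + 1] = prev.slopes[:, D]
    R = np.eye(T)
    R[:T_prev, :T_prev] = prev.correlation
    if spec.kind == "ers_plus_mrs" and prev.spec.kind == "ers_mrs":
        R = np.eye(T)
        R[:D, :D] = prev.correlation[:D, :D]
        R[D + 1, :D] = R[:D, D + 1] = -prev.correlation[D, :D]
        R[D, :D] = R[:D, D] = prev.correlation[D, :D]
        R[D, D + 1] = R[D + 1, D] = -0.5
    return slopes, prev.intercepts, _rescale_to_correlation(R)


def fitted_model_battery(data: ResponseMatrix, n_substantive: int = 1,
                         options: FitOptions = FitOptions(),
                         n_categories: int | None = None,
                         warm_start: bool = True) -> dict[str, FitResult]:
    """Fit the null, ERS/MRS and ERS+MRS models to the same data.

    Returns the three fits keyed by kind, in fixed order, with a consistent
    item-to-dimension assignment.  By default each larger model is
    warm-started from the preceding fit (a deterministic speed-up that does
    not change the likelihood being maximized); ``warm_start=False``
    restores the generic start values for every model.
    """
    K = n_categories or data.n_categories
    out: dict[str, FitResult] = {}
    prev: FitResult | None = None
    for kind in ("null", "ers_mrs", "ers_plus_mrs"):
        spec = ModelSpec.create(kind, data.n_items, n_substantive, K)
        start = _battery_start(prev, spec) if (warm_start and prev is not None) else None
        out[kind] = fit_mnrm(data, spec, options, start=start)
        prev = out[kind]
    return out
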