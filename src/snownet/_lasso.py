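"""Gram-based lasso paths for neighborhood selection.

Neighborhood selection solves p separate lasso regressions that all share
one Gram matrix, and StARS re-solves them on every subsample, so the solver
is the pipeline's hot loop.  The primary implementation is an active-set
coordinate descent on the Gram matrix with KKT violation screening,
compiled with numba and exposed as a *stepwise* path solver: the state for
one dataset can be advanced penalty by penalty (warm starts), which lets
stability selection stop as soon as the instability threshold is crossed
instead of solving the expensive dense end of the path.

A reference implementation built on scikit-learn's ``lasso_path`` solves
the identical objective,

    (1 / 2n) * ||y − X b||² + λ ||b||₁ ,

and serves as an independent cross-check in the test suite; the two agree
to solver tolerance.
"""

from __future__ import annotations

import logging

import numpy as np

logger = logging.getLogger(__name__)

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=True)
def _solve_response(Q, b, j, lam_n, tol, max_iter):  # pragma: no cover - numba
    """Lasso for response j (predictors = all other features) on Gram Q.

    ``b`` (length p) is the warm-start coefficient vector, updated in place.
    Active-set coordinate descent: converge on the current active set, then
    scan all coordinates for KKT violations, repeat until none remain.
    """
    p = Q.shape[0]
    in_active = np.zeros(p, dtype=np.bool_)
    for i in range(p):
        if b[i] != 0.0 and i != j:
            in_active[i] = True
    for _pass in range(100):
        active = np.flatnonzero(in_active)
        n_active = active.size
        if n_active > 0:
            for _it in range(max_iter):
                max_delta = 0.0
                for a in range(n_active):
                    i = active[a]
                    qii = Q[i, i]
                    if qii <= 0.0:
                        continue
                    r_i = Q[i, j]
                    for c in range(n_active):
                        k = active[c]
                        if k != i and b[k] != 0.0:
                            r_i -= Q[i, k] * b[k]
                    if r_i > lam_n:
                        new = (r_i - lam_n) / qii
                    elif r_i < -lam_n:
                        new = (r_i + lam_n) / qii
                    else:
                        new = 0.0
                    delta = abs(new - b[i])
                    if delta > max_delta:
                        max_delta = delta
                    b[i] = new
                if max_delta < tol:
                    break
            for a in range(n_active):
                if b[active[a]] == 0.0:
                    in_active[active[a]] = False
        # KKT scan over inactive coordinates
        active = np.flatnonzero(in_active)
        n_violations = 0
        for i in range(p):
            if i == j or in_active[i] or Q[i, i] <= 0.0:
                continue
            r_i = Q[i, j]
            for c in range(active.size):
                r_i -= Q[i, active[c]] * b[active[c]]
            if abs(r_i) > lam_n * (1.0 + 1e-12) + 1e-12:
                in_active[i] = True
                n_violations += 1
        if n_violations == 0:
            return
    return


@njit(cache=True)
def _neighborhood_step(Q, lam_n, B, tol, max_iter):  # pragma: no cover - numba
    """Advance every response's lasso to penalty ``lam_n`` (warm-started).

    ``B`` has shape (p, p) with row j holding response j's coefficients.
    """
    p = Q.shape[0]
    for j in range(p):
        _solve_response(Q, B[j], j, lam_n, tol, max_iter)


class NeighborhoodState:
    """Warm-start state of one dataset's neighborhood-selection path."""

    def __init__(self, z: np.ndarray, tol: float = 1e-6, max_iter: int = 1000):
        z = np.ascontiguousarray(z, dtype=np.float64)
        self.n = z.shape[0]
        self.p = z.shape[1]
        self.gram = np.ascontiguousarray(z.T @ z)
        self.B = np.zeros((self.p, self.p))  # row j = response j
        self.tol = tol
        self.max_iter = max_iter
        self.last_lambda = np.inf

    def step(self, lam: float) -> np.ndarray:
        """Solve at penalty ``lam`` (≤ previous λ) and return B (rows = responses)."""
        if lam > self.last_lambda:
            raise ValueError("stepwise path must use non-increasing lambdas")
        self.last_lambda = lam
        if self.p >= 2:
            _neighborhood_step(self.gram, lam * self.n, self.B, self.tol, self.max_iter)
        return self.B

    def support(self) -> np.ndarray:
        """Symmetric (OR-rule) adjacency of the current coefficients."""
        nz = self.B != 0
        return nz | nz.T


def neighborhood_paths_numba(z: np.ndarray, lambdas: np.ndarray,
                             tol: float = 1e-6, max_iter: int = 1000) -> np.ndarray:
    """B[l, i, j]: coefficient of predictor i for response j at lambdas[l]."""
    state = NeighborhoodState(z, tol=tol, max_iter=max_iter)
    out = np.zeros((len(lambdas), state.p, state.p))
    for l, lam in enumerate(lambdas):
        out[l] = state.step(float(lam)).T  # rows→responses ⇒ transpose to [i, j]
    return out


def neighborhood_paths_sklearn(z: np.ndarray, lambdas: np.ndarray) -> np.ndarray:
    """Reference path via scikit-learn's ``lasso_path`` (same objective)."""
    from sklearn.linear_model import lasso_path

    n, p = z.shape
    B = np.zeros((len(lambdas), p, p))
    if p < 2:
        return B
    gram = z.T @ z
    idx = np.arange(p)
    for j in range(p):
        mask = idx != j
        alphas, coefs, _ = lasso_path(
            z[:, mask],
            z[:, j],
            alphas=lambdas,
            precompute=gram[np.ix_(mask, mask)],
            Xy=gram[mask, j],
            copy_X=False,
        )
        order = np.argsort(-alphas)  # lasso_path returns its own (descending) order
        B[:, mask, j] = coefs[:, order].T
    return B


def neighborhood_paths(z: np.ndarray, lambdas: np.ndarray) -> np.ndarray:
    if HAVE_NUMBA:
        return neighborhood_paths_numba(z, lambdas)
    logger.warning("numba unavailable; using the slower scikit-learn path solver")
    return neighborhood_paths_sklearn(z, lambdas)
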