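"""Batch l1-regularized recovery of the source matrix.

Given the estimated mixing matrix ``A`` (2 x M, unit-norm columns) and the
two-row data ``X`` (2 x K), the source matrix is recovered by minimizing

    0.5 * ||A S - X||_F^2 + lambda * ||S||_1        (optionally S >= 0)

over ``S`` (M x K), all K columns solved simultaneously. The solver is an
accelerated proximal-gradient (momentum / fast iterative shrinkage-
thresholding) scheme: a gradient step on the quadratic term with step size
1/L (L = largest eigenvalue of A^T A) followed by soft-thresholding at
lambda/L, composed with projection onto the non-negative orthant when the
constraint is on (the rule used for gene-expression decompositions).
Momentum iterations can be non-monotone; a restart is applied if the
objective rises for 10 consecutive iterations.

``lambda`` is always specified relative to ``lambda_max = max |A^T X|``,
the smallest penalty at which the all-zero solution is optimal, and is
computed per decomposition problem (per two-row mixture), not globally.
At exit, entries below a hard-zero threshold are snapped to exact zero --
this shrinkage of noise-level residuals is what keeps the recovered sources
genuinely sparse.

Initialization: because the data have only two rows, the minimum-l1 exact
representation of a feature column is a basic solution supported on at
most two mixing columns. The solver enumerates the (at most M(M-1)/2)
column pairs, starts each feature column at its best basic solution, and
lets the proximal iterations handle shrinkage and any support corrections;
for ``lambda >= lambda_max`` it starts at the known optimum ``S = 0``,
which the iterations leave unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import SolverDivergenceError

__all__ = ["SolverConfig", "SourceEstimate", "lambda_max", "ist_solve",
           "sparseness_measure"]


@dataclass
class SolverConfig:
    """Solver settings; ``lambda = lambda_multiplier * lambda_max(A, X)``."""

    lambda_multiplier: float = 1e-4
    nonnegative: bool = False
    max_iter: int = 1000
    tol: float = 1e-8            # relative objective-change stopping rule
    hard_zero_scale: float = 1e-10  # snap |s| < scale * max|A^T X| to zero

    def __post_init__(self):
        if not 0.0 < self.lambda_multiplier <= 1.0:
            raise ValueError("lambda_multiplier must be in (0, 1]")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")


@dataclass
class SourceEstimate:
    """Recovered M x K source matrix and the final objective value."""

    S: np.ndarray
    objective: float
    iterations_run: int
    lam: float


def lambda_max(A: np.ndarray, X: np.ndarray) -> float:
    """Smallest l1 penalty for which ``S = 0`` is optimal: ``max |A^T X|``."""
    atx = np.asarray(A).T @ np.asarray(X)
    return float(np.abs(atx).max()) if atx.size else 0.0


def _basic_solution_start(A: np.ndarray, X: np.ndarray, lam: float,
                          nonnegative: bool) -> np.ndarray:
    """Warm start at the best two-column basic solution of each column.

    For a two-row mixture the minimum-l1 exact representation of a feature
    column is a basic solution of ``A s = x`` supported on (at most) two
    mixing columns, so enumerating all column pairs and keeping the lowest
    objective gives the linear-program vertex the lasso optimum shrinks
    from. Infeasible candidates under the non-negativity constraint are
    clipped and scored by the full objective. The zero vector competes too.
    """
    m = A.shape[1]
    k = X.shape[1]
    best_obj = 0.5 * np.sum(X * X, axis=0)  # the all-zero candidate
    best_pair = np.full(k, -1, dtype=int)
    best_c = np.zeros((2, k))
    pairs = [(i, j) for i in range(m) for j in range(i + 1, m)]
    for p, (i, j) in enumerate(pairs):
        B = A[:, (i, j)]
        det = B[0, 0] * B[1, 1] - B[0, 1] * B[1, 0]
        if abs(det) < 1e-12:
            continue
        C = np.linalg.solve(B, X)  # 2 x K
        if nonnegative:
            C = np.maximum(C, 0.0)
        resid = B @ C - X
        obj = 0.5 * np.sum(resid * resid, axis=0) + lam * np.abs(C).sum(axis=0)
        better = obj < best_obj
        best_obj = np.where(better, obj, best_obj)
        best_pair[better] = p
        best_c[:, better] = C[:, better]
    S = np.zeros((m, k))
    for p, (i, j) in enumerate(pairs):
        cols = best_pair == p
        S[i, cols] = best_c[0, cols]
        S[j, cols] = best_c[1, cols]
    return S


def _objective(AtA, AtX, x_sq, S, lam) -> float:
    # 0.5||AS - X||^2 expanded via the small Gram matrix; avoids forming A S
    fit = 0.5 * (np.sum(S * (AtA @ S)) - 2.0 * np.sum(S * AtX) + x_sq)
    return fit + lam * np.abs(S).sum()


def ist_solve(A: np.ndarray, X: np.ndarray, config: SolverConfig,
              lam: float | None = None) -> SourceEstimate:
    """Accelerated shrinkage-thresholding solve of all K columns in batch.

    ``lam`` overrides the multiplier-relative penalty when given (used by
    tests that probe absolute penalty levels).
    """
    A = np.asarray(A, dtype=float)
    X = np.asarray(X, dtype=float)
    m = A.shape[1]
    k = X.shape[1]
    AtA = A.T @ A
    AtX = A.T @ X
    x_sq = float(np.sum(X * X))
    if lam is None:
        lam = config.lambda_multiplier * lambda_max(A, X)
    L = float(np.linalg.eigvalsh(AtA)[-1])
    if L <= 0:  # A == 0: any S is a minimizer of the fit term
        return SourceEstimate(S=np.zeros((m, k)), objective=0.5 * x_sq,
                              iterations_run=0, lam=lam)
    thresh = lam / L

    if lam >= lambda_max(A, X) or m < 2:
        S = np.zeros((m, k))  # known optimum; iterations keep it fixed
    else:
        S = _basic_solution_start(A, X, lam, config.nonnegative)
    Y = S
    t = 1.0
    f = _objective(AtA, AtX, x_sq, S, lam)
    rising = 0
    it = 0
    for it in range(1, config.max_iter + 1):
        Z = Y - (AtA @ Y - AtX) / L
        if config.nonnegative:
            S_new = np.maximum(Z - thresh, 0.0)
        else:
            S_new = np.sign(Z) * np.maximum(np.abs(Z) - thresh, 0.0)
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        Y = S_new + ((t - 1.0) / t_new) * (S_new - S)
        S, t = S_new, t_new
        f_new = _objective(AtA, AtX, x_sq, S, lam)
        if not np.isfinite(f_new):
            raise SolverDivergenceError(
                f"non-finite objective at iteration {it} (lambda={lam:g})")
        if f_new > f:
            rising += 1
            if rising >= 10:  # momentum restart: drop to plain proximal step
                Y, t, rising = S, 1.0, 0
        else:
            rising = 0
        if abs(f - f_new) <= config.tol * max(abs(f), 1e-300):
            f = f_new
            break
        f = f_new

    snap = config.hard_zero_scale * (np.abs(AtX).max() if AtX.size else 0.0)
    S[np.abs(S) < snap] = 0.0
    f = _objective(AtA, AtX, x_sq, S, lam)
    return SourceEstimate(S=S, objective=float(f), iterations_run=it, lam=float(lam))


def sparseness_measure(s: np.ndarray, tau: float) -> float:
    """Fraction of entries at or below ``tau`` times the peak magnitude.

    Equals 1 for the all-zero vector (maximally sparse by convention).
    """
    if not 0.0 <= tau <= 1.0:
        raise ValueError(f"tau must be in [0, 1], got {tau}")
    s = np.abs(np.asarray(s, dtype=float))
    peak = s.max()
    if peak == 0:
        return 1.0
    return float(np.count_nonzero(s <= tau * peak)) / s.size
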