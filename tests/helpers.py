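"""Independent oracles and fixture builders shared across tests.

The oracles are deliberately naive implementations (per-column coordinate
descent, exhaustive active-set enumeration, brute-force selection rules) so
they share no code path with the package's solvers.
"""

import itertools

import numpy as np


def cd_l1_oracle(A, X, lam, sweeps=2000):
    """Per-column cyclic coordinate descent for 0.5||As-x||^2 + lam||s||_1."""
    A = np.asarray(A, dtype=float)
    X = np.asarray(X, dtype=float)
    m, k = A.shape[1], X.shape[1]
    d = np.sum(A * A, axis=0)
    S = np.zeros((m, k))
    for col in range(k):
        x = X[:, col]
        s = S[:, col]
        for _ in range(sweeps):
            for j in range(m):
                rho = A[:, j] @ (x - A @ s + A[:, j] * s[j])
                s[j] = np.sign(rho) * max(abs(rho) - lam, 0.0) / d[j]
    return S


def l1_objective(A, X, S, lam):
    return 0.5 * np.sum((A @ S - X) ** 2) + lam * np.abs(S).sum()


def nn_active_set_oracle(A, x, lam):
    """Exact minimum of 0.5||As-x||^2 + lam*1's over s >= 0 by enumerating
    free/active subsets (KKT-checked candidates; global by exhaustion)."""
    A = np.asarray(A, dtype=float)
    m = A.shape[1]
    best = 0.5 * float(x @ x)  # s = 0 candidate
    for r in range(1, m + 1):
        for free in itertools.combinations(range(m), r):
            B = A[:, free]
            s_f, *_ = np.linalg.lstsq(B.T @ B, B.T @ x - lam, rcond=None)
            if np.any(s_f < -1e-12):
                continue
            s = np.zeros(m)
            s[list(free)] = np.maximum(s_f, 0.0)
            f = 0.5 * np.sum((A @ s - x) ** 2) + lam * s.sum()
            best = min(best, f)
    return best


def selection_oracle(angles, reference_role):
    """Brute-force max/min-angle rule with lowest-index tie-breaking."""
    hi = lo = 0
    for i, a in enumerate(angles):
        if a > angles[hi]:
            hi = i
        if a < angles[lo]:
            lo = i
    if reference_role == "control":
        return hi, lo  # disease index, control index
    return lo, hi


def pure_two_row_mixture(seed, n_components=3, n_features=4500, min_gap=15.0):
    """Exact X = A S with interleaved disjoint supports (all features pure).

    Returns (A, X, true_angles_sorted, block_of_feature).
    """
    r = np.random.default_rng(seed)
    angs = np.sort(r.uniform(5, 85, n_components))
    while np.min(np.diff(angs)) < min_gap:
        angs = np.sort(r.uniform(5, 85, n_components))
    A = np.vstack([np.cos(np.radians(angs)), np.sin(np.radians(angs))])
    perm = r.permutation(n_features)
    b = n_features // n_components
    S = np.zeros((n_components, n_features))
    block_of = np.full(n_features, -1, dtype=int)
    for m in range(n_components):
        idx = perm[m * b:(m + 1) * b]
        S[m, idx] = r.uniform(0.5, 1.5, len(idx))
        block_of[idx] = m
    return A, A @ S, angs, block_of


def random_unit_mixing(rng, m):
    """Random 2 x m mixing matrix with unit non-negative columns."""
    ang = rng.uniform(0.0, 90.0, m)
    t = np.radians(ang)
    return np.vstack([np.cos(t), np.sin(t)]), ang
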