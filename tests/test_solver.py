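"""Batch l1 recovery: lambda_max, shrinkage iterations, sparseness measure."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scamix import SolverConfig, ist_solve, lambda_max, sparseness_measure
from scamix.errors import SolverDivergenceError

from helpers import cd_l1_oracle, l1_objective, random_unit_mixing


EYE = np.eye(2)


def test_lambda_max_identity_single_column():
    x = np.array([[3.0], [-1.0]])
    assert lambda_max(EYE, x) == 3.0
    # marginally above: zero solution; well below: nonzero
    cfg = SolverConfig(lambda_multiplier=1e-4)
    assert np.all(ist_solve(EYE, x, cfg, lam=3.0 * (1 + 1e-9)).S == 0.0)
    assert np.any(ist_solve(EYE, x, cfg, lam=3.0 * (1 - 1e-3)).S != 0.0)


def test_lambda_max_zero_data_and_positive_scaling():
    assert lambda_max(EYE, np.zeros((2, 3))) == 0.0
    rng = np.random.default_rng(1)
    a, _ = random_unit_mixing(rng, 3)
    x = rng.normal(size=(2, 5))
    assert lambda_max(a, 2.5 * x) == pytest.approx(2.5 * lambda_max(a, x))


def test_soft_threshold_closed_form_for_orthonormal_mixing():
    x = np.array([[2.0], [0.5]])
    est = ist_solve(EYE, x, SolverConfig(lambda_multiplier=1e-2), lam=1.0)
    np.testing.assert_allclose(est.S[:, 0], [1.0, 0.0], atol=1e-8)


def test_nonnegative_variant_clips_negative_coordinates():
    x = np.array([[-1.0], [2.0]])
    cfg = SolverConfig(lambda_multiplier=1e-2, nonnegative=True)
    est = ist_solve(EYE, x, cfg, lam=0.5)
    np.testing.assert_allclose(est.S[:, 0], [0.0, 1.5], atol=1e-8)
    assert est.S.min() >= 0.0


def test_penalty_at_lambda_max_zeroes_everything():
    rng = np.random.default_rng(2)
    for _ in range(20):
        a, _ = random_unit_mixing(rng, int(rng.integers(2, 6)))
        x = rng.normal(size=(2, 8))
        est = ist_solve(a, x, SolverConfig(lambda_multiplier=1.0))
        assert np.all(est.S == 0.0)
        assert est.objective == pytest.approx(0.5 * np.sum(x * x))


def test_matches_coordinate_descent_oracle_on_small_instances():
    rng = np.random.default_rng(3)
    for _ in range(20):
        m = int(rng.integers(2, 6))
        a, _ = random_unit_mixing(rng, m)
        x = rng.normal(size=(2, int(rng.integers(1, 9))))
        mult = float(rng.choice([1e-2, 1e-4]))
        lam = mult * lambda_max(a, x)
        est = ist_solve(a, x, SolverConfig(lambda_multiplier=mult,
                                           max_iter=20000, tol=1e-13))
        f_or = l1_objective(a, x, cd_l1_oracle(a, x, lam, sweeps=500), lam)
        assert est.objective <= f_or + 1e-8


def test_nonzero_count_non_increasing_in_lambda():
    rng = np.random.default_rng(4)
    precise = dict(max_iter=20000, tol=1e-12)
    for _ in range(30):
        m = int(rng.integers(2, 6))
        a, _ = random_unit_mixing(rng, m)
        x = rng.normal(size=(2, int(rng.integers(4, 13))))
        nnz = [int(np.count_nonzero(
            ist_solve(a, x, SolverConfig(lambda_multiplier=mult, **precise)).S))
            for mult in (1e-6, 1e-4, 1e-2, 1.0)]
        assert nnz == sorted(nnz, reverse=True)


def test_support_recovery_in_well_posed_limit():
    # true mixing known, sources sparse (<= 2 nonzeros per column)
    rng = np.random.default_rng(5)
    hits = 0
    total = 0
    for _ in range(10):
        m = 4
        a, ang = random_unit_mixing(rng, m)
        while np.min(np.diff(np.sort(ang))) < 5.0:  # well-separated columns
            a, ang = random_unit_mixing(rng, m)
        a = a[:, np.argsort(ang)]
        k = 50
        s_true = np.zeros((m, k))
        for col in range(k):
            j = int(rng.integers(0, m - 1))
            s_true[j, col] = rng.uniform(0.5, 1.5)
            if rng.random() < 0.5:  # second nonzero on the adjacent column
                s_true[j + 1, col] = rng.uniform(0.5, 1.5)
        x = a @ s_true
        est = ist_solve(a, x, SolverConfig(lambda_multiplier=1e-6,
                                           nonnegative=True,
                                           max_iter=20000, tol=1e-13))
        match = np.all((np.abs(est.S) > 1e-8) == (s_true != 0), axis=0)
        hits += int(match.sum())
        total += k
    assert hits / total >= 0.99


def test_divergent_input_raises():
    with pytest.raises((SolverDivergenceError, ValueError)):
        ist_solve(EYE, np.array([[np.inf], [1.0]]),
                  SolverConfig(lambda_multiplier=1e-4))


def test_hard_zero_snapping_produces_exact_zeros():
    rng = np.random.default_rng(6)
    a, _ = random_unit_mixing(rng, 3)
    x = rng.normal(size=(2, 30))
    est = ist_solve(a, x, SolverConfig(lambda_multiplier=1e-2))
    small = (np.abs(est.S) > 0) & (np.abs(est.S) < 1e-10 * lambda_max(a, x))
    assert not small.any()


@pytest.mark.parametrize("s,tau,expected", [
    ((0.0, 0.0, 5.0), 0.1, 2 / 3),
    ((1.0, 1.0, 1.0), 0.5, 0.0),
    ((0.0, 0.0, 0.0), 0.3, 1.0),
])
def test_sparseness_measure_examples(s, tau, expected):
    assert sparseness_measure(np.array(s), tau) == pytest.approx(expected)


@given(st.lists(st.floats(-10, 10), min_size=1, max_size=8))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_sparseness_measure_tau_one_saturates(s):
    assert sparseness_measure(np.array(s), 1.0) == 1.0


def test_sparseness_measure_tau_domain():
    with pytest.raises(ValueError):
        sparseness_measure(np.array([1.0]), 1.5)


@pytest.mark.parametrize("kwargs", [
    {"lambda_multiplier": 0.0}, {"lambda_multiplier": 2.0},
    {"max_iter": 0}, {"tol": 0.0},
])
def test_solver_config_validation(kwargs):
    with pytest.raises(ValueError):
        SolverConfig(**{**{"lambda_multiplier": 1e-4}, **kwargs})
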