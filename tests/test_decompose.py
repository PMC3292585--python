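"""Reference pairing, per-sample decomposition and component selection."""

import numpy as np
import pytest

from scamix import (ExpressionDataset, MixingEstimate, ReferencePairLMM,
                    SolverConfig, build_reference, decompose_sample,
                    extract_feature_sets, select_components)
from scamix.solver import SourceEstimate
from scamix.errors import ScamixError

from helpers import pure_two_row_mixture

SOLVER = SolverConfig(lambda_multiplier=1e-6)


def test_reference_is_classwise_mean(tiny_dataset):
    ref = build_reference(tiny_dataset, 1)
    np.testing.assert_allclose(ref, tiny_dataset.values[:3].mean(axis=0))
    one = build_reference(tiny_dataset, -1, exclude_ids=["s3", "s4"])
    np.testing.assert_allclose(one, tiny_dataset.values[5])


def test_reference_requires_a_survivor(tiny_dataset):
    with pytest.raises(ScamixError, match="control"):
        build_reference(tiny_dataset, -1, exclude_ids=["s3", "s4", "s5"])


def _lmm_from_pure(seed, angles=(15.0, 75.0)):
    rng = np.random.default_rng(seed)
    t = np.radians(np.asarray(angles))
    a = np.vstack([np.cos(t), np.sin(t)])
    k = 3000
    perm = rng.permutation(k)
    s = np.zeros((len(angles), k))
    b = k // len(angles)
    for m in range(len(angles)):
        s[m, perm[m * b:(m + 1) * b]] = rng.uniform(0.5, 1.5, b)
    return ReferencePairLMM(rows=a @ s, reference_role="control",
                            test_sample_id="t0", test_label=1), s


def test_known_two_component_angles_recovered_within_two_degrees():
    lmm, _ = _lmm_from_pure(0)
    mix, src = decompose_sample(lmm, 2, 1.0, SOLVER)
    np.testing.assert_allclose(np.sort(mix.angles), [15.0, 75.0], atol=2.0)
    assert src.S.shape == (2, 3000)


def test_full_penalty_zeroes_sources_but_estimates_mixing():
    lmm, _ = _lmm_from_pure(1)
    mix, src = decompose_sample(lmm, 2, 1.0,
                                SolverConfig(lambda_multiplier=1.0))
    assert np.all(src.S == 0.0)
    assert mix.A.shape == (2, 2)


def test_feature_permutation_equivariance():
    lmm, _ = _lmm_from_pure(2)
    mix, src = decompose_sample(lmm, 2, 1.0, SOLVER)
    rng = np.random.default_rng(0)
    perm = rng.permutation(lmm.rows.shape[1])
    lmm_p = ReferencePairLMM(rows=lmm.rows[:, perm], reference_role="control",
                             test_sample_id="t0", test_label=1)
    mix_p, src_p = decompose_sample(lmm_p, 2, 1.0, SOLVER)
    np.testing.assert_allclose(np.sort(mix_p.angles), np.sort(mix.angles),
                               atol=1e-9)
    order = np.argsort(mix.angles)
    order_p = np.argsort(mix_p.angles)
    np.testing.assert_allclose(src_p.S[order_p], src.S[order][:, perm],
                               atol=1e-8)


def test_decomposition_ignores_sample_label():
    lmm, _ = _lmm_from_pure(3)
    flipped = ReferencePairLMM(rows=lmm.rows, reference_role="control",
                               test_sample_id="t0", test_label=-1)
    mix_a, src_a = decompose_sample(lmm, 2, 1.0, SOLVER)
    mix_b, src_b = decompose_sample(flipped, 2, 1.0, SOLVER)
    np.testing.assert_array_equal(mix_a.A, mix_b.A)
    np.testing.assert_array_equal(src_a.S, src_b.S)


def test_errors_annotated_with_sample_context():
    rows = np.vstack([np.ones(50), np.ones(50) * 2.0])  # flat: no SCPs pass
    lmm = ReferencePairLMM(rows=rows, reference_role="control",
                           test_sample_id="bad_sample", test_label=1)
    with pytest.raises(ScamixError, match="bad_sample"):
        decompose_sample(lmm, 2, 1.0, SOLVER)


def _mixing_from_angles(angles):
    t = np.radians(np.asarray(angles, dtype=float))
    return MixingEstimate(A=np.vstack([np.cos(t), np.sin(t)]),
                          angles=np.asarray(angles, dtype=float),
                          n_scps_used=10)


def _sources(m, k=4):
    return SourceEstimate(S=np.arange(m * k, dtype=float).reshape(m, k),
                          objective=0.0, iterations_run=1, lam=0.0)


def test_control_reference_selects_max_angle_as_disease():
    sel = select_components(_mixing_from_angles([10.0, 45.0, 80.0]),
                            _sources(3), "control")
    assert sel.disease_angle == 80.0 and sel.control_angle == 10.0
    np.testing.assert_array_equal(sel.neutral_components, _sources(3).S[[1]])


def test_disease_reference_logic_is_opposite():
    sel = select_components(_mixing_from_angles([10.0, 45.0, 80.0]),
                            _sources(3), "disease")
    assert sel.disease_angle == 10.0 and sel.control_angle == 80.0


def test_two_components_leave_no_neutrals():
    sel = select_components(_mixing_from_angles([30.0, 60.0]),
                            _sources(2), "control")
    assert sel.disease_angle == 60.0 and sel.control_angle == 30.0
    assert sel.neutral_components.shape[0] == 0


def test_angle_ordering_invariant_holds_both_ways():
    for role in ("control", "disease"):
        sel = select_components(_mixing_from_angles([25.0, 70.0, 40.0]),
                                _sources(3), role)
        if role == "control":
            assert sel.disease_angle > sel.control_angle
        else:
            assert sel.disease_angle < sel.control_angle


def test_extract_produces_four_sets_with_shared_labels(small_sim):
    _, dataset, _ = small_sim
    fs = extract_feature_sets(dataset, 2, 5.0, SOLVER, reference_policy="all")
    assert set(fs.sets) == {"controlref_disease", "controlref_control",
                            "diseaseref_control", "diseaseref_disease"}
    for mat in fs.sets.values():
        assert mat.shape == dataset.values.shape
    np.testing.assert_array_equal(fs.labels, dataset.labels)


def test_train_only_references_do_not_see_test_samples(small_sim):
    _, dataset, _ = small_sim
    train = dataset.sample_ids[:5] + dataset.sample_ids[10:15]
    test_idx = 7  # held-out disease sample
    perturbed = ExpressionDataset(
        values=dataset.values.copy(), feature_ids=dataset.feature_ids,
        sample_ids=dataset.sample_ids, labels=dataset.labels)
    perturbed.values[test_idx] *= 3.0
    a = extract_feature_sets(dataset, 2, 5.0, SOLVER,
                             reference_policy="train_only", train_ids=train)
    b = extract_feature_sets(perturbed, 2, 5.0, SOLVER,
                             reference_policy="train_only", train_ids=train)
    train_rows = [i for i, sid in enumerate(dataset.sample_ids) if sid in set(train)]
    for name in a.sets:
        np.testing.assert_array_equal(a.sets[name][train_rows],
                                      b.sets[name][train_rows])


def test_disease_set_concentrates_on_true_disease_support(small_sim):
    _, dataset, truth = small_sim
    fs = extract_feature_sets(dataset, 3, 3.0, SOLVER, reference_policy="all")
    d_sup = set(truth.supports[truth.disease_index].tolist())
    c_sup = set(truth.supports[truth.control_index].tolist())
    recall_d, leak_c, recall_disease_rows = [], [], []
    for row, label in zip(fs.sets["controlref_disease"], fs.labels):
        sup = set(np.flatnonzero(row).tolist())
        recall_d.append(len(sup & d_sup) / len(d_sup))
        leak_c.append(len(sup & c_sup) / len(c_sup))
        if label == 1:
            recall_disease_rows.append(recall_d[-1])
    assert np.mean(recall_d) >= 0.7           # true disease features captured
    assert np.mean(recall_disease_rows) >= 0.9  # near-complete in disease samples
    assert np.mean(recall_d) > np.mean(leak_c) + 0.1  # control block less present
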