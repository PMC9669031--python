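"""Factorization models, consistency measures, dimensionality selection."""
from itertools import combinations, permutations

import numpy as np
import pytest

import emgmod as em
from emgmod.containers import DecompositionResult


# ---------------------------------------------------------------------------
# VAF and diagonality closed forms


def test_vaf_closed_forms():
    x = np.array([[1.0, 2.0, 3.0]])
    assert em.vaf(x, x) == pytest.approx(100.0)
    assert em.vaf(x, np.zeros_like(x)) == pytest.approx(0.0)
    assert em.vaf(x, np.array([[1.0, 2.0, 2.0]])) == pytest.approx(
        100.0 * (1 - 1 / 14)
    )
    with pytest.raises(ValueError):
        em.vaf(np.zeros((1, 3)), np.zeros((1, 3)))
    with pytest.raises(ValueError):
        em.vaf(x, np.zeros((2, 2)))


@pytest.mark.parametrize("n", [2, 3, 5])
def test_diagonality_identities(n):
    assert em.diagonality(np.eye(n)) == pytest.approx(1.0)
    assert em.diagonality(np.ones((n, n))) == pytest.approx(1.0 / n)


def test_diagonality_direct_value_and_guards():
    assert em.diagonality(np.array([[3.0, 1.0], [1.0, 3.0]])) == pytest.approx(0.75)
    with pytest.raises(ValueError):
        em.diagonality(np.zeros((2, 2)))
    with pytest.raises(ValueError):
        em.diagonality(np.array([[1.0, -1.0], [0.0, 1.0]]))


# ---------------------------------------------------------------------------
# decompositions on exact low-rank data


def test_noiseless_spatial_nnmf_exact(noiseless3):
    res = em.decompose(noiseless3.noisy, "spatial", "nnmf", 3, restarts=5, seed=0)
    assert res.vaf > 99.0


def test_rank_one_data_all_models():
    rng = np.random.default_rng(3)
    w = rng.uniform(0.5, 2.0, 8)
    c = np.abs(np.sin(np.linspace(0, np.pi, 200)))
    X = np.outer(w, np.tile(c, 7))
    for model in ("spatial", "temporal", "space_by_time"):
        res = em.decompose(X, model, "nnmf", 1, restarts=3, seed=1)
        assert res.vaf > 99.0, model


def test_generative_equivalence_recovery(noiseless3):
    """Noiseless identity-coefficient data: every model recovers >99% at
    the true N."""
    for model in ("spatial", "temporal", "space_by_time"):
        res = em.decompose(noiseless3.noisy, model, "nnmf", 3, restarts=5, seed=2)
        assert res.vaf > 99.0, model


def test_negative_input_rejected_for_nnmf():
    X = -np.ones((4, 400))
    with pytest.raises(ValueError):
        em.decompose(X, "spatial", "nnmf", 2)


def test_pca_vaf_nondecreasing(dataset3):
    vals = [
        em.decompose(dataset3.noisy, "spatial", "pca", n).vaf for n in range(1, 9)
    ]
    assert all(b >= a - 1e-9 for a, b in zip(vals, vals[1:]))


def test_nnmf_vaf_nondecreasing_within_tolerance(dataset3):
    rng = np.random.default_rng(7)
    vals = [
        em.decompose(dataset3.noisy, "temporal", "nnmf", n, restarts=5, seed=rng).vaf
        for n in range(1, 7)
    ]
    assert all(b >= a - 0.5 for a, b in zip(vals, vals[1:]))


def test_pca_rejected_for_space_by_time(dataset3):
    with pytest.raises(ValueError):
        em.decompose(dataset3.noisy, "space_by_time", "pca", 2)


# ---------------------------------------------------------------------------
# consistency measures


def _spatial_result(patterns, synergies):
    S, N, T = patterns.shape
    return DecompositionResult(
        model="spatial",
        algorithm="nnmf",
        n_modules=N,
        synergies=synergies,
        patterns=patterns,
        vaf=100.0,
        residuals=np.zeros((synergies.shape[1], S * T)),
    )


def test_identical_stride_patterns_give_unit_consistency():
    pat = np.tile(np.abs(np.random.default_rng(0).normal(size=(1, 2, 200))), (5, 1, 1))
    res = _spatial_result(pat, np.ones((2, 8)))
    assert em.stride_consistency(res) == pytest.approx(1.0)


def test_orthogonal_stride_patterns_give_zero_consistency():
    pat = np.zeros((2, 1, 200))
    pat[0, 0, 0] = 1.0
    pat[1, 0, 1] = 1.0
    res = _spatial_result(pat, np.ones((1, 8)))
    assert em.stride_consistency(res) == pytest.approx(0.0)


def test_single_stride_consistency_rejected():
    res = _spatial_result(np.ones((1, 2, 200)), np.ones((2, 8)))
    with pytest.raises(ValueError):
        em.stride_consistency(res)


def test_sxt_consistency_equals_enumeration_oracle(dataset3):
    """Mean diagonality from the pipeline equals a brute-force loop over
    strides on the same sorted coefficients."""
    res = em.sort_modules(
        em.decompose(dataset3.noisy, "space_by_time", "nnmf", 3, restarts=3, seed=5)
    )
    got = em.stride_consistency(res)
    oracle = np.mean(
        [a.trace() / a.sum() for a in res.activation_coeffs]
    )
    assert got == pytest.approx(float(oracle))


def test_spatial_consistency_equals_pairwise_enumeration(dataset3):
    res = em.decompose(dataset3.noisy, "spatial", "nnmf", 2, restarts=3, seed=6)
    got = em.stride_consistency(res)
    vals = []
    for i in range(res.patterns.shape[1]):
        per = []
        for a, b in combinations(range(res.patterns.shape[0]), 2):
            va, vb = res.patterns[a, i], res.patterns[b, i]
            per.append(va @ vb / (np.linalg.norm(va) * np.linalg.norm(vb)))
        vals.append(np.mean(per))
    assert got == pytest.approx(float(np.mean(vals)))


# ---------------------------------------------------------------------------
# module sorting


def test_sort_modules_idempotent(dataset3):
    res = em.decompose(dataset3.noisy, "space_by_time", "nnmf", 3, restarts=3, seed=8)
    once = em.sort_modules(res)
    twice = em.sort_modules(once)
    np.testing.assert_allclose(once.patterns, twice.patterns)
    np.testing.assert_allclose(once.synergies, twice.synergies)
    np.testing.assert_allclose(once.activation_coeffs, twice.activation_coeffs)


def test_sort_recovers_swapped_synergies(dataset3):
    res = em.sort_modules(
        em.decompose(dataset3.noisy, "space_by_time", "nnmf", 2, restarts=3, seed=9)
    )
    d0 = em.stride_consistency(res)
    swapped = DecompositionResult(
        model=res.model,
        algorithm=res.algorithm,
        n_modules=res.n_modules,
        synergies=res.synergies[::-1],
        patterns=res.patterns,
        vaf=res.vaf,
        residuals=res.residuals,
        activation_coeffs=res.activation_coeffs[:, :, ::-1],
    )
    assert em.stride_consistency(em.sort_modules(swapped)) == pytest.approx(d0)


def test_assignment_matches_exhaustive_permutations(rng):
    """The Hungarian synergy permutation equals the best of all 4!
    permutations for a random coefficient matrix."""
    from scipy.optimize import linear_sum_assignment

    A = rng.uniform(0.1, 1.0, (4, 4))
    _, perm = linear_sum_assignment(-A)
    best = max(permutations(range(4)), key=lambda p: sum(A[i, p[i]] for i in range(4)))
    assert sum(A[i, perm[i]] for i in range(4)) == pytest.approx(
        sum(A[i, best[i]] for i in range(4))
    )


# ---------------------------------------------------------------------------
# dimensionality selection


def test_linear_decline_ties_break_to_smallest_n():
    cons = {n: 1.0 - 0.1 * n for n in range(1, 9)}
    curve = em.select_dimensionality(cons)
    assert np.allclose(curve.slopes, 0.1)
    assert curve.selected_n == 1 and not curve.fallback_used


def test_fallback_rule_applies_at_low_vaf():
    cons = {1: 0.9, 2: 0.795, 3: 0.7, 4: 0.65, 5: 0.6, 6: 0.55, 7: 0.5, 8: 0.45}
    vafs = {n: 15.0 + 10 * (n - 1) for n in range(1, 9)}
    curve = em.select_dimensionality(cons, vafs)
    assert curve.selected_n == 2 and curve.fallback_used
    # same curve with healthy VAF keeps the maximum at N=1
    vafs_ok = {n: 50.0 + n for n in range(1, 9)}
    curve2 = em.select_dimensionality(cons, vafs_ok)
    assert curve2.selected_n == 1 and not curve2.fallback_used


def test_missing_n_rejected():
    with pytest.raises(ValueError):
        em.select_dimensionality({1: 0.9, 3: 0.7})


def test_consistency_curve_recovers_true_n_noiseless(noiseless3):
    """On noiseless 3-module data the diagonality stays near 1 up to the
    true N and drops sharply when a fourth module is forced."""
    curve = em.consistency_curve(
        noiseless3.noisy, "space_by_time", "nnmf", range(1, 9), restarts=5, seed=17
    )
    assert curve.measure == "diagonality"
    assert np.all(curve.values >= 0) and np.all(curve.values <= 1)
    assert curve.selected_n == 3
    assert curve.values[2] > 0.95


# ---------------------------------------------------------------------------
# across subjects and residuals


def _mini_result(patterns, synergies, model="temporal"):
    return DecompositionResult(
        model=model,
        algorithm="nnmf",
        n_modules=patterns.shape[0],
        synergies=synergies,
        patterns=patterns,
        vaf=100.0,
        residuals=np.zeros((synergies.shape[-1], patterns.shape[1] * 0 + 400)),
    )


def test_identical_subjects_full_similarity():
    pat = np.abs(np.random.default_rng(1).normal(size=(2, 200)))
    syn = np.abs(np.random.default_rng(2).normal(size=(2, 8)))
    out = em.inter_subject_consistency([_mini_result(pat, syn)] * 3)
    assert np.allclose(out["pattern_similarity"], 1.0)
    assert np.allclose(out["synergy_similarity"], 1.0)


def test_orthogonal_synergies_zero_similarity():
    pat = np.abs(np.random.default_rng(1).normal(size=(2, 200)))
    syn_a = np.zeros((2, 8))
    syn_a[0, 0] = syn_a[1, 1] = 1.0
    syn_b = np.zeros((2, 8))
    syn_b[0, 2] = syn_b[1, 3] = 1.0
    out = em.inter_subject_consistency(
        [_mini_result(pat, syn_a), _mini_result(pat, syn_b)]
    )
    assert np.allclose(out["synergy_similarity"], 0.0)
    assert np.allclose(out["pattern_similarity"], 1.0)


def test_mismatched_n_rejected():
    pat2 = np.abs(np.random.default_rng(1).normal(size=(2, 200)))
    pat3 = np.abs(np.random.default_rng(1).normal(size=(3, 200)))
    with pytest.raises(ValueError):
        em.inter_subject_consistency(
            [_mini_result(pat2, np.ones((2, 8))), _mini_result(pat3, np.ones((3, 8)))]
        )


def test_shared_modules_more_consistent_than_independent():
    """Subjects sharing ground-truth modules show higher cross-subject
    similarity than subjects with independent modules."""
    shared_mods = em.generate_modules(2, 8, seed=31)
    shared, indep = [], []
    for s in range(4):
        ds = em.simulate_emg(shared_mods, eta=1.0, seed=100 + s)
        shared.append(
            em.decompose(ds.noisy, "space_by_time", "nnmf", 2, restarts=5, seed=s)
        )
        mods = em.generate_modules(2, 8, seed=200 + s)
        di = em.simulate_emg(mods, eta=1.0, seed=300 + s)
        indep.append(
            em.decompose(di.noisy, "space_by_time", "nnmf", 2, restarts=5, seed=s)
        )
    sim_shared = em.inter_subject_consistency(shared)["synergy_similarity"].mean()
    sim_indep = em.inter_subject_consistency(indep)["synergy_similarity"].mean()
    assert sim_shared > sim_indep


def test_unstructured_residuals_ci_covers_zero(rng):
    res = DecompositionResult(
        model="space_by_time",
        algorithm="nnmf",
        n_modules=2,
        synergies=np.ones((2, 8)),
        patterns=np.ones((2, 200)),
        vaf=90.0,
        residuals=rng.normal(size=(8, 100 * 200)),
    )
    out = em.residual_structure(res)
    assert not out["structured"]
    assert out["ci"][0] < 0 < out["ci"][1]


def test_planted_residual_waveform_detected(rng):
    common = np.sin(np.linspace(0, 2 * np.pi, 200))
    resid = np.tile(common, (8, 20)) + 0.3 * rng.normal(size=(8, 20 * 200))
    res = DecompositionResult(
        model="space_by_time",
        algorithm="nnmf",
        n_modules=2,
        synergies=np.ones((2, 8)),
        patterns=np.ones((2, 200)),
        vaf=90.0,
        residuals=resid,
    )
    out = em.residual_structure(res)
    assert out["structured"] and out["similarity"] > 0.5


def test_zero_residuals_flagged_degenerate():
    res = DecompositionResult(
        model="space_by_time",
        algorithm="nnmf",
        n_modules=2,
        synergies=np.ones((2, 8)),
        patterns=np.ones((2, 200)),
        vaf=100.0,
        residuals=np.zeros((8, 1400)),
    )
    out = em.residual_structure(res)
    assert out["degenerate"]
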