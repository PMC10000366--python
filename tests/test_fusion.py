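"""Concatenation, kernel combination, MAX, Choquet/lambda-measure, adaptive."""

import itertools

import numpy as np
import pytest

import emofuse as ef


def test_concat_width_is_k_plus_l(rng):
    i1 = rng.standard_normal((20, 2))
    i2 = rng.standard_normal((20, 3))
    fused, _ = ef.concat_fuse(i1, i2)
    assert fused.shape == (20, 5)


def test_concat_columns_standardized_on_fit_split(rng):
    i1 = rng.standard_normal((200, 2)) * 5 + 3
    i2 = rng.standard_normal((200, 3)) - 7
    fused, _ = ef.concat_fuse(i1, i2)
    np.testing.assert_allclose(fused.mean(axis=0), 0.0, atol=1e-10)
    np.testing.assert_allclose(fused.std(axis=0, ddof=1), 1.0, atol=1e-10)


def test_concat_reuses_training_statistics(rng):
    tr1, tr2 = rng.standard_normal((50, 2)), rng.standard_normal((50, 2))
    te1, te2 = rng.standard_normal((10, 2)), rng.standard_normal((10, 2))
    _, stats = ef.concat_fuse(tr1, tr2)
    fused, _ = ef.concat_fuse(te1, te2, stats=stats)
    expected = np.hstack([(te1 - tr1.mean(0)) / tr1.std(0, ddof=1),
                          (te2 - tr2.mean(0)) / tr2.std(0, ddof=1)])
    np.testing.assert_allclose(fused, expected)


def test_concat_with_empty_block_is_normalized_identity(rng):
    i1 = rng.standard_normal((30, 4))
    fused, _ = ef.concat_fuse(i1, np.zeros((30, 0)))
    np.testing.assert_allclose(fused,
                               (i1 - i1.mean(0)) / i1.std(0, ddof=1))


def test_concat_drops_zero_variance_columns(rng):
    i1 = np.hstack([rng.standard_normal((20, 1)), np.ones((20, 1))])
    fused, _ = ef.concat_fuse(i1, rng.standard_normal((20, 1)))
    assert fused.shape == (20, 2)


def _psd(rng, n=6):
    a = rng.standard_normal((n, n))
    return a @ a.T


def test_single_kernel_is_identity(rng):
    k = _psd(rng)
    np.testing.assert_allclose(ef.combine_kernels([k], [1.0]), k)


def test_identical_kernels_convexity(rng):
    k = _psd(rng)
    np.testing.assert_allclose(ef.combine_kernels([k, k.copy()], [0.5, 0.5]),
                               k)


def test_combination_preserves_psd(rng):
    k = ef.combine_kernels([_psd(rng), _psd(rng)], [0.3, 0.7])
    np.testing.assert_allclose(k, k.T)
    assert np.linalg.eigvalsh(k).min() >= -1e-10


def test_offsimplex_weights_rejected(rng):
    with pytest.raises(ValueError):
        ef.combine_kernels([_psd(rng), _psd(rng)], [0.8, 0.8])
    with pytest.raises(ValueError):
        ef.combine_kernels([_psd(rng), _psd(rng)], [-0.2, 1.2])


def test_single_classifier_max_fuse_is_argmax(rng):
    probs = rng.dirichlet(np.ones(3), size=10)[None]  # U = 1
    np.testing.assert_array_equal(ef.max_fuse(probs),
                                  probs[0].argmax(axis=1))


def test_max_fuse_hand_example():
    table = np.array([[[0.6, 0.3, 0.1]], [[0.2, 0.7, 0.1]]])
    assert ef.max_fuse(table)[0] == 1


def test_uniform_tables_tie_to_first_class():
    table = np.full((2, 4, 3), 1 / 3)
    np.testing.assert_array_equal(ef.max_fuse(table), np.zeros(4, int))


def test_max_fuse_matches_double_loop_oracle(rng):
    for u, v in itertools.product([1, 2, 3, 4], [2, 3, 4]):
        table = rng.dirichlet(np.ones(v), size=(u, 5))
        got = ef.max_fuse(table)
        for t in range(5):
            best_val, best_class = -1.0, None
            for i in range(v):
                m = max(table[j, t, i] for j in range(u))
                if m > best_val:
                    best_val, best_class = m, i
            assert got[t] == best_class


def test_empty_table_rejected():
    with pytest.raises(ValueError):
        ef.max_fuse(np.zeros((2, 0, 3)))


def test_densities_summing_to_one_are_additive():
    m = ef.sugeno_lambda_measure([0.5, 0.5])
    assert m.lam == 0.0
    assert m(frozenset({0})) == pytest.approx(0.5)
    assert m(frozenset({0, 1})) == pytest.approx(1.0)


def test_lambda_root_solves_product_identity():
    g = np.array([0.2, 0.3])
    m = ef.sugeno_lambda_measure(g)
    lam = m.lam
    assert abs((1 + 0.2 * lam) * (1 + 0.3 * lam) - (1 + lam)) < 1e-12
    assert lam > 0  # densities sum below 1
    assert m(frozenset({0, 1})) == pytest.approx(1.0, abs=1e-10)


def test_measure_axioms_on_random_densities(rng):
    for _ in range(10):
        g = rng.uniform(0.05, 0.95, size=3)
        m = ef.sugeno_lambda_measure(g)
        assert m(frozenset()) == 0.0
        assert m(frozenset({0, 1, 2})) == pytest.approx(1.0)
        sets = [frozenset(s) for size in range(4)
                for s in itertools.combinations(range(3), size)]
        for a in sets:
            for b in sets:
                if a < b:
                    assert m(a) <= m(b) + 1e-12


def test_degenerate_densities_rejected():
    with pytest.raises(ValueError):
        ef.sugeno_lambda_measure([0.5])
    with pytest.raises(ValueError):
        ef.sugeno_lambda_measure([0.0, 0.5])
    with pytest.raises(ValueError):
        ef.sugeno_lambda_measure([1.0, 0.5])


def test_additive_choquet_is_weighted_mean(rng):
    m = ef.sugeno_lambda_measure([0.25, 0.75])  # lambda = 0
    h = rng.uniform(0, 1, 2)
    assert ef.choquet_fuse(h, m) == pytest.approx(0.25 * h[0] + 0.75 * h[1])


def test_constant_scores_integrate_to_constant():
    m = ef.sugeno_lambda_measure([0.2, 0.3, 0.4])
    assert ef.choquet_fuse(np.full(3, 0.7), m) == pytest.approx(0.7)


def _brute_choquet(h, measure):
    """Direct evaluation: sort ascending, weight increments by the measure
    of the sources whose score is at least the current one."""
    order = sorted(range(len(h)), key=lambda i: h[i])
    prev, total = 0.0, 0.0
    for rank in range(len(h)):
        a_i = frozenset(order[rank:])
        total += (h[order[rank]] - prev) * measure(a_i)
        prev = h[order[rank]]
    return total


def test_choquet_matches_bruteforce_on_three_sources(rng):
    m = ef.sugeno_lambda_measure([0.3, 0.4, 0.2])
    for _ in range(25):
        h = rng.uniform(0, 1, 3)
        assert ef.choquet_fuse(h, m) == pytest.approx(_brute_choquet(h, m))


def test_choquet_interpolates_between_min_and_max(rng):
    m = ef.sugeno_lambda_measure(rng.uniform(0.1, 0.9, 3))
    for _ in range(20):
        h = rng.uniform(0, 1, 3)
        assert h.min() - 1e-12 <= ef.choquet_fuse(h, m) <= h.max() + 1e-12


def test_choquet_label_picks_largest_integral(rng):
    m = ef.sugeno_lambda_measure([0.4, 0.4])
    table = rng.dirichlet(np.ones(3), size=(2, 6))
    labels = ef.choquet_label(table, m)
    for t in range(6):
        scores = [ef.choquet_fuse(table[:, t, v], m) for v in range(3)]
        assert labels[t] == int(np.argmax(scores))


def test_mismatched_scores_rejected():
    m = ef.sugeno_lambda_measure([0.3, 0.4])
    with pytest.raises(ValueError):
        ef.choquet_fuse([0.1, 0.2, 0.3], m)
    with pytest.raises(ValueError):
        ef.choquet_fuse([-0.1, 0.2], m)


def test_adaptive_continuous_at_threshold():
    for y_face in (0.0, 0.37, 1.0):
        below = ef.adaptive_fuse(0.4, y_face)
        assert below == pytest.approx((y_face + 0.4) / 2)
        just_above = ef.adaptive_fuse(0.4 + 1e-9, y_face)
        assert abs(just_above - below) < 1e-8


def test_adaptive_equal_weight_branch():
    assert ef.adaptive_fuse(0.2, 0.6) == pytest.approx(0.4)


def test_adaptive_monotone_in_eeg_score():
    grid = np.linspace(0, 1, 101)
    for y_face in (0.0, 0.5, 1.0):
        vals = [ef.adaptive_fuse(y, y_face) for y in grid]
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))


def test_adaptive_rejects_out_of_range():
    with pytest.raises(ValueError):
        ef.adaptive_fuse(1.2, 0.5)
    with pytest.raises(ValueError):
        ef.adaptive_fuse(0.5, -0.1)


def test_fusion_rules_are_pure(rng):
    table = rng.dirichlet(np.ones(3), size=(2, 5))
    np.testing.assert_array_equal(ef.max_fuse(table), ef.max_fuse(table))
    m = ef.sugeno_lambda_measure([0.3, 0.5])
    h = rng.uniform(0, 1, 2)
    assert ef.choquet_fuse(h, m) == ef.choquet_fuse(h, m)
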