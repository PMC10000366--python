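"""Closed-form CCA oracle, the differentiable correlation objective, and
the deep/linear transform training loop."""

import numpy as np
import pytest

import emofuse as ef
from emofuse.dcca import DCCATransformSpec, cca_loss_with_grad
from emofuse.nn import TrainConfig


def test_self_correlation_is_one(rng):
    x = rng.standard_normal((200, 4))
    _, corrs = ef.cca_closed_form(x, x.copy(), k=4, r=1e-10)
    np.testing.assert_allclose(corrs, 1.0, atol=1e-6)


def test_independent_views_have_near_zero_correlation(rng):
    x = rng.standard_normal((20000, 3))
    y = rng.standard_normal((20000, 3))
    _, corrs = ef.cca_closed_form(x, y, k=3)
    assert corrs.max() < 0.05


def test_population_correlations_recovered():
    x, y = ef.generate_correlated_pairs(5000, 8, 6, 2, [0.9, 0.5], seed=10)
    _, corrs = ef.cca_closed_form(x, y, k=2)
    np.testing.assert_allclose(corrs, [0.9, 0.5], atol=0.05)


def test_agreement_with_sklearn_cca():
    # independent iterative implementation as cross-check
    from sklearn.cross_decomposition import CCA

    x, y = ef.generate_correlated_pairs(3000, 5, 4, 2, [0.8, 0.4], seed=11)
    _, corrs = ef.cca_closed_form(x, y, k=2, r=1e-9)
    sk = CCA(n_components=2, max_iter=2000).fit(x, y)
    xt, yt = sk.transform(x, y)
    sk_corrs = [abs(np.corrcoef(xt[:, i], yt[:, i])[0, 1]) for i in range(2)]
    np.testing.assert_allclose(corrs, sk_corrs, atol=1e-3)


def test_invariance_to_invertible_affine_maps(rng):
    x, y = ef.generate_correlated_pairs(2000, 4, 4, 2, [0.7, 0.3], seed=12)
    _, base = ef.cca_closed_form(x, y, k=2, r=1e-12)
    a = rng.standard_normal((4, 4)) + 4 * np.eye(4)
    b = rng.standard_normal((4, 4)) + 4 * np.eye(4)
    _, moved = ef.cca_closed_form(x @ a + 1.5, y @ b - 2.0, k=2, r=1e-12)
    np.testing.assert_allclose(base, moved, atol=1e-6)


def test_rank_deficiency_without_regularizer_raises(rng):
    x = rng.standard_normal((50, 3))
    x = np.hstack([x, x[:, :1]])  # duplicated column: singular covariance
    with pytest.raises(np.linalg.LinAlgError, match="r > 0"):
        ef.cca_closed_form(x, rng.standard_normal((50, 3)), k=2, r=0.0)


def test_loss_of_identical_batches_is_minus_k(rng):
    o = rng.standard_normal((100, 5))
    assert ef.cca_loss(o, o.copy(), k=5, r=1e-10) == pytest.approx(-5.0,
                                                                   abs=1e-6)


def test_loss_invariant_under_invertible_linear_map(rng):
    o1 = rng.standard_normal((300, 4))
    o2 = 0.5 * o1 + rng.standard_normal((300, 4))
    base = ef.cca_loss(o1, o2, r=1e-12)
    m = rng.standard_normal((4, 4)) + 3 * np.eye(4)
    np.testing.assert_allclose(ef.cca_loss(o1 @ m, o2, r=1e-12), base,
                               atol=1e-8)


def test_loss_agrees_with_closed_form_sum(rng):
    o1 = rng.standard_normal((80, 3))
    o2 = rng.standard_normal((80, 4))
    _, corrs = ef.cca_closed_form(o1, o2, k=3, r=1e-5)
    assert -ef.cca_loss(o1, o2, k=3, r=1e-5) == pytest.approx(corrs.sum(),
                                                              abs=1e-8)


def test_gradient_matches_finite_differences(rng):
    o1 = rng.standard_normal((12, 3))
    o2 = rng.standard_normal((12, 4))
    loss, d1, d2 = cca_loss_with_grad(o1, o2, k=3, r=1e-4)
    eps = 1e-6
    for target, grad in ((o1, d1), (o2, d2)):
        num = np.zeros_like(target)
        for i in range(target.shape[0]):
            for j in range(target.shape[1]):
                old = target[i, j]
                target[i, j] = old + eps
                fp = ef.cca_loss(o1, o2, k=3, r=1e-4)
                target[i, j] = old - eps
                fm = ef.cca_loss(o1, o2, k=3, r=1e-4)
                target[i, j] = old
                num[i, j] = (fp - fm) / (2 * eps)
        rel = np.abs(num - grad).max() / np.abs(num).max()
        assert rel < 1e-4


def test_batch_of_one_rejected(rng):
    with pytest.raises(ValueError):
        ef.cca_loss(rng.standard_normal((1, 3)), rng.standard_normal((1, 3)))


def _linear_cfg():
    return TrainConfig(learning_rate=0.05, max_epochs=300,
                       early_stop_patience=50)


def test_linear_dcca_matches_closed_form_cca():
    # the module's master oracle
    x, y = ef.generate_correlated_pairs(2000, 6, 6, 2, [0.85, 0.45], seed=13)
    spec = DCCATransformSpec(architecture="linear", output_dim=6)
    model = ef.train_dcca(x, y, spec, _linear_cfg(), seed=0)
    o1, o2 = ef.transform(model, x, y)
    achieved = -ef.cca_loss(o1, o2, k=6)
    _, corrs = ef.cca_closed_form(x, y, k=6)
    assert achieved > corrs.sum() - 0.05


def test_uncorrelated_views_stay_uncorrelated():
    x, y = ef.generate_correlated_pairs(2000, 4, 4, 1, [0.0], seed=14)
    spec = DCCATransformSpec(architecture="linear", output_dim=1)
    model = ef.train_dcca(x, y, spec, _linear_cfg(), seed=1)
    o1, o2 = ef.transform(model, x, y)
    assert -ef.cca_loss(o1, o2, k=1) <= 0.1


def test_training_is_deterministic():
    x, y = ef.generate_correlated_pairs(400, 4, 4, 1, [0.8], seed=15)
    spec = DCCATransformSpec(architecture="linear", output_dim=2)
    cfg = TrainConfig(learning_rate=0.05, max_epochs=30)
    m1 = ef.train_dcca(x, y, spec, cfg, seed=2)
    m2 = ef.train_dcca(x, y, spec, cfg, seed=2)
    for (_, _, p1), (_, _, p2) in zip(m1.net1.parameters(),
                                      m2.net1.parameters()):
        np.testing.assert_array_equal(p1, p2)


def test_conv_transform_trains_and_transforms(rng):
    x, y = ef.generate_correlated_pairs(300, 32, 32, 2, [0.9, 0.6], seed=16)
    spec = DCCATransformSpec(architecture="conv", output_dim=8)
    cfg = TrainConfig(learning_rate=0.01, max_epochs=20,
                      early_stop_patience=20)
    model = ef.train_dcca(x, y, spec, cfg, seed=3)
    o1, o2 = ef.transform(model, x, y)
    assert o1.shape == o2.shape == (300, 8)
    o1b, _ = ef.transform(model, x, y)
    np.testing.assert_array_equal(o1, o1b)  # evaluation mode is pure


def test_transform_improves_on_raw_linear_correlation():
    x, y = ef.generate_correlated_pairs(1500, 6, 6, 1, [0.8], seed=17)
    spec = DCCATransformSpec(architecture="linear", output_dim=2)
    model = ef.train_dcca(x, y, spec, _linear_cfg(), seed=4)
    o1, o2 = ef.transform(model, x, y)
    per_dim = [abs(np.corrcoef(o1[:, i], o2[:, i])[0, 1]) for i in range(2)]
    best_raw = max(abs(np.corrcoef(x[:, i], y[:, j])[0, 1])
                   for i in range(6) for j in range(6))
    assert max(per_dim) >= best_raw - 1e-6


def test_dimension_mismatch_rejected():
    x, y = ef.generate_correlated_pairs(200, 4, 4, 1, [0.5], seed=18)
    model = ef.train_dcca(x, y,
                          DCCATransformSpec(architecture="linear",
                                            output_dim=2),
                          TrainConfig(learning_rate=0.01, max_epochs=5),
                          seed=5)
    with pytest.raises(ValueError):
        ef.transform(model, x[:, :3], y)


def test_fuse_rules():
    o1 = np.array([[2.0, 4.0]])
    o2 = np.array([[0.0, 0.0]])
    np.testing.assert_array_equal(ef.fuse(o1, o2, 1.0, 0.0), o1)
    np.testing.assert_array_equal(ef.fuse(o1, o1, 0.5, 0.5), o1)
    np.testing.assert_array_equal(ef.fuse(o1, o2, 0.5, 0.5),
                                  np.array([[1.0, 2.0]]))
    # linearity
    np.testing.assert_allclose(ef.fuse(3 * o1, 3 * o2, 0.3, 0.7),
                               3 * ef.fuse(o1, o2, 0.3, 0.7))
    with pytest.raises(ValueError):
        ef.fuse(o1, o2, 0.6, 0.6)
    with pytest.raises(ValueError):
        ef.fuse(o1, o2, 1.5, -0.5)


def test_classifier_probabilities_and_separable_accuracy(rng):
    n = 120
    labels = rng.integers(0, 3, n)
    fused = np.eye(3)[labels] * 4 + 0.1 * rng.standard_normal((n, 3))
    clf, probs = ef.classify_fused(
        fused, labels, TrainConfig(learning_rate=0.5, max_epochs=60), seed=6)
    np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)
    assert (probs.argmax(axis=1) == labels).mean() > 0.99
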