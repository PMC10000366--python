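"""The convolution/pooling primitives against brute-force oracles, plus
gradient checks and the early-stopping contract of the trainer."""

import numpy as np
import pytest

from emofuse import nn


def brute_conv1d(x, w, b):
    """Sliding dot product, no padding: the definition, written naively."""
    c_out, c_in, k = w.shape
    batch, _, length = x.shape
    out = np.zeros((batch, c_out, length - k + 1))
    for n in range(batch):
        for j in range(c_out):
            for t in range(length - k + 1):
                acc = b[j]
                for i in range(c_in):
                    for kk in range(k):
                        acc += w[j, i, kk] * x[n, i, t + kk]
                out[n, j, t] = acc
    return out


def test_conv1d_matches_bruteforce(rng):
    for c_in, c_out, k, length in [(1, 4, 3, 11), (3, 2, 5, 17), (2, 3, 3, 32)]:
        layer = nn.Conv1D(c_in, c_out, k, rng=rng)
        layer.params["b"] = rng.standard_normal(c_out)
        x = rng.standard_normal((2, c_in, length))
        w = layer.params["W"].reshape(c_out, c_in, k)
        np.testing.assert_allclose(layer.forward(x),
                                   brute_conv1d(x, w, layer.params["b"]),
                                   atol=1e-12)


def test_maxpool_matches_bruteforce(rng):
    x = rng.standard_normal((3, 2, 13))
    out = nn.MaxPool1D(2, 2).forward(x)
    assert out.shape == (3, 2, 6)
    for n in range(3):
        for c in range(2):
            for t in range(6):
                assert out[n, c, t] == max(x[n, c, 2 * t], x[n, c, 2 * t + 1])


def test_relu_definition():
    layer = nn.ReLU()
    np.testing.assert_array_equal(
        layer.forward(np.array([[-3.0, 0.0, 3.0]])),
        np.array([[0.0, 0.0, 3.0]]))


def _numeric_grad(f, x, eps=1e-6):
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        idx = it.multi_index
        old = x[idx]
        x[idx] = old + eps
        fp = f()
        x[idx] = old - eps
        fm = f()
        x[idx] = old
        g[idx] = (fp - fm) / (2 * eps)
        it.iternext()
    return g


@pytest.mark.parametrize("layer_fn,shape", [
    (lambda r: nn.Conv1D(2, 3, 3, rng=r), (2, 2, 9)),
    (lambda r: nn.Conv2D(2, 3, 3, pad=1, rng=r), (2, 2, 6, 6)),
    (lambda r: nn.BatchNorm(2), (3, 2, 8)),
    (lambda r: nn.Linear(5, 3, rng=r), (4, 5)),
    (lambda r: nn.MaxPool2D(2, 2), (2, 2, 6, 6)),
    (lambda r: nn.GlobalAvgPool1D(), (2, 3, 7)),
    (lambda r: nn.GlobalMaxPool2D(), (2, 3, 4, 4)),
])
def test_layer_gradients_match_finite_differences(layer_fn, shape, rng):
    layer = layer_fn(rng)
    x = rng.standard_normal(shape)
    target = rng.standard_normal(layer.forward(x, train=True).shape)

    def loss():
        return 0.5 * ((layer.forward(x, train=True) - target) ** 2).sum()

    out = layer.forward(x, train=True)
    dx = layer.backward(out - target)
    np.testing.assert_allclose(dx, _numeric_grad(loss, x),
                               rtol=1e-5, atol=1e-7)
    for name, p in layer.params.items():
        np.testing.assert_allclose(layer.grads[name],
                                   _numeric_grad(loss, p),
                                   rtol=1e-5, atol=1e-7)


def test_batchnorm_eval_uses_running_statistics(rng):
    layer = nn.BatchNorm(2, momentum=1.0)
    x = rng.standard_normal((16, 2, 10)) * 3 + 1
    layer.forward(x, train=True)
    y = layer.forward(x, train=False)
    assert abs(y.mean()) < 0.1 and abs(y.std() - 1) < 0.1


def test_dropout_eval_identity_and_train_scaling(rng):
    layer = nn.Dropout(0.5)
    x = np.ones((4, 10))
    np.testing.assert_array_equal(layer.forward(x, train=False), x)
    y = layer.forward(x, train=True, rng=np.random.default_rng(0))
    assert set(np.unique(y)) <= {0.0, 2.0}


def _toy_problem(rng, n=60):
    x = rng.standard_normal((n, 4))
    y = (x[:, 0] + x[:, 1] > 0).astype(int)
    net = nn.Network(nn.Sequential([nn.Linear(4, 2, rng=rng)]),
                     feature_index=-1)
    return net, x, y


def test_zero_learning_rate_freezes_parameters(rng):
    net, x, y = _toy_problem(rng)
    before = net.get_state()
    nn.fit_classifier(net, x, y,
                      nn.TrainConfig(learning_rate=0.0, max_epochs=1), seed=0)
    for a, b in zip(before, net.get_state()):
        np.testing.assert_array_equal(a, b)


def test_infinite_patience_trains_exactly_max_epochs(rng):
    net, x, y = _toy_problem(rng)
    hist = nn.fit_classifier(
        net, x, y, nn.TrainConfig(learning_rate=0.1, max_epochs=7,
                                  early_stop_patience=10 ** 9), seed=0)
    assert len(hist["train_loss"]) == 7


def test_early_stopping_halts_before_max_epochs(rng):
    net, x, y = _toy_problem(rng)
    hist = nn.fit_classifier(
        net, x, y, nn.TrainConfig(learning_rate=0.0, max_epochs=100,
                                  early_stop_patience=3), seed=0)
    # frozen optimizer: validation loss never improves after epoch 1
    assert len(hist["train_loss"]) <= 5


def test_single_class_labels_rejected(rng):
    net, x, _ = _toy_problem(rng)
    with pytest.raises(ValueError):
        nn.fit_classifier(net, x, np.zeros(len(x), int),
                          nn.TrainConfig(), seed=0)


def test_training_is_deterministic_given_seed(rng):
    results = []
    for _ in range(2):
        net = nn.Network(nn.Sequential(
            [nn.Linear(4, 8, rng=np.random.default_rng(3)), nn.ReLU(),
             nn.Dropout(0.2), nn.Linear(8, 2, rng=np.random.default_rng(4))]),
            feature_index=-1)
        r = np.random.default_rng(9)
        x = r.standard_normal((50, 4))
        y = (x[:, 0] > 0).astype(int)
        nn.fit_classifier(net, x, y,
                          nn.TrainConfig(learning_rate=0.05, max_epochs=5),
                          seed=11)
        results.append(net.get_state())
    for a, b in zip(*results):
        np.testing.assert_array_equal(a, b)
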