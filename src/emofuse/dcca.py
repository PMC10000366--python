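"""Deep canonical correlation analysis (DCCA) feature-level fusion.

Two transform networks f1, f2 map the EEG feature matrix I1 (M x n1) and
the video feature matrix I2 (M x n2) into a joint n-dimensional space,

    O1 = f1(I1; H1),   O2 = f2(I2; H2),

with parameters H1, H2 trained to maximize the canonical correlation
corr(O1, O2): the sum of the singular values of the whitened
cross-covariance T = S11^(-1/2) S12 S22^(-1/2), with a small ridge r added
to the auto-covariance diagonals for stability. The transformed features
are then fused by a convex weighted sum O = a*O1 + b*O2 (a + b = 1, equal
weights by default) and classified with a linear softmax classifier.

The closed-form *linear* CCA is implemented alongside as the module's
master oracle: a DCCA with single-layer linear transforms must recover
the same total correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import (Conv1D, GlobalAvgPool1D, Linear, MaxPool1D, Network, ReLU,
                 Sequential, TrainConfig, fit_classifier)

__all__ = ["DCCATransformSpec", "DCCAModel", "cca_closed_form", "cca_loss",
           "cca_loss_with_grad", "train_dcca", "transform", "fuse",
           "classify_fused"]


@dataclass
class DCCATransformSpec:
    """Architecture of one transform network.

    ``architecture="conv"`` is the three-stage 1-D convolution stack
    (128/256/512 kernels of sizes 3/5/3, each followed by max-pool 2/2)
    run over the feature axis, globally pooled and projected to
    ``output_dim``; ``architecture="linear"`` is a single linear map —
    the configuration whose optimum is classical CCA. The correlation
    path excludes dropout and any probability-producing output layer,
    which would destroy the correlation structure being maximized.
    """

    architecture: str = "conv"
    conv_filters: tuple[int, int, int] = (128, 256, 512)
    kernel_sizes: tuple[int, int, int] = (3, 5, 3)
    stride: int = 1
    pool_size: int = 2
    pool_stride: int = 2
    dropout: float = 0.4
    output_dim: int = 32

    def __post_init__(self) -> None:
        if self.architecture not in ("conv", "linear"):
            raise ValueError("architecture must be 'conv' or 'linear'")
        if self.output_dim < 1:
            raise ValueError("output_dim must be >= 1")
        if len(self.conv_filters) != 3 or len(self.kernel_sizes) != 3:
            raise ValueError("exactly three convolution stages")


@dataclass
class DCCAModel:
    """Fitted transform pair plus fusion weights."""

    net1: Sequential
    net2: Sequential
    output_dim: int
    r: float
    alpha: float = 0.5
    beta: float = 0.5
    in_stats: tuple | None = None  # ((mu1, sd1), (mu2, sd2)) z-scoring
    history: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if abs(self.alpha + self.beta - 1.0) > 1e-9 or \
                self.alpha < 0 or self.beta < 0:
            raise ValueError("fusion weights must be >= 0 and sum to 1")
        if self.r <= 0:
            raise ValueError("regularizer r must be > 0")


def _inv_sqrt_psd(s: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(s)
    if vals.min() <= 0:
        raise np.linalg.LinAlgError(
            "covariance is rank deficient; use a regularizer r > 0")
    return (vecs / np.sqrt(vals)) @ vecs.T


def cca_closed_form(x: np.ndarray, y: np.ndarray, k: int | None = None,
                    r: float = 1e-5):
    """Regularized linear CCA.

    Returns ``(wx, wy), correlations`` where the correlations are the
    descending top-k singular values of S11^(-1/2) S12 S22^(-1/2) (clipped
    to [0, 1]) and wx, wy are the projection weights reproducing them on
    column-centered data.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape[0] != y.shape[0]:
        raise ValueError("views must share the number of rows")
    m = x.shape[0]
    if m < 2:
        raise ValueError("need at least 2 rows")
    k = min(x.shape[1], y.shape[1]) if k is None else k
    if k > min(x.shape[1], y.shape[1]):
        raise ValueError("k exceeds a view dimension")
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    s11 = xc.T @ xc / (m - 1) + r * np.eye(x.shape[1])
    s22 = yc.T @ yc / (m - 1) + r * np.eye(y.shape[1])
    s12 = xc.T @ yc / (m - 1)
    i11, i22 = _inv_sqrt_psd(s11), _inv_sqrt_psd(s22)
    u, s, vt = np.linalg.svd(i11 @ s12 @ i22)
    corrs = np.clip(s[:k], 0.0, 1.0)
    return (i11 @ u[:, :k], i22 @ vt[:k].T), corrs


def cca_loss_with_grad(o1: np.ndarray, o2: np.ndarray, k: int | None = None,
                       r: float = 1e-5):
    """Negative total correlation of a batch and its gradients.

    Returns ``(loss, dO1, dO2)`` with loss = -(sum of the top-k singular
    values of the whitened cross-covariance); the gradients follow the
    analytic derivative of the singular-value sum.
    """
    o1 = np.asarray(o1, float)
    o2 = np.asarray(o2, float)
    m, n1 = o1.shape
    n2 = o2.shape[1]
    if m < 2:
        raise ValueError("batch must contain at least 2 rows")
    if o2.shape[0] != m:
        raise ValueError("batches must share the number of rows")
    k = min(n1, n2) if k is None else k
    h1 = (o1 - o1.mean(axis=0)).T  # (n1, M)
    h2 = (o2 - o2.mean(axis=0)).T
    s11 = h1 @ h1.T / (m - 1) + r * np.eye(n1)
    s22 = h2 @ h2.T / (m - 1) + r * np.eye(n2)
    s12 = h1 @ h2.T / (m - 1)
    i11, i22 = _inv_sqrt_psd(s11), _inv_sqrt_psd(s22)
    u, s, vt = np.linalg.svd(i11 @ s12 @ i22)
    uk, sk, vk = u[:, :k], s[:k], vt[:k].T
    corr = float(sk.sum())
    d12 = i11 @ uk @ vk.T @ i22
    d11 = -0.5 * i11 @ uk @ np.diag(sk) @ uk.T @ i11
    d22 = -0.5 * i22 @ vk @ np.diag(sk) @ vk.T @ i22
    g1 = (2.0 * d11 @ h1 + d12 @ h2) / (m - 1)
    g2 = (2.0 * d22 @ h2 + d12.T @ h1) / (m - 1)
    # centering: the covariances saw mean-subtracted data
    g1 = g1 - g1.mean(axis=1, keepdims=True)
    g2 = g2 - g2.mean(axis=1, keepdims=True)
    return -corr, -g1.T, -g2.T


def cca_loss(o1: np.ndarray, o2: np.ndarray, k: int | None = None,
             r: float = 1e-5) -> float:
    """Negative total correlation (see :func:`cca_loss_with_grad`)."""
    return cca_loss_with_grad(o1, o2, k, r)[0]


def _build_transform(spec: DCCATransformSpec, d_in: int,
                     rng: np.random.Generator) -> Sequential:
    if spec.architecture == "linear":
        return Sequential([Linear(d_in, spec.output_dim, rng=rng)])
    layers = []
    c_in = 1
    for f, ks in zip(spec.conv_filters, spec.kernel_sizes):
        layers += [Conv1D(c_in, f, ks, stride=spec.stride, rng=rng), ReLU(),
                   MaxPool1D(spec.pool_size, spec.pool_stride)]
        c_in = f
    layers += [GlobalAvgPool1D(),
               Linear(spec.conv_filters[-1], spec.output_dim, rng=rng)]
    return Sequential(layers)


def _transform_forward(net: Sequential, x: np.ndarray,
                       conv: bool) -> np.ndarray:
    return net.forward(x[:, None, :] if conv else x, train=False)


def train_dcca(i1: np.ndarray, i2: np.ndarray,
               spec: DCCATransformSpec | None = None,
               cfg: TrainConfig | None = None, seed: int = 0,
               r: float = 1e-5, alpha: float = 0.5) -> DCCAModel:
    """Fit the transform pair by full-batch gradient descent on the CCA loss.

    Inputs are z-scored with training statistics; a 90/10 row split
    provides the validation correlation used for early stopping (patience
    counts non-improving evaluations). Raises on a non-finite loss.
    """
    spec = spec or DCCATransformSpec()
    cfg = cfg or TrainConfig()
    i1 = np.asarray(i1, float)
    i2 = np.asarray(i2, float)
    if i1.shape[0] != i2.shape[0]:
        raise ValueError("views must share rows")
    rng = np.random.default_rng(seed)
    mu1, sd1 = i1.mean(axis=0), i1.std(axis=0) + 1e-8
    mu2, sd2 = i2.mean(axis=0), i2.std(axis=0) + 1e-8
    z1, z2 = (i1 - mu1) / sd1, (i2 - mu2) / sd2

    n_val = max(2, int(round(cfg.val_fraction * len(z1))))
    order = rng.permutation(len(z1))
    va, tr = order[:n_val], order[n_val:]
    z1tr, z2tr, z1va, z2va = z1[tr], z2[tr], z1[va], z2[va]

    net1 = _build_transform(spec, i1.shape[1], rng)
    net2 = _build_transform(spec, i2.shape[1], rng)
    conv = spec.architecture == "conv"
    k = spec.output_dim

    def snapshot():
        return ([p.copy() for _, _, p in net1.parameters()],
                [p.copy() for _, _, p in net2.parameters()])

    def restore(state):
        for (layer, name, _), saved in zip(net1.parameters(), state[0]):
            layer.params[name] = saved.copy()
        for (layer, name, _), saved in zip(net2.parameters(), state[1]):
            layer.params[name] = saved.copy()

    history = {"train_corr": [], "val_corr": []}
    best_val, best_state, stale = -np.inf, snapshot(), 0
    x1 = z1tr[:, None, :] if conv else z1tr
    x2 = z2tr[:, None, :] if conv else z2tr
    for _epoch in range(cfg.max_epochs):
        o1 = net1.forward(x1, train=True, rng=rng)
        o2 = net2.forward(x2, train=True, rng=rng)
        loss, d1, d2 = cca_loss_with_grad(o1, o2, k=k, r=r)
        if not np.isfinite(loss):
            restore(best_state)
            raise FloatingPointError(
                "DCCA objective diverged; best finite state restored on the "
                "returned model")
        net1.backward(d1)
        net2.backward(d2)
        for net in (net1, net2):
            for layer, name, param in net.parameters():
                g = layer.grads.get(name)
                if g is not None:
                    param -= cfg.learning_rate * g
        val_corr = -cca_loss(
            _transform_forward(net1, z1va, conv),
            _transform_forward(net2, z2va, conv), k=k, r=r)
        history["train_corr"].append(-loss)
        history["val_corr"].append(float(val_corr))
        if val_corr > best_val + 1e-12:
            best_val, best_state, stale = val_corr, snapshot(), 0
        else:
            stale += 1
            if stale >= cfg.early_stop_patience:
                break
    restore(best_state)
    return DCCAModel(net1=net1, net2=net2, output_dim=spec.output_dim, r=r,
                     alpha=alpha, beta=1.0 - alpha,
                     in_stats=((mu1, sd1), (mu2, sd2)),
                     history={**history, "spec": spec})


def transform(model: DCCAModel, i1: np.ndarray,
              i2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Map both feature matrices into the joint space (evaluation mode)."""
    (mu1, sd1), (mu2, sd2) = model.in_stats
    if i1.shape[1] != len(mu1) or i2.shape[1] != len(mu2):
        raise ValueError("feature dimensions differ from training")
    conv = model.history.get("spec", DCCATransformSpec()).architecture == "conv"
    o1 = _transform_forward(model.net1, (i1 - mu1) / sd1, conv)
    o2 = _transform_forward(model.net2, (i2 - mu2) / sd2, conv)
    return o1, o2


def fuse(o1: np.ndarray, o2: np.ndarray, alpha: float = 0.5,
         beta: float = 0.5) -> np.ndarray:
    """Convex weighted sum of the transformed features."""
    if abs(alpha + beta - 1.0) > 1e-9 or alpha < 0 or beta < 0:
        raise ValueError("weights must be >= 0 and sum to 1")
    o1 = np.asarray(o1, float)
    o2 = np.asarray(o2, float)
    if o1.shape != o2.shape:
        raise ValueError("transformed feature shapes differ")
    return alpha * o1 + beta * o2


def classify_fused(o: np.ndarray, labels, cfg: TrainConfig | None = None,
                   seed: int = 0):
    """Multinomial softmax classifier on fused features.

    Returns ``(network, probabilities)`` where probabilities are the
    per-class posteriors on the training rows.
    """
    cfg = cfg or TrainConfig()
    labels = np.asarray(labels, int)
    n_classes = int(labels.max()) + 1
    rng = np.random.default_rng(seed)
    net = Network(Sequential([Linear(o.shape[1], max(n_classes, 2),
                                     rng=rng)]), feature_index=-1)
    fit_classifier(net, o, labels, cfg, seed)
    return net, net.predict_proba(o)
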