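"""SGD training loop with validation-based early stopping.

Training follows one protocol for every network in the package:
cross-entropy loss, plain stochastic gradient descent (learning rate
0.001 by default), Xavier-initialized weights with zero biases, batch
size 32, at most 40 epochs, and early stopping once the validation loss
has failed to improve for 15 consecutive evaluations (one evaluation per
epoch). A stratified 10% validation split is carved out of the training
rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .layers import Sequential

__all__ = ["TrainConfig", "Network", "softmax", "cross_entropy_grad",
           "stratified_split", "fit_classifier"]


@dataclass
class TrainConfig:
    optimizer: str = "sgd"
    learning_rate: float = 0.001
    max_epochs: int = 40
    batch_size: int = 32
    early_stop_patience: int = 15
    val_fraction: float = 0.10

    def __post_init__(self) -> None:
        if self.optimizer != "sgd":
            raise ValueError("only plain SGD is supported")
        if self.learning_rate < 0:
            raise ValueError("learning rate must be non-negative")
        if self.max_epochs < 1 or self.early_stop_patience < 1:
            raise ValueError("max_epochs and patience must be >= 1")


class Network:
    """A sequential network with a designated feature tap.

    ``feature_index`` marks the layer whose (evaluation-mode) output is the
    feature vector handed to fusion; layers after it form the classifier
    head (dropout + linear softmax).
    """

    def __init__(self, seq: Sequential, feature_index: int,
                 meta: dict | None = None) -> None:
        self.seq = seq
        self.feature_index = feature_index
        self.meta = meta or {}

    def forward(self, x, train=False, rng=None):
        return self.seq.forward(x, train=train, rng=rng)

    def backward(self, grad):
        return self.seq.backward(grad)

    def features(self, x) -> np.ndarray:
        """Evaluation-mode activations at the feature tap."""
        for layer in self.seq.layers[: self.feature_index + 1]:
            x = layer.forward(x, train=False)
        return x

    def predict_proba(self, x) -> np.ndarray:
        return softmax(self.seq.forward(x, train=False))

    def predict(self, x) -> np.ndarray:
        return self.predict_proba(x).argmax(axis=1)

    def n_params(self, include_head: bool = True) -> int:
        if include_head:
            return self.seq.n_params()
        return sum(l.n_params()
                   for l in self.seq.layers[: self.feature_index + 1])

    def get_state(self) -> list[np.ndarray]:
        return [p.copy() for _, _, p in self.seq.parameters()]

    def set_state(self, state) -> None:
        for (layer, name, _), saved in zip(self.seq.parameters(), state):
            layer.params[name] = saved.copy()


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_grad(logits: np.ndarray,
                       y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = len(y)
    loss = -np.log(np.clip(p[np.arange(n), y], 1e-12, None)).mean()
    dlogits = p
    dlogits[np.arange(n), y] -= 1.0
    return float(loss), dlogits / n


def stratified_split(y: np.ndarray, val_fraction: float,
                     rng: np.random.Generator):
    """Indices of a class-stratified train/validation split."""
    train_idx, val_idx = [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = rng.permutation(idx)
        n_val = max(1, int(round(val_fraction * len(idx)))) \
            if len(idx) > 1 else 0
        val_idx.extend(idx[:n_val])
        train_idx.extend(idx[n_val:])
    return np.sort(np.array(train_idx, int)), np.sort(np.array(val_idx, int))


def _sgd_step(seq: Sequential, lr: float) -> None:
    for layer, name, param in seq.parameters():
        grad = layer.grads.get(name)
        if grad is not None:
            param -= lr * grad


def fit_classifier(net: Network, x: np.ndarray, y: np.ndarray,
                   cfg: TrainConfig, seed: int,
                   val_mask: np.ndarray | None = None) -> dict:
    """Train a softmax classifier network; returns a history dict.

    Deterministic for a fixed seed: the seed drives the validation split,
    batch shuffling and dropout masks. The best-validation-loss weights are
    restored at the end. ``val_mask`` designates the validation rows
    explicitly (otherwise a stratified split of ``val_fraction`` is drawn).
    """
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    rng = np.random.default_rng(seed)
    if val_mask is not None:
        val_mask = np.asarray(val_mask, bool)
        tr, va = np.flatnonzero(~val_mask), np.flatnonzero(val_mask)
    else:
        tr, va = stratified_split(y, cfg.val_fraction, rng)
    if len(va) == 0:
        raise ValueError("empty validation split")
    x_tr, y_tr, x_va, y_va = x[tr], y[tr], x[va], y[va]

    history = {"train_loss": [], "train_acc": [], "val_loss": [], "val_acc": []}
    best_val, best_state, stale = np.inf, net.get_state(), 0
    for _epoch in range(cfg.max_epochs):
        order = rng.permutation(len(x_tr))
        ep_loss, ep_correct = 0.0, 0
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start: start + cfg.batch_size]
            xb, yb = x_tr[idx], y_tr[idx]
            logits = net.forward(xb, train=True, rng=rng)
            loss, dlogits = cross_entropy_grad(logits, yb)
            net.backward(dlogits)
            _sgd_step(net.seq, cfg.learning_rate)
            ep_loss += loss * len(idx)
            ep_correct += int((logits.argmax(axis=1) == yb).sum())
        logits_va = net.forward(x_va, train=False)
        val_loss, _ = cross_entropy_grad(logits_va.copy(), y_va)
        history["train_loss"].append(ep_loss / len(x_tr))
        history["train_acc"].append(ep_correct / len(x_tr))
        history["val_loss"].append(val_loss)
        history["val_acc"].append(
            float((logits_va.argmax(axis=1) == y_va).mean()))
        if val_loss < best_val - 1e-12:
            best_val, best_state, stale = val_loss, net.get_state(), 0
        else:
            stale += 1
            if stale >= cfg.early_stop_patience:
                break
    net.set_state(best_state)
    return history
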