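"""Lightweight 1-D CNN feature extractor and classifier for EEG windows.

The network flattens each channels-by-samples window into one long 1-D
sequence (channel-major) and applies three convolution stages:

* Layer 1: batch-norm (on the single input channel) + Conv1D 1 -> 64,
  kernel 3, stride 1, no zero padding, ReLU;
* Layer 2: batch-norm + Conv1D 64 -> 64 + ReLU + max-pool (size 2, stride 2);
* Layer 3: batch-norm + Conv1D 64 -> 32 + ReLU + max-pool;

then dropout(0.5), a global average pool over time (in place of fully
connected layers — this is what keeps the model light), and a linear
softmax head for the three emotion classes. The feature extractor — all
convolution weights and biases plus the batch-norm scales and shifts,
head excluded — has exactly

    2 + (1*64*3 + 64) + 2*64 + (64*64*3 + 64) + 2*64 + (64*32*3 + 32)
      = 19,042

learnable parameters, independent of the input length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .eeg import EEGSegment
from .nn import (BatchNorm, Conv1D, Dropout, GlobalAvgPool1D, Linear,
                 MaxPool1D, Network, ReLU, Sequential, TrainConfig,
                 fit_classifier)

__all__ = ["EEGNetSpec", "build_eeg_network", "count_parameters",
           "train_eeg", "extract_eeg_features", "segments_to_matrix"]


@dataclass
class EEGNetSpec:
    conv_filters: tuple[int, int, int] = (64, 64, 32)
    kernel_size: int = 3
    stride: int = 1
    pool_size: int = 2
    pool_stride: int = 2
    dropout: float = 0.5
    n_classes: int = 3
    flatten_order: str = "channel-major"  # or "time-major"

    def __post_init__(self) -> None:
        if len(self.conv_filters) != 3:
            raise ValueError("exactly three convolution stages")
        if self.kernel_size % 2 == 0:
            raise ValueError("kernel size must be odd")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


def _min_input_length(spec: EEGNetSpec) -> int:
    # invert the valid-conv / pool arithmetic for a final length of >= 1
    k, p = spec.kernel_size, spec.pool_size
    length = 1
    length = length * p + (k - 1)        # undo pool3, conv3
    length = length * p + (k - 1)        # undo pool2, conv2
    return length + (k - 1)              # undo conv1


def build_eeg_network(spec: EEGNetSpec | None = None,
                      input_length: int = 640, seed: int = 0) -> Network:
    """Build the EEG classifier; ``input_length`` = channels x samples."""
    spec = spec or EEGNetSpec()
    if input_length < _min_input_length(spec):
        raise ValueError(
            f"input length {input_length} shorter than the network's "
            f"receptive field ({_min_input_length(spec)})")
    rng = np.random.default_rng(seed)
    f1, f2, f3 = spec.conv_filters
    k, s = spec.kernel_size, spec.stride
    layers = [
        BatchNorm(1),
        Conv1D(1, f1, k, stride=s, rng=rng),
        ReLU(),
        BatchNorm(f1),
        Conv1D(f1, f2, k, stride=s, rng=rng),
        ReLU(),
        MaxPool1D(spec.pool_size, spec.pool_stride),
        BatchNorm(f2),
        Conv1D(f2, f3, k, stride=s, rng=rng),
        ReLU(),
        MaxPool1D(spec.pool_size, spec.pool_stride),
        Dropout(spec.dropout),
        GlobalAvgPool1D(),
        Linear(f3, spec.n_classes, rng=rng),
    ]
    feature_index = len(layers) - 2  # tap: global-average-pooled activations
    net = Network(Sequential(layers), feature_index,
                  meta={"kind": "eeg-1dcnn", "input_length": input_length,
                        "spec": spec})
    return net


def count_parameters(net: Network, include_head: bool = False) -> int:
    """Exact count of learnable scalars (running BN statistics excluded)."""
    return net.n_params(include_head=include_head)


def segments_to_matrix(segments: list[EEGSegment],
                       flatten_order: str = "channel-major") -> np.ndarray:
    """Stack windows into (n_windows, 1, channels*samples) network input."""
    rows = []
    for seg in segments:
        if flatten_order == "channel-major":
            rows.append(seg.data.reshape(-1))
        elif flatten_order == "time-major":
            rows.append(seg.data.T.reshape(-1))
        else:
            raise ValueError("flatten_order must be channel- or time-major")
    return np.stack(rows)[:, None, :]


def train_eeg(net: Network, segments: list[EEGSegment], labels,
              cfg: TrainConfig | None = None, seed: int = 0,
              val_mask=None) -> dict:
    """Train on labelled windows; returns the per-epoch history."""
    cfg = cfg or TrainConfig()
    spec = net.meta.get("spec") or EEGNetSpec()
    x = segments_to_matrix(segments, spec.flatten_order)
    if x.shape[2] != net.meta["input_length"]:
        raise ValueError(
            f"window length {x.shape[2]} != build-time input length "
            f"{net.meta['input_length']}")
    return fit_classifier(net, x, np.asarray(labels, int), cfg, seed,
                          val_mask=val_mask)


def extract_eeg_features(net: Network, segment: EEGSegment) -> np.ndarray:
    """32-dimensional globally pooled feature vector (evaluation mode)."""
    spec = net.meta.get("spec") or EEGNetSpec()
    x = segments_to_matrix([segment], spec.flatten_order)
    if x.shape[2] != net.meta["input_length"]:
        raise ValueError(
            f"segment length {x.shape[2]} != build-time input length "
            f"{net.meta['input_length']}")
    return net.features(x)[0]
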