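"""Facial feature extractors: adapted ResNet-50 and a tiny test backbone.

The adapted ResNet-50 keeps the standard stage layout but replaces the
terminal global *average* pool with a global *max* pool, drops the original
1000-way classification layer, and ends in dropout(0.5) + a 3-class
softmax head; the 2048-dimensional activations before dropout are the
fusion features. The tiny backbone is a 3-stage convolutional network
with the identical head contract (feature tap before dropout, declared
feature dimension) sized for small synthetic frames, which makes it the
workhorse for tests and desk-scale experiments — no pretrained weights
are ever required.

Per-window features: frames are grouped into the same non-overlapping 5-s
windows as the EEG segments and the window feature is the mean of its
per-frame feature vectors (order-invariant, and aligned one-to-one with
the EEG windows of the same trial).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import (BatchNorm, Conv2D, Dropout, GlobalAvgPool2D,
                 GlobalMaxPool2D, Layer, Linear, MaxPool2D, Network, ReLU,
                 Sequential, TrainConfig, fit_classifier)
from .types import FrameSequence

__all__ = ["VideoNetSpec", "build_video_network", "extract_video_features",
           "train_video", "frames_to_batch", "group_frames_by_window"]


@dataclass
class VideoNetSpec:
    backbone: str = "tiny"  # or "resnet50-adapted"
    dropout: float = 0.5
    n_classes: int = 3
    input_size: int = 224
    in_channels: int = 3
    tiny_filters: tuple[int, int, int] = (8, 16, 32)

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


class _Bottleneck(Layer):
    """ResNet bottleneck block: 1x1 -> 3x3 (stride) -> 1x1 with skip."""

    def __init__(self, c_in: int, mid: int, c_out: int, stride: int,
                 rng: np.random.Generator, dtype=np.float32) -> None:
        super().__init__()
        self.main = Sequential([
            Conv2D(c_in, mid, 1, rng=rng, dtype=dtype), BatchNorm(mid, dtype=dtype), ReLU(),
            Conv2D(mid, mid, 3, stride=stride, pad=1, rng=rng, dtype=dtype),
            BatchNorm(mid, dtype=dtype), ReLU(),
            Conv2D(mid, c_out, 1, rng=rng, dtype=dtype), BatchNorm(c_out, dtype=dtype),
        ])
        if stride != 1 or c_in != c_out:
            self.shortcut: Sequential | None = Sequential([
                Conv2D(c_in, c_out, 1, stride=stride, rng=rng, dtype=dtype),
                BatchNorm(c_out, dtype=dtype),
            ])
        else:
            self.shortcut = None
        self.relu = ReLU()

    def children(self) -> list[Layer]:
        out: list[Layer] = [self.main]
        if self.shortcut is not None:
            out.append(self.shortcut)
        return out

    def forward(self, x, train=False, rng=None):
        main = self.main.forward(x, train=train, rng=rng)
        skip = x if self.shortcut is None else \
            self.shortcut.forward(x, train=train, rng=rng)
        return self.relu.forward(main + skip, train=train, rng=rng)

    def backward(self, grad):
        grad = self.relu.backward(grad)
        dx = self.main.backward(grad)
        if self.shortcut is None:
            return dx + grad
        return dx + self.shortcut.backward(grad)


def _resnet50_backbone(rng: np.random.Generator,
                       in_channels: int) -> list[Layer]:
    dtype = np.float32  # 25M parameters; halves the memory footprint
    layers: list[Layer] = [
        Conv2D(in_channels, 64, 7, stride=2, pad=3, rng=rng, dtype=dtype),
        BatchNorm(64, dtype=dtype), ReLU(), MaxPool2D(3, 2, pad=1),
    ]
    c_in = 64
    stage_defs = [(64, 256, 3, 1), (128, 512, 4, 2),
                  (256, 1024, 6, 2), (512, 2048, 3, 2)]
    for mid, c_out, blocks, first_stride in stage_defs:
        for b in range(blocks):
            layers.append(_Bottleneck(c_in, mid, c_out,
                                      first_stride if b == 0 else 1,
                                      rng, dtype=dtype))
            c_in = c_out
    layers.append(GlobalMaxPool2D())  # max pool replaces the average pool
    return layers


def _tiny_backbone(rng: np.random.Generator,
                   spec: VideoNetSpec) -> list[Layer]:
    f1, f2, f3 = spec.tiny_filters
    c = spec.in_channels
    layers: list[Layer] = []
    for c_out in (f1, f2, f3):
        layers += [Conv2D(c, c_out, 3, pad=1, rng=rng), BatchNorm(c_out),
                   ReLU(), MaxPool2D(2, 2)]
        c = c_out
    layers.append(GlobalAvgPool2D())
    return layers


def build_video_network(spec: VideoNetSpec | None = None,
                        seed: int = 0) -> Network:
    """Build a video classifier exposing a feature tap before dropout."""
    spec = spec or VideoNetSpec()
    rng = np.random.default_rng(seed)
    if spec.backbone == "resnet50-adapted":
        layers = _resnet50_backbone(rng, spec.in_channels)
        feat_dim = 2048
    elif spec.backbone == "tiny":
        layers = _tiny_backbone(rng, spec)
        feat_dim = spec.tiny_filters[-1]
    else:
        raise ValueError(f"unknown backbone {spec.backbone!r}")
    feature_index = len(layers) - 1  # global pool output
    layers += [Dropout(spec.dropout), Linear(feat_dim, spec.n_classes,
                                             rng=rng)]
    return Network(Sequential(layers), feature_index,
                   meta={"kind": f"video-{spec.backbone}", "spec": spec,
                         "feature_dim": feat_dim})


def frames_to_batch(frames: np.ndarray, in_channels: int = 1) -> np.ndarray:
    """(T, M, N[, 3]) pixel stack -> (T, C, M, N) network input in [0, 1]."""
    frames = np.asarray(frames, dtype=np.float64) / 255.0
    if frames.ndim == 3:
        batch = frames[:, None, :, :]
        if in_channels == 3:
            batch = np.repeat(batch, 3, axis=1)
    else:
        batch = frames.transpose(0, 3, 1, 2)
        if in_channels == 1:
            batch = batch.mean(axis=1, keepdims=True)
    return batch


def group_frames_by_window(seq: FrameSequence,
                           window_seconds: float = 5.0) -> list[np.ndarray]:
    """Split a (selected) sequence into the EEG-aligned 5-s windows.

    Grouping uses ``source_indices`` so that frames land in the window of
    their original timestamps even after frame selection; the trailing
    partial window is dropped, mirroring the EEG segmentation.
    """
    src = np.asarray(seq.source_indices)
    times = src / seq.fps
    n_source = int(seq.source_length)
    n_windows = int((n_source / seq.fps) // window_seconds)
    windows = []
    for w in range(n_windows):
        mask = (times >= w * window_seconds) & \
            (times < (w + 1) * window_seconds)
        if not mask.any():
            raise ValueError(
                f"trial {seq.trial_ref!r}: window {w} has no surviving frames")
        windows.append(np.asarray(seq.frames)[mask])
    return windows


def extract_video_features(net: Network, seq: FrameSequence,
                           window_seconds: float = 5.0) -> np.ndarray:
    """Per-window features: mean of per-frame feature vectors.

    Returns an array of shape (n_windows, feature_dim); the window count
    equals the EEG segment count of the same trial.
    """
    spec = net.meta["spec"]
    out = []
    for frames in group_frames_by_window(seq, window_seconds):
        batch = frames_to_batch(frames, spec.in_channels)
        out.append(net.features(batch).mean(axis=0))
    return np.stack(out)


def train_video(net: Network, windows: list[np.ndarray], labels,
                cfg: TrainConfig | None = None, seed: int = 0,
                val_mask=None) -> dict:
    """Train the frame classifier on labelled windows.

    Each window is a (T, M, N[, 3]) frame stack; its frames inherit the
    window label and are trained on individually. ``val_mask`` marks
    validation windows; their frames form the early-stopping set.
    """
    cfg = cfg or TrainConfig()
    spec = net.meta["spec"]
    labels = np.asarray(labels, int)
    xs, ys, vs = [], [], []
    for w, (frames, lab) in enumerate(zip(windows, labels)):
        batch = frames_to_batch(frames, spec.in_channels)
        xs.append(batch)
        ys.append(np.full(len(batch), lab))
        if val_mask is not None:
            vs.append(np.full(len(batch), bool(val_mask[w])))
    frame_val = np.concatenate(vs) if val_mask is not None else None
    return fit_classifier(net, np.concatenate(xs), np.concatenate(ys),
                          cfg, seed, val_mask=frame_val)
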