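"""Redundant-frame elimination and frame conditioning for facial video.

Consecutive facial frames are largely redundant. Each pair of consecutive
frames is scored by the mean absolute pixel difference

    m_t = sum_{x,y} |d_t(x, y)| / (M * N),

where d_t is the element-wise difference frame between frames t and t+1 on
an M x N canvas (colour frames are averaged over channels). Within each
1-second block the scores are ranked in descending order and only the
frames adjacent to the top 40% of scores are kept — frames carrying little
new information are discarded before feature extraction. Retained frames
are then center-cropped square, optionally brightness-normalized, and
resized to 224 x 224.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .types import FrameSequence

__all__ = ["DifferenceScore", "difference_scores", "select_frames",
           "condition_frame", "condition_sequence"]


@dataclass
class DifferenceScore:
    """Mean absolute difference between source frames ``index`` and ``index+1``."""

    index: int
    m: float


def _gray(frames: np.ndarray) -> np.ndarray:
    if frames.ndim == 4:
        return frames.mean(axis=3)
    return frames


def difference_scores(seq: FrameSequence) -> list[DifferenceScore]:
    """Score every consecutive frame pair; T frames give T-1 scores."""
    if len(seq) < 2:
        raise ValueError("need at least 2 frames for differencing")
    g = _gray(np.asarray(seq.frames, dtype=np.float64))
    diffs = np.abs(np.diff(g, axis=0))  # (T-1, M, N)
    means = diffs.mean(axis=(1, 2))
    return [DifferenceScore(t, float(m)) for t, m in enumerate(means)]


def select_frames(seq: FrameSequence, keep_fraction: float = 0.40,
                  retain: str = "later") -> FrameSequence:
    """Keep the most informative fraction of frames in each 1-s block.

    Blocks are non-overlapping, anchored at frame 0, ``fps`` frames long;
    a trailing partial block keeps ceil(keep_fraction * block length)
    frames. Within a block, difference scores are sorted in descending
    order (ties broken by earlier index) and the frame adjacent to each of
    the top scores is retained — the later frame of the pair by default
    (``retain="later"``), i.e. the frame that introduced the change.
    Output frames keep their temporal order and carry ``source_indices``
    back into the input sequence.
    """
    if not 0.0 < keep_fraction <= 1.0:
        raise ValueError("keep_fraction must be in (0, 1]")
    if retain not in ("later", "earlier"):
        raise ValueError("retain must be 'later' or 'earlier'")
    if len(seq) == 0:
        raise ValueError("empty sequence")
    block = int(round(seq.fps))
    if len(seq) < block:
        raise ValueError("sequence shorter than one second")
    scores = difference_scores(seq)
    offset = 1 if retain == "later" else 0

    kept: list[int] = []
    for start in range(0, len(seq), block):
        stop = min(start + block, len(seq))
        blen = stop - start
        n_keep = math.ceil(keep_fraction * blen)
        # difference scores whose retained neighbour lies in this block
        cand = [s for s in scores if start <= s.index + offset < stop]
        cand.sort(key=lambda s: (-s.m, s.index))
        chosen = sorted(s.index + offset for s in cand[:n_keep])
        if len(chosen) < n_keep:  # block edge: pad with earliest unkept frames
            extra = [i for i in range(start, stop) if i not in chosen]
            chosen = sorted(chosen + extra[: n_keep - len(chosen)])
        kept.extend(chosen)

    kept_arr = np.array(kept, dtype=int)
    return FrameSequence(frames=np.asarray(seq.frames)[kept_arr],
                         fps=seq.fps, trial_ref=seq.trial_ref,
                         source_indices=np.asarray(seq.source_indices)[kept_arr],
                         source_length=seq.source_length)


def _resize_bilinear(img: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """Bilinear resize of a 2-D (or 2-D + channel) array."""
    in_h, in_w = img.shape[:2]
    if (in_h, in_w) == (out_h, out_w):
        return img.astype(np.float64, copy=True)
    r = (np.arange(out_h) + 0.5) * in_h / out_h - 0.5
    c = (np.arange(out_w) + 0.5) * in_w / out_w - 0.5
    r = np.clip(r, 0, in_h - 1)
    c = np.clip(c, 0, in_w - 1)
    r0 = np.floor(r).astype(int)
    c0 = np.floor(c).astype(int)
    r1 = np.minimum(r0 + 1, in_h - 1)
    c1 = np.minimum(c0 + 1, in_w - 1)
    wr = (r - r0)[:, None]
    wc = (c - c0)[None, :]
    if img.ndim == 3:
        wr, wc = wr[..., None], wc[..., None]
    img = img.astype(np.float64)
    top = img[r0][:, c0] * (1 - wc) + img[r0][:, c1] * wc
    bot = img[r1][:, c0] * (1 - wc) + img[r1][:, c1] * wc
    return top * (1 - wr) + bot * wr


def condition_frame(frame: np.ndarray, out_size: int = 224,
                    crop_box: tuple[int, int, int, int] | None = None,
                    brightness_target: float | None = None) -> np.ndarray:
    """Crop (centered largest square by default), adjust brightness, resize.

    ``crop_box`` is (top, left, height, width). Brightness adjustment
    rescales the mean intensity to ``brightness_target`` when given.
    Returns a float array of shape (out_size, out_size) or (+3 channels).
    """
    frame = np.asarray(frame, dtype=np.float64)
    if frame.size == 0:
        raise ValueError("empty frame")
    h, w = frame.shape[:2]
    if crop_box is None:
        side = min(h, w)
        top, left = (h - side) // 2, (w - side) // 2
        crop_box = (top, left, side, side)
    top, left, ch, cw = crop_box
    if ch <= 0 or cw <= 0 or top < 0 or left < 0 or top + ch > h or left + cw > w:
        raise ValueError(f"degenerate crop_box {crop_box} for {h}x{w} frame")
    out = frame[top:top + ch, left:left + cw]
    if brightness_target is not None:
        mean = out.mean()
        out = out * (brightness_target / mean) if mean > 0 \
            else out + brightness_target
    return _resize_bilinear(out, out_size, out_size)


def condition_sequence(seq: FrameSequence, out_size: int = 224,
                       brightness_target: float | None = None) -> FrameSequence:
    """Apply :func:`condition_frame` to every frame of a sequence."""
    frames = np.stack([condition_frame(f, out_size,
                                       brightness_target=brightness_target)
                       for f in np.asarray(seq.frames)])
    return FrameSequence(frames=frames, fps=seq.fps, trial_ref=seq.trial_ref,
                         source_indices=seq.source_indices,
                         source_length=seq.source_length)
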