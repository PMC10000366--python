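"""Core containers shared across the pipeline.

An experiment trial pairs a multichannel EEG recording with the facial
video recorded during the same stimulus, plus the subject's self-assessment
ratings of valence and arousal on the 1-9 pictorial (SAM) scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["EEGRecording", "FrameSequence", "Trial", "LABELS"]

#: canonical 3-class label set, index order fixed throughout the package
LABELS = ("happy", "neutral", "sad")


@dataclass
class EEGRecording:
    """A channels-by-samples voltage matrix with named channels.

    Parameters
    ----------
    channel_names : ordered channel labels (10-20 system names).
    fs : sampling rate in Hz.
    data : array of shape (n_channels, n_samples), in microvolts.
    """

    channel_names: list[str]
    fs: float
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("EEG data must be a 2-D channels x samples matrix")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[0]} data rows"
            )
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.data.shape[1] == 0:
            raise ValueError("recording has no samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.data.shape[1] / self.fs


@dataclass
class FrameSequence:
    """An ordered stack of equally sized video frames.

    frames has shape (T, M, N) for grayscale or (T, M, N, 3) for colour,
    values in [0, 255] (float or uint8). ``source_indices`` maps each frame
    back to its index in the original, unselected sequence.
    """

    frames: np.ndarray
    fps: float
    trial_ref: str = ""
    source_indices: np.ndarray | None = None
    source_length: int | None = None  # frame count before any selection

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim not in (3, 4):
            raise ValueError("frames must be (T, M, N) or (T, M, N, 3)")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.source_indices is None:
            self.source_indices = np.arange(len(self.frames))
        else:
            self.source_indices = np.asarray(self.source_indices)
            if len(self.source_indices) != len(self.frames):
                raise ValueError("source_indices length mismatch")
        if self.source_length is None:
            self.source_length = int(len(self.frames))

    def __len__(self) -> int:
        return int(self.frames.shape[0])

    @property
    def duration(self) -> float:
        return len(self) / self.fps


@dataclass
class Trial:
    """One subject/trial pair: EEG + video + SAM ratings + class label."""

    subject_id: str
    trial_id: str
    eeg: EEGRecording
    video: FrameSequence
    valence_rating: float
    arousal_rating: float
    label: str = field(default="")

    def __post_init__(self) -> None:
        for r in (self.valence_rating, self.arousal_rating):
            if not (1.0 <= r <= 9.0):
                raise ValueError(f"SAM rating {r} outside [1, 9]")
        if self.label and self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")
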