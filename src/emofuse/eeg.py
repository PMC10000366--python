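"""EEG conditioning: band-pass filtering, electrode selection, windowing.

Emotion-related EEG content lives mostly in the 4-45 Hz band and in
frontal/temporal electrodes, so the pipeline keeps that band, restricts
the montage to five symmetric frontal/temporal pairs (FP1/FP2, AF3/AF4,
F3/F4, F7/F8, T7/T8), and then slices each trial into non-overlapping 5-s
windows (a 60-s trial yields 12 windows), which multiplies the number of
training examples per trial.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import signal

from .types import EEGRecording

__all__ = ["EEGSegment", "DEFAULT_CHANNELS", "bandpass", "select_channels",
           "segment", "preprocess_eeg"]

#: five symmetric frontal/temporal electrode pairs (10-20 system)
DEFAULT_CHANNELS = ["FP1", "FP2", "AF3", "AF4", "F3", "F4", "F7", "F8",
                    "T7", "T8"]


@dataclass
class EEGSegment:
    """One fixed-length analysis window cut from a trial's recording."""

    trial_ref: str
    window_index: int
    data: np.ndarray  # channels x (window_seconds * fs)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def bandpass(rec: EEGRecording, low: float = 4.0,
             high: float = 45.0, order: int = 4) -> EEGRecording:
    """Zero-phase Butterworth band-pass filter applied per channel.

    Forward-backward filtering (filtfilt) keeps the EEG time-locked to the
    video frames; a 4th-order design gives a flat passband with >20 dB
    attenuation one octave outside the band edges.
    """
    nyq = rec.fs / 2.0
    if not 0 < low < high:
        raise ValueError("need 0 < low < high")
    if high >= nyq:
        raise ValueError(f"high cutoff {high} Hz >= Nyquist {nyq} Hz")
    sos = signal.butter(order, [low, high], btype="bandpass",
                        fs=rec.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, rec.data, axis=1)
    return EEGRecording(list(rec.channel_names), rec.fs, filtered)


def select_channels(rec: EEGRecording,
                    wanted: Sequence[str] | None = None) -> EEGRecording:
    """Reorder/subset channels to ``wanted`` (case-insensitive names)."""
    wanted = list(DEFAULT_CHANNELS if wanted is None else wanted)
    lookup = {name.upper(): i for i, name in enumerate(rec.channel_names)}
    missing = [w for w in wanted if w.upper() not in lookup]
    if missing:
        raise KeyError(f"channels not in montage: {', '.join(missing)}")
    rows = [lookup[w.upper()] for w in wanted]
    return EEGRecording(wanted, rec.fs, rec.data[rows].copy())


def segment(rec: EEGRecording, window_seconds: float = 5.0,
            trial_ref: str = "") -> list[EEGSegment]:
    """Cut into non-overlapping windows; the trailing remainder is dropped."""
    n_win_samples = int(round(window_seconds * rec.fs))
    if n_win_samples > rec.n_samples:
        raise ValueError(
            f"window of {window_seconds} s ({n_win_samples} samples) longer "
            f"than recording ({rec.n_samples} samples)")
    n_windows = rec.n_samples // n_win_samples
    return [
        EEGSegment(trial_ref, w,
                   rec.data[:, w * n_win_samples:(w + 1) * n_win_samples].copy())
        for w in range(n_windows)
    ]


def preprocess_eeg(rec: EEGRecording, low: float = 4.0, high: float = 45.0,
                   channels: Sequence[str] | None = None,
                   window_seconds: float = 5.0,
                   apply_bandpass: bool = True,
                   artifact_fn: Callable[[EEGRecording], EEGRecording] | None = None,
                   trial_ref: str = "") -> list[EEGSegment]:
    """Full conditioning chain: band-pass -> artifact hook -> select -> window.

    ``apply_bandpass=False`` covers recordings distributed already filtered
    at 128 Hz. ``artifact_fn`` is an optional user-supplied artifact-removal
    stage (e.g. an ICA-based cleaner); by default nothing is removed.
    """
    if apply_bandpass:
        rec = bandpass(rec, low, high)
    if artifact_fn is not None:
        rec = artifact_fn(rec)
    rec = select_channels(rec, channels)
    return segment(rec, window_seconds, trial_ref=trial_ref)
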