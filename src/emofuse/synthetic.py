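"""Synthetic paired EEG / facial-video trials with known structure.

The generator emulates the structure of affective-computing datasets in
which each trial pairs a multichannel EEG recording with a facial video
and a SAM valence/arousal rating: a latent 3-class emotion label drives

* class-dependent band-limited oscillations (6 / 10 / 22 Hz) on the
  frontal/temporal electrodes, on top of 1/f background noise and a
  per-subject offset, and
* a facial "blob" whose horizontal position and motion depend on the
  class, with runs of near-duplicate frames injected so that keyframe
  selection is consequential.

``effect_size`` controls class separation (0 means no class information in
either modality), ``cross_modal_corr`` controls how strongly per-trial
signal quality is shared between the modalities, and
``complementary_noise`` makes each trial strong in exactly one modality —
the regime in which fusing the two modalities genuinely beats either one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .eeg import DEFAULT_CHANNELS
from .types import LABELS, EEGRecording, FrameSequence, Trial

__all__ = ["SyntheticConfig", "label_from_ratings", "generate_dataset",
           "generate_correlated_pairs", "DEFAULT_MONTAGE_32"]

#: a 32-channel 10-20 montage containing the ten selected electrodes
DEFAULT_MONTAGE_32 = [
    "FP1", "AF3", "F3", "F7", "FC5", "FC1", "C3", "T7", "CP5", "CP1",
    "P3", "P7", "PO3", "O1", "Oz", "Pz", "FP2", "AF4", "Fz", "F4",
    "F8", "FC6", "FC2", "Cz", "C4", "T8", "CP6", "CP2", "P4", "P8",
    "PO4", "O2",
]

#: class-specific oscillation frequencies (Hz), inside the 4-45 Hz band
CLASS_FREQS = (6.0, 10.0, 22.0)


@dataclass
class SyntheticConfig:
    n_subjects: int = 4
    trials_per_subject: int = 9
    trial_seconds: float = 60.0
    eeg_fs: float = 128.0
    eeg_channels: list[str] = field(
        default_factory=lambda: list(DEFAULT_MONTAGE_32))
    fps: float = 20.0
    frame_size: tuple[int, int] = (64, 64)
    class_probs: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    effect_size: float = 2.0
    cross_modal_corr: float = 0.7
    complementary_noise: bool = False
    noise_sd: float = 1.0
    duplicate_run_length: int = 3
    label_policy: str = "mean"  # or "valence"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.trials_per_subject < 1:
            raise ValueError("counts must be positive")
        if self.trial_seconds <= 0 or self.eeg_fs <= 0 or self.fps <= 0:
            raise ValueError("durations and rates must be positive")
        if min(self.frame_size) <= 0:
            raise ValueError("frame size must be positive")
        probs = np.asarray(self.class_probs, dtype=float)
        if probs.shape != (3,) or (probs < 0).any() or \
                abs(probs.sum() - 1.0) > 1e-12:
            raise ValueError("class_probs must be a 3-way distribution")
        if not 0.0 <= self.cross_modal_corr <= 1.0:
            raise ValueError("cross_modal_corr must be in [0, 1]")
        if self.label_policy not in ("mean", "valence"):
            raise ValueError("label_policy must be 'mean' or 'valence'")


def label_from_ratings(valence: float, arousal: float,
                       policy: str = "mean") -> str:
    """Map SAM ratings to {happy, neutral, sad}.

    The deciding rating (mean of valence and arousal by default, or
    valence alone) is thresholded: >= 5 happy, <= 4 sad, strictly between
    4 and 5 neutral.
    """
    for r in (valence, arousal):
        if not 1.0 <= r <= 9.0:
            raise ValueError(f"rating {r} outside [1, 9]")
    deciding = valence if policy == "valence" else 0.5 * (valence + arousal)
    if deciding >= 5.0:
        return "happy"
    if deciding <= 4.0:
        return "sad"
    return "neutral"


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-variance 1/f ("pink") noise of length n."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    spec /= np.sqrt(np.maximum(f, f[1] if n > 1 else 1.0))
    out = np.fft.irfft(spec, n)
    sd = out.std()
    return out / sd if sd > 0 else out


# class -> SAM rating band reproducing the label under both policies
_RATING_BANDS = {"happy": (5.0, 9.0), "sad": (1.0, 4.0),
                 "neutral": (4.05, 4.95)}


def _draw_ratings(rng: np.random.Generator, label: str) -> tuple[float, float]:
    lo, hi = _RATING_BANDS[label]
    return float(rng.uniform(lo, hi)), float(rng.uniform(lo, hi))


def _modality_gains(rng: np.random.Generator,
                    cfg: SyntheticConfig) -> tuple[float, float]:
    """Per-trial signal-quality gains for EEG and video.

    A shared log-normal factor (weight cross_modal_corr) couples the two;
    with complementary_noise each trial is additionally strong in exactly
    one modality and attenuated in the other.
    """
    rho = cfg.cross_modal_corr
    z_shared, z_e, z_v = rng.standard_normal(3)
    g_e = math.exp(0.25 * (math.sqrt(rho) * z_shared
                           + math.sqrt(1 - rho) * z_e))
    g_v = math.exp(0.25 * (math.sqrt(rho) * z_shared
                           + math.sqrt(1 - rho) * z_v))
    if cfg.complementary_noise:
        weak = 0.15
        if rng.random() < 0.5:
            g_v *= weak
        else:
            g_e *= weak
    return g_e, g_v


def _make_eeg(rng: np.random.Generator, cfg: SyntheticConfig, cls: int,
              gain: float, subject_offset: float) -> EEGRecording:
    n = int(round(cfg.trial_seconds * cfg.eeg_fs))
    t = np.arange(n) / cfg.eeg_fs
    signal_channels = {c.upper() for c in DEFAULT_CHANNELS}
    data = np.empty((len(cfg.eeg_channels), n))
    # class amplitude profile over the three oscillators
    amps = np.ones(3)
    amps[cls] += cfg.effect_size
    for i, name in enumerate(cfg.eeg_channels):
        row = cfg.noise_sd * _pink_noise(rng, n) + subject_offset
        if name.upper() in signal_channels:
            for a, freq in zip(amps, CLASS_FREQS):
                phase = rng.uniform(0, 2 * np.pi)
                row = row + gain * a * np.sin(2 * np.pi * freq * t + phase)
        data[i] = row
    return EEGRecording(list(cfg.eeg_channels), cfg.eeg_fs, data)


def _make_video(rng: np.random.Generator, cfg: SyntheticConfig, cls: int,
                gain: float) -> FrameSequence:
    h, w = cfg.frame_size
    n_frames = int(round(cfg.trial_seconds * cfg.fps))
    t = np.arange(n_frames) / cfg.fps
    sep = min(cfg.effect_size, 2.0) / 2.0  # saturate at full separation
    # class-dependent horizontal blob position and motion frequency
    cx0 = w * (0.5 + 0.18 * (cls - 1) * sep)
    motion_f = 0.4 + 0.3 * cls * sep
    cx = cx0 + 0.06 * w * np.sin(2 * np.pi * motion_f * t
                                 + rng.uniform(0, 2 * np.pi))
    cy = h * 0.5 + 0.04 * h * np.sin(2 * np.pi * 0.3 * t
                                     + rng.uniform(0, 2 * np.pi))
    yy, xx = np.mgrid[0:h, 0:w]
    sigma = 0.16 * min(h, w)
    peak = min(110.0 * gain, 200.0)
    frames = np.empty((n_frames, h, w))
    for i in range(n_frames):
        jitter_x = cfg.noise_sd * 0.01 * w * rng.standard_normal()
        blob = peak * np.exp(-(((xx - cx[i] - jitter_x) ** 2)
                               + (yy - cy[i]) ** 2) / (2 * sigma ** 2))
        frames[i] = 30.0 + blob + 4.0 * cfg.noise_sd * \
            rng.standard_normal((h, w))
    # inject runs of near-duplicate frames
    run = cfg.duplicate_run_length
    if run > 0 and n_frames > run + 1:
        stride = max(run * 4, 4)
        for start in range(1, n_frames - run, stride):
            for j in range(1, run + 1):
                frames[start + j] = frames[start] + \
                    0.5 * rng.standard_normal((h, w))
    np.clip(frames, 0.0, 255.0, out=frames)
    return FrameSequence(frames=frames, fps=cfg.fps)


def generate_dataset(cfg: SyntheticConfig) -> list[Trial]:
    """Generate paired trials; deterministic for a fixed ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    trials: list[Trial] = []
    for s in range(cfg.n_subjects):
        subject_offset = 0.3 * rng.standard_normal()
        for k in range(cfg.trials_per_subject):
            cls = int(rng.choice(3, p=np.asarray(cfg.class_probs)))
            label = LABELS[cls]
            g_e, g_v = _modality_gains(rng, cfg)
            eeg = _make_eeg(rng, cfg, cls, g_e, subject_offset)
            video = _make_video(rng, cfg, cls, g_v)
            valence, arousal = _draw_ratings(rng, label)
            trial_id = f"s{s:02d}_t{k:02d}"
            video.trial_ref = trial_id
            trials.append(Trial(subject_id=f"s{s:02d}", trial_id=trial_id,
                                eeg=eeg, video=video,
                                valence_rating=valence,
                                arousal_rating=arousal, label=label))
            assert label_from_ratings(valence, arousal,
                                      cfg.label_policy) == label
    return trials


def generate_correlated_pairs(n: int, d1: int, d2: int, k: int,
                              rho, seed: int = 0
                              ) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian feature pairs with prescribed population canonical correlations.

    ``k`` latent standard-normal variables are shared between the two
    views: coordinate i of each view is sqrt(rho_i) * z_i plus independent
    noise of matching variance, remaining coordinates are pure noise, and
    each view is mixed by a fixed random orthogonal matrix (canonical
    correlations are invariant to invertible linear maps, so the
    population canonical correlations of the pair are exactly ``rho``).
    """
    rho = np.asarray(rho, dtype=float)
    if k > min(d1, d2):
        raise ValueError("k exceeds a view dimension")
    if rho.shape != (k,):
        raise ValueError("rho must have length k")
    if (rho < 0).any() or (rho >= 1).any():
        raise ValueError("rho values must lie in [0, 1)")
    if k > 1 and not (np.diff(rho) < 0).all():
        raise ValueError("rho must be strictly decreasing")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, k))
    sq, sc = np.sqrt(rho), np.sqrt(1.0 - rho)
    x = np.empty((n, d1))
    y = np.empty((n, d2))
    x[:, :k] = sq * z + sc * rng.standard_normal((n, k))
    y[:, :k] = sq * z + sc * rng.standard_normal((n, k))
    x[:, k:] = rng.standard_normal((n, d1 - k))
    y[:, k:] = rng.standard_normal((n, d2 - k))
    q1 = np.linalg.qr(rng.standard_normal((d1, d1)))[0]
    q2 = np.linalg.qr(rng.standard_normal((d2, d2)))[0]
    return x @ q1.T, y @ q2.T
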