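"""Readers, writers and run configuration.

Canonical on-disk layout of a dataset directory:

    manifest.csv              subject_id, trial_id, eeg_path, video_path,
                              valence, arousal, label
    eeg/<trial>.npy + .json   channels x samples array + {channel_names, fs}
    video/<trial>/*.png       frame images + meta.json {fps}

EDF/BDF recordings are read through mne behind the same contract.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .types import EEGRecording, FrameSequence, Trial

__all__ = ["read_eeg", "write_eeg", "read_frames", "write_frames",
           "write_dataset", "read_dataset", "load_config", "CONFIG_DEFAULTS"]


def write_eeg(rec: EEGRecording, path) -> None:
    """Array file + JSON sidecar carrying channel names and rate."""
    path = Path(path)
    np.save(path.with_suffix(".npy"), rec.data)
    path.with_suffix(".json").write_text(json.dumps(
        {"channel_names": rec.channel_names, "fs": rec.fs}))


def read_eeg(path, format: str = "array") -> EEGRecording:
    """Load a recording from an array file pair or an EDF/BDF file."""
    path = Path(path)
    if format == "array":
        sidecar = path.with_suffix(".json")
        if not sidecar.exists():
            raise FileNotFoundError(
                f"array EEG at {path} lacks the channel-name/fs sidecar "
                f"{sidecar.name}")
        meta = json.loads(sidecar.read_text())
        return EEGRecording(meta["channel_names"], float(meta["fs"]),
                            np.load(path.with_suffix(".npy")))
    if format in ("edf", "bdf"):
        import mne
        reader = mne.io.read_raw_edf if format == "edf" else \
            mne.io.read_raw_bdf
        raw = reader(path, preload=True, verbose="error")
        return EEGRecording(list(raw.ch_names), float(raw.info["sfreq"]),
                            raw.get_data() * 1e6)  # volts -> microvolts
    raise ValueError(f"unknown EEG format {format!r}")


def write_frames(seq: FrameSequence, directory) -> None:
    import imageio.v3 as iio
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(np.asarray(seq.frames)):
        iio.imwrite(directory / f"frame_{i:06d}.png",
                    np.clip(frame, 0, 255).astype(np.uint8))
    (directory / "meta.json").write_text(json.dumps({"fps": seq.fps}))


def read_frames(path, fps: float | None = None) -> FrameSequence:
    """Read an ordered directory of PNG/JPEG frames."""
    import imageio.v3 as iio
    path = Path(path)
    meta = path / "meta.json"
    if fps is None:
        if not meta.exists():
            raise ValueError(f"{path}: fps unknown (no meta.json and no "
                             "fps argument)")
        fps = float(json.loads(meta.read_text())["fps"])
    files = sorted(p for p in path.iterdir()
                   if p.suffix.lower() in (".png", ".jpg", ".jpeg"))
    if not files:
        raise ValueError(f"no frames found under {path}")
    frames, shape = [], None
    for f in files:
        img = iio.imread(f)
        if shape is None:
            shape = img.shape
        elif img.shape != shape:
            raise ValueError(f"frame {f.name} has shape {img.shape}, "
                             f"expected {shape}")
        frames.append(img)
    return FrameSequence(frames=np.stack(frames), fps=fps,
                         trial_ref=path.name)


def write_dataset(trials: list[Trial], directory) -> Path:
    """Write trials + manifest.csv; returns the manifest path."""
    directory = Path(directory)
    (directory / "eeg").mkdir(parents=True, exist_ok=True)
    (directory / "video").mkdir(parents=True, exist_ok=True)
    rows = []
    for t in trials:
        eeg_path = directory / "eeg" / t.trial_id
        video_dir = directory / "video" / t.trial_id
        write_eeg(t.eeg, eeg_path)
        write_frames(t.video, video_dir)
        rows.append({"subject_id": t.subject_id, "trial_id": t.trial_id,
                     "eeg_path": f"eeg/{t.trial_id}.npy",
                     "video_path": f"video/{t.trial_id}",
                     "valence": t.valence_rating,
                     "arousal": t.arousal_rating, "label": t.label})
    manifest = directory / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_dataset(directory) -> list[Trial]:
    directory = Path(directory)
    df = pd.read_csv(directory / "manifest.csv")
    if df.duplicated(["subject_id", "trial_id"]).any():
        raise ValueError("duplicate (subject, trial) pairs in manifest")
    trials = []
    for row in df.itertuples():
        eeg = read_eeg(directory / row.eeg_path)
        video = read_frames(directory / row.video_path)
        video.trial_ref = str(row.trial_id)
        trials.append(Trial(subject_id=str(row.subject_id),
                            trial_id=str(row.trial_id), eeg=eeg, video=video,
                            valence_rating=float(row.valence),
                            arousal_rating=float(row.arousal),
                            label=str(row.label)))
    return trials


# run-configuration defaults: dataset generation + pipeline knobs
CONFIG_DEFAULTS: dict = {
    "n_subjects": 4, "trials_per_subject": 9, "trial_seconds": 60.0,
    "eeg_fs": 128.0, "fps": 20.0, "frame_size": [64, 64],
    "class_probs": [1 / 3, 1 / 3, 1 / 3], "effect_size": 2.0,
    "cross_modal_corr": 0.7, "complementary_noise": False, "noise_sd": 1.0,
    "duplicate_run_length": 3, "label_policy": "mean",
    "band": [4.0, 45.0], "apply_bandpass": True, "channels": None,
    "window_seconds": 5.0, "keep_fraction": 0.40,
    "learning_rate": 0.001, "max_epochs": 40, "batch_size": 32,
    "early_stop_patience": 15, "alpha": 0.5, "beta": 0.5,
    "dcca_output_dim": 32, "dcca_architecture": "conv",
    "dcca_regularizer": 1e-5, "video_backbone": "tiny",
    "methods": ["eeg", "video", "dcca", "concat", "max",
                "choquet", "adaptive", "kernels"],
    "seed": 0,
}


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Load a YAML/JSON run configuration, fill defaults, validate.

    Unknown keys are rejected with their paths; ``alpha``/``beta`` are
    closed to sum to 1 when only one is given.
    """
    cfg = dict(CONFIG_DEFAULTS)
    user: dict = {}
    if path is not None:
        text = Path(path).read_text()
        user = yaml.safe_load(text) or {}
    if overrides:
        user = {**user, **overrides}
    unknown = set(user) - set(cfg)
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    has_alpha, has_beta = "alpha" in user, "beta" in user
    cfg.update(user)
    if has_alpha and not has_beta:
        cfg["beta"] = 1.0 - cfg["alpha"]
    elif has_beta and not has_alpha:
        cfg["alpha"] = 1.0 - cfg["beta"]
    # range checks with field paths
    if not 0.0 < cfg["keep_fraction"] <= 1.0:
        raise ValueError("keep_fraction: must be in (0, 1]")
    if abs(cfg["alpha"] + cfg["beta"] - 1.0) > 1e-9 or cfg["alpha"] < 0 \
            or cfg["beta"] < 0:
        raise ValueError("alpha/beta: must be >= 0 and sum to 1")
    if cfg["learning_rate"] < 0:
        raise ValueError("learning_rate: must be >= 0")
    probs = np.asarray(cfg["class_probs"], float)
    if probs.shape != (3,) or abs(probs.sum() - 1) > 1e-9 or (probs < 0).any():
        raise ValueError("class_probs: must be a 3-way distribution")
    return cfg
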