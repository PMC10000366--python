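import numpy as np
import pytest

import emofuse as ef


@pytest.fixture(scope="session")
def tiny_trials():
    """12 desk-scale paired trials (3 subjects x 4), strong class signal."""
    cfg = ef.SyntheticConfig(
        n_subjects=3, trials_per_subject=4, trial_seconds=10.0, eeg_fs=64.0,
        eeg_channels=["FP1", "FP2", "T7", "T8"], fps=4.0, frame_size=(32, 32),
        effect_size=2.5, seed=42)
    return ef.generate_dataset(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def make_stub_trial(subject: str, trial: str, label: str = "happy"):
    """Featherweight trial for protocol-level tests (folds, manifests)."""
    ratings = {"happy": 7.0, "neutral": 4.5, "sad": 2.0}[label]
    eeg = ef.EEGRecording(["FP1", "FP2"], 8.0,
                          np.zeros((2, 16)))
    video = ef.FrameSequence(np.zeros((4, 2, 2)), fps=2.0, trial_ref=trial)
    return ef.Trial(subject_id=subject, trial_id=trial, eeg=eeg, video=video,
                    valence_rating=ratings, arousal_rating=ratings,
                    label=label)
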