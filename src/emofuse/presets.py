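"""Canonical study configurations.

``paper_scale`` mirrors the conditions of full recordings (60-s trials,
128 Hz EEG over the 32-channel montage, the 4-45 Hz band, 224-pixel
frames). ``desk_scale`` is the down-sized configuration used for the
package's own end-to-end experiments and tests: shorter trials, a 64-Hz
sampling rate with a Nyquist-safe 4-28 Hz band, four signal-carrying
electrodes, small grayscale frames and the tiny video backbone, chosen so
a complete leave-one-subject-out run of every method finishes in minutes
on one CPU while exercising the identical code paths.
"""

from __future__ import annotations

from .dcca import DCCATransformSpec
from .evaluate import PipelineConfig
from .nn import TrainConfig
from .synthetic import SyntheticConfig
from .videonet import VideoNetSpec

__all__ = ["desk_synthetic_config", "desk_pipeline_config"]

#: electrodes carrying the synthetic class signal at desk scale
DESK_CHANNELS = ["FP1", "FP2", "T7", "T8"]


def desk_synthetic_config(seed: int, effect_size: float = 2.5,
                          complementary: bool = True,
                          n_subjects: int = 4,
                          trials_per_subject: int = 9) -> SyntheticConfig:
    """Desk-scale paired dataset: 10-s trials, 64 Hz EEG, 4 fps video."""
    return SyntheticConfig(
        n_subjects=n_subjects, trials_per_subject=trials_per_subject,
        trial_seconds=10.0, eeg_fs=64.0, eeg_channels=list(DESK_CHANNELS),
        fps=4.0, frame_size=(32, 32), effect_size=effect_size,
        cross_modal_corr=0.7, complementary_noise=complementary,
        noise_sd=1.0, duplicate_run_length=3, seed=seed)


def desk_pipeline_config(methods=("eeg", "video", "dcca")) -> PipelineConfig:
    """Pipeline knobs matching :func:`desk_synthetic_config`."""
    return PipelineConfig(
        band=(4.0, 28.0), channels=list(DESK_CHANNELS),
        train_cfg=TrainConfig(learning_rate=0.05, max_epochs=10,
                              early_stop_patience=10),
        dcca_spec=DCCATransformSpec(architecture="linear", output_dim=32),
        video_spec=VideoNetSpec(backbone="tiny", in_channels=1,
                                input_size=32),
        methods=tuple(methods))
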