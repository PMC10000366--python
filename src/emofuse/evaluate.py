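"""Leave-one-subject-out evaluation and the end-to-end pipeline driver.

Every subject serves as the test set exactly once; the remaining subjects'
trials are split 90/10 (stratified by class) into training and validation
rows. All fitted statistics — feature-extractor weights, DCCA transforms,
normalization constants, fusion densities — are estimated on train +
validation rows only, never on the held-out subject.

Predictions are made per 5-s window and aggregated to per-trial labels by
majority vote (ties resolved by the higher mean class score); both window-
and trial-level accuracies are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn import metrics as skmetrics
from sklearn.svm import SVC

from . import dcca as dcca_mod
from . import fusion as fusion_mod
from .eeg import DEFAULT_CHANNELS, preprocess_eeg
from .eegnet import EEGNetSpec, build_eeg_network, train_eeg
from .nn import TrainConfig, softmax, stratified_split
from .types import LABELS, Trial
from .video import select_frames
from .videonet import (VideoNetSpec, build_video_network,
                       group_frames_by_window, train_video)

__all__ = ["LOSOFold", "MetricsReport", "PipelineConfig", "loso_folds",
           "compute_metrics", "run_pipeline", "ALL_METHODS"]

ALL_METHODS = ("eeg", "video", "dcca", "concat", "max", "choquet",
               "adaptive", "kernels")


@dataclass
class LOSOFold:
    test_subject: str
    train_subjects: list[str]
    train_rows: np.ndarray  # trial indices
    val_rows: np.ndarray
    test_rows: np.ndarray
    seed: int


@dataclass
class MetricsReport:
    """Macro-averaged rates; percentages on 0-100, F1 on 0-1."""

    accuracy: float
    recall: float
    precision: float
    f1: float
    per_class: dict
    n: int


@dataclass
class PipelineConfig:
    """Everything the end-to-end run needs besides the trials themselves."""

    band: tuple[float, float] = (4.0, 45.0)
    apply_bandpass: bool = True
    channels: list[str] = field(default_factory=lambda: list(DEFAULT_CHANNELS))
    window_seconds: float = 5.0
    keep_fraction: float = 0.40
    eeg_spec: EEGNetSpec = field(default_factory=EEGNetSpec)
    video_spec: VideoNetSpec = field(
        default_factory=lambda: VideoNetSpec(backbone="tiny", in_channels=1))
    dcca_spec: dcca_mod.DCCATransformSpec = field(
        default_factory=lambda: dcca_mod.DCCATransformSpec(
            architecture="linear", output_dim=16))
    train_cfg: TrainConfig = field(default_factory=TrainConfig)
    dcca_cfg: TrainConfig = field(
        default_factory=lambda: TrainConfig(learning_rate=0.05,
                                            max_epochs=200,
                                            early_stop_patience=30))
    alpha: float = 0.5
    methods: tuple[str, ...] = ALL_METHODS


def loso_folds(trials: list[Trial], seed: int = 0,
               val_fraction: float = 0.10) -> list[LOSOFold]:
    """One fold per subject; validation rows stratified by class."""
    subjects = sorted({t.subject_id for t in trials})
    if len(subjects) < 2:
        raise ValueError("leave-one-subject-out needs at least 2 subjects")
    labels = np.array([LABELS.index(t.label) for t in trials])
    subj = np.array([t.subject_id for t in trials])
    folds = []
    for f, test_subject in enumerate(subjects):
        rng = np.random.default_rng((seed, f))
        pool = np.flatnonzero(subj != test_subject)
        tr_local, va_local = stratified_split(labels[pool], val_fraction, rng)
        folds.append(LOSOFold(
            test_subject=test_subject,
            train_subjects=[s for s in subjects if s != test_subject],
            train_rows=pool[tr_local], val_rows=pool[va_local],
            test_rows=np.flatnonzero(subj == test_subject), seed=seed))
    return folds


def compute_metrics(predictions, labels) -> MetricsReport:
    """Accuracy and macro one-vs-rest precision/recall/F1."""
    y_pred = np.asarray(predictions, int)
    y_true = np.asarray(labels, int)
    if len(y_pred) == 0 or len(y_pred) != len(y_true):
        raise ValueError("predictions and labels must be aligned, non-empty")
    if (y_true < 0).any() or (y_true >= len(LABELS)).any():
        raise ValueError("unknown label index")
    classes = np.arange(len(LABELS))
    prec, rec, f1, support = skmetrics.precision_recall_fscore_support(
        y_true, y_pred, labels=classes, average=None, zero_division=0)
    per_class = {}
    for c in classes:
        tp = int(((y_pred == c) & (y_true == c)).sum())
        tn = int(((y_pred != c) & (y_true != c)).sum())
        per_class[LABELS[c]] = {
            "accuracy": 100.0 * (tp + tn) / len(y_true),
            "precision": 100.0 * prec[c], "recall": 100.0 * rec[c],
            "f1": float(f1[c]), "support": int(support[c]),
        }
    return MetricsReport(
        accuracy=100.0 * float(skmetrics.accuracy_score(y_true, y_pred)),
        recall=100.0 * float(rec.mean()),
        precision=100.0 * float(prec.mean()),
        f1=float(f1.mean()), per_class=per_class, n=len(y_true))


def _prepare_windows(trials: list[Trial], cfg: PipelineConfig):
    """Preprocess every trial once; returns per-window tables.

    Output arrays are aligned: ``win_trial[i]`` is the trial index of
    window i, ``eeg_x[i]`` its flattened EEG window, ``vid_windows[i]``
    its frame stack, ``win_label[i]`` its class index.
    """
    eeg_rows, vid_rows, win_trial, win_label = [], [], [], []
    for ti, trial in enumerate(trials):
        segs = preprocess_eeg(
            trial.eeg, low=cfg.band[0], high=cfg.band[1],
            channels=cfg.channels, window_seconds=cfg.window_seconds,
            apply_bandpass=cfg.apply_bandpass, trial_ref=trial.trial_id)
        selected = select_frames(trial.video, cfg.keep_fraction)
        vwins = group_frames_by_window(selected, cfg.window_seconds)
        if len(vwins) != len(segs):
            raise ValueError(
                f"trial {trial.trial_id}: {len(segs)} EEG windows vs "
                f"{len(vwins)} video windows")
        lab = LABELS.index(trial.label)
        for seg, vw in zip(segs, vwins):
            eeg_rows.append(seg)
            vid_rows.append(vw)
            win_trial.append(ti)
            win_label.append(lab)
    return eeg_rows, vid_rows, np.array(win_trial), np.array(win_label)


def _majority_vote(window_pred: np.ndarray, window_scores: np.ndarray,
                   groups: np.ndarray) -> dict[int, int]:
    """Trial label by majority over windows; ties -> higher mean score."""
    out = {}
    for g in np.unique(groups):
        mask = groups == g
        counts = np.bincount(window_pred[mask], minlength=len(LABELS))
        best = np.flatnonzero(counts == counts.max())
        if len(best) == 1:
            out[int(g)] = int(best[0])
        else:
            mean_scores = window_scores[mask].mean(axis=0)
            out[int(g)] = int(best[np.argmax(mean_scores[best])])
    return out


def _fit_softmax(x, y, cfg, seed, val_mask):
    from .nn import Linear, Network, Sequential, fit_classifier
    rng = np.random.default_rng(seed)
    net = Network(Sequential([Linear(x.shape[1], len(LABELS), rng=rng)]),
                  feature_index=-1)
    fit_classifier(net, x, y, cfg, seed, val_mask=val_mask)
    return net


def run_pipeline(trials: list[Trial], cfg: PipelineConfig | None = None,
                 seed: int = 0) -> dict:
    """Full LOSO evaluation of every requested method.

    Returns ``{"per_fold": DataFrame, "summary": {method: MetricsReport},
    "window_accuracy": {method: %}, "fold_reports": ...}``; the per-fold
    table has one row per test subject plus an "average" row, matching the
    usual per-user reporting convention.
    """
    cfg = cfg or PipelineConfig()
    eeg_rows, vid_rows, win_trial, win_label = _prepare_windows(trials, cfg)
    input_length = eeg_rows[0].data.size
    folds = loso_folds(trials, seed)

    methods = list(cfg.methods)
    fold_rows = []
    window_preds = {m: {} for m in methods}  # method -> {window idx: pred}
    trial_preds = {m: {} for m in methods}
    fold_reports = {m: [] for m in methods}

    for fi, fold in enumerate(folds):
        fseed = int(np.random.default_rng((seed, 7 + fi)).integers(2 ** 31))
        trainval = np.concatenate([fold.train_rows, fold.val_rows])
        w_trainval = np.flatnonzero(np.isin(win_trial, trainval))
        w_test = np.flatnonzero(np.isin(win_trial, fold.test_rows))
        val_mask = np.isin(win_trial[w_trainval], fold.val_rows)

        # --- per-modality feature extractors -------------------------------
        eeg_net = build_eeg_network(cfg.eeg_spec, input_length, seed=fseed)
        eeg_hist = train_eeg(eeg_net, [eeg_rows[i] for i in w_trainval],
                             win_label[w_trainval], cfg.train_cfg,
                             seed=fseed, val_mask=val_mask)
        vid_net = build_video_network(cfg.video_spec, seed=fseed + 1)
        vid_hist = train_video(vid_net, [vid_rows[i] for i in w_trainval],
                               win_label[w_trainval], cfg.train_cfg,
                               seed=fseed + 1, val_mask=val_mask)

        from .eegnet import segments_to_matrix
        from .videonet import frames_to_batch
        eeg_x_all = segments_to_matrix(eeg_rows,
                                       cfg.eeg_spec.flatten_order)
        feats_eeg = eeg_net.features(eeg_x_all)
        probs_eeg = softmax(eeg_net.forward(eeg_x_all))
        feats_vid = np.stack([
            vid_net.features(frames_to_batch(
                vid_rows[i], cfg.video_spec.in_channels)).mean(axis=0)
            for i in range(len(vid_rows))])
        probs_vid = np.stack([softmax(vid_net.forward(frames_to_batch(
            vid_rows[i], cfg.video_spec.in_channels))).mean(axis=0)
            for i in range(len(vid_rows))])

        per_method_scores = {}
        if "eeg" in methods:
            per_method_scores["eeg"] = probs_eeg
        if "video" in methods:
            per_method_scores["video"] = probs_vid

        # --- fusions --------------------------------------------------------
        if "dcca" in methods:
            model = dcca_mod.train_dcca(
                feats_eeg[w_trainval], feats_vid[w_trainval],
                cfg.dcca_spec, cfg.dcca_cfg, seed=fseed + 2,
                alpha=cfg.alpha)
            o1, o2 = dcca_mod.transform(model, feats_eeg, feats_vid)
            fused = dcca_mod.fuse(o1, o2, model.alpha, model.beta)
            clf = _fit_softmax(fused[w_trainval], win_label[w_trainval],
                               cfg.train_cfg, fseed + 3, val_mask)
            per_method_scores["dcca"] = clf.predict_proba(fused)
        if "concat" in methods:
            cat_tr, stats = fusion_mod.concat_fuse(feats_eeg[w_trainval],
                                                   feats_vid[w_trainval])
            cat_all, _ = fusion_mod.concat_fuse(feats_eeg, feats_vid,
                                                stats=stats)
            clf = _fit_softmax(cat_tr, win_label[w_trainval],
                               cfg.train_cfg, fseed + 4, val_mask)
            per_method_scores["concat"] = clf.predict_proba(cat_all)
        if "kernels" in methods:
            cat_tr, stats = fusion_mod.concat_fuse(feats_eeg[w_trainval],
                                                   feats_vid[w_trainval])
            z_eeg, _ = fusion_mod.concat_fuse(
                feats_eeg, np.zeros((len(feats_eeg), 0)),
                stats=(stats[0], stats[1], np.zeros(0), np.zeros(0)))
            z_vid, _ = fusion_mod.concat_fuse(
                np.zeros((len(feats_vid), 0)), feats_vid,
                stats=(np.zeros(0), np.zeros(0), stats[2], stats[3]))
            k_all = fusion_mod.combine_kernels(
                [z_eeg @ z_eeg.T, z_vid @ z_vid.T])
            svc = SVC(kernel="precomputed", random_state=fseed)
            svc.fit(k_all[np.ix_(w_trainval, w_trainval)],
                    win_label[w_trainval])
            pred = svc.predict(k_all[:, w_trainval])
            scores = np.zeros((len(feats_eeg), len(LABELS)))
            scores[np.arange(len(pred)), pred] = 1.0
            per_method_scores["kernels"] = scores

        if {"max", "choquet", "adaptive"} & set(methods):
            table = np.stack([probs_eeg, probs_vid])  # (U=2, T, V)
        if "max" in methods:
            pred = fusion_mod.max_fuse(table)
            per_method_scores["max"] = table.max(axis=0)
        if "choquet" in methods:
            acc_e = max(eeg_hist["val_acc"])
            acc_v = max(vid_hist["val_acc"])
            dens = np.clip([acc_e, acc_v], 0.01, 0.99)
            measure = fusion_mod.sugeno_lambda_measure(dens)
            scores = np.empty((table.shape[1], table.shape[2]))
            for t in range(table.shape[1]):
                for v in range(table.shape[2]):
                    scores[t, v] = fusion_mod.choquet_fuse(table[:, t, v],
                                                           measure)
            per_method_scores["choquet"] = scores
        if "adaptive" in methods:
            scores = np.empty((table.shape[1], table.shape[2]))
            for t in range(table.shape[1]):
                for v in range(table.shape[2]):
                    scores[t, v] = fusion_mod.adaptive_fuse(
                        probs_eeg[t, v], probs_vid[t, v])
            per_method_scores["adaptive"] = scores

        # --- aggregate to trials, score the fold ---------------------------
        row = {"test_subject": fold.test_subject}
        for m in methods:
            sc = per_method_scores[m]
            wpred = sc.argmax(axis=1)
            for wi in w_test:
                window_preds[m][int(wi)] = int(wpred[wi])
            votes = _majority_vote(wpred[w_test], sc[w_test],
                                   win_trial[w_test])
            for ti, p in votes.items():
                trial_preds[m][ti] = p
            t_true = [LABELS.index(trials[ti].label) for ti in votes]
            rep = compute_metrics(list(votes.values()), t_true)
            fold_reports[m].append(rep)
            row[m] = rep.accuracy
        fold_rows.append(row)

    per_fold = pd.DataFrame(fold_rows)
    avg_row = {"test_subject": "average",
               **{m: per_fold[m].mean() for m in methods}}
    per_fold = pd.concat([per_fold, pd.DataFrame([avg_row])],
                         ignore_index=True)

    summary, window_accuracy = {}, {}
    all_true = np.array([LABELS.index(t.label) for t in trials])
    for m in methods:
        t_idx = sorted(trial_preds[m])
        summary[m] = compute_metrics([trial_preds[m][i] for i in t_idx],
                                     all_true[t_idx])
        w_idx = sorted(window_preds[m])
        window_accuracy[m] = 100.0 * float(np.mean(
            [window_preds[m][i] == win_label[i] for i in w_idx]))
    return {"per_fold": per_fold, "summary": summary,
            "window_accuracy": window_accuracy,
            "fold_reports": fold_reports, "seed": seed}
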