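# Methods

## Problem and model

`emofuse` classifies short affective trials into three emotion classes
(happy, neutral, sad) from two synchronized modalities: multichannel scalp
EEG and facial video. Subjects rate each stimulus on the 1–9 SAM
(self-assessment manikin) valence and arousal scales; the deciding rating
(by default the mean of valence and arousal, optionally valence alone) is
thresholded into sad (≤ 4), neutral (strictly between 4 and 5) and happy
(≥ 5). Because the two readings of the rating→class rule (joint
valence/arousal vs a single scale) can disagree for discordant ratings,
both policies are exposed as `label_policy`; the synthetic generator draws
both ratings from the same class band so either policy reproduces the
latent class.

The pipeline has two stages.

**Stage 1 — per-modality feature extraction.**

*Video.* Consecutive frames are scored by the mean absolute difference
frame, m_t = Σ_{x,y} |d_t(x,y)| / (M·N). Differences are taken as absolute
values: a signed sum could cancel opposite-signed pixel changes and report
zero for a frame pair that clearly differs, while the absolute difference
is zero exactly when the frames match. Within each non-overlapping
1-second block (anchored at frame 0; a trailing partial block keeps
⌈keep_fraction·len⌉ frames), scores are ranked descending — ties broken by
the earlier index for determinism — and the frames adjacent to the top
40 % of scores are retained. The *later* frame of each scored pair is kept
by default (`retain="later"`): it is the frame that introduced the change;
the alternative is a config switch. Retained frames are center-cropped
square, optionally brightness-normalized to a target mean, and resized
(bilinear) to 224×224 for the full-size backbone. Features come from an
adapted ResNet-50 — terminal global *average* pool replaced by global
*max* pool, classification layer removed, dropout(0.5) + 3-class softmax
head added, feature tap (2048-d) before dropout — or from a tiny 3-stage
convolutional backbone with the identical head contract for desk-scale
work. Per-frame features are averaged within each 5-s window (an
order-invariant aggregator; alternatives such as max or median would also
respect the window alignment but the mean is the least committal), so per
trial the video windows align one-to-one with the EEG windows.

*EEG.* Recordings are band-pass filtered to 4–45 Hz with a zero-phase
forward–backward 4th-order Butterworth design (zero phase keeps the EEG
time-locked to the video; the passband is flat to well under 1 dB and
attenuation exceeds 20 dB at 1 Hz and at 0.9×Nyquist). An optional
`artifact_fn` hook takes the place of dataset-specific artifact removal
(e.g. ICA de-noising of head motion) and defaults to a no-op. Ten
frontal/temporal electrodes (FP1, FP2, AF3, AF4, F3, F4, F7, F8, T7, T8 —
five symmetric pairs) are selected case-insensitively, then each trial is
cut into non-overlapping 5-s windows (a 60-s trial yields exactly 12;
overlap would break that count). Each window is flattened channel-major
into one 1-D sequence and classified by a lightweight 1-D CNN: BN + valid
Conv1D 1→64 (k=3) + ReLU; BN + Conv1D 64→64 + ReLU + max-pool 2/2; BN +
Conv1D 64→32 + ReLU + max-pool 2/2; dropout 0.5; global average pooling
over time in place of fully connected layers; linear softmax head. The
feature extractor (convolution weights and biases plus the 2 learnable
batch-norm scalars per channel; running statistics are buffers and do not
count) has exactly

    2 + (1·64·3+64) + 2·64 + (64·64·3+64) + 2·64 + (64·32·3+32) = 19,042

learnable parameters, independent of the input length. This
batch-norm-counts-2-per-channel convention and the global-pooling head are
the only reading of the architecture consistent with that total; standard
(not depth-wise-separable) convolutions are likewise what the arithmetic
supports, so they are what is implemented.

**Stage 2 — fusion and classification.** The per-window feature matrices
I₁ ∈ R^{M×n₁} (EEG) and I₂ ∈ R^{M×n₂} (video) are mapped by two transform
networks O_i = f_i(I_i; H_i) into a joint n-dimensional space trained to
maximize the canonical correlation corr(f₁(I₁;H₁), f₂(I₂;H₂)) — the sum of
the singular values of T = Σ₁₁^{-1/2} Σ₁₂ Σ₂₂^{-1/2}, with a ridge r on the
auto-covariance diagonals and 1/(M−1) covariance normalization. Gradients
of the singular-value sum are the standard analytic ones; optimization is
full-batch SGD (the full-batch objective keeps the singular values stable
at these sample sizes), with Xavier initialization, zero biases, and early
stopping on a held-out validation correlation (patience 15 evaluations).
The objective uses all n directions (k = n) since the full transformed
vectors are fused. Transforms are either a single linear layer — whose
optimum is classical CCA, used as the module's master oracle — or a
three-stage 1-D convolution stack over the feature axis (128/256/512
kernels of sizes 3/5/3, max-pool 2/2 after each stage) pooled and
projected to n. Dropout (0.4 in the stack's classifier use) and any
softmax layer are excluded from the correlation path: a probability
simplex output would destroy the covariance structure the objective
maximizes. The transformed features are fused by the convex sum
O = αO₁ + βO₂ with α + β = 1 (equal weights by default) and classified by
a multinomial softmax layer.

The regularizer default is r = 1e-5. The corresponding "regulation
parameter" is configurable; a value of 1e+5 would swamp unit-scale feature
covariances and reduce T to (numerically) zero, so the conventional small
ridge is the default. The transformed dimension n defaults to 32, the EEG
feature width; it is config-exposed.

**Baseline fusions.** (1) z-scored concatenation of the two feature blocks
(normalization statistics from the training split only; zero-variance
columns dropped with a warning); (2) convex combination of per-modality
Gram matrices with fixed weights (uniform by default; the weights are not
learned) classified by a precomputed-kernel SVM; (3) MAX decision fusion
Ŷ = argmax_i max_j P_j(y_i|x_t), ties to the lowest class index; (4) the
discrete Choquet integral with respect to a Sugeno λ-fuzzy measure — λ is
the unique root > −1 (≠ 0) of ∏(1+λg_i) = 1+λ, solved by Brent's method to
1e-14, subset values by the recursion λ(A∪{i}) = λ(A) + g_i + λ·g_i·λ(A);
densities g_i default to each source's validation accuracy clipped to
(0.01, 0.99) (a quadratic-programming fit of the measure would need a
training-data layout the decision level does not provide; the
density-based construction satisfies the same axioms and accepts
user-supplied densities); (5) an adaptive rule on two scores in [0, 1]:
y = (y_F + (1 + (y_E − 0.4)/100)·y_E)/2 when y_E > 0.4, else
(y_E + y_F)/2 — the unique nearby reading of the rule that is continuous
at the 0.4 threshold while giving EEG more weight above it.

**Evaluation.** Leave-one-subject-out: each subject is the test set once;
the remaining subjects' trials are split 90/10 (stratified by class) into
training and validation rows. Feature extractors, DCCA transforms,
normalization statistics, fusion densities and classifiers see only
train + validation rows. Training uses cross-entropy, plain SGD
(lr 0.001, batch 32, ≤ 40 epochs by default), Xavier init, zero biases,
early stopping after 15 non-improving validation evaluations. Predictions
are made per 5-s window and aggregated to per-trial labels by majority
vote (ties resolved by the higher mean class score); both window- and
trial-level accuracies are reported, since per-user accuracies can be
defined at either granularity. Metrics: accuracy and macro one-vs-rest
precision/recall on the 0–100 scale, F1 on the 0–1 scale.

## Synthetic data

The generator emulates the *structure* of paired EEG/video affect
datasets, not their content. Per trial a latent class (from
`class_probs`) drives (i) three band-limited oscillations (6, 10, 22 Hz,
all inside 4–45 Hz) on the frontal/temporal electrodes only — so channel
selection is consequential — with the class's own oscillator amplified by
`effect_size`, on top of unit-variance 1/f noise and a per-subject
offset; and (ii) a Gaussian facial "blob" whose horizontal position and
motion frequency depend on the class (saturating at full separation for
effect_size ≥ 2), with pixel noise and injected runs of near-duplicate
frames (exact copies plus low-amplitude sensor noise, so the
difference-frame ranking is nontrivial but unambiguous). Ratings are
drawn from the class's SAM band (happy [5, 9], sad [1, 4], neutral
(4, 5)), so the rating→label rule reproduces the latent class under
either policy. `cross_modal_corr` couples the per-trial log-normal
signal-quality gains of the two modalities; `complementary_noise`
additionally makes each trial strong in exactly one modality (the other
attenuated to 0.15×) — the regime in which fusing modalities genuinely
beats either one, mirroring the motivating argument that EEG and facial
expression compensate for each other's failure modes.

What the generator does **not** emulate: realistic EEG spectra beyond
band-limited class signals, volume conduction, ocular/muscle artifacts,
photorealistic faces, head pose, illumination changes. Passing tests
therefore demonstrate that the pipeline recovers the statistical structure
it is designed for — not performance on real recordings.

`generate_correlated_pairs` provides the CCA oracle inputs: k shared
standard-normal latents give two Gaussian views whose population canonical
correlations equal the prescribed ρ exactly; each view is mixed by a fixed
random orthogonal matrix (canonical correlations are invariant to
invertible linear maps).

## Problem sizes and numerical choices

Default configuration mirrors full-scale recordings: 60-s trials, 128 Hz
(or 256 Hz) EEG over a 32-channel montage, 4–45 Hz band, 20–60 fps video,
224×224 frames, SGD lr 0.001 / batch 32 / ≤ 40 epochs / patience 15.

The package's own end-to-end experiments (tests and
`scripts/acceptance.py`) run a **desk-scale** configuration chosen once:
4 subjects × 9 trials, 10-s trials (2 windows each), 64 Hz EEG with a
4–28 Hz band (the upper edge kept below the 32 Hz Nyquist), the four
signal-carrying electrodes FP1/FP2/T7/T8, 4 fps 32×32 grayscale frames,
the tiny video backbone, lr 0.05 for ≤ 10 epochs, and a linear DCCA
transform of width 32. These sizes exercise the identical code paths and
keep a complete LOSO run of all eight methods to roughly two minutes on
one CPU; the CCA recovery experiments use M = 5000 samples.

Other numerical choices: covariance inverse square roots via symmetric
eigendecomposition, with an explicit error (advising r > 0) on a
non-positive spectrum; tie-breaks are deterministic everywhere (earlier
frame index, lower class index, first maximum); window remainders are
dropped, never padded; all randomness flows from explicit integer seeds
through numpy Generators (weight init, dropout masks, batch shuffling,
splits), so fixed-seed runs are bit-identical; the DCCA trainer restores
the best-validation state and raises on a non-finite objective.

## Design choices on genuinely open points

- Whether the 40 % frame retention counts frames or difference frames per
  second, and which neighbour of a difference frame is kept, are not
  derivable from the published description; both are config switches
  (defaults: difference scores per second; later frame).
- Whether band-passing precedes or follows channel selection is
  irrelevant here (a per-channel filter commutes with selection; verified
  by test); selection is applied after filtering.
- Whether the EEG rating threshold applies to valence and arousal jointly
  or to a single scale is exposed as `label_policy` (default: mean).
- Per-frame-then-aggregate vs aggregate-then-classify for video:
  features are aggregated per window, then classified, which matches the
  window-level fusion design.
- Layer 3 of the EEG net includes its own max-pool (parameter-neutral
  either way).

## Known limitations

- The neural-network engine is a compact numpy implementation (explicit
  forward/backward, plain SGD); it is sized for the lightweight models
  here, not for training full-size ResNet-50 — the adapted ResNet-50 is
  provided for feature extraction and architecture contracts, with the
  tiny backbone as the trainable workhorse.
- No face detection or landmarking: conditioning uses a centered square
  crop, so off-center faces in real video would need an upstream detector
  via `crop_box`.
- MKL weights are fixed (uniform/user-supplied), not optimized; the
  BLSTM-style sequence fusion is out of scope.
- EDF/BDF reading is best-effort through mne; the canonical interchange
  format is the npy + JSON sidecar pair, and no EDF writer is provided.
- Real-data accuracies from gated datasets are not reproduced here; the
  acceptance experiments validate structural and statistical properties on
  synthetic data only.
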