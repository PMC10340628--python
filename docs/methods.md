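# Methods

This note documents the models, the protocol, the synthetic data, and the
numerical choices behind `pdscreen`, in the spirit of a model-description
appendix. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Problem setting

Input: one spontaneous-monologue recording per speaker (mono WAV,
resampled to 8 kHz, peak-normalized) and its transliteration (token
sequence), with a binary label PD / HC. Output: a per-speaker decision
score in [0, 1] (PD = positive class) and cross-validated metrics.

## Audio front end

Recordings are polyphase-resampled to 8 kHz and peak-normalized (all-zero
signals pass through unchanged; codec-style amplitude processing is out of
scope). Each recording is segmented into 500 ms chunks with 250 ms shifts;
`floor((L-W)/S) + 1` chunks, the trailing remainder is dropped — for the
~10 s and longer recordings used here the loss is negligible and keeps all
chunks homogeneous.

Each 4000-sample chunk maps to a 128-band log-mel spectrogram. The STFT
parameters are package choices (the representation size 128x63 constrains
but does not determine them): Hann window of 512 samples (64 ms), hop 64,
centered reflection padding, 512-point FFT, 128 triangular mel filters
(HTK mel scale) spanning 0–4000 Hz, natural log with floor 1e-10. This
yields `floor(4000/64) + 1 = 63` frames, hence 128x63. With a 512-point
FFT the narrowest low-frequency filters can cover no FFT bin and stay
empty; they clamp to the log floor and carry no information, which is
harmless for the encoders. Log-mel inputs to the 2-D encoder are z-scored
per recording (statistics from that recording only, so standardization can
never mix speakers or folds).

## Speech encoders

**1D-CNN+LSTM.** Input: the raw 4000-sample chunk (the temporal-domain
representation; chosen deliberately to contrast with the spectrogram
encoder). Two 1-D convolutions with 16 and 32 channels (kernels 16 and 8,
strides 4 — strides are a package choice that keeps the recurrent sequence
short), each followed by temporal max pooling of size 2, giving a
61-step, 32-channel sequence into two 64-cell LSTM layers; the last hidden
state feeds dropout and a 2-class softmax head. LSTM gates follow the
standard formulation with logistic gates on `[h_{t-1}, x_t]`; the packed
implementation initializes the forget-gate bias to 1.

**Residual 2-D CNN.** Input: the standardized 128x63 log-mel chunk. Stem:
7x7 stride-2 convolution with 16 channels + 3x3 stride-2 max pooling (the
canonical residual-network stem; the stride is a package choice — it also
keeps numpy training tractable). Trunk: three stages of two residual
blocks with 16/32/64 feature maps; each block is conv3x3–BN–ReLU–conv3x3–BN
plus the identity skip, with a 1x1 stride-2 projection skip when a stage
changes width (stages 2 and 3). Global average pooling per channel gives
the 64-d chunk embedding, then dropout and the 2-class head. Learned
convolutions use the framework cross-correlation convention; the
flipped-kernel textbook convolution is exposed as `conv2d_apply` and used
as the reference oracle in tests.

**Pretrained adapter.** Any object exposing `frame_embeddings(waveform,
rate) -> (T, D)` plugs in; the speaker/chunk representation is the
temporal mean. The shipped `LogMelProjectionEmbedder` is a deterministic
synthetic stand-in (a fixed seed-determined random projection of log-mel
frames through tanh, D=768 by default); it carries whatever class signal
the mel frames carry and requires no downloads. Real self-supervised
models can be adapted behind the same interface.

Per-chunk class probabilities are averaged into the speaker score.

## Language encoders

Tokenization: lowercase, punctuation stripped, whitespace split. The
embedding matrix `M (n x d)` has one row per token, via a pluggable
embedder: a lookup table (word2vec text format supported), the topical toy
embedder, or a context-dependent plugin (word vectors as the mean of
subword/neighbor vectors; a deterministic toy contextual embedder is
provided). Out-of-vocabulary tokens get a pseudo-random vector seeded by a
stable hash of the token — reproducible across processes, and no word is
silently dropped.

**Functionals.** Per-dimension mean, *population* (ddof=0) standard
deviation, skewness, and raw (non-excess) kurtosis, stacked to `4d`.
Zero-variance dimensions define skewness = kurtosis = 0 to avoid NaN
propagation. These conventions are stated so the test oracles agree
exactly.

**n-gram CNN.** For each width `w` in {2,3,4}, `F` filters of shape
`w x d` (default F=64 per width — the filter count is a package choice)
slide over token positions (valid convolution, `n-w+1` positions); max
pooling per filter; the concatenated maxima (length `3F`) are the language
embedding, followed by dropout and a single fully connected softmax head.
Transcripts shorter than the widest kernel are zero-row padded, and
per-sample masking restricts the max to genuine positions.

## Fusion

- **Early:** speaker-level speech vector (temporal mean of chunk
  embeddings) concatenated with the language embedding; features are
  z-scored per dimension with training-fold statistics before the SVM.
- **Joint:** per-speaker GMM supervector concatenated to the language
  embedding just before the text CNN's head; training back-propagates the
  loss into the text filters while the supervector is a fixed input.
- **Late:** the 2-d vector [speech score, language score] trains and tests
  an SVM.

**GMM supervectors.** A diagonal-covariance Gaussian mixture is fitted
*per speaker* to that speaker's chunk embeddings (the simpler reading of
per-speaker encoding; universal-background-model MAP adaptation is an
extension hook). EM with seeded k-means initialization, variance floor
1e-6, at most 200 iterations, stopping when the log-likelihood gain drops
below 1e-6; the log-likelihood history is recorded and asserted
non-decreasing at every fit. Components are sorted by their mean vectors
(first coordinate primary, lexicographic) so the supervector layout
`[mu_1..mu_K | diagSigma_1..diagSigma_K]` is stable across refits. K=8 is
the default (K in {2,4,8} supported). With K=1 the supervector reduces to
the sample mean and population variance. Supervectors default to the
pretrained-adapter chunk embeddings; any chunk-embedding source works.

## Evaluation protocol

Stratified speaker-independent k-fold (k=10): speakers are shuffled within
class and dealt round-robin through a seed-permuted fold order, so fold
sizes differ by at most one and no speaker ever contributes to both sides
of a fold. All fitted quantities are training-fold-only by construction:

- feature standardization and SVM grid search see training speakers only;
- deep models carve a stratified 20% validation split out of the training
  speakers for early stopping and hyper-parameter selection;
- GMM supervectors are per-speaker (own chunks only) and are standardized
  with training-fold statistics.

Each fold's report records which speakers entered each fitted quantity
(`fit_log`), and the test suite asserts the no-leak property on every fold
of every branch.

SVMs: RBF kernel, C in {0.001,...,100} and gamma in {0.0001,...,100} (42
pairs), selected by mean accuracy over an inner stratified 5-fold split of
the training speakers; ties go to the smaller C, then smaller gamma —
nested selection is used because tuning on test folds would leak. Decision
values are mapped to [0,1] by a Platt-style logistic fit (Newton
iterations with smoothed targets) on the training fold, so score
histograms are comparable across models.

Deep training: Adam (lr 1e-3), cross-entropy, batch 32, up to 200 epochs,
early stopping with patience 40 (the best-validation-loss checkpoint is
restored), dropout {0.2,0.4,0.6} and coupled L2 {0.0001,0.005,0.001}
selectable by validation loss. Metrics: accuracy, sensitivity (PD
recall), specificity (HC recall), F1 of the PD class, in percent, at
threshold 0.5 with ties counted positive; fold aggregates are mean ±
population standard deviation.

**Desk-scale regimen.** The end-to-end synthetic experiments (tests,
acceptance script, CLI default) use reduced problem sizes chosen as
package defaults: 20 PD / 20 HC speakers, 10 s recordings, 8 chunks per
speaker for the 2-D encoder (evenly subsampled), speech CNNs trained up to
6 epochs with patience 3, text/joint CNNs up to 60 epochs with patience 10,
both at a single grid point (dropout 0.2, L2 1e-4). The synthetic class
effects saturate well before these budgets; the full regimen remains the
`TrainConfig` default and is exercised on tiny data in the unit tests.

## Synthetic cohort

The generator emulates a monologue corpus with two independent,
controllable class effects:

- **Audio:** a source–filter voice — a glottal pulse train at a
  speaker-specific f0 ~ N(120, 15) Hz through two resonators (600 and
  1200 Hz), with cycle-to-cycle jitter, per-cycle shimmer, additive
  aspiration noise, and a slow loudness modulation. HC baseline: jitter
  0.5%, shimmer 3%, noise 0.02. The PD class adds deltas (defaults
  +2% jitter, +10% shimmer, +0.10 noise) scaled by `audio_effect`; the
  baseline values sit in the normal range and the PD values in the
  clearly pathological range of perturbation measures. At
  `audio_effect=0` the classes are generatively identical.
- **Text:** tokens drawn from two disjoint synthetic topic vocabularies
  (60 pronounceable tokens each, Zipf-like within-topic frequencies);
  the class shifts the topic mixture weight by lambda (`text_effect`,
  default 0.8): HC draws topic A with probability 0.5 + lambda/2, PD with
  0.5 - lambda/2. Transcript length ~ N(80, 20) words shared across
  classes, so word counts carry no class signal (verified by Mann-Whitney
  in the tests).

Default duration is 10 s (a ~90 s monologue is supported; chunk counts
scale linearly and nothing in the method depends on absolute duration).
The toy word embedder generates unit-norm vectors clustered around one
random centroid per topic, so both language routes have genuine topical
signal.

What the generator does **not** emulate: real dysarthric phenomenology
beyond jitter/shimmer/noise (no articulatory imprecision, pauses, or
prosodic flattening), ASR transcription errors, recording-channel
variability, age/sex confounders, or any correlation between modalities
within a speaker. Passing pipelines therefore demonstrate that the
machinery is correct, leak-free and sensitive to a controlled effect — not
clinical accuracy.

## Numerical choices and degenerate inputs

- All model randomness flows through explicitly seeded generators; repeated
  runs with one config and seed reproduce reports bit-for-bit on one
  machine.
- The numpy layers default to float32; gradient-check tests switch to
  float64 for tight finite-difference tolerances.
- Empty recordings, empty transcripts, empty embedding-frame sequences,
  single-class training sets, upsampling requests, and K larger than the
  number of chunk embeddings raise immediately with specific messages.
- Zero-variance functional dimensions, all-zero chunks (log floor), and
  transcripts shorter than the widest n-gram kernel (zero-row padding) are
  defined, not errors.
- SVM inner model selection degrades gracefully when a class has fewer
  members than the inner fold count (fewer folds; a fixed mid-grid
  fallback below two).

## Known limitations

- The numpy core trains on one CPU; it is deliberately minimal (no GPU, no
  graph optimizations) and sized for desk-scale cohorts.
- The mel filterbank at 512 FFT bins leaves some low-frequency filters
  empty (see above).
- Per-speaker GMMs with K=8 on ~39 chunk embeddings are heavily floored;
  they encode coarse per-speaker structure rather than well-resolved
  mixtures — consistent with their role as a fixed-length encoding.
- The pretrained-embedder stub is a synthetic stand-in; conclusions about
  real self-supervised representations require plugging in a real model.
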