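# Methods

## Model and assumptions

The framework treats interpersonal vocal synchrony as a distribution-level
phenomenon: if two conversation partners entrain, the distribution of one
speaker's frame-level acoustic features drifts toward the other's over the
session. A bottleneck autoencoder trained on speaker X's frames is a
one-class model of X's feature distribution; reconstruction error on
unseen frames measures their novelty relative to that distribution. The
cross-partner reconstruction-error trace — X's model applied to partner
Y's frames in temporal order — therefore falls over time when Y's
distribution approaches X's, and the fitted linear trend of that trace is
the synchrony statistic.

Assumptions worth making explicit:

- Frames are treated as independent instances both in training and
  evaluation; temporal dependence within a turn is ignored by design. The
  trace's temporal structure comes only from the ordering of test frames.
- The autoencoder must generalize from X's frames without memorizing them,
  and its error must respond monotonically to distributional distance.
  This novelty property is tested directly (Gaussian training data, test
  sets mean-shifted by 0/1/2 sd: mean RMSE must increase in the shift).
- A linear trend is a deliberate simplification of however synchrony
  actually accumulates; the slope sign and magnitude are the readout, not
  a fitted dynamical model.

## Pipeline

1. **Features.** Delimited numeric tables (or openSMILE ARFF), one row per
   10 ms frame. Low-level-descriptor tables are standardized per recording
   to zero mean and unit population standard deviation per dimension
   (removing static channel/environment offsets between recordings);
   dimensions with σ < 1e−8 are zeroed rather than divided by a vanishing
   scale. High-dimensional CNN spectrogram embeddings
   (`feature_set_name="deep_spectrum"`) are consumed raw — rescaling them
   degrades reconstruction — and the pipeline enforces this. 65-dim base
   LLD tables are delta-augmented to 130 dims with plain first differences
   (d[0] = 0); tables that already carry toolkit-computed deltas should
   skip this step, since regression-window deltas differ numerically.
2. **Segmentation.** Each frame is assigned to the speaker whose turn
   interval [start, end) contains the frame's *start* time (half-open,
   0-based). Silence frames belong to nobody; frames claimed by both
   speakers (overlapping speech) are dropped by default (`"both"` keeps
   them on both sides for sensitivity analysis). Original frame times are
   retained so traces keep wall-clock positions.
3. **Autoencoders.** Palindromic fully-connected bottleneck nets. 130-dim
   input uses 130–64–32–12–32–64–130 and 4096-dim input
   4096–2048–1024–512–1024–2048–4096; any other dimensionality d gets
   encoder widths ⌊d/2⌋, ⌊d/4⌋, ⌊d/8⌋ mirrored. ReLU hidden activations
   with a linear output layer (standard for real-valued reconstruction;
   tanh and linear are config options), He-uniform initialization, zero
   biases. Training: minibatch MSE with Adagrad (lr 0.01, ε = 1e−10),
   batch 256, 512 epochs, per-epoch reshuffling, last partial batch kept,
   no early stopping or validation split. All randomness flows from one
   integer seed; two runs with the same seed and config are bit-identical.
   Models persist to a single .npz archive (architecture, weights, config,
   loss curve) and round-trip exactly.
4. **Synchrony statistic.** Per-frame RMSE across dimensions, then OLS of
   RMSE against session-normalized time t ∈ [0, 1] (default), or the
   mean-first-difference slope, implemented via its telescoped closed form
   (y_n − y_1)/(n − 1) per step so the identity with the mean of
   consecutive differences is exact, rescaled to the same normalized-time
   axis. Normalized time makes slopes comparable across sessions of
   different length but means magnitudes are not comparable to analyses
   that regress on seconds or frame index. No smoothing is applied before
   regression by default; a moving-average option exists for exploration.
5. **Aggregation.** Group mean slope over all 2n subject slopes, and the
   Pearson correlation of (slope_A, slope_B) pairs across the group's
   sessions, where A is the first speaker appearing in each transcript.
   PCC is undefined for a single session (NaN with a warning, or an error
   when explicitly required).
6. **Linguistic measures.** Sessions are halved by time (turns assigned by
   start time, half-open at the midpoint); tokenization is lowercasing,
   punctuation stripping and whitespace splitting — deliberately minimal
   and language-agnostic, no stemming or stop-word removal. The usage
   score sums both speakers' counts of shared word types and normalizes by
   the mean segment length, giving range [0, 2] with 2 iff every token's
   type is shared; this normalization is chosen so that scores above 1 are
   attainable (a simple shared fraction cannot exceed 1). Type-level
   Jaccard and histogram-intersection variants are available behind a
   switch but are not the default. Embedding similarity is the cosine of
   the two speakers' mean in-lexicon vectors within the same half;
   out-of-vocabulary tokens are skipped and reported as coverage. Lexicons
   load from word2vec text format; when none is supplied, embedding cells
   render as em dashes.

## Synthetic study conditions

The generator emulates exactly the structure the method assumes. Speakers
alternate fixed 5 s turns over a 60 s session; A's frames are i.i.d.
N(μ_A, σ²I) throughout, B's mean moves linearly in session time from μ_B0
toward μ_A by the fraction κ ∈ [0, 1] of the initial gap (variance fixed
— only the mean entrains). Defaults: 16 feature dimensions, 10 ms frames,
σ = 1, initial gap of 2σ per dimension — large enough that partner frames
are clearly novel at session start while distributions still overlap.
Only B converges by default, mirroring the directional-dominance case; a
mirrored config swaps the roles. Transcript tokens are drawn per turn from
a shared pool with probability 0.2 in the first half and 0.8 in the
second (else from speaker-private pools), emulating rising lexical
entrainment. The synthetic lexicon places same-topic words within a 30°
cone of a topic center on the unit sphere.

What the generator does **not** emulate: temporal dependence within turns
(real LLDs are strongly autocorrelated), non-Gaussian and multimodal
feature distributions, session-level nonstationarity other than the mean
drift, overlapping speech, silence, and any prosodic realism. Passing
tests therefore show that the statistic recovers distribution-mean
convergence under the model's own assumptions — not that real
conversational corpora would yield the same effect sizes.

## Numerical choices and test problem sizes

- Population (1/N) standard deviation in standardization; σ < 1e−8 ⇒
  zero output.
- Mel spectrogram: 500 ms Hann windows, 128 triangular HTK-scale Mel
  filters, log10 power with a 1e−10 floor. The default hop is 10 ms
  (matching the LLD frame rate); a literal-overlap reading (hop 490 ms)
  is available via `hop_seconds`.
- OLS slope via centered closed form; agreement with a normal-equations
  solve is tested to 1e−10 over random traces up to n = 1000.
- Training-seed derivation: the two partner models of a session train
  under seeds 2s and 2s+1; pipeline runs derive per-session seeds from
  the run seed and a CRC32 of the session id (salt-free, hence
  reproducible across processes).
- Test and demonstration runs use reduced training (8–64 epochs) and 16
  dimensional frames; the slope statistic's response to κ is already
  unambiguous there, and the library default remains 512 epochs. The
  autoencoder capacity check uses 10 frames spanning a rank-2 subspace —
  matching the generic rule's 2-unit bottleneck, since a capacity check
  is informative only within model capacity — with tanh hidden units
  (Adagrad with ReLU units plateaus well short of memorization on
  zero-mean data) and 8192 epochs.

## Known limitations

- Slope magnitudes depend on the time axis convention (normalized time
  here) and on feature scaling, so cross-study comparisons need care.
- With heavily imbalanced speaking time the two models train on very
  different sample sizes; no correction is applied.
- The per-frame independence assumption means the effective sample size
  of a trace is much smaller than its frame count; no significance tests
  on slopes are provided, deliberately.
- Overlapping speech is dropped rather than attributed, which biases
  against highly interactive stretches of conversation.
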