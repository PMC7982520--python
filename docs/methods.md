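# Methods

`erpdecode` decodes single-trial decisions (accept / reject) from epoched
multichannel EEG with a two-stage pipeline: an exact t-SNE embedding of
every (trial, channel) time series into five dimensions, followed by an
LSTM sequence classifier reading the embedded channels in montage order.
This note records the models, the numerical choices, and what the
synthetic benchmark does and does not demonstrate.

## Data model and preprocessing

Epochs are `trials x channels x samples` arrays in microvolts, cut from
-200 to +800 ms around stimulus onset at 1,000 Hz (1,000 samples), with a
binary behavioural label per trial. The preprocessing chain runs in a
fixed order:

1. **Ocular regression** (optional): per trial, each EEG channel's
   least-squares projection onto the EOG channels (plus intercept) is
   subtracted. This is an ordinary-least-squares stand-in for vendor
   regression correction; residuals are exactly orthogonal to the EOG
   regressors.
2. **Baseline correction**: subtract the mean of the pre-stimulus
   interval (-200...0 ms) per trial and channel. Idempotent by
   construction.
3. **Zero-phase low-pass**: 2nd-order Butterworth at 30 Hz applied
   forward-backward (`sosfiltfilt`, odd-reflection padding), so the *net*
   roll-off is 24 dB/octave with no phase delay. The net amplitude
   response is |H(f)|^2 = 1/(1 + (f/30)^4), which the tests verify at
   50 Hz to within 5 %.
4. **Amplitude rejection**: a trial is dropped when any channel leaves
   the +-80 uV window. The alternative reading of the criterion
   (max - min > threshold) is available as `mode="peak_to_peak"`. Values
   are never modified, only trial membership.
5. **Sweep gate**: a condition is kept only with *strictly more than* 30
   retained trials.

Every step is per-trial and label-free (except the final count gate), so
the chain is applied once before cross-validation; per-fold application
would be mathematically identical.

## t-SNE feature extraction

Each (trial, channel) series is one datapoint. Conditional affinities use
Gaussian kernels whose per-point bandwidth is bisected until the row
perplexity 2^H matches the target (default 30, clamped to (n-1)/3; default
tolerance 1e-7 bits, 64 bisection steps with dynamic bracket growth).
Distances are shifted per row before exponentiation so duplicate rows and
distant outliers never produce non-finite affinities.

The default cost is the canonical symmetric formulation: joint
probabilities p_ij = (p(j|i)+p(i|j))/2n against joint-normalized
Student-t similarities, minimized with the reference optimizer - N(0, 1e-4)
initialization, early exaggeration x4 for 50 iterations, momentum 0.5
switching to 0.8 at iteration 250, per-parameter adaptive gains, learning
rate 100 (or `"auto"` = max(100, n/12) for large n), 1,000 iterations. A
per-point "conditional" cost variant is selectable; its gradient is the
exact derivative of sum_i KL(P_i||Q_i) under row-normalized Student-t
similarities. In both variants the analytic gradient is held to central
finite differences of the implemented cost at 1e-4 relative - that
agreement is the binding correctness contract. Student-t similarities are
floored at 1e-12 inside logarithms.

Large inputs run in single precision through fused pairwise kernels
(numba) that never materialize the Q matrix; the plain numpy path is the
reference and the two are tested against each other term by term. With a
seeded random initialization the embedding is *not* equivariant to
datapoint permutation (the same seed hands the same initial coordinates to
different points); the affinity stage is, and is tested for it.

Embedding is transductive by default: one joint t-SNE over all trials, an
unsupervised computation that never sees labels, so no label leakage is
possible. For strict generalization measurement an inductive mode fits
t-SNE on training rows only and places held-out rows by a Gaussian-kernel
weighted average of training embeddings (bandwidth defaults to half the
median held-out-to-train distance).

## Sequence classifier

Sequences are ordered over channels (montage order defines step order),
five embedded features per step. The LSTM cell follows the standard gate
equations on the concatenation [h_{t-1}, I_t]; the default network is
LSTM(80, sequence-to-label) -> dropout 0.2 (inverted scaling; identity at
evaluation) -> fully connected (2) -> softmax, trained with mean
cross-entropy under SGDM (velocity = momentum*velocity - lr*grad).
Glorot-uniform weights, zero biases, momentum 0.9. Backpropagation through
time is hand-derived and every parameter's gradient is held to central
finite differences at 1e-4 relative, including through a frozen dropout
mask.

Training runs exactly epochs x ceil(n/batch) iterations with per-epoch
shuffling under the training seed; identical seeds reproduce runs
bit-for-bit. The *reference* schedule (learning rate 0.001, 20 epochs,
batch 100) is kept as the `TrainConfig` default; the evaluation harness
instead uses learning rate 0.01 and 60 epochs, because at desk-scale trial
counts (a few hundred trials) the reference schedule amounts to only a few
dozen SGDM updates and no freshly initialized network converges. The
harness also z-scores features with training-set statistics before
classification. These harness settings apply identically to every
compared method, keeping comparisons paired.

## Comparison methods

Sharing the preprocessing, folds and training harness: PCA and
FastICA-style (tanh-contrast, deflation) five-component extractors feeding
the same LSTM head; a deep LSTM with a 120-unit sequence-to-sequence
front-end trained end-to-end; an RBF-kernel SVM (SMO solver on the
soft-margin dual) and a 20-10 tanh back-propagation network on the
flattened t-SNE features; and a CNN (20 filters 5x5, batch-norm, ReLU, no
pooling, dense 2) on channel-averaged Morlet scalograms (32 log-spaced
scales covering 1-30 Hz, matching the filtered band). The printed
one-unit-plus-softmax BP head is degenerate (a softmax over one unit is
constant); the default head uses two units, with the literal variant
available as `bp_config(output_units=1)`.

## Cross-validation

"k-fold with a fresh 20 % test set per fold" cannot be a disjoint
partition, so the default scheme is k = 10 repeated random sub-sampling
rounds: each round draws test = floor(0.2 n) trials (stratified by label),
then splits the rest 9:1 - train = floor(0.9 - rest), remainder to
validation. Classical disjoint k-fold and leave-subject-out schemes are
first-class alternatives. Summaries report mean and population SD
(divide by k) over valid folds; folds that lose a class are flagged and
excluded with a warning.

## Synthetic benchmark

The generator emulates the statistical structure the decoder relies on:
1/f background (spectral shaping by f^-1/2, DC zeroed, scaled to 3 uV
RMS), 2 uV white noise, a 2 uV 10 Hz oscillation with random phase, and -
for accept trials only - an 8 uV Gaussian-windowed late positivity
(center 500 ms, FWHM 200 ms) on eight centro-parietal channels of the
16-channel montage (Pz strongest). Optional ocular artifacts are slow
+-120 uV half-waves on frontal channels at a configurable rate; at the
default rejection threshold they are caught by the +-80 uV criterion,
which the tests verify end to end. No volume conduction or realistic
blink morphology is claimed: passing the benchmark shows the pipeline
recovers a distributed, time-locked amplitude effect from colored noise
at realistic SNR, not that it reproduces results on any real recording.

The headline study (the acceptance script and `run_synthetic_study`) uses
desk-scale sizes chosen to keep an exact O(n^2) t-SNE over
trials x channels datapoints in the minutes range on one core: 200 trials
per class (6,400 datapoints at 16 channels), three generator seeds, two
Monte-Carlo folds each, t-SNE at 200 iterations in single precision with
auto learning rate, perplexity 30. Controls run at the same trial count:
a zero-effect dataset and a label-shuffled copy of the real features must
both score near chance (small-sample cross-validation is known to sit
slightly *below* 0.5 under the null; the band 0.5 +- 0.07 accommodates
this). The channel-subset experiment scores the same data restricted to
the nested 4-electrode midline montage against the full 16. Method
ordering is compared on mean test accuracy: at these sizes a 9:1
validation split holds only ~30 trials, too few to resolve orderings.

One caveat the benchmark makes explicit: at the generator's default
signal-to-noise ratio the class effect is close to linearly separable in
the embedded features, so the recurrent classifier and the
back-propagation baseline both saturate near ceiling and their ordering
comes down to one or two test trials per fold — it is not reliably
resolvable at desk scale. Orderings between saturated methods on this
benchmark should not be over-interpreted; the benchmark's discriminating
power lies in the effect-vs-null contrast and the channel-subset trend.

## Known limitations

- Exact t-SNE is O(n^2) in memory and time; tens of thousands of
  datapoints are the practical ceiling (no Barnes-Hut approximation).
- The out-of-sample map is a kernel average, not a parametric t-SNE; far
  outliers collapse toward the training centroid.
- Preset montages (active4 c active16 c active32 c active60) are standard
  10-20/10-10 expansions, fully user-overridable; they are a convention,
  not a claim about any particular amplifier layout.
- The EDF reader epochs continuous recordings around a supplied event
  table; it does not parse annotations embedded in the EDF itself.
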