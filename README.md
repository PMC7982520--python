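# erpdecode

Single-trial decoding of binary decisions from epoched EEG, built around a
**recurrent t-SNE** pipeline: every (trial, channel) time series is
embedded into five dimensions by an exact, from-scratch t-SNE, and the
per-trial sequence of embedded channel features is classified by a
from-scratch LSTM network. The package targets researchers who want a
fully inspectable implementation of this two-stage decoder — every
gradient is hand-derived and checked against finite differences — along
with the comparison architectures, preprocessing chain, evaluation
harness and synthetic ERP generator needed to study it end to end.

## The method

High-dimensional similarities between datapoints D_i (single-channel
epochs) are Gaussian conditional probabilities

```
p(j|i) = exp(-||D_i - D_j||² / 2σ_i²) / Σ_{k≠i} exp(-||D_i - D_k||² / 2σ_i²)
```

with each σ_i calibrated by bisection so the row perplexity 2^H matches a
common target (default 30). Symmetrized joint probabilities
p_ij = (p(j|i)+p(i|j))/2n are matched against Student-t similarities in
the embedding space, q_ij ∝ (1 + ||d_i − d_j||²)⁻¹, by minimizing the
Kullback–Leibler divergence C = Σ p_ij log(p_ij/q_ij) with momentum
gradient descent,

```
∂C/∂d_i = 4 Σ_j (p_ij − q_ij)(d_i − d_j)(1 + ||d_i − d_j||²)⁻¹ .
```

The embedded 5-vectors, ordered over channels, feed an LSTM
(sequence-to-label, 80 hidden units, gates f_t, U_t, O_t, candidate c̄_t,
cell C_t = f_t∗C_{t−1} + U_t∗c̄_t, h_t = O_t∗tanh C_t) with dropout,
a fully connected layer and a softmax head, trained by SGDM with
cross-entropy. Six comparison methods (PCA, ICA and deep-LSTM feature
extractors; SVM-RBF and back-propagation classifier heads; a CNN on
Morlet scalograms) share the same folds and training harness. See
`docs/methods.md` for assumptions, defaults and limitations.

## Worked example

```python
import numpy as np
from erpdecode import simulate, preprocess, evaluation

# two-condition synthetic ERP study: 8 uV late positivity on 8 of 16
# channels, 1/f + white + alpha background, 5% ocular artifacts
cfg = simulate.SynthConfig(n_trials_per_class=200, artifact_rate=0.05, seed=1)
epochs, truth = simulate.generate_epochs(cfg)

clean, report = preprocess.preprocess_pipeline(epochs)   # baseline, 30 Hz, +-80 uV
print(f"kept {clean.n_trials}/{epochs.n_trials} trials")

plan = evaluation.make_splits(labels=clean.labels, k=2, seed=1)
summary = evaluation.evaluate_pipeline("recurrent_tsne", clean, plan, seed=1)
print(f"mean validation accuracy {summary.mean_validation:.3f} "
      f"+- {summary.sd_validation:.3f}")
print(f"mean test accuracy       {summary.mean_test:.3f}")
```

Output from this exact script:

```
kept 382/400 trials
mean validation accuracy 0.952 +- 0.016
mean test accuracy       0.980
```

18 of 400 trials carried injected >80 uV ocular artifacts and fell to the
amplitude criterion. The decoder recovers the class effect at 98 % test
accuracy on this synthetic study; on zero-effect data the same pipeline
scores at chance (see the acceptance script below).

The same pipeline is scriptable from the shell:

```
erpdecode simulate --seed 1 --out runs/raw --trials-per-class 200
erpdecode preprocess --inp runs/raw --out runs/clean
erpdecode evaluate   --inp runs/clean --out runs/eval --folds 10
erpdecode compare    --inp runs/clean --out runs/cmp --methods recurrent_tsne,tsne_bp
erpdecode topo       --inp runs/clean --out runs/topo
```

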