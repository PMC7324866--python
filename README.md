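# eegmpm

Classification of single-channel epileptic EEG segments into healthy,
interictal (between seizures) and ictal (during seizure) regimes, for
researchers working on automated seizure detection.

The method combines:

1. **Linear + non-linear features** per segment: the *wave coefficient*
   of each wavelet subband — the mean absolute first difference
   `F = (1/(M−1)) Σ |a(j+1) − a(j)|` of the coefficient sequence — plus
   approximate entropy `AE(m, r)`, sample entropy `SE(m, r) = −ln(A/B)`
   and multiscale permutation entropy `h_P^s = H_P^s / ln(m!)` at scales
   `s = 1..5`.
2. **An RBF hidden layer**: features are lifted into the activations
   `f_k(x) = exp(−‖x − c_k‖² / σ_k²)` of `K` Gaussian neurons whose
   centers come from k-means and whose widths from a nearest-centers
   heuristic.
3. **Pairwise minimax probability machines (MPM)**: for each class pair,
   the hyperplane `wᵀz = b` solving
   `min_w √(wᵀΣ₊w) + √(wᵀΣ₋w)  s.t.  wᵀ(μ₊ − μ₋) = 1`,
   which maximizes the distribution-free lower bound
   `α = 1 / (1 + (√(wᵀΣ₊w) + √(wᵀΣ₋w))²)`
   on both classes' correct-classification probability given only the
   classes' means and covariances in the mapped space. `α` doubles as a
   separability index for the pair.
4. **An α-ordered one-against-one exclusion tree**: the most separable
   pair is compared first; each comparison permanently excludes the
   losing class, so any segment is classified in exactly `M−1` binary
   decisions with no voting ties or rejections.

A built-in synthetic generator produces the three regimes (alpha-band
background, spiky interictal, 3–5 Hz rhythmic ictal spike-wave) with
controllable separability, and segments in the Bonn single-column ASCII
format (4,097 samples at 173.61 Hz) can be read directly.

## Worked example

```python
from eegmpm import SynthConfig, generate_dataset, split_train_test
from eegmpm.model import EEGClassifier

data = generate_dataset(SynthConfig(n_per_class=30, seed=7))   # 3 regimes
train, test = split_train_test(data, 0.5, seed=7)              # 1:1 split
results = EEGClassifier(train, n_neurons=12, seed=7).fit()
print(results.summary())
ev = results.evaluate(test)
print(f"test accuracy: {ev['accuracy']:.3f}")
```

prints

```
EEG MPM exclusion-tree classifier
=================================================
classes:            [0, 1, 2]
features:           12 (db4, 4 levels; m=2, r=0.2; MPE m=3, scales=[1, 2, 3, 4, 5])
RBF neurons (K):    12
child rule:         winner_restricted
seed:               7

Pairwise separability (alpha), best first:
-------------------------------------------------
  alpha(0:2) = 0.9971
  alpha(1:2) = 0.9964
  alpha(0:1) = 0.9413
-------------------------------------------------
tree root pair:     (0, 2)  [global max alpha]
decisions per classification: 2

test accuracy: 0.978
```

Reading: healthy (0) vs ictal (2) is the most separable pair
(α ≈ 0.997, i.e. the worst-case correct-classification probability for
that comparison is 99.7%), so it sits at the tree root; healthy vs
interictal is hardest (α ≈ 0.94). Each test segment is decided in two
binary comparisons, and 97.8% of held-out segments are labeled
correctly. `results.evaluate(...)` also returns per-class
sensitivity/specificity and one-vs-rest ROC curves (here all AUC ≈ 1.0);
`results.plot_roc(ev)` draws them.

The same workflow is available from the shell:

```bash
eegmpm synth --n-per-class 30 --seed 7 --out data/
eegmpm features --in-dir data/ --out features.csv
eegmpm train --features features.csv --n-neurons 12 --seed 7 --out model.json
eegmpm evaluate --model model.json --in-dir data/ --out-dir report/
```

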