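# Methods

## Problem and pipeline

The package classifies short single-channel EEG segments into discrete
regimes (healthy background, interictal, ictal). Each segment is
z-scored, summarized by a fixed-order feature vector, lifted through a
radial-basis-function (RBF) hidden layer, and classified by a tree of
pairwise minimax probability machines (MPMs). The stages are
independently usable; `fit_pipeline` / `EEGClassifier.fit()` compose
them deterministically from a seed.

## Features

**Wave coefficient.** For each wavelet subband the mean absolute first
difference of the coefficient sequence,
`F = (1/(M−1)) Σ_{j=1}^{M−1} |a(j+1) − a(j)|`, a waveform-variability
measure. It is translation-invariant and absolutely homogeneous. The
default decomposition is Daubechies-4 at 4 levels (the common choice in
epilepsy EEG work: at 173.61 Hz the detail bands split near
87/43/22/11/5.4 Hz, bracketing the clinical delta–gamma ranges), in
periodization mode so an orthogonal wavelet preserves energy exactly.
One coefficient is computed per subband (d1..d4 plus the final
approximation); `levels=0` degrades to a single full-band coefficient.

**Approximate entropy** `AE(m, r) = φ^m(r) − φ^{m+1}(r)` with
`φ^m = mean_i ln C_i^m(r)` and `C_i^m` the fraction of length-`m`
templates within Chebyshev distance `r` of template `i`, self-matches
included (the classic Pincus estimator). Small negative values are
possible and returned unclipped.

**Sample entropy** `SE(m, r) = −ln(A/B)` where `B` and `A` count ordered
template pairs (`i ≠ j`) within `r` at lengths `m` and `m+1`; both use
the `N−m` templates whose extension exists, self-matches excluded.
`A = 0` or `B = 0` raises an explicit undefined-entropy error instead of
returning an infinity.

**Multiscale permutation entropy.** The series is coarse-grained by
non-overlapping means of width `s` (remainder dropped; `s = 1` is the
identity), delay-embedded with dimension `m` and delay `τ`, each window
mapped to its ascending ordinal pattern with ties broken by earlier
index (stable sort — a constant signal is a single pattern with entropy
0), and the Shannon entropy of the pattern distribution normalized by
`ln(m!)` so `h_P ∈ [0, 1]`. The normalized value is invariant under any
strictly increasing transform of the signal.

Defaults: `m = 2`, `r = 0.2` (in units of the z-scored signal, i.e.
0.2·sd) for ApEn/SampEn; `m = 3`, `τ = 1`, scales 1–5 for MPE — the
standard settings in the entropy-of-physiological-signals literature.
All are exposed in `EntropyParams`.

Feature order is fixed and documented:
`wc_d1..wc_dL, wc_aL, apen, sampen, mpe_s1..mpe_sS`.

## Normalization

Segments are z-scored per segment (population 1/N standard deviation)
before feature extraction. This puts signals of arbitrary amplitude
units on a uniform scale and makes `r = 0.2` equal to 0.2·sd for every
segment. Before the RBF layer, the *feature* columns are additionally
z-scored with the training set's means/sds (stored in the pipeline), so
wave coefficients (scale ~0.1–5) and entropies (~0–1) contribute
comparably to the Euclidean distances inside the RBF kernel.

## RBF hidden layer

`f_k(x) = exp(−‖x − c_k‖²/σ_k²)`. Centers are k-means centroids
(fixed seed, 10 restarts); each width is the mean distance from its
center to its two nearest other centers, keeping neighbouring kernels
overlapping without tuning. The defaults use `K = 50` neurons for
desk-scale runs (the tests and acceptance runs use 10–16); `K` is fully
configurable, but note that the downstream covariance estimates live in
`K` dimensions, so `K` should stay well below the number of training
segments per class pair. Degenerate cases: `K = 1` uses the data mean
with width 1; duplicate centers fall back to width 1.

## Class moments and ridge

Per class, the mapped vectors' sample mean and 1/N covariance are
estimated, then regularized with `λI`, `λ = 10⁻⁶·trace/K + 10⁻¹²`. RBF
activations are highly collinear, and the MPM solve requires an
invertible-enough covariance; the absolute floor keeps even a point
mass (zero scatter) positive-definite, which also caps the separability
index strictly below 1.

## Minimax probability machine

For a pair with moments `(μ₊, Σ₊)`, `(μ₋, Σ₋)` the MPM solves

    min_w  √(wᵀΣ₊w) + √(wᵀΣ₋w)   s.t.   wᵀ(μ₊ − μ₋) = 1,

giving `κ* = 1/objective`, the bound `α* = κ*²/(1+κ*²)`, and threshold
`b* = wᵀμ₊ − κ*·√(wᵀΣ₊w)`, which equalizes the two classes' worst-case
guarantees. `α` is distribution-free: *any* distributions with those
moments misclassify with probability at most `1 − α` per class.

The default solver is the classic iterative least-squares scheme: with
`β± = √(wᵀΣ±w)` at the current iterate, minimizing the convex quadratic
majorant `wᵀΣ₊w/(2β₊) + wᵀΣ₋w/(2β₋)` under the linear constraint is a
single Cholesky solve, and the true objective decreases monotonically;
since the program is convex the fixed point is the global optimum.
Tolerance 10⁻⁸ on the objective, at most 200 iterations (typical
convergence: < 20). A second path (`method="reduced"`, BFGS on the
constraint's null space) exists as an in-package cross-check; the test
suite additionally verifies both against an independent SLSQP solve and
a 1-D closed form.

Decision rule: `class₊` iff `wᵀz ≥ b`, ties to `class₊`. Pairs with
coincident means cannot be solved; they are kept as degenerate `α = 0`
models whose decision falls back to distance-to-mean, so the tree stays
total.

## Exclusion tree

All `M(M−1)/2` pairwise MPMs are trained (each from its own pair's data
only; the lower class index is the positive side). The tree's root is
the globally max-α pair; at each node the losing class is excluded, and
the child comparison is the max-α remaining pair *involving the winner*
(`child_rule="winner_restricted"`, the default; `"global_max"` drops
the restriction). α ties break lexicographically, making the build
deterministic. Equal subproblems share a node, so the structure is a
rooted DAG with exactly `M` leaves and every root-to-leaf path of
length `M−1`; classification therefore always takes `M−1` binary
decisions and can never reject. Ordering by α puts the most reliable
comparisons first, which limits error accumulation along the path.

For per-class ROC curves a one-vs-rest score is derived from the bank:
class `c`'s score for a sample is the *minimum* signed margin in `c`'s
favour over the `M−1` pairs involving `c` (the weakest pairwise
evidence). The tree itself outputs only labels.

## Synthetic generator

Each profile is: a sinusoid at a frequency drawn uniformly from the
profile's dominant band (random phase), plus 1/f-shaped Gaussian noise
rescaled to the profile's noise sd, plus 60 ms raised-cosine spike
transients. Defaults:

| profile    | band (Hz) | amplitude | spikes            | noise sd |
|------------|-----------|-----------|-------------------|----------|
| healthy    | 8–13      | 1.0       | none              | 0.5      |
| interictal | 8–13      | 1.0       | Poisson 2.0/s, 4× | 0.5      |
| ictal      | 3–5       | 4.0       | 1 per cycle, 1.5× | 0.5      |

The interictal rate of 2 discharges/s was chosen so that every ~6 s
segment reliably contains spikes (`P(no spike) = e^{−11.8}`): with
substantially sparser spikes a fraction of "interictal" segments is
statistically indistinguishable from healthy background, which makes
the intended well-separated regime impossible regardless of classifier.
Rates in the range of a few per second are within what active epileptic
foci show interictally. `default_profiles(noise_scale)` scales every
noise sd, which is how the tests dial class overlap up.

The generator emulates the qualitative spectral/transient structure of
the three regimes, not real EEG: no 1/f² drift, no artifacts, no
non-stationarity, single channel, stationary spike statistics. Passing
tests therefore demonstrate correctness of the machinery and the
expected ordering of difficulty (healthy vs interictal hardest), not
clinical performance. Real Bonn-format recordings can be substituted
via `read_bonn_ascii` wherever segments are accepted.

Synthetic datasets are a pure function of `SynthConfig` (per-segment
seeds derive from a `SeedSequence` over (seed, class, index)). Default
segment length is 1,024 samples for desk-scale speed; files read from
disk keep their native length (4,097 for Bonn segments).

An optional duplicate-with-jitter oversampling utility exists for
imbalanced experiments; it is off by default and unused by the
pipeline.

## Splits and evaluation

`split_train_test` stratifies per class (1:1 by default, halves within
one segment per class), seeded. SEN/SPE are one-vs-rest per class with
macro averages; ACC is overall; metrics with empty denominators are
reported as `None`, never 0. ROC curves sweep the unique scores with
trapezoid area and always span (0,0)–(1,1).

## Problem sizes used

Tests run on 1,024-sample segments, 10–20 segments per class, and
`K = 5–16` neurons; the acceptance script uses 40 segments per class
(20 train / 20 test per class) and `K = 16`. These sizes keep a full
run in the order of a minute while leaving the per-pair moment
estimates well-conditioned (≥ 40 vectors per pair in ≤ 16 dimensions).

## Known limitations

- `α` is a bound on pairwise error given exact moments; with estimated
  moments it is optimistic for small samples.
- The winner-restricted child rule can pick a lower-α comparison than
  the unrestricted optimum (see `test_global_max_rule_differs_when_it_should`).
- Covariance estimation limits useful `K`: with the stated ridge the
  solver stays stable, but `K` near or above the per-pair sample count
  degrades the bound's meaning.
- ApEn is biased for short series; SampEn may be undefined (and raises)
  for very short or very irregular series at tight tolerances.
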