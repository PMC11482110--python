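# Methods

## Model

Two embeddings X ∈ R^{n×p₁}, Y ∈ R^{n×p₂} of the same ordered samples are
compared through kernel Gram matrices K and L. The empirical
Hilbert–Schmidt independence criterion is

HSIC(K, L) = tr(K H L H)/(n−1)², with H = I − (1/n)·11ᵀ,

the biased-but-consistent estimator (denominator (n−1)², not n² or the
unbiased U-statistic form); this choice is fixed so values are comparable
across studies that use the same estimator. CKA normalizes HSIC by the two
self-terms, which removes sensitivity to isotropic scaling and confines the
index to [0, 1] for positive-semidefinite Grams. Centering is computed by
row/column mean subtraction (O(n²)) rather than explicit multiplication by H.

Two kernels are provided.

**Linear kernel.** K = XXᵀ. Induced CKA is invariant to orthogonal
transformation of either embedding — appropriate for learners whose
representations are defined only up to rotation.

**RF partition kernel.** A fitted random forest defines a distribution over
partitions of a sample set: select a tree uniformly at random, then a
truncation depth uniformly on {0, …, max_depth(tree)}, and cut the tree at
that depth. k(x, y) is the probability that x and y occupy the same node
under this draw. Design choices the definition leaves open, fixed here:

* *Depth distribution*: uniform over {0, …, max_depth(selected tree)} — the
  simplest distribution consistent with the description of sampling trees
  and depths, and with the fact that at the root every sample shares one
  block. Depth 0 is included; it contributes a constant all-ones partition
  that centering later removes, so it only damps all centered entries
  uniformly.
* *Leaf-before-depth rule*: a sample whose leaf is shallower than the
  sampled depth keeps that leaf as its block, so every partition assigns
  every sample to exactly one block.
* *Tie routing*: `x ≤ threshold` goes to the left child (the scikit-learn
  convention). Block identity depends on this, so it is part of the
  contract.
* *Two RNG stages*: forest fitting and partition sampling consume
  independent, separately seedable streams; in `cka_rf` the two Grams'
  partition streams are spawned from one seed so they never interact.

Tree induction is not this package's contribution and is delegated to
scikit-learn's `RandomForestClassifier`; the partition extraction, sampling,
and Gram construction traverse the exposed tree arrays directly. Default
forest hyperparameters are standard practice (100 trees, unrestricted depth,
Gini, sqrt(p) features per split), all exposed via `ForestParams`.

The sampled Gram averages the co-membership indicator over `n_partitions`
draws (default 500); identical draws are grouped so each distinct
(tree, depth) pair is routed once. `exact_rf_gram` enumerates all
(tree, depth) pairs — the mean over trees of the mean over that tree's
depths — and is the exact expectation the sampler estimates; it refuses
forests with more than 10,000 (tree, depth) pairs by default. Sampled RF
Grams are not exactly PSD, so the raw CKA ratio can stray marginally outside
[0, 1]; the reported `cka` is clipped to the interval and the raw ratio kept
in `cka_raw`. A constant Gram (zero self-HSIC, e.g. a forest of single-leaf
trees) raises an error rather than returning 0, because a silent zero would
read as "independent".

## Rotational-invariance check

A learner is rotationally invariant when fitting on rotated data and
predicting rotated points reproduces the unrotated predictions for every
rotation. The check fits on S and on MS, compares predictions on X_test and
M·X_test, and passes when the disagreement fraction is at most a tolerance
(default 0.02, configurable) — finite-precision optimizers are only
approximately invariant, so the exact definition is relaxed to a prediction
margin. The learner's determinism is verified first by comparing two
identical fits. Reflections are excluded: generated matrices are Haar-like
elements of SO(p) (QR of a Gaussian matrix with sign-corrected diagonal and
a column flip into the det = +1 component). The fixture learners are
L2-regularized logistic regression run to tight tolerance (isotropic
penalty, hence invariant) and a single decision tree (axis-aligned, hence
not).

## Agreement metric

Inter-model agreement is the Matthews correlation coefficient applied to two
prediction vectors. The numerator and the four denominator factors are
computed in exact integer arithmetic before one square root. A zero
denominator factor (all predictions one class) returns 0.0 by the standard
convention, keeping validation pipelines running on degenerate forests.

## Synthetic data

The generators are pure functions of their arguments; one global seed fans
out into named substreams per generator (CRC-32 of the generator name as the
spawn key), so adding a generator never perturbs existing fixtures.

* **2-D blobs**: two balanced isotropic unit-variance Gaussians whose
  centers are `separation` apart along the first axis — the classic fixture
  on which an axis-aligned learner visibly breaks under rotation.
* **Fingerprint-like bits**: independent Bernoulli(density) entries,
  emulating the binary, sparse shape of circular fingerprints (default
  density 0.1).
* **Correlated pair / rho family**: a latent Gaussian signal z (n×4, rank
  chosen small so forests of moderate size can learn it) determines labels
  through a fixed linear rule; embedding 1 is z mapped through an
  orthonormal loading plus Gaussian noise (σ = 0.5, signal-to-noise of a
  comfortably learnable task); embedding 2 is rho·(z·A₂) + (1−rho)·noise
  with a second orthonormal loading, i.e. a rotated image of the same
  signal, except that rho = 1 with equal widths returns an exact copy.
  Holding the seed fixed while varying rho yields embeddings of the *same*
  samples with graded shared signal — the engine for correlating embedding
  similarity with prediction agreement without external data.

What these fixtures do not emulate: real fingerprint bit correlations,
class imbalance, activity cliffs, and covariate shift. Passing tests
demonstrate the estimator's algebraic and statistical properties, not
predictive performance on chemical data.

## Experiment protocol (pipeline)

One stratified train/test split (default 80/20) is fixed per run and reused
across all strategies and seeds; comparing different sample subsets would
drive CKA toward 0 regardless of the models. Forests are fitted on the
training partition; Gram matrices are computed on the held-out test
partition by default (configurable to train or all — which samples populate
the Gram is a genuinely open protocol choice). Pairwise similarity matrices
average CKA over all seed combinations per strategy pair and report
cross-seed self-similarity on the diagonal instead of the constant 1,
because that is the reference baseline against which off-diagonal values
should be judged. The similarity-vs-agreement validation trains one forest
per (strategy, seed), collects CKA and inter-model MCC for every unordered
model pair, and delegates Pearson r/p to scipy; zero variance in either
column is flagged as degenerate rather than reported as a correlation.
Fingerprint featurization (circular/Morgan, radii 1–10, default 2048 bits —
recorded in every report since no canonical length exists) is delegated to
RDKit.

## Numerical choices and problem sizes

* Degenerate-Gram threshold: self-HSIC ≤ 1e−12 · max(1, ‖K‖∞)² raises.
* Gram symmetry is enforced to 1e−12; sampled RF Grams get their diagonal
  set to exactly 1 (a sample always shares its own block).
* Derived seeds (per embedding × seed index × stage) come from
  `numpy.random.SeedSequence` spawn keys reduced below 2³¹.
* Validation problem sizes are desk-scale: n = 300 samples with 10 features
  and 4–5 seeds for the correlation and robustness suites, forests of ≤ 5
  trees and ≤ 40 samples for oracle-equivalence trials (trial sizes drawn
  uniformly within those caps), 2000 partitions when checking the sampler
  against exhaustive enumeration, 500 in production use. The full suite
  runs in well under a minute on one CPU.

## Known limitations

* The RF Gram sampler's error scales as sqrt(0.25/n_partitions) per entry;
  with many samples the *maximum* entrywise error is the max over thousands
  of correlated entries and exceeds a per-entry 3σ band more often than a
  single entry would.
* No unbiased/minibatch HSIC, no RBF-kernel CKA, no regression forests, and
  no multi-class agreement metric.
* The RF kernel requires labels (forests are supervised); embeddings
  without a paired label vector can only be compared with the linear
  kernel.
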