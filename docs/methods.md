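# Methods

## Problem setting and model

The package selects a small discriminative feature subset from a numeric
classification table with few samples (tens) and many features (hundreds to
thousands), two or more classes, and possibly missing cells. It assumes
samples are exchangeable (no batch or time structure), features are
continuous measurements, and class labels are categorical. All stages
operate on a preprocessed matrix: missing cells are imputed with the
feature mean within the same class (falling back to the global feature mean
when a class has no observed value for a feature), then each feature is
z-scored with the sample (n−1) standard deviation and min-max rescaled to
[0, 1]. Constant columns map to all-0.5, which keeps them inert for
distance-based scoring. Preprocessing statistics are computed on the full
table, not per CV fold; this is a deliberate simplification and a known
information-leakage caveat for the absolute accuracy values the pipeline
reports.

## Stage 1 — filter ensemble and plateau truncation

Four filters rank all features, each descending (higher score better, ties
broken by ascending feature index):

- **Mutual information**: plug-in estimate, in bits, of I(X; Y) between an
  equal-frequency-binned feature and the class. Zero iff the empirical
  joint factorizes.
- **Chi-square**: Pearson χ² of the binned-feature × class contingency
  table against independence expectations from the margins. Larger values
  indicate stronger dependence; the package ranks larger-is-better, the
  standard reading of the statistic.
- **ReliefF** (multiclass): for each instance, the k nearest same-class
  hits reduce a feature's weight by the mean absolute value difference and
  the k nearest misses of every other class increase it, weighted by that
  class's prior over (1 − prior of the instance's class). Manhattan
  distance on the [0, 1]-scaled features; distance ties break by ascending
  sample index; all instances are sampled by default, making the weights
  deterministic and permutation-invariant.
- **Xvariance**: sum over classes of the feature's within-class sample
  variance (n−1 denominator; singleton classes contribute 0), ranked
  larger-is-better. Despite the "distance between classes" intuition often
  attached to this score, its literal construction aggregates within-class
  spread; it is implemented exactly as constructed.

The union of each ranker's top-m features (m defaults to 50 for tables up
to 1000 features, 100 up to 6000, 200 beyond, mirroring how the pool should
scale with width; always user-overridable) forms the candidate pool. Each
pooled feature is evaluated alone by KNN (K=5), RBF-SVM and Gaussian naive
Bayes with one shared seeded stratified fold assignment — sharing folds is
what makes the mean accuracies comparable across features and classifiers.
Features are sorted by mean accuracy (ties by index), and prefix sizes
step, 2·step, … (step = 5) up to the pool size are evaluated by pooled
10-fold stratified CV accuracy of an XGBoost classifier (library defaults,
seeded, single thread). Every size within ±step of the best coarse size is
then evaluated, and k is the smallest evaluated size attaining the global
maximum. This smallest-argmax rule is the formalization of "accuracy stops
increasing beyond k".

## Stage 2 — Pearson redundancy pruning

Pairwise Pearson r is computed over the k Stage-1 features, plus each
feature's r against the integer-encoded class (binary 0/1; multiclass uses
label-sorted integer codes — a documented crudeness, acceptable because the
intended use relabels to two classes). Absolute values are used both for
the redundancy test and the class-correlation comparison, since sign is
irrelevant to both redundancy and predictiveness. Pairs are visited in rank
order (outer ascending, inner ascending); when both members are still kept
and |r| > 0.7 (strict), the member with smaller |class r| is discarded,
ties going against the later-ranked member. Only currently-kept pairs are
ever tested, so a feature whose sole redundant partner was already removed
survives. Constant features get correlation 0 by convention (undefined
denominator) and are therefore never pruned — they rank last regardless.
The pruned list is re-truncated with the Stage-1 plateau rule to j
features.

## Stage 3 — binary whale optimization

Agents carry continuous positions in [−5, 5]^j (initialized uniform on
[−1, 1], clipped after every move to keep the sigmoid responsive). Per
agent per iteration, a scalar coin t ∈ [0, 1) chooses the move family:

- t < 0.5, encircling family: with v uniform per coordinate, K = 2sv − s
  and J = 2v. Coordinates with |K| < 1 move toward the leader X* by
  X ← X* − K·|J·X* − X| (shrinking encircling); coordinates with |K| ≥ 1
  move the same way toward a uniformly chosen random agent (exploration).
  The |K| < 1 gate is applied per coordinate, matching the per-coordinate
  draw of v.
- t ≥ 0.5, spiral: X ← |X* − X|·e^{bl}·cos(2πl) + X*, with scalar
  l uniform on [−1, 1] and spiral shape b = 1.

The shrink coefficient s = 2 − 2p/MaxIter decreases linearly from 2 to 0
over MaxIter = 100 iterations. Masks are obtained by sigmoid transfer with
stochastic thresholding (bit on iff σ(x) exceeds a uniform draw); an
all-zero mask is repaired by forcing the largest-σ coordinate on, so every
evaluated subset is non-empty. Fitness is
α(1 − accuracy) + (1 − α)|S|/j with α = 0.99 — error-dominant, with the
size term breaking accuracy ties toward smaller subsets; accuracy is pooled
stratified 10-fold CV accuracy of a K=5 KNN on the masked features. The
leader is updated immediately whenever any evaluated mask improves on it,
so leader fitness is non-increasing within a run by construction.

Twenty restarts with sub-seeds spawned from the master seed are averaged
(mean accuracy, mean subset size) and every per-run solution is reported.
The CV fold assignment for the fitness derives from the master seed and is
shared across restarts: fitness is then a pure function of the mask, which
both removes fold noise from the comparison of restarts and allows a
mask-level fitness cache shared across the whole repeated run. The KNN
inside the fitness is a vectorized implementation (full Euclidean distance
matrix, stable neighbor ordering so index ties resolve low-first, majority
vote with low-class tie-break); a unit test pins its predictions to
scikit-learn's `KNeighborsClassifier` on continuous data. This is purely a
throughput choice — the wrapper evaluates ~10^5 masks per repeated run.

## Evaluation utilities

Classifier evaluation pools out-of-fold predictions from a seeded
stratified k-fold split and reports accuracy, precision, recall and F1
(binary: positive class defaults to the second label in sorted order;
multiclass: macro averages). The one-sample t-test uses the sample (n−1)
standard deviation, t = (x̄ − μ₀)/(s/√n), with the one-sided lower-tail
p-value from Student's t on n−1 degrees of freedom — the variant that asks
whether a set of published competitor accuracies falls significantly below
a reference accuracy.

## Synthetic generator

`SyntheticSpec` plants: `n_informative` features with Gaussian
class-conditional distributions whose means are spaced `effect_size`
standard deviations apart; `n_redundant_per_informative` copies of each,
constructed as ρx + √(1−ρ²)·σₓ·ε so the population correlation with the
source is exactly ρ (σₓ includes the between-class variance); and `n_noise`
iid standard-normal features independent of the class. Columns are shuffled
by the seed so position carries no signal; the ground truth records the
informative/copy/noise partition. Optional missing cells are Bernoulli at
`missing_rate`, never blanking an entire (class, feature) group. Defaults
(60 samples, 5 informative groups, 2 copies at ρ = 0.9, 485 noise features,
effect 1.5) describe the package's reference recovery experiment.

What the generator does **not** emulate: heavy-tailed expression
distributions, platform or batch effects, class imbalance beyond the
near-balanced assignment, and correlated noise blocks. Passing tests
therefore demonstrate algorithmic correctness and recovery under a clean
Gaussian model, not performance on real expression data.

## Problem sizes and runtime choices

The test and acceptance workloads are sized for a single CPU: the filter
oracle comparison uses 100 random discrete tables of ≤ 50 samples; the
optimizer-vs-enumeration check uses 20 instances with 10 candidate features
(1023 masks each); the end-to-end recovery experiment uses five seeded
replicates of the 60 × 500 reference table with the full default
configuration (m = 50, 10-fold CV, 50 agents × 100 iterations × 20
restarts), feasible because of the mask-level fitness cache.

## Known limitations

- **Plateau truncation under noise.** With ~60 samples, pooled 10-fold CV
  accuracy has a standard error of several percent per evaluated prefix,
  and prefix accuracies beyond the first few informative features are
  statistically indistinguishable. The smallest-argmax rule then tends to
  truncate at spurious early maxima, and the wrapper's size penalty
  likewise prunes features whose marginal contribution is below the
  accuracy resolution (1/n per pooled prediction). Consequently, on the
  reference recovery experiment the pipeline reliably finds *a* small
  high-accuracy signature but does not reliably represent *every* planted
  group; the acceptance script reports the measured recovery fraction
  alongside accuracy and subset size. Larger samples, repeated CV, or a
  weaker size penalty would trade recovery against parsimony.
- Preprocessing is fit on the full dataset (leakage caveat above), so
  reported accuracies are optimistic relative to nested-CV estimates.
- Multiclass class-correlation encoding in Stage 2 imposes an arbitrary
  ordinal structure on the labels.
- The WOA binarization (sigmoid + stochastic threshold + non-empty repair)
  is one of several reasonable transfer schemes; results on other schemes
  may differ in subset size more than accuracy.
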