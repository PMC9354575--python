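# Methods

## The problem

Sample classifiers built on transcriptomic data are notoriously fragile
to *handling effects*: systematic signal introduced by who processed an
array, when, and in which batch, rather than by biology.  When the
order of array processing is correlated with the class label (for
example, tumors arrayed in the order they were collected, one diagnosis
before the other), a classifier can learn the handling signal instead of
the biology and collapse on independently handled data.

`precision_bench` measures how choices of (i) training-data
normalization, (ii) test-data normalization, (iii) classifier, (iv)
validation method, and (v) array-to-sample assignment design jointly
affect binary misclassification error.  Its reference scenario is a
paired microRNA microarray study: the same tumor samples (two tumor
types, equal numbers) profiled twice — once with uniform handling (one
technician, one batch, balanced assignment) and once arrayed over time
in collection order (two technicians, multiple batches).

## Effect decomposition and virtual re-hybridization

On the log2 scale the paired design gives an additive decomposition:

- **virtual samples** — each sample's profile in the uniformly handled
  dataset is taken as its biological effect;
- **virtual arrays** — the per-probe difference between a sample's two
  arrays (nonuniform minus uniform) is taken as the handling effect of
  its nonuniform array.

The estimator is the raw paired difference, deliberately model-free, so
`uniform + handling == nonuniform` holds exactly (bit-for-bit) by
construction.  New datasets are simulated by **virtual
re-hybridization**: assign arrays to samples under a chosen design and
add each sample's biological effect to its assigned array's handling
effect.  Because both ingredients are estimated from data rather than
drawn from a parametric model, the simulated data inherit realistic
marginal distributions and probe-level covariance.

Two dials rescale the decomposition:

- `reduce_signal(f)` rescales the between-class contrast.  For probe *g*
  and sample *j* of class *c*:  x'_gj = x_gj − (1−f)(m_gc − m̄_g), where
  m_gc is the class mean and m̄_g the unweighted midpoint of the two
  class means.  This makes the class-mean difference exactly *f* times
  the original, preserves within-class deviations, and composes
  multiplicatively (f1 then f2 ≡ f1·f2).  The formula is the package's
  own; it was chosen because it is verifiable by simple group-mean
  arithmetic.
- `amplify_handling_effects(a)` multiplies selected handling columns by
  *a* ≥ 0, with no re-centering — the simplest operator that scales the
  extent of handling effects, and the one that makes `a = 0` an exact
  additive identity (used by the simulator-equivalence test).

## Splits, designs, and the benchmark

Samples are split 2:1 into training and test, randomly but stratified by
class (per-class counts must divide by 3).  Arrays are split
*nonrandomly* by processing order: first third and last third to
training, middle third to test — generalizing the 192-array reference
study (64/64/64) to any size divisible by 3; other sizes fail loudly.

Array-to-sample assignment within each part follows one of three
designs:

- **confounding** — arrays in ascending processing order go to all
  samples of the lexicographically first class, then the second
  (within-class order seeded-random).  Processing order and class are
  then perfectly aligned: the first class occupies the minimal possible
  rank-sum.
- **balanced** — consecutive processing-order blocks of `block_size`
  arrays each receive an equal number of samples from both classes,
  placed randomly within the block (blocking + randomization +
  stratification).  Default block size is total-arrays/24 rounded to the
  nearest even number ≥ 2 (8 at the 192-array scale, 2 on the default
  fixture); the size must be even and divide the part.
- **complete_random** — a uniformly random bijection.

Training and test parts may use different designs.  The **benchmark**
test data are the test samples' biological effects with no handling
added: external validation against them measures what the classifier
learned about biology, uncontaminated by the test set's own artifacts.

## Preprocessing and normalization

The fixed chain is: load raw intensities → log2 → normalization →
probe-replicate summarization by the median (even-sized replicate sets
take the midpoint of the two central order statistics; replicate rows
are rows whose probe IDs are string-equal after trimming whitespace).
Estimation of the effects operates on log2 data; the order is fixed and
documented here because the alternative (estimating before log2) is not
additive.

Training normalizations (plus `none` as a reference):

- **median** — shift each array so its median equals the across-array
  median of per-array medians; that scalar is the frozen reference.
- **quantile** — replace each array's order statistics by the
  across-array mean of order statistics; ties share the mean of the
  reference values at their tied ranks, so tied inputs stay tied.  The
  mean-order-statistic vector is the frozen reference.
- **vsn (simplified)** — each array is affine-calibrated against the
  per-probe median profile (OLS slope/offset, slope guarded positive),
  passed through the inverse hyperbolic sine, and mapped onto the pooled
  target quantiles.  The contract tested is monotonicity and
  distributional alignment, not coefficient equality with any other
  variance-stabilizing implementation; full robust maximum-likelihood
  fitting is out of scope.

Seven test-data strategies: each method applied to the test set alone
(`*_alone`), each applied **frozen** toward the stored training
reference (`*_frozen` — every test array normalized one at a time,
never pooling test arrays, which is what a deployed classifier sees),
and `pooled_quantile` (train + test concatenated and quantile-normalized
jointly).  `none` is kept as an eighth reference-only entry so the seven
named strategies remain countable as seven.  Frozen strategies require a
matching-method training reference; mismatched pairings are structurally
invalid and are recorded as failed cells, not silently dropped.

An optional location-only batch correction (per probe, per batch:
subtract the batch mean, restore the grand mean) is available at the
library level and off by default.

## Classifiers

Seven registered methods consume preprocessed probes × samples data:

- **pam** — nearest shrunken centroids, implemented here.  Standardized
  centroid deviations d_kg = (x̄_kg − x̄_g)/(m_k(s_g + s0)) with
  m_k = √(1/n_k + 1/n) and s0 the median pooled within-class SD, are
  soft-thresholded at Δ; Δ is chosen from a 30-point grid spanning 0 to
  max|d| by cross-validated misclassification (ties → smallest Δ).
  Full shrinkage degenerates to the class priors.
- **dlda** — diagonal-covariance linear discriminant; zero-variance
  probes are excluded with a warning.
- **clanc** — class-specific nearest centroids, implemented here.  A
  probe is a candidate for the class in which it is up-regulated
  (positive standardized deviation), making the per-class sets disjoint
  by construction and the selection symmetric under label relabeling; a
  class whose candidate supply falls short fills up with its strongest
  remaining probes (so requesting all probes recovers plain standardized
  nearest centroids).  `genes_per_class` is tuned over {1, 2, 5, 10, 20}.
- **lasso / knn / rf / svm** — delegated to scikit-learn
  (L1-logistic regression via saga with the intercept unpenalized, so
  the infinite-penalty limit is the majority-class model; k-nearest
  neighbors with k ∈ {11, 9, 7, 5, 3, 1}; random forest with 500 trees
  and a fixed seed; linear-kernel SVM with cost ∈ {0.01, 0.1, 1, 10}).

Hyperparameters are tuned by seeded stratified k-fold cross-validated
misclassification (default 5 folds; 3 in the desk-scale test grids),
with ties broken toward the least complex setting (largest penalty,
largest k, smallest cost, smallest Δ).  Prediction score ties break to
the lexicographically first class label.  Every stochastic step takes an
explicit seed; fixed inputs give bit-identical models and predictions.

Validation is threefold per grid cell: pooled stratified k-fold
**cross-validation** on the training set (nested — each fold reruns the
full tuning protocol), **external validation on the simulated test set**
(handling-affected), and **external validation on the benchmark**
(handling-free).  All outputs are exact misclassified-count / tested-count
proportions.

## The assessment grid

`precision_simulate` repeats, per repetition *r* with seed
`base_seed + r`: split → assign (both parts, configured designs) →
re-hybridize → normalize → summarize → train → validate, over the full
train-norm × test-norm × classifier grid.  `uni_handled_simulate` runs
the same grid on biological effects alone (no handling), and
`precision_simulate_multiclass` merges per-classifier runs.  With
`handling_factor = 0` the two simulators agree cell-for-cell on shared
seeds.  Results stream to per-repetition checkpoint files keyed by a
configuration hash, so interrupted grids resume.  Aggregation reports
per-cell mean, SD (0 for a single repetition) and IQR, plus each cell's
delta against the no-normalization reference; plots are rendered from
TSVs written first, so the plotted numbers are auditable.

## The synthetic paired study

The generator emulates the paired structure the framework assumes, at a
desk scale chosen so the whole grid runs in seconds: 24 samples per
class, 120 probes × 3 replicates, 24 informative probes with a class
effect of 1.5 log2 units, per-probe baselines N(7, 1.5), biological
noise SD 0.5, replicate noise SD 0.1, a centered logistic-ramp handling
trend of amplitude 1 log2 unit across processing order, two batches at
±0.5, handling noise SD 0.3.  Processing order equals collection order
with one class collected entirely before the other, mirroring the
handling/biology confounding the framework exists to expose.  The trend
is a deterministic smooth monotone function (not free noise) so a
confounded assignment provably transfers class-correlated structure.
The nonuniform matrix is stored as the exact float sum of the biological
and handling layers, and the ground-truth handling layer is stored as
the realized difference, so the paired-difference estimator recovers it
bit-for-bit.

What the generator does **not** emulate: spatial array artifacts,
intensity-dependent (nonlinear) handling distortions, probe-specific
handling sensitivity, or heavy-tailed intensity distributions.  Passing
tests therefore demonstrate the correctness and the qualitative
behavior of the machinery, not the quantitative error rates of any real
study.

One consequence worth noting: because the generated handling trend is
shared across probes and the logistic ramp is centered, a confounded
training design biases centroids along a direction that cancels at the
decision midpoint.  At the default signal strength the benchmark
(handling-free) error therefore floors at zero for both the confounded
and the balanced training design, and the damage done by confounding
appears instead as a gap in cross-validation error (≈ 0 under
confounding — deceptively optimistic, because the classifier can lean
on the handling trend — versus ≈ 0.5 under the balanced design, where
handling variance is pushed inside classes) and in the simulated-test
external error.  The directional benchmark comparison (confounded ≥
balanced) holds with equality at these settings.

## Numerical and design choices

- Probe replicates are matched by exact string equality after trimming;
  no fuzzy matching.
- Missing values are rejected at load; no imputation.
- Processing order is 1-based; matrices are addressed by probe/array ID
  across module boundaries, never by raw index.
- File IO writes shortest round-tripping float representations and
  parses them back with a correctly-rounded parser, so write → load is
  an identity on values.
- The benchmark test set passes through the same test-normalization
  strategy (and frozen reference) as the simulated test set, so the
  benchmark comparison isolates handling effects rather than the mere
  presence of normalization.
- Structurally invalid grid cells (frozen strategy without its matching
  training reference) are retained with `status = incompatible_reference`
  and a NaN value, keeping the grid complete and auditable.
- Default repetitions for a full assessment: 20 (configurable); the
  packaged test grids use 1–2 repetitions with reduced method lists,
  and the design-effect check uses the full 20.

## Known limitations

- Binary endpoints only; the multiclass wrapper iterates classifiers,
  not classes.
- The simplified VSN is a calibration + arcsinh + quantile-mapping
  surrogate; it satisfies the monotonicity and variance-flattening
  contracts but is not interchangeable with likelihood-based fits.
- Handling-effect estimation requires the paired design; there is no
  model-based estimator for unpaired studies.
- The balanced design requires equal class counts and an even block
  size dividing each part.
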