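# Methods

## The valuation procedure

A valuation run takes a differentiable model f_θ, a loss ℒ, a source pool
𝒟ₛ (the samples being valued) and a target set 𝒟ₜ (the samples defining
the objective).  Plain constant-step SGD is driven by target mini-batches;
at every T-th iteration, *before* the parameter update, the cosine
similarity between each source sample's gradient and the current target
batch gradient is recorded.  A sample's value is the arithmetic mean of its
recorded similarities over iterations and over `n_runs` independently
seeded repetitions (fresh initialisation and batch order per run; run r
uses seed `base_seed + r`).  Averaging across runs probes several basins of
the loss surface and reduces the variance induced by any single
initialisation.

Properties that the implementation guarantees and the test suite asserts:

* recording is a pure observation — the SGD trajectory is bit-identical
  whether similarities are recorded at every iteration, every T-th, or not
  at all; consequently values at period T equal the T-strided subsample of
  the period-1 record;
* with cosine similarity every recorded entry, and hence every value, lies
  in [−1, 1]; duplicated source samples receive identical values; a source
  sample identical to a singleton target set is valued exactly 1;
* with period-T recording the mean is taken over the *recorded* iterations
  (count N_iter/T), not over N_iter, so the value remains a mean of
  cosines whatever T is.

Numerical conventions: the cosine of a zero-norm gradient pair is defined
as 0 (a vanished gradient carries no directional information); similarities
are clipped to [−1, 1] against floating-point overshoot; a non-finite model
output aborts the run with the failing iteration in the message.  Target
mini-batches are drawn without replacement within an epoch and reshuffled
each epoch.  Optional `pretrain_epochs` of target-only SGD precede
recording, which moves the measurements into the trained regime — useful
for reconstruction tasks, where early-training gradients are dominated by
the random initialisation.

Class imbalance in the target set would otherwise bias values toward the
majority class, so `class_balance=True` weights target-batch per-sample
losses inversely to the class frequencies of the *full* target set
(per-batch frequencies are too noisy at realistic batch sizes).  Source
gradients are always unweighted single-sample gradients.

## Models and gradients

The two architectures are small fully connected networks implemented
directly on numpy with hand-written backpropagation:

* **classifier** — input → hidden (ReLU, default width 100) → n_classes,
  softmax + cross-entropy uniformly (binary tasks use two output units);
* **autoencoder** — 2-layer encoder and 2-layer decoder with a default
  32-dimensional linear latent; the single hidden width defaults to the
  geometric mean of input and latent dimension (a deterministic,
  scale-free interpolation).

Weights are initialised N(0, 1/√fan_in) from a seeded generator, biases at
zero; construction is bit-reproducible per seed.  Hidden widths,
activations (ReLU) and the presence of biases are package choices — they
are standard defaults for small tabular problems, and nothing downstream
depends on them beyond the generic feedforward contract.

Per-sample gradients are exact (verified against central finite
differences at relative tolerance 1e-4).  The valuation loop never forms
the N_source × n_parameters per-sample gradient matrix: for an affine
layer, a sample's weight gradient is the outer product a dᵀ of its layer
input and backpropagated delta, so its dot product with a reference
gradient G is aᵀG d and its squared Frobenius norm is ‖a‖²‖d‖².  Summing
these per layer yields each sample's cosine against the target gradient in
one vectorised backward pass.  An explicit per-sample-gradient path is
retained and the two paths are required to agree to 1e-5 in the tests.

## Baselines

* **random** — Uniform(0,1) values; calibrates the evaluation statistics
  (mean corruption AUROC 1/2, mean noise Spearman 0).
* **leave-one-out** — ν_k = score(fit(S)) − score(fit(S∖{k})), sign chosen
  so that higher is better; degenerate refits yield NaN and the run
  continues.
* **TMC Data Shapley** — marginal contributions along random permutations;
  a permutation is truncated when the running score is within
  `truncation_tolerance` (default 1% of |full-data score|) of the
  full-data score; estimation stops when the running means move less than
  0.001 over the last 10 permutations, or at `max_permutations`.  The
  empty-set score is the metric of the learner's uninformed prediction.
  An `exhaustive` mode enumerates all n! permutations, which with zero
  truncation gives exact Shapley values and anchors the oracle tests.

Retraining-based methods and filter curves accept any object with the
fit/score/empty_score contract; provided learners are a seeded
scikit-learn logistic regression (a single-class training subset returns a
constant predictor with an uninformative score rather than an error), a
closed-form global-mean regressor used in exact-value tests, and a seeded
SGD-trained autoencoder for reconstruction tasks.

## Corruption and evaluation statistics

Label flipping relabels round(p·n) uniformly chosen samples, each to a
uniformly drawn *different* class.  Feature noise draws a per-sample rate
φ_i from a uniform range and adds N(0, φ_i) noise independently per
feature; φ_i is interpreted as the standard deviation (the notation
N(0, φ) is ambiguous between sd and variance; sd is the interpretable
choice and the induced ranking is identical either way).  The default
range (0, 1) on standardized features puts the strongest corruption at the
signal scale.

Detection quality is scored as AUROC(c, −ν) (mid-rank ties) and
ρ = Spearman(φ, −ν); both are invariant under strictly monotone
transformations of the values, which matches the method's contract — values
are an ordering, with no linearity or magnitude guarantees.

Filter-and-retrain curves drop the lowest- (or highest-) valued
floor(q·n) samples, refit `reps` seeded learners and score a held-out test
set; ties at the cutoff are broken by a seeded random order so the removed
count is exact.  Classification curves report AUROC, reconstruction curves
report R².

APC (average Pearson correlation) is the unweighted mean of pairwise
Pearson correlations over all unordered replicate pairs within a
perturbation group; groups with fewer than two replicates report NaN, and
pairs with a constant profile are dropped from the mean and counted in a
diagnostics field.  The conventional quality partition keeps groups with
APC strictly above 0.5.

## Synthetic data

**Blobs** — class-conditional unit-covariance Gaussians whose means lie
`separation` apart (symmetric along a random unit vector for two classes,
random orthogonal directions otherwise), standardized after sampling.
Separation 4 in 10 dimensions gives a cleanly learnable problem in which
label noise is nonetheless costly — the regime of the tabular benchmarks.

**Replicate expression** — each perturbation group has a true signature;
replicates observe it plus N(0, σ_r) noise with σ_r drawn per replicate
from a uniform range; level-5 signatures are replicate means.  Two
deliberate departures from the simplest model:

* *Low-rank signal.*  Signatures live on a latent subspace of rank
  min(20, n_genes) (latent scores × fixed loadings, scaled to the
  requested marginal sd).  Real expression signatures are strongly
  co-expressed; this is also a mathematical requirement for the
  unsupervised mechanism — against full-rank i.i.d. signatures a
  32-dimensional autoencoder can capture no structure, reconstruction R²
  is near zero for any training set, and neither valuation nor filtering
  can have any effect.  `signal_rank=None` restores i.i.d. signatures.
* *Contamination.*  Optionally, a fraction of *groups* draws all its
  replicate σ_r from a much larger range, emulating failed assays whose
  garbage survives replicate aggregation.  With a homogeneous noise
  population, removing the noisiest samples barely pays (their zero-mean
  noise still carries unbiased signal information, and the lost sample
  size dominates — we verified this holds even for oracle filtering); a
  contaminated tail is what makes quality filtering genuinely profitable,
  and is the realistic failure mode of high-throughput screens.

The real L1000 pipeline aggregates replicates with a moderated z-score
(MODZ) weighting; the plain mean used here is a declared simplification.
The generators emulate noise structure only — no dose/time/cell-line
covariates, no batch effects, no peak deconvolution — so passing tests
demonstrate the valuation mechanics, not performance on real LINCS data.

## Benchmark protocols and problem sizes

The `benchmarks` module fixes the protocols used by the test suite and by
`scripts/acceptance.py`; sizes were chosen to exercise the standard
conditions while fitting comfortably on a single CPU core.

* **Null calibration** — uniform random values vs a 20% corruption mask
  and vs uniform noise rates, n = 1000, mean over 25 repetitions.
* **Corrupted labels** — 1000 source / 400 target observations,
  separation-4 blobs in d = 10, 20% flipped; MLP (hidden 100), lr 0.05,
  batch 50, 1000 iterations, 3 runs.  Period stability is evaluated by
  striding the period-1 record (valid because recording cannot perturb the
  trajectory) and comparing rankings at T = 2…5 with Spearman.
* **Supervised noise** — same sizes, per-sample noise rates from
  Uniform(0, 2) on standardized features (spanning mild to
  signal-swamping corruption).
* **Unsupervised expression** — 700 groups × 3 replicates × 978 genes,
  clean σ_r ∈ U(0.2, 1.0), 20% contaminated groups with σ_r ∈ U(4, 8);
  the first 500 level-5 signatures are the valuation pool.  Following the
  clean-target protocol, the 200 held-out groups are partitioned by their
  replicate APC and the APC > 0.5 signatures are split at random into
  target and test halves; an autoencoder (978→32) with lr 0.2, 100
  pretraining epochs, 300 recorded iterations and 2 runs produces the
  values.  Filtering drops the lowest-valued 20% and refits the
  autoencoder learner (lr 0.2, 150 epochs, 2 seeded repetitions).  The
  clean target/test choice matters: when the evaluation set itself
  contains the contaminated tail, a model trained with garbage scores
  better on garbage and filtering cannot help, whichever values are used.

## Known limitations

* Values are a ranking, not an additive attribution: they do not satisfy
  the Shapley efficiency/nullity axioms, and high values should be read
  with more caution than low ones (similarity to the target is not the
  same as usefulness).
* Constant-step SGD requires a learning rate matched to the task; the
  reconstruction loss averages over features, so appropriate rates for the
  autoencoder are ~10× larger than for the classifier.  Divergence is
  detected and reported, not repaired.
* The numpy backprop covers fully connected ReLU/linear architectures
  only; convolutional or pretrained feature extractors are out of scope.
* Learners behind LOO/Shapley must be cheap: both retrain O(n) and
  O(n · permutations) times respectively.
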