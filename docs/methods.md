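# Methods

## Problem setting

A body-worn sensor network records gait with J sensor nodes, each carrying a
triaxial accelerometer and a biaxial gyroscope (5 channels per node).  Two
coupled problems are addressed:

1. **Energy-efficient acquisition.**  Each node compresses its own windowed
   signal locally with a random measurement matrix before transmission, so
   only M of every N samples leave the sensor.
2. **Classification at the receiver.**  Activity windows are labeled
   *directly from the compressed measurements* — no reconstruction step —
   by a joint sparse representation classifier whose dictionary is pruned
   per test sample.

## Models and algorithms

### Joint sparsity (JSM-2) and distributed compression

The ensemble X = [x_1, …, x_J] is modeled as jointly sparse with a *shared
support*: x_j = Ψ θ_j with one index set Ω common to all sensors and
per-sensor coefficient values (the JSM-2 model).  Measurement is
block-diagonal: y_j = Φ_j x_j with independent per-sensor blocks, either
sparse-binary (exactly two unit entries per column at distinct uniform
rows — the cheapest on-sensor operator) or Gaussian N(0, 1/M).  The
compression ratio is CR = (N − M)/N × 100%.

Joint reconstruction (used only as a baseline and for solver validation) is
greedy: **SOMP** selects, at each of k iterations, the atom maximizing the
sum over sensors of squared normalized residual correlations, then refits
every sensor by least squares on the selected set; **OSGA** does a single
correlation-ranking pass and is deliberately the weaker method.

### Windows to vectors

A window is a (5J × h) matrix (sensor-major channel rows).  For
compression, each sensor's five channel rows are compressed separately by
that sensor's block Φ_j (shared within the node) and concatenated
channel-major, giving y_j of length 5M and a stacked vector of length 5JM.
The CR is accounted on the window length h, which is what each channel's
compression actually reduces.

### Compressed-domain JSRC with SRCC pruning

The dictionary's atoms are the compressed training windows themselves, unit
normalized, grouped by class.  A test vector is coded over the atoms with
one task per sensor (each task sees only its own row block), coupled by a
shared row support — the l2/l0 mixed-norm model.  The label is the class
whose indicator-masked coefficients reconstruct the test vector with the
smallest l2 residual; argmin ties break toward the smallest class index.

Before coding, the dictionary is pruned per test sample.  The ridge
problem min ‖y_j − A_j w‖² + λ‖w‖² is solved in closed form per sensor
(through the dual identity Aᵀ(AAᵀ + λI)⁻¹y, so the factorization has the
row dimension and is reused across test samples), the per-atom coefficient
magnitudes are averaged over sensors, and the m top-scoring atoms of *each
class* are kept (per-class rather than global top-m, so no class is ever
eliminated before the residual rule).  A nearest-neighbor pruning variant
(smallest Euclidean distance to the unit-normalized test vector, per class)
is provided for comparison, as are single-measurement baselines (SRC on the
concatenated vector, KNN, Gaussian naive Bayes).

Two stated interpretation choices: the ridge scoring operates on
*compressed* atoms (the classifier never sees raw signals), and the
per-sensor ridge solves are aggregated by averaging |w| across sensors; a
pooled single-solve variant is available behind a flag.

### Multitask Bayesian solver (MBCS)

As an alternative to greedy coding, the coupled tasks y_j = A_j w_j + e_j
are solved under a hierarchical Gaussian model: noise precision β0 shared
by all tasks, and one prior precision α_i *per atom shared across tasks* —
the coupling that induces a common row support.  Hyperparameters are
estimated by evidence maximization with MacKay fixed-point updates

  α_i ← Σ_j γ_{ji} / Σ_j μ_{ji}²,  γ_{ji} = 1 − α_i Σ_{j,ii},
  β0 ← (Σ_j N_j − Σ_{j,i} γ_{ji}) / Σ_j ‖y_j − A_j μ_j‖²,

where μ_j, Σ_j are the per-task posterior moments.  Atoms whose precision
exceeds 1e8 are pruned from the model (their coefficients are exactly
zero), which is what makes the posterior row-sparse; β0 is capped at 1e10
so noiseless instances remain numerically well posed.  Convergence is a
relative hyperparameter change below `tol` (default 1e-6) within `max_iter`
(default 200) sweeps; non-convergence is flagged on the result and logged,
never raised.  With J = 1 the model reduces to single-task Bayesian CS.

### Metrics and cross-validation

Accuracy = diagonal/total, recall(i) = diagonal(i)/row-total(i),
precision(i) = diagonal(i)/column-total(i), all ×100; zero-denominator
entries are reported as undefined (NaN), never as zero.  Recall is
deliberately diagonal-over-row-total — the formula that reproduces the
worked-example table in `gaitjsrc.examples` — and that table's two
internally inconsistent rows (row sums 206 and 205 against 200 windows per
class) are excluded from any recall check.

Cross-validation is subject-wise: subjects are randomly partitioned into
outer folds (10 folds of 2 for the 20-subject cohort; 1620 training
windows per split), with a nested inner partition (9 folds) of each outer
training set recorded in the plan for model development.  One measurement
scheme is drawn per experiment and shared by training and test samples —
compressed-domain classification requires both to live in the same
measurement space.  Wall-clock time per classification is recorded for
information and never asserted: it is hardware-bound.

## Synthetic data

Two generators provide ground truth:

* **JSM-2 ensembles**: support drawn uniformly, nonzero coefficients
  standard normal per sensor (scale-free, the convention in CS
  simulations), optional Gaussian noise, identity or orthonormal-DCT basis
  (both offered; inertial data has no single canonical sparsifying basis).
* **Gait-like cohorts**: per class and channel row, a template that is a
  sum of 2–4 random-phase sinusoids with frequencies drawn below a
  class-specific cutoff in 1.5–5 Hz (mimicking quasi-periodic gait
  harmonics at a 20 Hz sampling rate), amplitude scaled by `class_sep`;
  per subject, a 10% s.d. amplitude jitter and a 50 ms s.d. timing shift;
  per window, additive Gaussian noise.

The default study cohort is 20 subjects × 9 classes × 10 windows of length
200 at 20 Hz with 5 sensors (1800 windows; 1620 per training split), with
`class_sep = 1.0` and `noise_sd = 0.1`.  These generator defaults define
the benchmark conditions and are fixed.

What the generator does *not* emulate: biomechanical structure, cross-axis
correlation within a node, sensor dropout, clock drift, subject-specific
harmonics beyond amplitude/phase jitter, or heavy-tailed sensor noise.
Passing benchmarks on this cohort therefore demonstrates the pipeline's
correctness and its qualitative compression behavior, not field
performance on real recordings: the synthetic classes are more separable
than real activities, and absolute accuracies here sit near the ceiling.

## Numerical choices

* Ridge penalty λ defaults to 1e-3: the closed form needs only a small
  stabilizer, and SRCC selection is invariant to positive rescaling of the
  test vector.
* Greedy row-sparsity bound k defaults to 20, well below the pruned
  dictionary size L·m, and is capped at the atom count.
* Dictionary columns are unit normalized, which makes the unnormalized
  sparse-binary measurement entries immaterial; zero training vectors are
  rejected rather than silently normalized.
* All argmax/argmin ties break toward the smallest index; all stochastic
  steps take explicit seeds (CLI default 0).
* The low-pass stage is zero-phase (forward-backward) order-5 Butterworth;
  a cutoff at or above Nyquist — including the 30 Hz default cutoff at the
  20 Hz default sampling rate, which is unrealizable — passes the signal
  through with a logged warning instead of erroring, so the documented
  preprocessing chain still runs.
* Records shorter than one window segment to an empty list with a warning;
  window stride is round(h(1 − overlap)) with a floor of 1.
* Per-sample classification cost scales with the pruned dictionary
  (O(w²·Lm)) rather than the full training set (O(w²·n)); the ridge
  factorizations are computed once per training set.

## Known limitations

* The WARD-style reader expects the documented CSV layout, not the
  original binary distribution of such databases.
* OSGA is a one-pass baseline only; no convex l1 or mixed-norm solver is
  provided (classification never needs reconstruction).
* MBCS pruning is irrevocable within a run; for atoms with near-equal
  small amplitudes under heavy noise the greedy solver is the safer
  default.
* Per-class pruning assumes every class has at least one informative atom;
  classes absent from a dictionary score the full test-vector norm.
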