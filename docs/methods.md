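# Methods

## Density-ratio model

The importance weight w(x) = p_pred(x)/p_train(x) is estimated directly,
without estimating either density, by KLIEP. The model is linear in its
parameters,

    ŵ(x) = Σ_{l=1..b} α_l φ_l(x),    φ_l(x) = exp(−‖x − c_l‖² / 2σ²),

with centers c_l drawn uniformly without replacement from the prediction
set (b = min(100, n_pred) by default) and a shared Gaussian bandwidth σ.
Substituting p̂_pred = ŵ · p_train into the Kullback–Leibler divergence
from p_pred to p̂_pred and dropping terms that do not depend on ŵ leaves
the objective

    maximize_α  Σ_j log ŵ(x_j^pred)
    subject to  (1/n_train) Σ_i ŵ(x_i^train) = 1,   α ≥ 0.

The constraint normalizes p̂_pred to unit mass over the training sample.
We adopt the *mean-one* convention (with the 1/n_train factor), so fitted
weights read directly as relative importances: a weight of 2 marks a
training molecule twice as representative of the prediction set as an
average one. The same convention makes weighted and unweighted
log-likelihoods comparable in the downstream classifier. Formulations
that state the constraint as an unnormalized sum differ only by a
constant rescaling of α.

Gaussian kernels are used on all feature types. Binary fingerprints are
embedded as 0/1 real vectors, where squared Euclidean distance equals
Hamming distance, so the kernel is a monotone function of the number of
differing bits.

### Optimization

The objective is concave on the feasible simplex-like set. It is solved
by projected gradient ascent: a gradient step on Σ_j log ŵ(x_j^pred),
projection back onto the affine constraint, clipping of α at zero, and a
final rescale to restore the constraint exactly. A backtracking rule
halves the step whenever the proposed move would lower the objective and
grows it by 1.2 after an accepted move, which makes the recorded
objective trace non-decreasing by construction. Iteration stops when one
step gains less than `tol` (default 1e-6) or after `max_iter` (5000)
iterations; non-convergence is reported, never raised. The training-mean
of the fitted weights equals 1 to well below 1e-6, and weight vectors are
clipped at zero when the model is evaluated on new points. A prediction
point receiving (numerically) zero mass from every basis function makes
the problem infeasible; this is raised with the advice to increase σ.

### Bandwidth

Two policies are provided:

* **median heuristic** (default): σ = median pairwise Euclidean distance
  among prediction points (subsampled to 1000 points for large sets);
* **likelihood cross-validation (LCV)**: the prediction set is split into
  folds; each candidate σ is scored by the mean log ŵ on held-out
  prediction points, and the maximizer wins (ties resolved toward the
  smaller σ so the choice is independent of grid order).

LCV behaves the way the theory says it should: when training and
prediction sets coincide it picks a large bandwidth and the weights
flatten toward 1; under a genuine shift it picks a resolving bandwidth.
The protocol code defaults to the median heuristic for speed; the
toy-example and diagnostic paths use LCV.

## Classifiers

**Weighted logistic regression** maximizes
Σ_i w_i [y_i log p_i + (1−y_i) log(1−p_i)] − (λ/2)‖β‖², solved via
scikit-learn's lbfgs with C = 1/λ and per-instance sample weights.
λ defaults to 1e-4 — a nearly-flat ridge that stabilizes the
high-dimensional sparse-fingerprint case (thousands of correlated
binary columns) without materially biasing the fit. Weights are rescaled
to mean one before fitting, so constant weights reproduce the unweighted
fit exactly and the effective penalty does not depend on the weight
scale. The classification threshold is fixed at 0.5 and performance is
plain fraction-correct accuracy.

**Tanimoto k-NN** (k = 5, always odd so binary votes cannot tie) predicts
the majority label of the k references most similar to the query under
Tanimoto similarity |a∩b|/|a∪b|. Similarity ties at the k-th rank are
broken by reference insertion order via a stable sort. The k-NN baseline
never uses importance weights: the comparison is between KL+LR, LR and
k-NN as three distinct methods.

## Chemistry layer

Molecule tables are delimited text with id, SMILES, assay value and
registration date columns (column names mapped via config). Featurization
uses RDKit hashed path fingerprints (2048 bits by default), with circular
(Morgan) and MACCS alternatives exposed; published comparisons of these
fingerprint families on the same task found the choice immaterial, and no
fingerprint length is canonical, so the length is a free parameter. A
`"hex"` pass-through scheme lets the synthetic generators ship bit
vectors through the same table format in place of SMILES.

Assay binarization follows per-assay cutoff rules with a discard band:
e.g. hERG actives at IC50 < 10 µM, inactives at IC50 > 15 µM, and values
in between (or exactly on a threshold — the rules use strict
inequalities) discarded to suppress label noise near the boundary.
Values are compared in the unit the assay declares; nothing converts
units. Temporal splitting sorts by registration date with a lexicographic
id tie-break, making the split a pure function of the record set.
Degenerate cases are defined rather than left to NaN: the Tanimoto
similarity of two all-zero fingerprints is 0 (with a warning).

## Synthetic generators

All generators are pure functions of config + seed.

**Importance curve.** The closed-form ratio of two 1-D Gaussian densities
on a grid — the textbook picture of importance weighting, and the oracle
for the KLIEP correlation benchmark (estimated vs analytic ratio,
Pearson r > 0.99 at n = 1000 in the acceptance run).

**Rotated-Gaussian toy.** Training points from two 2-D class Gaussians;
prediction points from the same mixture rotated about the midpoint of the
class means. Defaults: means (0,0) and (2,2), covariances diag(1.0, 0.1)
and diag(0.3, 0.9), 30° rotation, 500 points per class per set. The
unequal, anisotropic covariances are deliberate: with equal class
covariances the Bayes boundary is linear, logistic regression is
correctly specified, and the maximum-likelihood boundary is invariant to
input reweighting in the large-sample limit — the boundary shift the toy
exists to display vanishes. Under misspecification the weighted fit
converges to a genuinely different boundary, and the toy shows the
weighted angle strictly between the unweighted and the
train+prediction-oracle angles. The generator also exposes the exact
mixture density ratio (`toy_oracle_importance`) since it owns both
distributions.

**Fingerprint-drift simulator.** Train bits are independent Bernoulli
draws with per-bit probabilities sampled once from Uniform(0.05, 0.5)
(sparse-leaning, fingerprint-like); prediction bits use probabilities
drifted on the logit scale by `drift_magnitude` × a fixed standard-normal
per-bit shift, clipped to [0.01, 0.99]. Labels come from one fixed
logistic concept thresholded at zero, with independent label flips at
`label_noise` = 0.1 — the concept and its achievable accuracy (0.9) are
identical in both sets, so any train/pred performance difference is
attributable to the covariate shift alone. Defaults: 2000 + 2000
instances, 64 bits, drift 1.0 (detectably shifted: two-sample separation
accuracy ≈ 0.93–0.95 at these settings). Because the simulator owns both
factorized Bernoulli densities it emits the exact importance weight per
training instance, computed in log space. Records carry synthetic ids,
hex-encoded bits in the SMILES slot, assay values consistent with a
standard cutoff rule (no discards), and strictly increasing pseudo-dates
so a temporal split at n_train/(n_train+n_pred) reproduces the simulated
partition exactly.

What the simulator does *not* emulate: bit–bit correlation (real
fingerprint bits co-occur along substructures), popcount variation with
molecule size, and activity cliffs. Passing tests on this generator
therefore show that the pipeline is correct and that the protocols behave
as designed under a clean factorized shift; they do not certify accuracy
levels on real assay data.

## Evaluation protocols

* **Shift detection**: label train rows 0 / prediction rows 1, 5-fold
  stratified cross-validated logistic regression, mean held-out accuracy.
  ≈ 0.5 means no detectable shift; the protocols warn (but proceed) below
  0.7.
* **Temporal protocol**: master 75/25 split by date, then per run an
  independent random 80% subsample of each master file (without
  replacement); KLIEP is refit inside every run on that run's subsamples,
  since a shifted classifier is specific to its prediction set; 20 runs,
  mean ± sd per method. A run whose training subsample loses a class is
  redrawn with the next derived seed and logged.
* **Cluster protocol**: k-means (k = 2, non-empty clusters enforced with
  up to 10 seeded restarts) on fingerprints; separability verified by the
  shift detector; then per direction (A→B, B→A) ten subsample runs per
  method, 80% subsampling mirroring the temporal protocol (the subset
  size is otherwise unspecified in the source protocols).
* **Comparison rule**: "no statistical advantage" is operationalized as
  mean ± sd interval overlap (difference below one pooled sd), matching
  how such results are conventionally reported.

All protocol randomness derives from one root seed through
`default_rng([seed, run, attempt])`-style keyed streams, so identical
seeds give bit-identical results regardless of execution order.

Problem sizes used by the shipped analyses and the acceptance script —
n = 1000 per set for the 1-D ratio benchmark, 500/class for the toy,
2000 + 2000 × 64 bits for the drift protocols, 20 temporal runs and
10 cluster subsets per direction — keep every driver under a minute on a
single CPU while leaving Monte-Carlo error well inside the tolerances
asserted by the tests.

## Known limitations

* **Pointwise ratio recovery in high dimension.** On 64-bit Bernoulli
  data the exact importance weight is a product of 64 per-bit factors and
  is heavy-tailed; a Gaussian-kernel mixture with prediction-set centers
  recovers its rank structure well (Spearman ≈ 0.74 in the seed-1
  acceptance run) but not its pointwise values (Pearson ≈ 0.2–0.4 across
  seeds), and even a supervised projection of the exact weights onto the
  kernel basis leaves much of the Pearson correlation unexplained. This
  is a property of kernel density-ratio models on high-dimensional binary
  data, and it is consistent with the headline null result: over-smoothed
  weights act close to uniform reweighting.
* **Self-consistency is bandwidth-limited.** With train = prediction,
  deviations of ŵ from 1 reflect how finely the kernel resolves sampling
  fluctuations of the density; at a fixed bandwidth they do not shrink as
  n grows. LCV compensates by widening the bandwidth when no shift is
  present, which keeps all weights within a few percent of 1.
* **No regression targets, no probability calibration, no alternative
  ratio estimators** (uLSIF, KMM) — out of scope by design.
* The cluster and temporal experiments shipped here run on the synthetic
  drift generator; accuracy levels on real assay datasets depend on
  features of real chemistry the generator does not model.
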