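# covshift

Covariate-shift analysis for QSAR classification: KLIEP importance-weight
estimation, importance-weighted logistic regression, a Tanimoto k-NN
baseline, and the temporal- and cluster-split protocols used to compare
them.

## The problem

Drug-discovery project teams move through chemical space: a model trained
on the series explored last year is asked to predict assay outcomes
(hERG liability, microsomal stability, solubility, target IC50) for a
structurally different series today. The labeling concept — "binds hERG",
"stable in microsomes" — is unchanged, but the distribution of the input
feature vectors has drifted. That situation is *covariate shift*: training
and prediction inputs are not iid, while p(y | x) is stationary.

The classical correction reweights each training instance x by the
importance

    w(x) = p_pred(x) / p_train(x),

so that the reweighted training distribution matches the prediction
distribution. This package estimates w(x) with the Kullback–Leibler
Importance Estimation Procedure (KLIEP): the ratio is modeled as a
nonnegative linear combination of Gaussian kernels centered on
prediction-set points,

    ŵ(x) = Σ_l α_l exp(−‖x − c_l‖² / 2σ²),

with the α_l chosen to maximize Σ_j log ŵ(x_j^pred) subject to α ≥ 0 and
the normalization mean_i ŵ(x_i^train) = 1 — a concave maximization solved
by projected gradient ascent. The fitted weights plug into a weighted
logistic regression ("KL+LR"), which is compared against plain logistic
regression (LR) and a Tanimoto-similarity k-NN (k = 5) under two
protocols:

* **temporal** — sort molecules by registration date, first 75% = master
  training set, rest = master prediction set; repeat each method on
  twenty random 80% subsamples of both master files;
* **cluster** — k-means (k = 2) on fingerprints defines clusters A and B;
  train on subsamples of one cluster, predict on the other, both
  directions, with and without reweighting.

Molecules are featurized as hashed path fingerprints (RDKit, 2048 bits by
default); assay values are binarized by per-assay cutoff rules with a
discard band between the positive and negative thresholds. Everything can
also run on two synthetic generators with known ground truth: a
rotated-Gaussian 2-D toy (with the exact mixture density ratio as oracle)
and a Bernoulli fingerprint-drift simulator (with exact per-instance
oracle weights and a stationary logistic concept).

## Worked example

Fit KLIEP between a drifted training/prediction pair and compare the three
classifiers under the temporal protocol (about ten seconds):

```bash
python analysis/03_temporal_comparison.py --seed 1
```

```
 KL+LR: 84.49% +/- 0.53%
    LR: 84.42% +/- 0.58%
   kNN: 64.01% +/- 1.09%
KL+LR vs LR within one sd: True
```

The reweighted and plain logistic regressions agree within a fraction of
one standard deviation — reweighting buys nothing here even though the
shift is real and detectable — while both beat the k-NN baseline by ~20
accuracy points. The companion drivers tell the rest of the story:

```bash
python analysis/01_toy_example.py --seed 1       # weighted boundary moves toward the oracle
python analysis/02_shift_detection.py --seed 1   # train-vs-pred separability rises with drift
python analysis/04_cluster_protocol.py --seed 1  # shifted 83.21% vs unshifted 83.19%
python analysis/05_weight_diagnostics.py --seed 1  # weight CDF spreads, CV = 0.77
```

`analysis/05_weight_diagnostics.py` rules out the trivial explanation for
the null result: the fitted weights are *not* all alike (coefficient of
variation 0.77, Spearman rank agreement 0.74 with the simulator's exact
oracle weights).

The same computations are exposed as a CLI (`covshift toy | simulate |
weights | evaluate`) for running on your own molecule tables — delimited
text with id, SMILES, assay value and registration date columns, plus a
YAML config naming the cutoff rules.

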