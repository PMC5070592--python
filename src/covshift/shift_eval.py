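"""Evaluation protocols for covariate-shift experiments.

Four protocols:

* :func:`detect_shift` — the two-sample classifier test: label training
  rows 0 and prediction rows 1 and cross-validate a logistic regression.
  Held-out accuracy near 0.5 means the sets are indistinguishable; well
  above 0.5 means they are drawn from different distributions, the
  precondition for covariate-shift correction to have anything to do.
* :func:`run_temporal_protocol` — time-split comparison: a 75/25 master
  split by registration date, then repeated runs each on a random 80%
  subsample of both master files, comparing KLIEP-weighted logistic
  regression (KL+LR), plain LR and Tanimoto k-NN by accuracy on the
  prediction subsample. KLIEP is refit inside every run on that run's
  subsamples, since a shifted classifier is specific to its prediction set.
* :func:`run_cluster_protocol` — cluster-split comparison: k-means (k=2)
  on fingerprints defines clusters A and B; repeated subsample runs train
  on one cluster and predict on the other, in both directions, comparing
  shifted (KL+LR) against unshifted (LR) accuracy.
* :func:`weight_cdf` — empirical CDF of fitted importance weights, the
  diagnostic that the weights actually spread (a degenerate all-equal
  weight distribution would make reweighting a no-op).

Method comparisons are reported as mean +/- sd over runs; "no statistical
advantage" is read as overlapping mean +/- sd intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.cluster import KMeans
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_score

from covshift.chemdata import (
    AssayCutoffs,
    MoleculeRecord,
    fingerprint_matrix,
    label_records,
    temporal_split,
)
from covshift.classifiers import (
    KNNModel,
    fit_weighted_logistic,
    knn_predict_many,
    predict_label,
)
from covshift.kliep import ImportanceWeights, estimate_weights, fit_kliep, make_basis

logger = logging.getLogger(__name__)

METHODS = ("KL+LR", "LR", "kNN")

__all__ = [
    "METHODS",
    "EvalResult",
    "ShiftReport",
    "WeightCDF",
    "detect_shift",
    "run_temporal_protocol",
    "kmeans_clusters",
    "run_cluster_protocol",
    "weight_cdf",
]


@dataclass(frozen=True)
class EvalResult:
    """Per-method accuracy summary over repeated runs."""

    method: str
    per_run_accuracy: tuple[float, ...]
    mean_accuracy: float
    sd_accuracy: float
    n_runs: int
    direction: str | None = None  # e.g. "A->B" for the cluster protocol

    @classmethod
    def from_runs(
        cls, method: str, accuracies: Sequence[float], direction: str | None = None
    ) -> "EvalResult":
        accs = tuple(float(a) for a in accuracies)
        return cls(
            method=method,
            per_run_accuracy=accs,
            mean_accuracy=float(np.mean(accs)),
            sd_accuracy=float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0,
            n_runs=len(accs),
            direction=direction,
        )


@dataclass(frozen=True)
class ShiftReport:
    """Two-sample classifier test result."""

    separation_accuracy: float
    n_train: int
    n_pred: int


@dataclass(frozen=True)
class WeightCDF:
    sorted_weights: np.ndarray
    cumulative_fraction: np.ndarray


def detect_shift(
    train_X: np.ndarray,
    pred_X: np.ndarray,
    folds: int = 5,
    seed: int = 0,
) -> ShiftReport:
    """Cross-validated train-vs-prediction separation accuracy."""
    train_X = np.atleast_2d(np.asarray(train_X, dtype=float))
    pred_X = np.atleast_2d(np.asarray(pred_X, dtype=float))
    if train_X.shape[0] < folds or pred_X.shape[0] < folds:
        raise ValueError(f"need at least {folds} instances in each set")
    X = np.vstack([train_X, pred_X])
    y = np.concatenate([np.zeros(train_X.shape[0]), np.ones(pred_X.shape[0])])
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    clf = LogisticRegression(max_iter=2000)
    scores = cross_val_score(clf, X, y, cv=cv, scoring="accuracy")
    return ShiftReport(
        separation_accuracy=float(np.mean(scores)),
        n_train=int(train_X.shape[0]),
        n_pred=int(pred_X.shape[0]),
    )


def _subsample(rng: np.random.Generator, n: int, fraction: float) -> np.ndarray:
    m = max(1, int(round(n * fraction)))
    return rng.choice(n, size=min(m, n), replace=False)


def _run_methods(
    methods: Sequence[str],
    train_X: np.ndarray,
    train_y: np.ndarray,
    test_X: np.ndarray,
    test_y: np.ndarray,
    k: int = 5,
    lam: float = 1e-4,
    kliep_b: int | None = None,
    kliep_sigma: float | None = None,
    kliep_seed: int = 0,
) -> dict[str, float]:
    """One run: fit each requested method and score accuracy on the test set."""
    accs: dict[str, float] = {}
    for method in methods:
        if method == "KL+LR":
            basis = make_basis(test_X, b=kliep_b, sigma=kliep_sigma, seed=kliep_seed)
            model, _ = fit_kliep(train_X, test_X, config=basis)
            w = estimate_weights(model, train_X)
            lr = fit_weighted_logistic(train_X, train_y, weights=w, lam=lam)
            accs[method] = float(np.mean(predict_label(lr, test_X) == test_y))
        elif method == "LR":
            lr = fit_weighted_logistic(train_X, train_y, lam=lam)
            accs[method] = float(np.mean(predict_label(lr, test_X) == test_y))
        elif method == "kNN":
            knn = KNNModel(
                k=k,
                reference_bits=np.asarray(train_X > 0.5, dtype=np.uint8),
                reference_labels=np.asarray(train_y, dtype=int),
            )
            pred = knn_predict_many(knn, np.asarray(test_X > 0.5, dtype=np.uint8))
            accs[method] = float(np.mean(pred == test_y))
        else:
            raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    return accs


def run_temporal_protocol(
    records: Sequence[MoleculeRecord],
    cutoffs: AssayCutoffs,
    methods: Sequence[str] = METHODS,
    n_runs: int = 20,
    subsample_fraction: float = 0.8,
    seed: int = 0,
    train_fraction: float = 0.75,
    n_bits: int = 2048,
    scheme: str = "path",
    lam: float = 1e-4,
    kliep_b: int | None = None,
    kliep_sigma: float | None = None,
) -> list[EvalResult]:
    """Time-split method comparison.

    Labels records by the cutoff rules (dropping the discard band), splits
    the labeled data 75/25 by registration date into master train and
    prediction sets, then per run draws an independent random
    ``subsample_fraction`` of each master file (without replacement),
    refits every method on the run's training subsample, and scores it on
    the run's prediction subsample. Runs whose training subsample loses a
    class are redrawn with the next sub-seed (logged).
    """
    for m in methods:
        if m not in METHODS:
            raise ValueError(f"unknown method {m!r}; choose from {METHODS}")
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    kept, labels, n_discarded = label_records(records, cutoffs)
    logger.info(
        "temporal protocol: %d labeled records (%d discarded in band)",
        len(kept),
        n_discarded,
    )
    id_to_row = {rec.id: i for i, rec in enumerate(kept)}
    X = fingerprint_matrix(kept, n_bits=n_bits, scheme=scheme)
    master_train, master_pred = temporal_split(kept, train_fraction)
    tr_idx = np.array([id_to_row[r.id] for r in master_train])
    pr_idx = np.array([id_to_row[r.id] for r in master_pred])

    per_method: dict[str, list[float]] = {m: [] for m in methods}
    for run in range(n_runs):
        for attempt in range(20):
            rng = np.random.default_rng([seed, run, attempt])
            sub_tr = tr_idx[_subsample(rng, len(tr_idx), subsample_fraction)]
            sub_pr = pr_idx[_subsample(rng, len(pr_idx), subsample_fraction)]
            if len(np.unique(labels[sub_tr])) == 2:
                break
            logger.warning("run %d attempt %d lost a class; redrawing", run, attempt)
        else:
            raise ValueError("could not draw a two-class training subsample")
        accs = _run_methods(
            methods,
            X[sub_tr],
            labels[sub_tr],
            X[sub_pr],
            labels[sub_pr],
            lam=lam,
            kliep_b=kliep_b,
            kliep_sigma=kliep_sigma,
            kliep_seed=int(np.random.default_rng([seed, run, 999]).integers(2**31)),
        )
        for m, a in accs.items():
            per_method[m].append(a)
    return [EvalResult.from_runs(m, per_method[m]) for m in methods]


def kmeans_clusters(
    fingerprints: np.ndarray, k: int = 2, seed: int = 0, max_restarts: int = 10
) -> np.ndarray:
    """K-means on bit vectors treated as reals; guarantees non-empty clusters."""
    X = np.atleast_2d(np.asarray(fingerprints, dtype=float))
    if k < 2:
        raise ValueError("k must be >= 2")
    if np.unique(X, axis=0).shape[0] < k:
        raise ValueError(f"need at least {k} distinct fingerprints")
    for r in range(max_restarts):
        km = KMeans(n_clusters=k, random_state=seed + r, n_init=10)
        assign = km.fit_predict(X)
        if len(np.unique(assign)) == k:
            return assign
        logger.warning("empty cluster with seed %d; restarting", seed + r)
    raise RuntimeError("k-means produced an empty cluster in every restart")


def run_cluster_protocol(
    records: Sequence[MoleculeRecord],
    cutoffs: AssayCutoffs,
    methods: Sequence[str] = ("KL+LR", "LR"),
    n_subsets: int = 10,
    subsample_fraction: float = 0.8,
    seed: int = 0,
    n_bits: int = 2048,
    scheme: str = "path",
    lam: float = 1e-4,
    kliep_b: int | None = None,
    kliep_sigma: float | None = None,
) -> tuple[ShiftReport, list[EvalResult]]:
    """Cluster-split comparison of shifted vs unshifted classifiers.

    K-means (k=2) on the fingerprints defines clusters A and B; their
    separability is verified with :func:`detect_shift` (a warning is
    logged below 0.7 separation accuracy — weak covariate-shift
    precondition). For each direction (train on A predict on B, and the
    reverse) and each method, ``n_subsets`` seeded runs subsample both
    clusters and score accuracy on the target subsample.
    """
    kept, labels, n_discarded = label_records(records, cutoffs)
    logger.info(
        "cluster protocol: %d labeled records (%d discarded in band)",
        len(kept),
        n_discarded,
    )
    X = fingerprint_matrix(kept, n_bits=n_bits, scheme=scheme)
    assign = kmeans_clusters(X, k=2, seed=seed)
    idx_a = np.where(assign == 0)[0]
    idx_b = np.where(assign == 1)[0]
    shift = detect_shift(X[idx_a], X[idx_b], seed=seed)
    if shift.separation_accuracy < 0.7:
        logger.warning(
            "clusters separate with accuracy %.3f < 0.7; covariate-shift "
            "precondition is weak, proceeding anyway",
            shift.separation_accuracy,
        )

    results: list[EvalResult] = []
    for dir_id, (direction, (src, dst)) in enumerate(
        (("A->B", (idx_a, idx_b)), ("B->A", (idx_b, idx_a)))
    ):
        per_method: dict[str, list[float]] = {m: [] for m in methods}
        for run in range(n_subsets):
            for attempt in range(20):
                rng = np.random.default_rng([seed, dir_id, run, attempt])
                sub_src = src[_subsample(rng, len(src), subsample_fraction)]
                sub_dst = dst[_subsample(rng, len(dst), subsample_fraction)]
                if len(np.unique(labels[sub_src])) == 2:
                    break
            else:
                raise ValueError("could not draw a two-class training subsample")
            accs = _run_methods(
                methods,
                X[sub_src],
                labels[sub_src],
                X[sub_dst],
                labels[sub_dst],
                lam=lam,
                kliep_b=kliep_b,
                kliep_sigma=kliep_sigma,
                kliep_seed=seed + run,
            )
            for m, a in accs.items():
                per_method[m].append(a)
        for m in methods:
            results.append(EvalResult.from_runs(m, per_method[m], direction=direction))
    return shift, results


def weight_cdf(weights: ImportanceWeights | np.ndarray) -> WeightCDF:
    """Empirical CDF of the importance weights."""
    w = np.sort(np.asarray(weights, dtype=float))
    if w.size == 0:
        raise ValueError("weights must be non-empty")
    frac = np.arange(1, w.size + 1) / w.size
    return WeightCDF(sorted_weights=w, cumulative_fraction=frac)
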