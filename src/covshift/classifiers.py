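"""The two learners compared: weighted logistic regression and Tanimoto k-NN.

Importance-weighted logistic regression maximizes the weighted
log-likelihood sum_i w_i [y_i log p_i + (1-y_i) log(1-p_i)] with a small
ridge penalty for stability on high-dimensional sparse fingerprints;
all-ones weights recover plain logistic regression. The k-NN baseline
votes the majority label among the k references most Tanimoto-similar to
the query and never uses importance weights — the three methods under
comparison are KLIEP-weighted LR, plain LR, and k-NN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LogisticRegression

from covshift.chemdata import Fingerprint
from covshift.kliep import ImportanceWeights

__all__ = [
    "LogisticModel",
    "KNNModel",
    "fit_weighted_logistic",
    "predict_proba",
    "predict_label",
    "knn_predict",
    "knn_predict_many",
]


@dataclass(frozen=True)
class LogisticModel:
    coefficients: np.ndarray
    intercept: float
    regularization: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.coefficients)) or not np.isfinite(
            self.intercept
        ):
            raise ValueError("model parameters must be finite")

    def to_text(self) -> str:
        lines = [f"intercept\t{self.intercept!r}", f"lam\t{self.regularization!r}"]
        lines += [f"coef_{i}\t{c!r}" for i, c in enumerate(self.coefficients)]
        return "\n".join(lines)


@dataclass(frozen=True)
class KNNModel:
    """Reference fingerprints + labels; k must be odd so binary votes never tie."""

    k: int
    reference_bits: np.ndarray  # (n_ref, n_bits) 0/1
    reference_labels: np.ndarray  # (n_ref,) in {0,1}

    def __post_init__(self) -> None:
        if self.k < 1 or self.k % 2 == 0:
            raise ValueError("k must be a positive odd integer")
        if self.k > self.reference_bits.shape[0]:
            raise ValueError("k exceeds the reference set size")
        if self.reference_bits.shape[0] != self.reference_labels.shape[0]:
            raise ValueError("reference bits and labels must align")


def _as_weight_array(
    weights: ImportanceWeights | np.ndarray | None, n: int
) -> np.ndarray:
    if weights is None:
        return np.ones(n)
    w = np.asarray(weights, dtype=float)
    if w.shape != (n,):
        raise ValueError(f"expected {n} weights, got shape {w.shape}")
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    return w


def fit_weighted_logistic(
    X: np.ndarray,
    y: np.ndarray,
    weights: ImportanceWeights | np.ndarray | None = None,
    lam: float = 1e-4,
) -> LogisticModel:
    """Fit logistic regression with per-instance importance weights.

    Weights are rescaled to mean one before fitting, so a constant weight
    vector reproduces the unweighted fit exactly and the effective ridge
    strength ``lam`` does not depend on the weight scale. Solved by
    scikit-learn's lbfgs on the ridge-penalized weighted log-likelihood
    (deterministic: the problem is strictly convex).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=int)
    n = X.shape[0]
    if y.shape != (n,):
        raise ValueError("X and y must align")
    w = _as_weight_array(weights, n)
    total = w.sum()
    if total <= 0:
        raise ValueError("total weight must be positive")
    w = w * (n / total)
    classes = np.unique(y[w > 0])
    if classes.size < 2:
        raise ValueError("both classes must be present with positive weight")
    if lam <= 0:
        raise ValueError("lam must be positive (use a tiny value for ~no penalty)")
    clf = LogisticRegression(
        C=1.0 / lam, solver="lbfgs", max_iter=5000, tol=1e-10
    )
    clf.fit(X, y, sample_weight=w)
    return LogisticModel(
        coefficients=clf.coef_.ravel().copy(),
        intercept=float(clf.intercept_[0]),
        regularization=float(lam),
    )


def predict_proba(model: LogisticModel, X: np.ndarray) -> np.ndarray:
    """P(class 1 | x) = logistic(beta . x + intercept)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.coefficients.shape[0]:
        raise ValueError("feature dimension mismatch")
    z = X @ model.coefficients + model.intercept
    return 1.0 / (1.0 + np.exp(-z))


def predict_label(model: LogisticModel, X: np.ndarray) -> np.ndarray:
    """Class 1 iff the predicted probability is >= 0.5."""
    return (predict_proba(model, X) >= 0.5).astype(int)


def _tanimoto_to_references(model: KNNModel, query_bits: np.ndarray) -> np.ndarray:
    q = np.asarray(query_bits, dtype=np.int64)
    R = np.asarray(model.reference_bits, dtype=np.int64)
    inter = R @ q
    union = R.sum(axis=1) + q.sum() - inter
    sims = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    return sims


def knn_predict(model: KNNModel, query: Fingerprint | np.ndarray) -> int:
    """Majority label among the k most Tanimoto-similar references.

    Similarity ties at the k-th rank are broken by reference insertion
    order (stable sort), so predictions are reproducible.
    """
    bits = query.bits if isinstance(query, Fingerprint) else np.asarray(query)
    if bits.shape[0] != model.reference_bits.shape[1]:
        raise ValueError("query fingerprint length mismatch")
    sims = _tanimoto_to_references(model, bits)
    top = np.argsort(-sims, kind="stable")[: model.k]
    votes = model.reference_labels[top]
    return int(votes.sum() * 2 > model.k)


def knn_predict_many(model: KNNModel, query_bits: np.ndarray) -> np.ndarray:
    """Vectorized :func:`knn_predict` over rows of a query bit matrix."""
    Q = np.asarray(query_bits, dtype=np.int64)
    R = np.asarray(model.reference_bits, dtype=np.int64)
    inter = Q @ R.T  # (n_q, n_ref)
    union = Q.sum(axis=1)[:, None] + R.sum(axis=1)[None, :] - inter
    sims = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    # stable argsort along each row keeps insertion-order tie-breaking
    order = np.argsort(-sims, axis=1, kind="stable")[:, : model.k]
    votes = model.reference_labels[order].sum(axis=1)
    return (votes * 2 > model.k).astype(int)
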