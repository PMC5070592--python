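"""Kullback-Leibler Importance Estimation Procedure (KLIEP).

Estimates the importance weight w(x) = p_pred(x) / p_train(x) — the ratio
of the prediction-set density to the training-set density — directly,
without estimating either density. The ratio is modeled as a nonnegative
linear combination of Gaussian kernels centered on prediction points,

    w_hat(x) = sum_l alpha_l * exp(-||x - c_l||^2 / (2 sigma^2)),

and the alphas are chosen to maximize the prediction-set log-likelihood of
the implied density estimate w_hat(x) * p_train(x),

    maximize   sum_j log( w_hat(x_j^pred) )
    subject to mean_i w_hat(x_i^train) = 1,   alpha >= 0.

The constraint normalizes w_hat(x) * p_train(x) to (approximately) a
probability density over the training sample and makes the fitted weights
interpretable as relative importances with mean one. The problem is
concave in alpha and is solved here by projected gradient ascent with
backtracking, so the recorded objective trace is non-decreasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "BasisConfig",
    "KLIEPModel",
    "ImportanceWeights",
    "KLIEPFitReport",
    "gaussian_basis",
    "kliep_objective",
    "make_basis",
    "median_heuristic_sigma",
    "fit_kliep",
    "estimate_weights",
    "select_sigma_lcv",
]

_FEASIBILITY_EPS = 1e-300


@dataclass(frozen=True)
class BasisConfig:
    """Gaussian kernel basis: centers (drawn from the prediction set) and bandwidth."""

    centers: np.ndarray  # (b, d)
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.centers.ndim != 2 or self.centers.shape[0] < 1:
            raise ValueError("centers must be a non-empty (b, d) array")

    @property
    def b(self) -> int:
        return int(self.centers.shape[0])


@dataclass(frozen=True)
class KLIEPModel:
    """Fitted density-ratio model w_hat(x) = sum_l alpha_l phi_l(x)."""

    basis: BasisConfig
    alphas: np.ndarray  # (b,), all >= 0
    normalizer: float  # value of mean_i w_hat(x_i^train) at the solution

    def __post_init__(self) -> None:
        if np.any(self.alphas < 0):
            raise ValueError("alphas must be nonnegative")
        if self.alphas.shape[0] != self.basis.b:
            raise ValueError("alphas must match the number of basis centers")


@dataclass(frozen=True)
class ImportanceWeights:
    """Per-instance nonnegative importance weights.

    When evaluated on the training sample the fit was normalized against,
    the arithmetic mean is 1 (within optimizer tolerance).
    """

    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 1 or w.size == 0:
            raise ValueError("weights must be a non-empty 1-D vector")
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")

    def __array__(self, dtype=None, copy=None) -> np.ndarray:
        return np.asarray(self.weights, dtype=dtype)

    def __len__(self) -> int:
        return int(self.weights.size)

    @property
    def mean(self) -> float:
        return float(np.mean(self.weights))


@dataclass
class KLIEPFitReport:
    """Diagnostics of one KLIEP fit."""

    objective_trace: list[float] = field(default_factory=list)
    iterations: int = 0
    converged: bool = False
    selected_sigma: float | None = None


def gaussian_basis(x: np.ndarray, center: np.ndarray, sigma: float) -> float:
    """Single Gaussian kernel value exp(-||x - center||^2 / (2 sigma^2))."""
    x = np.asarray(x, dtype=float)
    center = np.asarray(center, dtype=float)
    if x.shape != center.shape:
        raise ValueError(f"dimension mismatch: {x.shape} vs {center.shape}")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    d2 = float(np.sum((x - center) ** 2))
    return float(np.exp(-d2 / (2.0 * sigma**2)))


def _phi(X: np.ndarray, centers: np.ndarray, sigma: float) -> np.ndarray:
    """Kernel design matrix: phi[i, l] = gaussian_basis(X[i], centers[l], sigma)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != centers.shape[1]:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match centers "
            f"({centers.shape[1]})"
        )
    d2 = cdist(X, centers, metric="sqeuclidean")
    return np.exp(-d2 / (2.0 * sigma**2))


def kliep_objective(alphas: np.ndarray, phi_pred: np.ndarray) -> float:
    """Prediction-set log-likelihood proxy sum_j log(phi_pred @ alphas).

    Returns -inf if any inner sum is nonpositive (infeasible point).
    """
    inner = phi_pred @ np.asarray(alphas, dtype=float)
    if np.any(inner <= 0):
        return -np.inf
    return float(np.sum(np.log(inner)))


def median_heuristic_sigma(X: np.ndarray, max_points: int = 1000, seed: int = 0) -> float:
    """Median pairwise Euclidean distance, subsampled for large inputs."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] > max_points:
        rng = np.random.default_rng(seed)
        X = X[rng.choice(X.shape[0], size=max_points, replace=False)]
    d = cdist(X, X)
    vals = d[np.triu_indices_from(d, k=1)]
    med = float(np.median(vals))
    if med <= 0:
        # all points identical; any positive bandwidth behaves the same
        return 1.0
    return med


def make_basis(
    pred_X: np.ndarray,
    b: int | None = None,
    sigma: float | None = None,
    seed: int = 0,
) -> BasisConfig:
    """Choose basis centers uniformly without replacement from the prediction set.

    Defaults: b = min(100, n_pred); sigma by the median pairwise-distance
    heuristic on the prediction points.
    """
    pred_X = np.atleast_2d(np.asarray(pred_X, dtype=float))
    n_p = pred_X.shape[0]
    if b is None:
        b = min(100, n_p)
    if b > n_p:
        raise ValueError(f"b={b} exceeds the number of prediction points ({n_p})")
    rng = np.random.default_rng(seed)
    idx = rng.choice(n_p, size=b, replace=False)
    if sigma is None:
        sigma = median_heuristic_sigma(pred_X, seed=seed)
    return BasisConfig(centers=pred_X[np.sort(idx)].copy(), sigma=float(sigma))


def fit_kliep(
    train_X: np.ndarray,
    pred_X: np.ndarray,
    config: BasisConfig | None = None,
    step: float = 1e-4,
    max_iter: int = 5000,
    tol: float = 1e-6,
    seed: int = 0,
) -> tuple[KLIEPModel, KLIEPFitReport]:
    """Fit the density ratio by projected gradient ascent.

    Each iteration takes a gradient step on the log-likelihood, projects
    back onto the mean-one training constraint, clips the alphas at zero,
    and renormalizes; backtracking halves the step whenever a move would
    decrease the objective, so the trace is non-decreasing. Stops when the
    objective gain falls below ``tol`` or after ``max_iter`` iterations
    (in which case ``converged`` is False and the best iterate is kept).
    """
    train_X = np.atleast_2d(np.asarray(train_X, dtype=float))
    pred_X = np.atleast_2d(np.asarray(pred_X, dtype=float))
    n_t, n_p = train_X.shape[0], pred_X.shape[0]
    if n_t < 2 or n_p < 2:
        raise ValueError("need at least 2 training and 2 prediction points")
    if config is None:
        config = make_basis(pred_X, seed=seed)

    phi_pred = _phi(pred_X, config.centers, config.sigma)
    phi_train = _phi(train_X, config.centers, config.sigma)

    if np.any(phi_pred.max(axis=1) <= _FEASIBILITY_EPS):
        raise ValueError(
            "some prediction points receive zero basis mass; increase sigma"
        )
    # mean-one constraint: bvec @ alpha == 1 where bvec_l = mean_i phi_train[i, l]
    bvec = phi_train.mean(axis=0)
    if bvec.max() <= _FEASIBILITY_EPS:
        raise ValueError(
            "training points receive zero basis mass; increase sigma"
        )

    bb = float(bvec @ bvec)

    def project(a: np.ndarray) -> np.ndarray | None:
        a = a + (1.0 - bvec @ a) * bvec / bb
        a = np.clip(a, 0.0, None)
        s = float(bvec @ a)
        if s <= 0:
            return None
        return a / s

    alpha = project(np.ones(config.b))
    if alpha is None:
        raise ValueError("could not find a feasible starting point; increase sigma")
    obj = kliep_objective(alpha, phi_pred)
    if not np.isfinite(obj):
        raise ValueError(
            "objective infeasible at the starting point; increase sigma"
        )

    trace = [obj]
    cur_step = float(step)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        inner = phi_pred @ alpha
        grad = phi_pred.T @ (1.0 / inner)
        accepted = False
        while cur_step > 1e-14:
            cand = project(alpha + cur_step * grad)
            if cand is not None:
                cand_obj = kliep_objective(cand, phi_pred)
                if cand_obj >= obj:
                    gain = cand_obj - obj
                    alpha, obj = cand, cand_obj
                    trace.append(obj)
                    accepted = True
                    cur_step *= 1.2  # cautious step growth after a success
                    break
            cur_step *= 0.5
        if not accepted:
            converged = True  # no ascent direction at resolvable step size
            break
        if gain < tol:
            converged = True
            break

    normalizer = float(bvec @ alpha)
    model = KLIEPModel(basis=config, alphas=alpha, normalizer=normalizer)
    report = KLIEPFitReport(
        objective_trace=trace, iterations=it, converged=converged
    )
    return model, report


def estimate_weights(model: KLIEPModel, X: np.ndarray) -> ImportanceWeights:
    """Evaluate w_hat on new points (clipped at zero).

    On the training set used in the fit, the weights have mean 1 by the
    normalization constraint.
    """
    phi = _phi(X, model.basis.centers, model.basis.sigma)
    w = np.clip(phi @ model.alphas, 0.0, None)
    return ImportanceWeights(weights=w)


def select_sigma_lcv(
    train_X: np.ndarray,
    pred_X: np.ndarray,
    sigma_grid: list[float],
    folds: int = 5,
    seed: int = 0,
    b: int | None = None,
    step: float = 1e-4,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> float:
    """Likelihood cross-validation over a bandwidth grid.

    The prediction set is split into ``folds`` parts; for each candidate
    sigma, KLIEP is fit with the held-out part removed and scored by the
    mean log w_hat on the held-out prediction points. Returns the sigma
    maximizing the mean held-out score (ties broken toward the smaller
    sigma, so the choice does not depend on grid order).
    """
    if len(sigma_grid) == 0:
        raise ValueError("sigma grid must be non-empty")
    if folds < 2:
        raise ValueError("need at least 2 folds")
    pred_X = np.atleast_2d(np.asarray(pred_X, dtype=float))
    n_p = pred_X.shape[0]
    if n_p < folds:
        raise ValueError("fewer prediction points than folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_p)
    fold_ids = np.array_split(perm, folds)

    scores: dict[float, float] = {}
    for sigma in sigma_grid:
        fold_scores = []
        try:
            for held in fold_ids:
                mask = np.ones(n_p, dtype=bool)
                mask[held] = False
                fit_pred = pred_X[mask]
                basis = make_basis(fit_pred, b=b, sigma=float(sigma), seed=seed)
                model, _ = fit_kliep(
                    train_X, fit_pred, config=basis,
                    step=step, max_iter=max_iter, tol=tol,
                )
                w_held = np.asarray(estimate_weights(model, pred_X[held]))
                if np.any(w_held <= 0):
                    fold_scores.append(-np.inf)
                else:
                    fold_scores.append(float(np.mean(np.log(w_held))))
        except ValueError:
            scores[float(sigma)] = -np.inf
            continue
        scores[float(sigma)] = float(np.mean(fold_scores))

    best = max(sorted(scores), key=lambda s: (scores[s], -s))
    if not np.isfinite(scores[best]):
        raise ValueError("no bandwidth in the grid produced a feasible fit")
    return best
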