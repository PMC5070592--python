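"""Synthetic generators with known ground truth.

Three generators cover the inputs the pipeline needs without any external
data, each a pure function of its config and seed:

* :func:`make_importance_curve` — the closed-form importance weight
  w(x) = N(x; mu_p, sigma_p^2) / N(x; mu_t, sigma_t^2) between a training
  and a prediction Gaussian on a 1-D grid.
* :func:`make_gaussian_toy` — the rotated two-Gaussian classification toy:
  training points from two 2-D class Gaussians, prediction points from a
  rotated version of the same distributions (covariate shift with an
  unchanged class concept), plus the "oracle" boundary fit on the union.
* :func:`make_fingerprint_drift` — binary-fingerprint-like feature drift
  emulating a chemistry team moving from one structural series to another:
  train and prediction bits are independent Bernoulli draws whose per-bit
  probabilities drift between the sets, while labels come from one fixed
  logistic concept (stationary concept). Because the simulator owns both
  factorized Bernoulli densities, it also emits the exact importance
  weight for every training instance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
from scipy.stats import norm

from covshift.chemdata import AssayCutoffs, MoleculeRecord, bits_to_hex
from covshift.classifiers import LogisticModel, fit_weighted_logistic

__all__ = [
    "GaussianToyConfig",
    "GaussianToyData",
    "DriftSimConfig",
    "DriftSimData",
    "make_gaussian_toy",
    "make_importance_curve",
    "make_fingerprint_drift",
    "boundary_angle_deg",
    "write_molecule_table",
]


# ---------------------------------------------------------------------------
# closed-form importance curve for a 1-D Gaussian pair


def make_importance_curve(
    mu_t: float,
    sigma_t: float,
    mu_p: float,
    sigma_p: float,
    grid: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Training density, prediction density and their ratio w on a grid."""
    if sigma_t <= 0 or sigma_p <= 0:
        raise ValueError("standard deviations must be positive")
    grid = np.asarray(grid, dtype=float)
    p_t = norm.pdf(grid, loc=mu_t, scale=sigma_t)
    p_p = norm.pdf(grid, loc=mu_p, scale=sigma_p)
    w = p_p / p_t
    return p_t, p_p, w


# ---------------------------------------------------------------------------
# Rotated-Gaussian toy


@dataclass(frozen=True)
class GaussianToyConfig:
    """Two 2-D class Gaussians; the prediction set is rotated about the
    midpoint of the class means, shifting covariates but not the concept.

    The default class covariances are unequal and anisotropic on purpose:
    with equal covariances the Bayes boundary is linear, logistic
    regression is correctly specified, and importance weighting provably
    has no effect on the limiting boundary — the reweighting effect the
    toy is meant to display only exists under model misspecification.
    """

    n_per_class_train: int = 500
    n_per_class_pred: int = 500
    class_means: tuple[tuple[float, float], tuple[float, float]] = ((0.0, 0.0), (2.0, 2.0))
    class_covariances: tuple[np.ndarray, np.ndarray] = (
        np.array([[1.0, 0.0], [0.0, 0.1]]),
        np.array([[0.3, 0.0], [0.0, 0.9]]),
    )
    rotation_deg: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        for cov in self.class_covariances:
            cov = np.asarray(cov, dtype=float)
            if cov.shape != (2, 2) or not np.allclose(cov, cov.T):
                raise ValueError("covariances must be symmetric 2x2")
            if np.any(np.linalg.eigvalsh(cov) < -1e-12):
                raise ValueError("covariances must be positive semi-definite")


@dataclass
class GaussianToyData:
    train_X: np.ndarray
    train_y: np.ndarray
    pred_X: np.ndarray
    pred_y: np.ndarray
    oracle_boundary: LogisticModel
    config: GaussianToyConfig


def _rotation_matrix(deg: float) -> np.ndarray:
    th = np.deg2rad(deg)
    return np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])


def make_gaussian_toy(config: GaussianToyConfig | None = None) -> GaussianToyData:
    """Sample the rotated-Gaussian toy and fit the oracle boundary.

    The oracle boundary is the logistic regression trained on the pooled
    train + prediction points — the best achievable linear classifier if
    the prediction labels were available.
    """
    if config is None:
        config = GaussianToyConfig()
    rng = np.random.default_rng(config.seed)
    means = [np.asarray(m, dtype=float) for m in config.class_means]
    covs = [np.asarray(c, dtype=float) for c in config.class_covariances]
    center = (means[0] + means[1]) / 2.0
    R = _rotation_matrix(config.rotation_deg)

    def sample(n_per_class: int, rotate: bool) -> tuple[np.ndarray, np.ndarray]:
        xs, ys = [], []
        for cls in (0, 1):
            m, c = means[cls], covs[cls]
            if rotate:
                m = R @ (m - center) + center
                c = R @ c @ R.T
            xs.append(rng.multivariate_normal(m, c, size=n_per_class))
            ys.append(np.full(n_per_class, cls))
        return np.vstack(xs), np.concatenate(ys)

    train_X, train_y = sample(config.n_per_class_train, rotate=False)
    pred_X, pred_y = sample(config.n_per_class_pred, rotate=True)
    oracle = fit_weighted_logistic(
        np.vstack([train_X, pred_X]), np.concatenate([train_y, pred_y])
    )
    return GaussianToyData(
        train_X=train_X,
        train_y=train_y,
        pred_X=pred_X,
        pred_y=pred_y,
        oracle_boundary=oracle,
        config=config,
    )


def toy_oracle_importance(config: GaussianToyConfig, X: np.ndarray) -> np.ndarray:
    """Exact importance weight p_pred(x) / p_train(x) for the toy mixtures.

    Available because the generator owns both class-mixture densities;
    serves as the ground truth against which KLIEP estimates are judged.
    """
    from scipy.stats import multivariate_normal

    X = np.atleast_2d(np.asarray(X, dtype=float))
    means = [np.asarray(m, dtype=float) for m in config.class_means]
    covs = [np.asarray(c, dtype=float) for c in config.class_covariances]
    center = (means[0] + means[1]) / 2.0
    R = _rotation_matrix(config.rotation_deg)
    p_t = sum(multivariate_normal.pdf(X, m, c) for m, c in zip(means, covs)) / 2.0
    p_p = (
        sum(
            multivariate_normal.pdf(X, R @ (m - center) + center, R @ c @ R.T)
            for m, c in zip(means, covs)
        )
        / 2.0
    )
    return p_p / p_t


def boundary_angle_deg(model: LogisticModel) -> float:
    """Orientation of a 2-D decision line in degrees, in [0, 180).

    Measured as the angle of the boundary's normal vector (the coefficient
    vector); lines are orientation-less so angles are taken modulo 180.
    """
    beta = model.coefficients
    if beta.shape[0] != 2:
        raise ValueError("boundary angle is defined for 2-D models only")
    ang = np.degrees(np.arctan2(beta[1], beta[0]))
    return float(ang % 180.0)


# ---------------------------------------------------------------------------
# Fingerprint drift simulator


@dataclass(frozen=True)
class DriftSimConfig:
    """Bernoulli bit-vector drift with a stationary logistic concept.

    Per-bit on-probabilities drift between train and prediction on the
    logit scale: logit p'_b = logit p_b + drift_magnitude * z_b with fixed
    standard-normal z_b, clipped to [0.01, 0.99]. Labels are the fixed
    concept sign(beta . x + beta_0) flipped independently with probability
    ``label_noise`` — the concept (and hence the achievable Bayes accuracy,
    1 - label_noise) is identical in both sets.
    """

    n_train: int = 2000
    n_pred: int = 2000
    n_bits: int = 64
    base_bit_probs: np.ndarray | None = None  # default: Uniform(0.05, 0.5) draws
    drift_magnitude: float = 1.0
    concept_coefficients: np.ndarray | None = None  # default: N(0,1) draws
    concept_intercept: float | None = None  # default: centers the classes
    label_noise: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.drift_magnitude < 0:
            raise ValueError("drift_magnitude must be >= 0")
        if not 0.0 <= self.label_noise < 0.5:
            raise ValueError("label_noise must be in [0, 0.5)")
        if self.base_bit_probs is not None:
            p = np.asarray(self.base_bit_probs, dtype=float)
            if p.shape != (self.n_bits,):
                raise ValueError("base_bit_probs must have length n_bits")
            if np.any(p <= 0) or np.any(p >= 1):
                raise ValueError("base_bit_probs must lie strictly in (0, 1)")


@dataclass
class DriftSimData:
    train_records: list[MoleculeRecord]
    train_labels: np.ndarray
    pred_records: list[MoleculeRecord]
    pred_labels: np.ndarray
    train_bits: np.ndarray
    pred_bits: np.ndarray
    oracle_weights: np.ndarray  # exact p_pred/p_train at each train instance
    base_bit_probs: np.ndarray
    drifted_bit_probs: np.ndarray
    concept_coefficients: np.ndarray
    concept_intercept: float
    config: DriftSimConfig

    @property
    def cutoffs(self) -> AssayCutoffs:
        """Cutoff rule matching the synthetic assay values (no discard hits)."""
        return AssayCutoffs(
            assay_name="synthetic-drift",
            positive_threshold=10.0,
            positive_direction="<",
            negative_threshold=15.0,
            negative_direction=">",
        )

    @property
    def all_records(self) -> list[MoleculeRecord]:
        return list(self.train_records) + list(self.pred_records)

    def concept_accuracy(self, which: str = "pred") -> float:
        """Accuracy of the true concept on the realized (noisy) labels."""
        if which == "train":
            bits, labels = self.train_bits, self.train_labels
        elif which == "pred":
            bits, labels = self.pred_bits, self.pred_labels
        else:
            raise ValueError("which must be 'train' or 'pred'")
        z = bits @ self.concept_coefficients + self.concept_intercept
        return float(np.mean((z > 0).astype(int) == labels))


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p / (1.0 - p))


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def make_fingerprint_drift(config: DriftSimConfig | None = None) -> DriftSimData:
    """Simulate binary-fingerprint drift with exact oracle importance weights.

    Records carry hex-encoded bit vectors in the SMILES slot (fingerprint
    scheme ``"hex"``), synthetic assay values consistent with
    ``DriftSimData.cutoffs``, and monotone pseudo-dates: every training
    record predates every prediction record, so a
    ``temporal_split`` at fraction n_train / (n_train + n_pred) on the
    concatenated records reproduces the simulated partition exactly.
    """
    if config is None:
        config = DriftSimConfig()
    rng = np.random.default_rng(config.seed)

    if config.base_bit_probs is None:
        base = rng.uniform(0.05, 0.5, size=config.n_bits)
    else:
        base = np.asarray(config.base_bit_probs, dtype=float)
    base = np.clip(base, 0.01, 0.99)
    z_shift = rng.standard_normal(config.n_bits)
    drifted = _sigmoid(_logit(base) + config.drift_magnitude * z_shift)
    drifted = np.clip(drifted, 0.01, 0.99)

    if config.concept_coefficients is None:
        beta = rng.standard_normal(config.n_bits)
    else:
        beta = np.asarray(config.concept_coefficients, dtype=float)
    if config.concept_intercept is None:
        # center the concept between the two sets' mean feature vectors
        beta0 = -float(beta @ ((base + drifted) / 2.0))
    else:
        beta0 = float(config.concept_intercept)

    train_bits = (rng.random((config.n_train, config.n_bits)) < base).astype(np.uint8)
    pred_bits = (rng.random((config.n_pred, config.n_bits)) < drifted).astype(np.uint8)

    def labels_for(bits: np.ndarray) -> np.ndarray:
        y = (bits @ beta + beta0 > 0).astype(int)
        flips = rng.random(bits.shape[0]) < config.label_noise
        return np.where(flips, 1 - y, y)

    train_y = labels_for(train_bits)
    pred_y = labels_for(pred_bits)

    # exact factorized Bernoulli likelihood ratio, in log space for stability
    log_ratio_on = np.log(drifted) - np.log(base)
    log_ratio_off = np.log1p(-drifted) - np.log1p(-base)
    log_w = train_bits @ log_ratio_on + (1 - train_bits) @ log_ratio_off
    oracle_w = np.exp(log_w)

    t0 = date(2015, 1, 1)

    def records_for(bits: np.ndarray, y: np.ndarray, prefix: str, day0: int):
        recs = []
        for i in range(bits.shape[0]):
            recs.append(
                MoleculeRecord(
                    id=f"{prefix}{i:06d}",
                    smiles=bits_to_hex(bits[i]),
                    assay_value=5.0 if y[i] == 1 else 20.0,
                    registration_date=t0 + timedelta(days=day0 + i),
                )
            )
        return recs

    train_records = records_for(train_bits, train_y, "trn", 0)
    pred_records = records_for(pred_bits, pred_y, "prd", config.n_train)

    return DriftSimData(
        train_records=train_records,
        train_labels=train_y,
        pred_records=pred_records,
        pred_labels=pred_y,
        train_bits=train_bits,
        pred_bits=pred_bits,
        oracle_weights=oracle_w,
        base_bit_probs=base,
        drifted_bit_probs=drifted,
        concept_coefficients=beta,
        concept_intercept=beta0,
        config=config,
    )


def write_molecule_table(path: str, records, labels=None) -> None:
    """Write records in the delimited dialect ``read_molecule_table`` reads."""
    import pandas as pd

    cols = {
        "id": [r.id for r in records],
        "smiles": [r.smiles for r in records],
        "value": [r.assay_value for r in records],
        "date": [r.registration_date.isoformat() for r in records],
    }
    if labels is not None:
        cols["label"] = list(labels)
    pd.DataFrame(cols).to_csv(path, index=False)
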