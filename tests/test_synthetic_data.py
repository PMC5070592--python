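"""Synthetic generators: importance curve, rotated toy, fingerprint drift."""

import numpy as np
import pytest

from covshift.kliep import (
    estimate_weights,
    fit_kliep,
    make_basis,
    median_heuristic_sigma,
    select_sigma_lcv,
)
from covshift.chemdata import label_records, temporal_split
from covshift.synthetic_data import (
    DriftSimConfig,
    GaussianToyConfig,
    make_fingerprint_drift,
    make_gaussian_toy,
    make_importance_curve,
    toy_oracle_importance,
)


class TestImportanceCurve:
    def test_identical_distributions_give_unit_ratio(self):
        grid = np.linspace(-3, 3, 101)
        _, _, w = make_importance_curve(0.0, 1.0, 0.0, 1.0, grid)
        np.testing.assert_allclose(w, 1.0)

    def test_equidistant_point_between_equal_width_gaussians(self):
        _, _, w = make_importance_curve(0.0, 1.0, 1.0, 1.0, np.array([0.5]))
        assert w[0] == pytest.approx(1.0)

    def test_narrow_prediction_peaks_importance_near_its_mean(self):
        grid = np.linspace(-3, 3, 601)
        _, _, w = make_importance_curve(0.0, 1.0, 1.0, 0.4, grid)
        x_at_max = grid[np.argmax(w)]
        assert abs(x_at_max - 1.0) < abs(x_at_max - 0.0)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            make_importance_curve(0.0, 0.0, 1.0, 1.0, np.zeros(3))


class TestGaussianToy:
    def test_reruns_are_bit_identical(self):
        a = make_gaussian_toy(GaussianToyConfig(seed=9))
        b = make_gaussian_toy(GaussianToyConfig(seed=9))
        np.testing.assert_array_equal(a.train_X, b.train_X)
        np.testing.assert_array_equal(a.pred_X, b.pred_X)

    def test_empirical_class_means_match_configured(self, gaussian_toy):
        cfg = gaussian_toy.config
        for cls in (0, 1):
            pts = gaussian_toy.train_X[gaussian_toy.train_y == cls]
            mean = pts.mean(axis=0)
            se = pts.std(axis=0, ddof=1) / np.sqrt(len(pts))
            assert np.all(np.abs(mean - np.asarray(cfg.class_means[cls])) < 3 * se + 1e-9)

    def test_zero_rotation_gives_near_unit_kliep_weights(self):
        data = make_gaussian_toy(GaussianToyConfig(rotation_deg=0.0, seed=2))
        med = median_heuristic_sigma(data.pred_X)
        sigma = select_sigma_lcv(
            data.train_X, data.pred_X, [med * s for s in (0.5, 1, 2, 4, 8)], seed=0
        )
        model, _ = fit_kliep(
            data.train_X, data.pred_X, config=make_basis(data.pred_X, sigma=sigma, seed=0)
        )
        w = np.asarray(estimate_weights(model, data.train_X))
        assert w.min() > 0.7 and w.max() < 1.4

    def test_half_turn_with_symmetric_means_preserves_distribution(self):
        # rotating 180 degrees about the midpoint maps each class Gaussian
        # onto the other, so the pooled prediction mixture equals the
        # pooled training mixture when the class covariances coincide
        cov = (np.array([[0.8, 0.0], [0.0, 0.3]]), np.array([[0.8, 0.0], [0.0, 0.3]]))
        cfg = GaussianToyConfig(
            n_per_class_train=2000,
            n_per_class_pred=2000,
            class_covariances=cov,
            rotation_deg=180.0,
            seed=3,
        )
        data = make_gaussian_toy(cfg)
        np.testing.assert_allclose(
            data.train_X.mean(axis=0), data.pred_X.mean(axis=0), atol=0.08
        )
        np.testing.assert_allclose(
            np.cov(data.train_X.T), np.cov(data.pred_X.T), atol=0.15
        )

    def test_non_psd_covariance_rejected(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError, match="positive semi-definite"):
            GaussianToyConfig(class_covariances=(bad, bad))

    def test_oracle_importance_is_unit_without_rotation(self):
        cfg = GaussianToyConfig(rotation_deg=0.0, seed=0)
        X = np.random.default_rng(0).normal(1, 1, (50, 2))
        np.testing.assert_allclose(toy_oracle_importance(cfg, X), 1.0, rtol=1e-10)


class TestFingerprintDrift:
    def test_reruns_are_bit_identical(self):
        a = make_fingerprint_drift(DriftSimConfig(n_train=100, n_pred=100, seed=4))
        b = make_fingerprint_drift(DriftSimConfig(n_train=100, n_pred=100, seed=4))
        np.testing.assert_array_equal(a.train_bits, b.train_bits)
        np.testing.assert_array_equal(a.oracle_weights, b.oracle_weights)
        assert [r.id for r in a.pred_records] == [r.id for r in b.pred_records]

    def test_zero_drift_gives_unit_oracle_weights(self, noshift_sim):
        np.testing.assert_allclose(noshift_sim.oracle_weights, 1.0)

    def test_oracle_weights_match_per_bit_product(self, drift_sim):
        # independent oracle: plain per-bit Bernoulli ratio product
        sim = drift_sim
        for i in (0, 17, 1999):
            x = sim.train_bits[i]
            w = 1.0
            for b in range(sim.config.n_bits):
                p, q = sim.base_bit_probs[b], sim.drifted_bit_probs[b]
                w *= (q / p) if x[b] else ((1 - q) / (1 - p))
            assert sim.oracle_weights[i] == pytest.approx(w, rel=1e-10)

    def test_oracle_weights_average_near_one_under_training_density(self, drift_sim):
        # E_train[p_pred/p_train] = 1 exactly; the sample mean concentrates
        assert drift_sim.oracle_weights.mean() == pytest.approx(1.0, abs=0.5)

    def test_single_strong_bit_ratio(self):
        # one bit with base 0.5; an instance with the bit on carries the
        # exact ratio drifted/0.5
        cfg = DriftSimConfig(
            n_train=200, n_pred=200, n_bits=1,
            base_bit_probs=np.array([0.5]), drift_magnitude=1.0, seed=8,
        )
        sim = make_fingerprint_drift(cfg)
        q = sim.drifted_bit_probs[0]
        on = sim.train_bits[:, 0] == 1
        np.testing.assert_allclose(sim.oracle_weights[on], q / 0.5, rtol=1e-12)
        np.testing.assert_allclose(sim.oracle_weights[~on], (1 - q) / 0.5, rtol=1e-12)

    def test_temporal_split_reproduces_partition(self, drift_sim):
        frac = drift_sim.config.n_train / (
            drift_sim.config.n_train + drift_sim.config.n_pred
        )
        train, pred = temporal_split(drift_sim.all_records, frac)
        assert [r.id for r in train] == [r.id for r in drift_sim.train_records]
        assert [r.id for r in pred] == [r.id for r in drift_sim.pred_records]

    def test_cutoff_labels_reproduce_simulated_labels(self, drift_sim):
        kept, labels, n_discarded = label_records(
            drift_sim.train_records, drift_sim.cutoffs
        )
        assert n_discarded == 0
        np.testing.assert_array_equal(labels, drift_sim.train_labels)

    def test_concept_is_stationary_across_sets(self, drift_sim):
        # the fixed concept scores the noisy labels equally well in both
        # sets: the shift is in the covariates, not in the concept
        acc_train = drift_sim.concept_accuracy("train")
        acc_pred = drift_sim.concept_accuracy("pred")
        noise = drift_sim.config.label_noise
        assert abs(acc_train - (1 - noise)) < 0.03
        assert abs(acc_train - acc_pred) < 0.03

    def test_kliep_weights_track_oracle_ranks(self, drift_sim):
        # pointwise recovery of the heavy-tailed 64-bit product ratio is
        # limited for a kernel model; rank agreement is the robust check
        from scipy.stats import spearmanr

        tr = drift_sim.train_bits.astype(float)
        pr = drift_sim.pred_bits.astype(float)
        med = median_heuristic_sigma(pr)
        model, _ = fit_kliep(tr, pr, config=make_basis(pr, sigma=0.4 * med, seed=0))
        w = np.asarray(estimate_weights(model, tr))
        assert spearmanr(w, drift_sim.oracle_weights).statistic > 0.5
        assert np.corrcoef(w, drift_sim.oracle_weights)[0, 1] > 0.15

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError):
            DriftSimConfig(n_bits=2, base_bit_probs=np.array([0.0, 0.5]))
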