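import numpy as np
import pytest
from scipy import stats

from oracles import chi_squared_2x2, rank_sum_statistic
from seqsig.region_io import ExpressionTable
from seqsig.expression_models import (
    ConvergenceError,
    auc_score,
    chisq_2x2,
    expression_target,
    fit_autoencoder,
    fit_expression_net,
    fit_logistic,
    metrics,
    split_train_validation,
    tss_window_features,
    wilcoxon_rank_sum,
    _sigmoid,
)


class TestExpressionTarget:
    def test_ratio_to_max_log_level(self):
        t = ExpressionTable({"a": 2 ** 5 - 1, "b": 2 ** 10 - 1})
        p = expression_target(t)
        assert p["a"] == pytest.approx(0.5)
        assert p["b"] == 1.0

    def test_zero_fpkm_maps_to_zero(self):
        p = expression_target(ExpressionTable({"a": 0.0, "b": 3.0}))
        assert p["a"] == 0.0

    def test_all_zero_is_error(self):
        with pytest.raises(ValueError):
            expression_target(ExpressionTable({"a": 0.0}))


class TestLogistic:
    def test_zero_coefficients_predict_half(self):
        from seqsig.expression_models import LogisticModel

        m = LogisticModel(intercept=0.0, coef=np.zeros(3))
        np.testing.assert_allclose(m.predict(np.random.default_rng(0).random((5, 3))), 0.5)

    def test_planted_coefficient_recovery(self):
        rng = np.random.default_rng(1)
        n, k = 5000, 10
        X = rng.uniform(0, 1, (n, k))
        beta = np.array([1.5, -1.2, 0.8, -0.6, 1.0, -1.4, 0.7, -0.9, 1.1, -0.5])
        p = _sigmoid(-0.5 + X @ beta)
        model = fit_logistic(X, p)
        assert (np.sign(model.coef) == np.sign(beta)).sum() == 10
        assert np.sqrt(np.mean((model.coef - beta) ** 2)) < 0.1
        assert model.intercept == pytest.approx(-0.5, abs=0.1)

    def test_monotone_in_positive_feature(self):
        rng = np.random.default_rng(2)
        X = rng.uniform(0, 1, (200, 2))
        p = _sigmoid(X @ np.array([2.0, -1.0]))
        m = fit_logistic(X, p)
        x = np.array([[0.2, 0.5], [0.4, 0.5], [0.9, 0.5]])
        pred = m.predict(x)
        assert pred[0] < pred[1] < pred[2]

    def test_feature_reordering_invariance(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(0, 1, (500, 4))
        p = _sigmoid(X @ np.array([1.0, -2.0, 0.5, 0.0]) - 0.2)
        m1 = fit_logistic(X, p)
        perm = [2, 0, 3, 1]
        m2 = fit_logistic(X[:, perm], p)
        np.testing.assert_allclose(m2.coef, m1.coef[perm], atol=1e-4)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            fit_logistic(np.ones((5, 2)), np.array([0.5, 1.2, 0.1, 0.3, 0.4]))
        with pytest.raises(ValueError):
            fit_logistic(np.ones((3, 5)), np.full(3, 0.5))

    def test_window_features_shape(self):
        H = np.random.default_rng(4).uniform(0, 1, (7, 334))
        F = tss_window_features(H)
        assert F.shape == (7, 10)
        assert ((F >= 0) & (F <= 1)).all()


class TestAutoencoder:
    @staticmethod
    def rank2_data(n=400, seed=0):
        rng = np.random.default_rng(seed)
        z = rng.uniform(-1, 1, (n, 2))
        basis = rng.normal(size=(2, 334))
        basis /= np.abs(z @ basis).max() * 2.5
        return np.clip(0.5 + z @ basis, 0, 1)

    def test_rank2_data_fully_explained(self):
        S = self.rank2_data()
        ae = fit_autoencoder(S, latent=2, seed=0)
        assert ae.explained_variance >= 0.999

    def test_full_latent_capacity_reconstructs(self):
        rng = np.random.default_rng(1)
        S = rng.uniform(0, 1, (50, 334))
        ae = fit_autoencoder(S, latent=334, seed=0, epochs=50)
        assert ae.explained_variance >= 0.999

    def test_seed_stability(self):
        S = self.rank2_data(seed=2)
        ev = [fit_autoencoder(S, latent=2, seed=s).explained_variance for s in (0, 1)]
        assert abs(ev[0] - ev[1]) < 0.01

    def test_deterministic_per_seed(self):
        S = self.rank2_data(seed=3)
        a = fit_autoencoder(S, latent=2, seed=5)
        b = fit_autoencoder(S, latent=2, seed=5)
        np.testing.assert_array_equal(a.W_enc, b.W_enc)
        np.testing.assert_array_equal(a.W_dec, b.W_dec)

    def test_constant_input_is_error(self):
        with pytest.raises(ValueError):
            fit_autoencoder(np.full((10, 334), 0.3), seed=0)

    def test_out_of_range_input_is_error(self):
        with pytest.raises(ValueError):
            fit_autoencoder(np.full((4, 10), 1.5), seed=0)


class TestExpressionNet:
    @staticmethod
    def planted(n=1300, seed=0, noise=0.0):
        rng = np.random.default_rng(seed)
        z = rng.uniform(0, 1, (n, 2))
        basis = np.abs(rng.normal(size=(2, 334)))
        S = np.clip(z @ basis / basis.sum(0).max(), 0, 1)
        y = 8 * z[:, 0] + noise * rng.normal(size=n)
        return S, y

    def test_noiseless_monotone_signal_ceiling(self):
        S, y = self.planted()
        ae = fit_autoencoder(S, latent=2, seed=0)
        pred = fit_expression_net(ae, S, y, detected=y > 4, seed=0)
        assert pred.metrics["spearman"] >= 0.95

    def test_shuffled_labels_are_chance(self):
        S, y = self.planted(n=3000, seed=1)
        rng = np.random.default_rng(2)
        y_shuf = rng.permutation(y)
        ae = fit_autoencoder(S, latent=2, seed=0)
        pred = fit_expression_net(ae, S, y_shuf, detected=y_shuf > 4, seed=0)
        assert abs(pred.metrics["spearman"]) < 0.05

    def test_split_autoscaling_warns(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="seqsig"):
            tr, va = split_train_validation(130, 10_000, 3_000, seed=0)
        assert len(tr) == 100 and len(va) == 30
        assert "scaling split" in caplog.text
        assert set(tr).isdisjoint(va)

    def test_split_too_small_is_error(self):
        with pytest.raises(ValueError):
            split_train_validation(3)


class TestMetrics:
    def test_perfect_separation_auc(self):
        flags = np.array([0, 0, 1, 1], bool)
        assert auc_score(flags, np.array([0.1, 0.2, 0.8, 0.9])) == 1.0

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=200)
        flags = rng.random(200) < _sigmoid(scores)
        a1 = auc_score(flags, scores)
        a2 = auc_score(flags, np.exp(3 * scores))
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_single_class_auc_is_error(self):
        with pytest.raises(ValueError):
            auc_score(np.ones(5, bool), np.arange(5))

    def test_chi_squared_against_hand_oracle(self):
        table = np.array([[10, 20], [20, 10]])
        chi2, p = chisq_2x2(table)
        assert chi2 == pytest.approx(chi_squared_2x2(table))
        assert chi2 == pytest.approx(20 / 3)
        assert 0 < p < 1

    def test_rank_sum_small_example(self):
        W, p = wilcoxon_rank_sum([1, 2], [3, 4])
        assert W == 3.0  # ranks 1 + 2
        assert W == rank_sum_statistic([1, 2], [3, 4])

    def test_rank_sum_matches_bruteforce_with_ties(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            x = rng.integers(0, 6, rng.integers(2, 15)).astype(float)
            y = rng.integers(0, 6, rng.integers(2, 15)).astype(float)
            W, _ = wilcoxon_rank_sum(x, y)
            assert W == pytest.approx(rank_sum_statistic(x, y))

    def test_rank_sum_matches_mann_whitney(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=40), rng.normal(0.5, 1, 60)
        W, p = wilcoxon_rank_sum(x, y)
        U, p_mw = stats.mannwhitneyu(x, y, alternative="two-sided")
        assert W == pytest.approx(U + 40 * 41 / 2)
        assert p == pytest.approx(p_mw, rel=0.05)

    def test_metrics_bundle(self):
        rng = np.random.default_rng(3)
        truth = rng.uniform(0, 8, 500)
        pred = truth + rng.normal(0, 1, 500)
        m = metrics(pred, truth)
        assert 0.9 < m["pearson"] <= 1
        assert m["auc"] > 0.9
        assert m["wilcoxon_p"] < 1e-10
        assert m["chisq"] > 0


class TestEndToEnd:
    def test_pipeline_recovers_expression_classes(self, default_dataset, default_pipeline):
        """Generator -> peaks -> spectrum -> HMM -> network separates
        expressed from silent genes."""
        ds, res = default_dataset, default_pipeline
        detected = ds.truth.fpkm["cellA"] > 1.0
        pred = res.predictor.predict(res.gamma)
        assert auc_score(detected, pred) >= 0.80

    def test_logistic_from_measured_heights(self, default_dataset, default_pipeline):
        """The fractional logistic model on measured ChIP heights ranks
        expressed genes above silent ones."""
        ds, res = default_dataset, default_pipeline
        X = tss_window_features(res.heights)
        table = ds.expression["cellA"]
        p_target = expression_target(table).loc[res.gene_ids].to_numpy()
        model = fit_logistic(X, p_target)
        pred = model.predict(X)
        detected = table.detected.loc[res.gene_ids].to_numpy()
        assert auc_score(detected, pred) > 0.8
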