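"""Bayesian marker models and GBLUP: oracles, edge cases, equivalences."""

import numpy as np
import pandas as pd
import pytest

from polygs.kinship import RelationshipMatrix, blend, build_k
from polygs.wgr import (
    GblupFit,
    WgrSpec,
    fit_bayesian,
    fit_gblup,
    narrow_heritability,
    predict_gebv,
)
from tests.conftest import make_dosage


@pytest.fixture(scope="module")
def ridge_instance():
    rng = np.random.default_rng(0)
    n, p = 50, 20
    X = rng.binomial(4, 0.5, size=(n, p)).astype(float)
    X -= X.mean(axis=0)  # centered instance: ridge formula applies verbatim
    beta = rng.normal(0, 0.3, p)
    y = X @ beta + rng.normal(0, 1, n)
    return X, y


class TestBayesianSamplers:
    def test_brr_matches_closed_form_ridge(self, ridge_instance):
        # degenerate hyperpriors freeze the variances; the posterior mean of
        # beta is then the ridge solution with lambda = s2e/s2b
        X, y = ridge_instance
        s2e, s2b = 1.0, 0.09
        spec = WgrSpec(model="BRR", s_beta=s2b, s_eps=s2e, update_hyper=False,
                       iterations=50_000, burn_in=2_000, seed=1)
        post = fit_bayesian(spec, X, y)
        lam = s2e / s2b
        ridge = np.linalg.solve(X.T @ X + lam * np.eye(X.shape[1]), X.T @ (y - y.mean()))
        assert np.abs(post.beta.to_numpy() - ridge).max() < 0.02

    def test_all_zero_markers_recover_mean(self):
        rng = np.random.default_rng(1)
        y = rng.normal(5.0, 1.0, 40)
        X = np.zeros((40, 6))
        for model in ("BRR", "BA", "BB", "BC", "BL"):
            spec = WgrSpec(model=model, iterations=2_000, burn_in=500, seed=2)
            post = fit_bayesian(spec, X, y)
            assert post.mu == pytest.approx(y.mean(), abs=3 * y.std() / np.sqrt(40))
            assert np.abs(post.beta.to_numpy()).max() == 0.0

    @pytest.mark.parametrize("model", ["BB", "BC"])
    def test_full_spike_zeroes_all_effects(self, model, ridge_instance):
        X, y = ridge_instance
        spec = WgrSpec(model=model, pi=1.0, iterations=1_500, burn_in=500, seed=3)
        post = fit_bayesian(spec, X, y)
        assert np.abs(post.beta.to_numpy()).max() == 0.0
        assert post.inclusion.max() == 0.0

    def test_residual_variance_consistent_without_markers(self):
        # y ~ N(0, 4) and no markers: posterior sigma2_e within 10%
        rng = np.random.default_rng(4)
        y = rng.normal(0.0, 2.0, 500)
        spec = WgrSpec(model="BRR", iterations=4_000, burn_in=1_000, seed=5)
        post = fit_bayesian(spec, np.zeros((500, 1)), y)
        assert post.sigma2_eps == pytest.approx(float(np.var(y)), rel=0.10)

    def test_scaling_equivariance(self, ridge_instance):
        # X -> cX divides beta by c and leaves GEBVs unchanged (fixed hypers,
        # prior variance rescaled with the columns)
        X, y = ridge_instance
        c = 2.0
        base = dict(s_eps=1.0, update_hyper=False, iterations=20_000, burn_in=2_000, seed=6)
        post1 = fit_bayesian(WgrSpec(model="BRR", s_beta=0.09, **base), X, y)
        post2 = fit_bayesian(WgrSpec(model="BRR", s_beta=0.09 / c**2, **base), c * X, y)
        assert np.allclose(post2.beta.to_numpy(), post1.beta.to_numpy() / c, atol=0.01)
        g1 = np.asarray(predict_gebv(post1, X))
        g2 = np.asarray(predict_gebv(post2, c * X))
        assert np.allclose(g1, g2, atol=0.05)

    def test_seed_reproducibility_and_chain_agreement(self, ridge_instance):
        X, y = ridge_instance
        spec = WgrSpec(model="BA", iterations=6_000, burn_in=1_000, seed=7)
        a = fit_bayesian(spec, X, y)
        b = fit_bayesian(spec, X, y)
        assert np.array_equal(a.beta.to_numpy(), b.beta.to_numpy())
        c = fit_bayesian(WgrSpec(model="BA", iterations=6_000, burn_in=1_000, seed=8), X, y)
        ga, gc = a.gebv.to_numpy(), c.gebv.to_numpy()
        assert np.corrcoef(ga, gc)[0, 1] > 0.99

    def test_models_agree_on_strong_signal(self):
        # matched fixed variance hyperparameters and no spike: all five
        # samplers shrink identically, GEBVs agree with each other and GBLUP
        rng = np.random.default_rng(9)
        n, p = 80, 60
        X = rng.binomial(4, 0.4, size=(n, p)).astype(float)
        beta = rng.normal(0, 0.2, p)
        g = (X - X.mean(0)) @ beta
        y = g + rng.normal(0, g.std(), n)
        s2e = float(np.var(y)) / 2
        s2b = s2e / (X - X.mean(0)).var(axis=0).sum()
        gebvs = {}
        for model in ("BRR", "BA", "BB", "BC", "BL"):
            spec = WgrSpec(model=model, pi=0.0, s_beta=s2b, s_eps=s2e,
                           update_hyper=False, iterations=8_000, burn_in=1_000, seed=10)
            gebvs[model] = fit_bayesian(spec, X, y).gebv.to_numpy()
        K = build_k(make_dosage(X.astype(np.int8)))
        Kb = blend(K, RelationshipMatrix(np.eye(n), K.ids, "pedigree"), 0.99)
        gebvs["GBLUP"] = fit_gblup(Kb, y).g.to_numpy()
        models = list(gebvs)
        for i in range(len(models)):
            for j in range(i + 1, len(models)):
                r = np.corrcoef(gebvs[models[i]], gebvs[models[j]])[0, 1]
                assert r > 0.98, (models[i], models[j], r)

    def test_input_validation(self, ridge_instance):
        X, y = ridge_instance
        with pytest.raises(ValueError):
            fit_bayesian(WgrSpec(model="GBLUP"), X, y)
        with pytest.raises(ValueError):
            fit_bayesian(WgrSpec(model="BRR"), X[:1], y[:1])
        with pytest.raises(ValueError):
            fit_bayesian(WgrSpec(model="BRR"), X, np.full_like(y, np.nan))
        with pytest.raises(ValueError):
            WgrSpec(model="BRR", iterations=100, burn_in=100)


class TestGblup:
    def make_pd_K(self, n, p, seed):
        rng = np.random.default_rng(seed)
        X = rng.binomial(4, rng.uniform(0.1, 0.9, p), size=(n, p)).astype(np.int8)
        K = build_k(make_dosage(X))
        A = RelationshipMatrix(np.eye(n), K.ids, "pedigree")
        return blend(K, A, 0.99), X

    def test_constant_y_gives_zero_genetic_variance(self):
        K, _ = self.make_pd_K(20, 100, 0)
        fit = fit_gblup(K, np.full(20, 3.0) + np.random.default_rng(1).normal(0, 1e-8, 20))
        assert fit.sigma2_g < 1e-6
        assert np.abs(fit.g.to_numpy()).max() < 1e-6

    def test_eigen_path_matches_dense_mme(self):
        # 5-individual toy: brute-force V-inverse BLUP at the REML optimum
        K, _ = self.make_pd_K(5, 50, 2)
        rng = np.random.default_rng(3)
        y = rng.normal(0, 1, 5)
        fit = fit_gblup(K, y)
        V = fit.sigma2_g * K.values + fit.sigma2_eps * np.eye(5)
        Vi = np.linalg.inv(V)
        ones = np.ones((5, 1))
        mu = ((ones.T @ Vi @ y) / (ones.T @ Vi @ ones).ravel()).item()
        ghat = fit.sigma2_g * K.values @ Vi @ (y - mu)
        assert np.abs(fit.g.to_numpy() - ghat).max() < 1e-8
        assert fit.mu == pytest.approx(mu, abs=1e-10)

    def test_rrblup_gblup_prediction_equivalence(self):
        # uncentered W keeps WW' full rank; with sigma2_beta = sigma2_g / c
        # the marker-based ridge prediction equals the GBLUP BLUP exactly
        rng = np.random.default_rng(4)
        n, p = 30, 100
        W = rng.normal(0, 1, size=(n, p))
        c = np.trace(W @ W.T) / n
        K = RelationshipMatrix(W @ W.T / c, pd.Index([f"i{k}" for k in range(n)]), "genomic")
        y = rng.normal(0, 1, n)
        fit = fit_gblup(K, y)
        lam = c * fit.sigma2_eps / fit.sigma2_g
        beta = np.linalg.solve(W.T @ W + lam * np.eye(p), W.T @ (y - fit.mu))
        assert np.abs(W @ beta - fit.g.to_numpy()).max() < 1e-6

    def test_h2_recovery(self):
        # y = g + e with matched unit variances: h2 estimates center on 0.5
        estimates = []
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            K, _ = self.make_pd_K(300, 400, seed)
            L = np.linalg.cholesky(K.values)
            g = L @ rng.normal(0, 1, 300)
            y = g + rng.normal(0, 1, 300)
            estimates.append(narrow_heritability(fit_gblup(K, y)))
        assert abs(np.mean(estimates) - 0.5) < 0.1

    def test_h2_edge_cases(self):
        ids = pd.Index(["a", "b"])
        fit = GblupFit(sigma2_g=1.0, sigma2_eps=0.0, mu=0.0,
                       g=pd.Series([0.0, 0.0], index=ids), loglik=0.0)
        assert narrow_heritability(fit) == 1.0
        fit0 = GblupFit(sigma2_g=0.0, sigma2_eps=1.0, mu=0.0,
                        g=pd.Series([0.0, 0.0], index=ids), loglik=0.0)
        assert narrow_heritability(fit0) == 0.0

    def test_non_pd_matrix_rejected(self):
        rng = np.random.default_rng(5)
        X = rng.binomial(4, 0.5, size=(10, 3)).astype(np.int8)  # rank deficient
        K = build_k(make_dosage(X))
        with pytest.raises(ValueError, match="blend"):
            fit_gblup(K, rng.normal(0, 1, 10))


class TestPrediction:
    def test_training_prediction_equals_fit_gebv(self, ridge_instance):
        X, y = ridge_instance
        spec = WgrSpec(model="BRR", iterations=2_000, burn_in=500, seed=11)
        post = fit_bayesian(spec, X, y)
        assert np.allclose(np.asarray(predict_gebv(post, X)), post.gebv.to_numpy())

    def test_mean_dosage_row_predicts_zero_deviation(self):
        rng = np.random.default_rng(12)
        X = rng.binomial(4, 0.5, size=(30, 10)).astype(float)
        y = rng.normal(0, 1, 30)
        spec = WgrSpec(model="BRR", iterations=2_000, burn_in=500, seed=13)
        post = fit_bayesian(spec, X, y)
        x_mean = X.mean(axis=0, keepdims=True)
        pred = predict_gebv(post, x_mean)
        # a mean-dosage individual sits at the centroid: GEBV = mean training GEBV
        assert pred[0] == pytest.approx(float(post.gebv.mean()), abs=1e-10)

    def test_panel_mismatch_rejected(self, ridge_instance):
        X, y = ridge_instance
        post = fit_bayesian(WgrSpec(model="BRR", iterations=1_500, burn_in=500, seed=14), X, y)
        with pytest.raises(ValueError):
            predict_gebv(post, X[:, :5])

    def test_gblup_cross_prediction_consistency(self):
        rng = np.random.default_rng(15)
        X = rng.binomial(4, rng.uniform(0.2, 0.8, 200), size=(40, 200)).astype(np.int8)
        K = build_k(make_dosage(X))
        Kb = blend(K, RelationshipMatrix(np.eye(40), K.ids, "pedigree"), 0.99)
        y = rng.normal(0, 1, 40)
        fit = fit_gblup(Kb, y)
        # predicting the training set through the cross-block recovers g
        pred = predict_gebv(fit, K_cross=Kb.values)
        assert np.allclose(pred, fit.g.to_numpy(), atol=1e-8)
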