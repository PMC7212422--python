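"""Unit tests for the rectified factor network core."""

import numpy as np
import pytest
from scipy import stats as sps

from rfnsurv import (
    EMConfig,
    FactorModel,
    PosteriorStats,
    compute_posterior,
    fit_rfn,
    init_model,
    log_likelihood,
    m_step,
    project_means,
)

from conftest import projection_oracle


class TestInitModel:
    def test_default_shapes_and_noise(self):
        model = init_model(5, 2, seed=0)
        assert model.W.shape == (5, 2)
        np.testing.assert_array_equal(model.psi, np.ones(5))

    def test_deterministic(self):
        a = init_model(5, 2, seed=0)
        b = init_model(5, 2, seed=0)
        np.testing.assert_array_equal(a.W, b.W)

    def test_data_sets_noise_to_gene_variance(self, rng):
        V = rng.normal(size=(5, 40))
        model = init_model(5, 2, seed=0, data=V)
        np.testing.assert_allclose(model.psi, V.var(axis=1))

    @pytest.mark.parametrize("m,r", [(5, 0), (1, 2), (0, 1)])
    def test_invalid_dimensions(self, m, r):
        with pytest.raises(ValueError):
            init_model(m, r, seed=0)


class TestPosterior:
    def test_zero_loadings_give_prior(self, rng):
        model = FactorModel(W=np.zeros((4, 2)), psi=np.ones(4))
        stats = compute_posterior(model, rng.normal(size=(4, 3)))
        np.testing.assert_array_equal(stats.mu_p, np.zeros((2, 3)))
        np.testing.assert_array_equal(stats.K_pp, np.eye(2))

    def test_orthonormal_loadings_unit_noise(self, rng):
        # with W'W = I and Psi = I: K = (I + I)^-1 = I/2, mu = W'V / 2
        q, _ = np.linalg.qr(rng.normal(size=(5, 2)))
        model = FactorModel(W=q, psi=np.ones(5))
        v = rng.normal(size=(5, 1))
        stats = compute_posterior(model, v)
        np.testing.assert_allclose(stats.K_pp, 0.5 * np.eye(2), atol=1e-12)
        np.testing.assert_allclose(stats.mu_p, 0.5 * q.T @ v, atol=1e-12)

    def test_matches_dense_inverse_oracle(self, rng):
        W = rng.normal(size=(4, 2))
        psi = rng.uniform(0.5, 2.0, size=4)
        V = rng.normal(size=(4, 3))
        stats = compute_posterior(FactorModel(W=W, psi=psi), V)
        PsiInv = np.diag(1.0 / psi)
        K = np.linalg.inv(np.eye(2) + W.T @ PsiInv @ W)
        np.testing.assert_allclose(stats.K_pp, K, atol=1e-10)
        np.testing.assert_allclose(stats.mu_p, K @ W.T @ PsiInv @ V, atol=1e-10)

    def test_covariance_shared_and_spd(self, rng):
        W = rng.normal(size=(6, 3))
        stats = compute_posterior(FactorModel(W=W, psi=np.ones(6)),
                                  rng.normal(size=(6, 10)))
        np.testing.assert_allclose(stats.K_pp, stats.K_pp.T, atol=1e-10)
        assert np.all(np.linalg.eigvalsh(stats.K_pp) > 0)

    def test_dimension_mismatch(self, rng):
        model = FactorModel(W=np.zeros((4, 2)), psi=np.ones(4))
        with pytest.raises(ValueError):
            compute_posterior(model, rng.normal(size=(5, 3)))

    def test_nonfinite_model_rejected(self, rng):
        model = FactorModel(W=np.full((4, 2), np.nan), psi=np.ones(4))
        with pytest.raises(FloatingPointError):
            compute_posterior(model, rng.normal(size=(4, 3)))


class TestProjection:
    def test_rectify_then_rescale_example(self):
        # one unit, n=3: (3, -1, 0) -> clip (3,0,0) -> scale to mean-square 1
        stats = PosteriorStats(mu_p=np.array([[3.0, -1.0, 0.0]]), K_pp=np.eye(1))
        np.testing.assert_allclose(
            project_means(stats), [[np.sqrt(3.0), 0.0, 0.0]], atol=1e-12
        )

    def test_feasible_point_is_fixed(self, rng):
        mu = np.abs(rng.normal(size=(2, 4)))
        mu /= np.sqrt((mu**2).mean(axis=1, keepdims=True))
        out = project_means(PosteriorStats(mu_p=mu, K_pp=np.eye(2)))
        np.testing.assert_allclose(out, mu, atol=1e-12)

    def test_nonpositive_row_annihilated(self):
        stats = PosteriorStats(mu_p=np.array([[-1.0, -2.0, 0.0]]), K_pp=np.eye(1))
        np.testing.assert_array_equal(project_means(stats), np.zeros((1, 3)))

    def test_invariants_hold(self, rng):
        mu = project_means(PosteriorStats(mu_p=rng.normal(size=(3, 6)), K_pp=np.eye(3)))
        assert np.all(mu >= 0)
        rms2 = (mu**2).mean(axis=1)
        active = mu.any(axis=1)
        np.testing.assert_allclose(rms2[active], 1.0, atol=1e-8)

    def test_matches_constrained_solver_oracle(self, rng):
        for _ in range(10):
            mu_p = rng.normal(scale=2.0, size=(2, 4))
            ours = project_means(PosteriorStats(mu_p=mu_p, K_pp=np.eye(2)))
            oracle = projection_oracle(mu_p)
            obj_ours = ((ours - mu_p) ** 2).sum()
            obj_oracle = ((oracle - mu_p) ** 2).sum()
            assert obj_ours <= obj_oracle + 1e-6


class TestMStep:
    def _config(self, **kw):
        defaults = dict(dropout_rate=0.0, l1_weight=0.0, seed=0)
        defaults.update(kw)
        return EMConfig(**defaults)

    def test_zero_data_floors_noise(self, rng):
        mu = np.abs(rng.normal(size=(2, 5)))
        model = m_step(np.zeros((4, 5)), mu, np.zeros((2, 2)), self._config())
        np.testing.assert_allclose(model.W, 0.0, atol=1e-12)
        np.testing.assert_array_equal(model.psi, np.full(4, 1e-4))

    def test_least_squares_limit(self, rng):
        # K_pp = 0, no shrinkage/dropout: W solves the normal equations of
        # V ~ W mu, i.e. the least-squares regression of V on the codes.
        V = rng.normal(size=(4, 30))
        mu = np.abs(rng.normal(size=(2, 30)))
        model = m_step(V, mu, np.zeros((2, 2)), self._config())
        W_ls = np.linalg.lstsq(mu.T, V.T, rcond=None)[0].T
        np.testing.assert_allclose(model.W, W_ls, atol=1e-8)

    def test_l1_soft_threshold_shrinks(self, rng):
        V = rng.normal(size=(4, 30))
        mu = np.abs(rng.normal(size=(2, 30)))
        plain = m_step(V, mu, np.zeros((2, 2)), self._config())
        shrunk = m_step(V, mu, np.zeros((2, 2)), self._config(l1_weight=0.05))
        expected = np.sign(plain.W) * np.maximum(np.abs(plain.W) - 0.05, 0.0)
        np.testing.assert_allclose(shrunk.W, expected, atol=1e-10)

    def test_dropout_mask_deterministic(self, rng):
        V = rng.normal(size=(6, 20))
        mu = np.abs(rng.normal(size=(4, 20)))
        a = m_step(V, mu, np.eye(4) * 0.1, self._config(dropout_rate=0.5), iteration=3)
        b = m_step(V, mu, np.eye(4) * 0.1, self._config(dropout_rate=0.5), iteration=3)
        np.testing.assert_array_equal(a.W, b.W)


class TestLogLikelihood:
    def test_standard_normal_at_zero(self):
        model = FactorModel(W=np.zeros((1, 1)), psi=np.ones(1))
        ll = log_likelihood(model, np.zeros((1, 1)))
        assert ll == pytest.approx(-0.5 * np.log(2 * np.pi))

    def test_standard_normal_at_one(self):
        model = FactorModel(W=np.zeros((1, 1)), psi=np.ones(1))
        ll = log_likelihood(model, np.ones((1, 1)))
        assert ll == pytest.approx(-0.5 * np.log(2 * np.pi) - 0.5)

    def test_matches_dense_gaussian_oracle(self, rng):
        W = rng.normal(size=(5, 2))
        psi = rng.uniform(0.5, 2.0, size=5)
        V = rng.normal(size=(5, 4))
        ll = log_likelihood(FactorModel(W=W, psi=psi), V)
        cov = W @ W.T + np.diag(psi)
        oracle = sps.multivariate_normal(mean=np.zeros(5), cov=cov).logpdf(V.T).sum()
        assert ll == pytest.approx(oracle, abs=1e-8)


class TestFitRFN:
    def test_bit_reproducible(self, rng):
        V = rng.normal(size=(20, 30))
        V -= V.mean(axis=1, keepdims=True)
        a = fit_rfn(V, 3, EMConfig(n_iters=20, seed=7))
        b = fit_rfn(V, 3, EMConfig(n_iters=20, seed=7))
        np.testing.assert_array_equal(a.model.W, b.model.W)
        np.testing.assert_array_equal(a.means, b.means)
        assert a.loglik == b.loglik

    def test_nan_rejected(self):
        V = np.zeros((4, 5))
        V[0, 0] = np.nan
        with pytest.raises(ValueError):
            fit_rfn(V, 2, EMConfig())

    def test_unrectified_loglik_monotone(self, rng):
        V = rng.normal(size=(15, 40))
        V -= V.mean(axis=1, keepdims=True)
        cfg = EMConfig(n_iters=50, dropout_rate=0.0, l1_weight=0.0,
                       rectify=False, tol=0.0, seed=1)
        fit = fit_rfn(V, 2, cfg)
        diffs = np.diff(fit.loglik)
        assert np.all(diffs >= -1e-6)

    def test_codes_satisfy_constraints(self, rng):
        V = rng.normal(size=(20, 30))
        V -= V.mean(axis=1, keepdims=True)
        fit = fit_rfn(V, 3, EMConfig(n_iters=15, seed=2))
        assert np.all(fit.means >= 0)
        rms2 = (fit.means**2).mean(axis=1)
        active = fit.means.any(axis=1)
        np.testing.assert_allclose(rms2[active], 1.0, atol=1e-8)
        assert np.all(fit.model.psi >= 1e-4)

    def test_rank_one_block_recovered(self, rng):
        # planted nonnegative rank-1 block plus small noise, single unit
        V = rng.normal(scale=0.05, size=(30, 40))
        block_genes = np.arange(8)
        V[np.ix_(block_genes, np.arange(15))] += 1.0
        V -= V.mean(axis=1, keepdims=True)
        fit = fit_rfn(V, 1, EMConfig(n_iters=50, dropout_rate=0.0, seed=3))
        w = np.abs(fit.model.W[:, 0])
        top = np.argsort(-w)[:8]
        assert set(top) == set(block_genes)
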