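"""EM engine: E-step and M-step oracles, GEM monotonicity, recovery."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.stats import pearsonr

import hire_ewas as h
from hire_ewas.data import ValidationError
from hire_ewas.em import (
    FitConfig,
    e_step,
    initialize,
    m_step_mu_B,
    m_step_proportions,
    m_step_variances,
)
from hire_ewas.qp import solve_simplex_qp


def _monotone(trace, slack=1e-6):
    t = np.asarray(trace)
    return np.all(np.diff(t) >= -slack * np.abs(t[:-1]) - 1e-9)


class TestSimplexQP:
    def test_interior_optimum_returned_exactly(self):
        # A = I, b chosen so A^{-1} b is inside the simplex
        b = np.array([0.5, 0.3, 0.2])
        p = solve_simplex_qp(np.eye(3), b)
        assert np.allclose(p, b, atol=1e-12)

    def test_single_cell_type(self):
        assert solve_simplex_qp(np.array([[2.0]]), np.array([3.0])) == pytest.approx([1.0])

    @pytest.mark.parametrize("seed", range(8))
    def test_beats_dense_grid_search(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.normal(0, 1, (3, 3))
        A = A @ A.T + 0.05 * np.eye(3)
        b = rng.normal(0, 1, 3)
        p = solve_simplex_qp(A, b)
        assert p.min() >= 0 and p.sum() == pytest.approx(1.0)
        obj = p @ A @ p - 2 * b @ p
        step = 0.001
        g = np.arange(0.0, 1.0 + step, step)
        best = np.inf
        for a1 in g:
            a2 = g[g <= 1 - a1 + 1e-12]
            pp = np.column_stack([np.full(a2.size, a1), a2, 1 - a1 - a2])
            vals = np.einsum("ij,jk,ik->i", pp, A, pp) - 2 * pp @ b
            best = min(best, vals.min())
        assert obj <= best + 1e-6


class TestEStep:
    def test_uninformative_observation_returns_prior(self, small_params, rng):
        p = small_params.copy()
        p.sigma_eps = np.full(p.m, 100.0)  # sigma_eps^2 >> sigma_jk^2
        O = h.MethylationMatrix(rng.uniform(0.2, 0.8, (p.m, p.n)))
        X = h.PhenotypeMatrix(rng.normal(0, 1, (p.n, p.q)))
        mom = e_step(p, O, X)
        prior = p.mu[None] + np.einsum("mkq,nq->nmk", p.B, X.values)
        assert np.allclose(mom.mean, prior, atol=1e-4)

    def test_K1_conjugate_normal_posterior(self):
        s2, se2, m0, O_val = 0.004, 0.009, 0.3, 0.6
        params = h.HireParams(
            P=np.ones((1, 1)), mu=np.array([[m0]]), B=np.zeros((1, 1, 0)),
            Sigma=np.array([[s2]]), sigma_eps=np.array([se2]),
        )
        mom = e_step(params, h.MethylationMatrix(np.array([[O_val]])),
                     h.PhenotypeMatrix(np.zeros((1, 0))))
        expected = (m0 / s2 + O_val / se2) / (1 / s2 + 1 / se2)
        assert mom.mean[0, 0, 0] == pytest.approx(expected)

    def test_matches_joint_gaussian_conditional(self, small_params, rng):
        """Posterior equals the conditional of the assembled (u, O) Gaussian."""
        p = small_params
        Ov = rng.uniform(0.2, 0.8, (p.m, p.n))
        Xv = rng.normal(0, 1, (p.n, p.q))
        mom = e_step(p, h.MethylationMatrix(Ov), h.PhenotypeMatrix(Xv))
        for i in range(p.n):
            for j in range(p.m):
                pi = p.P[:, i]
                prior = p.mu[j] + p.B[j] @ Xv[i]
                Suu = np.diag(p.Sigma[j])
                SuO = p.Sigma[j] * pi
                SOO = pi @ Suu @ pi + p.sigma_eps[j]
                cond_mean = prior + SuO * (Ov[j, i] - pi @ prior) / SOO
                cond_cov = Suu - np.outer(SuO, SuO) / SOO
                assert np.allclose(mom.mean[i, j], cond_mean, atol=1e-12)
                assert np.allclose(
                    mom.second_moment(i, j),
                    cond_cov + np.outer(cond_mean, cond_mean), atol=1e-12)

    def test_posterior_covariance_psd(self, small_params, rng):
        p = small_params
        mom = e_step(p, h.MethylationMatrix(rng.uniform(0.2, 0.8, (p.m, p.n))),
                     h.PhenotypeMatrix(rng.normal(0, 1, (p.n, p.q))))
        for i in range(p.n):
            for j in range(p.m):
                V = mom.second_moment(i, j) - np.outer(mom.mean[i, j], mom.mean[i, j])
                assert np.all(np.linalg.eigvalsh((V + V.T) / 2) >= -1e-12)


def _random_moments(rng, n=12, m=4, K=2):
    P = rng.dirichlet(np.ones(K), n).T
    Sigma = rng.uniform(0.002, 0.01, (m, K))
    mean = rng.normal(0.5, 0.2, (n, m, K))
    denom = (Sigma @ (P ** 2)).T + rng.uniform(0.002, 0.01, m)[None, :]
    a2 = (Sigma[None] * P.T[:, None, :]) ** 2
    var_diag = Sigma[None] - a2 / denom[:, :, None]
    return h.LatentMoments(mean=mean, var_diag=var_diag, denom=denom,
                           Sigma=Sigma, P=P)


class TestMStepMuB:
    def test_q0_reduces_to_clipped_mean(self, rng):
        mom = _random_moments(rng)
        X = h.PhenotypeMatrix(np.zeros((12, 0)))
        mu, B = m_step_mu_B(mom, X)
        assert np.allclose(mu, np.clip(mom.mean.mean(axis=0), 0, 1))
        assert B.shape == (4, 2, 0)

    def test_matches_normal_equations_oracle(self, rng):
        mom = _random_moments(rng)
        Xv = rng.normal(0, 1, (12, 2))
        mu, B = m_step_mu_B(mom, h.PhenotypeMatrix(Xv))
        D = np.hstack([np.ones((12, 1)), Xv])
        for j in range(4):
            for k in range(2):
                theta = np.linalg.solve(D.T @ D, D.T @ mom.mean[:, j, k])
                if 0 <= theta[0] <= 1:
                    assert mu[j, k] == pytest.approx(theta[0], abs=1e-10)
                    assert np.allclose(B[j, k], theta[1:], atol=1e-10)

    def test_out_of_range_baseline_projected(self, rng):
        mom = _random_moments(rng)
        mom.mean += 1.0  # push all baselines above 1
        Xv = rng.normal(0, 1, (12, 1))
        mu, B = m_step_mu_B(mom, h.PhenotypeMatrix(Xv))
        assert np.all(mu == 1.0)
        # refit oracle: B given mu = 1, no intercept
        for j in range(4):
            for k in range(2):
                b_ref = np.linalg.lstsq(Xv, mom.mean[:, j, k] - 1.0, rcond=None)[0]
                assert np.allclose(B[j, k], b_ref, atol=1e-10)

    def test_constant_covariate_rejected_by_name(self, rng):
        mom = _random_moments(rng)
        X = h.PhenotypeMatrix(np.ones((12, 1)), phenotype_names=["batch"])
        with pytest.raises(ValidationError, match="batch"):
            m_step_mu_B(mom, X)


class TestMStepVariances:
    def test_single_sigma_pools_per_entry_updates(self, rng):
        mom = _random_moments(rng)
        Xv = rng.normal(0, 1, (12, 2))
        X = h.PhenotypeMatrix(Xv)
        O = h.MethylationMatrix(rng.uniform(0.2, 0.8, (4, 12)))
        mu, B = m_step_mu_B(mom, X)
        Sig_per, _ = m_step_variances(mom, mu, B, O, X, "per_site_celltype")
        Sig_pool, _ = m_step_variances(mom, mu, B, O, X, "single_sigma")
        assert np.allclose(Sig_pool, Sig_per.mean())

    def test_matches_numeric_maximizer_of_expected_loglik(self, rng):
        """Closed-form variance update maximizes Q as a function of variances."""
        mom = _random_moments(rng, n=8, m=2, K=2)
        Xv = rng.normal(0, 1, (8, 1))
        X = h.PhenotypeMatrix(Xv)
        O = h.MethylationMatrix(rng.uniform(0.2, 0.8, (2, 8)))
        mu, B = m_step_mu_B(mom, X)
        Sigma_new, se_new = m_step_variances(mom, mu, B, O, X)
        j = 0
        fitted = mu[j] + (B[j] @ Xv.T).T  # n x K
        E_sq = (mom.mean[:, j, :] - fitted) ** 2 + mom.var_diag[:, j, :]

        def neg_q_sigma(log_s2):
            s2 = np.exp(log_s2)
            return np.sum(0.5 * np.log(s2)[None, :] + E_sq / (2 * s2[None, :]))

        res = minimize(neg_q_sigma, np.log(Sigma_new[j] * 1.7), method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-14})
        assert np.allclose(np.exp(res.x), Sigma_new[j], rtol=1e-5)

    def test_perfect_fit_floors_variances(self, rng):
        mom = _random_moments(rng)
        mom.var_diag[:] = 0.0
        X = h.PhenotypeMatrix(np.zeros((12, 0)))
        mu = np.clip(mom.mean.mean(axis=0), 0, 1)
        mom.mean[:] = mu[None]  # every sample exactly at the baseline
        sig_obs = np.einsum("nmk,kn->mn", mom.mean, mom.P)
        O = h.MethylationMatrix(np.clip(sig_obs, 0, 1))
        Sigma, se = m_step_variances(mom, mu, np.zeros((4, 2, 0)), O, X)
        assert np.all(Sigma == 1e-10)


class TestMStepProportions:
    def test_K1_returns_ones(self, rng):
        mom = _random_moments(rng, K=1)
        O = h.MethylationMatrix(rng.uniform(0.2, 0.8, (4, 12)))
        P = m_step_proportions(mom, O, np.full(4, 0.005))
        assert np.allclose(P, 1.0)

    def test_matches_per_sample_qp_objective(self, rng):
        """The QP assembled per sample matches a direct objective evaluation."""
        mom = _random_moments(rng, n=4, m=6, K=3)
        O = h.MethylationMatrix(rng.uniform(0.2, 0.8, (6, 4)))
        se = rng.uniform(0.003, 0.01, 6)
        P = m_step_proportions(mom, O, se)

        def objective(i, p):
            val = 0.0
            for j in range(6):
                Euu = mom.second_moment(i, j)
                Eu = mom.mean[i, j]
                val += (p @ Euu @ p - 2 * O.values[j, i] * Eu @ p) / se[j]
            return val

        for i in range(4):
            base = objective(i, P[:, i])
            for _ in range(50):
                alt = np.random.default_rng(i).dirichlet(np.ones(3) * 0.5)
                assert base <= objective(i, alt) + 1e-9


class TestInitialize:
    def test_effects_start_at_zero(self, tiny_dataset):
        params = initialize(tiny_dataset.O, tiny_dataset.X, 3,
                            np.random.default_rng(0))
        assert not params.B.any()
        assert params.Sigma.mean() < 0.01  # "small" initial variances

    def test_K1_composition_is_all_ones(self, tiny_dataset):
        params = initialize(tiny_dataset.O, tiny_dataset.X, 1,
                            np.random.default_rng(0))
        assert np.allclose(params.P, 1.0)

    def test_noiseless_mixture_recovered(self):
        rng = np.random.default_rng(20240917)
        m, K, n = 600, 3, 60
        mu = rng.beta(3, 6, (m, K))
        P = rng.dirichlet(np.ones(K), n).T
        O = h.MethylationMatrix(np.clip(mu @ P, 0, 1))
        X = h.PhenotypeMatrix(np.zeros((n, 0)))
        params = initialize(O, X, K, np.random.default_rng(1),
                            n_alternations=200, n_restarts=5)
        perm = h.align_cell_types(params.mu, mu)
        assert np.abs(params.P[perm] - P).max() < 0.05
        assert np.linalg.norm(O.values - params.mu @ params.P) < 0.01

    def test_K_larger_than_n_rejected(self, tiny_dataset):
        with pytest.raises(ValidationError):
            initialize(tiny_dataset.O, tiny_dataset.X, 1000,
                       np.random.default_rng(0))


class TestFit:
    def test_loglik_trace_monotone(self, tiny_dataset):
        res = h.fit(tiny_dataset.O, tiny_dataset.X, 3,
                    FitConfig(max_iter=40, seed=1))
        assert _monotone(res.loglik_trace)
        assert res.n_iter == len(res.loglik_trace) - 1

    def test_single_sigma_mode_also_monotone(self, tiny_dataset):
        res = h.fit(tiny_dataset.O, tiny_dataset.X, 3,
                    FitConfig(max_iter=40, seed=1, variance_mode="single_sigma"))
        assert _monotone(res.loglik_trace)
        # pooled mode: one shared cell-layer variance
        assert np.unique(res.params.Sigma).size == 1

    def test_iterates_satisfy_invariants(self, tiny_dataset):
        res = h.fit(tiny_dataset.O, tiny_dataset.X, 3, FitConfig(max_iter=25, seed=3))
        res.params.validate()  # simplex, [0,1], positive variances

    def test_truth_is_fixed_point_on_noiseless_data(self):
        """From the truth on noiseless data, EM stays there while the residual
        variances collapse to the floor."""
        from hire_ewas.simulate import generate_observations
        design = h.SimulationDesign(n=30, K=3, m=150, scenario="true_null", seed=8)
        data = h.simulate_dataset(design)
        t = data.truth.params
        O_clean, _ = generate_observations(
            t.mu, t.B, t.P, data.X, np.random.default_rng(0), sd_u=0.0, sd_eps=0.0)
        res = h.fit(h.MethylationMatrix(O_clean), data.X, 3,
                    FitConfig(max_iter=100, tol=1e-6, init=t))
        assert res.converged
        assert res.params.sigma_eps.max() < 1e-8  # at/near the variance floor
        perm = h.align_cell_types(res.params.mu, t.mu)
        assert np.abs(res.params.P[perm] - t.P).mean() < 0.01

    def test_equivariant_to_initial_relabelling(self, tiny_dataset):
        init = initialize(tiny_dataset.O, tiny_dataset.X, 3,
                          np.random.default_rng(5))
        perm = np.array([2, 0, 1])
        res_a = h.fit(tiny_dataset.O, tiny_dataset.X, 3,
                      FitConfig(max_iter=15, init=init))
        res_b = h.fit(tiny_dataset.O, tiny_dataset.X, 3,
                      FitConfig(max_iter=15, init=init.permute_cell_types(perm)))
        assert np.allclose(res_b.params.mu, res_a.params.mu[:, perm], atol=1e-8)
        assert res_b.loglik_trace[-1] == pytest.approx(res_a.loglik_trace[-1])

    def test_small_sample_warning(self, rng):
        O = h.MethylationMatrix(rng.uniform(0.3, 0.7, (20, 6)))
        X = h.PhenotypeMatrix(rng.normal(0, 1, (6, 2)))
        with pytest.warns(UserWarning, match="below"):
            h.fit(O, X, 3, FitConfig(max_iter=2, seed=0))
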