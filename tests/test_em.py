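import numpy as np
import pytest

from hybbr.datamodel import MixturePrior, TraitData, build_grm
from hybbr.em import (EmConfig, em_check_convergence, em_responsibilities,
                      em_update_beta, em_update_pr, em_update_sigma_e,
                      em_update_snp, em_update_v, residual_correct, run_em)
from hybbr.gblup import PevCache, VarianceComponents, compute_pev
from hybbr.study import ridge_oracle


def _zero_pev(n, m):
    return PevCache(PEV=np.zeros((n, n)), trace_terms=np.zeros(m), trace_resid=0.0)


class TestResidualCorrect:
    def test_zero_effect_is_identity(self):
        r = np.arange(4.0)
        Z = np.ones((4, 2))
        assert np.allclose(residual_correct(r, Z, np.array([0.0, 1.0]), 0), r)

    def test_matches_full_recomputation(self):
        rng = np.random.default_rng(0)
        n, m = 8, 5
        Z = rng.standard_normal((n, m))
        g = rng.standard_normal(m)
        X = np.ones((n, 1))
        beta = np.array([0.3])
        y = rng.standard_normal(n)
        resid = y - X @ beta - Z @ g
        for i in range(m):
            full = y - X @ beta - sum(Z[:, j] * g[j] for j in range(m) if j != i)
            assert np.allclose(residual_correct(resid, Z, g, i), full, atol=1e-10)


class TestResponsibilities:
    def test_prior_dominance(self):
        prior = MixturePrior(sigma_g2=1.0, Pr=np.array([1.0, 0.0, 0.0, 0.0]))
        P = em_responsibilities(rhs=5.0, zEz_i=10.0, t_i=0.0, sigma_e2=1.0,
                                prior=prior)
        assert P[0] > 1 - 1e-6

    def test_rows_sum_to_one(self):
        prior = MixturePrior(sigma_g2=2.0)
        P = em_responsibilities(rhs=3.0, zEz_i=50.0, t_i=4.0, sigma_e2=1.5,
                                prior=prior)
        assert P.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(P >= 0)

    def test_scalar_mixture_posterior_oracle(self):
        # n=1, Z_i=1, E=I, t=0: responsibilities must equal the normalized
        # Gaussian marginal densities N(0, s2_k + se2) at the observed value,
        # weighted by Pr (spike = N(0, se2))
        prior = MixturePrior(sigma_g2=1.0, Pr=np.array([0.25, 0.25, 0.25, 0.25]))
        x = 1.7
        P = em_responsibilities(rhs=x, zEz_i=1.0, t_i=0.0, sigma_e2=1.0,
                                prior=prior)
        s2 = prior.component_variances
        dens = np.array([np.exp(-x**2 / (2 * (v + 1.0))) / np.sqrt(v + 1.0)
                         for v in s2])
        assert np.allclose(P, dens / dens.sum(), atol=1e-10)

    def test_negative_corrected_projection_clipped(self):
        prior = MixturePrior(sigma_g2=1.0)
        P1 = em_responsibilities(rhs=0.5, zEz_i=10.0, t_i=-100.0, sigma_e2=1.0,
                                 prior=prior)
        P2 = em_responsibilities(rhs=0.0, zEz_i=10.0, t_i=0.0, sigma_e2=1.0,
                                 prior=prior)
        assert np.allclose(P1, P2, atol=1e-12)


class TestSnpUpdate:
    def test_zero_projection_gives_zero(self):
        prior = MixturePrior(sigma_g2=1.0)
        assert em_update_snp(0.0, 10.0, np.array([0.1, 0.3, 0.3, 0.3]), 1.0,
                             prior) == 0.0

    def test_hand_arithmetic(self):
        # Z'Z=10, Z'e*=5, se2=1, all mass on component 2 with s2=0.1
        prior = MixturePrior(sigma_g2=100.0)  # 1e-3 * 100 = 0.1
        g = em_update_snp(5.0, 10.0, np.array([0.0, 0.0, 1.0, 0.0]), 1.0, prior)
        assert g == pytest.approx(5.0 / (10.0 + 1.0 / 0.1))

    def test_no_shrinkage_limit(self):
        prior = MixturePrior(sigma_g2=1e12)
        g = em_update_snp(5.0, 10.0, np.array([0.0, 0.0, 0.0, 1.0]), 1.0, prior)
        assert g == pytest.approx(0.5, rel=1e-6)  # OLS Z'e*/Z'Z

    def test_spike_mass_shrinks_to_zero(self):
        prior = MixturePrior(sigma_g2=1.0)
        g_half = em_update_snp(5.0, 10.0, np.array([0.5, 0.0, 0.0, 0.5]), 1.0, prior)
        g_none = em_update_snp(5.0, 10.0, np.array([0.0, 0.0, 0.0, 1.0]), 1.0, prior)
        g_full = em_update_snp(5.0, 10.0, np.array([1.0, 0.0, 0.0, 0.0]), 1.0, prior)
        assert abs(g_half) < abs(g_none)
        assert g_full == 0.0

    def test_monotone_shrinkage_in_spike_mass(self):
        prior = MixturePrior(sigma_g2=1.0)
        prev = np.inf
        for p1 in np.linspace(0.0, 1.0, 11):
            rest = (1 - p1)
            P = np.array([p1, 0.2 * rest, 0.3 * rest, 0.5 * rest])
            g = abs(em_update_snp(5.0, 10.0, P, 1.0, prior))
            assert g <= prev + 1e-12
            prev = g


class TestGlobalUpdates:
    def test_pr_update_lagrange_form(self):
        rng = np.random.default_rng(1)
        P = rng.dirichlet(np.ones(4), size=20)
        scaled = P * np.array([10, 5, 3, 2]) / P.sum(axis=0)
        pr = em_update_pr(scaled)
        assert np.allclose(pr, np.array([11, 6, 4, 3]) / 24.0)

    def test_pr_update_corner_cases(self):
        m = 12
        all_spike = np.zeros((m, 4))
        all_spike[:, 0] = 1.0
        assert np.allclose(em_update_pr(all_spike),
                           np.array([m + 1, 1, 1, 1]) / (m + 4))
        uniform = np.full((m, 4), 0.25)
        assert np.allclose(em_update_pr(uniform), 0.25)

    def test_sigma_e_update(self):
        r = np.array([1.0, -2.0, 2.0])
        assert em_update_sigma_e(r, np.ones(3), 0.0) == pytest.approx(3.0)
        assert em_update_sigma_e(np.zeros(3), np.ones(3), 6.0) == pytest.approx(2.0)
        E = np.array([1.0, 2.0, 4.0])
        expect = (r @ (r / E) + 1.5) / 3
        assert em_update_sigma_e(r, E, 1.5) == pytest.approx(expect, abs=1e-12)

    def test_beta_update(self):
        y_adj = np.array([1.0, 2.0, 6.0])
        X = np.ones((3, 1))
        assert em_update_beta(y_adj, X, np.ones(3))[0] == pytest.approx(3.0)
        # weighted GLS against the closed form sum(y/E)/sum(1/E)
        E = np.array([1.0, 2.0, 4.0])
        expect = np.sum(y_adj / E) / np.sum(1.0 / E)
        assert em_update_beta(y_adj, X, E)[0] == pytest.approx(expect)

    def test_v_update_limits_and_oracle(self):
        rng = np.random.default_rng(2)
        n = q = 6
        W = np.eye(n)
        A = np.eye(q)
        y_adj = rng.standard_normal(n)
        # sa2 -> 0 gives v -> 0
        v0 = em_update_v(y_adj, W, A, np.ones(n), 1e-12, 1.0)
        assert np.all(np.abs(v0) < 1e-9)
        # scalar BLUP: v_j = r_j * sa2/(sa2 + se2)
        v = em_update_v(y_adj, W, A, np.ones(n), 2.0, 1.0)
        assert np.allclose(v, y_adj * 2.0 / 3.0, atol=1e-10)
        # pedigree toy vs dense mixed-model solve
        from hybbr.datamodel import build_a_matrix

        ped = build_a_matrix(["a", "b", "c", "d", "e", "f"],
                             [None, None, "a", "a", "c", "c"],
                             [None, None, "b", "b", "d", "d"])
        v = em_update_v(y_adj, W, ped.A, np.ones(n), 1.5, 0.7)
        lhs = 1.5 * W.T @ W + 0.7 * np.linalg.inv(ped.A)
        oracle = np.linalg.solve(lhs, 1.5 * W.T @ y_adj)
        assert np.allclose(v, oracle, atol=1e-8)

    def test_convergence_statistic(self):
        ok, stat = em_check_convergence(np.array([1.0, 2.0]), np.array([1.0, 2.0]), 1e-10)
        assert ok and stat == 0.0
        ok, stat = em_check_convergence(np.array([1.0, 0.0]), np.zeros(2), 1e-10)
        assert not ok and stat == pytest.approx(1.0)
        ok, stat = em_check_convergence(np.array([1.0, 1.0]),
                                        np.array([1.0, 1.0 + 1e-6]), 1e-10)
        assert ok and stat == pytest.approx(5e-13, rel=1e-3)
        ok, _ = em_check_convergence(np.zeros(2), np.zeros(2), 1e-10)
        assert ok


class TestRunEm:
    def test_null_data_shrinks_everything(self):
        # slab variances large enough to be distinguishable from the spike
        # at this n; pure-noise phenotypes must drive effects and the slab
        # proportions toward zero
        rng = np.random.default_rng(3)
        n, m = 150, 60
        Z = rng.standard_normal((n, m))
        Z -= Z.mean(axis=0)
        trait = TraitData(y=rng.standard_normal(n), E_diag=None, X=None)
        vc = VarianceComponents(sigma_e2=1.0, sigma_g2=50.0)
        prior = MixturePrior(sigma_g2=vc.sigma_g2)
        res = run_em(trait, Z, prior, _zero_pev(n, m), vc)
        assert res.converged
        # the fitted genetic signal explains almost none of the variance
        assert np.var(Z @ res.state.g) / np.var(trait.y) < 0.1
        # the spike share can only be weakly identified at m=60, but it
        # must move up from its 0.5 start, not down
        assert res.state.Pr[0] > 0.5

    def test_pinned_component_equals_ridge(self, small_data):
        trait, Z = small_data["trait"], small_data["geno"].Z
        vc, prior = small_data["vc"], small_data["prior"]
        lam = vc.sigma_e2 / prior.component_variances[3]
        _, g_ridge = ridge_oracle(trait, Z, lam)
        res = run_em(trait, Z, prior, _zero_pev(trait.n, Z.shape[1]), vc,
                     config=EmConfig(pin_component=3, update_sigma_e=False,
                                     update_pr=False, tol=1e-16, max_iter=5000))
        rel = np.linalg.norm(res.state.g - g_ridge) / np.linalg.norm(g_ridge)
        assert rel < 1e-6

    def test_deterministic(self, small_data):
        trait, Z = small_data["trait"], small_data["geno"].Z
        G = build_grm(Z)
        pev = compute_pev(trait, Z, G, vc=small_data["vc"])
        r1 = run_em(trait, Z, small_data["prior"], pev, small_data["vc"],
                    config=EmConfig(max_iter=50))
        r2 = run_em(trait, Z, small_data["prior"], pev, small_data["vc"],
                    config=EmConfig(max_iter=50))
        assert np.array_equal(r1.state.g, r2.state.g)
        assert r1.state.sigma_e2 == r2.state.sigma_e2

    def test_sweep_matches_python_reference(self, small_data):
        """The fused numba sweep must agree with the one-SNP-at-a-time ops."""
        trait, Z = small_data["trait"], small_data["geno"].Z
        vc, prior = small_data["vc"], small_data["prior"]
        G = build_grm(Z)
        pev = compute_pev(trait, Z, G, vc=vc)
        cfg = EmConfig(max_iter=1)
        res = run_em(trait, Z, prior, pev, vc, config=cfg)
        # python reference of the first sweep
        n, m = Z.shape
        g = np.full(m, cfg.g_init)
        beta = em_update_beta(trait.y - Z @ g, trait.X, trait.E_diag)
        resid = trait.y - trait.X @ beta - Z @ g
        E = trait.E_diag
        P = np.zeros((m, 4))
        Pr = np.asarray(cfg.Pr_init)
        for i in range(m):
            e_star = residual_correct(resid, Z, g, i)
            rhs = Z[:, i] @ (e_star / E)
            zEz = Z[:, i] @ (Z[:, i] / E)
            P[i] = em_responsibilities(rhs, zEz, -pev.trace_terms[i],
                                       vc.sigma_e2, prior, Pr=Pr)
            g_new = em_update_snp(rhs, zEz, P[i], vc.sigma_e2, prior)
            resid = e_star - Z[:, i] * g_new
            g[i] = g_new
        assert np.allclose(res.state.P, P, atol=1e-10)
        sigma_e2 = em_update_sigma_e(resid, E, pev.trace_resid)
        assert res.state.sigma_e2 == pytest.approx(sigma_e2, abs=1e-10)

    def test_simplex_conservation(self, small_data):
        trait, Z = small_data["trait"], small_data["geno"].Z
        res = run_em(trait, Z, small_data["prior"],
                     _zero_pev(trait.n, Z.shape[1]), small_data["vc"],
                     config=EmConfig(max_iter=20))
        assert np.allclose(res.state.P.sum(axis=1), 1.0, atol=1e-10)
        assert res.state.Pr.sum() == pytest.approx(1.0, abs=1e-10)

    def test_residual_cache_consistent(self, small_data):
        trait, Z = small_data["trait"], small_data["geno"].Z
        res = run_em(trait, Z, small_data["prior"],
                     _zero_pev(trait.n, Z.shape[1]), small_data["vc"],
                     config=EmConfig(max_iter=30))
        st = res.state
        recomputed = st.recompute_residual(trait.y, Z, trait.X)
        assert np.allclose(st.residual, recomputed, atol=1e-8)
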