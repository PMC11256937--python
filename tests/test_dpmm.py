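import numpy as np
import pytest
from scipy import stats

from adaclust import dpmm
from adaclust.errors import DomainError, ValidationError
from adaclust.synthetic import simulate_latent_mixture

from _oracles import VariationalDP1D


class TestStickToWeights:
    def test_hand_product(self):
        w = dpmm.stick_to_weights(dpmm.StickBreaking(np.array([0.5, 0.5, 0.5]), 1.0))
        np.testing.assert_allclose(w.pi, [0.5, 0.25, 0.125], atol=1e-15)

    def test_full_first_stick_limit(self):
        w = dpmm.stick_to_weights(
            dpmm.StickBreaking(np.array([1 - 1e-14, 0.3, 0.7]), 1.0))
        assert w.pi[0] == pytest.approx(1.0, abs=1e-12)
        assert w.pi[1] == pytest.approx(0.0, abs=1e-12)

    def test_telescoping_identity(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            delta = rng.uniform(0.01, 0.99, size=8)
            w = dpmm.stick_to_weights(dpmm.StickBreaking(delta, 1.0))
            assert w.pi.sum() == pytest.approx(1.0 - np.prod(1.0 - delta), rel=1e-12)
            assert w.pi.sum() <= 1.0 + 1e-12
            partial = np.cumsum(w.pi)
            assert np.all(np.diff(partial) > 0)

    def test_monotone_in_each_delta(self):
        rng = np.random.default_rng(1)
        delta = rng.uniform(0.2, 0.8, size=5)
        base = dpmm.stick_to_weights(dpmm.StickBreaking(delta, 1.0)).pi
        for k in range(5):
            bumped = delta.copy()
            bumped[k] = min(bumped[k] + 0.05, 0.99)
            new = dpmm.stick_to_weights(dpmm.StickBreaking(bumped, 1.0)).pi
            assert new[k] > base[k]

    def test_domain_error(self):
        with pytest.raises(DomainError):
            dpmm.StickBreaking(np.array([0.0, 0.5]), 1.0)
        with pytest.raises(DomainError):
            dpmm.StickBreaking(np.array([0.5, 1.0]), 1.0)


class TestComponentLoglik:
    def test_standard_normal_mode(self):
        val = dpmm.component_loglik(np.array([0.0]), np.array([0.0]), np.array([[1.0]]))
        assert val == pytest.approx(-0.5 * np.log(2 * np.pi), abs=1e-12)
        assert val == pytest.approx(-0.91893853, abs=1e-7)

    def test_translation_invariance(self):
        rng = np.random.default_rng(2)
        z, mu = rng.normal(size=3), rng.normal(size=3)
        a = rng.standard_normal((3, 3))
        lam = a @ a.T + 3 * np.eye(3)
        shift = rng.normal(size=3)
        v1 = dpmm.component_loglik(z, mu, lam)
        v2 = dpmm.component_loglik(z + shift, mu + shift, lam)
        assert v1 == pytest.approx(v2, rel=1e-12)

    def test_identity_precision_factorizes(self):
        z = np.array([1.2, -0.7])
        mu = np.array([0.3, 0.4])
        got = dpmm.component_loglik(z, mu, np.eye(2))
        expected = (stats.norm.logpdf(z[0] - mu[0]) + stats.norm.logpdf(z[1] - mu[1]))
        assert got == pytest.approx(expected, rel=1e-12)

    def test_matches_scipy_full_covariance(self):
        rng = np.random.default_rng(3)
        a = rng.standard_normal((4, 4))
        lam = a @ a.T + 4 * np.eye(4)
        z, mu = rng.normal(size=4), rng.normal(size=4)
        expected = stats.multivariate_normal.logpdf(z, mean=mu, cov=np.linalg.inv(lam))
        assert dpmm.component_loglik(z, mu, lam) == pytest.approx(expected, rel=1e-9)

    def test_non_spd_rejected(self):
        with pytest.raises(DomainError):
            dpmm.component_loglik(np.zeros(2), np.zeros(2), -np.eye(2))


def _toy_state(means, precisions, delta, alpha=1.0, n=4):
    k = len(means)
    sticks = dpmm.StickBreaking(np.asarray(delta, dtype=float), alpha)
    weights = dpmm.stick_to_weights(sticks)
    comps = dpmm.ComponentParams(means=np.asarray(means, dtype=float),
                                 precisions=np.asarray(precisions, dtype=float))
    resp = np.tile(weights.normalized(), (n, 1))
    return dpmm.DPMMState(sticks=sticks, weights=weights, components=comps,
                          responsibilities=resp, hard_labels=resp.argmax(axis=1))


class TestLogPriorS:
    def test_uniform_beta_contributes_zero(self):
        # alpha = 1: Beta(1,1) log-density is 0 for every stick value
        state = _toy_state([[0.0]], [[[1.0]]], [0.4], alpha=1.0, n=3)
        hyper = dpmm.NWHyper(sigma=np.zeros(1), kappa0=1.0, nu0=1.0, zeta=np.eye(1))
        val = dpmm.log_prior_S(state, hyper, alpha=1.0)
        no_beta = (stats.wishart.logpdf(1.0, df=1.0, scale=hyper.wishart_scale[0, 0])
                   + stats.norm.logpdf(0.0, 0.0, 1.0)
                   + 3 * np.log(state.weights.pi[0]))
        assert val == pytest.approx(no_beta, rel=1e-9)

    def test_one_component_categorical_term(self):
        state = _toy_state([[0.0]], [[[1.0]]], [0.7], alpha=2.0, n=5)
        v1 = dpmm.log_prior_S(state, dpmm.NWHyper(np.zeros(1), 1.0, 1.0, np.eye(1)), 2.0)
        # categorical part must be 5 * ln pi_1
        beta_nw = v1 - 5 * np.log(state.weights.pi[0])
        expected_beta = stats.beta.logpdf(0.7, 1, 2)
        assert beta_nw - expected_beta == pytest.approx(
            stats.wishart.logpdf(1.0, df=1.0, scale=1.0)
            + stats.norm.logpdf(0.0, 0.0, 1.0), rel=1e-9)

    def test_1d_oracle_full_evaluation(self):
        # independent evaluation: Beta x (Normal-Gamma) x Categorical in 1-D
        delta, mu, lam, alpha = 0.3, 1.2, 2.5, 0.7
        kappa0, nu0, var0 = 1.0, 1.0, 2.0
        state = _toy_state([[mu]], [[[lam]]], [delta], alpha=alpha, n=2)
        hyper = dpmm.NWHyper(np.array([0.5]), kappa0, nu0, np.array([[var0]]))
        got = dpmm.log_prior_S(state, hyper, alpha)
        w0 = 1.0 / (nu0 * var0)
        oracle = (
            stats.beta.logpdf(delta, 1, alpha)
            + stats.gamma.logpdf(lam, a=nu0 / 2.0, scale=2.0 * w0)
            + stats.norm.logpdf(mu, loc=0.5, scale=1.0 / np.sqrt(kappa0 * lam))
            + 2 * np.log(delta)  # pi_1 = delta_1; two cells labeled 0
        )
        assert got == pytest.approx(oracle, rel=1e-9)


class TestFitS:
    def test_two_blob_recovery(self):
        Z, _ = simulate_latent_mixture(200, 2, 2, 10.0, seed=0)
        state = dpmm.fit_S(Z, alpha=1e-10, K_max=10, seed=0)
        assert dpmm.effective_cluster_count(state) == 2

    def test_single_blob_collapse(self):
        Z, _ = simulate_latent_mixture(200, 2, 1, 0.0, seed=1)
        state = dpmm.fit_S(Z, alpha=1e-10, K_max=10, seed=0)
        assert dpmm.effective_cluster_count(state) == 1

    def test_elbo_monotone(self):
        Z, _ = simulate_latent_mixture(300, 3, 3, 6.0, seed=2)
        state = dpmm.fit_S(Z, alpha=1e-2, K_max=12, seed=0, tol=1e-10, max_iter=80)
        diffs = np.diff(state.elbo_trace)
        assert np.all(diffs >= -1e-6)

    def test_responsibilities_rows_sum_to_one(self):
        Z, _ = simulate_latent_mixture(120, 2, 2, 8.0, seed=3)
        state = dpmm.fit_S(Z, alpha=1.0, K_max=8, seed=0)
        np.testing.assert_allclose(state.responsibilities.sum(axis=1), 1.0, atol=1e-9)

    def test_permutation_equivariance(self):
        Z, _ = simulate_latent_mixture(150, 2, 3, 8.0, seed=4)
        state = dpmm.fit_S(Z, alpha=1e-10, K_max=8, seed=0)
        rng = np.random.default_rng(5)
        perm = rng.permutation(Z.shape[0])
        state_p = dpmm.fit_S(Z[perm], alpha=1e-10, K_max=8, seed=0,
                             warm_start=dpmm.DPMMState(
                                 sticks=state.sticks, weights=state.weights,
                                 components=state.components,
                                 responsibilities=state.responsibilities[perm],
                                 hard_labels=state.responsibilities[perm].argmax(axis=1),
                             ))
        # same partition up to component relabeling
        from sklearn.metrics import adjusted_rand_score
        assert adjusted_rand_score(state.hard_labels[perm], state_p.hard_labels) == 1.0

    def test_input_validation(self):
        with pytest.raises(ValidationError):
            dpmm.fit_S(np.zeros((1, 2)))
        with pytest.raises(ValidationError):
            dpmm.fit_S(np.array([[np.nan, 0.0], [0.0, 1.0]]))
        with pytest.raises(DomainError):
            dpmm.fit_S(np.random.default_rng(0).normal(size=(10, 2)), alpha=0.0)

    def test_1d_agrees_with_bruteforce_oracle(self):
        rng = np.random.default_rng(11)
        z = np.concatenate([rng.normal(-4, 1, 60), rng.normal(4, 1, 60)])[:, None]
        alpha = 1.0
        hyper = dpmm.default_hyper(z)
        state = dpmm.fit_S(z, alpha=alpha, hyper=hyper, K_max=2, seed=0,
                           max_iter=500, tol=1e-12)
        oracle = VariationalDP1D(alpha=alpha, k=2, mean0=float(hyper.sigma[0]),
                                 kappa0=1.0, nu0=1.0,
                                 var0=float(hyper.zeta[0, 0]))
        init = np.zeros((120, 2))
        labels0 = (z[:, 0] > z[:, 0].mean()).astype(int)
        init[np.arange(120), labels0] = 1.0
        resp_oracle = oracle.fit(z[:, 0], init, n_iter=500)
        r1 = state.responsibilities
        agree = min(np.abs(r1 - resp_oracle).max(),
                    np.abs(r1 - resp_oracle[:, ::-1]).max())
        assert agree < 1e-3

    def test_adaptive_k_recovery(self):
        for K in range(2, 9):
            Z, _ = simulate_latent_mixture(150 * K, 2, K, 8.0, seed=K)
            state = dpmm.fit_S(Z, alpha=1e-10, K_max=20, seed=0)
            assert dpmm.effective_cluster_count(state) == K, f"K={K}"

    def test_concentration_monotonicity(self):
        Z, _ = simulate_latent_mixture(600, 2, 4, 8.0, seed=3)
        ks = []
        for a in [1e-10, 1e-2, 1.0, 1e2, 1e5]:
            st = dpmm.fit_S(Z, alpha=a, K_max=20, seed=0)
            ks.append(dpmm.effective_cluster_count(st))
        assert all(k2 >= k1 for k1, k2 in zip(ks, ks[1:]))

    def test_cross_check_sklearn(self):
        # same model family as sklearn's DP mixture: occupied components agree
        from sklearn.mixture import BayesianGaussianMixture

        Z, y = simulate_latent_mixture(450, 2, 3, 9.0, seed=6)
        state = dpmm.fit_S(Z, alpha=1e-3, K_max=10, seed=0)
        bgm = BayesianGaussianMixture(
            n_components=10, weight_concentration_prior_type="dirichlet_process",
            weight_concentration_prior=1e-3, random_state=0, max_iter=300,
        ).fit(Z)
        from sklearn.metrics import adjusted_rand_score
        assert adjusted_rand_score(bgm.predict(Z), state.hard_labels) > 0.99


class TestLossZ:
    def _single_state(self):
        return _toy_state([[0.0]], [[[1.0]]], [0.999999999999], alpha=1.0)

    def test_single_component_at_mode(self):
        state = self._single_state()
        assert dpmm.loss_z(np.array([0.0]), state) == pytest.approx(
            0.5 * np.log(2 * np.pi), abs=1e-9)

    def test_two_component_midpoint_oracle(self):
        state = _toy_state([[-1.0], [1.0]], [[[1.0]], [[1.0]]], [0.5, 0.999999999999])
        z = np.array([0.0])
        pis = state.weights.normalized()
        direct = -np.log(pis[0] * stats.norm.pdf(0, -1, 1) + pis[1] * stats.norm.pdf(0, 1, 1))
        assert dpmm.loss_z(z, state) == pytest.approx(direct, rel=1e-12)

    def test_logsumexp_bound(self):
        rng = np.random.default_rng(7)
        state = _toy_state([[-2.0], [2.0]], [[[1.5]], [[0.5]]], [0.3, 0.9])
        pis = state.weights.normalized()
        for _ in range(20):
            z = rng.normal(scale=3, size=1)
            best = max(np.log(pis[k]) + dpmm.component_loglik(
                z, state.components.means[k], state.components.precisions[k])
                for k in range(2))
            val = dpmm.loss_z(z, state)
            assert val >= -best - np.log(2) - 1e-10
            assert val <= -best + 1e-10

    def test_gradient_matches_finite_difference(self):
        rng = np.random.default_rng(8)
        Z, _ = simulate_latent_mixture(50, 3, 2, 5.0, seed=9)
        state = dpmm.fit_S(Z, alpha=1.0, K_max=4, seed=0)
        z0 = rng.normal(size=(1, 3))
        loss, grad = dpmm.loss_z_grad(z0, state)
        eps = 1e-6
        for d in range(3):
            zp, zm = z0.copy(), z0.copy()
            zp[0, d] += eps
            zm[0, d] -= eps
            fd = (dpmm.loss_z(zp[0], state) - dpmm.loss_z(zm[0], state)) / (2 * eps)
            assert grad[0, d] == pytest.approx(fd, rel=1e-4, abs=1e-6)


class TestResponsibilities:
    def test_single_component(self):
        state = _toy_state([[0.0]], [[[1.0]]], [0.5])
        np.testing.assert_allclose(dpmm.responsibilities(np.array([3.0]), state), [1.0])

    def test_far_separated_assignment(self):
        state = _toy_state([[-20.0], [20.0]], [[[1.0]], [[1.0]]], [0.5, 0.999999999999])
        r = dpmm.responsibilities(np.array([-20.0]), state)
        assert r[0] > 0.999

    def test_rows_sum_to_one_extreme_inputs(self):
        state = _toy_state([[-5.0], [5.0]], [[[2.0]], [[2.0]]], [0.5, 0.999999999999])
        for z in ([1e3], [-1e3], [0.0]):
            r = dpmm.responsibilities(np.array(z), state)
            assert np.isfinite(r).all()
            assert r.sum() == pytest.approx(1.0, abs=1e-12)


class TestEffectiveClusterCount:
    def test_all_one_component(self):
        resp = np.zeros((5, 4))
        resp[:, 3] = 1.0
        state = _toy_state([[0.0]] * 4, [np.eye(1)] * 4, [0.5, 0.5, 0.5, 0.5], n=5)
        state.responsibilities = resp
        state.hard_labels = resp.argmax(axis=1)
        assert dpmm.effective_cluster_count(state) == 1

    def test_direct_count(self):
        resp = np.eye(4)[[0, 0, 1, 2]]
        state = _toy_state([[0.0]] * 4, [np.eye(1)] * 4, [0.5, 0.5, 0.5, 0.5], n=4)
        state.responsibilities = resp
        state.hard_labels = resp.argmax(axis=1)
        assert dpmm.effective_cluster_count(state) == 3

    def test_equals_bruteforce_definition(self):
        Z, _ = simulate_latent_mixture(200, 2, 3, 8.0, seed=10)
        state = dpmm.fit_S(Z, alpha=1e-10, K_max=8, seed=0)
        wins = set(int(state.responsibilities[n].argmax())
                   for n in range(Z.shape[0]))
        assert dpmm.effective_cluster_count(state) == len(wins)
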