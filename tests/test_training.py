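import numpy as np
import pytest

from arhohmm import training as tr
from arhohmm.inference import enumerate_loglikelihood, forward_backward
from arhohmm.model import context_index
from arhohmm.simulate import SimulationSpec, default_generating_model, simulate_profiles
from conftest import make_random_model


def empty_counts(N, L, P):
    return tr.ExpectedCounts(
        pi_counts=np.zeros(N),
        xi=[np.zeros((N**d, N)) for d in range(1, L + 1)],
        weight=np.zeros(N),
        gram=np.zeros((N, P + 1, P + 1)),
        moment=np.zeros((N, P + 1)),
        sum_sq=np.zeros(N),
    )


class TestInitModel:
    def test_stationarity_of_initial_matrix(self):
        model = tr.init_model(N=3, L=1, P=0, pi_init=(0.9, 0.05, 0.05), rho=0.1)
        pi, M = model.transitions.pi, model.transitions.A[0]
        assert np.abs(pi @ M - pi).max() < 1e-12

    def test_uniform_pi_rho_one_gives_uniform_matrix(self):
        third = 1.0 / 3.0
        model = tr.init_model(N=3, L=1, P=0, pi_init=(third, third, third), rho=1.0)
        assert np.allclose(model.transitions.A[0], third)

    def test_higher_order_rows_copy_most_recent_state_row(self):
        model = tr.init_model(N=3, L=2, P=0)
        M, A2 = model.transitions.A[0], model.transitions.A[1]
        for code in range(9):
            assert np.array_equal(A2[code], M[code % 3])

    def test_zero_coefficients_make_init_non_autoregressive(self, rng):
        model = tr.init_model(N=3, L=1, P=3)
        obs = rng.normal(0, 1, 30)
        plain = tr.init_model(N=3, L=1, P=0)
        assert forward_backward(obs, model).loglik == pytest.approx(
            forward_backward(obs, plain).loglik
        )

    def test_rho_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="rho"):
            tr.init_model(rho=0.0)
        with pytest.raises(ValueError, match="rho"):
            tr.init_model(rho=1.5)


class TestDefaultPrior:
    def test_pseudocount_arithmetic(self):
        model = tr.init_model(N=3, L=1, P=0, pi_init=(0.8, 0.1, 0.1))
        prior = tr.default_prior(model, kappa_A=10.0)
        row = model.transitions.A[0][0]
        assert np.allclose(prior.dirichlet_A[0][0], 1.0 + 10.0 * row)

    def test_zero_strength_gives_flat_pi_prior(self):
        model = tr.init_model()
        prior = tr.default_prior(model, kappa_pi=0.0)
        assert np.allclose(prior.dirichlet_pi, 1.0)

    def test_map_update_with_zero_data_is_identity(self):
        """The prior mode is the initialization: the zero-data fixed point."""
        model = tr.init_model(N=3, L=2, P=1)
        prior = tr.default_prior(model)
        updated = tr.map_update(empty_counts(3, 2, 1), model, prior)
        assert np.allclose(updated.transitions.pi, model.transitions.pi)
        for a, b in zip(updated.transitions.A, model.transitions.A):
            assert np.allclose(a, b)
        assert np.allclose(updated.emissions.mu, model.emissions.mu)
        assert np.allclose(updated.emissions.sigma, model.emissions.sigma, atol=1e-12)
        assert np.allclose(updated.emissions.coef, 0.0)

    def test_negative_strength_rejected(self):
        with pytest.raises(ValueError):
            tr.default_prior(tr.init_model(), kappa_pi=-1.0)


class TestEStep:
    def test_single_observation_counts(self, rng):
        model = make_random_model(rng, 3, 1, 0)
        counts = tr.e_step([np.array([0.4])], model)
        post = forward_backward(np.array([0.4]), model)
        assert np.allclose(counts.weight, post.gamma[0])
        assert np.allclose(counts.pi_counts, post.gamma[0])
        assert counts.xi[0].sum() == pytest.approx(0.0)

    def test_counts_additive_over_duplicated_profiles(self, rng):
        model = make_random_model(rng, 3, 2, 1)
        obs = rng.normal(0, 1, 12)
        one = tr.e_step([obs], model)
        two = tr.e_step([obs, obs], model)
        assert np.allclose(two.weight, 2 * one.weight)
        assert np.allclose(two.gram, 2 * one.gram)
        for a, b in zip(two.xi, one.xi):
            assert np.allclose(a, 2 * b)

    def test_counts_match_enumeration_weighted_paths(self, rng):
        """Expected transition counts agree with explicit path enumeration."""
        from itertools import product

        model = make_random_model(rng, 3, 2, 1)
        obs = rng.normal(0, 1, 4)
        counts = tr.e_step([obs], model)
        N, L, T = 3, 2, 4
        # path posterior weights from the exact joint
        from arhohmm.model import emission_logdensity

        logb = np.array([
            [emission_logdensity(model, s, t + 1, obs[t], obs[:t]) for s in range(N)]
            for t in range(T)
        ])
        weights = {}
        for path in product(range(N), repeat=T):
            lp = np.log(model.transitions.pi[path[0]])
            for t in range(1, T):
                d = min(t, L)
                lp += np.log(model.transitions.A[d - 1][context_index(path[t - d:t], N), path[t]])
            lp += logb[np.arange(T), list(path)].sum()
            weights[path] = np.exp(lp)
        Z = sum(weights.values())
        xi_expected = [np.zeros((N, N)), np.zeros((N * N, N))]
        for path, w in weights.items():
            for t in range(1, T):
                d = min(t, L)
                xi_expected[d - 1][context_index(path[t - d:t], N), path[t]] += w / Z
        for got, want in zip(counts.xi, xi_expected):
            assert np.abs(got - want).max() < 1e-10


class TestMSteps:
    def test_transition_map_closed_form(self):
        counts = empty_counts(3, 1, 0)
        counts.xi[0][0] = [3.0, 1.0, 0.0]
        counts.pi_counts[:] = [1.0, 0.0, 0.0]
        prior = tr.PriorSpec(
            dirichlet_pi=np.ones(3), dirichlet_A=[np.full((3, 3), 2.0)],
            m=np.zeros(3), kappa=np.zeros(3), a=-np.ones(3), b=np.zeros(3),
        )
        _, A = tr.m_step_transitions(counts, prior)
        assert np.allclose(A[0][0], [4 / 7, 2 / 7, 1 / 7])

    def test_flat_prior_gives_ml_row_and_empty_rows_fall_back(self):
        counts = empty_counts(3, 1, 0)
        counts.xi[0][0] = [3.0, 1.0, 0.0]
        prior = tr.PriorSpec.flat(3, 1)
        _, A = tr.m_step_transitions(counts, prior)
        assert np.allclose(A[0][0], [0.75, 0.25, 0.0])
        assert np.allclose(A[0][1], 1 / 3)  # no data, flat prior -> uniform

    def test_symmetric_pseudocounts_with_zero_counts_give_uniform(self):
        counts = empty_counts(3, 1, 0)
        prior = tr.PriorSpec(
            dirichlet_pi=np.full(3, 2.0), dirichlet_A=[np.full((3, 3), 2.0)],
            m=np.zeros(3), kappa=np.zeros(3), a=-np.ones(3), b=np.zeros(3),
        )
        pi, A = tr.m_step_transitions(counts, prior)
        assert np.allclose(pi, 1 / 3) and np.allclose(A[0], 1 / 3)

    def test_weighted_mean_for_order_zero_flat_prior(self, rng):
        model = make_random_model(rng, 3, 1, 0)
        obs = rng.normal(0, 1, 50)
        counts = tr.e_step([obs], model)
        mu, _, _ = tr.m_step_emissions(counts, tr.PriorSpec.flat(3, 1))
        post = forward_backward(obs, model)
        for s in range(3):
            expected = float((post.gamma[:, s] * obs).sum() / post.gamma[:, s].sum())
            assert mu[s] == pytest.approx(expected, abs=1e-10)

    def test_ar1_solution_matches_normal_equations_oracle(self, rng):
        """Equal-weight AR(1) M-step equals ordinary regression coefficients."""
        # two indistinguishable states force gamma = 1/2 everywhere, so the
        # weighted least-squares problem reduces to plain OLS per state
        model = make_random_model(rng, 2, 0, 1)
        model.transitions.pi[:] = 0.5
        model.emissions.mu[:] = 0.1
        model.emissions.sigma[:] = 1.0
        model.emissions.coef[:] = 0.2
        obs = rng.normal(0, 1, 200)
        counts = tr.e_step([obs], model)
        assert np.allclose(counts.weight, 100.0)
        mu, coef, _ = tr.m_step_emissions(counts, tr.PriorSpec.flat(2, 0))
        X = np.column_stack([np.ones(200), np.r_[0.0, obs[:-1]]])
        beta = np.linalg.solve(X.T @ X, X.T @ obs)
        for s in range(2):
            assert mu[s] == pytest.approx(beta[0], abs=1e-10)
            assert coef[s, 0] == pytest.approx(beta[1], abs=1e-10)

    def test_zero_residuals_engage_sigma_floor(self):
        counts = empty_counts(1, 0, 0)
        counts.weight[:] = 10.0
        counts.gram[0, 0, 0] = 10.0
        counts.moment[0, 0] = 5.0  # all observations 0.5 -> zero residual
        counts.sum_sq[0] = 2.5
        _, _, sigma = tr.m_step_emissions(counts, tr.PriorSpec.flat(1, 0))
        assert sigma[0] == pytest.approx(tr.SIGMA_FLOOR)


class TestLogPosterior:
    def test_flat_prior_equals_loglikelihood(self, rng):
        model = make_random_model(rng, 3, 1, 1)
        obs = rng.normal(0, 1, 30)
        flat = tr.PriorSpec.flat(3, 1)
        assert tr.log_posterior([obs], model, flat) == pytest.approx(
            forward_backward(obs, model).loglik
        )

    def test_additive_in_profiles(self, rng):
        model = make_random_model(rng, 3, 1, 0)
        prior = tr.default_prior(tr.init_model(N=3, L=1, P=0))
        a, b = rng.normal(0, 1, 20), rng.normal(0, 1, 25)
        lp_a = tr.log_posterior([a], model, prior)
        lp_ab = tr.log_posterior([a, b], model, prior)
        assert lp_ab - lp_a == pytest.approx(forward_backward(b, model).loglik)

    def test_map_row_is_local_optimum_of_auxiliary(self, rng):
        """Perturbing a transition row away from its MAP lowers the objective."""
        counts = empty_counts(3, 1, 0)
        counts.xi[0][:] = rng.uniform(1, 5, (3, 3))
        eta = np.full((3, 3), 2.0)
        _, A = tr.m_step_transitions(
            counts,
            tr.PriorSpec(dirichlet_pi=np.ones(3), dirichlet_A=[eta],
                         m=np.zeros(3), kappa=np.zeros(3), a=-np.ones(3), b=np.zeros(3)),
        )

        def objective(row):
            return float(((counts.xi[0][0] + eta[0] - 1) * np.log(row)).sum())

        best = objective(A[0][0])
        for _ in range(20):
            d = rng.normal(0, 0.01, 3)
            d -= d.mean()
            row = A[0][0] + d
            if (row > 0).all():
                assert objective(row / row.sum()) < best


class TestFit:
    def test_log_posterior_never_decreases(self, rng):
        gen = default_generating_model(L=1, P=0)
        profiles, _ = simulate_profiles(SimulationSpec(model=gen, n_sequences=10, T=80, seed=2))
        m0 = tr.init_model(N=3, L=2, P=1)
        res = tr.fit(profiles, m0, tr.default_prior(m0), tr.TrainingConfig(max_iterations=40))
        assert np.all(np.diff(res.log_posteriors) >= -1e-8)

    def test_flat_prior_mixture_matches_independent_gmm_em(self, rng):
        """AR(0)-HMM(0) flat-prior EM equals a standalone GMM EM iterate-for-iterate."""
        X = np.concatenate([
            rng.normal(0, 0.5, 300), rng.normal(-2, 1, 60), rng.normal(2, 1, 60),
        ])
        rng.shuffle(X)
        n_iter = 60
        m0 = tr.init_model(N=3, L=0, P=0)
        res = tr.fit(
            [X], m0, tr.PriorSpec.flat(3, 0),
            tr.TrainingConfig(stop_epsilon=1e-300, max_iterations=n_iter),
        )
        w = np.array([0.9, 0.05, 0.05])
        mu = np.array([0.0, -2.0, 2.0])
        var = np.array([0.25, 1.0, 1.0])
        for _ in range(n_iter):
            dens = np.exp(-0.5 * (X[:, None] - mu) ** 2 / var) / np.sqrt(2 * np.pi * var) * w
            r = dens / dens.sum(axis=1, keepdims=True)
            Wk = r.sum(axis=0)
            w = Wk / Wk.sum()
            mu = (r * X[:, None]).sum(axis=0) / Wk
            var = np.maximum((r * (X[:, None] - mu) ** 2).sum(axis=0) / Wk, tr.SIGMA_FLOOR**2)
        assert np.abs(res.model.transitions.pi - w).max() < 1e-6
        assert np.abs(res.model.emissions.mu - mu).max() < 1e-6
        assert np.abs(res.model.emissions.sigma - np.sqrt(var)).max() < 1e-6

    def test_higher_order_fit_not_worse_on_higher_order_data(self):
        """On L=2-structured data the fitted order-2 model attains at least the
        order-1 model's training log-likelihood."""
        gen = default_generating_model(L=2, P=0, pi_init=(0.8, 0.1, 0.1))
        # make the order-2 structure real: persistence depends on the older state
        A2 = gen.transitions.A[1].copy()
        for code in range(9):
            older = code // 3
            row = A2[code].copy()
            row[older] += 0.3
            A2[code] = row / row.sum()
        gen.transitions.A[1] = A2
        profiles, _ = simulate_profiles(SimulationSpec(model=gen, n_sequences=30, T=150, seed=9))
        from arhohmm.inference import loglikelihood

        fits = {}
        for L in (1, 2):
            m0 = tr.init_model(N=3, L=L, P=0)
            res = tr.fit(profiles, m0, tr.PriorSpec.flat(3, L), tr.TrainingConfig(max_iterations=60))
            fits[L] = loglikelihood(profiles, res.model)
        assert fits[2] >= fits[1] - 1e-6

    def test_recovers_generating_ar1_hmm1_parameters(self):
        """Simulation-recovery study: 200 sequences x T=500 from a known
        AR(1)-HMM(1); transitions within ±0.03, means ±0.05, coefficients ±0.05."""
        gen = default_generating_model(L=1, P=1, ar_coef=0.3, pi_init=(0.8, 0.1, 0.1))
        profiles, _ = simulate_profiles(SimulationSpec(model=gen, n_sequences=200, T=500, seed=7))
        m0 = tr.init_model(N=3, L=1, P=1)
        res = tr.fit(profiles, m0, tr.default_prior(m0), tr.TrainingConfig(stop_epsilon=1e-6))
        assert np.abs(res.model.transitions.A[0] - gen.transitions.A[0]).max() < 0.03
        assert np.abs(res.model.emissions.mu - gen.emissions.mu).max() < 0.05
        assert np.abs(res.model.emissions.coef - gen.emissions.coef).max() < 0.05
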