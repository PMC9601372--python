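"""Dirichlet-process mixture prior: stick-breaking, centering and the
conjugate full-conditional updates, each checked against its closed form by
Monte Carlo."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from simplexmm import cdpmm
from simplexmm.priors import PriorSpec


def make_state(G=4, q=2, n=6, seed=0, prior_kind="cdpmm"):
    rng = np.random.default_rng(seed)
    spec = PriorSpec(prior_kind=prior_kind, G=G)
    state = cdpmm.init_state(spec, n=n, q=q, rng=rng)
    return state, spec, rng


def repeat_draws(update, state, n_draws, extract):
    out = []
    for _ in range(n_draws):
        s = state.copy()
        update(s)
        out.append(extract(s))
    return np.asarray(out)


class TestStickBreaking:
    def test_printed_example(self):
        pi = cdpmm.stick_break(np.array([0.5, 0.5, 1.0]))
        np.testing.assert_allclose(pi, [0.5, 0.25, 0.25])

    def test_first_stick_takes_all(self):
        np.testing.assert_allclose(
            cdpmm.stick_break(np.array([1.0, 0.3, 1.0])), [1.0, 0.0, 0.0]
        )

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=12))
    @settings(max_examples=100, derandomize=True)
    def test_sums_to_one(self, sticks):
        v = np.append(np.asarray(sticks), 1.0)
        pi = cdpmm.stick_break(v)
        assert pi.sum() == pytest.approx(1.0, abs=1e-15)
        assert np.all(pi >= 0.0)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            cdpmm.stick_break(np.array([1.2, 1.0]))


class TestCentering:
    def test_equal_locations_center_to_zero(self):
        mu_star = np.ones((5, 2)) * 3.7
        pi = np.full(5, 0.2)
        np.testing.assert_allclose(cdpmm.center_locations(mu_star, pi), 0.0,
                                   atol=1e-12)

    def test_two_component_example(self):
        mu = cdpmm.center_locations(np.array([[-1.0], [3.0]]), np.array([0.5, 0.5]))
        np.testing.assert_allclose(mu, [[-2.0], [2.0]])

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=50, derandomize=True)
    def test_weighted_mean_is_zero(self, seed):
        rng = np.random.default_rng(seed)
        G, q = 6, 3
        pi = rng.dirichlet(np.ones(G))
        mu_star = rng.normal(0, 3, size=(G, q))
        mu = cdpmm.center_locations(mu_star, pi)
        np.testing.assert_allclose(pi @ mu, 0.0, atol=1e-12)


class TestConjugateUpdates:
    """Each Gibbs step is compared with its stated closed-form conditional
    by the moments of repeated draws from a frozen state."""

    N_DRAWS = 4000

    def test_xi_normal_moments(self):
        state, spec, rng = make_state(G=3, q=2)
        draws = repeat_draws(
            lambda s: cdpmm.update_xi(s, spec, rng), state, self.N_DRAWS,
            lambda s: s.xi,
        )
        B = 1.0 / (state.G / state.psi + 1.0)
        A = B * (state.mu_star.sum(axis=0) / state.psi)
        se = np.sqrt(B / self.N_DRAWS)
        np.testing.assert_array_less(np.abs(draws.mean(axis=0) - A), 4 * se)
        np.testing.assert_allclose(draws.var(axis=0, ddof=1), B, rtol=0.15)

    def test_xi_single_component_identity_prior(self):
        # G=1, Psi=I: B = I/2, A = mu*_1/2
        state, spec, rng = make_state(G=2, q=2)
        state.psi = np.ones(2)
        state.mu_star = np.ones((2, 2))
        # both components at location 1: sum mu* = 2, so with G=2 and
        # Psi = Psi0 = I the closed form gives B = 1/3, A = 2/3
        draws = repeat_draws(
            lambda s: cdpmm.update_xi(s, spec, rng), state, self.N_DRAWS,
            lambda s: s.xi,
        )
        assert draws.mean() == pytest.approx(2.0 / 3.0, abs=0.05)
        assert draws.var(ddof=1) == pytest.approx(1.0 / 3.0, rel=0.15)

    def test_psi_gamma_moments(self):
        state, spec, rng = make_state(G=5, q=2)
        draws = repeat_draws(
            lambda s: cdpmm.update_psi(s, spec, rng), state, self.N_DRAWS,
            lambda s: 1.0 / s.psi,
        )
        shape = spec.c1 + state.G / 2.0
        rate = spec.c2 + 0.5 * ((state.mu_star - state.xi) ** 2).sum(axis=0)
        np.testing.assert_allclose(draws.mean(axis=0), shape / rate, rtol=0.05)
        np.testing.assert_allclose(draws.var(axis=0, ddof=1), shape / rate**2, rtol=0.2)

    def test_psi_degenerate_locations(self):
        state, spec, rng = make_state(G=4, q=1)
        state.mu_star = np.tile(state.xi, (state.G, 1))  # zero scatter
        draws = repeat_draws(
            lambda s: cdpmm.update_psi(s, spec, rng), state, self.N_DRAWS,
            lambda s: 1.0 / s.psi,
        )
        shape = spec.c1 + state.G / 2.0
        assert draws.mean() == pytest.approx(shape / spec.c2, rel=0.05)

    def test_varpi_gamma_moments(self):
        # conjugate shape includes omega_a per component: varpi_a + G*omega_a
        state, spec, rng = make_state(G=4, q=2, n=10)
        va = spec.resolve_varpi_a(10)
        draws = repeat_draws(
            lambda s: cdpmm.update_varpi(s, spec, va, rng), state, self.N_DRAWS,
            lambda s: s.varpi,
        )
        shape = va + state.G * spec.omega_a
        rate = spec.varpi_b + (1.0 / state.omega).sum(axis=0)
        np.testing.assert_allclose(draws.mean(axis=0), shape / rate, rtol=0.05)
        np.testing.assert_allclose(
            draws.var(axis=0, ddof=1), shape / rate**2, rtol=0.2
        )

    def test_tau_gamma_moments_and_monotonicity(self):
        state, spec, rng = make_state(G=6)
        state.nu_star = np.full(state.G - 1, 0.3)
        draws = repeat_draws(
            lambda s: cdpmm.update_tau(s, spec, rng), state, self.N_DRAWS,
            lambda s: s.tau,
        )
        rate = spec.a2 - np.log1p(-state.nu_star).sum()
        shape = spec.a1 + state.G - 1
        assert draws.mean() == pytest.approx(shape / rate, rel=0.05)
        # larger sticks -> larger rate -> stochastically smaller tau
        state.nu_star = np.full(state.G - 1, 0.9)
        draws_hi = repeat_draws(
            lambda s: cdpmm.update_tau(s, spec, rng), state, self.N_DRAWS,
            lambda s: s.tau,
        )
        assert draws_hi.mean() < draws.mean()

    def test_tau_degenerate_sticks(self):
        state, spec, rng = make_state(G=6)
        state.nu_star = np.zeros(state.G - 1)
        draws = repeat_draws(
            lambda s: cdpmm.update_tau(s, spec, rng), state, 2000,
            lambda s: s.tau,
        )
        assert draws.mean() == pytest.approx((spec.a1 + state.G - 1) / spec.a2, rel=0.07)

    def test_pi_all_mass_in_first_cluster(self):
        state, spec, rng = make_state(G=4, n=40)
        state.labels[:] = 0
        state.tau = 2.0
        draws = repeat_draws(
            lambda s: cdpmm.update_pi(s, rng), state, self.N_DRAWS,
            lambda s: s.pi,
        )
        # E[nu*_1] = (1+n)/(1+n+tau)
        expected = (1.0 + 40) / (1.0 + 40 + 2.0)
        assert draws[:, 0].mean() == pytest.approx(expected, rel=0.02)
        np.testing.assert_allclose(draws.sum(axis=1), 1.0, atol=1e-12)

    def test_pi_prior_reduction_when_unoccupied(self, rng):
        # with no observations in any cluster (n=0 analogue: labels absent),
        # the conditional Beta(1, tau + 0) matches the prior stick law
        state, spec, _ = make_state(G=3, n=1)
        state.labels = np.zeros(0, dtype=np.intp)
        state.tau = 3.0
        draws = repeat_draws(
            lambda s: cdpmm.update_pi(s, rng), state, self.N_DRAWS,
            lambda s: s.nu_star,
        )
        assert draws.mean() == pytest.approx(1.0 / (1.0 + 3.0), rel=0.05)

    def test_mu_star_single_member_identity_covariances(self):
        # one occupied cluster, Psi = Omega = I: F = I/2, E = (xi + b)/2
        state, spec, rng = make_state(G=3, q=2, n=1)
        spec.mu_star_mode = "literal"
        state.psi = np.ones(2)
        state.omega = np.ones((3, 2))
        state.labels = np.array([1])
        b = np.array([[0.7, -0.4]])
        draws = repeat_draws(
            lambda s: cdpmm.update_mu_star(s, spec, b, rng), state, self.N_DRAWS,
            lambda s: s.mu_star[1],
        )
        expected = 0.5 * (state.xi + b[0])
        se = np.sqrt(0.5 / self.N_DRAWS)
        np.testing.assert_array_less(np.abs(draws.mean(axis=0) - expected), 4 * se)
        np.testing.assert_allclose(draws.var(axis=0, ddof=1), 0.5, rtol=0.15)

    def test_mu_star_unoccupied_from_base(self):
        state, spec, rng = make_state(G=3, q=1, n=1, prior_kind="discrete_dp")
        state.labels = np.array([0])
        draws = repeat_draws(
            lambda s: cdpmm.update_mu_star(s, spec, np.zeros((1, 1)), rng),
            state, self.N_DRAWS, lambda s: s.mu_star[2, 0],
        )
        assert draws.mean() == pytest.approx(state.xi[0], abs=4 * np.sqrt(
            state.psi[0] / self.N_DRAWS))
        assert draws.var(ddof=1) == pytest.approx(state.psi[0], rel=0.15)

    def test_omega_conjugacy(self):
        state, spec, rng = make_state(G=3, q=1, n=5)
        state.labels = np.array([1, 1, 1, 0, 0])
        state.mu = np.zeros((3, 1))
        b = np.array([[0.5], [-0.5], [1.0], [0.2], [-0.2]])
        draws = repeat_draws(
            lambda s: cdpmm.update_omega(s, spec, b, rng), state, self.N_DRAWS,
            lambda s: 1.0 / s.omega[:, 0],
        )
        ssq = {1: 0.5**2 + 0.5**2 + 1.0, 0: 0.04 + 0.04}
        for g, d_g in [(0, 2), (1, 3), (2, 0)]:
            shape = d_g / 2.0 + spec.omega_a
            rate = state.varpi[0] + 0.5 * ssq.get(g, 0.0)
            assert draws[:, g].mean() == pytest.approx(shape / rate, rel=0.06), g
            assert draws[:, g].var(ddof=1) == pytest.approx(shape / rate**2, rel=0.25), g

    def test_labels_uniform_when_components_identical(self):
        state, spec, rng = make_state(G=3, n=3000)
        state.mu = np.zeros((3, 2))
        state.omega = np.ones((3, 2))
        state.pi = np.array([0.5, 0.3, 0.2])
        b = np.zeros((3000, 2))
        cdpmm.update_labels(state, b, rng)
        freq = np.bincount(state.labels, minlength=3) / 3000
        np.testing.assert_allclose(freq, state.pi, atol=0.03)

    def test_labels_separated_components(self):
        state, spec, rng = make_state(G=2, n=4)
        state.mu = np.array([[-5.0, -5.0], [5.0, 5.0]])
        state.omega = np.full((2, 2), 0.1)
        state.pi = np.array([0.5, 0.5])
        b = np.array([[-5.0, -5.0]] * 2 + [[5.0, 5.0]] * 2)
        cdpmm.update_labels(state, b, rng)
        assert state.labels.tolist() == [0, 0, 1, 1]

    def test_label_weights_normalize(self):
        state, spec, rng = make_state(G=4, n=7)
        b = rng.standard_normal((7, 2))
        logw = cdpmm.label_log_weights(state, b)
        w = np.exp(logw - logw.max(axis=1, keepdims=True))
        w /= w.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(w.sum(axis=1), 1.0, atol=1e-12)


class TestPriorParams:
    def test_single_cluster_lookup(self):
        state, spec, rng = make_state(G=3, n=4)
        state.labels = np.array([2, 0, 1, 2])
        mu, om = cdpmm.random_effect_prior_params(state, 0)
        np.testing.assert_array_equal(mu, state.mu[2])
        np.testing.assert_array_equal(om, state.omega[2])
        mu1, om1 = cdpmm.random_effect_prior_params(state, 1)
        np.testing.assert_array_equal(mu1, state.mu[0])

    @pytest.mark.parametrize("mode", ["literal", "offset", "joint"])
    def test_centering_identity_maintained_by_updates(self, mode):
        state, spec, rng = make_state(G=5, q=2, n=20)
        spec.mu_star_mode = mode
        b = rng.standard_normal((20, 2))
        for _ in range(10):
            cdpmm.update_pi(state, rng)
            cdpmm.update_mu_star(state, spec, b, rng)
            assert np.all(np.isfinite(state.mu_star))
            np.testing.assert_allclose(np.abs(state.pi @ state.mu), 0.0, atol=1e-10)
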