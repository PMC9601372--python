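"""Truncated (centered) Dirichlet process mixture prior for random effects.

The random effects are modelled as

    b_i ~ sum_g pi_g N_q(mu_g, Omega_g),   mu_g = mu*_g - sum_h pi_h mu*_h,

with stick-breaking weights pi built from Beta(1, tau) sticks, normal base
measure mu*_g ~ N_q(xi, Psi), and diagonal component covariances Omega_g
whose precisions carry Gamma priors.  The centering of the component
locations makes the mixture mean exactly zero, so the fixed-effect intercept
stays identifiable while the mixture remains absolutely continuous.

This module holds the mixture state and the conjugate Gibbs updates for all
of its blocks; cluster membership is tracked through latent labels L_i.
All Gamma draws are shape--rate.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular

# numerical floor for component variances and rate parameters: when the
# hyperparameters put the precision/rate feedback loop in its mean-unstable
# regime (G * omega_a >= varpi_a), cluster variances can collapse toward
# zero; the floor keeps the arithmetic finite without affecting stable runs
_VAR_FLOOR = 1e-12

__all__ = [
    "CDPMMState",
    "stick_break",
    "center_locations",
    "init_state",
    "update_xi",
    "update_psi",
    "update_varpi",
    "update_tau",
    "update_pi",
    "update_mu_star",
    "update_omega",
    "update_labels",
    "random_effect_prior_params",
]


@dataclass
class CDPMMState:
    """Mutable mixture state.

    ``omega`` and ``psi`` store variances (the Gamma priors act on their
    reciprocals).  ``mu`` caches the centered locations; for the uncentered
    ``discrete_dp`` prior it simply equals ``mu_star``.
    """

    vartheta: np.ndarray   # (G,) stick proportions, last entry 1
    pi: np.ndarray         # (G,) mixture weights
    tau: float             # DP concentration
    mu_star: np.ndarray    # (G, q) raw component locations
    mu: np.ndarray         # (G, q) centered locations
    omega: np.ndarray      # (G, q) component variances (diagonal Omega_g)
    xi: np.ndarray         # (q,) base-measure mean
    psi: np.ndarray        # (q,) base-measure variances (diagonal Psi)
    varpi: np.ndarray      # (q,) rate parameters for the omega precisions
    labels: np.ndarray     # (n,) cluster labels in 0..G-1
    nu_star: np.ndarray = None  # (G-1,) Beta draws from the latest pi update

    @property
    def G(self) -> int:
        return self.pi.shape[0]

    @property
    def q(self) -> int:
        return self.mu_star.shape[1]

    def counts(self) -> np.ndarray:
        """Cluster occupancy d_g, recounted fresh from the labels."""
        return np.bincount(self.labels, minlength=self.G)

    def copy(self) -> "CDPMMState":
        return replace(
            self,
            vartheta=self.vartheta.copy(), pi=self.pi.copy(),
            mu_star=self.mu_star.copy(), mu=self.mu.copy(),
            omega=self.omega.copy(), xi=self.xi.copy(), psi=self.psi.copy(),
            varpi=self.varpi.copy(), labels=self.labels.copy(),
            nu_star=None if self.nu_star is None else self.nu_star.copy(),
        )


def stick_break(vartheta) -> np.ndarray:
    """Weights pi_1 = v_1, pi_g = v_g prod_{i<g}(1 - v_i); sums to 1 exactly.

    Requires each stick in [0, 1] and the last stick equal to 1; the last
    weight is assigned the remainder so the simplex constraint is exact in
    floating point.
    """
    v = np.asarray(vartheta, dtype=float)
    if np.any((v < 0.0) | (v > 1.0)):
        raise ValueError("stick proportions must lie in [0, 1]")
    if v[-1] != 1.0:
        raise ValueError("the final stick proportion must equal 1")
    pi = np.empty_like(v)
    rem = np.cumprod(1.0 - v[:-1])
    pi[0] = v[0]
    pi[1:] = v[1:] * rem
    pi[-1] = max(1.0 - pi[:-1].sum(), 0.0)
    return pi


def center_locations(mu_star, pi) -> np.ndarray:
    """mu_g = mu*_g - sum_h pi_h mu*_h; weighted mean of the result is 0."""
    mu_star = np.asarray(mu_star, dtype=float)
    pi = np.asarray(pi, dtype=float)
    return mu_star - pi @ mu_star


def init_state(spec, n: int, q: int, rng) -> CDPMMState:
    """Draw an initial mixture state from the hierarchical prior."""
    G = spec.G
    varpi_a = spec.resolve_varpi_a(n)
    if spec.prior_kind == "gaussian":
        varpi = rng.gamma(varpi_a, 1.0 / spec.varpi_b, size=q)
        omega = 1.0 / rng.gamma(spec.omega_a, 1.0 / varpi, size=(1, q))
        zeros = np.zeros((1, q))
        return CDPMMState(
            vartheta=np.ones(1), pi=np.ones(1), tau=spec.a1 / spec.a2,
            mu_star=zeros.copy(), mu=zeros.copy(), omega=omega,
            xi=np.zeros(q), psi=np.ones(q), varpi=varpi,
            labels=np.zeros(n, dtype=np.intp),
        )
    tau = rng.gamma(spec.a1, 1.0 / spec.a2)
    vartheta = np.append(rng.beta(1.0, tau, size=G - 1), 1.0)
    pi = stick_break(vartheta)
    psi = 1.0 / rng.gamma(spec.c1, 1.0 / spec.c2, size=q)
    xi = rng.normal(size=q)  # xi0 = 0, Psi0 = I
    mu_star = xi + np.sqrt(psi) * rng.standard_normal((G, q))
    varpi = rng.gamma(varpi_a, 1.0 / spec.varpi_b, size=q)
    omega = 1.0 / rng.gamma(spec.omega_a, 1.0 / varpi, size=(G, q))
    labels = np.searchsorted(np.cumsum(pi), rng.uniform(size=n)).astype(np.intp)
    labels = np.clip(labels, 0, G - 1)
    mu = center_locations(mu_star, pi) if spec.prior_kind == "cdpmm" else mu_star.copy()
    return CDPMMState(
        vartheta=vartheta, pi=pi, tau=float(tau), mu_star=mu_star, mu=mu,
        omega=omega, xi=xi, psi=psi, varpi=varpi, labels=labels,
    )


# ---------------------------------------------------------------------------
# Gibbs steps.  Each mutates the state in place and returns it.
# ---------------------------------------------------------------------------


def update_xi(state: CDPMMState, spec, rng) -> CDPMMState:
    """Step (a): xi | mu*, Psi ~ N_q(A, B), conjugate under xi0=0, Psi0=I."""
    G, q = state.G, state.q
    psi_inv = 1.0 / state.psi
    # Psi0 = I, xi0 = 0: B = (G Psi^-1 + I)^-1 diagonal
    B = 1.0 / (G * psi_inv + 1.0)
    A = B * (psi_inv * state.mu_star.sum(axis=0))
    state.xi = A + np.sqrt(B) * rng.standard_normal(q)
    return state


def update_psi(state: CDPMMState, spec, rng) -> CDPMMState:
    """Step (b): psi_j^-1 ~ Gamma(c1 + G/2, c2 + 0.5 sum_g (mu*_gj - xi_j)^2)."""
    shape = spec.c1 + 0.5 * state.G
    rate = spec.c2 + 0.5 * ((state.mu_star - state.xi) ** 2).sum(axis=0)
    state.psi = 1.0 / rng.gamma(shape, 1.0 / rate)
    return state


def update_varpi(state: CDPMMState, spec, varpi_a: float, rng) -> CDPMMState:
    """Step (c): varpi_j ~ Gamma(varpi_a + G omega_a,
    varpi_b + sum_g omega_gj^-1).

    The shape term G*omega_a is the likelihood contribution of the G
    conditionally-Gamma precisions omega_gj^-1 ~ Gamma(omega_a, varpi_j);
    with it the varpi/omega feedback loop is unconditionally mean-stable.
    """
    shape = varpi_a + state.G * spec.omega_a
    rate = spec.varpi_b + (1.0 / state.omega).sum(axis=0)
    state.varpi = np.maximum(rng.gamma(shape, 1.0 / rate), _VAR_FLOOR)
    return state


def update_pi(state: CDPMMState, rng) -> CDPMMState:
    """Step (e): pi | L, tau via independent Beta sticks of a generalized
    Dirichlet; nu*_g ~ Beta(1 + d_g, tau + sum_{l>g} d_l)."""
    d = state.counts()
    tail = d[::-1].cumsum()[::-1]  # tail[g] = sum_{l>=g} d_l
    a = 1.0 + d[:-1]
    b = state.tau + tail[1:]
    nu = rng.beta(a, b)
    state.nu_star = nu
    state.vartheta = np.append(nu, 1.0)
    state.pi = stick_break(state.vartheta)
    return state


def update_tau(state: CDPMMState, spec, rng) -> CDPMMState:
    """Step (d): tau ~ Gamma(a1 + G - 1, a2 - sum_g log(1 - nu*_g)),
    using the Beta sticks nu* drawn in step (e) of the same sweep."""
    if state.nu_star is None:
        raise RuntimeError("update_tau requires the nu* draws from update_pi")
    nu = np.clip(state.nu_star, 0.0, 1.0 - 1e-15)
    rate = spec.a2 - np.log1p(-nu).sum()
    state.tau = float(rng.gamma(spec.a1 + state.G - 1, 1.0 / rate))
    return state


def _recentre(state: CDPMMState, spec) -> None:
    if spec.prior_kind == "cdpmm":
        state.mu = center_locations(state.mu_star, state.pi)
    else:
        state.mu = state.mu_star.copy()


def update_mu_star(state: CDPMMState, spec, b, rng) -> CDPMMState:
    """Step (f): component locations mu*_g | xi, Psi, Omega, L, b.

    Three variants (``spec.mu_star_mode``):

    ``literal``
        occupied clusters get the printed conjugate normal with the raw b_i
        as targets; unoccupied clusters are redrawn from the base measure;
    ``offset``
        same, but each target is b_i plus the current mixture mean
        sum_h pi_h mu*_h, so that the conjugate update acts on the centered
        residual b_i - mu_{L_i};
    ``joint``
        all G locations drawn jointly from their exact multivariate-normal
        full conditional under the centered parameterization (every
        component enters every likelihood term through the centering sum).

    For the uncentered ``discrete_dp`` prior all three coincide with the
    literal conjugate update.  The centered locations are recomputed at the
    end either way.
    """
    b = np.asarray(b, dtype=float)
    G, q = state.G, state.q
    d = state.counts()
    mode = spec.mu_star_mode if spec.prior_kind == "cdpmm" else "literal"

    if mode == "joint":
        _update_mu_star_joint(state, b, rng)
        _recentre(state, spec)
        return state

    if mode == "offset":
        target = b + state.pi @ state.mu_star
    else:
        target = b
    psi_inv = 1.0 / state.psi
    # per-cluster sums of Omega_g^-1-weighted targets
    om_inv = 1.0 / state.omega[state.labels]          # (n, q)
    wsum = np.zeros((G, q))
    np.add.at(wsum, state.labels, om_inv * target)
    prec_sum = np.zeros((G, q))
    np.add.at(prec_sum, state.labels, om_inv)
    F = 1.0 / (psi_inv + prec_sum)                    # (G, q) diagonal covs
    E = F * (psi_inv * state.xi + wsum)
    draw = E + np.sqrt(F) * rng.standard_normal((G, q))
    empty = d == 0
    if np.any(empty):
        base = state.xi + np.sqrt(state.psi) * rng.standard_normal((int(empty.sum()), q))
        draw[empty] = base
    state.mu_star = draw
    _recentre(state, spec)
    return state


def _update_mu_star_joint(state: CDPMMState, b, rng) -> None:
    # Exact full conditional of all locations under centering: for each
    # random-effect component j independently (Psi, Omega diagonal),
    #   b_ij ~ N( (e_{L_i} - pi)' v_j, omega_{L_i j} ),  v_j ~ N(xi_j 1, psi_j I)
    # so v_j is multivariate normal with a G x G precision.
    G, q = state.G, state.q
    n = b.shape[0]
    A = -np.tile(state.pi, (n, 1))
    A[np.arange(n), state.labels] += 1.0            # (n, G) rows e_{L_i} - pi
    for j in range(q):
        w = 1.0 / state.omega[state.labels, j]      # (n,)
        P = (A * w[:, None]).T @ A
        P[np.diag_indices(G)] += 1.0 / state.psi[j]
        rhs = state.xi[j] / state.psi[j] + A.T @ (w * b[:, j])
        try:
            c, low = cho_factor(P, lower=True)
        except np.linalg.LinAlgError:
            # near-singular precision (extreme cluster precisions); a tiny
            # relative jitter restores a usable factorization
            P[np.diag_indices(G)] += 1e-10 * np.abs(P).max()
            c, low = cho_factor(P, lower=True)
        mean = cho_solve((c, low), rhs)
        # sample: v = mean + L^-T z with P = L L'
        z = rng.standard_normal(G)
        state.mu_star[:, j] = mean + solve_triangular(c, z, lower=True, trans="T")


def update_omega(state: CDPMMState, spec, b, rng) -> CDPMMState:
    """Step (g): component precisions omega_gj^-1.

    Occupied clusters: Gamma(d_g/2 + omega_a,
    varpi_j + 0.5 sum_{i: L_i=g} (b_ij - mu_gj)^2) with the centered mu;
    unoccupied clusters are redrawn from the Gamma(omega_a, varpi_j) prior.
    The conditional is placed on the precision (the conjugate reading of the
    hierarchy, which puts the Gamma on omega^-1).
    """
    b = np.asarray(b, dtype=float)
    G, q = state.G, state.q
    d = state.counts()
    resid2 = (b - state.mu[state.labels]) ** 2
    ssq = np.zeros((G, q))
    np.add.at(ssq, state.labels, resid2)
    shape = 0.5 * d[:, None] + spec.omega_a
    rate = state.varpi + 0.5 * ssq
    state.omega = np.maximum(1.0 / rng.gamma(shape, 1.0 / rate), _VAR_FLOOR)
    return state


def update_labels(state: CDPMMState, b, rng) -> CDPMMState:
    """Step (h): L_i ~ multinomial with P(L_i = g) ∝ pi_g N_q(b_i; mu_g, Omega_g),
    evaluated in the log domain with the centered component means."""
    b = np.asarray(b, dtype=float)
    logw = label_log_weights(state, b)
    logw -= logw.max(axis=1, keepdims=True)
    w = np.exp(logw)
    w /= w.sum(axis=1, keepdims=True)
    u = rng.uniform(size=b.shape[0])
    cum = np.cumsum(w, axis=1)
    state.labels = (u[:, None] > cum).sum(axis=1).astype(np.intp)
    np.clip(state.labels, 0, state.G - 1, out=state.labels)
    return state


def label_log_weights(state: CDPMMState, b) -> np.ndarray:
    """Unnormalized log membership weights, shape (n, G)."""
    b = np.asarray(b, dtype=float)
    diff = b[:, None, :] - state.mu[None, :, :]            # (n, G, q)
    log_norm = -0.5 * (
        (diff**2 / state.omega[None]).sum(axis=2)
        + np.log(state.omega).sum(axis=1)[None, :]
    )
    with np.errstate(divide="ignore"):
        return np.log(np.maximum(state.pi, 1e-300))[None, :] + log_norm


def random_effect_prior_params(state: CDPMMState, i: int):
    """Prior mean and diagonal covariance of b_i: (mu_{L_i}, Omega_{L_i})."""
    g = int(state.labels[i])
    return state.mu[g], state.omega[g]
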