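"""Hybrid block-Gibbs / Metropolis--Hastings sampler.

One sweep updates, in a fixed scan order:

* Block A — the fixed effects beta, as a single Metropolis block with a
  normal proposal whose covariance is the inverse of the expected-information
  matrix of the simplex likelihood plus the shrinkage precision;
* the Bayesian-Lasso scales h^2 and global penalty nu^2 (conjugate);
* Block B — the dispersion sigma^-2 (conjugate Gamma);
* Block C — the Dirichlet-process mixture blocks (base mean, base scales,
  precision rates, weights, concentration, component locations, component
  scales, cluster labels), then each subject's random effect b_i by a
  Metropolis step with an information-based normal proposal.

Step scales for the Metropolis blocks are adapted by Robbins--Monro during
burn-in only (target acceptance 0.25); adaptation is frozen afterwards so
the kept draws leave the posterior invariant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from . import cdpmm
from .blasso import BLassoState, update_h2, update_nu2, update_sigma2
from .cdpmm import CDPMMState
from .data import LongitudinalData
from .priors import PriorSpec
from .simplex import (
    default_expected_d2_table,
    unit_deviance,
    unit_deviance_dmu,
    unit_deviance_d2mu,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ChainConfig",
    "ChainResult",
    "MCMCState",
    "proposal_cov_beta",
    "mh_update_beta",
    "mh_update_b",
    "sweep",
    "run_chain",
    "run",
]


@dataclass
class ChainConfig:
    """Run-length and tuning configuration for the MCMC."""

    n_burnin: int = 7000
    n_keep: int = 5000
    n_chains: int = 3
    target_accept: float = 0.25
    adapt_window: int = 100
    seed: int | None = None
    store_b: bool = True
    # b_i proposal curvature: expected information (guaranteed PD) or the
    # observed Hessian of the log-likelihood with PD fallback
    bi_proposal: str = "expected"
    progress_every: int = 0  # log acceptance summaries every k iterations

    def __post_init__(self):
        if self.n_burnin < 1 or self.n_keep < 1 or self.n_chains < 1:
            raise ValueError("n_burnin, n_keep and n_chains must be >= 1")
        if not 0.0 < self.target_accept < 1.0:
            raise ValueError("target_accept must lie in (0, 1)")
        if self.bi_proposal not in ("expected", "observed"):
            raise ValueError("bi_proposal must be 'expected' or 'observed'")


@dataclass
class MCMCState:
    """Complete sampler state: shrinkage block, dispersion, random effects
    and the mixture state."""

    blasso: BLassoState
    sigma2: float
    b: np.ndarray            # (n, q)
    mix: CDPMMState

    def copy(self) -> "MCMCState":
        return MCMCState(
            blasso=self.blasso.copy(), sigma2=self.sigma2,
            b=self.b.copy(), mix=self.mix.copy(),
        )


@dataclass
class ChainResult:
    """Kept draws and acceptance bookkeeping for one chain."""

    draws: dict
    accept_beta: float
    accept_b: np.ndarray
    final_scales: dict
    config: ChainConfig
    seed_sequence: object = None

    @property
    def n_keep(self) -> int:
        return self.draws["beta"].shape[0]


# ---------------------------------------------------------------------------
# proposal covariances
# ---------------------------------------------------------------------------


def _info_weights(mu, sigma2, d2tab):
    # expected information per record w.r.t. the linear predictor:
    # E[d''(y; mu)] / (2 sigma2) * (d mu / d eta)^2, logit link
    return d2tab(mu, sigma2) * (mu * (1.0 - mu)) ** 2 / (2.0 * sigma2)


def proposal_cov_beta(data: LongitudinalData, mu_fit, sigma2, h2, d2tab=None):
    """Sigma_beta = [sum_ij w_ij x_ij x_ij' + H_beta^-1]^-1 (symmetric PD)."""
    if d2tab is None:
        d2tab = default_expected_d2_table()
    w = _info_weights(np.asarray(mu_fit, dtype=float), sigma2, d2tab)
    info = (data.X * w[:, None]).T @ data.X + np.diag(1.0 / np.asarray(h2))
    info = 0.5 * (info + info.T)
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise RuntimeError(f"singular beta information matrix: {exc}")
    eig = np.linalg.eigvalsh(cov)
    if eig.min() <= 0.0:
        raise RuntimeError(
            f"beta proposal covariance is not positive definite "
            f"(smallest eigenvalue {eig.min():.3e})"
        )
    return 0.5 * (cov + cov.T)


# guard for saturated inverse-link values: a candidate far in the tail gets
# an astronomically large deviance (and is rejected) instead of an error
_MU_EPS = 1e-12


def _log_target_beta(data, beta, b, sigma2, h2):
    mu = np.clip(data.mu(beta, b), _MU_EPS, 1.0 - _MU_EPS)
    dev = unit_deviance(data.y, mu).sum()
    return -0.5 * (dev / sigma2 + (beta**2 / h2).sum())


def _log_mvn_prec(x, mean, prec_chol, scale):
    # log N(x; mean, scale^2 * prec^-1) given cholesky(prec) (lower)
    d = x - mean
    u = prec_chol.T @ d / scale
    logdet = np.log(np.diag(prec_chol)).sum()
    k = x.shape[0]
    return -0.5 * (k * np.log(2.0 * np.pi * scale**2) + u @ u) + logdet


def mh_update_beta(data, state: MCMCState, scale, d2tab, rng):
    """One Metropolis--Hastings update of the beta block.

    The proposal N(beta, scale^2 Sigma_beta) has a covariance that depends
    on the current beta (through the fitted means entering the expected
    information), so it is not symmetric; the acceptance ratio therefore
    includes the forward/reverse proposal densities.  Returns the accepted
    flag.
    """
    beta = state.blasso.beta
    mu_cur = data.mu(beta, state.b)
    cov = proposal_cov_beta(data, mu_cur, state.sigma2, state.blasso.h2, d2tab)
    L = np.linalg.cholesky(cov)
    cand = beta + scale * (L @ rng.standard_normal(beta.shape[0]))
    lt_cur = _log_target_beta(data, beta, state.b, state.sigma2, state.blasso.h2)
    lt_new = _log_target_beta(data, cand, state.b, state.sigma2, state.blasso.h2)
    if not np.isfinite(lt_cur):
        raise RuntimeError("non-finite log target for beta at current state")
    mu_cand = np.clip(data.mu(cand, state.b), _MU_EPS, 1.0 - _MU_EPS)
    cov_cand = proposal_cov_beta(data, mu_cand, state.sigma2, state.blasso.h2, d2tab)
    prec_chol_fwd = np.linalg.cholesky(np.linalg.inv(cov))
    prec_chol_rev = np.linalg.cholesky(np.linalg.inv(cov_cand))
    log_q_fwd = _log_mvn_prec(cand, beta, prec_chol_fwd, scale)
    log_q_rev = _log_mvn_prec(beta, cand, prec_chol_rev, scale)
    accept = np.log(rng.uniform()) < lt_new - lt_cur + log_q_rev - log_q_fwd
    if accept:
        state.blasso.beta = cand
    return bool(accept)


def _bi_curvature(data, mu, sigma2, d2tab, kind):
    """Per-subject curvature matrices Xi_i of -log p(Y_i | b_i), (n, q, q)."""
    n, q = data.n_subjects, data.n_random
    if kind == "observed":
        dmu_deta = mu * (1.0 - mu)
        w = (
            unit_deviance_d2mu(data.y, mu) * dmu_deta**2
            + unit_deviance_dmu(data.y, mu) * dmu_deta * (1.0 - 2.0 * mu)
        ) / (2.0 * sigma2)
    else:
        w = _info_weights(mu, sigma2, d2tab)
    zz = data.Z[:, :, None] * data.Z[:, None, :]
    xi = np.zeros((n, q, q))
    np.add.at(xi, data.subject, w[:, None, None] * zz)
    return xi


def mh_update_b(data, state: MCMCState, scales, d2tab, rng,
                use_likelihood=True, curvature=None):
    """Metropolis update of every subject's random effect, vectorized.

    Each b_i gets an independent normal proposal N(b_i, s_i^2 Sigma_bi) with
    Sigma_bi = (Omega_{L_i}^-1 + Xi_i)^-1; acceptances are decided per
    subject.  With ``use_likelihood=False`` the target reduces to the
    mixture prior (used by prior-reproduction checks).  Returns the boolean
    acceptance vector.
    """
    n, q = data.n_subjects, data.n_random
    mix = state.mix
    eta = data.eta(state.blasso.beta, state.b)
    mu = np.clip(expit(eta), _MU_EPS, 1.0 - _MU_EPS)
    kind = curvature or "expected"
    om_inv = _omega_inv_diag(mix)
    prec = _bi_proposal_precision(data, state, mu, om_inv, d2tab, kind,
                                  use_likelihood)
    cov = np.linalg.inv(prec)
    cov = 0.5 * (cov + np.swapaxes(cov, 1, 2))
    L = np.linalg.cholesky(cov)
    step = np.einsum("nij,nj->ni", L, rng.standard_normal((n, q)))
    scales = np.asarray(scales)
    cand = state.b + scales[:, None] * step

    mu_prior = mix.mu[mix.labels]
    om = mix.omega[mix.labels]
    d_prior = -0.5 * (((cand - mu_prior) ** 2 - (state.b - mu_prior) ** 2) / om).sum(axis=1)
    if use_likelihood:
        eta_new = eta + np.einsum("nq,nq->n", data.Z, (cand - state.b)[data.subject])
        mu_new = np.clip(expit(eta_new), _MU_EPS, 1.0 - _MU_EPS)
        ddev = unit_deviance(data.y, mu_new) - unit_deviance(data.y, mu)
        d_lik = -np.bincount(data.subject, weights=ddev, minlength=n) / (2.0 * state.sigma2)
        # the proposal covariance depends on the current b_i through the
        # curvature, so the kernel needs the full Hastings correction
        prec_cand = _bi_proposal_precision(
            data, state, mu_new, om_inv, d2tab, kind, True, eta=eta_new
        )
        diff = cand - state.b
        log_q = _batch_mvn_logq(diff, prec, scales)
        log_q_rev = _batch_mvn_logq(-diff, prec_cand, scales)
        d_hastings = log_q_rev - log_q
    else:
        d_lik = 0.0
        d_hastings = 0.0  # precision is b-independent without the likelihood
    log_ratio = d_prior + d_lik + d_hastings
    if not np.all(np.isfinite(log_ratio)):
        raise RuntimeError("non-finite log acceptance ratio in b update")
    accept = np.log(rng.uniform(size=n)) < log_ratio
    state.b[accept] = cand[accept]
    return accept


def _bi_proposal_precision(data, state, mu, om_inv, d2tab, kind,
                           use_likelihood, eta=None):
    n, q = data.n_subjects, data.n_random
    if not use_likelihood:
        return om_inv.copy()
    xi = _bi_curvature(data, mu, state.sigma2, d2tab, kind)
    if kind == "observed":
        bad = ~_is_pd_batch(xi + om_inv)
        if np.any(bad):
            logger.debug("observed curvature indefinite for %d subjects; "
                         "using expected information there", int(bad.sum()))
            xi_exp = _bi_curvature(data, mu, state.sigma2, d2tab, "expected")
            xi[bad] = xi_exp[bad]
    return xi + om_inv


def _batch_mvn_logq(diff, prec, scales):
    # log N(diff; 0, scale^2 prec^-1) per subject, up to the shared 2*pi term
    pc = np.linalg.cholesky(prec)
    u = np.einsum("nji,nj->ni", pc, diff) / scales[:, None]
    logdet_half = np.log(np.diagonal(pc, axis1=1, axis2=2)).sum(axis=1)
    q = diff.shape[1]
    return logdet_half - q * np.log(scales) - 0.5 * (u**2).sum(axis=1)


def translation_pairs(data: LongitudinalData):
    """Indices (k, m) where fixed-effect column k equals random-effect
    column m for every record (e.g. both contain the intercept, or both the
    observation time).  Along such pairs the likelihood is invariant under
    beta_k -> beta_k + delta, b_im -> b_im - delta for all i."""
    pairs = []
    for m in range(data.n_random):
        for k in range(data.n_fixed):
            if np.array_equal(data.Z[:, m], data.X[:, k]):
                pairs.append((k, m))
                break
    return pairs


def mh_translate(data, state: MCMCState, pairs, scales, rng):
    """Joint translation move along each likelihood-invariant direction.

    The linear predictor is unchanged, so the acceptance ratio involves
    only the beta shrinkage prior and the mixture prior of b.  This move
    decorrelates the intercept-type coefficients from the sample mean of
    the corresponding random-effect column, which is the slowest direction
    of the plain one-at-a-time scan.
    """
    mix = state.mix
    beta = state.blasso.beta
    h2 = state.blasso.h2
    accepted = np.zeros(len(pairs), dtype=bool)
    for idx, (k, m) in enumerate(pairs):
        delta = scales[idx] * rng.standard_normal()
        bk_new = beta[k] + delta
        col_new = state.b[:, m] - delta
        mu_p = mix.mu[mix.labels, m]
        om = mix.omega[mix.labels, m]
        dlog = -0.5 * (bk_new**2 - beta[k] ** 2) / h2[k]
        dlog -= 0.5 * (
            ((col_new - mu_p) ** 2 - (state.b[:, m] - mu_p) ** 2) / om
        ).sum()
        if np.log(rng.uniform()) < dlog:
            beta[k] = bk_new
            state.b[:, m] = col_new
            accepted[idx] = True
    return accepted


def _omega_inv_diag(mix: CDPMMState):
    n = mix.labels.shape[0]
    q = mix.q
    out = np.zeros((n, q, q))
    idx = np.arange(q)
    out[:, idx, idx] = 1.0 / mix.omega[mix.labels]
    return out


def _is_pd_batch(mats):
    # small q: positive definiteness via eigenvalues
    eig = np.linalg.eigvalsh(mats)
    return eig[..., 0] > 0.0


# ---------------------------------------------------------------------------
# sweep and chain driver
# ---------------------------------------------------------------------------


def sweep(data, state: MCMCState, spec: PriorSpec, rng, scales, d2tab=None,
          varpi_a=None, pairs=None):
    """One full scan; mutates ``state`` and returns per-block acceptances."""
    if d2tab is None:
        d2tab = default_expected_d2_table()
    if varpi_a is None:
        varpi_a = spec.resolve_varpi_a(data.n_subjects)
    if pairs is None:
        pairs = translation_pairs(data)
    acc_beta = mh_update_beta(data, state, scales["beta"], d2tab, rng)
    state.blasso.h2 = update_h2(state.blasso.beta, state.blasso.nu2, rng)
    state.blasso.nu2 = update_nu2(state.blasso.h2, spec, rng)
    state.sigma2 = update_sigma2(
        data.y,
        np.clip(data.mu(state.blasso.beta, state.b), _MU_EPS, 1.0 - _MU_EPS),
        spec, rng,
    )
    mix = state.mix
    if spec.prior_kind == "gaussian":
        cdpmm.update_varpi(mix, spec, varpi_a, rng)           # step (c)
        cdpmm.update_omega(mix, spec, state.b, rng)           # step (g)
    else:
        cdpmm.update_xi(mix, spec, rng)                       # step (a)
        cdpmm.update_psi(mix, spec, rng)                      # step (b)
        cdpmm.update_varpi(mix, spec, varpi_a, rng)           # step (c)
        cdpmm.update_pi(mix, rng)                             # step (e)
        cdpmm.update_tau(mix, spec, rng)                      # step (d)
        cdpmm.update_mu_star(mix, spec, state.b, rng)         # step (f)
        cdpmm.update_omega(mix, spec, state.b, rng)           # step (g)
        cdpmm.update_labels(mix, state.b, rng)                # step (h)
    acc_b = mh_update_b(data, state, scales["b"], d2tab, rng)  # step (i)
    acc_t = mh_translate(
        data, state, pairs, scales.get("translate", np.ones(len(pairs))), rng
    )
    return acc_beta, acc_b, acc_t


def initial_state(data, spec, rng, overdispersed=0) -> MCMCState:
    """Prior-based starting state; ``overdispersed`` indexes the chain for
    spread starting points (EPSR requires distinct initializations)."""
    p1, q, n = data.n_fixed, data.n_random, data.n_subjects
    beta = rng.normal(0.0, 2.0, size=p1)
    sigma2 = (0.5, 1.0, 2.0)[overdispersed % 3]
    b = rng.standard_normal((n, q))
    mix = cdpmm.init_state(spec, n, q, rng)
    bl = BLassoState(beta=beta, h2=np.ones(p1), nu2=spec.nu2_a / spec.nu2_b)
    return MCMCState(blasso=bl, sigma2=sigma2, b=b, mix=mix)


def run_chain(data, spec, config, rng, chain_index=0, d2tab=None,
              start=None) -> ChainResult:
    """Run one adaptive-burn-in chain and collect kept draws."""
    if d2tab is None:
        d2tab = default_expected_d2_table()
    n, q, p1 = data.n_subjects, data.n_random, data.n_fixed
    varpi_a = spec.resolve_varpi_a(n)
    state = start.copy() if start is not None else initial_state(
        data, spec, rng, overdispersed=chain_index
    )
    pairs = translation_pairs(data)
    scales = {"beta": 1.0, "b": np.ones(n), "translate": np.ones(len(pairs))}
    log_sb = np.zeros(n)
    log_sbeta = 0.0
    log_st = np.zeros(len(pairs))
    acc_beta_win = 0
    acc_b_win = np.zeros(n)
    acc_t_win = np.zeros(len(pairs))
    total = config.n_burnin + config.n_keep

    L = config.n_keep
    draws = {
        "beta": np.empty((L, p1)),
        "sigma2": np.empty(L),
        "nu2": np.empty(L),
        "tau": np.empty(L),
    }
    if config.store_b:
        draws["b"] = np.empty((L, n, q))
    acc_beta_keep = 0
    acc_b_keep = np.zeros(n)

    for it in range(total):
        ab, avec, at = sweep(data, state, spec, rng, scales, d2tab, varpi_a,
                             pairs)
        in_burnin = it < config.n_burnin
        if in_burnin:
            acc_beta_win += ab
            acc_b_win += avec
            acc_t_win += at
            if (it + 1) % config.adapt_window == 0:
                rate_beta = acc_beta_win / config.adapt_window
                rate_b = acc_b_win / config.adapt_window
                gain = 1.0
                log_sbeta += np.clip(gain * (rate_beta - config.target_accept), -0.5, 0.5)
                log_sb += np.clip(gain * (rate_b - config.target_accept), -0.5, 0.5)
                # 1-D translation move: tune toward the scalar-optimal 0.44
                log_st += np.clip(
                    gain * (acc_t_win / config.adapt_window - 0.44), -0.5, 0.5
                )
                scales["beta"] = float(np.exp(log_sbeta))
                scales["b"] = np.exp(log_sb)
                scales["translate"] = np.exp(log_st)
                acc_beta_win = 0
                acc_b_win[:] = 0.0
                acc_t_win[:] = 0.0
        else:
            k = it - config.n_burnin
            draws["beta"][k] = state.blasso.beta
            draws["sigma2"][k] = state.sigma2
            draws["nu2"][k] = state.blasso.nu2
            draws["tau"][k] = state.mix.tau
            if config.store_b:
                draws["b"][k] = state.b
            acc_beta_keep += ab
            acc_b_keep += avec
        if config.progress_every and (it + 1) % config.progress_every == 0:
            logger.info(
                "chain %d iter %d/%d: beta scale %.3f, mean b accept %.3f",
                chain_index, it + 1, total, scales["beta"],
                float(avec.mean()),
            )

    return ChainResult(
        draws=draws,
        accept_beta=acc_beta_keep / L,
        accept_b=acc_b_keep / L,
        final_scales={"beta": scales["beta"], "b": scales["b"].copy(),
                      "translate": scales["translate"].copy()},
        config=config,
    )


def run(data, spec, config: ChainConfig, d2tab=None) -> list[ChainResult]:
    """Run ``config.n_chains`` chains from overdispersed starts."""
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_chains)
    results = []
    for c, child in enumerate(children):
        rng = np.random.default_rng(child)
        results.append(
            run_chain(data, spec, config, rng, chain_index=c, d2tab=d2tab)
        )
    return results
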