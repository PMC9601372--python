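"""Synthetic longitudinal proportional data and the replication driver.

The generators reproduce a standard benchmark layout for simplex
mixed-effects models: n subjects observed at n_i equally spaced times
t_j = 0.2 j (j = 0..n_i-1), fixed-effect design
x_ij = (1, x1, x2, x3, t_ij) with x1 a symmetric +-1 factor and x2, x3
standard normal, random-effect design z_ij = (1, t_ij), responses

    y_ij | b_i ~ S^-(mu_ij, sigma2),   logit(mu_ij) = x_ij' beta + z_ij' b_i,

true coefficients beta = (-0.45, 0, 0.45, 0, 0.45) and sigma2 = 1.  Two
random-effects laws are used, both with mean zero:

* ``normal_gamma`` — b_i1 ~ N(0, variance 0.8) and b_i2 = g - 2 with
  g ~ Gamma(shape 4, rate 2): one symmetric and one right-skewed component
  (population SDs 0.894 and 1.000);
* ``normal_mixture`` — b_i1 ~ 0.6 N(-0.8, sd 0.5) + 0.4 N(1.2, sd 0.5) and
  b_i2 ~ 0.6 N(0.8, sd 0.5) + 0.4 N(-1.2, sd 0.5): bimodal components
  (population SD 1.100 each).

Note the deliberate asymmetry in the second-argument conventions: the
normal law of the first design is parameterized by its variance (0.8 gives
SD sqrt(0.8) = 0.894) while the mixture components are parameterized by
their SD 0.5 (mixture SD sqrt(0.25 + 0.96) = 1.100); both are forced by the
population-moment targets above.

Four numbered designs pair a data law with a fitting prior: 1 = normal_gamma
data with the CDPMM prior, 2 = normal_mixture with CDPMM, 3 = normal_gamma
with the uncentered discrete DP, 4 = normal_mixture with a single Gaussian.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import LongitudinalData
from .diagnostics import rmse_random_effects, select_variables
from .priors import PriorSpec
from .sampler import ChainConfig, run_chain
from .simplex import rvs, default_expected_d2_table

__all__ = [
    "SimulationDesign",
    "design",
    "BETA_TRUE",
    "generate_covariates",
    "draw_random_effects",
    "true_density_fns",
    "population_moments",
    "generate_dataset",
    "run_replications",
    "ReplicationTable",
]

BETA_TRUE = np.array([-0.45, 0.0, 0.45, 0.0, 0.45])
SIGMA2_TRUE = 1.0

_LAWS = ("normal_gamma", "normal_mixture")
_DESIGN_MAP = {
    1: ("normal_gamma", "cdpmm"),
    2: ("normal_mixture", "cdpmm"),
    3: ("normal_gamma", "discrete_dp"),
    4: ("normal_mixture", "gaussian"),
}


@dataclass
class SimulationDesign:
    """One benchmark configuration (data-generating law + fitting prior)."""

    n: int = 100
    n_i: int = 6
    beta_true: np.ndarray = field(default_factory=lambda: BETA_TRUE.copy())
    sigma2_true: float = SIGMA2_TRUE
    random_effects_law: str = "normal_gamma"
    fit_prior: str = "cdpmm"

    def __post_init__(self):
        if self.random_effects_law not in _LAWS:
            raise ValueError(f"unknown random-effects law {self.random_effects_law!r}")
        self.beta_true = np.asarray(self.beta_true, dtype=float)


def design(index: int, **overrides) -> SimulationDesign:
    """Numbered benchmark design (1-4); keyword overrides are applied last."""
    if index not in _DESIGN_MAP:
        raise ValueError(f"design index must be one of {sorted(_DESIGN_MAP)}")
    law, prior = _DESIGN_MAP[index]
    return SimulationDesign(random_effects_law=law, fit_prior=prior, **overrides)


def generate_covariates(n, n_i, rng):
    """Stacked covariates: returns (X, Z, t, subject) for n x n_i records."""
    N = n * n_i
    t = np.tile(0.2 * np.arange(n_i), n)
    x1 = rng.choice([-1.0, 1.0], size=N)
    x2 = rng.standard_normal(N)
    x3 = rng.standard_normal(N)
    X = np.column_stack([np.ones(N), x1, x2, x3, t])
    Z = np.column_stack([np.ones(N), t])
    subject = np.repeat(np.arange(n), n_i)
    return X, Z, t, subject


def draw_random_effects(law, n, rng):
    """Draw the (n, 2) matrix of true random effects for one dataset."""
    if law == "normal_gamma":
        b1 = rng.normal(0.0, np.sqrt(0.8), size=n)
        b2 = rng.gamma(4.0, 1.0 / 2.0, size=n) - 2.0
    elif law == "normal_mixture":
        comp1 = rng.uniform(size=n) < 0.6
        b1 = np.where(comp1, rng.normal(-0.8, 0.5, n), rng.normal(1.2, 0.5, n))
        comp2 = rng.uniform(size=n) < 0.6
        b2 = np.where(comp2, rng.normal(0.8, 0.5, n), rng.normal(-1.2, 0.5, n))
    else:
        raise ValueError(f"unknown random-effects law {law!r}")
    return np.column_stack([b1, b2])


def true_density_fns(law):
    """True marginal densities of (b_1, b_2) under a generating law."""
    if law == "normal_gamma":
        return (
            lambda x: stats.norm.pdf(x, 0.0, np.sqrt(0.8)),
            lambda x: stats.gamma.pdf(np.asarray(x) + 2.0, a=4.0, scale=0.5),
        )
    if law == "normal_mixture":
        def mix(means):
            m1, m2 = means
            return lambda x: (
                0.6 * stats.norm.pdf(x, m1, 0.5) + 0.4 * stats.norm.pdf(x, m2, 0.5)
            )
        return (mix((-0.8, 1.2)), mix((0.8, -1.2)))
    raise ValueError(f"unknown random-effects law {law!r}")


def population_moments(law):
    """Analytic (mean, sd) per random-effect component."""
    if law == "normal_gamma":
        return np.array([[0.0, np.sqrt(0.8)], [0.0, np.sqrt(4.0 / 4.0)]])
    if law == "normal_mixture":
        var = 0.25 + 0.6 * 0.8**2 + 0.4 * 1.2**2
        return np.array([[0.0, np.sqrt(var)], [0.0, np.sqrt(var)]])
    raise ValueError(f"unknown random-effects law {law!r}")


def generate_dataset(design: SimulationDesign, seed=None, rng=None):
    """Simulate one dataset; returns (LongitudinalData, true b matrix)."""
    if rng is None:
        rng = np.random.default_rng(seed)
    X, Z, t, subject = generate_covariates(design.n, design.n_i, rng)
    b = draw_random_effects(design.random_effects_law, design.n, rng)
    eta = X @ design.beta_true + np.einsum("nq,nq->n", Z, b[subject])
    mu = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-12, 1.0 - 1e-12)
    y = rvs(mu, design.sigma2_true, rng=rng)
    data = LongitudinalData(y=y, X=X, Z=Z, subject=subject, time=t)
    return data, b


# ---------------------------------------------------------------------------
# replication driver
# ---------------------------------------------------------------------------


@dataclass
class ReplicationTable:
    """Aggregated Monte-Carlo replication results.

    ``params``: per-coefficient Bias, RMS and F0 (percentage of replications
    whose 95% credible interval contains zero) plus a sigma2 row;
    ``random_effects``: true and estimated mean/SD per component (``est_sd``
    is the cross-subject SD of the posterior-mean effects, averaged over
    replications; ``post_sd`` the average posterior SD);
    ``rmse_quantiles``: 5/25/50/75% quantiles of the density-recovery RMSE.
    """

    params: pd.DataFrame
    random_effects: pd.DataFrame
    rmse_quantiles: pd.Series
    n_replications: int
    n_failed: int

    def to_csv(self, prefix):
        self.params.to_csv(f"{prefix}_params.csv")
        self.random_effects.to_csv(f"{prefix}_random_effects.csv")
        self.rmse_quantiles.to_frame("rmse").to_csv(f"{prefix}_rmse.csv")


def _default_fitter(spec_kind):
    def fit(data, seed):
        spec = PriorSpec(prior_kind=spec_kind)
        config = ChainConfig(n_burnin=3000, n_keep=2000, n_chains=1, seed=seed)
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        res = run_chain(data, spec, config, rng)
        sel = select_variables(res.draws["beta"])
        return {
            "beta_mean": res.draws["beta"].mean(axis=0),
            "beta_ci": sel[["ci_low", "ci_high"]].to_numpy(),
            "sigma2_mean": float(res.draws["sigma2"].mean()),
            "bhat": res.draws["b"].mean(axis=0),
            "b_post_sd": res.draws["b"].std(axis=0, ddof=1),
        }
    return fit


def run_replications(design: SimulationDesign, n_replications=50, base_seed=0,
                     chain_config: ChainConfig | None = None, fitter=None,
                     progress=False) -> ReplicationTable:
    """Monte-Carlo study: simulate, fit and aggregate over replications.

    Bias = mean(estimate) - truth, RMS = sqrt(mean((estimate - truth)^2));
    F0 = 100 x fraction of replications whose 95% CI contains zero.  A
    replication whose fit raises is recorded, excluded and counted.

    ``fitter(data, seed)`` may be injected (it must return a dict with keys
    ``beta_mean``, ``beta_ci``, ``sigma2_mean``, ``bhat``); the default runs
    the package's own sampler with the design's fitting prior.
    """
    if fitter is None:
        if chain_config is None:
            fitter = _default_fitter(design.fit_prior)
        else:
            def fitter(data, seed, _cc=chain_config):
                spec = PriorSpec(prior_kind=design.fit_prior)
                rng = np.random.default_rng(np.random.SeedSequence(seed))
                res = run_chain(data, spec, _cc, rng)
                sel = select_variables(res.draws["beta"])
                return {
                    "beta_mean": res.draws["beta"].mean(axis=0),
                    "beta_ci": sel[["ci_low", "ci_high"]].to_numpy(),
                    "sigma2_mean": float(res.draws["sigma2"].mean()),
                    "bhat": res.draws["b"].mean(axis=0),
                    "b_post_sd": res.draws["b"].std(axis=0, ddof=1),
                }
    default_expected_d2_table()  # build the shared spline table up front
    dens = true_density_fns(design.random_effects_law)
    betas, sig2s, contains0, bhat_means, bhat_sds, post_sds, rmses = (
        [], [], [], [], [], [], []
    )
    n_failed = 0
    for r in range(n_replications):
        seed = base_seed + r
        data, b_true = generate_dataset(design, seed=seed)
        try:
            fit = fitter(data, seed)
        except Exception as exc:  # noqa: BLE001 - recorded, not fatal
            import warnings

            warnings.warn(f"replication {r} failed and was excluded: {exc}")
            n_failed += 1
            continue
        betas.append(np.asarray(fit["beta_mean"], dtype=float))
        sig2s.append(fit["sigma2_mean"])
        ci = np.asarray(fit["beta_ci"], dtype=float)
        contains0.append((ci[:, 0] <= 0.0) & (ci[:, 1] >= 0.0))
        bhat = np.asarray(fit["bhat"], dtype=float)
        bhat_means.append(bhat.mean(axis=0))
        bhat_sds.append(bhat.std(axis=0, ddof=1))
        if "b_post_sd" in fit:
            post_sds.append(np.asarray(fit["b_post_sd"]).mean(axis=0))
        rmses.append(rmse_random_effects(dens, bhat))
        if progress:
            print(f"replication {r + 1}/{n_replications} done", flush=True)

    if not betas:
        raise RuntimeError("all replications failed")
    betas = np.asarray(betas)
    sig2s = np.asarray(sig2s)
    contains0 = np.asarray(contains0)
    p1 = betas.shape[1]
    names = [f"beta{k}" for k in range(p1)] + ["sigma2"]
    truth = np.append(design.beta_true, design.sigma2_true)
    est = np.column_stack([betas, sig2s])
    bias = est.mean(axis=0) - truth
    rms = np.sqrt(((est - truth) ** 2).mean(axis=0))
    f0 = np.append(100.0 * contains0.mean(axis=0), np.nan)
    params = pd.DataFrame(
        {"true": truth, "bias": bias, "rms": rms, "f0": f0},
        index=pd.Index(names, name="par"),
    )

    mom = population_moments(design.random_effects_law)
    re = pd.DataFrame(
        {
            "mean": mom[:, 0],
            "est_mean": np.asarray(bhat_means).mean(axis=0),
            "sd": mom[:, 1],
            "est_sd": np.asarray(bhat_sds).mean(axis=0),
        },
        index=pd.Index([f"b{m + 1}" for m in range(mom.shape[0])], name="effect"),
    )
    if post_sds:
        re["post_sd"] = np.asarray(post_sds).mean(axis=0)
    rq = pd.Series(
        np.quantile(rmses, [0.05, 0.25, 0.50, 0.75]),
        index=["5%", "25%", "50%", "75%"],
        name="rmse",
    )
    return ReplicationTable(
        params=params, random_effects=re, rmse_quantiles=rq,
        n_replications=n_replications, n_failed=n_failed,
    )
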