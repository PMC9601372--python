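"""Model / Results objects for the semiparametric simplex mixed-effects model.

``SimplexMixedLasso`` bundles a longitudinal dataset with a hierarchical
prior; ``fit`` runs the hybrid Gibbs / Metropolis sampler and returns a
``SimplexMixedLassoResults`` carrying posterior draws, point estimates,
credible intervals, acceptance diagnostics and a text summary, in the style
of statsmodels model classes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import LongitudinalData
from .diagnostics import epsr, select_variables
from .priors import PriorSpec
from .sampler import ChainConfig, run

__all__ = ["SimplexMixedLasso", "SimplexMixedLassoResults"]


class SimplexMixedLasso:
    """Bayesian simplex mixed-effects model with Lasso-type shrinkage.

    Parameters
    ----------
    data : LongitudinalData
        Long-format responses in (0, 1) with fixed- and random-effect
        designs.
    prior : PriorSpec, optional
        Hierarchical prior; defaults to the CDPMM random-effects prior with
        the reference hyperparameters.

    Examples
    --------
    >>> model = SimplexMixedLasso.from_csv("study.csv")
    >>> res = model.fit(n_burnin=3000, n_keep=2000, seed=1)
    >>> print(res.summary())
    """

    def __init__(self, data: LongitudinalData, prior: PriorSpec | None = None):
        self.data = data
        self.prior = prior if prior is not None else PriorSpec()
        self.exog_names = list(getattr(data, "x_names", None) or
                               ["const"] + [f"x_{k}" for k in range(1, data.n_fixed)])

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, prior: PriorSpec | None = None):
        return cls(LongitudinalData.from_dataframe(df), prior=prior)

    @classmethod
    def from_csv(cls, path, prior: PriorSpec | None = None):
        return cls.from_dataframe(pd.read_csv(path), prior=prior)

    def fit(self, n_burnin=7000, n_keep=5000, n_chains=3, seed=None,
            **config_kwargs) -> "SimplexMixedLassoResults":
        """Run the sampler and return a results object.

        ``n_chains >= 2`` enables the EPSR convergence table (chains start
        from overdispersed initial values).  Extra keyword arguments are
        passed to :class:`~simplexmm.sampler.ChainConfig`.
        """
        config = ChainConfig(
            n_burnin=n_burnin, n_keep=n_keep, n_chains=n_chains, seed=seed,
            **config_kwargs,
        )
        chains = run(self.data, self.prior, config)
        return SimplexMixedLassoResults(self, chains, config)


class SimplexMixedLassoResults:
    """Posterior summaries for a fitted simplex mixed-effects model.

    Point estimates are posterior means of the pooled kept draws; ``bse``
    are posterior standard deviations and ``conf_int`` equal-tailed credible
    intervals.  ``selection`` applies the 95%-CI rule: a coefficient is
    declared zero when its interval contains zero.
    """

    def __init__(self, model, chains, config):
        self.model = model
        self.chains = chains
        self.config = config
        self.draws = {
            k: np.concatenate([c.draws[k] for c in chains], axis=0)
            for k in chains[0].draws
        }

    # -- point estimates ---------------------------------------------------
    @property
    def params(self) -> pd.Series:
        return pd.Series(self.draws["beta"].mean(axis=0), index=self.model.exog_names)

    @property
    def bse(self) -> pd.Series:
        return pd.Series(
            self.draws["beta"].std(axis=0, ddof=1), index=self.model.exog_names
        )

    def conf_int(self, alpha=0.05) -> pd.DataFrame:
        lo = np.quantile(self.draws["beta"], alpha / 2, axis=0)
        hi = np.quantile(self.draws["beta"], 1 - alpha / 2, axis=0)
        return pd.DataFrame(
            {"lower": lo, "upper": hi}, index=self.model.exog_names
        )

    @property
    def sigma2(self) -> float:
        return float(self.draws["sigma2"].mean())

    @property
    def random_effects(self) -> pd.DataFrame:
        """Posterior means of the subject random effects (n x q)."""
        if "b" not in self.draws:
            raise AttributeError("random-effect draws were not stored")
        bhat = self.draws["b"].mean(axis=0)
        return pd.DataFrame(
            bhat,
            index=pd.Index(np.asarray(self.model.data.subject_ids), name="subject"),
            columns=[f"b{m + 1}" for m in range(bhat.shape[1])],
        )

    @property
    def selection(self) -> pd.DataFrame:
        return select_variables(self.draws["beta"], names=self.model.exog_names)

    @property
    def acceptance(self) -> dict:
        return {
            "beta": float(np.mean([c.accept_beta for c in self.chains])),
            "b_mean": float(np.mean([c.accept_b.mean() for c in self.chains])),
        }

    def epsr_table(self) -> pd.Series:
        """Gelman--Rubin EPSR per monitored scalar (needs >= 2 chains)."""
        if len(self.chains) < 2:
            raise ValueError("EPSR requires at least two chains")
        rows = {}
        beta = np.stack([c.draws["beta"] for c in self.chains])  # (m, L, p+1)
        for k, name in enumerate(self.model.exog_names):
            rows[name] = epsr(beta[:, :, k])
        for key in ("sigma2", "nu2", "tau"):
            rows[key] = epsr(np.stack([c.draws[key] for c in self.chains]))
        return pd.Series(rows, name="EPSR")

    def converged(self, threshold=1.2) -> bool:
        """All monitored EPSR values below ``threshold`` (default 1.2)."""
        return bool((self.epsr_table() < threshold).all())

    # -- output ------------------------------------------------------------
    def summary(self) -> str:
        sel = self.selection
        lines = [
            "Semiparametric simplex mixed-effects model (Bayesian Lasso)",
            "=" * 62,
            f"subjects: {self.model.data.n_subjects}   "
            f"records: {self.model.data.n_obs}   "
            f"random-effects prior: {self.model.prior.prior_kind}",
            f"chains: {len(self.chains)}   kept draws/chain: "
            f"{self.chains[0].n_keep}   burn-in: {self.config.n_burnin}",
            f"acceptance: beta {self.acceptance['beta']:.3f}, "
            f"random effects {self.acceptance['b_mean']:.3f}",
            "-" * 62,
            sel.round(4).to_string(),
            "-" * 62,
            f"sigma2: {self.sigma2:.4f} "
            f"(sd {float(self.draws['sigma2'].std(ddof=1)):.4f})",
        ]
        if len(self.chains) >= 2:
            et = self.epsr_table()
            lines.append(f"max EPSR: {float(et.max()):.3f} "
                         f"({'<' if et.max() < 1.2 else '>='} 1.2)")
        return "\n".join(lines)

    def save_draws(self, path) -> None:
        """Store pooled draws in a compressed ``.npz`` container."""
        np.savez_compressed(path, **self.draws)

    def plot_random_effect_density(self, component=0, ax=None, n_grid=200):
        """Kernel-density plot of the posterior-mean random effects."""
        import matplotlib.pyplot as plt

        from .diagnostics import kde_density

        bhat = self.random_effects.to_numpy()[:, component]
        grid = np.linspace(bhat.min() - 1.0, bhat.max() + 1.0, n_grid)
        dens = kde_density(bhat, grid)
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(grid, dens)
        ax.set_xlabel(f"b{component + 1}")
        ax.set_ylabel("density")
        return ax
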