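"""The simplex distribution S^-(mu, sigma2) on (0, 1).

The simplex distribution is a two-parameter dispersion model for continuous
proportions.  Its density is

    p(y; mu, sigma2) = [2 pi sigma2 {y(1-y)}^3]^{-1/2} exp{-d(y; mu) / (2 sigma2)}

for 0 < y < 1, where the unit deviance is

    d(y; mu) = (y - mu)^2 / [y (1-y) mu^2 (1-mu)^2].

``mu`` in (0, 1) is the mean parameter (it equals the distribution mean) and
``sigma2 > 0`` the dispersion.  This module provides the density, the unit
deviance and its mu-derivatives, the expected curvature E[d''(y; mu)] used to
build information-based MCMC proposals, and random variate generation by
numerical inversion of the CDF.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import integrate
from scipy.special import expit, logit

__all__ = [
    "SimplexParams",
    "unit_deviance",
    "unit_deviance_dmu",
    "unit_deviance_d2mu",
    "logpdf",
    "pdf",
    "cdf",
    "rvs",
    "expected_d2",
    "ExpectedD2Table",
]

# evaluation-time guard for y; stored data is never clipped
_EPS = 1e-10


def _validate_mu_sigma2(mu, sigma2) -> None:
    mu = np.asarray(mu, dtype=float)
    if np.any(~((mu > 0.0) & (mu < 1.0))):
        bad = np.asarray(mu)[~((mu > 0.0) & (mu < 1.0))].ravel()
        raise ValueError(f"mu must lie in the open interval (0, 1); got {bad[0]!r}")
    if sigma2 is not None:
        s = np.asarray(sigma2, dtype=float)
        if np.any(~(s > 0.0)):
            raise ValueError(f"sigma2 must be strictly positive; got {s!r}")


def _validate_y(y) -> None:
    y = np.asarray(y, dtype=float)
    if np.any(~((y > 0.0) & (y < 1.0))):
        bad = y[~((y > 0.0) & (y < 1.0))].ravel()
        raise ValueError(f"y must lie in the open interval (0, 1); got {bad[0]!r}")


@dataclass(frozen=True)
class SimplexParams:
    """Parameter pair (mu, sigma2) of a simplex distribution."""

    mu: float
    sigma2: float

    def __post_init__(self) -> None:
        _validate_mu_sigma2(self.mu, self.sigma2)


def unit_deviance(y, mu):
    """Unit deviance d(y; mu) = (y-mu)^2 / [y(1-y) mu^2 (1-mu)^2].

    Nonnegative, and zero iff y == mu.  Invariant under the reflection
    (y, mu) -> (1-y, 1-mu).
    """
    _validate_y(y)
    _validate_mu_sigma2(mu, None)
    y = np.clip(np.asarray(y, dtype=float), _EPS, 1.0 - _EPS)
    mu = np.asarray(mu, dtype=float)
    return (y - mu) ** 2 / (y * (1.0 - y) * mu**2 * (1.0 - mu) ** 2)


def _g(mu):
    # g(mu) = 1 / (mu (1-mu))^2 and its first two mu-derivatives
    u = mu * (1.0 - mu)
    up = 1.0 - 2.0 * mu
    g = u**-2
    g1 = -2.0 * u**-3 * up
    g2 = 6.0 * u**-4 * up**2 + 4.0 * u**-3
    return g, g1, g2


def unit_deviance_dmu(y, mu):
    """First mu-derivative of the unit deviance."""
    y = np.clip(np.asarray(y, dtype=float), _EPS, 1.0 - _EPS)
    g, g1, _ = _g(np.asarray(mu, dtype=float))
    a = 1.0 / (y * (1.0 - y))
    r = y - mu
    return a * (-2.0 * r * g + r**2 * g1)


def unit_deviance_d2mu(y, mu):
    """Second mu-derivative of the unit deviance."""
    y = np.clip(np.asarray(y, dtype=float), _EPS, 1.0 - _EPS)
    g, g1, g2 = _g(np.asarray(mu, dtype=float))
    a = 1.0 / (y * (1.0 - y))
    r = y - mu
    return a * (2.0 * g - 4.0 * r * g1 + r**2 * g2)


def logpdf(y, mu, sigma2):
    """Log density of S^-(mu, sigma2); -inf outside (0, 1)."""
    _validate_mu_sigma2(mu, sigma2)
    y = np.asarray(y, dtype=float)
    out = np.full(np.broadcast(y, np.asarray(mu), np.asarray(sigma2)).shape, -np.inf)
    inside = (y > 0.0) & (y < 1.0)
    yc = np.clip(y, _EPS, 1.0 - _EPS)
    mu = np.asarray(mu, dtype=float)
    sigma2 = np.asarray(sigma2, dtype=float)
    val = -0.5 * (np.log(2.0 * np.pi * sigma2) + 3.0 * np.log(yc * (1.0 - yc)))
    val = val - unit_deviance(yc, mu) / (2.0 * sigma2)
    out = np.where(inside, np.broadcast_to(val, out.shape), out)
    if out.ndim == 0:
        return float(out)
    return out


def pdf(y, mu, sigma2):
    """Density of S^-(mu, sigma2)."""
    return np.exp(logpdf(y, mu, sigma2))


def cdf(y, mu, sigma2):
    """CDF by adaptive quadrature (scalar y).  Reference implementation."""
    _validate_mu_sigma2(mu, sigma2)
    y = float(y)
    if y <= 0.0:
        return 0.0
    if y >= 1.0:
        return 1.0
    val, _ = integrate.quad(
        lambda t: pdf(t, mu, sigma2), 0.0, y, limit=200,
        points=[mu] if 0 < mu < y else None,
    )
    return min(max(val, 0.0), 1.0)


# ---------------------------------------------------------------------------
# random variates: numerical inversion of the CDF on a logit-spaced grid
# ---------------------------------------------------------------------------

_GRID_LOGIT_HALFWIDTH = 14.0
_GRID_SIZE = 3001


def _cdf_grid(mu, sigma2, n_grid=_GRID_SIZE):
    """Tabulated CDF of S^-(mu, sigma2) on per-row logit-spaced y grids.

    Each row's grid is the union of a global logit grid and a local grid of
    +-40 spike widths sqrt(sigma2 mu(1-mu)) around logit(mu), so the narrow
    density spike at extreme mu stays resolved.  ``mu``/``sigma2`` may be
    vectors (broadcast together); returns (y_grid, cdf), both (k, n_grid).
    """
    mu = np.atleast_1d(np.asarray(mu, dtype=float))[:, None]
    sigma2 = np.atleast_1d(np.asarray(sigma2, dtype=float))
    sigma2 = np.broadcast_to(sigma2, (mu.shape[0],))[:, None]
    lm = np.log(mu / (1.0 - mu))
    w = np.sqrt(sigma2 * mu * (1.0 - mu))
    n_half = n_grid // 2
    vg_global = np.broadcast_to(
        np.linspace(-_GRID_LOGIT_HALFWIDTH, _GRID_LOGIT_HALFWIDTH, n_half),
        (mu.shape[0], n_half),
    )
    vg_local = lm + w * np.linspace(-40.0, 40.0, n_grid - n_half)
    vg = np.sort(np.concatenate([vg_global, vg_local], axis=1), axis=1)
    vg = np.clip(vg, -34.0, 34.0)
    yg = expit(vg)
    dens_v = np.exp(
        -0.5 * (np.log(2.0 * np.pi * sigma2) + 3.0 * np.log(yg * (1.0 - yg)))
        - (yg - mu) ** 2 / (yg * (1.0 - yg) * mu**2 * (1.0 - mu) ** 2) / (2.0 * sigma2)
    ) * yg * (1.0 - yg)  # density in v = logit(y); integrate in v
    c = integrate.cumulative_trapezoid(dens_v, vg, axis=-1, initial=0.0)
    c /= c[:, -1:]
    return yg, c


def rvs(mu, sigma2, size=None, rng=None):
    """Draw simplex variates by inverse-CDF sampling.

    The CDF is tabulated on a dense logit-spaced grid (quadrature of the
    density) and inverted by monotone linear interpolation.  ``mu`` may be a
    vector, in which case one draw per element is returned and ``size`` must
    be None or match ``len(mu)``.
    """
    _validate_mu_sigma2(mu, sigma2)
    if rng is None:
        rng = np.random.default_rng()
    mu_arr = np.atleast_1d(np.asarray(mu, dtype=float))
    scalar_params = np.ndim(mu) == 0
    if scalar_params:
        n = 1 if size is None else int(size)
        if n < 1:
            raise ValueError("size must be >= 1")
        yg, c = _cdf_grid(mu_arr, sigma2)
        u = rng.uniform(size=n)
        out = np.interp(u, c[0], yg[0])
        return float(out[0]) if size is None else out
    if size is not None and int(size) != mu_arr.shape[0]:
        raise ValueError("size must match len(mu) for vector mu")
    yg, c = _cdf_grid(mu_arr, sigma2)
    u = rng.uniform(size=mu_arr.shape[0])
    # row-wise inversion: each row carries its own support grid and CDF
    idx = np.empty(mu_arr.shape[0], dtype=np.intp)
    for i in range(mu_arr.shape[0]):
        idx[i] = np.searchsorted(c[i], u[i])
    idx = np.clip(idx, 1, yg.shape[1] - 1)
    rows = np.arange(mu_arr.shape[0])
    c_lo = c[rows, idx - 1]
    c_hi = c[rows, idx]
    w = np.where(c_hi > c_lo, (u - c_lo) / np.maximum(c_hi - c_lo, 1e-300), 0.0)
    y_lo = yg[rows, idx - 1]
    return y_lo + w * (yg[rows, idx] - y_lo)


# ---------------------------------------------------------------------------
# expected curvature of the unit deviance
# ---------------------------------------------------------------------------


def expected_d2(mu, sigma2):
    """E_y[d''(y; mu)] under S^-(mu, sigma2), by adaptive quadrature.

    This is the expected information factor entering the proposal covariances
    of the Metropolis steps.  Strictly positive; symmetric under mu -> 1-mu.

    Raises
    ------
    RuntimeError
        if the quadrature fails to converge to relative tolerance 1e-8.
    """
    _validate_mu_sigma2(mu, sigma2)
    mu = float(mu)
    sigma2 = float(sigma2)

    # integrate on the logit scale: the density can be a very narrow spike
    # near mu when mu is extreme and sigma2 small, and the spike has O(1)
    # width in v = logit(y), which adaptive subdivision resolves reliably
    def integrand(v):
        y = expit(v)
        jac = y * (1.0 - y)
        return unit_deviance_d2mu(y, mu) * pdf(y, mu, sigma2) * jac

    # the density concentrates around logit(mu) with width ~ sqrt(sigma2 *
    # mu(1-mu)) on the logit scale; seed the subdivision there so the spike
    # cannot be stepped over when it is much narrower than the interval
    lm = float(logit(mu))
    w = float(np.sqrt(sigma2 * mu * (1.0 - mu)))
    lo, hi = -_GRID_LOGIT_HALFWIDTH - 26.0, _GRID_LOGIT_HALFWIDTH + 26.0
    pts = sorted({min(max(p, lo), hi) for k in (-30.0, -6.0, 0.0, 6.0, 30.0)
                  for p in (lm + k * w,)})
    val, err = integrate.quad(
        integrand, lo, hi, points=pts, limit=400, epsabs=0.0, epsrel=1e-9,
    )
    if not np.isfinite(val) or (val > 0 and err / val > 1e-4):
        raise RuntimeError(
            f"expected_d2 quadrature did not converge at mu={mu}, sigma2={sigma2}: "
            f"value={val}, abserr={err}"
        )
    return val


def _expected_d2_dense(mu_vec, sigma2, n_grid=4001):
    """Vectorized E[d''] for a vector of mu at one sigma2, by trapezoid
    quadrature on a logit-spaced grid refined around each density spike.
    Used to build the lookup table; :func:`expected_d2` (adaptive
    quadrature) is the reference."""
    mu = np.asarray(mu_vec, dtype=float)[:, None]
    lm = np.log(mu / (1.0 - mu))
    w = np.sqrt(sigma2 * mu * (1.0 - mu))
    n_half = n_grid // 2
    vg_global = np.broadcast_to(
        np.linspace(-_GRID_LOGIT_HALFWIDTH, _GRID_LOGIT_HALFWIDTH, n_half),
        (mu.shape[0], n_half),
    )
    # local refinement: +-40 spike widths around logit(mu)
    vg_local = lm + w * np.linspace(-40.0, 40.0, n_grid - n_half)
    vg = np.sort(np.concatenate([vg_global, vg_local], axis=1), axis=1)
    vg = np.clip(vg, -34.0, 34.0)
    yg = expit(vg)
    dens_v = np.exp(
        -0.5 * (np.log(2.0 * np.pi * sigma2) + 3.0 * np.log(yg * (1.0 - yg)))
        - (yg - mu) ** 2 / (yg * (1.0 - yg) * mu**2 * (1.0 - mu) ** 2) / (2.0 * sigma2)
    ) * yg * (1.0 - yg)  # density in v = logit(y)
    d2 = unit_deviance_d2mu(yg, mu)
    num = np.trapezoid(d2 * dens_v, vg, axis=-1)
    den = np.trapezoid(dens_v, vg, axis=-1)
    return num / den


class ExpectedD2Table:
    """Lookup table of log E[d''] over (logit mu, log sigma2).

    Exact quadrature for every observation at every MCMC iteration would
    dominate the run time; the expectation is smooth in both arguments, so
    bilinear interpolation of the log value on a fine tensor grid over
    logit(mu) in [-lim, lim] and log(sigma2) over a wide range reproduces
    it to ~1e-4 relative error at a few microseconds per point.  Queries
    outside the table are clamped to its edge.
    """

    def __init__(self, logit_lim=8.0, n_mu=641, log_s2_range=(-6.0, 6.0),
                 n_s2=121):
        self.logit_lim = float(logit_lim)
        self.log_s2_range = (float(log_s2_range[0]), float(log_s2_range[1]))
        lm = np.linspace(-self.logit_lim, self.logit_lim, n_mu)
        ls = np.linspace(*self.log_s2_range, n_s2)
        # the mu -> 1-mu symmetry of the family halves the quadrature work
        half = (n_mu + 1) // 2
        vals = np.empty((n_mu, n_s2))
        mu_half = expit(lm[:half])
        for b, s in enumerate(ls):
            vals[:half, b] = _expected_d2_dense(
                mu_half, float(np.exp(s)), n_grid=1001
            )
        vals[half:] = vals[: n_mu - half][::-1]
        self._logv = np.log(vals)
        self._lm0, self._hm = lm[0], lm[1] - lm[0]
        self._ls0, self._hs = ls[0], ls[1] - ls[0]
        self._nm, self._ns = n_mu, n_s2

    def __call__(self, mu, sigma2):
        mu = np.asarray(mu, dtype=float)
        sigma2 = np.asarray(sigma2, dtype=float)
        lm = np.clip(logit(mu), -self.logit_lim, self.logit_lim)
        ls = np.clip(np.log(sigma2), self.log_s2_range[0], self.log_s2_range[1])
        lm, ls = np.broadcast_arrays(lm, ls)
        fi = np.clip((lm - self._lm0) / self._hm, 0.0, self._nm - 1.000001)
        fj = np.clip((ls - self._ls0) / self._hs, 0.0, self._ns - 1.000001)
        i = fi.astype(np.intp)
        j = fj.astype(np.intp)
        wi = fi - i
        wj = fj - j
        v = self._logv
        out = np.exp(
            (1 - wi) * ((1 - wj) * v[i, j] + wj * v[i, j + 1])
            + wi * ((1 - wj) * v[i + 1, j] + wj * v[i + 1, j + 1])
        )
        return float(out) if out.ndim == 0 else out


@lru_cache(maxsize=1)
def default_expected_d2_table() -> ExpectedD2Table:
    """Shared table instance; built lazily once per process."""
    return ExpectedD2Table()
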