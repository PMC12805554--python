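"""Conjugate sampling primitives used by the Gibbs sampler.

Each function draws from an exact full-conditional distribution; they are
deliberately small and stateless so the closed-form oracles in the test
suite can verify them in isolation.
"""

from __future__ import annotations

import numpy as np
from scipy.special import log_ndtr, ndtri_exp


def sample_truncated_normal(rng, mean, sd, positive) -> np.ndarray:
    """Draw from N(mean, sd^2) truncated to (0, inf) or (-inf, 0] per element.

    Inverse-CDF method in log probability space (via ``log_ndtr`` /
    ``ndtri_exp``), which stays exact arbitrarily far into the tails where
    naive CDF inversion saturates.
    """
    mean = np.asarray(mean, dtype=float)
    positive = np.asarray(positive, dtype=bool)
    alpha = mean / sd
    logu = np.log1p(-rng.random(mean.shape))  # log of Uniform(0, 1]
    x_pos = mean - sd * ndtri_exp(logu + log_ndtr(alpha))   # invert the sf
    x_neg = mean + sd * ndtri_exp(logu + log_ndtr(-alpha))  # invert the cdf
    return np.where(positive, x_pos, x_neg)


def sample_normal_regression(rng, X, y, noise_var, prior_var, offset=0.0):
    """Draw coefficients of ``y = offset + X @ beta + N(0, noise_var)``.

    Independent N(0, prior_var) priors on each coefficient.  Returns the
    draw; posterior mean/precision are recomputable from the inputs (see
    :func:`normal_regression_moments`).
    """
    mean, cov = normal_regression_moments(X, y, noise_var, prior_var, offset)
    return mean + np.linalg.cholesky(cov) @ rng.standard_normal(mean.size)


def normal_regression_moments(X, y, noise_var, prior_var, offset=0.0):
    """Posterior mean and covariance of the conjugate regression block."""
    X = np.asarray(X, dtype=float)
    r = np.asarray(y, dtype=float) - offset
    P = X.T @ X / noise_var + np.eye(X.shape[1]) / prior_var
    b = X.T @ r / noise_var
    cov = np.linalg.inv(P)  # block dimension is tiny (a handful of coefficients)
    return cov @ b, cov


def sample_inverse_gamma(rng, shape, rate):
    """Draw from InverseGamma(shape, rate) (density ∝ x^{-shape-1} e^{-rate/x})."""
    return rate / rng.gamma(shape, 1.0)


def sample_variance(rng, resid, prior_shape, prior_rate) -> float:
    """Conjugate inverse-gamma update for an error variance given residuals."""
    resid = np.asarray(resid, dtype=float).ravel()
    return float(sample_inverse_gamma(rng, prior_shape + 0.5 * resid.size,
                                      prior_rate + 0.5 * resid @ resid))


def sample_scale_gridded(rng, deviations, prior_scale, grid_size=400, upper_mult=4.0):
    """Draw a scale parameter tau with a half-normal(prior_scale) prior.

    Exact up to grid resolution: inverse-CDF sampling of the posterior of
    ``tau`` given i.i.d. N(0, tau^2) ``deviations``, on a log-spaced grid.
    Used for the random-effect spread, where the half-normal prior is not
    conjugate.
    """
    d = np.asarray(deviations, dtype=float).ravel()
    ss = d @ d
    taus = np.geomspace(1e-4, upper_mult * prior_scale, grid_size)
    logp = (-d.size * np.log(taus) - 0.5 * ss / taus**2
            - 0.5 * taus**2 / prior_scale**2)
    logp -= logp.max()
    w = np.exp(logp)
    cdf = np.cumsum(w)
    cdf /= cdf[-1]
    return float(np.interp(rng.random(), cdf, taus))
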