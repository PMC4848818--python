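"""Deterministic cross-checks of the sampler on tiny models.

For a one-factor, two-item, two-category instrument with *fixed* cut
points, the posterior of the single free loading can be computed without
MCMC: marginalizing the latent factor by Gauss-Hermite quadrature gives
the exact likelihood of each of the four response patterns, and a dense
grid over (loading, factor variance) with the model's own priors gives
posterior moments by direct summation.  The Gibbs sampler must reproduce
these moments to Monte-Carlo accuracy; this module provides the
grid-quadrature side of that comparison, sharing no code with the sampler.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr
from scipy.stats import gamma

__all__ = ["GridPosterior", "tiny_model_grid_posterior"]


@dataclass
class GridPosterior:
    """Posterior moments of the free loading from grid integration."""

    loading_mean: float
    loading_sd: float
    lam_grid: np.ndarray
    lam_marginal: np.ndarray


def tiny_model_grid_posterior(
    y: np.ndarray,
    cut1: float,
    cut2: float,
    *,
    loading_var: float = 1e6,
    wishart_df: float = 10.0,
    lam_range: tuple[float, float] = (-2.0, 6.0),
    n_lam: int = 321,
    phi_range: tuple[float, float] = (0.02, 8.0),
    n_phi: int = 241,
    n_nodes: int = 80,
) -> GridPosterior:
    """Exact (quadrature) posterior of the free loading in the tiny model.

    Model: ``eta ~ N(0, phi)``; item 1 is the marker (loading 1), item 2
    has the free loading ``lam``; unit residual variances; binary responses
    ``y_j = 2`` iff the latent response exceeds the item's fixed cut.
    Priors as in the fitted model: ``lam ~ N(0, loading_var)``; the factor
    precision is Wishart (here gamma) with ``wishart_df`` degrees of
    freedom and scale ``1/wishart_df``, so its prior mean is 1.

    ``y`` is an (n, 2) array of categories in {1, 2}.
    """
    y = np.asarray(y, dtype=int)
    assert y.shape[1] == 2 and np.isin(y, (1, 2)).all()
    # count the four response patterns
    pat = (y[:, 0] - 1) * 2 + (y[:, 1] - 1)   # 0..3 = (1,1),(1,2),(2,1),(2,2)
    counts = np.bincount(pat, minlength=4)

    nodes, weights = np.polynomial.hermite_e.hermegauss(n_nodes)  # weight e^{-x^2/2}
    weights = weights / np.sqrt(2 * np.pi)    # now integrates N(0,1) densities

    lam = np.linspace(*lam_range, n_lam)
    phi = np.linspace(*phi_range, n_phi)
    # prior over phi: precision w = 1/phi ~ Gamma(df/2, rate df/2);
    # transform to a density in phi with Jacobian 1/phi^2
    shape = wishart_df / 2.0
    rate = wishart_df / 2.0
    log_prior_phi = (gamma.logpdf(1.0 / phi, shape, scale=1.0 / rate)
                     - 2.0 * np.log(phi))
    log_prior_lam = -0.5 * lam**2 / loading_var

    # P(y1=1 | eta) = ndtr(cut1 - eta); P(y2=1 | eta, lam) = ndtr(cut2 - lam*eta)
    # eta = sqrt(phi) * node
    eta = np.sqrt(phi)[:, None] * nodes[None, :]          # (n_phi, n_nodes)
    p1_low = ndtr(cut1 - eta)                              # marker item
    logpost = np.empty((n_phi, n_lam))
    for il, l in enumerate(lam):
        p2_low = ndtr(cut2 - l * eta)
        pats = np.stack([
            p1_low * p2_low,
            p1_low * (1 - p2_low),
            (1 - p1_low) * p2_low,
            (1 - p1_low) * (1 - p2_low),
        ])                                                # (4, n_phi, n_nodes)
        probs = pats @ weights                            # (4, n_phi)
        probs = np.clip(probs, 1e-300, None)
        logpost[:, il] = counts @ np.log(probs)
    logpost += log_prior_phi[:, None] + log_prior_lam[None, :]
    logpost -= logpost.max()
    post = np.exp(logpost)
    lam_marg = np.trapezoid(post, phi, axis=0)
    lam_marg /= np.trapezoid(lam_marg, lam)
    mean = np.trapezoid(lam * lam_marg, lam)
    var = np.trapezoid((lam - mean) ** 2 * lam_marg, lam)
    return GridPosterior(loading_mean=float(mean), loading_sd=float(np.sqrt(var)),
                         lam_grid=lam, lam_marginal=lam_marg)
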