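"""Gibbs sampler with data augmentation for the ordinal-probit factor model.

One sweep updates, in fixed order: the latent responses z (truncated-normal
draws for observed cells, untruncated for missing cells — the data
augmentation), the latent factors eta (exact multivariate-normal full
conditional), the free loadings (conjugate normal regression updates), the
residual variances (paper mode only: truncated inverse-gamma), the factor
covariance (inverse of a Wishart-drawn precision), and the free thresholds
(each drawn uniformly on its exact full-conditional bracket — the flat
threshold prior makes the conditional uniform between the neighbouring
cuts and the extreme latent responses of the adjacent categories).

Truncated-normal sampling uses the inverse-CDF in log space
(``log_ndtr`` / ``ndtri_exp``), which stays exact deep into the tails.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy.special import log_ndtr, ndtri_exp
from scipy.stats import invgamma, wishart

from .data_io import ResponseTable
from .instrument import InstrumentSpec
from .model import OrdinalCFAModel, PriorSpec, init_model

__all__ = [
    "ChainConfig",
    "PosteriorDraws",
    "SamplerError",
    "truncated_normal",
    "update_latent_mlv",
    "update_factors",
    "update_loadings",
    "update_residual_variances",
    "update_factor_cov",
    "update_factor_scale",
    "update_thresholds",
    "run",
]


class SamplerError(RuntimeError):
    """Numerical failure inside the sampler, carrying the iteration index."""

    def __init__(self, message: str, iteration: int | None = None):
        super().__init__(message)
        self.iteration = iteration


@dataclass(frozen=True)
class ChainConfig:
    """MCMC run settings.

    Defaults: 2 chains of 10,000 iterations, 5,000 burn-in, no thinning.
    ``sample_thresholds=False`` freezes thresholds at their initialization
    (the behaviour of treating the standard-normal-quantile cuts as known).
    """

    n_iterations: int = 10_000
    burn_in: int = 5_000
    thinning: int = 1
    n_chains: int = 2
    seed: int = 0
    identification_mode: str = "probit"
    sample_thresholds: bool = True
    save_fields: tuple[str, ...] = (
        "loadings", "residual_var", "thresholds", "factor_cov")
    save_log_joint: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < self.n_iterations):
            raise ValueError("require 0 <= burn_in < n_iterations")
        if self.thinning < 1 or self.n_chains < 1:
            raise ValueError("thinning >= 1 and n_chains >= 1 required")
        if self.identification_mode not in ("probit", "paper"):
            raise ValueError(f"unknown mode {self.identification_mode!r}")

    @property
    def n_draws(self) -> int:
        return (self.n_iterations - self.burn_in) // self.thinning


@dataclass
class PosteriorDraws:
    """Retained parameter states: arrays of shape (n_chains, n_draws, ...)."""

    params: dict
    spec: InstrumentSpec
    config: ChainConfig
    log_joint: np.ndarray | None = None  # (n_chains, n_draws) if saved

    @property
    def n_chains(self) -> int:
        return next(iter(self.params.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.params.values())).shape[1]

    def scalar_series(self) -> dict:
        """Flatten to named scalar series of shape (n_chains, n_draws).

        Markers and mode-fixed residual variances are skipped (constant by
        construction); anchored thresholds are kept only if they vary.
        """
        out = {}
        spec = self.spec
        marker = np.asarray(spec.marker_mask())
        if "loadings" in self.params:
            for j, name in enumerate(spec.item_names):
                if not marker[j]:
                    out[f"loading[{name}]"] = self.params["loadings"][:, :, j]
        if "residual_var" in self.params and self.config.identification_mode == "paper":
            for j, name in enumerate(spec.item_names):
                out[f"residual_var[{name}]"] = self.params["residual_var"][:, :, j]
        if "thresholds" in self.params and self.config.sample_thresholds:
            for j, name in enumerate(spec.item_names):
                for c in range(self.params["thresholds"].shape[-1]):
                    s = self.params["thresholds"][:, :, j, c]
                    if np.ptp(s) > 0:
                        out[f"threshold[{name},{c + 1}]"] = s
        if "factor_cov" in self.params:
            fn = spec.factor_names
            for a in range(len(fn)):
                for b in range(a + 1):
                    out[f"factor_cov[{fn[a]},{fn[b]}]"] = \
                        self.params["factor_cov"][:, :, a, b]
        return out

    def pooled(self, key: str) -> np.ndarray:
        """All chains concatenated along the draw axis."""
        arr = self.params[key]
        return arr.reshape(-1, *arr.shape[2:])

    def save(self, directory) -> None:
        """Columnar delimited-text draws plus a JSON metadata file."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        series = self.scalar_series()
        nC, nD = self.n_chains, self.n_draws
        cols = {"chain": np.repeat(np.arange(nC), nD),
                "draw": np.tile(np.arange(nD), nC)}
        for k, v in series.items():
            cols[k] = v.reshape(-1)
        # full parameter arrays, flattened, so draws round-trip exactly
        for k, v in self.params.items():
            flat = v.reshape(nC * nD, -1)
            for idx in range(flat.shape[1]):
                cols[f"_raw:{k}:{idx}"] = flat[:, idx]
        pd.DataFrame(cols).to_csv(d / "draws.csv", index=False)
        meta = {
            "shapes": {k: list(v.shape[2:]) for k, v in self.params.items()},
            "config": {
                "n_iterations": self.config.n_iterations,
                "burn_in": self.config.burn_in,
                "thinning": self.config.thinning,
                "n_chains": self.config.n_chains,
                "seed": self.config.seed,
                "identification_mode": self.config.identification_mode,
                "sample_thresholds": self.config.sample_thresholds,
                "save_fields": list(self.config.save_fields),
            },
            "items": list(self.spec.item_names),
            "factors": list(self.spec.factor_names),
        }
        (d / "meta.json").write_text(json.dumps(meta, indent=1))
        from .instrument import save_instrument
        save_instrument(self.spec, d / "instrument.yaml")

    @classmethod
    def load(cls, directory) -> "PosteriorDraws":
        from .instrument import load_instrument
        d = Path(directory)
        meta = json.loads((d / "meta.json").read_text())
        spec = load_instrument(d / "instrument.yaml")
        cfg = ChainConfig(**{**meta["config"],
                             "save_fields": tuple(meta["config"]["save_fields"])})
        df = pd.read_csv(d / "draws.csv")
        nC = int(df["chain"].max()) + 1
        nD = int(df["draw"].max()) + 1
        params = {}
        for k, shape in meta["shapes"].items():
            cols = [c for c in df.columns if c.startswith(f"_raw:{k}:")]
            cols.sort(key=lambda c: int(c.rsplit(":", 1)[1]))
            arr = df[cols].to_numpy().reshape(nC, nD, *shape)
            params[k] = arr
        return cls(params=params, spec=spec, config=cfg)


# -- numerics --------------------------------------------------------------


def truncated_normal(rng, mean, sd, lower, upper):
    """Draw from N(mean, sd^2) truncated to (lower, upper], elementwise.

    Inverse-CDF in log space: with a = (lower-mean)/sd, b likewise, the
    draw is ``ndtri_exp(log F)`` where F interpolates between the CDF at
    the bounds; the interval is reflected into the lower tail first so the
    CDF difference never cancels catastrophically.
    """
    mean = np.asarray(mean, dtype=float)
    sd = np.broadcast_to(np.asarray(sd, dtype=float), mean.shape)
    a = (np.asarray(lower) - mean) / sd
    b = (np.asarray(upper) - mean) / sd
    if np.any(a >= b):
        raise ValueError("empty truncation interval")
    flip = (a + b) > 0
    a2 = np.where(flip, -b, a)
    b2 = np.where(flip, -a, b)
    la = log_ndtr(a2)
    lb = log_ndtr(b2)
    u = rng.random(mean.shape)
    # F = Fb * (d + u(1-d)), d = Fa/Fb in (0,1]
    d = np.exp(np.clip(la - lb, -745.0, 0.0))
    x = ndtri_exp(lb + np.log(np.maximum(d + u * (1.0 - d), 1e-300)))
    x = np.where(flip, -x, x)
    x = np.clip(x, np.where(np.isfinite(a), a, -np.inf),
                np.where(np.isfinite(b), b, np.inf))
    return mean + sd * x


def _sweep_arrays(model: OrdinalCFAModel, table: ResponseTable):
    """Precompute per-dataset index structures used by every sweep.

    Responses are taken in recoded (reversal-applied) orientation, the
    scale the latent model lives on.
    """
    from .model import model_responses

    y = model_responses(table)
    observed = ~np.isnan(y)
    cat = np.where(observed, y, 1).astype(int) - 1  # 0-based category
    # per (item, category): row indices of observed cells, for threshold updates
    J, C = model.spec.n_items, model.spec.n_categories
    cells = [[np.flatnonzero(observed[:, j] & (cat[:, j] == c))
              for c in range(C)] for j in range(J)]
    return {"y": y, "observed": observed, "cat": cat, "cells": cells}


# -- full-conditional updates ---------------------------------------------


def update_latent_mlv(model: OrdinalCFAModel, table: ResponseTable,
                      rng: np.random.Generator, arrays=None) -> OrdinalCFAModel:
    """Redraw every latent response z.

    Observed cells: normal around the factor prediction, truncated to the
    category's threshold bracket.  Missing cells: the same normal,
    untruncated (data augmentation).
    """
    arrays = arrays or _sweep_arrays(model, table)
    observed, cat = arrays["observed"], arrays["cat"]
    J = model.spec.n_items
    f = model.item_factor
    mean = model.eta[:, f] * model.loadings[None, :]
    sd = np.sqrt(model.residual_var)[None, :].repeat(len(mean), axis=0)

    tau = model.thresholds
    lo_t = np.concatenate([np.full((J, 1), -np.inf), tau], axis=1)
    hi_t = np.concatenate([tau, np.full((J, 1), np.inf)], axis=1)
    lower = lo_t[np.arange(J)[None, :], cat]
    upper = hi_t[np.arange(J)[None, :], cat]

    z = np.empty_like(model.z)
    z[observed] = truncated_normal(rng, mean[observed], sd[observed],
                                   lower[observed], upper[observed])
    miss = ~observed
    z[miss] = mean[miss] + sd[miss] * rng.standard_normal(int(miss.sum()))
    model.z = z
    return model


def update_factors(model: OrdinalCFAModel,
                   rng: np.random.Generator) -> OrdinalCFAModel:
    """Redraw the latent factors from their exact Gaussian full conditional.

    Precision ``Phi^-1 + Lambda' Psi^-1 Lambda`` (common to all respondents
    since z is complete after augmentation); mean the usual normal-normal
    combination with each respondent's z.
    """
    K, J = model.spec.n_factors, model.spec.n_items
    f = model.item_factor
    lam_over_psi = model.loadings / model.residual_var  # (J,)
    # Lambda' Psi^-1 Lambda is diagonal-per-factor accumulation
    ltl = np.zeros((K, K))
    contrib = model.loadings * lam_over_psi
    np.add.at(ltl, (f, f), contrib)
    try:
        phi_inv = sla.cho_solve(sla.cho_factor(model.factor_cov), np.eye(K))
    except sla.LinAlgError as exc:
        raise SamplerError(f"factor covariance not PD: {exc}") from exc
    P = phi_inv + ltl
    P = 0.5 * (P + P.T)
    try:
        L = np.linalg.cholesky(P)
    except np.linalg.LinAlgError as exc:
        raise SamplerError(f"singular factor precision: {exc}") from exc
    # b_i = Lambda' Psi^-1 z_i, accumulated per factor
    B = np.zeros((len(model.z), K))
    np.add.at(B.T, f, (model.z * lam_over_psi[None, :]).T)
    mean = sla.cho_solve((L, True), B.T).T
    eps = rng.standard_normal(mean.shape)
    model.eta = mean + sla.solve_triangular(L.T, eps.T, lower=False).T
    return model


def update_loadings(model: OrdinalCFAModel,
                    rng: np.random.Generator) -> OrdinalCFAModel:
    """Conjugate normal update of each non-marker loading.

    Regression of the item's latent responses on its factor, combined with
    the N(0, 1e6) prior.  Marker loadings are never touched.  A factor with
    zero variance across respondents leaves the prior as the conditional
    (with a warning).
    """
    pri = model.priors
    f = model.item_factor
    marker = model.marker
    for j in np.flatnonzero(~marker):
        x = model.eta[:, f[j]]
        sxx = float(x @ x)
        psi = model.residual_var[j]
        if sxx == 0.0:
            warnings.warn("zero factor variance; loading drawn from prior")
            prec = 1.0 / pri.loading_var
            mean = pri.loading_mean
        else:
            prec = 1.0 / pri.loading_var + sxx / psi
            mean = (pri.loading_mean / pri.loading_var
                    + float(x @ model.z[:, j]) / psi) / prec
        model.loadings[j] = mean + rng.standard_normal() / np.sqrt(prec)
    return model


def update_residual_variances(model: OrdinalCFAModel,
                              rng: np.random.Generator) -> OrdinalCFAModel:
    """Truncated inverse-gamma update of residual variances (paper mode).

    With a flat prior on (0, 100) the conditional kernel is
    ``psi^(-n/2) exp(-S/(2 psi))`` — an inverse-gamma with shape n/2 - 1
    and scale S/2 — truncated to (0, 100); drawn by inverse-CDF.  In probit
    mode residual variances stay fixed at 1.
    """
    if model.mode == "probit":
        return model
    lo, hi = model.priors.residual_var_bounds
    n = model.z.shape[0]
    f = model.item_factor
    resid = model.z - model.eta[:, f] * model.loadings[None, :]
    S = np.sum(resid**2, axis=0)
    shape = n / 2.0 - 1.0
    if shape <= 0:
        raise SamplerError(f"too few respondents ({n}) for the variance update")
    for j in range(model.spec.n_items):
        b = 0.5 * S[j]
        if b <= 0:
            warnings.warn("all residuals zero; variance floored")
            model.residual_var[j] = 1e-8
            continue
        F_hi = invgamma.cdf(hi, shape, scale=b)
        u = rng.random() * F_hi
        draw = float(invgamma.ppf(max(u, 1e-300), shape, scale=b))
        model.residual_var[j] = float(np.clip(draw, 1e-8, hi * (1 - 1e-12)))
    return model


def update_factor_cov(model: OrdinalCFAModel,
                      rng: np.random.Generator) -> OrdinalCFAModel:
    """Wishart update of the factor precision; covariance is its inverse.

    Posterior: ``Wishart(df0 + n, (S0^-1 + sum eta_i eta_i')^-1)`` with the
    prior ``Wishart(df0=10, S0=I/10)`` on the precision.
    """
    K = model.spec.n_factors
    pri = model.priors
    n = model.eta.shape[0]
    S0_inv = np.linalg.inv(pri.wishart_scale(K))
    S_post = S0_inv + model.eta.T @ model.eta
    S_post = 0.5 * (S_post + S_post.T)
    try:
        scale = np.linalg.inv(S_post)
    except np.linalg.LinAlgError as exc:
        raise SamplerError(f"non-invertible Wishart scale: {exc}") from exc
    scale = 0.5 * (scale + scale.T)
    W = np.atleast_2d(wishart.rvs(df=pri.wishart_df + n, scale=scale,
                                  random_state=rng))
    W = 0.5 * (W + W.T)
    try:
        cov = np.linalg.inv(W)
    except np.linalg.LinAlgError as exc:
        raise SamplerError(f"singular precision draw: {exc}") from exc
    cov = 0.5 * (cov + cov.T)
    np.linalg.cholesky(cov)  # raises if numerical drift broke PD
    model.factor_cov = cov
    return model


def _log_invwishart_kernel(cov: np.ndarray, df: float, K: int) -> float:
    """Log density kernel of the factor covariance implied by the Wishart
    prior on its inverse (scale I/df), constants dropped:
    ``-(df+K+1)/2 log|Phi| - df/2 tr(Phi^-1)``."""
    sign, logdet = np.linalg.slogdet(cov)
    if sign <= 0:
        return -np.inf
    tr = float(np.trace(np.linalg.inv(cov)))
    return -0.5 * (df + K + 1) * logdet - 0.5 * df * tr


def update_factor_scale(model: OrdinalCFAModel,
                        rng: np.random.Generator) -> OrdinalCFAModel:
    """Metropolis move along each factor's scale ridge.

    With the marker loading pinned at 1, the posterior has a weakly
    identified direction per factor: scaling the factor's latent scores
    (and its covariance row/column) up while scaling its non-marker
    loadings down changes the likelihood only through the marker item.
    The componentwise Gibbs updates cross that ridge very slowly, so this
    move proposes the rescaling directly — ``eta_f -> s eta_f``,
    ``Phi_f. -> s Phi_f.`` (diagonal by s^2), ``lambda_j -> lambda_j / s``
    for the factor's non-marker items, with log-normal s — and accepts on
    the marker item's latent-response likelihood, the loading and
    covariance priors, and the transform's Jacobian (the latent-factor
    prior term cancels the eta Jacobian exactly).  Latent responses and
    thresholds are untouched, so no bracket can be violated.
    """
    K = model.spec.n_factors
    pri = model.priors
    f_of = model.item_factor
    marker = model.marker
    n = model.eta.shape[0]
    for f in range(K):
        items = np.flatnonzero(f_of == f)
        mk = items[marker[items]][0]
        nonmkr = items[~marker[items]]
        width = 0.5 if rng.random() < 0.1 else 0.1
        s = float(np.exp(width * rng.standard_normal()))
        eta_f = model.eta[:, f]
        # marker-item likelihood: mean eta_f -> s*eta_f
        zm = model.z[:, mk]
        psi = model.residual_var[mk]
        dlik = (-0.5 * np.sum((zm - s * eta_f) ** 2 - (zm - eta_f) ** 2) / psi)
        # loading prior for the rescaled non-markers
        lam = model.loadings[nonmkr]
        dlam = -0.5 * np.sum((lam / s) ** 2 - lam**2) / pri.loading_var
        # covariance prior (inverse-Wishart kernel), exact transform
        cov_new = model.factor_cov.copy()
        cov_new[f, :] *= s
        cov_new[:, f] *= s
        dcov = (_log_invwishart_kernel(cov_new, pri.wishart_df, K)
                - _log_invwishart_kernel(model.factor_cov, pri.wishart_df, K))
        # Jacobian: K+1 covariance entries, minus the inverted loadings;
        # the eta factor s^n cancels against the latent-factor prior
        logj = (K + 1 - len(nonmkr)) * np.log(s)
        if np.log(rng.random() + 1e-300) < dlik + dlam + dcov + logj:
            model.eta[:, f] = s * eta_f
            model.factor_cov = cov_new
            model.loadings[nonmkr] = lam / s
            model.factor_scale_accepts = getattr(
                model, "factor_scale_accepts", 0) + 1
        model.factor_scale_proposals = getattr(
            model, "factor_scale_proposals", 0) + 1
    return model


def update_thresholds(model: OrdinalCFAModel, table: ResponseTable,
                      rng: np.random.Generator, arrays=None) -> OrdinalCFAModel:
    """Redraw each free cut uniformly on its full-conditional bracket.

    Two moves per item, both leaving the joint invariant.  First each free
    cut is drawn uniformly on its exact full-conditional bracket: cut c
    must stay above every latent response observed in category c (and the
    previous cut) and below every latent response in category c+1 (and the
    next cut); with the flat prior the conditional is uniform there, so
    the draw always accepts.  Because that bracket narrows like 1/n, a
    second, per-item Metropolis *scale* move then proposes rescaling the
    whole cut vector (log-normal multiplier), accepting on the
    ordinal-probit likelihood with the item's latent responses integrated
    out, and redraws them on acceptance — this restores fast mixing of the
    overall threshold scale.  Acceptance counts are kept on
    ``model.threshold_scale_accepts`` / ``.threshold_scale_proposals``.
    Anchored cuts (mode-dependent) are never touched; the scale move runs
    only when every cut of the item is free.
    """
    arrays = arrays or _sweep_arrays(model, table)
    cells = arrays["cells"]
    observed, cat = arrays["observed"], arrays["cat"]
    tau = model.thresholds
    C = model.spec.n_categories
    f = model.item_factor
    n_free = len(model.free_threshold_idx)
    scale_move = n_free == C - 1  # all cuts free (probit mode)
    for j in range(model.spec.n_items):
        zj = model.z[:, j]
        for c in model.free_threshold_idx:
            below = cells[j][c]       # observed rows in 0-based category c
            above = cells[j][c + 1]
            lo = tau[j, c - 1] if c > 0 else -np.inf
            hi = tau[j, c + 1] if c < C - 2 else np.inf
            if len(below):
                lo = max(lo, float(zj[below].max()))
            if len(above):
                hi = min(hi, float(zj[above].min()))
            if not np.isfinite(lo) and not np.isfinite(hi):
                continue  # nothing constrains this cut; keep state
            if not np.isfinite(lo):
                lo = hi - 1.0
            if not np.isfinite(hi):
                hi = lo + 1.0
            if hi <= lo:
                raise SamplerError("empty threshold bracket; z/tau inconsistent")
            tau[j, c] = lo + rng.random() * (hi - lo)

        if not scale_move:
            continue
        obs = observed[:, j]
        if not obs.any():
            continue
        eta_j = model.eta[obs, f[j]]
        lam_j = model.loadings[j]
        sd = np.sqrt(model.residual_var[j])
        cj = cat[obs, j]
        # mixture proposal: mostly local, occasionally wide — the wide
        # component lets the chain hop between item-scale basins
        width = 1.0 if rng.random() < 0.1 else 0.25
        s = float(np.exp(width * rng.standard_normal()))
        # non-marker items: rescale loading together with the cuts — this
        # walks the item's own scale ridge (for high-communality items the
        # likelihood is nearly flat along it); markers: cuts only
        joint = not model.marker[j]
        lam_new = lam_j * s if joint else lam_j
        logr = (_ordinal_loglik(tau[j] * s, lam_new * eta_j, sd, cj)
                - _ordinal_loglik(tau[j], lam_j * eta_j, sd, cj)
                + (n_free + (1 if joint else 0)) * np.log(s))
        if joint:
            V = model.priors.loading_var
            logr += -0.5 * (lam_new**2 - lam_j**2) / V
        model.threshold_scale_proposals = getattr(
            model, "threshold_scale_proposals", 0) + 1
        if np.log(rng.random() + 1e-300) < logr:
            model.threshold_scale_accepts = getattr(
                model, "threshold_scale_accepts", 0) + 1
            tau[j] *= s
            model.loadings[j] = lam_new
            # latent responses must be redrawn under the new state
            lo_t = np.concatenate([[-np.inf], tau[j]])
            hi_t = np.concatenate([tau[j], [np.inf]])
            model.z[obs, j] = truncated_normal(
                rng, lam_new * eta_j, sd, lo_t[cj], hi_t[cj])
            miss = ~obs
            if miss.any():
                model.z[miss, j] = (lam_new * model.eta[miss, f[j]]
                                    + sd * rng.standard_normal(int(miss.sum())))
    return model


def _ordinal_loglik(cuts: np.ndarray, mu: np.ndarray, sd: float,
                    cat: np.ndarray) -> float:
    """Ordinal-probit log likelihood of one item, latent response integrated."""
    from scipy.special import ndtr

    lo = np.concatenate([[-np.inf], cuts])
    hi = np.concatenate([cuts, [np.inf]])
    p = ndtr((hi[cat] - mu) / sd) - ndtr((lo[cat] - mu) / sd)
    return float(np.sum(np.log(np.maximum(p, 1e-300))))


# -- orchestration ---------------------------------------------------------

def run(
    table: ResponseTable,
    spec: InstrumentSpec | None = None,
    config: ChainConfig | None = None,
    *,
    fixed_thresholds: np.ndarray | None = None,
    priors: PriorSpec | None = None,
) -> PosteriorDraws:
    """Run the Gibbs sampler and return retained posterior draws.

    Chains are independent, each seeded from a child of ``config.seed``,
    so the whole run is reproducible.  ``fixed_thresholds`` initializes the
    cuts at given values (combine with ``sample_thresholds=False`` to hold
    them fixed).
    """
    spec = spec or table.spec
    config = config or ChainConfig()
    root = np.random.SeedSequence(config.seed)
    child_seeds = root.spawn(config.n_chains)

    n_draws = config.n_draws
    J, K, C = spec.n_items, spec.n_factors, spec.n_categories
    shapes = {
        "loadings": (J,), "residual_var": (J,),
        "thresholds": (J, C - 1), "factor_cov": (K, K),
        "eta": None,  # filled below if requested
    }
    store = {}
    for name in config.save_fields:
        if name == "eta":
            store[name] = np.empty((config.n_chains, n_draws,
                                    table.n_respondents, K))
        else:
            store[name] = np.empty((config.n_chains, n_draws, *shapes[name]))
    lj = (np.empty((config.n_chains, n_draws))
          if config.save_log_joint else None)

    from .model import log_joint as _log_joint

    for chain in range(config.n_chains):
        rng = np.random.default_rng(child_seeds[chain])
        model = init_model(table, spec, mode=config.identification_mode,
                           thresholds=fixed_thresholds, priors=priors)
        arrays = _sweep_arrays(model, table)
        saved = 0
        for it in range(config.n_iterations):
            try:
                update_latent_mlv(model, table, rng, arrays)
                update_factors(model, rng)
                update_loadings(model, rng)
                update_residual_variances(model, rng)
                update_factor_cov(model, rng)
                update_factor_scale(model, rng)
                if config.sample_thresholds:
                    update_thresholds(model, table, rng, arrays)
            except SamplerError as exc:
                raise SamplerError(
                    f"chain {chain}, iteration {it}: {exc}", iteration=it
                ) from exc
            if (it >= config.burn_in and saved < n_draws
                    and (it - config.burn_in) % config.thinning == 0):
                for name in config.save_fields:
                    store[name][chain, saved] = getattr(
                        model, name if name != "eta" else "eta")
                if lj is not None:
                    lj[chain, saved] = _log_joint(model, table)
                saved += 1
        assert saved == n_draws
    return PosteriorDraws(params=store, spec=spec, config=config, log_joint=lj)
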