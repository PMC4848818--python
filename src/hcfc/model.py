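"""Bayesian ordinal-probit confirmatory factor model: state and priors.

Each ordinal item j is driven by a continuous latent response
``z_ij = lambda_j * eta_{i,f(j)} + eps_ij`` with Gaussian residual; the
observed category is the bracket of ordered cut-points (thresholds) the
latent response falls in.  Latent factors ``eta_i`` are multivariate normal
with free covariance ``Phi``; one marker item per factor has its loading
fixed at 1 to set the factor scale, and latent-response means are 0.

Priors (chosen to be non-informative): loadings N(0, 1e6); residual
variances uniform on (0, 100); factor *precision* Wishart with 10 degrees
of freedom and scale I/10, so its prior expectation is the identity;
thresholds flat on the ordered region.

Two identification modes are provided.  ``probit`` fixes every residual
variance at 1 (the textbook-identified ordinal probit CFA) and leaves all
thresholds free.  ``paper`` keeps residual variances free with their
uniform prior — the priors exactly as stated above — and, because free
thresholds plus a free residual variance are jointly scale-redundant,
anchors each item's first and last interior thresholds at their
initialization values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtri
from scipy.stats import norm

from .data_io import ResponseTable, apply_reversals
from .instrument import InstrumentSpec

__all__ = [
    "PriorSpec",
    "OrdinalCFAModel",
    "init_thresholds",
    "init_model",
    "log_joint",
    "model_responses",
]


def model_responses(table: ResponseTable) -> np.ndarray:
    """Responses on the scale the latent model lives on.

    Reversal flags are applied, so every item points in the
    higher-is-better direction and all loadings are expected positive (as
    the study reports them).  Returns an n x J float array with NaN for
    missing cells.
    """
    return apply_reversals(table.responses, table.spec).to_numpy(dtype=float)


#: Loading-prior variance of the as-stated non-informative prior set.
VAGUE_LOADING_VAR = 1e6
#: Default loading-prior variance in probit mode.  The essentially flat
#: N(0, 1e6) prior makes the probit-identified posterior pathological for
#: high-communality items: jointly scaling an item's loading and cuts
#: degenerates it into a near-deterministic bin-indicator of its factor,
#: the marginal likelihood plateaus (a bounded deficit of a few dozen log
#: units), and the ordered-cut volume grows polynomially, so a flat prior
#: puts most posterior mass at absurd loading scales.  The sd-5 slab is
#: diffuse where loadings live (penalty < 0.2 log units up to loading 4,
#: i.e. ~95% communality with a unit residual) yet penalizes the
#: degenerate regime by tens of log units, removing the plateau.  Paper
#: mode anchors each item's extreme cuts instead, which pins the item
#: scale, so it keeps the literal flat prior.
PROBIT_LOADING_VAR = 25.0


@dataclass(frozen=True)
class PriorSpec:
    """Hyperparameters of the prior set (defaults: the stated
    non-informative choices)."""

    loading_mean: float = 0.0
    loading_var: float = VAGUE_LOADING_VAR
    residual_var_bounds: tuple[float, float] = (0.0, 100.0)
    wishart_df: float = 10.0

    def wishart_scale(self, dim: int) -> np.ndarray:
        """Scale matrix of the Wishart prior on the factor precision.

        ``I/df`` so that the prior expectation of the precision,
        ``df * scale``, is the identity.
        """
        if self.wishart_df < dim:
            raise ValueError(
                f"Wishart degrees of freedom ({self.wishart_df}) must be >= "
                f"factor dimension ({dim})"
            )
        return np.eye(dim) / self.wishart_df


@dataclass
class OrdinalCFAModel:
    """Full parameter-and-latent state of the ordinal CFA.

    Arrays are in item order (loadings, residual variances, thresholds) and
    factor order (factor covariance); ``eta`` is respondents x factors and
    ``z`` respondents x items (latent responses, including augmented values
    for missing cells).
    """

    spec: InstrumentSpec
    mode: str                      # 'probit' or 'paper'
    loadings: np.ndarray
    residual_var: np.ndarray
    thresholds: np.ndarray         # J x (C-1), strictly increasing rows
    factor_cov: np.ndarray         # K x K
    eta: np.ndarray                # n x K
    z: np.ndarray                  # n x J
    priors: PriorSpec = field(default_factory=PriorSpec)
    #: threshold columns updated by the sampler (mode-dependent)
    free_threshold_idx: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.mode not in ("probit", "paper"):
            raise ValueError(f"unknown identification mode {self.mode!r}")
        if not self.free_threshold_idx:
            C = self.spec.n_categories
            if self.mode == "probit":
                idx = tuple(range(C - 1))
            else:
                # anchor first and last cut; with C=2 the single cut is anchored
                idx = tuple(range(1, C - 2))
            object.__setattr__(self, "free_threshold_idx", idx)

    @property
    def item_factor(self) -> np.ndarray:
        return np.asarray(self.spec.item_factor_index())

    @property
    def marker(self) -> np.ndarray:
        return np.asarray(self.spec.marker_mask())

    def validate(self) -> None:
        """Assert every structural invariant of the state."""
        if not np.all(self.loadings[self.marker] == 1.0):
            raise AssertionError("marker loadings must be exactly 1")
        if np.any(np.diff(self.thresholds, axis=1) <= 0):
            raise AssertionError("thresholds must be strictly increasing")
        if not np.allclose(self.factor_cov, self.factor_cov.T, atol=1e-10):
            raise AssertionError("factor covariance must be symmetric")
        try:
            np.linalg.cholesky(self.factor_cov)
        except np.linalg.LinAlgError as exc:
            raise AssertionError("factor covariance must be PD") from exc
        if self.mode == "probit":
            if not np.all(self.residual_var == 1.0):
                raise AssertionError("probit mode requires residual variances 1")
        else:
            lo, hi = self.priors.residual_var_bounds
            if np.any(self.residual_var <= lo) or np.any(self.residual_var >= hi):
                raise AssertionError(
                    f"residual variances must lie in ({lo}, {hi})")

    def copy(self) -> "OrdinalCFAModel":
        return OrdinalCFAModel(
            spec=self.spec, mode=self.mode,
            loadings=self.loadings.copy(),
            residual_var=self.residual_var.copy(),
            thresholds=self.thresholds.copy(),
            factor_cov=self.factor_cov.copy(),
            eta=self.eta.copy(), z=self.z.copy(),
            priors=self.priors,
            free_threshold_idx=self.free_threshold_idx,
        )


def init_thresholds(frequencies: np.ndarray, *, eps: float = 1e-3,
                    tail: float = 1e-4) -> np.ndarray:
    """Cut-points from observed category frequencies.

    Each cut is the standard-normal quantile of the cumulative frequency
    through its category (the latent response is taken as standard normal
    at initialization).  Cumulative frequencies are clipped away from 0/1,
    and coincident adjacent cuts are separated by ``eps`` so rows are
    strictly increasing.  An item with all observed mass in a single
    category admits no finite cuts and raises, advising a category merge.
    """
    freqs = np.atleast_2d(np.asarray(frequencies, dtype=float))
    J, C = freqs.shape
    if np.any(~np.isfinite(freqs)):
        raise ValueError("frequencies must be finite")
    for j in range(J):
        if np.max(freqs[j]) >= 1.0 - 1e-12:
            raise ValueError(
                f"item {j}: all responses in one category; no finite "
                "thresholds exist — merge categories or drop the item"
            )
    cum = np.cumsum(freqs, axis=1)[:, :-1]
    cum = np.clip(cum, tail, 1 - tail)
    tau = ndtri(cum)
    # enforce strict increase where categories are empty
    for j in range(J):
        for c in range(1, C - 1):
            if tau[j, c] <= tau[j, c - 1]:
                tau[j, c] = tau[j, c - 1] + eps
    return tau


def init_model(
    table: ResponseTable,
    spec: InstrumentSpec | None = None,
    mode: str = "probit",
    seed: int | None = None,
    *,
    thresholds: np.ndarray | None = None,
    priors: PriorSpec | None = None,
) -> OrdinalCFAModel:
    """Deterministic starting state for the Gibbs sampler.

    Responses enter in recoded orientation (reversal flags applied via
    :func:`model_responses`), so all loadings point positive.  Thresholds
    come from :func:`init_thresholds` on the observed category
    frequencies (or are supplied, e.g. to hold them fixed at known values);
    when no prior set is given, probit mode defaults to the sd-10 loading
    slab (see :data:`PROBIT_LOADING_VAR`) and paper mode to the literal
    flat choices;
    loadings start at 1, residual variances at 1, factor covariance at the
    identity, factors at 0, and each observed latent response at the
    midpoint of its category's bracket (half a unit beyond the last cut for
    the extreme categories); missing latent responses start at 0.
    """
    spec = spec or table.spec
    if priors is None:
        priors = (PriorSpec(loading_var=PROBIT_LOADING_VAR)
                  if mode == "probit" else PriorSpec())
    priors.wishart_scale(spec.n_factors)  # validates df >= dim
    J, K, C = spec.n_items, spec.n_factors, spec.n_categories
    n = table.n_respondents

    y = model_responses(table)
    if thresholds is None:
        freqs = np.empty((J, C))
        for j in range(J):
            col = y[:, j][~np.isnan(y[:, j])]
            if len(col) == 0:
                raise ValueError(
                    f"cannot initialize thresholds: item "
                    f"{spec.item_names[j]!r} has no data")
            freqs[j] = np.bincount(col.astype(int), minlength=C + 1)[1:C + 1] / len(col)
        tau = init_thresholds(freqs)
    else:
        tau = np.asarray(thresholds, dtype=float).reshape(J, C - 1)

    observed = ~np.isnan(y)
    for k, fac in enumerate(spec.factors):
        cols = [spec.item_names.index(nm) for nm in fac.item_names]
        if np.nanstd(y[:, cols]) == 0:
            warnings.warn(
                f"factor {fac.name!r}: no observed variability across its items")

    # mid-interval latent responses consistent with the observed categories
    lo = np.concatenate([np.full((J, 1), -np.inf), tau], axis=1)
    hi = np.concatenate([tau, np.full((J, 1), np.inf)], axis=1)
    z = np.zeros((n, J))
    cat = np.where(observed, y, 1).astype(int) - 1
    zlo = np.take_along_axis(lo[None, :, :].repeat(n, 0), cat[:, :, None], 2)[:, :, 0]
    zhi = np.take_along_axis(hi[None, :, :].repeat(n, 0), cat[:, :, None], 2)[:, :, 0]
    mid = np.where(
        np.isinf(zlo), zhi - 0.5,
        np.where(np.isinf(zhi), zlo + 0.5, 0.5 * (zlo + zhi)),
    )
    z[observed] = mid[observed]

    model = OrdinalCFAModel(
        spec=spec, mode=mode,
        loadings=np.ones(J),
        residual_var=np.ones(J),
        thresholds=tau,
        factor_cov=np.eye(K),
        eta=np.zeros((n, K)),
        z=z,
        priors=priors,
    )
    model.validate()
    return model


def log_joint(model: OrdinalCFAModel, table: ResponseTable) -> float:
    """Log of the complete-data joint density at the current state.

    Sum of: factor prior ``N(eta_i; 0, Phi)``; latent-response densities
    ``N(z_ij; lambda_j eta, psi_j)`` for every cell (augmented missing
    cells included); the category-consistency indicator for observed cells
    (``-inf`` if any observed z falls outside its category's bracket); and
    the parameter priors (flat threshold prior contributes a constant,
    omitted).  Used as a testing oracle, not by the sampler.
    """
    spec, J, K = model.spec, model.spec.n_items, model.spec.n_factors
    y = model_responses(table)
    observed = ~np.isnan(y)
    f = model.item_factor
    pri = model.priors

    # category consistency of observed cells
    tau = model.thresholds
    lo = np.concatenate([np.full((J, 1), -np.inf), tau], axis=1)
    hi = np.concatenate([tau, np.full((J, 1), np.inf)], axis=1)
    cat = np.where(observed, y, 1).astype(int) - 1
    n = y.shape[0]
    zlo = np.take_along_axis(lo[None].repeat(n, 0), cat[:, :, None], 2)[:, :, 0]
    zhi = np.take_along_axis(hi[None].repeat(n, 0), cat[:, :, None], 2)[:, :, 0]
    inside = (model.z > zlo) & (model.z <= zhi)
    if not np.all(inside[observed]):
        return -np.inf

    # factor prior
    sign, logdet = np.linalg.slogdet(model.factor_cov)
    if sign <= 0:
        return -np.inf
    prec = np.linalg.inv(model.factor_cov)
    quad = np.einsum("ik,kl,il->i", model.eta, prec, model.eta)
    lp = -0.5 * np.sum(quad) - 0.5 * n * (logdet + K * np.log(2 * np.pi))

    # latent responses (all cells)
    mean = model.eta[:, f] * model.loadings[None, :]
    resid2 = (model.z - mean) ** 2
    lp += -0.5 * np.sum(resid2 / model.residual_var[None, :]
                        + np.log(2 * np.pi * model.residual_var)[None, :])

    # loading priors (non-markers)
    free = ~model.marker
    lp += np.sum(norm.logpdf(model.loadings[free], pri.loading_mean,
                             np.sqrt(pri.loading_var)))
    # residual-variance prior: uniform (0,100) in paper mode
    if model.mode == "paper":
        lo_b, hi_b = pri.residual_var_bounds
        if np.any(model.residual_var <= lo_b) or np.any(model.residual_var >= hi_b):
            return -np.inf
        lp += -J * np.log(hi_b - lo_b)
    # Wishart prior on the factor precision (density in the precision)
    df, S = pri.wishart_df, pri.wishart_scale(K)
    W = prec
    sW, ldW = np.linalg.slogdet(W)
    if sW <= 0:
        return -np.inf
    lp += 0.5 * (df - K - 1) * ldW - 0.5 * np.trace(np.linalg.solve(S, W))
    return float(lp)
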