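"""Posterior summaries, convergence diagnostics and report tables.

Produces the study-style outputs from retained draws: a per-parameter
summary (mean, sd, median, credible interval, split-chain Gelman-Rubin
statistic and effective sample size, via arviz), the latent factor
correlation matrix with posterior-probability significance stars, and the
factor-loadings listing with per-factor latent standard deviations.

Significance of a parameter against a test value is the two-sided
posterior tail probability ``2 min(P(theta > t), P(theta < t))``, starred
at the conventional 0.05 / 0.01 / 0.001 levels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import significance_stars
from .gibbs import PosteriorDraws
from .instrument import InstrumentSpec

__all__ = [
    "summarize",
    "bayes_significance",
    "factor_correlation_report",
    "FactorCorrelationReport",
    "loadings_report",
    "LoadingsReport",
]


def _diagnostics(series: np.ndarray) -> tuple[float, float]:
    """Split-chain rank-normalized Rhat and bulk ESS for (chains, draws)."""
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ess = float(az.ess(series))
        if series.shape[0] >= 2:
            rhat = float(az.rhat(series))
        else:
            rhat = float("nan")
    return rhat, ess


def summarize(draws: PosteriorDraws, level: float = 0.95) -> pd.DataFrame:
    """Per-parameter posterior summary pooled across chains.

    Rows are the non-constant scalar parameters; columns: mean, sd, median,
    central credible bounds at ``level``, split-chain Gelman-Rubin ``rhat``
    (omitted with a notice for single-chain runs) and effective sample
    size.  Invariant to the order chains are concatenated in.
    """
    if not (0 < level < 1):
        raise ValueError("level must be in (0, 1)")
    series = draws.scalar_series()
    if draws.n_draws < 2:
        raise ValueError("need at least 2 retained draws")
    if draws.n_chains < 2:
        warnings.warn("single chain: Gelman-Rubin diagnostic omitted")
    alpha = (1 - level) / 2
    rows = []
    for name, s in series.items():
        pooled = s.reshape(-1)
        if np.ptp(pooled) == 0:
            rhat, ess = float("nan"), float("nan")
        else:
            rhat, ess = _diagnostics(s)
        rows.append({
            "parameter": name,
            "mean": float(pooled.mean()),
            "sd": float(pooled.std(ddof=1)),
            "median": float(np.median(pooled)),
            "lower": float(np.quantile(pooled, alpha)),
            "upper": float(np.quantile(pooled, 1 - alpha)),
            "rhat": rhat,
            "ess": ess,
        })
    return pd.DataFrame(rows).set_index("parameter")


def bayes_significance(draws: np.ndarray, test_value: float) -> float:
    """Two-sided posterior tail probability against a test value.

    ``2 min(P(theta > t), P(theta < t))`` estimated from the draws; 0.0
    when the test value lies outside the whole draw range (resolution
    1/n_draws), approximately 1 at the posterior median.
    """
    x = np.asarray(draws, dtype=float).reshape(-1)
    if len(x) < 100:
        raise ValueError(f"need >= 100 draws, got {len(x)}")
    p_hi = float(np.mean(x > test_value))
    p_lo = float(np.mean(x < test_value))
    return min(1.0, 2.0 * min(p_hi, p_lo))


def _cov_to_corr(cov: np.ndarray) -> np.ndarray:
    sd = np.sqrt(np.diag(cov))
    return cov / np.outer(sd, sd)


@dataclass
class FactorCorrelationReport:
    """Posterior-mean latent factor correlations with significance tiers."""

    corr: pd.DataFrame      # posterior means, unit diagonal
    p: pd.DataFrame         # two-sided posterior tail probability vs 0
    stars: pd.DataFrame
    source: str = "posterior latent factors"

    def render(self) -> str:
        names = list(self.corr.columns)
        width = max(len(n) for n in names) + 2
        lines = [f"Correlation matrix ({self.source})"]
        for i, ni in enumerate(names):
            cells = [f"{self.corr.iloc[i, j]:6.3f}{self.stars.iloc[i, j]:<3}"
                     for j in range(i)]
            lines.append(f"{ni:<{width}}" + " ".join(cells))
        lines.append("Significance: * p<0.05  ** p<0.01  *** p<0.001")
        return "\n".join(lines)


def factor_correlation_report(draws: PosteriorDraws) -> FactorCorrelationReport:
    """Latent factor correlations from the factor-covariance draws.

    Each retained covariance draw is converted to a correlation matrix;
    the report holds elementwise posterior means and, per pair, the
    two-sided posterior probability against zero with its star tier.
    Scale-invariant: rescaling the covariance draws leaves it unchanged.
    """
    if "factor_cov" not in draws.params:
        raise KeyError("factor_cov draws were not retained")
    cov = draws.pooled("factor_cov")         # (draws, K, K)
    sd = np.sqrt(np.einsum("dkk->dk", cov))
    corr = cov / (sd[:, :, None] * sd[:, None, :])
    mean = corr.mean(axis=0)
    np.fill_diagonal(mean, 1.0)
    K = mean.shape[0]
    p = np.ones((K, K))
    for a in range(K):
        for b in range(a):
            p[a, b] = p[b, a] = bayes_significance(corr[:, a, b], 0.0)
    stars = np.vectorize(significance_stars)(p)
    np.fill_diagonal(stars, "")
    names = list(draws.spec.factor_names)
    mk = lambda m: pd.DataFrame(m, index=names, columns=names)
    return FactorCorrelationReport(corr=mk(mean), p=mk(p), stars=mk(stars))


@dataclass
class LoadingsReport:
    """Per-item posterior loadings and per-factor latent sd."""

    items: pd.DataFrame       # factor, item, marker, mean, sd, lower, upper
    factor_sd: pd.Series      # posterior mean of sqrt(Phi_ff)
    top_item: dict            # factor -> item with the largest mean loading

    def render(self) -> str:
        lines = ["Factor loadings (markers fixed at 1.00) and factor sd"]
        for fac, sub in self.items.groupby("factor", sort=False):
            lines.append(f"{fac}  (sd = {self.factor_sd[fac]:.2f})")
            for _, r in sub.iterrows():
                if r["marker"]:
                    lines.append(f"  {r['item']:<28} 1.00  (fixed)")
                else:
                    lines.append(
                        f"  {r['item']:<28} {r['mean']:.2f}  "
                        f"[{r['lower']:.2f}, {r['upper']:.2f}]")
        return "\n".join(lines)


def loadings_report(draws: PosteriorDraws, spec: InstrumentSpec | None = None,
                    level: float = 0.95) -> LoadingsReport:
    """Posterior loadings table plus factor standard deviations.

    Markers are shown as the fixed 1.00 with no interval; the factor sd is
    the posterior mean of ``sqrt(Phi_ff)`` (not the sqrt of the mean); the
    maximal-loading item per factor is identified from the posterior
    means.
    """
    spec = spec or draws.spec
    lam = draws.pooled("loadings")           # (draws, J)
    cov = draws.pooled("factor_cov")
    alpha = (1 - level) / 2
    marker = np.asarray(spec.marker_mask())
    f = np.asarray(spec.item_factor_index())
    rows = []
    for j, item in enumerate(spec.item_names):
        fac = spec.factor_names[f[j]]
        if marker[j]:
            rows.append({"factor": fac, "item": item, "marker": True,
                         "mean": 1.0, "sd": 0.0, "lower": np.nan,
                         "upper": np.nan})
        else:
            s = lam[:, j]
            rows.append({"factor": fac, "item": item, "marker": False,
                         "mean": float(s.mean()), "sd": float(s.std(ddof=1)),
                         "lower": float(np.quantile(s, alpha)),
                         "upper": float(np.quantile(s, 1 - alpha))})
    items = pd.DataFrame(rows)
    fsd = pd.Series(
        {spec.factor_names[k]: float(np.mean(np.sqrt(cov[:, k, k])))
         for k in range(spec.n_factors)},
        name="factor_sd",
    )
    top = {fac: sub.loc[sub["mean"].idxmax(), "item"]
           for fac, sub in items.groupby("factor", sort=False)}
    return LoadingsReport(items=items, factor_sd=fsd, top_item=top)
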