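"""Respondent data I/O and the classical (non-Bayesian) descriptive layer.

Reads delimited-text response tables, validates them against an instrument,
and computes the conventional questionnaire summaries: 0-100 transformed
factor scores, Cronbach's alpha, descriptive tables of scores by
socio-demographic subgroup, and pairwise score correlations with
significance stars.

The 0-100 score is the linear min-max rescaling of the (reversal-applied)
item mean, the convention used by Whoqol-bref domain scores:
``score = (mean - 1) / (n_categories - 1) * 100``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .instrument import InstrumentSpec

__all__ = [
    "DataValidationError",
    "ResponseTable",
    "read_responses",
    "write_responses",
    "apply_reversals",
    "score_factor",
    "scale_scores",
    "cronbach_alpha",
    "factor_alphas",
    "subgroup_table",
    "score_correlations",
    "ScoreCorrelations",
    "significance_stars",
]

logger = logging.getLogger(__name__)

#: Socio-demographic fields the survey collects; any non-item column in an
#: input file is kept as a covariate, these are just the recognised names.
KNOWN_COVARIATES = (
    "sex",
    "age",
    "relationship",
    "education",
    "occupation",
    "occupational_situation",
    "income",
)


class DataValidationError(ValueError):
    """Raised when a response file violates the instrument's constraints."""


@dataclass
class ResponseTable:
    """Respondents x items ordinal responses plus optional covariates.

    ``responses`` holds float codes in ``1..n_categories`` with NaN for
    missing cells; columns are exactly the instrument's items, in
    instrument order.
    """

    responses: pd.DataFrame
    spec: InstrumentSpec
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        cols = list(self.responses.columns)
        want = list(self.spec.item_names)
        if set(cols) != set(want):
            missing = sorted(set(want) - set(cols))
            extra = sorted(set(cols) - set(want))
            raise DataValidationError(
                f"response columns do not match instrument items; "
                f"missing={missing}, unexpected={extra}"
            )
        self.responses = self.responses[want].astype(float)
        vals = self.responses.to_numpy()
        ok = np.isnan(vals) | ((vals >= 1) & (vals <= self.spec.n_categories)
                               & (vals == np.round(vals)))
        if not ok.all():
            bad = np.argwhere(~ok)[0]
            raise DataValidationError(
                f"response out of range 1..{self.spec.n_categories} at "
                f"row {bad[0]}, column {want[bad[1]]!r}: {vals[tuple(bad)]!r}"
            )
        if self.covariates is not None and len(self.covariates) != len(self.responses):
            raise DataValidationError("covariates and responses differ in length")

    @property
    def n_respondents(self) -> int:
        return len(self.responses)

    @property
    def n_missing(self) -> int:
        return int(self.responses.isna().to_numpy().sum())


def read_responses(
    path,
    spec: InstrumentSpec,
    *,
    sep: str = ",",
    decimal: str = ".",
    na_token: str = "NA",
) -> ResponseTable:
    """Read and validate a delimited response file.

    Item columns must exactly match the instrument; every other column is
    kept as a covariate. The count of missing cells is logged.
    """
    df = pd.read_csv(path, sep=sep, decimal=decimal, na_values=[na_token],
                     keep_default_na=False)
    if df.empty or df.shape[1] == 0:
        raise DataValidationError(f"{path}: empty response file")
    item_cols = [c for c in df.columns if c in set(spec.item_names)]
    cov_cols = [c for c in df.columns if c not in set(spec.item_names)]
    responses = df[item_cols].apply(pd.to_numeric, errors="coerce")
    # non-numeric tokens other than the missing token are validation errors
    for c in item_cols:
        bad = responses[c].isna() & df[c].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise DataValidationError(
                f"{path}: non-numeric response at row {row}, column {c!r}: "
                f"{df[c].iloc[row]!r}"
            )
    covariates = df[cov_cols] if cov_cols else None
    if covariates is not None and "age" in covariates.columns:
        age = pd.to_numeric(covariates["age"], errors="coerce")
        bad = age.isna() & covariates["age"].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise DataValidationError(
                f"{path}: non-numeric age at row {row}: "
                f"{covariates['age'].iloc[row]!r}"
            )
        covariates = covariates.assign(age=age)
    table = ResponseTable(responses=responses, spec=spec, covariates=covariates)
    logger.info(
        "read %d respondents x %d items from %s (%d missing cells)",
        table.n_respondents, table.responses.shape[1], path, table.n_missing,
    )
    return table


def write_responses(table: ResponseTable, path, *, sep: str = ",",
                    na_token: str = "NA") -> None:
    """Write a response table (items as integer codes, then covariates)."""
    out = table.responses.copy()
    out = out.astype("Int64")
    if table.covariates is not None:
        out = pd.concat([out, table.covariates.reset_index(drop=True)], axis=1)
    out.to_csv(path, sep=sep, index=False, na_rep=na_token)


# -- scoring ---------------------------------------------------------------


def apply_reversals(responses: pd.DataFrame, spec: InstrumentSpec) -> pd.DataFrame:
    """Return responses with reversed items inverted (missing preserved)."""
    out = responses.copy()
    C = spec.n_categories
    for it in spec.items:
        if it.reversed:
            out[it.name] = C + 1 - out[it.name]
    return out


def score_factor(factor_responses: pd.DataFrame, spec: InstrumentSpec) -> pd.Series:
    """0-100 score of one factor per respondent.

    ``factor_responses`` are that factor's raw item columns; reversal flags
    are applied, then the mean over non-missing items is rescaled linearly
    so all-lowest maps to 0 and all-highest to 100.  All items missing
    gives a missing score.
    """
    rev = factor_responses.copy()
    C = spec.n_categories
    for c in factor_responses.columns:
        item = next(it for it in spec.items if it.name == c)
        if item.reversed:
            rev[c] = C + 1 - rev[c]
    mean = rev.mean(axis=1, skipna=True)
    return (mean - 1.0) / (C - 1.0) * 100.0


def scale_scores(table: ResponseTable) -> pd.DataFrame:
    """0-100 scores for every factor (columns) per respondent (rows)."""
    spec = table.spec
    out = {}
    for fac in spec.factors:
        out[fac.name] = score_factor(table.responses[list(fac.item_names)], spec)
    return pd.DataFrame(out)


def cronbach_alpha(items: pd.DataFrame | np.ndarray) -> float:
    """Cronbach's alpha of a (reversal-applied) item matrix.

    ``alpha = k/(k-1) * (1 - sum(item variances) / var(item sum))``, using
    complete rows only (listwise deletion); sample variances with ddof=1.
    May be negative.  Returns NaN with a warning when fewer than 2 complete
    rows remain.
    """
    X = pd.DataFrame(items).dropna(axis=0, how="any").to_numpy(dtype=float)
    k = X.shape[1]
    if k < 2:
        raise DataValidationError(f"alpha needs >=2 items, got {k}")
    if X.shape[0] < 2:
        warnings.warn("cronbach_alpha: fewer than 2 complete rows; undefined")
        return float("nan")
    item_vars = X.var(axis=0, ddof=1)
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var == 0:
        warnings.warn("cronbach_alpha: zero total variance; undefined")
        return float("nan")
    return float(k / (k - 1) * (1.0 - item_vars.sum() / total_var))


def factor_alphas(table: ResponseTable) -> pd.Series:
    """Cronbach's alpha per factor (reversals applied first)."""
    rev = apply_reversals(table.responses, table.spec)
    return pd.Series(
        {f.name: cronbach_alpha(rev[list(f.item_names)]) for f in table.spec.factors},
        name="alpha",
    )


# -- descriptive tables ----------------------------------------------------


def _two_group_p(groups: list[np.ndarray]) -> tuple[float, float]:
    """Welch t statistic and p for two groups, degenerate cases handled."""
    a, b = groups
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        return (0.0, 1.0) if a.mean() == b.mean() else (float("inf"), 0.0)
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def subgroup_table(
    scores: pd.DataFrame,
    covariates: pd.DataFrame,
    grouping: str,
) -> pd.DataFrame:
    """Descriptive table of factor scores by one socio-demographic variable.

    For a categorical grouping the table holds, per factor and group level,
    ``n``, ``mean`` and ``sd``, plus a per-factor ``p`` from a Welch
    two-sample t-test (2 levels) or a one-way ANOVA (3+ levels).  For the
    continuous covariate ``age`` it holds the Pearson correlation
    coefficient and its t-test p per factor.  Groups with fewer than 2
    members keep their mean but have sd flagged missing and are excluded
    from the test.
    """
    if grouping not in covariates.columns:
        raise DataValidationError(f"unknown covariate {grouping!r}")
    g = covariates[grouping]
    continuous = pd.api.types.is_numeric_dtype(g) and g.dropna().nunique() > 10

    rows = []
    if continuous:
        x = pd.to_numeric(g, errors="coerce")
        for fac in scores.columns:
            pair = pd.concat([x, scores[fac]], axis=1).dropna()
            if len(pair) < 3:
                rows.append({"factor": fac, "corr_coeff": np.nan, "p": np.nan})
                continue
            r, p = stats.pearsonr(pair.iloc[:, 0], pair.iloc[:, 1])
            rows.append({"factor": fac, "corr_coeff": float(r), "p": float(p)})
        return pd.DataFrame(rows)

    levels = [lv for lv in g.dropna().unique()]
    for fac in scores.columns:
        groups, kept = [], []
        for lv in levels:
            vals = scores.loc[g == lv, fac].dropna().to_numpy(dtype=float)
            mean = vals.mean() if len(vals) else np.nan
            sd = vals.std(ddof=1) if len(vals) >= 2 else np.nan
            rows.append({"factor": fac, "group": lv, "n": len(vals),
                         "mean": mean, "sd": sd, "p": np.nan})
            if len(vals) >= 2:
                groups.append(vals)
                kept.append(lv)
        if len(groups) < 2:
            p = np.nan
        elif len(groups) == 2:
            _, p = _two_group_p(groups)
        else:
            if all(v.var(ddof=1) == 0 for v in groups):
                means = {v.mean() for v in groups}
                p = 1.0 if len(means) == 1 else 0.0
            else:
                _, p = stats.f_oneway(*groups)
        # attach p to this factor's rows
        for r in rows:
            if r["factor"] == fac and np.isnan(r["p"]):
                r["p"] = float(p)
    return pd.DataFrame(rows)


def significance_stars(p: float) -> str:
    """Star codes at the conventional levels 0.05 / 0.01 / 0.001."""
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class ScoreCorrelations:
    """Pairwise-complete correlation matrix of factor scores with stars."""

    r: pd.DataFrame
    p: pd.DataFrame
    stars: pd.DataFrame
    n_pairs: pd.DataFrame

    def render(self) -> str:
        """Lower-triangular fixed-width rendering with significance stars."""
        names = list(self.r.columns)
        width = max(len(n) for n in names) + 2
        lines = []
        for i, ni in enumerate(names):
            cells = []
            for j in range(i):
                v = self.r.iloc[i, j]
                cell = "   --  " if not np.isfinite(v) else f"{v:6.3f}{self.stars.iloc[i, j]:<3}"
                cells.append(cell)
            lines.append(f"{ni:<{width}}" + " ".join(cells))
        lines.append("Significance: * p<0.05  ** p<0.01  *** p<0.001")
        return "\n".join(lines)


def score_correlations(scores: pd.DataFrame, *, min_pairs: int = 3) -> ScoreCorrelations:
    """Pearson correlations between factor scores, pairwise-complete.

    Cells with fewer than ``min_pairs`` complete pairs are flagged missing.
    The diagonal is exactly 1 and the matrix symmetric by construction.
    """
    names = list(scores.columns)
    k = len(names)
    r = np.eye(k)
    p = np.zeros((k, k))
    n = np.full((k, k), len(scores))
    for i in range(k):
        for j in range(i):
            pair = scores[[names[i], names[j]]].dropna()
            n[i, j] = n[j, i] = len(pair)
            if len(pair) < min_pairs:
                r[i, j] = r[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
                continue
            if pair.iloc[:, 0].var() == 0 or pair.iloc[:, 1].var() == 0:
                r[i, j] = r[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
                continue
            ri, pi = stats.pearsonr(pair.iloc[:, 0], pair.iloc[:, 1])
            r[i, j] = r[j, i] = ri
            p[i, j] = p[j, i] = pi
    stars = np.vectorize(significance_stars)(p)
    np.fill_diagonal(stars, "")
    mk = lambda a: pd.DataFrame(a, index=names, columns=names)
    return ScoreCorrelations(r=mk(r), p=mk(p), stars=mk(stars), n_pairs=mk(n))
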