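# Methods

## Model

Ordinal confirmatory factor analysis with a probit link.  Respondent *i*
answers 20 five-point Likert items grouped into 8 factors.  Item *j*
(after reverse-coding flagged items so higher always means better) is
driven by a continuous latent response

    z_ij = lambda_j * eta_{i, f(j)} + eps_ij,   eps_ij ~ N(0, psi_j)

and the observed category is the ordered-cut-point bracket containing
z_ij (tau_{j,0} = -inf, tau_{j,C} = +inf).  Latent factors are
multivariate normal, eta_i ~ N_8(0, Phi), with free covariance.
Identification: latent-response means are 0 and one marker item per
factor carries loading 1.

Priors: loadings N(0, V) (V mode-dependent, below); residual variances
uniform on (0, 100); the factor *precision* Phi^-1 is Wishart with 10
degrees of freedom and scale I/10, so its prior expectation is the
identity; cut-points are flat on the ordered region.

## Sampler

Gibbs with data augmentation, fixed sweep order: latent responses ->
factors -> loadings -> [residual variances] -> factor covariance ->
factor-scale move -> [cut-points].  All conditionals are exact:

* z: truncated normal via inverse-CDF computed in log space
  (`log_ndtr`/`ndtri_exp`), stable arbitrarily deep in the tails;
  missing cells are drawn untruncated (the data-augmentation treatment of
  missingness, assumed completely at random).
* eta: one shared 8x8 Cholesky per sweep (the precision
  Phi^-1 + Lambda' Psi^-1 Lambda is respondent-independent once z is
  complete).
* loadings: conjugate normal regression updates; markers never move.
* residual variances (paper mode only): inverse-gamma kernel truncated to
  (0,100) by inverse-CDF.
* factor covariance: Wishart draw for the precision, df 10 + n.
* cut-points: exact uniform draws on the full-conditional bracket
  (between neighbouring cuts and the extreme latent responses of the
  adjacent categories; with the flat prior the conditional *is* uniform
  there, so this Metropolis move always accepts).

Two additional Metropolis scale moves are part of every sweep because the
componentwise updates cross two posterior ridges arbitrarily slowly:

1. **Factor-scale move.**  With the marker pinned at 1, scaling a
   factor's latent scores (and its covariance row/column) while inversely
   scaling its non-marker loadings changes the likelihood only through
   the marker item.  The move proposes that rescaling directly
   (log-normal multiplier; mixture of 90% sd 0.1 and 10% sd 0.5) and
   accepts on the marker-item likelihood, the loading and
   inverse-Wishart priors, and the transform Jacobian (the latent-factor
   prior cancels the eta Jacobian exactly).
2. **Item-scale move.**  For a high-communality item, scaling its cut
   vector together with its loading (non-markers; cuts only for markers)
   leaves the ordinal likelihood almost unchanged.  The move proposes the
   joint rescaling with the item's latent responses integrated out
   (probit likelihood given the current factors), redrawing them on
   acceptance; proposal mixture 90% sd 0.25, 10% sd 1.0, the wide
   component letting the chain hop between item-scale basins.

Both moves were validated against a deterministic grid-quadrature
posterior on a one-factor, two-item binary model (agreement within
Monte-Carlo error of mean and sd) and an isolated known-factor
cut-recovery oracle.

Randomness: one root seed; per-chain generators from `SeedSequence`
children, consumed in the fixed sweep order, so runs are exactly
reproducible.

## Identification modes and the loading prior

* **paper mode** keeps the stated priors literally (free residual
  variances with U(0,100), flat N(0, 1e6) loadings) and anchors each
  item's first and last interior cuts at their initialization values
  (standard-normal quantiles of the observed cumulative frequencies).
  Free cuts + free residual variance + free loading are jointly
  scale-redundant per item; the anchor removes that redundancy and
  effectively standardizes each item, which is what makes this mode
  robust at survey scale (tens of respondents).
* **probit mode** (default) is the textbook identification: residual
  variances fixed at 1, all cuts free.  Here the flat loading prior is
  *pathological*: jointly scaling an item's loading and cuts degenerates
  the item into a near-deterministic bin-indicator of its factor; the
  marginal likelihood approaches a plateau only a few dozen log-units
  below the mode while the ordered-cut volume grows polynomially, so an
  essentially flat prior puts most posterior mass at absurd loading
  scales.  Probit mode therefore defaults to a N(0, 25) slab — a penalty
  below 0.2 log-units anywhere up to loading 4 (≈95% communality), but
  tens of log-units in the degenerate regime.  The literal 1e6 variance
  remains available through `PriorSpec`.

A related intrinsic limit: the polychoric correlation between an item and
its factor's marker saturates as the loading grows, so for items with
communality ≥ 0.8 the data carry little information about the loading's
upper range.  Posteriors for such loadings are wide and right-skewed at
any realistic sample size (e.g. sd ≥ 0.5 at n = 800 under the default
truth), which is why the recovery experiment reports interval coverage
and dominant-item identification as its primary yardsticks; point
recovery of loadings near 3 to within a few tenths is not achievable at
these sample sizes by any method.

## Synthetic data

The generator draws factors (optionally shifted by socio-demographic
covariates, in factor-sd units), forms latent responses, cuts them into
categories, mirrors reversed items into raw orientation, and masks cells
completely at random.  The default truth uses: marker loadings 1; the
published non-marker loadings where the study reports them (2.83 feeling
tired, 2.92 feeling abandoned, 1.39 enjoy caring) and plausible values
consistent with its qualitative statements elsewhere; the published
8-factor score-correlation matrix (positive definite as printed) as the
latent correlation with common factor sd 0.7; unit residual variances;
right-skewed category distributions (0.05/0.10/0.25/0.35/0.25) scaled to
each item's latent sd; 2% missingness; n = 62.  Covariate margins follow
the study sample (64.5% women, age 59.3 ± 13.7, 28.9% low income, ...),
with moderate latent shifts reproducing its subgroup contrasts (women
lower on physical/psychological functioning, low income lower on
lifestyle value / social capital / material conditions, self-efficacy
rising with age).

What the generator does *not* emulate: informative missingness,
differential item functioning, response styles (straight-lining,
acquiescence), or cluster structure.  Passing recovery tests therefore
show the estimator works when its assumptions hold, not robustness to
their violation.

## Numerical choices

* Cut initialization: standard-normal quantiles of cumulative observed
  frequencies, clipped to [1e-4, 1-1e-4], epsilon-separated (1e-3) when
  adjacent categories are empty; an item with all mass in one category is
  rejected with advice to merge categories.
* Latent responses start mid-bracket (half a unit beyond the last finite
  cut for extreme categories); factors at 0; covariance at identity.
* Truncated inverse-gamma sampling by inverse-CDF with a 1e-8 floor;
  Wishart scale matrices re-symmetrized before and after inversion, with
  a Cholesky check surfacing any loss of positive definiteness.
* Chain defaults: 2 chains, 10,000 iterations, 5,000 burn-in, no
  thinning.
* Gelman-Rubin is the split-chain rank-normalized variant and effective
  sample size the bulk-ESS, both via arviz.
* Significance from draws is the two-sided posterior tail probability
  2*min(P(theta > t), P(theta < t)), starred at 0.05/0.01/0.001.
* Factor sd is reported as the posterior mean of sqrt(Phi_ff), not the
  square root of the mean variance.

## Problem sizes used in the test-suite experiments

The tiny-oracle comparison runs 2 chains x 25,000 iterations at n = 30;
the recovery experiment n = 800 with 2 x 10,000 iterations; the
correlation null/power experiments n = 800 with 500 retained draws;
moment-level oracles use 20,000-50,000 draws.  These sizes put
Monte-Carlo error comfortably inside each test's tolerance while keeping
the full suite runnable on a laptop-class single core.

## Known limitations

* Scores and alphas use listwise/pairwise deletion; only the Bayesian
  layer models missingness.
* MCAR missingness is assumed throughout.
* No regression structure on the factors (covariates only *generate*
  shifts in simulation; the fitted model has correlated factors only).
* The subgroup tables apply no multiple-testing correction.
* Single-site cut updates plus the two scale moves mix well at
  questionnaire scale (20 items, 5 categories) but are not tuned for
  hundreds of categories or items.
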