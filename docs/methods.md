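# Methods

## The problem and the model

The package measures *misutilization* of a hospital resource — a specific
imaging study during in-patient visits — when no clinical gold standard of
appropriateness is available.  Appropriateness is replaced by *industry
standard practice*: a visit is misutilized when its actual use of the
resource disagrees with what a risk-adjustment model, fitted to the whole
industry's visits, expects at a calibrated probability threshold.  The
approach is forensic (after the visit), not a bedside decision rule.

### Risk adjustment

Let `yᵢ ∈ {0,1}` indicate use of the outcome resource in visit *i*.  We fit

    logit P(yᵢ = 1) = β₀ + xᵢᵀβ

by maximum likelihood (IRLS, via statsmodels' binomial GLM), where `xᵢ`
contains dummy-coded patient categoricals (reference levels: White for
race, Medicare Traditional for payor, otherwise the modal level), binary
comorbidity flags, length of stay as an untransformed continuous term, and
the seven competing-resource bits.  Three covariate sets are exposed:
(a) patient + resources, (b) patient only, (c) resources only.  Set (a)
nests (b) and (c), so its log-likelihood bounds theirs — an invariant the
tests assert.  Near separation (|β| > 15) the fit is stabilized with a
tiny ridge penalty (1e-8) and a warning; Wald standard errors then come
from the unpenalized Hessian at the stabilized estimate.  Hard
non-convergence raises.

Category collapsing precedes fitting, mirroring standard administrative
practice: charity/indigent payors merge; age-group levels wholly at or
below 45 merge; discharge-status levels with strictly less than 0.1% share
move to 'other'; comorbidity flags and MS-DRG levels need at least 500
visits to stay (low-count MS-DRGs pool into a catch-all level).  The share
rule is strict-less-than and the count rule inclusive, matching the
conventional reading of those thresholds; collapsing is idempotent.

### Discrimination

AUC is the Mann–Whitney statistic with ties counted ½, computed by
midranks.  Its variance and the paired model comparison use DeLong's
structural components: for events `X` and non-events `Y`,
`V₁₀ᵢ = mean_j ψ(Xᵢ, Yⱼ)`, `V₀₁ⱼ = mean_i ψ(Xᵢ, Yⱼ)`, and
`Var(AUC) = S₁₀/m + S₀₁/n`.  The implementation is checked against an
O(n²) pair-counting oracle (exact to 1e-12) and a 2000-resample paired
bootstrap of the difference variance (within 15%).

### Joint usage patterns and tetrachorics

The seven competing resources define 2⁷ = 128 possible usage bitstrings
(fixed alphabetical resource order for reproducibility).  Outcome-rate
homogeneity across *observed* patterns is tested with a Pearson chi-square
without continuity correction; degrees of freedom count observed patterns
only, and expected counts below 5 are logged, not fatal.  Pairwise
dependence is summarized by tetrachoric correlations: thresholds are set
from the margins and ρ maximizes the bivariate-normal multinomial
likelihood over [−0.999, 0.999] (1-D bounded search; the bivariate normal
CDF comes from scipy).  ML was preferred over the cosine approximation
because it can be validated against a copula simulation oracle.  Pairs
with an empty margin are flagged undefined rather than raised.

### Decision analysis

Net benefit at threshold *t* is `TP/n − FP/n · t/(1−t)`; treat-all and
treat-none are the comparators (`NB_all(t) = π − (1−π)·t/(1−t)`,
`NB_none ≡ 0`, π the outcome prevalence).  The grid is 0.001 steps over
(0, 0.99], matching the two-decimal resolution at which value ranges are
reported.  The operating threshold is the grid point, inside the range
where the model strictly beats both comparators, whose flagged share
`P(p̂ ≥ t)` is closest to the observed utilization intensity (cohort
prevalence); ties go to the smaller threshold.  Visits exactly at the
threshold count as expected use (≥), a declared convention.  The
calibration target can instead be a subset of reference facilities
("industry leaders") by fitting the model on that subset.

Labels: over-utilized = used ∧ p̂ < t; under-utilized = unused ∧ p̂ ≥ t.
The four label counts always partition the cohort, and
mis = over + under at both visit and facility level.

### Disparities

For each characteristic level the odds ratio of carrying the under- (or
over-) utilization label, relative to a reference level, comes from a
logistic regression of the label indicator on the characteristic's
dummies.  The default is unadjusted (one characteristic at a time),
matching the tabular presentation this mirrors; a covariate-adjusted
variant is available via `adjust_columns`.  All visits form the
denominator for both label kinds so the two ORs are comparable.  Levels
with zero (or all) events yield flagged rows with undefined CIs instead of
exceptions.

### Facility profiling

Under the null of a common per-visit misutilization rate, facility *f*'s
count `c_f` is Poisson(λ̂·v_f) with λ̂ = Σc/Σv — the MLE of an
intercept-only Poisson rate model with volume exposure (verified against
an offset-GLM oracle).  The flag criterion is the exact upper tail
P(X ≥ c_f) < α (default α = 0.01, no multiplicity correction;
Benjamini–Hochberg available behind a flag).  The exact tail was chosen
over a per-facility Wald z because it remains valid at small volumes and
is reproducible to machine precision; it is conservative on discrete
counts, so the null flag rate sits at or below α.  The pooled rate
includes the facility under test by default (leave-one-out available).
Rankings are deterministic: p ascending, rate descending, facility id.
Facility rates (in percent) are regressed on natural-log volume by
unweighted OLS.

## Synthetic cohort generator

The generator emulates a single-disease, visit-level all-payor extract:

- **Facility volumes**: log-normal weights (defaults: log-mean 3.2,
  log-sd 1.0 — right-skewed, median facility a few dozen visits) turned
  into integers by proportional allocation with largest-remainder
  rounding and clamped to ≥ 1, so the total matches the target within the
  facility count and the degenerate log-sd → 0 limit yields equal volumes.
- **Covariates**: i.i.d. draws from configured marginals.  Defaults follow
  the descriptive profile of a 2019 U.S. prostate-cancer in-patient cohort
  of ~51k visits: ~72% of patients over 65, ~72% White, 43% Medicare
  Traditional, and so on; length of stay is gamma with mean 4.57 / sd 5.44
  days.
- **Competing resources**: a 7-variate latent Gaussian with configurable
  correlation (default compound symmetry, ρ = 0.25) thresholded at
  quantiles matching the configured prevalences — so the *tetrachoric*
  correlations, the quantity the analysis estimates, equal the latent ones
  exactly, with exact marginals.
- **Outcome**: Bernoulli with logit = intercept + Σ coefficients, so
  covariate set (a) is well specified.  The default intercept (−3.88) was
  calibrated once by Monte-Carlo so the default coefficient set yields a
  marginal outcome prevalence near the 11.7% intensity the cohort profile
  implies, and then frozen.
- **Planted outliers** multiply (mode "over") or divide (mode "under") a
  facility's outcome odds, leaving case mix untouched — so outlier
  recovery is a pure test of the volume-adjusted flagging, not of the risk
  adjustment.  Ground-truth expected-use labels use the *unshifted*
  probability.

What the generator does **not** emulate: within-facility case-mix
clustering (configurable but off by default — the emulated design does not
state any), ICD/MS-DRG code structure, LOS–cost joint distributions, or
seasonal effects.  Passing tests therefore demonstrate the statistical
machinery under a well-specified logistic world with independent visits;
they do not certify behaviour under model misspecification or clustered
real claims data.

## Problem sizes and numerical choices

The test suite exercises cohorts up to 50,000 visits / 400 facilities and
the acceptance script runs at 1056 facilities / ~51,111 visits — the scale
the cohort profile describes.  Coefficient recovery is checked over 20
seeds (≥95% of coefficients within 3 SE); outlier recovery over 50
replicates of 10 planted 3×-rate facilities among 1000 nulls (sensitivity
≥ 80%, null flag rate ≤ 2% at α = 0.01).  IRLS runs to tol 1e-10 with the
score equations checked at max-norm 1e-6; tetrachoric search tolerance is
1e-6; AUC matches pair counting to 1e-12; Poisson tails match pmf
summation to 1e-10.

## Known limitations

- Classical (homoskedastic) OLS intervals for the rate-vs-log-volume slope
  run slightly below nominal coverage (~85–90% observed) because binomial
  noise inflates the variance of small-volume facility rates; the slope
  itself is unbiased.  A weighted or robust-variance regression would fix
  this but would no longer be the plain regression this package mirrors.
- Unadjusted disparity ORs conflate group composition with group effects;
  the adjusted variant is provided but causal interpretation is out of
  scope.
- The exact Poisson flags assume counts are independent across visits;
  within-facility correlation would make them anti-conservative.
- The common-rate null treats the industry average as the benchmark;
  facilities are flagged for *difference from peers*, not clinical
  inappropriateness.
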