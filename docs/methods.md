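# Methods

## The model

`bsclock` predicts chronological age `Y` from per-CpG methylation betas
`X_1..X_p` and, optionally, binary disease indicators `D_1..D_q`
(one-hot over the disease vocabulary, with `normal` as the dropped
reference level):

    Y_hat = b0 + sum_i b_i * X_i + sum_j g_j * D_j

fit by minimizing the Elastic Net objective

    (1/2n) * sum (Y - Y_hat)^2  +  lam1 * sum_i |b_i|  +  lam2 * sum_i b_i^2 .

Both penalty sums run over the *site* coefficients only. The intercept
and the covariate coefficients are never penalized: shrinking `g_j`
toward zero would bias exactly the quantity the covariates exist to
measure, and an unpenalized `g_j` is directly interpretable as an age
shift in years. The covariate-free variant ("Model 2") is the identical
objective with `q = 0`, and the implementation treats it as such — the
two variants agree coefficient-for-coefficient when the covariate matrix
is empty.

Site columns are standardized to zero mean and unit variance on the
training samples; the means and scales are stored in the fitted model,
which makes predictions invariant to affine rescaling of any input
column. Ages are left unscaled.

### Solver

The site block at fixed intercept/covariates is a standard Elastic Net
problem and is solved with scikit-learn's coordinate descent, using the
mapping `alpha = lam1 + 2*lam2`, `l1_ratio = lam1 / alpha` between this
package's penalty pair and scikit-learn's parameterization. Because no
off-the-shelf solver leaves a coefficient subset unpenalized, the full
model alternates two exact block solves — coordinate descent on the site
block, least squares on the intercept+covariate block — until the joint
parameter change falls below 1e-9 (capped at 500 rounds). The objective
is convex and the nonsmooth L1 term is separable within one block, so
this block descent converges to the global minimum; the test suite
verifies the KKT stationarity conditions of the result. With `lam1 =
lam2 = 0` the problem must be overdetermined (`n > p + q + 1`) and is
solved by ordinary least squares; a pure ridge site block (`lam1 = 0`)
uses its closed form.

### Covariate sign convention

The model is trained against *chronological* age. If a disease makes
methylation look `delta` years older, then conditional on the
methylation profile a diseased sample is `delta` years *younger*
chronologically, so the fitted regression coefficient converges to
`-delta`. The disease's effect on epigenetic age — the quantity aging
studies report — is therefore the *negated* coefficient, and
`covariate_ci` returns both views (`coefficient` and `age_effect`, each
with bounds). Forest-plot style statements such as "lymphoma accelerates
aging" refer to the `age_effect` column.

## Feature selection

1. **Coverage filter.** Keep sites with at least `min_coverage` reads in
   *every* sample (default 50; an inclusive ≥ rule, switchable to
   strict). The default suits deeply sequenced cohorts; for a cohort
   whose mean depth is near the threshold the filter should be relaxed —
   counting noise alone makes a site with mean depth `m` fail an
   every-sample threshold `c` unless `m` exceeds `c` by several Poisson
   standard deviations, so at mean depth 60 a threshold of 50 would
   discard most of the genome regardless of biology. The recovery tests
   and the acceptance script therefore filter their depth-60 synthetic
   cohorts at 20 reads.
2. **Correlation filter.** Spearman correlation (average ranks for ties;
   zero-variance sites get correlation 0) between each site's beta and
   age; keep `|rho| > min_abs_correlation` (default 0.2, strict).
   Pearson is available by flag. Both filters are monotone: a stricter
   threshold always yields a subset.
3. **Penalty tuning.** 10-fold cross-validation over a grid of
   `(lam1, lam2)` pairs on the filtered matrix (the filtered matrix, not
   the genome-wide one — tuning on millions of unfiltered sites would be
   both circular and computationally pointless). The default grid
   crosses mixing ratios {0.1, 0.3, 0.5, 0.7, 0.9, 1.0} with 20
   log-spaced total-penalty values per ratio, from the smallest value
   that zeroes every coefficient down to 1e-3 of it. Exact ties on CV
   error resolve toward the strongest total penalty, then the
   lexicographically smallest pair — determinism plus parsimony.
4. **Stability selection.** `B` bootstrap resamples (default 500), each
   drawn with replacement and fit at the tuned penalties; a site's
   selection frequency is the fraction of fits in which its coefficient
   is nonzero, and the final set is `{frequency > f}` (default 0.5,
   strict). Replicate `b` is seeded from `(master seed, b)`, so results
   do not depend on execution order; a degenerate resample with constant
   age is redrawn (logged) so `B` stays fixed. Setting `lam2 = 0`
   reproduces a LASSO-style, more aggressive reduction.

## Evaluation protocol

Leave-one-out cross-validation: for each sample, penalties are re-tuned
by inner 5-fold CV on the remaining `n-1` samples (skipped when the
supplied grid has a single pair), the model is refit on those `n-1`, and
the held-out sample is predicted. The held-out sample's age is never
visible to its own fold — the suite includes a leak-detector test that
corrupts one sample's age and verifies its held-out prediction does not
move. Samples are processed in id-sorted order and each fold's inner
seed derives from `(master seed, sample id)`, making results invariant
to input row order.

Accuracy is summarized by the Pearson correlation `r` between predicted
and chronological ages and the mean absolute error in years. Per-fold
covariate coefficients are summarized by their mean and empirical
2.5/97.5 percentiles (linear interpolation); note these folds overlap in
`n-2` samples, so the interval reflects fit stability across folds, not
an independent-sampling confidence interval — a normal-approximation
alternative is available by flag.

Aging rate is `predicted / chronological` (defined for positive ages)
and age discrepancy is `predicted - chronological`; they satisfy
`discrepancy = chronological * (rate - 1)` exactly. Group contrasts use
the two-sided Mann–Whitney U test by default (rates are ratios with
skewed distributions; Welch's t by flag), computed exactly by
enumerating group assignments when the pooled sample is small (≤ 18,
correct under ties) and by the tie-corrected normal approximation
otherwise. Ten-year age bins are left-closed `[a, a+10)` anchored at 0.
Raw p-values are reported; a Benjamini–Hochberg flag exists but is off
by default.

Cross-tissue application of a trained clock imputes model sites absent
from the target matrix (and missing cells) with the training-mean beta,
refusing to predict when more than half the model's sites are absent
(configurable). Imputed counts are logged and surfaced by the CLI.

## The synthetic cohort generator

Each sample draws a chronological age uniformly from the configured
range (default 1–85 years), a sex, and a disease label from the
configured prevalences (remainder `normal`). Its *latent epigenetic age*
is

    A = age + offset(disease) + Normal(0, noise_sd)

with `noise_sd` defaulting to 3 years. Disease acts on latent epigenetic
age, in years — the only construction under which covariate recovery has
a crisp known target. A causal site `s` tracks the latent age linearly,

    mu_s(A) = clip(b_s + slope_s * A / 100, 0.01, 0.99),

with slope magnitudes drawn from the configured range (default 0.3–0.6
beta-units per 100 years, random sign); non-causal sites have an
age-independent mean. Causal baselines `b_s` are drawn so the mean track
stays within [0.05, 0.95] across the whole age range — otherwise
clipping would silently flatten the stated slope at the extremes.

Coverage is drawn per (sample, site) as `C = 1 + Poisson(m_s)` with the
per-site mean depth `m_s ~ Gamma(shape = dispersion, mean = mean_coverage
- 1)` — marginally a shifted negative binomial (defaults: mean 60,
dispersion 16). The observed beta is `Binomial(C, mu) / C`: binomial
counting noise rather than Gaussian noise on the beta, which is what
makes coverage thresholds meaningful and reproduces the
variance-shrinks-as-1/C behavior of real sequencing. Everything is
deterministic given the config seed.

The multi-tissue generator shares one sample roster across tissues and a
configurable fraction of causal sites (identical slopes); each tissue's
remaining causal sites come from disjoint pools, so the ground-truth
causal overlap equals the configured fraction exactly. Latent ages and
read draws are tissue-specific.

What the generator does *not* emulate: genomic coordinate structure and
between-site correlation beyond the shared age signal (sites are
independent given latent age), cell-type composition and its
deconvolution, batch effects, and nonlinear methylation–age
trajectories. Passing recovery tests therefore demonstrates that the
pipeline's machinery is correct under its own model assumptions — not
that those assumptions hold in any particular real cohort.

## Reference problem sizes

The recovery checks run at 200 samples × 2000 sites with 100 causal
sites, mean depth 60, and 3-year latent noise; stability selection there
uses B = 100 bootstraps in the test suite and B = 500 in the acceptance
script; LOOCV tuning uses a reduced grid (8 total-penalty values × 3
mixing ratios). Covariate recovery uses 20 replicates of 150 samples ×
250 sites with a +5-year disease at prevalence 0.3, tuning once globally
per replicate (10-fold) and running LOOCV at the fixed pair.
Cross-tissue contrast uses 5 seeded pairs of 80 × 400 cohorts with
disjoint causal sets. These sizes keep every property of interest
measurable — recall, prediction accuracy, covariate CIs, transfer
failure — at desk-scale runtimes; all of them are configurable.

## Known limitations

- The mHap-style parser handles the plain 6-column text dialect only and
  assumes minus-strand records are already projected to forward-strand
  CpG coordinates by upstream tooling; it does not implement the binary
  compression codec, read mapping, or methylation calling.
- The clock is linear; saturating or nonlinear methylation–age
  trajectories are approximated at best.
- Covariate CIs are fold-stability intervals (see above), matching the
  LOOCV-coefficient summary convention rather than a bootstrap over
  cohorts.
- The accuracy-vs-site-count curve ranks sites by correlation on the
  full cohort before LOOCV, so the site *ranking* (not the fitting) sees
  all ages; this mirrors the usual construction of such curves and
  slightly flatters small-m points.
- With heavily correlated informative sites, stability selection at
  near-ridge tuned penalties keeps correlated groups together; it
  controls noise inclusion, not redundancy.
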