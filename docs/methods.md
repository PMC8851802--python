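# Methods

This note records the models, conventions and numerical choices behind
`u5dgap`, in the order the pipeline applies them, together with what the
synthetic validation does and does not establish.

## Data model and recoding

The unit of analysis is a live birth. `died_u5` is 1 if the child died
within 0–59 months of birth. Covariates are categorical with fixed
canonical labels (see `data_model.COVARIATE_CATEGORIES`); a codebook maps
arbitrary source columns and category codes onto them, so survey-specific
naming lives in configuration, not code. Two derived variables have
explicit rules: the preceding birth interval is cut at 36 months
(firstborns are their own category), and housing quality is a composite
that is "improved" only when floor, wall and roof materials all are.

Missing covariate values are flagged, not imputed; every analysis uses
complete cases for exactly the variables it needs and logs the exclusions.
Records missing the outcome, sex, or a positive sampling weight are dropped
at read time and counted.

The packaged country summary table stores the published per-country sample
sizes, percent male and per-1000 death rates verbatim (integers per 1000;
percent male to one decimal). Regional subtotal and grand-total rows are
flagged rather than re-derived, and load-time checks enforce the published
totals (59 countries, 856,987 children, 66,495 clusters).

## Reconstructing 2×2 tables from printed summaries

When only the summary table is available, each country's sex-by-death table
is rebuilt as `n_male = round(n·pct_male/100)`, `male_deaths =
round(n_male·rate_male/1000)` (round-half-up, deaths capped at the margin),
and likewise for females. Recomputing rates from the rebuilt tables
reproduces every printed rate to within 0.5 per 1000, which bounds the
rounding error this reconstruction can introduce into pooled statistics.
The reconstruction cannot recover sampling-weight or design information, so
statistics that were computed on weighted microdata are only approximated.

## Inequality statistics

- Prevalence: `1000·Σw·y / Σw` over any subgroup.
- Risk difference per 1000 with the binomial Wald variance
  `p_m(1−p_m)/n_m + p_f(1−p_f)/n_f` and a pooled-variance z-test.
- Weighted tables use sampling weights as frequency-style weights for
  point estimates; variances use Kish effective counts `(Σw)²/Σw²` per
  sex, so rescaling all weights changes nothing and unequal weights
  reduce effective precision. This convention is ours (survey
  linearization variances are out of scope) and is configurable by
  passing unweighted tables.
- Mantel–Haenszel pooled OR with the Robins–Breslow–Greenland variance.
  A 0.5 continuity correction is applied to a stratum's cells only when a
  zero cell would otherwise block a crude log OR.
- Heterogeneity of ORs: Cochran's Q on log ORs with inverse-variance
  weights (default) or the Breslow–Day statistic around the MH OR;
  `I² = 100·max(0,(Q−df)/Q)`.
- Random-effects meta-analysis of RDs: DerSimonian–Laird τ² floored at
  zero; fixed effect by inverse variance; random effect with weights
  `1/(v_i+τ²)`.
- Four-quadrant classification: prevalence high/low against a threshold
  (default: the median country prevalence, since no absolute cut is
  canonical), inequality direction by RD sign, significance by the RD CI
  excluding zero.

## Neighborhood SES index

Cluster-level proportions of mothers with no education, households in the
two lowest wealth quintiles, no media access, and unemployment are
aggregated unweighted ("share of respondents in the cluster"). The index
is the first principal component of the four standardized proportions —
i.e. PCA on their correlation matrix, the conservative choice when inputs
share a scale but not necessarily a variance — with the sign fixed so that
larger scores mean more disadvantage (positive correlation with the mean of
the four proportions; PCA sign is otherwise arbitrary). Quintiles use
nearest-rank 20/40/60/80th percentile boundaries with ties kept in the
lower category, matching common survey-software behavior; 1 = least
disadvantaged, 5 = most.

## Collinearity screening

Categorical covariates enter as reference-coded dummies. Each coded column
is regressed on all the others (with intercept); VIF = 1/(1−R²), and a
variable's VIF is the worst over its dummies. Variables are dropped when
VIF exceeds 2.5 *strictly* (a value numerically equal to the threshold is
kept), worst-first with recomputation after each drop so one collinear pair
cannot cascade into over-removal. An explicit exclusion list supports
dropping variables for availability rather than statistical reasons.

## The decomposition

Group A is male, group B female. The two-term split uses group-fitted
maximum-likelihood logits; because a weighted logit MLE with an intercept
mean-matches its sample, explained + unexplained equals the observed
weighted gap to numerical precision (checked to 1e−8).

Detailed contributions use the sequential-substitution procedure:

1. **Pooled coefficients.** A logit on the concatenated sample, including
   a sex indicator (the standard recommendation for pooled reference
   coefficients; switchable). Substitution predictions set the indicator
   to its reference level, so both sides of every difference share one
   consistent response surface. Sampling weights enter the fit; matching
   and pair means are unweighted (the reference procedure is silent on
   weights in matching).
2. **Matching.** The larger group is uniformly subsampled to the smaller
   group's size; both groups are sorted by predicted probability and
   paired rank-to-rank.
3. **Substitution.** Walking the covariates in an ordering, variable k's
   contribution is the change in the mean predicted probability over pairs
   when its paired B values are replaced by A values (visited variables
   hold A's values, unvisited hold B's). Categorical variables switch as
   whole dummy blocks. Contributions telescope exactly (1e−10) to the
   matched explained term for every ordering.
4. **Replication.** D = 100 replications by default, with fresh subsample
   draws and (by default) fresh random orderings; reported values are
   replication means, SEs are replication SDs, and percentages are given
   against both the total gap and the explained term, since both
   normalizations appear in applied work and neither is canonical.
   Seeds are mandatory and recorded in the output.

With the identity link the same code path reproduces Blinder–Oaxaca
`β_k(X̄_A,k − X̄_B,k)` exactly, for any D and ordering — an exact oracle
used in the tests. Delta-method standard errors and probit links are out
of scope, and no normalization for categorical reference-level dependence
is applied (contributions of dummy blocks depend on the chosen reference
levels; users comparing specifications should keep references fixed).

## Synthetic data and what the oracles mean

The generator emulates a two-level survey: children in clusters in
countries, death Bernoulli with
`logit p = α_country + b_cluster + s·1[male] + η(x)`,
`b_cluster ~ N(0, σ²)`, covariate categories drawn from sex-specific
probability vectors, gamma(4) sampling weights with mean one (weights
never enter the outcome model, so all truth quantities are
weight-invariant). The default scenario is a desk-scale version of a
59-country pooled analysis: 10 countries × 50 clusters × 30 children,
marginal mortality 51/1000 (the intercept is solved numerically for the
target), cluster SD 0.3, sex effect s = 0.10 and a male-shifted
birth-weight composition, giving a population pro-male gap of 7.0/1000
(2.5 explained, 4.5 structural).

Two distinct population "truths" are computed from the generator's own
parameters, with the cluster effect integrated by 41-node Gauss–Hermite
quadrature:

- **Single-covariate swaps** (`method="swap"`): change one covariate's law
  from female to male, all else at the female law, by exact enumeration of
  the finite covariate space (Monte Carlo above 200k patterns). This is
  the natural "independent contribution" quantity and the one used in the
  construction-style checks.
- **Matched-procedure value** (`method="matched"`): the large-sample limit
  of the estimator itself — male- and female-law draws comonotonically
  coupled on the true risk score, contributions averaged over all variable
  orderings. The ordering average is computed exactly as a Shapley value
  over the 2^k switch subsets, which removes ordering noise; rank coupling
  makes pairs dependent, so the Monte-Carlo error is estimated across
  independent batches, not across pairs.

These two truths differ systematically (for the default scenario the
birth-weight contribution is 2.32/1000 under independent swaps but
2.75/1000 under the matched procedure): rank matching correlates the
substituted values with the partner's risk, and the logistic response turns
that correlation into a larger mean change. Parameter-recovery validation
therefore compares the estimator to the matched-procedure truth — the
estimand it actually targets — and passes within Monte-Carlo error over 200
desk-scale replicates at D = 100. Users should read reported contributions
as matched-procedure quantities, not as independent law swaps.

The simulator does not model survey nonresponse, recall bias, age heaping,
informative weights, or within-cluster covariate correlation; passing
recovery tests therefore demonstrates correctness of the estimator under
the stated model, not robustness to those real-data features.

## Pipeline conventions

Stage order: recode → SES quintiles → per-country prevalence/RD/z-test →
MH OR + heterogeneity → RD meta-analysis → quadrant table → selection of
countries with a significant pro-male OR (OR > 1, p < α; an RD-based
switch exists) → VIF screen on the pooled selected countries →
per-country decomposition. Every stage logs inputs, exclusions and seeds;
all artifacts are plain CSV/JSON without timestamps, and a re-run with the
same configuration and seed is byte-identical. Per-country decomposition
seeds are drawn sequentially from the run seed over the alphabetically
sorted selection, so a country's result is reproducible given the same
configuration but will change if the selected set changes.

## Known limitations

- Variance conventions for weighted 2×2 tables are effective-count
  approximations, not design-based estimates.
- Reconstruction from printed per-1000 rates carries rounding of up to
  0.5/1000 per cell into pooled statistics; borderline significance
  decisions (p near 0.05) can flip relative to analyses of the underlying
  microdata, and heterogeneity statistics are particularly sensitive to a
  few extreme strata.
- Contributions from the sequential procedure are reference-level and
  coupling dependent (see above); they sum to the explained term but their
  apportionment is a convention.
- The desk-scale default trades Monte-Carlo precision for speed; per-run
  decomposition SEs at 15k children are large relative to true
  contributions, and conclusions should rest on replication averages.
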