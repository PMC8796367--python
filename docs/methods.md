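# Methods

## Model

A sample mapping pairs one individual's phenotype record (trait
measurements, age, reported sex) with one genotype record (polygenic
scores, genotype-inferred sex). The provided mappings are assumed mostly
correct; a mix-up is a row whose genotype record belongs to a different
individual. Detection rests on a two-population contrast: per trait, the
residual of the phenotype with respect to its PGS-based prediction is drawn
from a narrower distribution when the mapping is correct than when the
genotype is foreign. Pairing each phenotype row with randomly chosen other
genotype columns ("permuted mappings") gives an empirical sample of the
mix-up residual distribution without needing any labelled mix-ups; on
simulated cohorts a Kolmogorov–Smirnov test cannot distinguish permuted
residuals from the residuals of genuinely deranged samples (see
`tests/test_mapping.py`).

Per-trait regressions use the phenotype's own data type: ordinary least
squares for quantitative traits, logistic regression for binary traits and
a proportional-odds ordered logistic model for ordinal traits (statsmodels
implementations). Covariates are age (mean-centred at fit time; the centring
constant is stored with the model), sex, and age×sex — these effects are
usually regressed out of GWAS summary statistics and therefore are not
carried by the PGS itself. Linear residuals are signed raw residuals.
Logistic-family residuals are deviance residuals √(−2 ln P_obs) of the
model's probability of the observed outcome; the ordinal case applies the
same formula to the observed category's predicted probability, which
reduces exactly to the binary form at two categories. Binary and ordinal
residuals are used unsigned: the downstream histogram likelihoods are
sign-agnostic, and no principled sign exists for K > 2. Predicted
probabilities below a floor (default 1e-12) are clamped, with a warning,
to keep residuals finite.

## Likelihood models and LLRs

Quantitative traits: Gaussian densities with the sample mean and sd
(ddof=1) of each residual arm. Binary/ordinal traits: histogram densities
on equal-width bins over the provided-residual range. The initial bin count
is ⌊n/avg_per_bin⌋ (at least two); terminal bins absorb their neighbours
until they hold at least min_per_bin provided samples; any interior bin
still below the minimum is split at its midpoint with each half merged into
its nearest neighbour, processed left to right and re-checked after every
merge until stable. Defaults: 80 average and 10 minimum provided samples
per bin. An equal-frequency scheme (quantile breaks, per-bin counts within
one) is available for comparison, as is binning for quantitative traits.
Breaks always come from the provided arm only and are applied unchanged to
the permuted arm; residuals outside the break range fall into the nearest
terminal bin. Bin masses are Laplace-smoothed with pseudo-count one per bin
in both arms — this keeps every LLR finite, is negligible at the default
occupancies, and still normalises exactly.

The LLR of residual r is ln(f_permuted(r)/f_provided(r)), oriented so
positive values favour the mix-up hypothesis. For ordinal traits one
density pair is fitted per observed phenotype category (the category is a
property of the phenotype row, so it is shared by a row's provided and
permuted entries); categories with too few provided residuals to bin are
excluded and score zero, with a warning.

## Aggregation, scaling, sex check

Traits are screened with a one-sided Welch t-test (permuted LLRs greater
than provided; default α = 0.05, no multiplicity correction — a deliberately
permissive filter whose only job is to drop uninformative traits). LLRs of
the selected traits are summed per sample over the traits available for
that sample; a permuted pair contributes to a row's permuted sums only if
it was scored in every trait used for that row, so both sums cover the same
trait set. Each row's summed LLR is then z-scored against the mean and sd
of its own permuted sums, putting samples with different trait availability
on one scale ("row-permuted" scaling; a global across-samples z-score is
available behind `scaling="across_samples"` for sensitivity analysis).
Samples with fewer than min_traits_used (default 3) usable traits are
flagged `insufficient_data` rather than trusted.

The sex check is converted into the same LLR currency: a random swap
crosses sexes with probability 2 f_m (1 − f_m) (f_m = male fraction), while
a correct mapping mismatches only through assay error ε (default 0.001), so
a mismatch contributes ln(2 f_m(1−f_m)/ε) and a match
ln((1−2 f_m(1−f_m))/(1−ε)); unknown genotype sex contributes zero. The
combined score is the scaled trait LLR plus the sex LLR — additive because
both are log-likelihood ratios of independent evidence.

## Mix-up budgeting

With the sex check catching the fraction 2(1−f_m)f_m of random swaps, the
flagged count inflates to an estimate of the total swap count and, after
subtracting everything already removed, of the residual cohort rate:
mr_estimated = (swaps_sexcheck/(2(1−f_m)f_m) − swaps_total)/N, clamped at
zero. For a candidate threshold (each sample's own score), the sensitivity
s is the fraction of permuted-pair scores strictly above it; the expected
rate among the n_pass samples at or below it is
mr_pass = mr_estimated·(1−s)·N/n_pass — the undetected share of the
expected mr_estimated·N mix-ups spread over the passers. This reading is
fixed by its limit cases: s = 1 must give zero, and s = 0 with n_pass = N
must return mr_estimated. A sample passes iff its mr_pass is below the
configured maximum rate (default 0.01%, the strict end of the diagnostic
mix-up range; `select --max-mixup-rate` accepts fractions or percentages).
Pass decisions are made per sample; under score distributions where
mix-ups dominate, the passing set is a contiguous lower tail of the
ranking.

## Permutation budget

The full permuted matrix is quadratic in cohort size, so each phenotype row
draws at most permutation_cap (default 1000) distinct foreign genotype
columns without replacement, independently per row; `--full-permutations`
restores the complete off-diagonal. The likelihood fits only need a stable
estimate of the permuted distribution, and in practice 50–200 pairs per
row are indistinguishable from the full matrix for AUC purposes. One pair
set is drawn per run and shared by all traits so that summed permuted LLRs
are defined over a common pair set.

## Synthetic cohorts

The generator draws per-trait PGSs and latent noise from a joint Gaussian
with a configurable cross-trait correlation matrix, then assembles each
latent phenotype as L = r·PGS + a·age_z + s·sex_z + i·age_z·sex_z + c·noise
with c chosen so Var(L) = 1, making corr(PGS, L) = r exactly on the latent
scale. Binary and ordinal phenotypes threshold the latent value (Gaussian
copula construction). Ages are uniform on 18–80 years; sex is Bernoulli
with configurable male fraction. Two experiment knobs: `power_factor`
rescales every target correlation via r' = sign(r)·√(tanh(factor·atanh(r²)))
(identity at 1, bounded in (−1,1)); `n_copies` duplicates the panel
block-diagonally, sharing covariates but nothing genetic across copies.
Mix-ups are induced by a single-cycle (Sattolo) derangement of the
genotype-side data — all PGS columns and genotype sex move together — within
a randomly selected subset, so every selected sample is genuinely
mismatched.

The default panel is a synthetic stand-in for a biobank trait battery:
20 quantitative traits with PGS-explained variance spread over ~3–34%,
four binary conditions (prevalences 5–15%) and one 3-level ordinal trait,
with exchangeable correlations (ρ = 0.35) inside three plausibility
clusters. It reproduces the *structure* the detector relies on — mixed
data types, correlated traits, covariate effects — but not any real
cohort's marginals, missingness patterns, phenotype measurement error or
population stratification. Passing tests therefore demonstrate internal
correctness and the expected qualitative behaviour (AUC rising with PGS
power and trait count, calibrated subset selection under the generator's
assumptions), not field performance on real data.

## Evaluation protocol

Discrimination is measured by simulating a clean cohort, splitting it in
half, deranging a fraction (default 50%) of the test half, fitting all
models on the clean training half only — including trait selection, to
avoid leakage — and computing ROC curves for three predictors: the scaled
trait LLR, the bare sex check, and the combined score. AUC is trapezoidal
with half credit for ties (equal to the Mann–Whitney probability; verified
against brute-force enumeration). The budgeting calibration experiment
instead induces 1% mix-ups, removes the sex-flagged samples, estimates
mr_estimated from the flagged count, selects at a maximum rate using the
trait-LLR score (the sex check has been spent on the exclusion), and
compares the realized mix-up fraction among passers with the configured
budget. A discretization-comparison harness fits every (scheme,
average-bin-size) combination on a common split for ANOVA-style
comparisons.

## Problem sizes and numerical choices

Test and reference computations use cohort sizes of 1 500–5 000 with
permutation caps of 40–200 (the calibration experiment: 20 replicates at
n = 5 000, 1% mix-ups, cap 50; monotonicity sweeps: n = 2 000, five seeds
per condition; simulator correlation checks: n = 20 000). Minimum training
samples per trait defaults to 100 — ordered-logistic fits in particular
degrade below that. Fits that fail (separation, non-convergence, too few
samples) skip the trait with a warning rather than aborting a run. Rows
whose permuted sums have fewer than two entries or zero spread pass
through unscaled with a warning; degenerate LLR arms mark a trait
not-significant. All randomness flows from explicit integer seeds;
identical seeds give identical output bytes.

## Known limitations

- The majority-correct assumption: regressions and likelihoods are biased
  if a large fraction of the training data is mixed up; fit on data that
  has already passed basic QC, or on a split believed clean.
- The sex-check rate estimator assumes swaps are random with respect to
  sex; batch-structured swaps violate it.
- mr_estimated inherits binomial noise from the sex-check count; at very
  small cohorts or very low mix-up rates the budget is noisy, and
  replicates with underestimated rates admit proportionally more passers.
- Covariates are fixed at age, sex and age×sex; traits driven by other
  strong non-genetic factors will have wide provided-residual
  distributions and carry little signal.
- Ordinal support targets small category counts; many-category ordinal
  traits will fragment the per-category likelihood fits.
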