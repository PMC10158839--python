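# Methods

This note documents the models, estimators, numerical conventions and design
choices behind `medtriad`, and what the synthetic-data studies do and do not
establish about real data.

## The measurement-error model

A triplet (X, M, Y) — QTL genotype, candidate mediator, target trait — is
modeled as noisy surrogates of error-free causal variables (X\*, M\*, Y\*).
All parameters are correlations: three causal correlations among the causal
variables and three error correlations between each causal variable and its
measurement. Error correlations live in (0, 1]; a value of 0 would make a
variable pure noise (all of its data correlations vanish identically), so it
is rejected at validation rather than silently producing degenerate output.

The constrained structures (Causal, Independent, Reactive) each have a
middle variable, and the causal correlation of the non-middle pair equals
the product of the other two (zero partial correlation given the middle
variable). Validation enforces this with tolerance `1e-8` for exact
configurations; estimated triples go through `check_structure_constraint`
with a user-settable tolerance instead. Positive semidefiniteness of
correlation matrices is tested with eigenvalue tolerance `1e-10`; boundary
matrices are accepted.

Correlations are stored **signed** throughout. The simulation study samples
only positive values (the Beta prior's support), but real systems include
negative regulation; every formula in the package is a plain product and
therefore sign-correct. The three-parameter latent model exposes only
marginal correlations; partial correlations are derived quantities, not
parameters.

## The latent one-factor model and its estimator

Each constrained measurement-error model is observationally equivalent to a
single-factor model: data correlations are pairwise products of three latent
correlations, with the middle variable's latent correlation equal to its
error correlation and each non-middle latent correlation equal to (error
correlation) x (causal correlation with the middle variable). The package
verifies algebraically (property tests) that the forward map commutes with
the data-correlation composition.

The latent correlations are estimated by the classical tetrad closed form,

    |rho_xu| = sqrt(|r_xy r_xm / r_ym|),  etc.

which is the canonical method-of-moments inversion of the pairwise-product
equations (for an exactly-identified one-factor model with three indicators
it coincides with maximum likelihood). Conventions:

- identification floor `min_abs = 1e-6`: below this, a tetrad ratio is
  numerically meaningless and the estimator refuses;
- a one-factor representation requires the product of the three data
  correlations to be positive; violations raise a sign-consistency error;
- the factor's orientation is arbitrary, fixed by `rho_mu >= 0`;
- finite-sample estimates above 1 in magnitude (Heywood cases) are clipped
  to 1 and flagged (`clipped=True`) rather than rejected, so bootstrap
  pipelines never crash on boundary resamples.

The consistency diagnosis maps the strongest latent correlation to the model
three-choice selection tends toward asymptotically (`rho_mu` → Causal,
`rho_xu` → Independent, `rho_yu` → Reactive). The tie margin defaults to 0
(strict argmax) and is exposed for sensitivity analyses.

## Synthetic data

Configurations: for each constrained structure, the two on-edge causal
correlations and the three error correlations are iid Beta(5, 1.25) — mean
0.8, 95% HDI ≈ (0.5, 1) — a realistic distribution for QTL-scale effect and
error correlations favoring moderate-to-strong values. The off-edge causal
correlation is their product, which automatically yields a positive
semidefinite causal matrix.

Datasets are standardized linear-Gaussian: X\* ~ N(0, 1), each downstream
causal variable is `rho * parent + sqrt(1 - rho^2) * noise` in the
structure's topological order, and measured variables are generated from
their causal counterparts the same way with the error correlations (effect
size rho² on the variance scale). Every variable has population mean 0 and
variance 1. For the Complex structure, Y\* regresses on both X\* and M\*
with coefficients solved from the target correlations.

Multistate genotypes (defaults: 8 states, emulating haplotype dosages in
multiparental populations): X\* is a uniformly drawn state; a mean-centered,
unit-variance state-effect vector (one draw per configuration, shared by all
children of X\*) scaled by rho gives the child R² = rho², i.e. the canonical
correlation between the dosage block and the child equals rho — the
univariate convention has no unique multistate analog, and this one
preserves the product composition of data correlations under canonical
correlation. Genotyping error relabels the measured state uniformly with
probability `1 - err_x`, making the measured-vs-causal canonical correlation
exactly `err_x`; the measured genotype is reported as one-hot dosage rows.
Real dosage uncertainty (soft probabilities) and unbalanced state
frequencies are not emulated; neither are kinship, polygenic background, or
linkage between loci.

Reproducibility: one master seed feeds a `SeedSequence` tree; configuration
sampling and each configuration's dataset use independent spawned
substreams, so experiments are parallelizable without seed collisions and
aggregate rates are invariant to processing order.

## Bayesian model selection

Candidate DAGs are edge subsets of {a: X→M, b: M→Y, c: X→Y, b_rev: Y→M}
without b/b_rev cycles. The expanded set keeps 10 models: all eight M→Y
subsets plus {a, b_rev} and Reactive {c, b_rev}; {b_rev} alone and the
complete {a, c, b_rev} are excluded as likelihood equivalent to {b} and
Complex respectively. Three-choice enumerates only Causal, Independent,
Reactive. Selection uses a uniform prior over the enumerated set; posterior
ties (gap < 1e-12) resolve by enumeration order and are flagged.

The marginal likelihood factorizes as p(M | parents) · p(Y | parents). Each
factor is a conjugate Gaussian linear model: variables are centered
(covariates residualized out, identically across models, with the effective
degrees of freedom reduced accordingly) and standardized to unit population
variance; each edge effect has prior N(0, phi² sigma²); sigma² has an
inverse-gamma(kappa/2, lambda/2) prior. Defaults `phi² = 1`,
`kappa = lambda = 0.001` are weakly informative; `phi²` is the main knob for
expanded-option selection rates. Standardizing both responses and
predictors makes selection scale-invariant and makes the {b} / {b_rev}
equivalence exact. The excluded complete reversed model agrees with Complex
only approximately under this factored per-node prior (typically < 0.05 log
units at N=200, exactly equal in the flat-prior limit of the fit term);
since it is excluded by rule, this has no effect on selection.

A multistate genotype enters as its dosage-column block. The block's
sum-to-one redundancy with the intercept is absorbed by the proper effect
prior (no column dropping); a constant column, i.e. rank deficiency beyond
that redundancy, raises a design error.

For univariate X without covariates, all marginal likelihoods are functions
of the sample correlation matrix and N alone; `select_from_correlations`
vectorizes this across many datasets and is verified against the
design-matrix path to < 1e-8. A corollary of the factorized form: the
three-choice winner is always the model with no direct edge inside the pair
whose sample correlation is weakest in magnitude (`weakest_correlation_rule`,
univariate X only); the property suite checks ≥ 99% agreement.

## The classification-rate study

`run_classification_study` samples configurations per structure, simulates
one dataset each, classifies, and tabulates column percentages. Default
scale is 10,000 configurations per structure (binomial standard error on a
60% cell ≈ 0.5 percentage points); the acceptance script uses 10,000 per
structure at N=200, 5,000 at N=5,000 (three-choice) and 2,000 at N=5,000
(expanded) — chosen so each reported rate's Monte-Carlo error is well below
the differences that matter. `rate_vs_latent_curve` bins the middle
variable's true latent correlation (width 0.05), stratified by whether X or
Y carries the stronger latent correlation; empty bins are omitted rather
than reported as zero.

## Bootstrap feasible-parameter diagnostic

`bootstrap_correlations` case-resamples rows (not residuals) and records the
correlation triple per resample — first canonical correlation for a dosage
block (computed as sqrt of the regression R², to which it reduces for a
univariate response), Pearson otherwise; covariates are residualized out of
M and Y first. The region is the central 95% interval per correlation;
"jointly within the range" is implemented as joint membership in the three
per-coordinate intervals. A full min/max region is available behind
`region="minmax"` but is noisier and widens with the number of resamples.
Degenerate resamples are redrawn with a counter; more than 1% aborts.

`build_config_library` stores each configuration with the *estimated*
correlations it realized in one finite-sample dataset (not population
values), simulated at a sample size that should match the observed N.
`filter_configs` keeps configurations of the assumed structure whose
realized correlations fall inside all three intervals and summarizes every
parameter by median and 95% HDI; an empty survivor set is reported
explicitly as infeasible at the library's resolution. The HDI uses the
sorted-window method (shortest contiguous interval containing the mass);
with fewer than 20 survivors the plain min/max range is reported instead.
No formal posterior over structures is computed — the tool reports parameter
ranges for qualitative judgment against biological context.

## What the synthetic studies do and do not show

Passing tests establish the package's internal mathematics (composition,
latent equivalence, estimator exactness, selection behavior) and reproduce
the behavior of standardized linear-Gaussian triplets with independent
measurement error, no hidden confounders, and Beta-distributed parameter
draws. They say nothing about non-Gaussian traits, correlated or shared
measurement error, confounding, linkage, or kinship structure — all of
which real QTL data contain to some degree. Closed-loop recovery checks
(bootstrap filter brackets the generating parameters) quantify
self-consistency of the diagnostic, not identification: individual causal
and error correlations remain non-identifiable from three variables, and
only their identified combinations concentrate as samples grow.

## Known limitations

- No measurement-error-corrected likelihood is provided; the point of the
  package is to quantify and diagnose what the uncorrected analysis does.
- The three-variable scope is fixed: no extra causal variables, no
  multivariate M or Y, no hidden-confounder terms.
- The weakest-correlation rule and the latent estimator require univariate
  X, M, Y (canonical correlations feed the bootstrap diagnostic instead for
  multistate X).
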