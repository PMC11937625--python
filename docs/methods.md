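# Methods

This note documents the statistical models, the synthetic data generator,
the numerical choices, and the known limitations of `daarep`.

## The replication protocol

A DAA method is evaluated by how well its findings replicate between an
*exploratory* and a *validation* dataset.

**Split-data protocol.** One dataset is split at random into two
equal-sized halves (default five independent repeats). Splits are
stratified by group so each half preserves the case/control sizes; when a
group has an odd count the extra sample goes to the exploratory half. Each
group must contribute at least `min_group_size` (default 10) samples to
each half, so a group needs at least 20 samples in total. Both halves are
prevalence-filtered independently after splitting.

**Separate-study protocol.** Every dataset whose groups both meet the
minimum size serves once as the exploratory dataset, with all other
datasets sharing its condition label as validation datasets. When a
candidate taxon meets different outcomes in different validation datasets,
the default `any` policy counts it replicated if replicated in at least one
and conflicting if conflicting in at least one; a taxon achieving both
increments both numerators over a single-candidate denominator, and the
number of such double-counted taxa is reported separately
(`n_double_counted`). A `first`-outcome-wins policy is available.

**Candidates and outcomes.** Significance in the exploratory dataset means
BH-adjusted *P* (q) < α. A significant taxon present in the filtered
validation dataset is a candidate. Validation significance uses the
unadjusted *P* < .05 — the validation step tests only a handful of
pre-formed hypotheses — with an optional BH-adjusted variant
(`validation_adjust="bh"`). Direction is the sign of the estimate (positive
= more abundant in cases); estimates at numerical zero (|estimate| <
1e−12) get direction 0 and are never counted as replicated or conflicting.

**Pooling.** Conflict%, Replication% and CI% are ratios of summed
numerators to summed denominators over all pairs, never means of per-pair
ratios. Spearman correlations of estimates are pooled on the Fisher-z
scale, tanh(mean(atanh ρ)), with |ρ| clipped to 1 − 1e−12; by default the
correlation uses all taxa shared by both filtered datasets (a
candidates-only variant is available via the estimate-pair helper). Pairs
with fewer than three shared estimates are skipped.

**The ideal Conflict% bound.** If a method's error control works, at most a
fraction α of candidates are false positives. An ideally behaved test
validates a false positive with probability 0.05 and assigns it the
opposite direction with probability 0.5, giving the approximate upper
bound α × 0.50 × 0.05 for Conflict%. Under a *global* null every candidate
is a false positive, so conflicts among candidates instead arise at rate
0.5 × 0.05; the acceptance suite checks the observed conflict count against
the exact binomial envelope of that process.

**CI overlap.** Intervals are closed: a shared endpoint counts as overlap
(a measure-zero convention fixed for exactness). The metric defaults to
83.4% intervals because two independent 83.4% Wald intervals for normal
estimates with equal standard errors overlap with probability
2Φ(√2·z₀.₉₁₇) − 1 ≈ 95%. Eligibility requires at least 10% prevalence in
both experimental groups (checked in both datasets); methods without CIs
report the metric as absent.

**Ranking.** Per nominal FDR level, √Conflict% (sign-flipped), Replication%
and NHits are standardized to zero mean and unit variance across methods
(population SD; a zero-variance column contributes zeros) and a method's
score is the mean of its standardized values; the square root compresses
the heavy right tail of Conflict%. A metric missing for any method at a
level is dropped for all methods at that level.

**α calibration.** NHits(α) = #{q < α} steps exactly on the sorted pooled
q-values, so the smallest α reaching a target count is the floating-point
successor of the target-th smallest q; exact attainment holds whenever the
grid has no tie there.

## Elementary DAA methods

All methods receive the prevalence-filtered dataset, model the group
indicator (case = 1) plus any covariates, and report per taxon: estimate,
SE, CI (any level; 83.4% in the overlap analysis, 95% otherwise),
direction, unadjusted *P*, and BH q-value. Taxa carrying no information
(constant response, or a group with 0%/100% presence for the logistic
model) are reported `degenerate` with *P* = 1; non-converging fits are
`failed` and excluded downstream.

**`orm` — ordinal (proportional-odds) regression.** The distinct TSS
proportions of a taxon form the ordered response categories (ties share a
category); the model is P(Y ≤ j | x) = expit(αⱼ − xβ) and the estimate is
the group log odds ratio. With only a binary group, the model's score test
is the tie-corrected Wilcoxon rank-sum test, and the reported Wald test
agrees closely: across simulated datasets the equivalent normal z-scores
agree within 10% relative and the median *P*-value relative difference is
below 5% (the documented tolerance; the Wald and rank statistics are
first-order but not exactly equal). Fitting uses a dedicated Newton solver
with analytic gradient and Hessian, started at the empirical cumulative
logits, with step-halving that preserves threshold ordering; it is verified
against a generic ordinal-regression implementation to ~1e−4 relative
accuracy in the tests. A slope exceeding 20 in absolute value is treated as
separation: the estimate is capped there with its sign intact; the Wald
*P*-value is then uninformative (Hauck–Donner), which is acceptable because
such taxa are vanishingly rare after prevalence filtering.

**`logtss-lm` — linear model on log relative abundances.** OLS of
log(proportion + pseudocount) on group (+ covariates); without covariates
this is exactly the pooled-variance two-sample *t*-test, and the estimate
is a log fold-change of relative abundance on the geometric-mean scale.
The default pseudocount is half the smallest nonzero proportion of the
whole matrix (`half-min-nonzero`); per-sample and fixed-constant policies
are selectable. The pseudocount makes the estimand the group difference in
population means of the transformed variable; for zero-heavy taxa this
differs from the log-ratio of mean relative abundances (zeros pull the
transformed mean toward log of the pseudocount), which is why the
parameter-recovery check evaluates CI coverage against the transformed-mean
estimand computed by an independent large Monte-Carlo draw.

**`logr` — presence/absence logistic regression.** Logistic regression of
the indicator count > 0 on group (+ covariates); the estimate is the group
log odds ratio of presence with Wald inference, fitted by batched
Newton/IRLS across taxa (verified against a reference implementation to
machine precision). Exact separation of the group term (0% or 100%
presence in a group) is reported `degenerate` rather than penalized-fitted,
keeping the method elementary; a Firth-type correction is deliberately not
applied. Known property: because presence counts are discrete and the Wald
log-odds-ratio test is conservative for sparse 2×2 tables, the pooled null
*P* < .05 rate at n = 50 + 50 is ≈ 3.7–4.0%, slightly below the nominal
5% — driven almost entirely by taxa present in over 90% of samples, whose
few absences make the Wald SE large. This is the correct behavior of the
specified test, not an implementation artifact.

**`nb-glm` — negative-binomial GLM (foil).** Per-taxon NB regression of
raw counts with a log library-size offset and ML dispersion. It is
included as a documented inconsistency foil: on null microbiome-like data
its unadjusted *P* < .05 rate typically exceeds 5%, and its behavior is
recorded, not asserted as correct.

**External methods.** Results of other tools are ingested from TSV tables
(`taxon_id`, `estimate`, `p`, optional `se`, `ci_low`, `ci_high`, `q`);
q-values are recomputed by BH unless the table is flagged as carrying its
own adjustment.

## Preprocessing

Prevalence is the fraction of samples with a nonzero count, computed on raw
counts. Filtering removes taxa strictly below the 10% threshold (a taxon at
exactly 10% is retained) and is always applied per dataset, never jointly
across a pair. Proportions are recomputed after filtering (each retained
column re-normalized to sum 1); normalizing before filtering is available
via the preprocessing functions if a workflow requires it. The BH
adjustment is the standard step-up procedure.

## Synthetic data generator

The generator emulates the statistical structure of case/control
taxonomic-profiling datasets, not any particular cohort:

1. baseline mean relative abundances ~ Gamma(shape = 0.3) normalized to
   sum 1 — a heavy-tailed composition with a few dominant and many rare
   taxa;
2. a fraction (default 10%) of taxa receives a group effect: case-group
   means multiplied by exp(±1.5) with random sign, then the composition is
   re-closed — the planted truth is a relative-abundance effect, and the
   closure shifts every taxon's realized log-ratio by one common constant,
   recorded as `closure_norm` (the per-taxon realized values are in the
   ground-truth table);
3. library sizes ~ Uniform{10,000 … 50,000};
4. counts ~ Poisson(library × proportion × G) with
   G ~ Gamma(shape = 0.3, mean 1) per cell — gamma-Poisson overdispersion.

Defaults (50 + 50 samples, 150 taxa) leave ≈ 90 taxa after the 10% filter
with a broad prevalence profile, matching the scale of real genus-level
studies; zero inflation arises implicitly from low means plus
overdispersion, with an explicit dropout probability available for
stress tests. Covariates (continuous or binary) act multiplicatively on
the log scale on a random subset of taxa and can be correlated with the
group to induce confounding.

What the generator does **not** emulate: taxon-wise experimental detection
bias, platform (16S vs shotgun) differences, phylogenetic correlation
between taxa, or absolute-abundance shifts between groups. Passing tests
on this generator therefore demonstrate internal consistency of the
pipeline and correct calibration under a compositional gamma-Poisson
world, not performance on any particular real cohort.

## Numerical choices and problem sizes

- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; identical config + seed gives bit-identical
  output.
- Ordinal Newton: convergence at max |gradient| < 1e−8, at most 100
  iterations, ridge fallback for singular Hessians; cell probabilities
  clipped at 1e−300.
- Logistic IRLS: linear predictors clipped at ±30, weights at 1e−10,
  score tolerance 1e−8.
- The acceptance suite uses 200 global-null replicates for type-I
  calibration, 40 datasets × 5 splits for the null conflict-bound check,
  100 replicates for CI coverage, and 100,000 pairs for the
  interval-overlap Monte Carlo — sizes chosen so Monte-Carlo error is
  well below the tolerances being checked while the suite completes in a
  few minutes.

## Known limitations

- The Wald *P*-values of `logr` are conservative on near-saturated taxa
  (see above); a likelihood-ratio variant would be closer to nominal but
  is not what the method specifies.
- Under separation the ORM estimate is capped and its Wald *P* approaches
  1; downstream metrics treat such taxa as ordinary results.
- The separate-study aggregation reconstructs a generic same-condition
  pairing; study-specific pairing schemes can be expressed by editing the
  dataset manifest.
- Rarefaction and alternative normalizations (CSS, TMM, GMPR, Wrench) are
  out of scope; TSS is the only normalization implemented.
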