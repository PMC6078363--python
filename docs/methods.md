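# Methods

`cadgrs` implements a genetic-risk-score (GRS) incremental-value analysis
for case-control studies of coronary artery disease (CAD): panel quality
control, score construction, quantile risk-gradient logistic models, a
paired ROC comparison, and reclassification metrics, together with a
synthetic cohort generator so the entire chain can be exercised and
tested without access to individual-level registry data.

## The disease and scoring model

Disease status follows a logistic model on the log-odds scale,

    logit P(case) = b0 + sum_i f_i(g_i) + sum_j x_j ln(OR_j),

where `g_i` in {0, 1, 2} is the risk-allele dosage at locus *i*, `x_j`
are binary traditional risk factors (TRFs), and `f_i` encodes the locus's
inheritance pattern via its per-allele odds ratio `w_i`: genotype relative
risks `(1, w, w^2)` (additive), `(1, w, w)` (dominant), `(1, 1, w)`
(recessive).

Two scores summarise a subject's genetic load over the `m` loci that
survive QC:

* **additive GRS (AGRS)** — the accumulated sum of risk-allele dosages,
  an integer in `[0, 2m]` (0–62 for a 31-SNP panel);
* **multiplicative GRS (MGRS)** — the product over loci of the genotype
  relative risk. By default each factor is divided by its expected value
  under Hardy-Weinberg equilibrium (HWE),
  `E[r] = q^2 + 2pq r1 + p^2 r2` with `p` the risk-allele frequency, so a
  reference population has mean factor 1 per locus. Without some such
  per-locus scaling a product of risks ≥ 1 grows with panel size and its
  cohort mean cannot fall below 1, whereas normalised scores sit around 1
  with the case distribution shifted upward. Normalisation is
  config-switchable (`normalize=False` gives the raw product).

Missing genotypes: the additive score imputes the cohort mean dosage at
the locus (optionally a fixed vector of means, which makes the score a
per-subject deterministic function and is what the subsample validation
uses); the multiplicative score multiplies by the locus's HWE-expected
mean relative risk, i.e. a factor of exactly 1 when normalised. A subject
missing every locus is flagged unscorable and excluded downstream, with a
log entry.

## Panel quality control

Filters run in a fixed order so each exclusion has a deterministic
reason: call rate ≥ 0.95, then estimated MAF > 0.05, then HWE p ≥ 0.002
(1-df chi-square goodness of fit against `(q^2, 2pq, p^2)` at the
estimated allele frequency; monomorphic loci are defined as chi-square 0,
p 1, flagged), then LD pruning at dosage `r^2` ≥ 0.8, keeping the
earlier-listed SNP of an offending pair. HWE is tested in controls only
by default (conventional, since case ascertainment distorts genotype
proportions at truly associated loci); a combined-sample option exists.
The 0.002 threshold is a Bonferroni-style cut for a panel of ~33
candidates (0.05/33 ≈ 0.0015, rounded as printed in common practice) and
is configurable, as is the LD cut, for which 0.8 is the conventional
choice. Note the multiplicity this implies: testing ~31 null loci at
α = 0.002 excludes at least one clean locus in about 6% of datasets —
visible in simulation and intrinsic to the stated thresholds.

## Association models

Logistic regression is fitted by iteratively reweighted least squares
(IRLS), converging when the largest coefficient update is below 1e-8
(max 25 iterations); standard errors come from the observed information
at the optimum, and all confidence intervals are Wald-type
`exp(beta ± 1.96 SE)`. Complete separation is surfaced as a
non-convergence flag naming the diverging coefficients. The quantile
risk-gradient model codes score bins as indicators against the first
quantile (or any chosen reference bin, e.g. the 5th decile for decile
gradients on control-based cutpoints), optionally adjusted by preset
covariate sets (`age_sex`, the four classical TRFs, and two extended
sets differing by alcohol intake, reflecting two common conventions for
a "7-covariate" adjustment). Forward stepwise selection admits, per
round, the candidate with the smallest Wald p below the entry threshold
(default 0.05), with deterministic order-based tie-breaks.

Quantile cutpoints are `i/k` sample quantiles with linear interpolation
between order statistics; a value exactly at a cutpoint goes to the
lower bin. Cutpoints are computed on the combined sample by default
(cases and controls then share bin boundaries, which is what makes
per-bin score means nearly identical across groups), with a
controls-only basis available for decile analyses.

Calibration uses the Hosmer-Lemeshow statistic over deciles of predicted
risk, `sum (O - E)^2 / (n pbar (1 - pbar))` with df = groups − 2 (the
in-sample convention; for externally supplied probabilities the
statistic is compared against chi-square on *g* df in the tests). Empty
risk bins are merged with a flag. Collinearity is reported as per-
predictor tolerance (1 − R² of the auxiliary least-squares regression on
the other predictors) and VIF = 1/tolerance, with perfectly collinear
columns flagged as infinite.

## Discrimination and reclassification

AUC uses the Mann-Whitney identity (ties count 1/2, midranks), which
equals the trapezoidal area under the empirical ROC; both routes are
kept and cross-checked. The DeLong test compares the two correlated
AUCs of the baseline TRF model and the TRF + GRS-quartiles model via
placement-value covariance; identical orderings yield a degenerate
result (z = 0, p = 1) rather than a division by zero. Two-sided p-values
are reported.

Categorical NRI works on fixed risk categories (< 25%, 25–50%, 50–75%,
75–100% by default; configurable): among events the net proportion
moving up, among nonevents the net proportion moving down, total their
exact sum; a predicted risk exactly at a boundary goes to the higher
category. The category-free NRI counts any increase/decrease, ties as
neither. Standard errors follow the usual asymptotics for net
proportions of movers, components combined by independence of the event
and nonevent samples; percentile-bootstrap CIs are available for small
samples. IDI is the difference in discrimination slopes, with SE from
the per-subject risk improvements as a two-sample problem.

A caution documented rather than hidden: *apparent* (in-sample) cfNRI
and IDI computed after refitting the extended model are biased upward
even when the added marker is pure noise (with ~3 added parameters on
~1,000 subjects the apparent cfNRI averages ~+0.12). The package
computes the statistics exactly as defined on the supplied predictions;
the null-centred behaviour is therefore verified on unfitted noise
increments, and users comparing nested in-sample fits should interpret
small positive NRI/IDI accordingly (cross-validated or split-sample
predictions avoid the bias).

## Synthetic cohorts

The generator emulates the structure the analysis assumes, not any
particular population:

* **Genotypes.** Independent biallelic loci with genotype proportions
  `(q^2 + pqF, 2pq(1−F), p^2 + pqF)` for risk-allele frequency `p`
  (equal to the MAF, or 1 − MAF when the risk allele is the major one)
  and inbreeding coefficient `F` (0 = HWE; the bundled panel's designed
  HWE violator uses F = 0.35, which fails the 0.002 test overwhelmingly
  at n ≈ 1,500 controls). An LD duplicate copies its parent's dosage and
  redraws a fraction `1 − sqrt(r2)` of entries from its own marginal,
  landing the empirical dosage correlation near the target. Per-locus
  missingness is applied at 1 − call rate, after phenotype assignment
  (missingness is an assay property, not a disease one).
* **Covariates.** Binary TRFs from a latent multivariate normal
  thresholded at prevalence quantiles (identity correlation unless
  configured); sex male with probability 0.77 and age normal (53, 8)
  truncated to [30, 65], matching the registry-style design the analysis
  targets; continuous vitals (heart rate, pulse-wave velocity, BMI,
  alcohol) carried with null effects so extended adjustment presets are
  exercisable.
* **Phenotype.** The logistic model above, with the intercept calibrated
  by bisection so mean population risk equals the target prevalence
  (default 10%) to within 0.5 percentage points.
* **Ascertainment.** All requested cases and controls are drawn from a
  simulated source population (default 50× the cohort size; smaller
  multipliers are used in tests and the acceptance script, where 10–20×
  is ample at 10% prevalence); controls are frequency-matched to the
  sampled cases' sex × 5-year-age-band distribution by largest-remainder
  allocation, mirroring group-level gender/age matching without
  individual pairing.

Default effect magnitudes: four TRFs with ORs 3.44 / 3.14 / 2.07 / 1.30
at control-population prevalences 23.4% / 13.2% / 53.0% / 83.4%, and 33
candidate loci with per-allele ORs 1.10–1.30 at MAFs 0.08–0.48 — the
ranges the SNP-selection criteria demand (OR ≥ 1.1, MAF > 5%). Per-SNP
values are illustrative placeholders, not any study's inputs; the
composite APOE locus stands in for an unphased two-SNP haplotype. What
passing tests show is that the *machinery* is correct under this
idealised structure (independent loci, exact logistic link, binary
covariates); they do not certify behaviour under population
stratification, genotyping batch effects, haplotype-level LD, or
miscalibrated baseline models, none of which the generator emulates.

## Numerical and design choices

* Single seed per run; every random draw flows from
  `numpy.random.default_rng(seed)`, so fixed seed ⇒ byte-identical
  outputs (asserted in tests).
* Intercept bisection brackets `logit(prevalence) ± 30` and errors,
  reporting the bracket, if the target is unreachable.
* IRLS weights are clipped at 1e-10 to keep the weighted normal
  equations solvable near fitted probabilities of 0/1; coefficients with
  |beta| > 25 mark separation.
* Chi-square vs Fisher for 2×2 tables: Fisher is auto-selected when any
  expected cell is below 5 (the conventional switch); the chi-square
  uses no continuity correction by default, configurable.
* Quantile assignment errors (rather than silently merging) when there
  are fewer distinct values than bins or tied cutpoints.
* The subsample score validation (default 20% of subjects) recomputes
  scores independently and demands bit-identical agreement, listing any
  mismatching subject IDs.

## Problem sizes used in the checks

Simulation-based tests run at the sizes where each property lives:
genotype-frequency convergence at n = 1e5; effect-recovery CI coverage
over 20 replicates of n = 5e4; DeLong variance against a 10,000-replicate
bootstrap at n = 30; null coverage of quantile-bin Wald CIs at 400
subjects per group (Wald intervals are known to undercover by a few
percent at ~100 subjects per bin, and the ~95% claim is asymptotic); the
end-to-end analysis on cohorts of a few hundred to ~1,500 subjects. The
acceptance script reruns panel QC on a simulated 3,000-subject cohort.

## Known limitations

* Independent loci apart from explicit pairwise duplicates; no
  haplotype-level LD, no phasing, no population structure or PCA screen.
* No weighted score trained on the cohort itself; weights are inputs.
* In-sample incremental-value statistics carry the apparent-improvement
  bias discussed above.
* Wald intervals throughout; no profile-likelihood or exact logistic
  CIs.
* Binary outcomes only; no survival-time reclassification metrics.
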