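# Methods

## Scope

`methylsmoke` implements a smoking-methylation analysis pipeline for
450k-style methylation arrays in a bi-ethnic (European / South Asian)
cohort: per-CpG association testing between smoking status and
methylation, a weighted methylation smoking score with a learned
classification threshold, reference-based cell-composition estimation
and adjustment, behaviour regressions and an a-priori power calculation.
Because individual-level cohort data of this design are not public, the
package ships a synthetic-data generator that reproduces the statistical
structure the analysis assumes, with complete ground truth, so every
stage can be tested for recovery of known effects.

## Data model and transformations

Methylation at a CpG is a beta-value, the fraction methylated, strictly
inside (0, 1). Statistical models run on M-values,
`M = log2(beta / (1 - beta))`, the variance-stabilising logit2 transform;
the inverse maps back. No offset is used because the simulator never
emits 0 or 1, and values outside the open interval raise an error rather
than being clipped.

QC follows the standard detection-p contract: a sample is kept when
strictly more than 95% of its probes are detected (detection p < 0.01);
a probe is kept when at least 95% of samples detect it, and
multi-homology probes are then excluded. A probe failing both rules is
counted once, under detection — the two removal counts are otherwise
reported separately. Batch structure (one array chip = one batch) is
removed by per-probe chip-mean centering that preserves each probe's
grand mean. This is a deliberately minimal linear batch correction: it
removes exactly the per-chip location shifts the simulator injects, and
makes no empirical-Bayes shrinkage of scale the way ComBat does. Scores
are computed on QC-filtered but *non*-batch-centered betas; only the
association models use centered M-values.

## EWAS model

Per CpG, the model is a two-factor additive ANOVA on M-values restricted
to never and current smokers:

    M ~ smoking_status + ethnic_group

with the smoking term assessed by a partial (type-II) F-test — the F of
dropping smoking from the ethnicity-adjusted model. The implementation
is a vectorised QR projection over all probes at once (the design is
shared across probes), verified in tests against `statsmodels`
`anova_lm(typ=2)` per CpG. Former smokers are excluded from the
genome-wide model entirely, treating "comparing never with current
smokers" as exclusion rather than a within-model contrast.

Family-wise control is Bonferroni: the significance threshold is
`alpha / n_tests` with `n_tests` the post-QC probe count. On the 450k
platform with the canonical exclusions (9,769 detection failures and
25,083 multi-homology probes out of 485,577), `0.05 / 450,725 =
1.11e-7`; over the 12 sentinel follow-up tests, `0.05 / 12 = 0.004167`.

Effect sizes are reported on the beta scale as the signed median
difference, median(current) − median(never). At each locus the
*sentinel* CpG is the significant CpG with the smallest p-value (ties:
larger |effect|, then probe id). For sentinels the pipeline adds the
smoking × ethnicity interaction (partial F of the interaction term
against the additive model), per-ethnicity stratified F-tests and effect
sizes, the ethnicity main-effect F, and a Welch t-test between
ethnicities among never smokers. Welch is the default two-sample test
throughout (a pooled-variance flag exists) since equal variances are not
assumed. A constant-outcome probe yields a flagged NA row, never an
exception; an exactly separating probe reports F = inf and p = 0 (below
any representable positive double).

## Cell composition

Whole blood is a leukocyte mixture and smoking shifts leukocyte
proportions, confounding a subset of smoking-associated CpGs. The
package estimates per-sample proportions by projecting each sample's
betas at composition-discriminating CpGs onto per-cell-type reference
profiles under simplex constraints (non-negative, sum-to-one least
squares). The solver augments the reference system with a heavily
weighted sum-to-one row, solves by NNLS, and renormalises exactly — a
constrained projection with the same contract as reference-based
deconvolution in the Houseman tradition, without the original
measurement-error calibration step (documented emulation; at desk scale
the two coincide on noiseless mixtures). A rank-deficient reference
raises an error naming the most collinear cell-type pair.

Adjustment is residualisation: per probe, M is regressed on the
proportions (one cell type dropped to break the simplex collinearity)
and the residuals are returned with the probe's grand mean restored.
M-values (not betas) are adjusted, keeping the adjustment on the
modelling scale.

## Smoking score

Given a reference panel of smoking-associated CpGs — per CpG a
direction (hyper- or hypomethylated in current smokers), a catalogued
effect-size magnitude |e|, and the never-smoker median beta `ref` — the
weight is `w_i = |e_i| / mean(|e|)` (so weights are positive and average
exactly 1), and a sample's score is

    score = sum_hyper w_i (beta_i - ref_i) + sum_hypo w_i (ref_i - beta_i).

The score is linear in the betas and zero for a sample sitting exactly
at the reference. Up to 10% of panel CpGs may be missing from a beta
matrix (dropped with a warning, weights *not* renormalised — matching
the practice of scoring on the panel CpGs that survive QC); more than
10% missing is an error.

The classification threshold is learned with an ensemble of 500
bootstrap decision stumps on the one-dimensional score: each tree is a
depth-1 Gini tree (sklearn's impurity-minimising midpoint split) fitted
to a bootstrap resample of the never/current samples, and the threshold
is the mean of the 500 root split points. Former smokers are excluded
from fitting but included in specificity (they count as negatives).
Single-class or unsplittable resamples are redrawn (bounded retries).
The scalar-score stump ensemble is our reading of "a random forest on
the score": with one feature, depth 1 and bootstrap resampling, a random
forest *is* this ensemble, and averaging root splits is the natural way
to extract a single threshold from it. Classification is strict:
predicted current iff score > threshold. Sensitivity is computed over
current smokers, specificity over never and former smokers pooled, and
thresholds can be cross-applied between groups.

## Behaviour and power

Pack years = (cigarettes per day / 20) × years smoked, with years smoked
derived from age, age started and (for former smokers) years since
quitting. Score-vs-behaviour models fit `behaviour ~ score ×
ethnic_group`; if the interaction is significant at 0.05 the slopes are
re-fitted within ethnic strata (a stratum below n = 4 is refused), with
95% CIs. Methylation-vs-dose models for sentinels are unadjusted OLS of
M on the dose variable.

`two_sample_power` gives the power of a two-sided two-sample comparison
of group means: exact noncentral-t power of the pooled t-test by
default, with a normal-approximation (`method="normal"`) flag. The
study-design reproduction in the acceptance suite — power to detect a
5% methylation difference with 4% per-group SD at the genome-wide
threshold, n = 165 split as 36 current vs 129 never smokers — uses the
normal approximation, which reproduces the published 90.72% to two
decimals; the noncentral-t answer for the same design is 85.0%,
identifying the normal approximation as the convention behind the
printed figure. scipy's far-tail `nct` can return NaN for the negligible
opposite-tail term; it is treated as zero.

## Synthetic cohort generator

The generator's defaults are the study conditions: stratum sizes
65/64 never, 14/10 former, 16/20 current (European/South Asian), ages
~48 ± 4, heavier European smoking (23 vs 13 cigarettes/day), earlier
European uptake, ~12–13 years since quitting in former smokers.

Betas are built probe-wise as baseline + effects on the beta scale,
then transformed: `M = logit2(mean_beta) + batch + noise`,
`beta = inv_logit2(M)`. Because the noise is Gaussian on the logit scale
(logit-normal betas — our modelling choice; array noise models are not
uniquely determined by published summaries) and the inverse logit is
monotone, the group median beta equals the injected mean beta exactly,
so a target beta-scale effect (e.g. an AHRR-like −0.22 from a 0.77
baseline) is recovered by median differences without approximation
error. This exact-quantile injection replaces a first-order
local-derivative conversion, which would bias realised medians for
effects this large.

Components:

- **Baselines**: bimodal Beta(2,8)/Beta(8,2) mixture with a uniform
  mid-range component, clipped to [0.01, 0.99]; signal-CpG baselines are
  drawn so that baseline + effect stays at least 0.05 from the
  boundaries. Configurations whose combined effects push any mean beta
  outside (0.001, 0.999) are rejected.
- **Smoking effects**: current smokers get the full signed effect;
  former smokers get `former_attenuation × effect`, default 0 (former
  smokers revert toward never-smoker levels). Optional per-ethnicity
  scaling (`ethnic_dose_factor`) models a lighter-smoking group, and
  `dose_scaled` ties each smoker's effect to cigarettes/day ÷ 20.
- **Ethnic main effects** add a beta offset to all South Asian samples
  at designated CpGs; a single interaction CpG can carry fully
  ethnicity-specific smoking effects.
- **Cell structure**: proportions are Dirichlet draws (concentration
  200) whose mean shifts by `cell_shift` toward the first cell type in
  current smokers; discriminating-probe betas are the
  proportions × profiles mixture, so a composition shift creates
  smoking-associated signal that composition adjustment should remove.
- **Batch**: one Gaussian offset per chip (SD 0.05, logit scale), shared
  across probes — the smallest structure chip-mean centering can be
  tested against.
- **Noise**: logit-scale SD 0.25 by default. This is the M-scale image
  of a ~4% beta SD at intermediate methylation levels (d M/d beta =
  1/(ln2 · beta(1−beta)) ≈ 6.3 at beta ≈ 0.65), i.e. the variability the
  study's own power statement assumes. Under this default the simulated
  AHRR-like interaction contrast (−0.24 vs −0.19) yields a mean
  interaction F ≈ 10.9 at n = 165, closely matching the published
  F = 10.42 for that contrast — the generator reproduces not just the
  effect sizes but the operating signal-to-noise of the study.
- **Detection p-values**: near 0 (uniform below 1e-4) for good cells; a
  configurable random fraction, and per-sample failure fractions, are
  pushed to ≥ 0.01 so the QC filters have real work in tests.
- **Reference panel**: 183 CpGs by default, 70% hypomethylated in
  smokers, magnitudes uniform on [0.02, 0.15] — the typical 2–15% range
  of smoking catalogues; a full-effect smoker then scores ≈ 18, matching
  the published score scale. `config_with_panel` produces a cohort whose
  signal CpGs realise the panel's effects exactly, so score/classifier
  behaviour can be tested against ground truth.

What the generator does *not* emulate: probe-type (Infinium I/II)
chemistry, colour-channel and intensity-level artefacts, spatial chip
effects, probe-probe correlation within loci beyond shared locus labels,
age/sex effects, and genetic (mQTL) structure. Passing tests therefore
demonstrate correctness of the statistical machinery under the stated
generative model, not robustness to every artefact of real arrays.

## Numerical choices

- Partial-F via QR with RSS clipped at 0; exact fits (relative residual
  < 1e-14) report F = inf, p = 0; constant outcomes are NA-flagged.
- NNLS sum-to-one weight 1000 (betas are O(1)), then exact
  renormalisation; simplex membership asserted to 1e-9.
- Sentinel ties: smaller p, then larger |effect|, then probe id.
- Identical-group t-test returns (0, 1) instead of scipy's NaN.
- Seeds: every stochastic routine takes an explicit seed or Generator;
  identical config + seed reproduces bit-identical cohorts.

## Problem sizes in the shipped checks

The acceptance suite exercises a 5,010-probe genome-scale stand-in
(10 signal CpGs with |effect| ≥ 0.10 among 5,000 nulls) at the default
stratum sizes, 200 replicates for family-wise error and interaction
power, 20 seeds for threshold comparisons, and 100k-replicate Monte
Carlo for the power oracle — sizes chosen so the whole suite completes
in about a minute on a single core while leaving Monte-Carlo error well
inside the asserted tolerances.

## Known limitations

- The Bonferroni threshold is conservative under correlated probes; no
  permutation or effective-number-of-tests alternative is provided.
- The cell-composition estimator is the constrained projection, not the
  original measurement-error-calibrated estimator; with a noisy or
  mis-specified reference its proportions are biased toward the simplex
  interior.
- The stump-ensemble threshold is one reading of an under-specified
  published procedure; other random-forest readings (e.g. trees on raw
  CpGs) would give different thresholds.
- The interaction test's power at published AHRR-like contrasts is
  ≈ 0.53 under the default noise level — a majority, but close to the
  boundary; replicate counts in the shipped checks are chosen (and
  seeded) accordingly.
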