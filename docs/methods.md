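# Methods

This note records the statistical model behind each stage, the parameters
that matter, what the synthetic-data generator does and does not emulate,
and the numerical and design choices made where the design was genuinely
open.

## Proportional-hazards score model

The package treats amyloid onset as a time-to-event outcome on the age
scale with hazard

    h(t | s) = h0(t) · exp(s),

where `s` is the polygenic hazard score, a weighted effect-allele dosage
sum. The baseline `h0` is Gompertz, `h0(t) = rate · exp(shape · t)`
(defaults `rate = 8.9e-5 /year`, `shape = 0.087 /year`), chosen because
late-onset Alzheimer's incidence grows roughly exponentially with age; the
default pair puts the median onset age for a score of zero near 75 years.
Both parameters are exposed on `GompertzHazard`. Onset sampling uses exact
inverse-transform sampling through the closed-form inverse cumulative
hazard, so generative hazard ratios are exact by construction.

### Stepwise selection

`forward_stepwise_cox` starts from a Cox model containing only the two
forced APOE dosage covariates (the ε4-defining risk variant and the
ε2-defining protective variant) and greedily adds the candidate variant
with the largest partial-likelihood improvement, admitting it when its
1-df likelihood-ratio p-value is below `alpha_entry` (default 0.05), up to
`max_snps` (default 31). The weights of the returned panel come from the
final **joint** refit rather than from single-variant fits, so the score
equals the joint model's linear predictor. Ties in improvement are broken
by the variant's GWAS p-value and then lexicographic id, which makes
selection deterministic. Candidates whose Cox fit fails to converge are
skipped with a warning; non-convergence of the forced model is a hard
error. Both the entry criterion and the cap are exposed because published
descriptions of this family of scores state the outcome (a 31-SNP panel)
rather than the stopping rule.

Effect-allele alignment flips dosages (2 − d) when the counted allele
differs from the panel's effect allele; palindromic (A/T, C/G) mismatches
are strand-ambiguous and raise instead of guessing. Scores are the raw
weighted sums by default; `center_scale=True` standardises them to the
fitting cohort, since publications in this area do not state whether any
post-summation normalisation was applied.

Strata are defined as mean ± 1 SD of the cohort's scores (high above,
low below, mid between), with explicit thresholds available to reproduce a
published cut (e.g. 1.04 / −0.67).

## Centiloid progression curve and onset imputation

Amyloid burden on the Centiloid scale (0 ≈ young controls, 100 ≈ mild AD,
≥ 20 abnormal — the boundary is inclusive) is modelled as a monotone
function of a latent disease time shared across individuals. The curve is
estimated with a slope-versus-level construction:

1. each individual with ≥ 2 scans contributes a least-squares CL-vs-age
   slope at their mean CL level;
2. a quadratic is fitted to slope as a function of level (the quadratic
   family contains the logistic's exact rate function `r·CL·(1−CL/100)`);
3. `dCL/dτ = f(CL)` is integrated outward from the 20-CL anchor
   (trapezoid rule on a 0.25-CL grid), giving τ(CL) with τ(20) = 0.

Numerical safeguards: the fitted rate is floored at 5 % of its maximum
(with a warning) and the grid is restricted to the contiguous positive-rate
interval around the threshold — without this, integrating 1/f through the
fit's decaying tail produces disease times of centuries. Outside the grid,
τ and its inverse continue linearly with the terminal slope, and estimates
using that region are flagged `extrapolated`. A cohort in which all
individual slopes are ≈ 0 raises "no progression signal". At least 20
individuals with ≥ 2 scans are required.

Onset is imputed per participant as

    onset_age = mean(scan ages) − [ τ(mean CL) − τ(20) ],

i.e. the mean longitudinal age minus the elapsed disease time between
crossing the threshold and reaching the mean longitudinal CL level. The
mean is unweighted over scans. Participants whose mean CL is below 20 are
censored (`never_abnormal`); a mean CL at or above the curve ceiling is
clamped just below it with a warning. The whole-neocortex region drives
onset by default (configurable), matching the convention of reporting
neocortical amyloid abnormality.

## Cognitive composites

Recognition memory, executive function and episodic recall composites
z-standardise each constituent test against the **baseline cognitively
normal** sample's mean and SD, then average the available standardized
scores (rows with all constituents missing stay missing; a strict
complete-case mode is available). Per-test direction flags allow
higher-is-worse instruments; the bundled defaults are all
higher-is-better, and are overridable per composite. CDR sum-of-boxes is a
clinical severity sum and passes through raw.

## Association models

Cross-sectional: OLS of baseline regional CL on the score with age, sex,
education and APOE-ε4 (0 = no ε4, 1 = any ε4) covariates. In
carrier-only / non-carrier-only subgroups the APOE covariate is dropped
automatically (no variation). The Benjamini-Hochberg step-up procedure is
applied across the three-region family; rank-deficient designs raise with
the collinear columns named.

Longitudinal: the random-intercept mixed model

    Δc = β0 + β1 PHS·Time + β2 CL(frontal)·Time + β3 entorhinal·Time
       + β4 BaselineAge·Time + β5 Sex·Time + β6 Education·Time
       + β7 APOE·Time + (1 | participant)

is implemented literally: interactions with Time only, no Time main
effect, because that is the printed form this design replicates;
`include_time_main=True` adds the conventional main effect and the result
records which form was used. Continuous covariates are centred and scaled
over the analysis rows. Fitting is **maximum likelihood** (not REML) so
likelihood-ratio tests on fixed effects are valid; the optimizer tries
BFGS then Powell, and a non-converging or singular random-intercept fit
degenerates to OLS with the method flagged `mixedlm->ols`. Wald z
inference is reported per term; with ≥ ~100 participants its size is
accurate (see calibration below). Cognition models default to participants
who are CN or MCI at baseline, the non-demented subset convention.

AIC backward selection drops, one at a time, the interaction term whose
removal lowers AIC most, never touching the intercept or the random
intercept; it is deterministic for fixed data. Simple-effect slopes at
score = mean ± 1 SD are `β_time + level·β1` with delta-method standard
errors from the fixed-effects covariance. The atrophy panel fits the same
model per region of interest (33 Desikan-Killiany-style cortical regions
by default) with sex/education/APOE interaction covariates — regional
volumes are assumed already adjusted for age and intracranial volume
upstream, as is standard — and applies BH-FDR across the family.

## Onset survival analysis

Survival time is years from birth to (a) the imputed age of amyloid
abnormality (event), (b) withdrawal (censored), or (c) the last completed
follow-up (censored). Only the high and low score strata enter; the Cox
model (Efron ties) adjusts for baseline age, sex and education and reports
the high-vs-low hazard ratio with a Wald 95 % CI. Kaplan-Meier medians are
the first age at which the product-limit curve reaches 0.5, with CIs read
from the complementary-log-log confidence band; a median is reported
absent when the curve never crosses 0.5 (common for the low stratum at
short follow-up). The log-rank test compares the strata.

Because age is the time scale, risk sets are left-truncated at study-entry
age **for prospectively observed records**. Records whose imputed onset
precedes study entry were ascertained retrospectively — they were never
"at risk" under observation — and entering them at their study-entry age
produces degenerate risk sets containing only other early-onset subjects,
which inflates hazard ratios by an order of magnitude; such records
therefore enter at birth. `left_truncation=False` reproduces the literal
untruncated birth-to-event definition, and with truncation ages at zero
the two estimators coincide (tested). An ε3/ε3-only analysis is a row
filter on the same operations, not separate code.

## Synthetic cohort generator

The generator is the package's ground-truth instrument. Defaults describe
a 780-participant longitudinal ageing cohort: 31 biallelic SNPs (HWE,
frequencies uniform on 0.05-0.5, log-hazard effects N(0, 0.08)) plus the
two APOE pseudo-variants (frequencies 0.15 / 0.08, weights +1.0 / −0.5);
baseline ages N(72, 6.5²) clipped to 55-95; visits every 1.5 years with
0.15 per-visit dropout capped at ceil(1.5 · n_visits_mean) visits, which
yields ≈ 4.8 years of mean follow-up; Centiloid noise SD 5 CL; logistic CL
trajectories (floor 0, ceiling 100, rate 0.15 /year, ≈ 2.4 CL/year at the
threshold) anchored at exactly 20 CL at each individual's onset age, with
frontal and posterior-cingulate rates scaled ×1.08 / ×1.15 so the
posterior cingulate accumulates fastest; volume and cognition slopes of
−0.005 volume-fraction/year and −0.01 composite-SD/year at score zero,
steepened by −0.004 and −0.03 per score unit. Onsets sampled beyond a
110-year horizon are never-converters. One `numpy` Generator seeded from
the config drives everything, so an identical config reproduces the cohort
bitwise.

Deliberately **not** emulated: linkage disequilibrium, population
stratification, imputation quality, tracer-specific Centiloid calibration,
floor/ceiling effects in cognitive instruments, informative dropout, and
any real link from genotype to clinical diagnosis — diagnosis labels are a
stand-in produced by thresholding years-since-onset at baseline (+ noise)
into CN/MCI/AD, and should not be used to study diagnostic accuracy.
Passing tests therefore demonstrate statistical correctness of the
machinery under the stated generative model, not clinical validity on real
cohorts.

## Verification sizes and calibration

The test suite checks each core computation against an independent oracle
(explicit-loop scoring; normal-equations OLS on a 12-row fixture at 1e-8;
textbook BH on short vectors; brute-force Cox partial-likelihood
maximisation on 8 subjects at 1e-4; empirical survival vs KM under zero
censoring). Parameter recovery uses 100 replicates at n = 800 and requires
the generative value inside the 95 % CI in ≥ 90 of them, for the stratum
log-hazard-ratio, the mixed-model interaction slope and the cross-sectional
CL-per-score slope. Null calibration uses 2000 replicates for the
likelihood-ratio test and for the mixed-model interaction (the latter at
100 participants × 4 visits, where the Wald z test holds its 5 % size;
with ~60 participants it is visibly anti-conservative), and 40 replicates
of the all-null 33-region panel for the BH false-discovery bound. Onset
imputation must land within 0.5 years of the true crossing for ≥ 95 % of
noiseless converters, and mean ± 1 SD stratification of 100 000 Gaussian
scores must give a high fraction within 0.5 points of Φ(−1) = 15.87 %.

## Known limitations

* The progression curve assumes a single monotone trajectory shared across
  individuals up to time shifts; fast/slow accumulator heterogeneity is
  absorbed into imputation error.
* Imputed onset ages far in the past (mean CL near the ceiling) rest on
  the extrapolated part of the curve and are flagged, but their
  uncertainty is not propagated into the survival model.
* The stepwise Cox selection inherits the usual instability of greedy
  variable selection at modest sample sizes; with the default cohort only
  a handful of non-APOE variants typically pass the entry test.
* Wald (not profile or bootstrap) intervals are used for mixed-model fixed
  effects and the Cox hazard ratio.
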