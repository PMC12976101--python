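# Methods

This note documents the models implemented in `ttehta`, the defaults
chosen where the design was genuinely open, and what the synthetic
validation does and does not establish.

## Synthetic registry generator

The generator emulates a national biologics register for rheumatoid
arthritis at the level of detail the downstream pipeline consumes.

**Covariates.** Seven continuous baseline covariates (age, disease
duration, tender and swollen 28-joint counts, ESR, patient global
assessment, HAQ) are drawn through a Gaussian copula whose default
correlation matrix couples the disease-activity cluster (joint counts,
patient global, HAQ at r ≈ 0.25–0.45; ESR more weakly) and age with
disease duration (r = 0.35).  Marginals are location/scale families
(normal or lognormal) with medians chosen to resemble a
moderate-to-severe second-line RA population: DAS28 ≈ 5.5, HAQ ≈ 1.9,
disease duration ≈ 15 y, ESR ≈ 34 mm/h.  Binary covariates (female
0.80, RF-positive 0.67, comorbidity 0.645, glucocorticoids 0.46,
inefficacy stop 0.50) and discrete ones (previous DMARD count, weekly
methotrexate dose on the clinical grid 5–25 mg) are drawn directly.
The DAS28 at every visit is computed from its components by the
standard four-variable composite

    DAS28 = 0.56·√TJC28 + 0.28·√SJC28 + 0.70·ln(ESR) + 0.014·PGA,

so the stored score is consistent with its components by construction;
the EULAR machinery presupposes this composite even though no formula
is restated by the response criteria themselves.

**Treatment assignment.** P(rituximab | x) is logistic in standardized
covariates.  Default coefficients produce register-like imbalance: the
inefficacy-stop fraction is ≈ 60% in the rituximab arm vs ≈ 45% under
nonbiologic therapy, DAS28 medians ≈ 5.6 vs 5.4, and an overall
rituximab share of ≈ 0.35.  The same covariates (with opposite-leaning
signs) enter the outcome model, producing confounding by indication
that biases the crude odds ratio toward the null by ≈ −0.12 on the log
scale — large enough that an unadjusted analysis is visibly wrong and
the weighting step demonstrably repairs it.

**Outcome generation and the meaning of `true_log_or`.** Individual
EULAR categories are drawn from a conditional proportional-odds model
`logit P(Y ≥ k | T, x) = α_k + γ'x + β_c T`.  Because odds ratios are
non-collapsible, β_c is *not* the quantity an IPTW analysis estimates.
The generator therefore defines its ground truth `true_log_or` as the
marginal proportional-odds odds ratio over the eligible (DAS28 > 3.2)
population — exactly the probability limit of the weighted
proportional-odds fit — and internally calibrates β_c by root-finding:
the marginal category distributions under treat-all and treat-none are
computed over a fixed large covariate sample and KL-projected onto the
proportional-odds family, and β_c is solved so the projected log odds
ratio equals `true_log_or`.  The cutpoints are calibrated the same way
so that the marginal control-arm probabilities hit the configured
targets (defaults 0.174 at-least-moderate, 0.066 good).  Without this
calibration the attenuation between conditional and marginal effects
(~0.01 on the log scale at the default prognostic strengths) would be
mistaken for estimator bias.

**Follow-up DAS28.** Given the drawn category and the baseline score,
the follow-up DAS28 is sampled uniformly from the interval of follow-up
values consistent with that category (each EULAR cell is a single
interval of follow-up scores for a fixed baseline).  This guarantees
that re-classifying the stored scores reproduces the generated category
exactly — the generation layer and the classification layer cannot
drift apart.  Components for the follow-up measurement are back-solved:
joint counts and patient global are set near their expected share of
the composite and ESR absorbs the residual exactly.

**Visits and episodes.** Routine visits sit on a jittered grid
(183 ± 30 days; the misalignment between visit dates and treatment
dates in a real register is not reported anywhere we could verify, so
the jitter default is an explicit guess).  The measurement visits
nearest the protocol baseline and follow-up dates are placed within
±45 days of them and carry the structural DAS28 values; other visits
within 100 days of a measurement visit are removed so the closest-visit
rule deterministically finds the intended measurement.  A configurable
fraction of patients (`missing_followup_rate`, default 0.05) miss their
entire follow-up assessment window, exercising the visit-gap tolerance.
Episodes comprise a methotrexate backbone (92% coverage), a stopped
first-line biologic, and the assigned second line.  Non-overlap of
episodes is enforced *within* drug label: concurrent methotrexate
alongside a biologic is constitutive of the treatment strategies being
compared, so a global non-overlap rule would be wrong.  Post-enrollment
dropout (15% rituximab discontinuation before week 24; 12% + 3% of the
nonbiologic arm starting a biologic before/within weeks 20–24) is
drawn independently of covariates and outcome, and the two arms'
total selection probabilities are equal by default, so the marginal
estimand is unchanged by adherence restriction.

**Missingness.** `inject_missingness` masks baseline covariates
missing-at-random; each rate is either a scalar or a triple applied by
baseline-DAS28 tertile (DAS28 and the assignment-side covariates remain
always observed, so the mechanism is MAR given observed data).  Default
rates (1%–25% per covariate) are milder than the sparsest columns of a
real register extract; heavier missingness works but slows multiple
imputation.

**What the generator does not emulate:** informative visit scheduling,
outcome-dependent dropout, measurement error correlated with treatment,
unmeasured confounding, calendar drift in prescribing. Passing the
recovery tests therefore shows the estimator chain is correct under a
point-treatment MAR world, not that any real-world analysis is
unconfounded.

## Target-trial emulation

Eligibility predicates run in a fixed documented order (allowed
first-line biologic stop → a qualifying strategy → a baseline visit
within tolerance → DAS28 strictly greater than 3.2 → methotrexate
episode spanning baseline), so each excluded candidate carries exactly
one primary reason code and the tallies always reconcile.  The
nonbiologic arm requires ≥ 20 weeks without any biologic after the
first-line stop; its baseline is the stop date itself.  Follow-up is
baseline + 24 weeks exactly; measurements may attach from nearby visits
(closest by absolute distance, ties to the earlier visit, default
tolerance 90 days ≈ half the visit interval).  A patient qualifying for
both strategies (a long nonbiologic spell followed by rituximab) is
enrolled once, in the strategy qualified for first (the nonbiologic
arm); a configuration switch flips this preference.  Adherence
restriction drops rituximab rows whose course stops before follow-up
and nonbiologic rows with any biologic start before follow-up; whether
the original analysis censored, excluded or retained such switchers is
not decidable from the available description, and this is one defensible
reading.

## Causal estimation

Missing covariates are imputed by chained equations with predictive
mean matching (statsmodels `MICEData`; donor pool k = 5, m = 10 by
default — the method is stated by the source analysis, m and k are
not), with the treatment indicator and outcome included as predictors.
Per completed dataset: a maximum-likelihood logistic propensity model
on the 13 baseline characteristics (perfect separation is detected and
reported with the offending covariate), unstabilized ATE weights
(stabilization and 1st/99th-percentile truncation available;
ATT by configuration), and a weighted proportional-odds fit with the
treatment indicator as the sole regressor — the weights carry the
covariate adjustment.  Estimates are pooled by Rubin's rules with
Barnard–Rubin degrees of freedom.

**Variance.** For weighted fits the default is a stacked M-estimation
sandwich that treats the propensity coefficients and the outcome
parameters as jointly estimated: the outcome scores are replaced by
their residuals off the projection onto the propensity scores before
forming the meat.  Treating estimated ATE weights as known is
conservative; in the recovery study the naive sandwich covered 98.5%
while the stacked variance covers 97.5% at nominal 95%.  The
correction applies to unstabilized, untruncated weights; otherwise the
code falls back to the conservative estimator.

**Finite-sample behaviour.** At the validation scale (registry
n = 5,000, analysis n ≈ 2,900) the weighted estimator is unbiased
within Monte-Carlo error across independent seed ranges.  At smaller
scales (analysis n ≲ 2,300) a positive finite-sample bias of ≈ +0.03
log-odds appears — the familiar small-sample behaviour of inverse
weighting with estimated scores over many covariates.  Users running
the pipeline on small extracts should prefer truncated or stabilized
weights and treat point estimates cautiously.

The population comparison (`compare_populations`) fits the same
proportional-odds model to two ordered count vectors with a population
indicator.  Printed proportions are converted to integer counts by the
largest-remainder rule so category counts always sum to the arm size.

## Evidence synthesis

The conditional-binomial fixed-effect model pools arm-level counts per
treatment: `r_mod+ ~ Binomial(n, p1[t])`,
`r_good ~ Binomial(r_mod+, p2[t])`, logit links, Normal(0, 10) priors.
The posterior factorizes into independent one-dimensional terms, which
a per-coordinate adaptive random-walk Metropolis sampler (4 chains ×
2,000 post-warmup draws by default, acceptance tuned to 0.44) handles
easily; split-R̂ and effective sample size are computed with arviz and
summaries refuse to run below 400 effective draws.  The sampler is
validated three ways: a quadrature oracle for the exact 1-D posterior,
a conjugate flat-prior comparison, and simulation-based calibration
(rank uniformity under the prior) at reduced scale.

Per draw, the three category probabilities are (1−p1, p1−p2·p1, p1·p2)
with the middle category stored as the exact residual, so mass is
conserved to the last floating-point ulp.  `posterior_to_econ_inputs`
hands the draw cloud (tagged with its evidence source) to the PSA.

**A reproduction caveat.** Feeding the model the two rituximab arms
reconstructed from printed inputs (298 at 0.650/0.150; 1,360 at
0.215/0.090) yields a pooled mean of 0.293 for at-least-moderate —
the combined count fraction, as any count-level fixed-effect
likelihood must — with a credible interval a few percentage points
wide.  The originally reported pooled value, 0.336 (0.119, 0.636), has
an interval an order of magnitude wider than 1,658 Bernoulli trials can
produce, implying the original synthesis propagated the adjusted
emulation estimate's full posterior rather than its point counts; that
extra machinery is not described and is not reimplemented here.  An
effective-sample-size option (`use_effective_tte_n`) down-weights the
emulation arm to match its reported interval width for sensitivity
analysis.  Likewise, the reported population-comparison odds ratio of
0.30 (0.23, 0.37) is not recoverable from the two printed rituximab
arms alone (they give 0.21 with the *same* standard error as reported,
0.12 on the log scale); adding a placebo arm with externally plausible
values moves the estimate to ≈ 0.35, suggesting the original regression
included both treatment groups using arm data not printed.  The package
reports what the printed inputs yield.

## Economic model

A deliberately simplified reconstruction of a sequence-based RA
cost-effectiveness model, with every structural parameter a documented,
configurable illustrative default — absolute cost/QALY magnitudes are
**not** reproduction targets, only internal consistency and directions
of effect.

Structure per individual: treatments run in sequence (first-line
biologic → rituximab → nonbiologic therapy as the absorbing line).  At
6 months on a line the EULAR category is drawn; "none" switches
immediately, responders gain a HAQ improvement (−0.32 moderate, −0.55
good) and stay for an exponential time-on-treatment (means 2.0/3.5
years), after which HAQ rebounds to its pre-treatment level (the
standard rebound-equal-to-gain assumption) and the next line starts.
On nonbiologic therapy HAQ progresses at 0.045/year, bounded in [0, 3].
Utility is `clip(0.89 − 0.28·HAQ, −0.5, 1)`; mortality is a constant
baseline hazard 0.02/year times 1.33 per HAQ point, integrated
piecewise; death occurs when the accumulated hazard crosses a
pre-drawn exponential threshold.  Costs (biologic £4,600, rituximab
£3,500, nonbiologic £150 per 6 months, plus administration) are charged
at the start of each 6-month period begun.  Costs and utilities are
discounted continuously at ln(1 + 0.035) — so a constant utility u over
T years equals the exact annuity u·(1−(1+d)^−T)/ln(1+d), which the
test-suite verifies to 1e−9 along with per-trace conservation of every
discounted increment.

**Randomness and coupling.** Each individual owns a fixed pool of
uniforms: one per treatment slot for the response category (inverted
from the top, so stochastically better response vectors map the same
uniform to the same-or-better category), one per slot for
time-on-treatment, one cumulative-hazard threshold for death, and a
baseline HAQ draw.  With common random numbers (default) the same pool
is reused by both strategies and by every PSA iteration, so (a)
identical strategies produce identical results exactly, (b) improving
one treatment's response distribution cannot lower its strategy's mean
QALY, and (c) PSA spread isolates parameter uncertainty.  The PSA
draws rituximab response vectors from the evidence-synthesis posterior
(or a point mass), first-line response from a Dirichlet, drug costs
from Gammas (CV 0.15), and HAQ improvements from truncated normals;
600 iterations of 2,000 individuals are the configured defaults, with
tests and the packaged scenarios running reduced sizes (60 × 500) that
leave all directional conclusions unchanged.  The mean ICER is the mean
of per-iteration ratios (iterations with ΔQALY = 0 are excluded with an
explicit count); the ratio of mean increments is reported alongside.

## Workflow

The three scenarios differ only in the evidence source feeding the
rituximab response probabilities: the trial arm alone, the emulated
registry analysis alone, or their pooled posterior.  Each stage writes
CSV/JSON artifacts plus SVG figures, and a manifest containing the
configuration and SHA-256 of every table; identical configuration and
seed reproduce identical manifests.  Scenario costs and ICERs in the
comparison table are rounded to the nearest £100, half away from zero.

## Known limitations

- The economic model omits adverse-event pathways, differentiated
  biologics, age/sex-specific mortality and the original
  HAQ-to-hospital-cost mapping; its magnitudes are illustrative.
- The stacked variance assumes unstabilized, untruncated ATE weights.
- The meta-analysis is fixed-effect by design; between-study
  heterogeneity is out of scope.
- Multiple imputation assumes MAR given the observed covariates, which
  the generator satisfies by construction; real registers may not.
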