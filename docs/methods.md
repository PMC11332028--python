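# Methods

This package implements, end to end on synthetic cohorts, the analysis
stack of a two-phase experiment: a two-arm reversal bandit whose
trial-unique stimuli carry normed perceptual-memorability ratings,
followed by an old/new recognition test for those stimuli. The question
the stack answers is how the reward prediction error (RPE) attached to a
stimulus at encoding, and the stimulus' intrinsic memorability (PM),
jointly shape later recognition — and whether transdiagnostic affect
moderates the RPE–memory link at the subject level.

## Task and generative model

**Bandit.** 60 trials; one arm pays 1 (displayed as 100 points) with
probability 0.8 and the other with 0.2; the assignment reverses 4 times,
every 12 ± 1 trials. Block lengths are drawn uniformly from
{11, 12, 13}; the final block absorbs the remainder so the total is
exactly 60. Rewards are coded 0/1 internally — the fitted inverse
temperatures are only on the reported scale (β ≈ 5) under unit-scaled
rewards; the 100-point display is cosmetic. The within-block trial
counter restarts at 1 after every reversal and is a covariate of the
memory models.

**Agents.** Three generative policies mirror the candidate decision
models (below). Cohort simulations draw Rescorla–Wagner parameters from
α ~ N(0.73, 0.19) clipped to [0.05, 0.98] and β ~ N(4.9, 2.9) clipped to
[0.5, 12], the reported cohort distribution of the study population this
generator emulates. Subject traits: age ~ N(40, 14) clipped to [18, 80],
sex Bernoulli(0.5).

**Stimuli.** Each trial shows a unique stimulus with a memorability
d′ drawn from a truncated normal (mean 2.2, SD 0.25, support
[1.5, 3.0]) — a "highly memorable" pool with modest variance, chosen
once as a realistic emulation of a face-memorability database subset;
no published pool distribution was available. Lures draw from the same
distribution (distribution-matched, not item-matched).

**Recognition phase.** Per subject, the 60 encoded stimuli return as old
probes together with 60 lures in random order. The probability of a
*correct* old/new judgment is logistic in the 2-SD-standardized encoding
RPE, stimulus PM and within-block trial, with per-subject random
intercepts (SD 0.5) and random RPE/PM slopes (SD 0.2 each). Group
coefficients default to the effect sizes the design targets
(b₀ = 1.0, b_RPE = 0.17, b_PM = 0.16, b_trial = −0.12). RPE and trial
are undefined for lures and are zero-imputed on the standardized
(mean-centered) scale — the shared convention of every downstream model.
Random-slope SDs are a generator extension beyond the group-level
coefficients: without them, subject-level "reliance on RPE" would be
degenerate and the moderation analyses untestable.

Reaction times come from a Wiener diffusion whose drift is
±v₀ + v_RPE·RPE_std + v_PM·PM_std (positive baseline toward the "old"
boundary for old probes, negative for lures; defaults a = 1.8, z = 0.5,
t = 0.35 s, v₀ = 0.8, v_RPE = 0.046, v_PM = 0.038). Two coupling modes
exist. In the default mode the response comes from the logistic model
and the RT is the unconditional first-passage time — accuracy then has
exactly the stated logistic structure, but choice and RT are conditionally
independent, which real data are not. In the coupled mode
(`couple_rt_to_response=True`) response and RT are generated jointly by
the diffusion (response = boundary reached); this is the mode used to
validate the DDM fits, where choice/RT coherence is the point.
Consequently, passing tests show that each estimator recovers its own
generative structure; they do not show that one latent process produces
both regularities at once, as presumably happens in real subjects.
Confidence ratings are generated (uniform 1–4) only for format fidelity
and are never modeled.

**Surveys.** 58 Likert items emulating three symptom scales (20 trait
anxiety, 20 depression, 18 obsessive–compulsive) load 0.7 on one of
three correlated factors; uniqueness completes unit marginal variance;
continuous scores are discretized to 4 levels at equal-probability
normal thresholds, and a fixed subset of items is stored reverse-coded.
Default factor correlations are (−0.62, −0.22, −0.38) — the correlations
reported for the transdiagnostic scores this generator emulates. A
caveat discovered in validation: under those strong correlations the
first two eigenvalues dominate (≈15, 10, 2.2, …) and the CNG scree test
genuinely selects 2 factors; with uniform factor correlations of −0.4
(the configuration used in the factor-pipeline validation) it selects 3.
CNG is a scree heuristic, not an estimator of the generative rank, and
this sensitivity is expected behavior, not an implementation artifact.

## Decision models

* **Rescorla–Wagner**: Q-learning with delta rule
  Q_{t+1}^c = Q_t^c + α(r_t − Q_t^c) and softmax choice with inverse
  temperature β. Q₀ = 0.5 for both arms — the uninformative midpoint of
  the 0/1 reward scale (not otherwise specified by the design). The
  trial-level RPE is r_t − Q_t^c *before* the update; under 0/1 rewards
  it lies in [−1, 1].
* **Win-stay/lose-shift**: the rule-consistent action (repeat after a
  win, switch after a loss) is emitted with probability ε; trial 1 has
  probability 0.5. ε is a per-trial adherence probability — the
  plainest reading of a one-parameter "choice bias".
* **Bayesian filter**: two hidden states (which arm is correct), mixed
  each trial by the transition matrix [[1−p_switch, p_switch],
  [p_switch, 1−p_switch]], then updated by the reward likelihood
  (p_reward for the state-correct arm, 1−p_reward otherwise). The
  action probability is the *predictive* (post-transition, pre-outcome)
  state probability of the chosen arm — probability matching. A
  softmax-on-expected-reward alternative is exposed through the
  likelihood's ``action_rule`` argument, but probability matching is the
  default and the rule used by the fitted model.

**Fitting.** Per subject (no pooling), by adaptive random-walk
Metropolis in an unconstrained parameterization (logit for probabilities,
log for β) with per-chain empirical proposal covariance adapted during
warm-up and frozen afterwards. Priors: α, ε ~ Beta(1, 1),
β ~ HalfNormal(10), p_reward ~ U(0.5, 1), p_switch ~ U(0, 0.5) — weakly
informative and bound-respecting. Default settings are 4 chains × 4000
retained draws after 4000 warm-up; every fit reports per-parameter
split-R-hat and warns above 1.05 rather than failing silently.
Degenerate (constant-choice) data are rejected up front.

**Comparison.** WAIC on the deviance scale, −2(lppd − p_waic) with the
variance-based penalty (sample variance, n−1 denominator), computed from
the full pointwise log-likelihood table. Per-subject winners are counted
and tested against uniform expectation with a chi-square test of
proportions. Point estimates are posterior means; RPE extraction is a
forward pass of the delta rule at the posterior-mean α.

## Drift-diffusion models of recognition

RTs are cleaned by the study's rules: drop < 300 ms or > 10 s, then drop
trials beyond 3 subject-level SDs of the subject mean (computed on the
absolute-bound survivors); subjects left with fewer than 2 trials are
flagged and excluded from hierarchical fitting.

The Wiener first-passage-time density is implemented with the standard
dual series expansion and per-point small/large-time branch selection by
truncation-error bound (capped at 120 terms; both branches agree to
better than 1e-6 in the crossover region). The upper boundary codes an
"old" response; the reflection identity f_upper(rt; v, z) =
f_lower(rt; −v, 1−z) maps all evaluations onto the lower-boundary form.
Density is 0 at rt ≤ t.

Drift is regressed on one standardized covariate (RPE or PM; links:
linear, quadratic, or a shifted log, log(x − min(x) + 1), since signed
RPEs make a raw logarithm undefined) with a group intercept and slope
plus per-subject random deviations; a, z, t are pooled across subjects.
Fits use old-probe trials by default (RPE does not exist for lures; the
RPE and PM models are compared on identical trial sets), with an
all-trials option under the shared zero-imputation convention. Priors:
slope/intercept ~ N(0, 2); a ~ Gamma(2, 1) on (0, 5); z ~ Beta(2, 2);
t ~ U(0.05, 0.99·min RT); random-effect SDs ~ HalfNormal(1). Model
ranking is by WAIC with the SE of each pairwise difference computed from
paired pointwise elpd contributions, on identical trial sets only.

## Memory regression

Hits and correct rejections are correct; misses and false alarms are
incorrect. d′ = Φ⁻¹(hit rate) − Φ⁻¹(FA rate), with extreme rates clamped
to [1/(2N), 1 − 1/(2N)] — the standard correction; the source design did
not specify one. All numeric predictors are standardized by centering
and dividing by **two** SDs (sample SD, n−1 denominator), putting them
on the scale of a ±0.5 binary predictor; sex is sum-coded ±0.5.

The mixed-effects logistic regression has fixed effects for the
trial-level covariates (RPE, PM, within-block trial) and optional
subject-level traits (age, sex, fitted α and β, total reward, factor
scores), with per-subject random intercepts and random RPE/PM slopes.
Priors: N(0, 2.5) on standardized fixed effects, HalfNormal(1) on
random-effect SDs. An effect is "meaningful" iff its 95% highest-density
interval excludes zero. Exported per-subject slopes (β_RPE, β_PM) are
the group effect plus the posterior-mean deviation.

## Hierarchical sampling

Hierarchical models (DDM and GLM) are fit by Metropolis-within-Gibbs:
an adaptive joint update of the shared/group block alternates with a
vectorized per-subject update of non-centered random-effect deviations
(deviation = SD × raw, raw ~ N(0, 1)). Plain alternation mixes slowly
along two well-known ridges, so each sweep adds exact, likelihood-
invariant interweaving moves: (i) translation — a fixed effect and its
subjects' deviations shift jointly (closed-form Gaussian conditional),
generalized with per-subject weights so subject-constant covariates
(age, sex, …) can trade against the random intercepts; (ii) scale — each
log-SD is re-sampled in the centered parameterization with the
deviations held fixed (short 1-D MH on its conditional). The shared
block is updated 3× and the subject block 2× per sweep. With these
moves the default-settings fits reach split-R-hat ≈ 1.01 or below;
convergence is always reported and warned on, never assumed.

WAIC for the hierarchical fits is computed from a thinned posterior
(≤ 250 draws per chain) to bound the pointwise log-likelihood table;
with thousands of retained draws the thinning error in lppd and the
penalty is far below the comparison SEs.

## Subject-level moderation and equivalence

Memory performance (d′ by default; the proportion-correct alternative is
a one-line change) is regressed by OLS on an exported random slope, a
factor score, and their interaction, with the 2-SD rule applied to the
predictors and a condition-number guard against collinearity. Every null
coefficient is accompanied by a TOST equivalence test against the
prespecified bounds [−0.1, 0.1]: two one-sided t tests at the OLS
residual df, p_eq = max of the two one-sided p values, equivalence
concluded at p_eq < 0.05. Tercile splits of factor scores are a plotting
convenience only and never enter inference.

## Exclusions and pipeline

A subject is retained when a one-sided exact binomial test rejects
chance (0.5) accuracy — proportion of higher-probability-arm choices —
in the above-chance direction at p ≤ 0.05 (threshold configurable; the
direction and test are this package's choice). The pipeline runs
simulate → exclude → decision models + WAIC → RPE extraction → DDMs →
factor analysis → memory GLM → moderation + equivalence; every stage is
seeded from the run seed via spawned seed sequences, all randomness is
reproducible (identical seeds give byte-identical data files), and the
final report is assembled strictly from the stage artifact files.

## Factor analysis

Pearson correlations on the recoded Likert items (polychoric
correlations are out of scope, matching common practice in the
transdiagnostic literature); singular correlation matrices receive a
1e-8 ridge with a logged warning. KMO and Bartlett's sphericity test use
their textbook formulas. CNG selects the factor count at the maximal
difference between slopes of successive 3-eigenvalue linear fits of the
raw correlation-matrix scree (the communality-adjusted alternative was
not used). Extraction is maximum likelihood (statsmodels), followed by
varimax and an in-repo promax with power 4 (the conventional default);
factor correlations are Φ = (UᵀU)⁻¹ of the normalized rotation, so
communalities are preserved exactly. Heywood cases are flagged and
uniquenesses floored at 0.005. ten Berge scores use the
correlation-preserving construction W = R^{−1/2} C Φ^{1/2} with
C = R^{−1/2} L* (L*ᵀ R^{−1} L*)^{−1/2}, L* = Λ Φ^{1/2}; the sample
correlations among score columns equal Φ̂ by construction. Recovery
tests align estimated to generating factors by brute-force permutation
and sign search over Tucker congruence (k ≤ 4).

## Problem sizes and numerical choices

Validation runs use cohorts of 10–50 subjects with the full 60-trial
design, 25 subjects for the hierarchical DDM recovery (one cohort),
30 agents per model for identifiability, 20 cohorts of 15 subjects for
GLM calibration, and n = 10,000 respondents for the factor pipeline —
sizes at which each property is comfortably decided by the statistics
involved. Reduced sampler settings (hundreds rather than thousands of
draws) are used where only point estimates or rankings matter;
convergence-discipline checks always run at the default 4 × 4000/4000.
WFPT quadrature checks integrate to 90 s with SciPy's adaptive rule
(tolerance 1e-4); the forward-simulation oracle uses Euler–Maruyama at
dt = 1e-4 (Kolmogorov–Smirnov D < 0.01 against the analytic density;
at dt = 1e-3 the discretization bias itself is visible at D ≈ 0.02).

## Known limitations

* The default recognition generator decouples choice from RT (see
  above); only the coupled mode exercises the joint DDM likelihood.
* Random-walk Gibbs sampling, even with interweaving, has a finite
  mixing speed: very weakly identified scale parameters (random-slope
  SDs in small cohorts) can sit at R-hat ≈ 1.01–1.07 at moderate draw
  counts. The diagnostics expose this; nothing hides it.
* WSLS's ε and the Bayes filter's action rule are each one of several
  defensible readings of a one-line verbal description; both are
  documented above and isolated behind their likelihood functions.
* The memorability pool, survey factor correlations and random-effect
  SDs are package choices where no published value exists; all are
  explicit defaults, set once, and recorded here.
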