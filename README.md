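# rpe-memory

How do the reward prediction errors (RPEs) we generate while learning
shape our later memories of the stimuli we learned from — and does
affect regulate that link? This package implements the full analysis
stack for a two-phase behavioral design that asks exactly that: a
60-trial two-arm bandit with reward reversals, whose trial-unique
stimuli carry normed perceptual-memorability (PM) ratings, followed by
an old/new recognition test with memorability-matched lures. Everything
runs on synthetic cohorts generated by the package itself — no data
download — so every estimator can be validated against known generative
truth. It is written for computational-psychiatry and decision-
neuroscience researchers who want a tested, reusable reference
implementation of this kind of pipeline.

The stack comprises:

* **Decision models** — Rescorla–Wagner value learning
  (Q_{t+1}^c = Q_t^c + α(r_t − Q_t^c), softmax choice with inverse
  temperature β), a win-stay/lose-shift heuristic (adherence ε), and a
  two-hidden-state Bayesian filter (p_reward, p_switch) — each fit per
  subject by 4-chain MCMC and compared by WAIC with a chi-square test on
  the winner counts. Trial-level RPEs (r_t − Q_t^c) come from the
  posterior-mean learning rate.
* **Hierarchical drift-diffusion models** of recognition RT and choice:
  an in-repo Wiener first-passage-time likelihood (dual series
  expansion), the standard RT exclusions (300 ms / 10 s, 3-SD
  subject-level), and drift regressed on standardized RPE or PM with
  random intercepts/slopes per subject and pooled boundary a, start
  point z, non-decision time t.
* **A Bayesian mixed-effects logistic regression** of memory success
  (hits + correct rejections vs misses + false alarms) on RPE, PM,
  within-block trial and subject-level traits, with the 2-SD
  standardization rule and the 95%-HDI-excludes-zero decision criterion;
  signal-detection d′ with extreme-rate clamping.
* **Transdiagnostic factor analysis** of synthetic symptom surveys
  (trait anxiety / depression / obsessive-compulsive items): KMO,
  Bartlett's sphericity test, CNG factor-count selection, ML extraction
  with promax rotation, and correlation-preserving ten Berge factor
  scores.
* **Subject-level moderation**: OLS of memory performance on the
  per-subject random slopes × factor scores, with TOST equivalence
  tests (bounds ±0.1) for every null coefficient.

The generative layer (`synthetic` task schedules, agents, recognition
outcomes/RTs, Likert surveys) is first-class, tested code; see
`docs/methods.md` for the model, its assumptions, all defaults and their
rationale.

## Worked example

The numbered drivers under `analysis/` run the whole study on a
simulated 30-subject cohort and write their tables under `results/`:

```bash
python analysis/01_simulate_cohort.py
python analysis/02_fit_decision_models.py
python analysis/03_fit_recognition_ddm.py
python analysis/04_factor_analysis.py
python analysis/05_fit_memory_glm.py
python analysis/06_subject_moderation.py
```

Output of the first two stages (default seeds):

```
simulated 30 subjects; excluded 9 at chance (['s008', 's012', ...])
retained accuracy: mean 0.71 (range 0.63-0.83)

WAIC winners: {'bayes': 4, 'rw': 17, 'wsls': 0} (chi2=22.6, p=1.3e-05)
cohort estimates: alpha 0.68 +/- 0.16, beta 8.1 +/- 4.4; max R-hat 1.0267
reward landscape peak at alpha=0.9, beta=8.0 (37.9/60 wins)
```

Nine of 30 simulated subjects fail the above-chance binomial test and
are excluded (the cohort deliberately includes slow/noisy learners).
Among the retained, the value-learning model wins the WAIC comparison
for 17 of 21 subjects, the recovered learning rates average 0.68, and a
grid search over (α, β) confirms that fast learning plus nearly
deterministic choice maximizes reward on this task — 37.9 of 60 possible
wins, versus 30 for random choice. Later stages print the drift-rate
slopes with their 95% HDIs and the WAIC ranking of the RPE- vs
PM-driven DDM, the fixed-effect table of the memory regression (at this
21-subject scale most individual-difference HDIs straddle zero, as
expected), the factor solution (KMO = 0.95, Bartlett χ²(1653) = 9454),
and the moderation table with TOST equivalence verdicts.

Everything the drivers do is importable:

```python
import rpe_memory as rm

sched = rm.generate_task_schedule(rm.TaskConfig(seed=1))
agent = rm.simulate_agent(rm.AgentSpec("rw", {"alpha": 0.7, "beta": 5.0}), sched, seed=2)
fit = rm.fit_model("rw", agent)          # 4 chains x 4000 draws
print(fit.point_estimate, fit.max_rhat)  # {'alpha': 0.72..., 'beta': ...} 1.00...
```

`rm.run_pipeline(rm.RunConfig(seed=0), "out/")` runs every stage in one
call and writes a stage-traceable report.

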