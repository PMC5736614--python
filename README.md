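# feedlearn

Simulation and longitudinal analysis of feedback learning across
development: a deterministic engine for a three-stimulus rule-sorting task,
trial-by-trial classification of feedback events by informative value and
valence, the learning-performance statistic, and the accelerated-longitudinal
mixed-model machinery (polynomial age ladders, peak ages, ICC, residualized
brain–behaviour regressions, lagged prediction, and a correlated-variables
multiplicity correction) — all runnable end to end on synthetic cohorts with
known ground truth.

## The problem

In a developmental fMRI design, participants aged 8–25 at enrollment perform
a feedback-learning task at up to three biannual waves. On each trial they
sort one of three stimuli into one of three squares and receive positive or
negative feedback; a sequence ends after 12 trials or once every stimulus
has been sorted correctly twice. Feedback early in a sequence carries
*informative value* (the rule is still being learned); once a stimulus has
been sorted correctly and continues to be, feedback is mere *application*.
The questions this package's machinery addresses: how do neural sensitivity
to informative value and to valence, and learning performance itself, change
with age — and does striatal sensitivity predict current and future
performance?

## Core statistics

**Learning performance.** Each feedback event is classified per stimulus:
learning-phase events (no prior correct sort) are *used* when the next
responded presentation stays after positive or switches after negative
feedback. Performance is

    P = 100 · (used learning events) / (all evaluable learning events)

**Age ladder.** For outcome y (ROI activity or performance) with subject
random intercepts u_i:

    degree 0:  y_ij = β0 + u_i + ε_ij
    degree 1:  … + β1·age_ij
    degree 2:  … + β1·age_ij + β2·age_ij²

fitted by full ML on an orthonormal age basis, compared by AIC and step-up
χ²(1) likelihood-ratio tests. A concave degree-2 fit yields a peak age
−β1/(2β2) (raw basis) with a parametric-bootstrap CI. ICC is
σ²_u/(σ²_u+σ²_ε) from the degree-0 fit.

**Brain–behaviour.** Activity is residualized against its selected age
model (fixed effects only), then `performance ~ age + age² + residual +
(1|subject)` tests the coupling; significance is judged against a
Bonferroni threshold softened for correlated tests, α_adj = α / k^(1−r̄)
(k = 6 tests, mean inter-variable correlation r̄ = 0.66 → α_adj = 0.027).

## Worked example

The numbered drivers under `analysis/` run the whole chain on synthetic
data and write their tables to `results/`:

```sh
python analysis/01_simulate_behavior.py --seed 0
python analysis/02_fit_trajectories.py  --seed 0
python analysis/03_brain_behavior.py    --seed 0
```

`01` simulates win-stay/lose-shift agents through the task and scores them:

```
trial ceilings: waves 1-2 session 180 trials, wave 3 session 120 trials
       n  performance_mean  performance_sd  learning_trials_mean ...
wave
1     79             93.80            3.12                 89.97
2     79             95.01            2.87                 89.73
3     79             94.50            3.41                 59.08
3 session(s) flagged as extreme low performers
```

— the 180/120 ceilings are the task arithmetic (15×12 and 10×12 trials),
and mean performance sits in the low-to-mid 90s with the wave-3 session
shorter by design. `02` fits the age ladder per ROI×contrast stratum and
for performance on the default synthetic cohort (271 subjects, 744
subject-waves):

```
behavior/performance: degree 2 (any-step 2), ICC 0.459, peak 20.9 y [19.7, 22.8]
dorsal_caudate/informative_value: degree 0 (any-step 2), ICC 0.450
nucleus_accumbens/informative_value: degree 2 (any-step 2), ICC 0.427, peak 17.3 y [16.9, 17.8]
ventral_caudate/informative_value: degree 2 (any-step 2), ICC 0.399, peak 18.0 y [17.6, 18.4]
```

Performance peaks at ~21 y (generating truth 20.5) and informative-value
sensitivity peaks in late adolescence. Dorsal caudate illustrates the two
selection rules: its generating peak sits mid-range, so the linear step is
flat and the conservative forward-sequential rule stops at degree 0 while
the any-step rule finds the quadratic. `03` links activity residuals to
performance:

```
adjusted alpha 0.027 (m_eff 1.84); measured mean correlation 0.59
  dorsal_caudate/informative_value: B = 0.69 (SE 0.12), p = 0.0000 **
  ventral_caudate/informative_value: B = 0.54 (SE 0.12), p = 0.0000 **
  wave 1 dorsal_caudate -> wave 2 performance: beta = 0.23, p = 0.0002, N = 244
  wave 1 nucleus_accumbens -> wave 2 performance: beta = 0.09, p = 0.1677, N = 244
```

— the generated couplings (dorsal/ventral caudate only) are recovered, the
adjusted threshold is 0.027, and earlier-wave caudate activity predicts
next-wave performance. The same chain runs from a single config file:

```sh
feedlearn pipeline --config configs/default.yaml --seed 0 --out-dir results/pipeline
```

Other CLI subcommands (`simulate`, `classify`, `cohort`, `fit`, `link`,
`lagged`) expose the individual stages; `python -m feedlearn.cli --help`
lists them.

## Layout

```
src/feedlearn/        task_engine, agents, phase_classifier, synthetic_cohort,
                      trajectory_models, brain_behavior, pipeline, cli
analysis/             numbered drivers writing tables to results/
configs/default.yaml  the one-file pipeline configuration
docs/methods.md       models, defaults, numerical choices, limitations
tests/                pytest suite incl. independent brute-force oracles
```
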