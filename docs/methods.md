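# Methods

`feedlearn` implements, as tested and reusable code, the analysis chain of a
developmental feedback-learning study: a rule-sorting task with trial-by-trial
feedback, classification of every feedback event by informative value and
valence, a learning-performance statistic, and the accelerated-longitudinal
mixed-model machinery that maps ROI activity and behaviour onto age
trajectories and links them to each other. Because the original scan-level
data are not deposited, every downstream stage is exercised on synthetic
cohorts with known ground truth; this note records the models, the defaults
and why, the numerical choices, and what the synthetic results do and do not
show.

## Task model

Each sequence presents three novel stimuli to be sorted into three squares
under a bijective stimulus→square rule. Feedback is positive iff the chosen
square is correct. A sequence ends after 12 trials or as soon as every
stimulus has been sorted correctly at least twice, whichever comes first; a
session is 15 sequences at waves 1–2 (≤180 trials) and 10 at wave 3 (≤120).
Trial timing is fixation 500 ms, stimulus+response 2500 ms, feedback
1000 ms, with a uniform 0–6 s jittered inter-trial interval (only the
marginal jitter range is modelled; design-efficiency optimisation of the
jitter sequence is out of scope).

Choices the task description leaves open, decided here:

- **Presentation schedule.** Within a sequence, stimuli appear in permuted
  blocks of three (no stimulus twice before each has appeared once). This
  matches common practice and guarantees the interleaving the classifier
  needs to evaluate "use on the next presentation".
- **Criterion timing.** The criterion is checked after every completed
  trial, so a sequence can end mid-block.
- **Too-late trials** carry no feedback, count toward the 12-trial cap but
  not toward the criterion counters, and are events of no interest
  downstream.

The floor/ceiling arithmetic is exact: a never-correct responder produces
180 (waves 1–2) or 120 (wave 3) trials; an always-correct responder needs
6 trials per sequence (90 per wave-1 session).

## Feedback classification and learning performance

Classification runs per stimulus in presentation order. A presentation with
no prior correct response is in the **learning phase**; its feedback is
*used* when the next responded presentation of the same stimulus stays after
positive feedback or switches after negative feedback. Used learning events
are `learning_pos`/`learning_neg`; unused ones are `excluded_nonlearning`.
After a prior correct response, a correct presentation whose next responded
presentation is also correct (or which has none) is `application`;
everything else — too-late trials, relapses after a correct sort, the
correct trial immediately preceding a relapse, and final learning-phase
trials with no later response — is `no_interest`.

Learning performance is
`100 · (learning_pos + learning_neg) / (learning_pos + learning_neg + excluded_nonlearning)`,
undefined (and the session flagged) when the denominator is empty.

Interpretation choices, each a potential deviation from the original
analysis and therefore exposed or documented:

- A switch after negative feedback counts as *use* even when it lands on
  the other wrong square: use is stay/switch, not success.
- "Next presentation" skips too-late trials (a missing response cannot
  confirm or disconfirm feedback use).
- Unevaluable final learning trials are excluded from the performance
  denominator by default; `include_unevaluable_final=True` counts them as
  unused instead.
- A relapse never re-enters the learning phase: once a stimulus has been
  sorted correctly, its feedback is no longer treated as informative.
- Behavioural outliers are flagged wave-wise at performance more than 3 SD
  *below* the wave mean (the direction that indicates not understanding the
  task); the threshold is configurable.

The classifier is verified against an independently written brute-force
walker of the same rules (per-trial full scans, no shared code or state) on
thousands of random sessions.

## Behavioural agents

The generative participant is a stochastic win-stay/lose-shift learner:
stay after positive feedback with probability `p_use_positive`; switch
after negative feedback with probability `p_use_negative`, avoiding
squares already disconfirmed for that stimulus when elimination memory
fires (`p_elim_memory`); respond too late with probability `p_too_late`;
choose uniformly on first presentations. This is the minimal policy family
whose summary statistic is exactly the learning-performance measure.

A developmental profile maps age to the two use-probabilities through a
concave quadratic on the logit scale peaking at `peak_age` (default 20.5 y),
plus a subject-level logit offset (SD 0.35) for stable individual
differences. Defaults (peak logits 3.2/2.9, curvature 0.007 y⁻²,
`p_elim_memory` 0.5, `p_too_late` 0.02) put wave-level mean performance in
the low-to-mid 90s with SD ≈ 3, rising from childhood to a peak around age
20 — the target performance profile. The elimination-memory default is
arbitrary: nothing in the behavioural statistic identifies it, and no claim
is made that real participants eliminate.

Known limitation: the agent's memory is per-stimulus only. A learner using
cross-stimulus exclusion (stimulus 1 is in square A, so stimulus 2 is in B
or C) learns faster than any within-stimulus policy; the observed trial
economy of real participants (≈70 learning trials in a wave-1 session,
versus ≈90 for this agent at chance-level first guesses) indicates such
exclusion. Simulated trial-count summaries are therefore conservative, and
the agent should not be read as a cognitive model — it is a behaviour
generator whose performance statistic is controllable.

## Synthetic accelerated-longitudinal cohort

Subjects enter at ages uniform on 8–25 (wave 1), return at 2-year gaps for
up to three waves; wave 1 is enrollment, later waves are retained
independently with probability 0.86, emulating observed inclusion counts
(271/233/232) and allowing non-monotone attrition. Ages are centred at
18.5 y — the midpoint of the observable 8–29 span — so quadratic
coefficients and vertex formulas are interpretable.

Activity per ROI×contrast stratum is
`b0 + b1·c + b2·c² + u_subject + e`, with `c` the centred age, and both the
subject intercepts and the observation noise drawn equicorrelated across
strata (default r = 0.66) so the observed mean inter-variable correlation
matches the analysis' multiplicity assumption. Default trajectories:
informative-value sensitivity concave in every striatal ROI (b2 = −0.025,
peaks 17.5–18.5 y); valence sensitivity flat in dorsal caudate, linearly
decreasing in ventral caudate, shallowly convex in nucleus accumbens —
the qualitative pattern the analysis is meant to detect. Unit SDs for both
variance components give ICC = 0.5, the "moderate reliability" regime.

Performance is its own quadratic (peak 95 at 20.5 y, between-subject SD 4,
residual SD 3 → ICC ≈ 0.6 before truncation) plus a coupling term
`Σ coupling_r · (activity residual)_r` (default: +0.5 and +0.45 performance
points per residual unit in dorsal and ventral caudate informative-value,
0 elsewhere), truncated to [0, 100]. Ceiling scorers arise two ways:
truncation itself, plus an injected exact-100 fraction per wave (2/5/15%),
jointly producing observed ceiling rates that rise with wave as in the
emulated design. Because truncation also creates exact-100 scores, the
injected rate is *not* the observed rate; tests that need the two to
coincide set the performance curve far below 100.

The generator emulates the design's structure, not its physiology: no
scanner noise, no motion, no practice effects, no cross-wave change in
coupling, Gaussian everything. Passing recovery tests therefore shows the
*analysis machinery* is correct and calibrated under the design's sampling
structure — not that the original effect sizes are reproducible from real
data.

## Mixed models and the age ladder

All trajectory models are random-intercept linear mixed models estimated by
full maximum likelihood (never REML, because the ladder compares models
with different fixed effects). The ladder fits degree 0 (intercept only),
1 (linear age) and 2 (quadratic age); steps are compared by χ²(1)
likelihood-ratio tests on 2·Δloglik (no boundary correction — the variance
components are common to the compared models) and by AIC
(`2k − 2·loglik`, k = fixed effects + 2 variance parameters).

**Estimation.** For a fixed variance ratio λ = σ²ᵤ/σ²ₑ the GLS coefficients
and σ²ₑ have closed forms through the Sherman–Morrison identity on the
compound-symmetric within-subject covariance, leaving a univariate profiled
log-likelihood in λ. It is maximised deterministically: a 37-point grid on
log λ ∈ [−10, 8], bounded Brent refinement between the flanking grid points
(xatol 10⁻¹⁰), and an explicit λ = 0 boundary evaluation. This replaces
multi-start optimisation of the joint problem: the profiled objective is
one-dimensional, so the grid+refine scheme is both deterministic and
exhaustive at this tolerance. The fit is verified in the test suite against
(a) a dense-linear-algebra brute-force profile likelihood on tiny data
(agreement to 10⁻⁴ in loglik) and (b) statsmodels `MixedLM` with ML on a
moderate cohort (loglik to 10⁻⁴, variance components to 0.1%). Residual
variance is floored at 10⁻¹² so degenerate (constant-outcome) fits return
finite log-likelihoods; a fitted λ ≈ 0 is flagged as a singular random
intercept but retained.

**Age basis.** Fits use an orthonormal polynomial basis built by QR
factorisation of the standardised-age monomials on the fitting sample
(column 0 is the constant). Reported coefficients always carry their basis;
every fit also exposes the polynomial mapped back to the raw-age scale, and
predicted curves are basis-invariant (verified against a raw centred-basis
fit). Curves and peak ages — not coefficient values — are the comparable
surface across software, since printed coefficients from other pipelines
sit on undeclared age codings.

**Selection rule.** The default is *forward-sequential*: climb the ladder
while each step's LRT is significant at α = 0.05 and stop at the first
non-significant step. Under the no-age null this holds the probability of
selecting any age effect at the nominal 5% (verified at 4.8% over 500 null
cohorts); the alternative "highest significant step" rule has a ≈ 1−0.95² ≈
9.8% family rate by construction. The cost is a blind spot the alternative
rule does not have: a concave trajectory peaking near the centre of the age
range has almost no linear component, so the forward rule can stop at
degree 0 even when the quadratic step is strongly significant. Both rules
(plus plain lowest-AIC) are available everywhere (`rule=` /
`ModelComparison.select`), and the trajectory driver reports both
selections side by side.

**Peaks, bands, ICC.** Trajectory curves carry pointwise delta-method 95%
bands from the fixed-effect covariance. The peak age of a degree-2 fit is
the vertex −b₁/(2b₂) of the raw-age polynomial, valid only when b₂ < 0 and
the vertex lies inside the observed age range; its CI is a parametric
bootstrap (default 2000 draws from the coefficient sampling distribution,
concave draws only). ICC is σ²ᵤ/(σ²ᵤ+σ²ₑ) from the degree-0 fit. Recovery
under the default design: mean recovered peak within 0.1 y of a true
18.5-y vertex over 100 cohorts of 250 subjects; mean recovered ICC within
0.01 of a true 0.5 at 1000 subjects (single-dataset sampling SD ≈ 0.017 at
that size, which is why recovery is assessed on the replicate mean).

## Brain–behaviour analyses

- **Residualisation** subtracts each stratum's selected-age-model *fixed*
  prediction from activity. Random intercepts are deliberately not
  subtracted — they carry exactly the stable between-subject signal the
  brain–behaviour question concerns. On a balanced design the fitting-sample
  residuals average to exactly zero; under dropout the zero mean holds in
  the GLS-weighted sense.
- **Hierarchical test**: performance ~ age + age² + residual with subject
  random intercept (ML); the residual coefficient is reported with its Wald
  z-test and the AIC change against the age-only model. Calibration: 5.0%
  type-I rate at zero coupling over 500 cohorts; 99% power for a coupling
  of 0.5 performance points per residual unit at 250 subjects.
- **Ceiling sensitivity** removes subject-waves scoring exactly 100 and
  reports removals per wave.
- **Lagged prediction** regresses later-wave performance on earlier-wave
  activity, both standardised, over subjects present at both waves (≥10
  complete pairs required). The default has no age covariate; an
  `age_adjust` switch adds predictor-wave age, since either reading of the
  original analysis is defensible. Note that with age-graded trajectories
  in both variables an unadjusted lagged β is partly age-carried; the
  synthetic-null test for this regression therefore uses flat trajectories.
- **Multiplicity correction**: the effective number of tests is
  m_eff = k^(1−r̄) with Bonferroni division α/m_eff. With k = 6 (3 ROIs × 2
  contrasts) and r̄ = 0.66 this yields α = 0.027 at 3-decimal reporting
  precision, reproducing the target adjusted threshold; the Šidák-style
  variant 1−(1−α)^(1/m_eff) rounds to 0.028 and is not used. k, r̄ and the
  family α are arguments, and r̄ can be measured from the data
  (`mean_pairwise_correlation`, mean Pearson r over complete pairs,
  constant variables skipped with a warning).

## Problem sizes and determinism

Every stochastic stage takes a NumPy `Generator` or integer seed and is
bit-reproducible under a fixed seed. The shipped analysis drivers use the
default cohort (271 subjects, ≈740 subject-waves). Calibration suites use
500 replicates for type-I rates and 100 for power/recovery at 150–250
subjects — sizes at which the binomial error of a 5% rate is below one
point and a full ladder fits in ~15 ms. The one-config pipeline
(`configs/default.yaml`) runs the complete chain in a few seconds.
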