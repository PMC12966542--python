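# Methods notes

## The scientific setting

Ecological momentary assessment (EMA) studies of hearing prompt
participants several times per day to report their current listening
context, perceived listening effort, mood and fatigue. The analytical
questions this package addresses are (a) whether moments of
higher-than-usual auditory demand raise listening effort, worsen affect
and raise fatigue; (b) whether those within-person effects are amplified
by hearing loss (pure-tone average, PTA); and (c) whether listening
effort and/or affect *mediate* the within-person demand→fatigue
association. Because raw EMA datasets of this kind are rarely
deposited, the package pairs the analysis chain with a synthetic study
generator whose defaults emulate a realistic 130-participant protocol,
so every stage is exercised and validated end to end.

## Demand scoring

* **Environmental demand (0–3)** from the 7-option multi-select
  "listening situation" item: {passive listening, ambient noise} → 0;
  {actively listening live, actively listening to TV/radio} → 1;
  {conversation with 1 person, phone conversation} → 2; {conversation
  with >1 person} → 3. *Phone conversation* is treated as a live
  two-party conversation (rank 2). Multi-selects take the **maximum**
  base score among the selected options: the highest-demand activity in
  the window dominates. This rule reproduces every singleton assignment,
  is deterministic for unseen combinations, and is monotone under set
  inclusion (property-tested over all 127 subsets).
* **Social demand (0–2)** from the "who were you with" item: alone → 0;
  {partner, children} → 1 (the familiar-family bucket); everyone else,
  including extended family, colleagues and friends → 2 (less familiar
  interlocutors carry more listening burden). Same max rule.
* **Subjective demand (0–2)**: the product of listening difficulty and
  importance-to-hear-well (each ordinal 1–5; product 1–25) is ranked by
  tertiles of the pooled observed product distribution. Quantiles use
  the inverse empirical CDF (R type 1) so cutpoints are observed values;
  ties fall in the *lower* rank (score ≤ cutpoint). Cutpoints are fitted
  once per run on all answered prompts and stored in a JSON sidecar.
  With discrete products, exact thirds are unattainable; the test suite
  asserts rank shares in [0.20, 0.46].
* **Affect**: means of the four positive and five negative 1–7 mood
  sliders, each computed when at least half its items are present
  (package rule); the primary affect variable is the 0–10 "feeling now"
  item unchanged.

## The synthetic study generator

**Design.** 130 participants × 5.5 days. Seven daytime 30-minute prompt
windows start at 9:00, 11:00, 13:30, 15:00, 17:00, 19:00 and 21:00; each
prompt fires at its window midpoint plus uniform ±15-minute jitter. The
half day is realised as the final day's first three windows (through the
~13:30 window). Response latency is exponential (mean 2 min) truncated
at the 40-minute survey expiry. Each prompt is answered with its day's
compliance probability (0.83, 0.79, 0.75, 0.75, 0.70, 0.67), giving an
overall answered fraction of ≈ 0.75; missingness is independent of all
generated values (MCAR), which the suite checks with a logistic
regression of the answered flag on generated fatigue.

**Covariates.** PTA is drawn from a truncated normal on [−5, 93.75]
dB HL whose *truncated* mean and SD equal the targets 27.4 and 20.1 (the
parent-normal parameters are solved numerically; naive truncation of
N(27.4, 20.1²) would inflate the mean to ≈ 29.7). Age ~ N(58.3, 8.6²),
30% male, person-mean sleep quality ~ N(4.9, 0.9²) on 1–7, sleep hours
~ N(7.3, 0.8²), hearing-aid use with probability increasing in PTA.

**Contexts and items.** Context mixes are categorical distributions over
the printed option vocabularies, exponentially tilted per person along
the demand axis (person tilt SD 0.4) so participants differ in their
typical environments; "Alone" is the modal who-with state. A second
option joins the selection with probability 0.15. Difficulty and
importance are 1 + Binomial(4, p_i) ordinals with person-specific
propensities; the difficulty propensity increases with PTA at 0.0045 per
dB (latent scale) with person noise SD 0.14. This calibration — fixed
once, before the validation suite was run — yields a between-person
slope of mean subjective-demand rank on raw PTA of ≈ 0.009 per dB HL,
R² ≈ 0.21, and a person-mean rank SD of ≈ 0.39, matching the observed
person-level structure the defaults emulate. The three demand streams
are conditionally independent within person by default; real momentary
demands are likely correlated, so recovery results should be read as
validation of the estimators, not as claims about real-world
confounding.

**Causal truth model.** Per prompt,

```
effort  = covs + Σ_k a_k·demand_k,wp + Σ_k a_k,bp·mean_k
        + PTA_z·Σ_k m_k·demand_k,wp + u_i + ε
affect  = covs + Σ_k α_k·demand_k + u_i + ε
fatigue = covs + b_eff·effort + b_aff·affect + Σ_k δ_k·demand_k + u_i + ε
```

where `demand_k,wp` is the deviation from the person's realised mean,
PTA_z is the roster-sample z-score, and fatigue consumes the *observed*
(post-censoring) mediators so the analyst's b-path is the generating
one. Default slopes follow the within-person effect sizes the package
emulates: a = 0.77/0.96/1.81 (environmental/social/subjective → effort),
a-path moderation 0.35 per SD of PTA, b_eff = 0.22, b_aff = −0.30,
direct demand→fatigue paths −0.10/−0.06/+0.02, time-of-day fatigue slope
0.12/h, sleep-quality slopes −0.40/+0.78/−0.60 on effort/affect/fatigue.
Random-intercept SDs are ~1.0–1.2 and residual SDs ~1.3–1.5, placing
outcome means near the emulated study's (effort ≈ 2.7, affect ≈ 7.8,
fatigue ≈ 4.1 on 0–10).

**Censoring.** Outcomes are generated linearly and clipped to their 0–10
slider bounds. Clipping is reported per outcome and a warning fires
above 5%: under the default conditions roughly 19% of effort and 10% of
affect values sit at a bound, which attenuates fitted slopes — visible
in the worked example, and deliberate: real slider data have exactly
this feature. `clip_outcomes=False` disables censoring for estimator
studies.

## Analysis models

* **Decomposition.** Within = value − person mean (over answered
  prompts); between = person mean − grand mean, the grand mean taken
  over person means *unweighted* by prompt count (the between component
  is a person-level quantity, so unequal panels should not reweight
  people). Moderator z-scores use the sample SD (n−1) of the current
  analysis set, and each fit records the centre/scale used.
* **Mixed models.** `statsmodels` MixedLM, participant random intercept,
  REML. Fixed-effect CIs are Wald (β ± 1.96·SE) with two-sided normal
  p-values and a global α = .01 significance flag; no small-sample df
  correction. Random slopes are not fitted by default. Complete cases
  per model; within-flagged columns are verified to sum to zero within
  participant, and rank-deficient designs fail with the collinear terms
  named. A singular random-intercept variance is reported as zero with a
  warning. The default optimizer is used with a Powell fallback (L-BFGS
  produced singular intermediate systems on some replicates).
* **Correlation structure.** Between-subject: Pearson over per-person
  medians, pairwise complete, ≥3 participants per pair. Within-subject:
  per-person Pearson matrices computed when the participant has ≥4
  complete pairs (the smallest n giving a positive Fisher weight n−3);
  the median matrix and the variance-weighted Fisher-z pool
  tanh(Σwᵢzᵢ/Σwᵢ) are both reported; |r| = 1 is winsorized to ±0.9999
  before atanh. The between-vs-within contrast is a two-sample Fisher
  z-test with variance 1/(n_b−3) + 1/Σwᵢ at α = .007; the contrast uses
  the median-based between matrix against the pooled within matrix.
* **Mediation.** Models A/B/C share one complete-case row set (asserted
  equal). Model A moderates the a-path by PTA_z; B and C retain the
  demand × PTA_z term so all three condition on the same design, and a
  and b are read at PTA_z = 0 (sample-mean hearing); a conditional
  indirect-effect curve over PTA_z is available. Model B includes the
  focal demand only by default; a flag adds the other demand
  definitions' components. The Monte-Carlo CI draws a* and b*
  independently — they come from different fitted models and no joint
  covariance is available — with 4,000 draws by default; the suite
  verifies the 10⁶-draw CI against numerical quantiles of the analytic
  product-of-independent-normals distribution. Pattern labels: indirect
  CI covering 0 → *no mediation*; else significant opposite-sign direct
  effect → *suppression*; nonsignificant direct → *full/attenuated*;
  significant same-sign direct → *partial* (α = .01).

## Validation designs and problem sizes

* **Slope recovery** (`study_designs.parameter_recovery_study`): 200
  participants × 35 prompts, full compliance, generating values a = 0.77,
  a × PTA moderation = 0.34, b = 0.23, time-of-day fatigue slope = 0.13
  (entering fatigue only, so the fitted total-model coefficient equals
  it exactly), moderate noise, outcome means mid-scale and **censoring
  disabled**. The censoring choice is substantive: pilot runs showed
  that even ~0.5% clipped prompts — concentrated exactly in the
  high-PTA × high-demand cells — attenuate the interaction estimate by
  ~4% and drop its 95% CI coverage from ~95% to ~80%. Censoring is a
  generator realism feature, not an estimator defect, so the recovery
  design evaluates the estimators under the linear model they assume.
  The acceptance suite runs 100 replicates and requires ≥90% CI coverage
  and mean bias ≤0.05 for all four quantities.
* **Null calibration** (`study_designs.null_mediation_study`): 40
  participants × 10 prompts with every demand→mediator path zero; over
  200 replicates the 95% Monte-Carlo indirect CI must exclude zero in at
  most 7% (observed ≈ 5%, the nominal a-path test level, since b is
  bounded away from zero).
* **Exact-fit limits.** Noise-free tests use a scale separation —
  mediator residual 10⁻⁵, outcome residual 10⁻¹⁰ — because a fully
  interpolating generator makes the mediator collinear with demand in
  Model B; the tiny mediator noise identifies the b-path while leaving
  every estimate at its generating value to <10⁻⁶, and the path algebra
  c = c′ + a·b then holds to machine precision.

## Known limitations

* Missingness is MCAR only; mood- or fatigue-dependent (MNAR) compliance
  is not modelled.
* The generator's demand streams are conditionally independent within
  person; cross-demand confounding in real data would bias
  single-demand models in ways the recovery suite does not measure.
* Outcome sliders are generated as continuous values; real EMA sliders
  are often integer-valued, adding rounding error not represented here.
* Mixed-model inference uses normal approximations throughout; with 130
  participants, Wald CIs for between-person terms can be mildly
  anti-conservative.
* The subjective-demand tertile cutpoints are sample-dependent by
  construction; scores are comparable only within a run (cutpoints are
  therefore stored with each run's outputs).
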