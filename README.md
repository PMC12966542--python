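# audema

Simulation and multilevel analysis of **auditory demand, listening
effort, affect and fatigue** in daily-life ecological momentary
assessment (EMA) studies of people with varying degrees of hearing loss.

People with hearing loss often report pronounced daily-life fatigue. One
candidate mechanism is the extra *listening effort* required to process
speech and sound under adverse conditions: momentary auditory demand
drives effort, and sustained effort drives fatigue, with the
demand→effort link amplified by the degree of hearing loss (pure-tone
average, PTA, in dB HL). `audema` implements the complete analysis chain
needed to study this mechanism with intensive longitudinal smartphone
data — and, because such datasets are rarely shareable, a faithful
synthetic study generator so every stage is testable end to end.

## What the package does

1. **Simulate** (`audema.simulate`) — a configurable EMA study: a
   participant roster (truncated-normal PTA, age, sex, sleep covariates),
   a 5.5-day × 7-prompt daytime schedule with ±15-min jitter, momentary
   contexts and ordinal items, outcomes generated from a multilevel
   causal truth model, and day-specific missing-completely-at-random
   compliance (83/79/75/75/70/67%).
2. **Score** (`audema.scoring`) — reduce raw items to the derived
   demand measures:
   * *environmental demand* (0–3) from the multi-select listening
     situation (passive/ambient < active listening < conversation with
     one person < group conversation),
   * *social demand* (0–2) from who the participant was with
     (alone < family < others),
   * *subjective demand* (0–2): tertile rank of the difficulty ×
     importance product (each 1–5, product 1–25),
   plus positive/negative affect item means and the 0–10 "feeling now"
   overall-affect item.
3. **Decompose** (`audema.decompose`) — person-mean centering into
   within-person (x_it − x̄_i) and between-person (x̄_i − x̄) components;
   z-scoring of person-level moderators.
4. **Correlate** (`audema.correlation`) — between-subject correlations of
   participant medians vs within-subject structure (median of per-person
   matrices and a variance-weighted Fisher-z pool with weights n_i − 3),
   contrasted cell by cell with two-sample Fisher z-tests at α = .007.
5. **Model** (`audema.models`) — REML linear mixed models

   ```
   y_it = β0 + β1·demand_wp,it + β2·demand_bp,i + β3·PTA_z,i
        + β4·demand_wp,it × PTA_z,i + covariates + u_i + ε_it
   ```

   with participant random intercepts, Wald 95% CIs, and the person-level
   OLS regression of mean demand on raw PTA.
6. **Mediate** (`audema.mediation`) — the three-model multilevel
   mediation triplet (Model A: demand→mediator with PTA-moderated
   a-path; Model B: b-path and direct effect c′; Model C: total effect
   c), the indirect effect a·b with a 4,000-draw Monte-Carlo CI, and a
   mediation-pattern label (no mediation / partial / full-attenuated /
   suppression).

The `analysis/` directory holds numbered narrative drivers
(`01_simulate_study.py` … `06_parameter_recovery.py`) that run these
stages in order and write tables under `results/`; `audema` is also a
CLI (`audema simulate|score|correlate|model|mediate|run-all`).

## Worked example

```bash
python analysis/01_simulate_study.py --seed 20260925
python analysis/04_moderation_models.py
python analysis/05_mediation.py
```

prints, among other lines:

```
simulated 130 participants, 4940 prompts, 74.9% answered
PTA -> mean subjective demand: beta = 0.0081/dB (SE 0.0014), R^2 = 0.205, p = 6.23e-08
effort ~ environmental: within beta 0.59 (p=1e-86), x PTA 0.34 (p=1.2e-27), n=3699
environmental -> effort -> fatigue: a=0.59, b=0.24, a*b=0.14 [0.12, 0.17], c'=-0.09, c=0.05 -> suppression
```

Reading: prompts above a participant's usual environmental demand raise
their listening effort (within-person β = 0.59), more steeply for worse
hearing (demand × PTA interaction 0.34 per SD ≈ 20 dB HL); worse hearing
also predicts higher *average* subjective demand (0.0081 per dB,
R² ≈ 0.21). The mediation triplet shows the demand→fatigue association
carried through effort (indirect a·b = 0.14, 95% CI [0.12, 0.17]) with a
sign-reversed direct effect — a suppression pattern: high demand without
the accompanying effort is, if anything, slightly less fatiguing.
Moderation and within-person main effects here are attenuated relative
to their generating values because the default study conditions put real
probability mass at the 0–10 slider floors/ceilings (the generator logs
these clip rates); `analysis/06_parameter_recovery.py` quantifies
estimator behaviour free of that censoring.

## Layout

```
src/audema/          library (config, simulate, scoring, decompose,
                     correlation, models, mediation, pipeline, cli,
                     study_designs, validation)
analysis/            numbered narrative drivers writing results/
scripts/acceptance.py  headline-number reproduction
tests/               pytest suite incl. tests/test_acceptance.py
docs/methods.md      model and design notes
```
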