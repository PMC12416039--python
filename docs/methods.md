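# Methods

`adrec` implements the analytical core of a decision aid for antidepressant
selection in major depressive disorder (MDD): a per-drug response
knowledgebase learned from claims-like dispensing data, a subgroup bias
audit, an information-gain adaptive intake, rule-based explained advice,
suicide-risk triage, and a dialogue topic network. This note records the
models, the parameters that matter, and the design choices made where the
design was genuinely open.

## Surrogate outcome and treatment episodes

Claims data carry no symptom scores, so remission is proxied by *medication
persistence*: a treatment attempt counts as a response when the patient
stays on the index antidepressant through the response window (default 70
days = 10 weeks). Premature abandonment — discontinuation, switching, or
augmentation — marks the initial choice as incorrect regardless of the
reason (inefficacy or intolerable side effects).

Episodes are segmented per patient from dispensing records
`(patient_id, drug, fill_date, days_supply)`. A fill opens an episode; all
fills before `start + disposition_window_days` (default 100) belong to it;
the next fill at or past that horizon opens a new episode. Index-drug
coverage is the union of fill intervals `[date, date + supply)` bridged
across gaps of at most `gap_tolerance_days` (default 15, a standard
persistence convention). Disposition rules, in order:

* **augmented** — another antidepressant starts while index coverage is
  alive (the gap-bridged union contains the start day);
* **switched** — another antidepressant starts after index coverage lapsed;
* **continued** — no other drug, and the lapse at window end is still
  within tolerance (`coverage_end + gap_tolerance ≥ window_end`);
* **discontinued** — otherwise.

Two readings of the outcome are implemented behind `response_mode`:
`"strict"` (default) requires `disposition == continued` *and* coverage
spanning the response window, making response logically consistent with the
disposition; `"coverage"` grants response to any episode whose coverage
reaches the response window even if it changes later in the (longer)
disposition window. The windows are day counts on an integer timeline (day
0 = cohort start, intervals half-open) to keep tests free of calendar
parsing. By default switched/augmented episodes carry response = 0 and
enter model fitting; excluding them instead is a caller-side row filter on
the episode table.

Printed summary tables use half-up decimal rounding (one decimal for the
four-way disposition split, two for treatment shares) so recomputed tables
match published layouts digit for digit.

## Synthetic cohorts

`synthetic_cohort` generates every input a real claims extract would
provide, with known ground truth:

* binary history events with configurable prevalence (default 0.3, a
  mid-range prevalence that keeps binary columns informative); optional
  block-equicorrelation via a thresholded latent Gaussian
  (`event_correlation`, `correlation_block_size`) to exercise screening
  under collinearity — real event catalogs are strongly correlated;
* a ground-truth logistic response model per drug; each patient's response
  is Bernoulli with probability `expit(intercept + x·β)`, with per-drug
  coefficient deltas added inside a designated subgroup;
* dispensing streams built from per-disposition templates (30-day fills)
  so that episode construction recovers the planted disposition exactly:
  responders continue, non-responders draw a disposition from a
  conditional mix (discontinued 0.652 / switched 0.238 / augmented 0.110,
  the conditional split implied by a 46.3/12.8/35.1/5.9 four-way cohort).

`plant_disposition_mix` apportions target proportions into exact counts by
largest-remainder rounding. Proportions copied from percentages printed to
one decimal can sum to 1.001; sums within 0.01 of 1 are therefore
renormalized, anything further off is rejected. All randomness flows from a
single integer seed; identical configs produce byte-identical CSV output.

What the generator does *not* emulate: real ICD/NDC/CPT code semantics,
calendar time, dosing, stockpiling, eligibility gaps, or realistic event
co-occurrence structure beyond block equicorrelation. Passing tests
demonstrate the pipeline's statistical machinery is correct under known
truth, not that real-world accuracy figures transfer.

## Knowledgebase fitting

For each drug: episodes × binary events, outcome = surrogate response.

1. **Screening.** Events are ranked by
   `|⟨x−x̄, y−ȳ⟩| / ‖x−x̄‖` and the top `k` kept (default 1000) —
   the score a penalized regression's first-entry criterion uses, so events
   a LASSO at a loose penalty would pick first rank highest. Constant
   columns are dropped; ties break lexicographically. The classical exact
   pre-fit discard inequality is available separately (`safe_discard`) for
   callers who want a certified screen at a given penalty fraction.
2. **Penalty choice.** The L1 penalty is chosen by 5-fold cross-validated
   deviance on the full data, scored *end-to-end for this pipeline*: each
   candidate penalty's training-fold support is refit (lightly ridged,
   `C = 1e4`) and that refit's held-out deviance is minimized, with ties
   favoring the stronger penalty. Scoring the shrunken fit instead is
   prediction-optimal but notoriously over-selects; because the final
   coefficients here come from a refit on the retained support, the
   relaxed scoring matches what is actually deployed and is
   model-selection consistent in practice (planted 3-event supports are
   recovered exactly; see `validation.support_recovery_experiment`).
3. **Stability selection.** L1 fits are repeated on 40 random subsamples
   (80% without replacement, seeds derived from the master seed). An event
   is retained iff its coefficient is nonzero in ≥ `retain_threshold`
   (default 0.5) of subsamples; `retained_fraction` is recorded for every
   screened event. Final coefficients come from the lightly ridged refit on
   the retained set — effectively unpenalized, but finite under separation.
4. **Evaluation.** AUC is the rank (Mann–Whitney) statistic with ties
   counted ½; sensitivity/specificity use the 0.5 probability threshold
   (fixed so tabulated outputs are well-defined); McFadden's pseudo-R² is
   `1 − ℓ_model/ℓ_null` with the intercept-only null on the same rows, so
   the null model scores exactly 0. Pipeline-reported metrics are 5-fold
   cross-validated.

The L1 solver is scikit-learn's `saga` (unpenalized intercept, matching the
textbook objective `C·Σ log-loss + ‖β‖₁`). When the penalty empties the
support, the intercept is set to its closed form (log-odds of the base
rate), where the stochastic solver can stall short of full precision.

The knowledgebase JSON is versioned; loading validates schema membership of
every coefficient, routing referential integrity, and acyclicity of the
imputation network. The full production-scale schema counts 1499 events:
700 diagnoses, 550 medications, 151 procedures, 98 prior antidepressant
responses.

## Bias audit

For a drug and a subgroup, the audit compares the fixed general model with
a subgroup-specific model (same screening + stability pipeline, restricted
to subgroup rows) by held-out McFadden R² over 5 subgroup folds. Both
models are scored on the same held-out rows against the same training-fold
base-rate null; the penalty is selected once on the full subgroup data and
reused across folds. The routing table adopts the population-specific model
iff its R² beats the general model's by more than `decision_margin`.

"Significantly improved" is not a settled criterion; the margin default is
0 (any held-out improvement), exposed as a parameter rather than hidden.
Drugs with fewer than `min_cases = 68` subgroup trials are skipped with an
explicit status — too little data to audit honestly. Routing updates are
idempotent, and unaudited (drug, subgroup) pairs route to the general
model.

## Adaptive intake

The survey intake works from a *prototype table*: observed feature-value
combinations with at least `min_support` patients (default 100) and
per-drug empirical response rates. Each row induces a recommendation label
via the advice rules (severity fixed at "moderate" for labeling); the
interview's objective is to pin that label down. This target was a design
choice — the alternative (response-probability variance) is supported by
passing a custom `label_fn`.

`next_question` proposes the unasked feature with maximal expected
information gain in bits: prior label entropy minus count-weighted expected
conditional entropy, answers weighted by surviving patient counts. Rows
with an undefined feature value form an explicit `"unknown"` branch —
conversational respondents decline questions, so unknown is an answer, not
a skip. The interview stops when survivors share one label, every feature
is asked, or the question budget (default 25) is exhausted. Preclusion
rules (e.g. sex = male rules out pregnancy questions) block features
outright. Answers prune survivors monotonically, and pruning is
order-independent.

Greedy question selection is not optimal in general; on randomized 16-row
tables its expected interview length sits within one expected question of
the exact optimal adaptive policy found by exhaustive tree search (the
acceptance suite recomputes this).

## Advice

Given a patient profile (reported events as present/absent, severity,
subgroup tags):

1. **Completion.** Unreported events are either assumed absent
   (`assume-absent`, matching a deployment that treats unmentioned events
   as not having occurred) or imputed (`expected`): linked logistic
   regressions, one per imputable event, evaluated in topological order of
   their acyclic dependency graph; still-missing predictors count 0;
   reported values are never overwritten.
2. **Prediction.** Response probability per drug from the routed model
   (general or population-specific per the patient's subgroup tags).
3. **Rules**, in fixed precedence: low severity → no antidepressant
   (non-drug referral, e.g. exercise); best probability ≤ 0.10 →
   non-oral-antidepressant options; top two within 0.05 → either of the
   two; else the single best drug. The 10% rule is read as an absolute
   probability floor (a relative-to-baseline mode exists but is off by
   default); "within 5%" is an absolute 0.05 difference. Ties break by
   drug name.
4. **Explanation.** An exhaustive one-flip scan over schema events:
   flipping absent/unreported → present (or present → absent), re-running
   completion, prediction, and rules; an event is listed iff the branch or
   named drug set changes. Lists are sorted by the induced change in the
   top probability. A `max_events` cap (off by default) truncates the scan
   for very large schemas and flags the result truncated.
5. **Rendering.** A four-section document (history summary, recommendation,
   explanation, per-drug information links) from fixed templates only —
   no generated text — plus bar-chart data over all drugs. The history
   summary lists reported-present events carrying a nonzero coefficient in
   *any* drug model (not just the recommended drug's), the broader of the
   two defensible readings.

## Risk triage

A fixed 14-category suicide-risk-factor taxonomy (ids 1–14, from active
ideation through recklessness/impulsivity). Detection of categories in free
text happens upstream and is out of scope; this module aggregates detected
ids: duplicates collapse, and the count routes the patient — count > 3 →
crisis line, 1–3 → Safety Plan supporter, 0 → no referral. Only the >3
boundary is empirically anchored; the ≥1 lower boundary is a conservative
default, and both thresholds are parameters. Adding a category never
lowers acuity.

## Dialogue topic network

Schema events are grouped into broad topics; a directed acyclic topic
network is derived by counting cross-topic dependencies (imputation-model
predictor→target pairs and co-occurring predictors within a drug model)
and keeping pairs at or above a threshold, with edges oriented by a fixed
topic priority — acyclic by construction, so the priority order is always
a valid topological order. The production network behind the deployed
system is not derivable from public information; this derivation is the
package's own reproducible stand-in. The controller redirects digressions,
stays on an open topic up to a per-topic turn cap (default 6, bounding
stalls), advances to the highest-priority unvisited topic whose
predecessors are resolved, and ends when all topics are resolved — so any
dialogue terminates within `topics × cap` stay-decisions.

## Validation experiment sizes

`validation.py` fixes the synthetic study conditions: 50 candidate events
at prevalence 0.3, a three-event planted support with β = (1.0, −1.0, 0.9)
and intercept −0.3; support recovery over 20 replications at n = 2000;
held-out AUC vs the simulated generator ceiling at n = 5000 (ceiling
estimated from 200 000 simulated patients); audit discrimination over 20
replications with subgroup n = 1500 against a general model fit at
n = 4000, with sign-flipping subgroup deltas (−2.0, +2.0, −1.8) in the
shifted scenario and 10 stability subsamples per fit. These sizes give the
experiments clear statistical margins while each finishes in minutes on a
single core.

## Known limitations

* Persistence is an imperfect remission surrogate; patients persist on
  partially effective drugs and abandon effective ones.
* Episode segmentation ignores stockpiling, dose changes, and coverage
  gaps from insurance churn.
* The synthetic generator's independence (or block-equicorrelation)
  assumption understates real event dependence; recovery rates measured
  here do not bound real-data behavior.
* The audit's R²-margin criterion answers "does the specific model predict
  better held-out", not any causal fairness question.
* Greedy intake optimality is only near-optimal; the one-question bound is
  an empirical property of small tables, not a theorem.
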