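# Methods

## Model structure

The model is a two-arm decision tree for diagnosing LVEF < 50% in patients
referred with suspected heart failure, evaluated from a health-system
perspective over a 1-year horizon in 2023 SGD.  Costs are counted until the
two pathways become equivalent, i.e. through diagnosis and the first year
of its downstream consequences:

* Both arms charge one cardiologist consultation and one exam.
* **True positives** receive 12 months of quadruple therapy (SGLT2i +
  ACEi/ARB + beta-blocker + MRA) and carry the on-treatment hospitalization
  risk (0.17/yr).
* **False negatives** receive no therapy and carry the off-treatment risk
  (0.19/yr).
* **False positives** receive therapy without benefit; **true negatives**
  accrue nothing further.
* At most one HF hospitalization can occur in the year.  The tree folds the
  admission into the payoff as risk × cost — identical in expectation to an
  explicit chance node with a smaller tree; the microsimulator draws it as
  an event.
* In the AI-POC arm the images are interpretable with probability 0.96;
  uninterpretable cases fall back to a sonographer TTE rescan by default.

Expected costs are exact probability-weighted rollbacks; node probabilities
and payoffs are stored as symbolic expressions over the named parameters,
so the identical tree object serves scalar evaluation, vectorized PSA
evaluation, and JSON/text export for audit.

## Open structural assumptions

The published description leaves four structural points open; each is an
explicit `StructureOptions` field, and the defaults reproduce the published
base case to 0.05%:

| option | default | alternatives |
|---|---|---|
| fate of uninterpretable AI images | TTE rescan (extra exam cost, TTE accuracy) | no diagnosis (untreated, off-treatment risk) |
| false-positive therapy duration | full horizon (12 months) | 0–12 months |
| false-positive hospitalization risk | 0 | any probability |
| false-negative follow-up cost | 0 | any cost |

The consultation is arm-neutral and charged once per patient in both arms
(`consult_in_both_arms=False` removes it from both, for analyses that treat
it as upstream of the comparison).

## Distribution fitting

Every uncertain input is published as a point estimate with a 95% interval
and a family — Gamma for costs, Beta for probabilities.  The printed
"(a, b)" pairs are interval *endpoints*: read as Beta shape parameters,
(0.88, 0.93) would imply a mean of 0.486, inconsistent with any published
accuracy near 0.91.  Two parameterizations are implemented, because a
two-parameter family cannot match a mean and two quantiles at once:

* **Quantile matching** (default of `fit_gamma` / `fit_beta`): solve the
  shapes so the 2.5%/97.5% quantiles equal the interval endpoints.  Gamma
  uses the scale-free quantile ratio q97.5/q2.5, strictly decreasing in the
  shape, bracketed over [1e-3, 1e5] on the log scale (brentq, xtol 1e-13);
  Beta uses 2-D root finding on log-shapes (hybr, residuals verified below
  1e-8; externally asserted at 1e-6).  The discrepancy between the fitted
  mean and the published point estimate is stored on the fit, never
  discarded.  One interval reaches 1.0 at printed precision (probability of
  interpretable images, CI 0.86–1.00); a proper Beta cannot place its 97.5%
  quantile at exactly 1, so that row matches its lower quantile and its
  mean instead (fitted Beta(25.0, 1.04); its own 97.5% quantile is 0.9988,
  i.e. 1.00 at printed precision).
* **Moment matching** (`method="moments"`): mean anchored at the point
  estimate, SD = interval width / (2 × 1.96), the standard convention in
  decision-analytic software.

The **PSA samples moment-matched fits by default**.  The choice matters for
exactly one input: the hospitalization-cost interval [1586, 33709] is so
right-skewed that its quantile-matched Gamma has mean 12,289 versus the
9,074 point estimate (+35%).  Propagating that fit shifts the PSA mean of
the TTE arm about 5% above the deterministic base case, whereas the
published sensitivity analysis sits within about 1% of its base case —
behaviour only consistent with mean-anchored sampling.  Quantile matching
remains the reporting/audit fit (`fit-params`), and either parameterization
can be selected with `--fit-method`.

## Prevalence calibration

The prevalence of LVEF < 50% in the referred population is not published.
Per-arm expected cost is affine in prevalence (prevalence enters every
root-to-leaf probability exactly once), so given one published per-patient
cost the prevalence has the closed form p = (target − C(0)) / (C(1) − C(0)),
verified by re-evaluation to 1e-9.  Calibrating on the published TTE base
case (S$1386.63/patient) gives p = 0.2727; the model then predicts the
AI-POC arm within 0.05% of its published value, and the reverse calibration
agrees to the same precision — a genuine cross-arm consistency check, since
each calibration uses only the other arm's number.  The calibrated
prevalence is held fixed during the PSA (it has no published uncertainty
distribution); `sweep-prevalence` explores it separately.

## Probabilistic sensitivity analysis

1000 iterations by default, matching the published analysis.  Each
iteration draws all twelve parameters independently (no correlation
structure is published) and re-evaluates both arms from the same draw by
exact vectorized rollback, so arm costs are coupled through the shared
draws.  One master seed spawns one `numpy` SeedSequence sub-stream per
parameter in fixed table-row order; adding a parameter never perturbs
earlier streams, and identical seeds give bit-identical iteration tables.
Summary intervals are empirical 2.5/97.5 percentiles (numpy linear
interpolation), recorded in the output metadata; the probability of
cost-saving is the fraction of iterations with strictly negative
incremental cost (ties count against saving).  All computation is in SGD;
USD columns are derived once at report time with a fixed factor, default
1.20047, the value implied by the published SGD/USD pairs (it reproduces
all five printed USD mirrors at their printed precision; no web converter
is queried).

## Cohort microsimulation

The simulator draws each patient's disease status, image interpretability,
test outcome and hospitalization as Bernoullis and accrues costs under
exactly the terminal-payoff rules, producing one CSV row per patient.  It
emulates a cross-sectional diagnostic cohort at a configurable prevalence;
it does not model time-to-event within the year, repeat examinations, loss
to follow-up, or correlation between a patient's test result and their
hospitalization beyond treatment status.  Agreement of its empirical mean
with the rollback (within 3 standard errors at n = 10^6, across random
parameter sets and all structure options) validates the tree's algebra, not
the realism of those published inputs.

## Numerical choices and problem sizes

* Root-finding: 1e-13 xtol internally; 1e-6 asserted externally (relative
  for costs).
* Chance-node probabilities must sum to 1 within 1e-12 at evaluation.
* Default analysis sizes: cohort 100, PSA 1000 iterations; the test suite
  uses 10^5–10^6 patients for oracle comparisons and 20 × 1000 iterations
  for the cost-saving probability, sizes at which Monte Carlo error is well
  below the tolerances being asserted.
* Reported tables round cohort totals to whole SGD and per-patient/per-exam
  figures to cents; stored CSVs keep full precision.

## Known limitations

* Cost-minimization only: no QALYs, utilities or discounting; equal
  diagnostic effectiveness is assumed, not modelled.
* One-year horizon with a single possible hospitalization; no Markov
  extension.
* The micro-costing inputs behind the two published per-exam totals
  (S$12.46 AI-POC, S$33.98 TTE) are not public; the micro-costing module is
  validated on synthetic books and the published totals are taken as
  authoritative.
* Singapore 2023 unit costs throughout; transferring the conclusion to
  another setting requires local costs and prevalence.
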