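# pocus-cma

A decision-analytic **cost-minimization model** comparing two pathways for
diagnosing a reduced left ventricular ejection fraction (LVEF < 50%) in
patients with suspected heart failure:

* **AI-POC** — a novice operator acquires images with an AI-enabled
  point-of-care ultrasound device; the AI classifies image quality and
  annotates LVEF;
* **TTE** — a conventional transthoracic echocardiogram performed and
  interpreted by a trained cardiac sonographer.

Because the two pathways diagnose with comparable accuracy, the comparison
is on cost alone (a cost-minimization analysis), from a health-system
perspective over a 1-year horizon, in 2023 Singapore dollars.  The package
is for health-economics analysts who want to reproduce, audit or adapt the
model with their own local costs and epidemiology.

## The model

Each arm is a decision tree.  A referred patient has LVEF < 50% with
probability *p* (the prevalence); the exam classifies them with the arm's
sensitivity *Se* and specificity *Sp*; each outcome accrues costs over 12
months (consultation *c*<sub>con</sub>, exam *c*<sub>exam</sub>, monthly
quadruple therapy *c*<sub>rx</sub> — SGLT2i + ACEi/ARB + BB + MRA — one HF
hospitalization *c*<sub>hosp</sub> at most, with on/off-treatment risks
*h*<sub>t</sub> / *h*<sub>u</sub>):

```
E[C] = c_con + c_exam
     + p   [ Se (12 c_rx + h_t c_hosp) + (1 − Se) h_u c_hosp ]
     + (1−p) (1 − Sp) 12 c_rx
```

The AI-POC arm first draws whether the images are interpretable
(probability *q* = 0.96); uninterpretable cases fall back to a sonographer
TTE rescan (extra exam cost, TTE accuracy).  Expected costs are computed by
exact rollback — no sampling in the base case.

On top of the tree the package provides:

* **distribution fitting** — every published input is a point estimate with
  a 95% interval and a family (Gamma for costs, Beta for probabilities);
  fits either match both interval quantiles exactly (with the mean
  discrepancy reported) or anchor the mean at the point estimate
  (moment matching, used for uncertainty propagation);
* **prevalence calibration** — the published model's prevalence is not
  printed; expected cost is affine in prevalence, so it is recovered in
  closed form from a published per-patient cost;
* **probabilistic sensitivity analysis** — Monte Carlo propagation of all
  twelve parameter distributions through the tree, reporting per-arm cohort
  costs, the incremental cost, and the probability of cost-saving;
* **micro-costing** — rebuild per-exam unit costs from annual equipment /
  software books and salary-derived personnel time;
* **cohort microsimulation** — an individual-patient Bernoulli simulator
  that produces record-level synthetic study data and doubles as a
  brute-force oracle for the analytic rollback.

## Worked example

```
$ pocus-cma base-case
          quantity       sgd       usd
   per_patient_tte   1386.63   1664.61
 per_patient_aipoc   1175.72   1411.42
        cohort_tte 138663.00 166460.77
      cohort_aipoc 117572.02 141141.68
incremental_cohort -21090.98 -25319.09
prevalence used: 0.272747
```

The prevalence 0.2727 is calibrated so the TTE arm reproduces its published
per-patient cost (S$1386.63); the model then *predicts* the AI-POC arm at
S$1175.72 per patient — within 0.05% of the published S$1175 — and a saving
of about S$21,091 per 100 patients at the point estimates.

```
$ pocus-cma psa --n 1000 --seed 1
   quantity  mean_sgd  ci_lower_sgd  ci_upper_sgd  ...
        tte 138790.85      80156.19     257102.46  ...
      aipoc 117767.74      64856.82     231412.70  ...
incremental -21023.11     -35549.39     -10646.10  ...
probability of cost-saving: 1.000
```

Under parameter uncertainty the AI-POC pathway remains cheaper in
essentially every iteration; the mean incremental cohort cost is about
−S$21,000.  Other commands: `fit-params`, `calibrate`, `simulate-cohort`,
`sweep-prevalence`, `microcost` (see `pocus-cma --help`).

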