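# Published model inputs for the novice-led AI-POCUS vs sonographer-led TTE
# cost-minimization model.  Costs are 2023 SGD; every uncertain input carries
# a 95% interval and a distribution family.  The prevalence of LVEF <50% in
# the referred population was not published; it is calibrated so the TTE arm
# reproduces its published per-patient base-case cost.
model:
  horizon_months: 12
  cohort_size: 100
  sgd_to_usd: 1.20047   # factor implied by the published SGD/USD pairs
  prevalence: null

calibration:
  arm: tte
  target_per_patient_sgd: 1386.63   # published TTE base case, per patient

parameters:
  - name: cost_consult
    family: gamma
    estimate: 145.0
    ci: [127.0, 162.0]
    source: cardiologist outpatient consultation, NHCS
  - name: cost_hosp
    family: gamma
    estimate: 9074.0
    ci: [1586.0, 33709.0]
    source: HF hospitalisation episode
  - name: cost_aipoc_exam
    family: gamma
    estimate: 12.46
    ci: [2.52, 25.76]
    source: novice-led AI-POC exam (device average, incl. personnel/overhead)
  - name: cost_tte_exam
    family: gamma
    estimate: 33.98
    ci: [19.90, 52.57]
    source: sonographer-led TTE exam (incl. personnel/overhead)
  - name: cost_treatment_monthly
    family: gamma
    estimate: 158.78
    ci: [90.51, 227.04]
    source: quadruple therapy per month (SGLT2i + ACEi/ARB + BB + MRA), SGH formulary
  - name: sens_ai
    family: beta
    estimate: 0.91
    ci: [0.88, 0.93]
    source: AI-POC sensitivity for LVEF <50%
  - name: spec_ai
    family: beta
    estimate: 0.92
    ci: [0.87, 0.95]
    source: AI-POC specificity for LVEF <50%
  - name: p_interpretable
    family: beta
    estimate: 0.96
    ci: [0.86, 1.0]
    source: probability of interpretable AI images, PANES-HF
  - name: sens_tte
    family: beta
    estimate: 0.92
    ci: [0.89, 0.93]
    source: TTE sensitivity for LVEF <50%
  - name: spec_tte
    family: beta
    estimate: 0.78
    ci: [0.74, 0.85]
    source: TTE specificity for LVEF <50%
  - name: p_hosp_treated
    family: beta
    estimate: 0.17
    ci: [0.13, 0.22]
    source: 1-year HF hospitalisation risk on quadruple therapy, SingCLOUD
  - name: p_hosp_untreated
    family: beta
    estimate: 0.19
    ci: [0.15, 0.24]
    source: 1-year HF hospitalisation risk without therapy, SingCLOUD
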