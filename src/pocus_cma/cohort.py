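"""Individual-level cohort microsimulation: synthetic data and oracle.

Simulates patients one at a time through either diagnostic pathway with
Bernoulli draws for disease status, image interpretability, test outcome
and hospitalization, accruing costs under exactly the same rules as the
decision tree's terminal payoffs.  Its two jobs:

* generate realistic record-level synthetic study data (one CSV row per
  patient: true state, test trajectory, cost breakdown);
* serve as a brute-force oracle — the empirical mean cost must converge to
  the analytic rollback, which the tree computes in expectation.

The one deliberate structural difference from the tree: the tree folds the
hospitalization risk into the payoff as probability x cost, while the
simulator draws the admission as an event.  Means agree; records carry a
genuine 0/1 admission flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parameters import ModelParameters
from .tree import StructureOptions

__all__ = ["CohortSummary", "simulate_cohort", "cohort_summary", "write_cohort_csv"]

RECORD_COLUMNS = [
    "patient_id",
    "arm",
    "true_lvef_lt50",
    "image_interpretable",
    "diagnosed",
    "test_positive",
    "classification",
    "treated",
    "hospitalized",
    "cost_consult",
    "cost_exam",
    "cost_therapy",
    "cost_hospitalization",
    "cost_followup",
    "total_cost",
]


@dataclass(frozen=True)
class CohortSummary:
    n: int
    tp: int
    fp: int
    tn: int
    fn: int
    hospitalizations: int
    mean_cost: float
    se_mean_cost: float


def simulate_cohort(
    params: ModelParameters,
    opts: StructureOptions | None,
    arm: str,
    n: int,
    seed: int,
) -> pd.DataFrame:
    """Simulate ``n`` patients through ``arm`` ('aipoc' or 'tte')."""
    if arm not in ("aipoc", "tte"):
        raise ValueError("arm must be 'aipoc' or 'tte'")
    if n < 1:
        raise ValueError("n must be >= 1")
    opts = opts or StructureOptions()
    prevalence = params.require_prevalence()
    fp_months = opts.resolved_fp_months(params.horizon_months)
    rng = np.random.default_rng(seed)

    diseased = rng.random(n) < prevalence

    if arm == "aipoc":
        interpretable = rng.random(n) < params.p_interpretable
        sens = np.where(interpretable, params.sens_ai, params.sens_tte)
        spec = np.where(interpretable, params.spec_ai, params.spec_tte)
        rescan = ~interpretable if opts.uninterpretable_fallback == "tte_rescan" else np.zeros(n, bool)
        diagnosed = interpretable | rescan
        exam_cost = params.cost_aipoc_exam + np.where(rescan, params.cost_tte_exam, 0.0)
    else:
        interpretable = np.full(n, True)
        sens, spec = params.sens_tte, params.spec_tte
        diagnosed = np.full(n, True)
        exam_cost = np.full(n, float(params.cost_tte_exam))

    u_test = rng.random(n)
    p_positive = np.where(diseased, sens, 1.0 - np.asarray(spec))
    test_positive = diagnosed & (u_test < p_positive)

    treated = test_positive
    classification = np.where(
        diseased,
        np.where(test_positive, "TP", "FN"),
        np.where(test_positive, "FP", "TN"),
    )

    p_hosp = np.zeros(n)
    p_hosp[diseased & treated] = params.p_hosp_treated
    p_hosp[diseased & ~treated] = params.p_hosp_untreated
    p_hosp[~diseased & treated] = opts.fp_hospitalization_prob
    hospitalized = rng.random(n) < p_hosp  # at most one admission per patient-year

    cost_consult = np.full(n, float(params.cost_consult) if opts.consult_in_both_arms else 0.0)
    therapy_months = np.where(diseased, params.horizon_months, fp_months)
    cost_therapy = np.where(treated, therapy_months * params.cost_treatment_monthly, 0.0)
    cost_hospitalization = np.where(hospitalized, float(params.cost_hosp), 0.0)
    cost_followup = np.where(diagnosed & diseased & ~treated, opts.fn_followup_cost, 0.0)
    total = cost_consult + exam_cost + cost_therapy + cost_hospitalization + cost_followup

    return pd.DataFrame(
        {
            "patient_id": np.arange(n),
            "arm": arm,
            "true_lvef_lt50": diseased,
            "image_interpretable": interpretable if arm == "aipoc" else pd.NA,
            "diagnosed": diagnosed,
            "test_positive": test_positive,
            "classification": classification,
            "treated": treated,
            "hospitalized": hospitalized,
            "cost_consult": cost_consult,
            "cost_exam": exam_cost,
            "cost_therapy": cost_therapy,
            "cost_hospitalization": cost_hospitalization,
            "cost_followup": cost_followup,
            "total_cost": total,
        },
        columns=RECORD_COLUMNS,
    )


def cohort_summary(records: pd.DataFrame) -> CohortSummary:
    """Confusion counts, admissions, and the mean cost with its SE."""
    if len(records) == 0:
        raise ValueError("empty cohort")
    counts = records["classification"].value_counts()
    costs = records["total_cost"].to_numpy()
    n = len(records)
    sd = float(costs.std(ddof=1)) if n > 1 else 0.0
    return CohortSummary(
        n=n,
        tp=int(counts.get("TP", 0)),
        fp=int(counts.get("FP", 0)),
        tn=int(counts.get("TN", 0)),
        fn=int(counts.get("FN", 0)),
        hospitalizations=int(records["hospitalized"].sum()),
        mean_cost=float(costs.mean()),
        se_mean_cost=sd / np.sqrt(n),
    )


def write_cohort_csv(records: pd.DataFrame, path, manifest_line: str | None = None) -> None:
    """Record-level CSV, one row per patient, optional manifest header."""
    with open(path, "w", newline="") as fh:
        if manifest_line:
            fh.write(f"# {manifest_line}\n")
        records.to_csv(fh, index=False)
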