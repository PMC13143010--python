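"""Decision-tree construction, rollback, calibration and currency."""

import numpy as np
import pytest

from pocus_cma import (
    StructureOptions,
    build_model,
    calibrate_prevalence,
    convert_currency,
    evaluate_base_case,
    rollback_expected_cost,
)
from pocus_cma.tree import ChanceNode, TerminalNode, TreeStructureError, _rollback, tree_to_dict, tree_to_text

from conftest import TTE_BASE_PER_PATIENT


def hand_rollback(p, params, arm):
    """Independent oracle: explicit arithmetic over the published pathway.

    Consultation + exam, then prevalence x accuracy splits into the four
    outcome payoffs; AI arm mixes in the TTE-rescan fallback.
    """
    tp = 12 * params.cost_treatment_monthly + params.p_hosp_treated * params.cost_hosp
    fn = params.p_hosp_untreated * params.cost_hosp
    fp = 12 * params.cost_treatment_monthly
    tte_outcomes = p * (params.sens_tte * tp + (1 - params.sens_tte) * fn) + (1 - p) * (
        (1 - params.spec_tte) * fp
    )
    if arm == "tte":
        return params.cost_consult + params.cost_tte_exam + tte_outcomes
    ai_outcomes = p * (params.sens_ai * tp + (1 - params.sens_ai) * fn) + (1 - p) * (
        (1 - params.spec_ai) * fp
    )
    return (
        params.cost_consult
        + params.cost_aipoc_exam
        + params.p_interpretable * ai_outcomes
        + (1 - params.p_interpretable) * (params.cost_tte_exam + tte_outcomes)
    )


class TestRollback:
    def test_two_point_average(self):
        node = ChanceNode("toss", [("0.5", TerminalNode("a", [("c", "10")])),
                                   ("0.5", TerminalNode("b", [("c", "30")]))])
        assert _rollback(node, {}) == pytest.approx(20.0)

    def test_degenerate_chain_sums_path_costs(self):
        leaf = TerminalNode("leaf", [("c", "7")])
        mid = ChanceNode("mid", [("1.0", leaf)], [("m", "5")])
        top = ChanceNode("top", [("1.0", mid)], [("t", "1")])
        assert _rollback(top, {}) == pytest.approx(13.0)

    def test_unnormalized_probabilities_rejected(self):
        node = ChanceNode("bad", [("0.6", TerminalNode("a")), ("0.6", TerminalNode("b"))])
        with pytest.raises(TreeStructureError, match="sum"):
            _rollback(node, {})

    def test_negative_cost_component_rejected(self):
        node = TerminalNode("neg", [("c", "-1.0")])
        with pytest.raises(TreeStructureError, match="negative"):
            _rollback(node, {})


class TestBuildModel:
    def test_degenerate_tree_collapses_to_consult_plus_exam(self, paper_params):
        p = paper_params.model_copy(
            update=dict(prevalence=0.0, spec_ai=1.0, spec_tte=1.0, p_interpretable=1.0)
        )
        costs = rollback_expected_cost(build_model(p))
        assert costs["aipoc"] == pytest.approx(p.cost_consult + p.cost_aipoc_exam)
        assert costs["tte"] == pytest.approx(p.cost_consult + p.cost_tte_exam)

    def test_unset_prevalence_raises_with_calibration_hint(self, paper_config):
        with pytest.raises(Exception, match="calibrate"):
            build_model(paper_config.params)

    @pytest.mark.parametrize("prevalence", [0.1, 0.27, 0.9])
    @pytest.mark.parametrize("arm", ["aipoc", "tte"])
    def test_engine_matches_hand_rollback(self, paper_params, prevalence, arm):
        params = paper_params.with_prevalence(prevalence)
        engine = rollback_expected_cost(build_model(params))[arm]
        assert engine == pytest.approx(hand_rollback(prevalence, params, arm), abs=1e-9)

    def test_no_diagnosis_fallback_drops_rescan_cost(self, paper_params):
        opts = StructureOptions(uninterpretable_fallback="no_diagnosis")
        c_rescan = rollback_expected_cost(build_model(paper_params))["aipoc"]
        c_nodiag = rollback_expected_cost(build_model(paper_params, opts))["aipoc"]
        assert c_nodiag < c_rescan

    def test_exports_are_self_consistent(self, paper_params):
        tree = build_model(paper_params)
        d = tree_to_dict(tree)
        assert set(d["root"]["strategies"]) == {"aipoc", "tte"}
        text = tree_to_text(tree)
        assert "p_interpretable" in text and "cost_tte_exam" in text


class TestStructuralProperties:
    def test_cost_is_affine_in_prevalence(self, paper_params):
        """Three-point collinearity at p in {0, 0.5, 1} to 1e-9."""
        tree = build_model(paper_params)
        for arm in ("aipoc", "tte"):
            c = [float(rollback_expected_cost(tree, {"prevalence": p})[arm]) for p in (0.0, 0.5, 1.0)]
            assert c[1] == pytest.approx(0.5 * (c[0] + c[2]), abs=1e-9)

    @pytest.mark.parametrize(
        "field", ["cost_consult", "cost_hosp", "cost_tte_exam", "cost_aipoc_exam",
                  "cost_treatment_monthly", "p_hosp_treated", "p_hosp_untreated"]
    )
    def test_cost_non_decreasing_in_unit_costs_and_risks(self, paper_params, field):
        lo = rollback_expected_cost(build_model(paper_params))
        bumped = paper_params.model_copy(update={field: getattr(paper_params, field) * 1.05})
        hi = rollback_expected_cost(build_model(bumped))
        assert hi["aipoc"] >= lo["aipoc"] - 1e-12
        assert hi["tte"] >= lo["tte"] - 1e-12

    def test_aipoc_dominates_tte_at_any_prevalence(self, paper_params):
        """The headline direction holds over the whole prevalence range."""
        tree = build_model(paper_params)
        grid = np.linspace(0.0, 1.0, 21)
        costs = rollback_expected_cost(tree, {"prevalence": grid})
        assert np.all(costs["aipoc"] < costs["tte"])


class TestBaseCase:
    def test_cohort_figures_scale_exactly(self, paper_params):
        base = evaluate_base_case(paper_params)
        assert base.cohort_cost_aipoc == base.per_patient_cost_aipoc * 100
        assert base.cohort_cost_tte == base.per_patient_cost_tte * 100

    def test_all_diseased_perfect_tests_difference_is_exam_cost(self, paper_params):
        p = paper_params.model_copy(
            update=dict(prevalence=1.0, sens_ai=1.0, sens_tte=1.0, p_interpretable=1.0)
        )
        base = evaluate_base_case(p)
        assert base.per_patient_cost_tte - base.per_patient_cost_aipoc == pytest.approx(
            p.cost_tte_exam - p.cost_aipoc_exam
        )


class TestCalibration:
    def test_boundary_targets(self, paper_config):
        params = paper_config.params
        tree = build_model(params.with_prevalence(0.0))
        c0 = float(rollback_expected_cost(tree, {"prevalence": 0.0})["tte"])
        c1 = float(rollback_expected_cost(tree, {"prevalence": 1.0})["tte"])
        assert calibrate_prevalence(params, None, "tte", c0) == pytest.approx(0.0, abs=1e-12)
        assert calibrate_prevalence(params, None, "tte", 0.5 * (c0 + c1)) == pytest.approx(0.5)

    def test_published_target_matches_bisection_oracle(self, paper_config):
        params = paper_config.params
        p_closed = calibrate_prevalence(params, None, "tte", TTE_BASE_PER_PATIENT)
        assert p_closed == pytest.approx(0.27, abs=0.005)

        tree = build_model(params.with_prevalence(0.0))

        def cost_at(p):
            return float(rollback_expected_cost(tree, {"prevalence": p})["tte"])

        lo, hi = 0.0, 1.0
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if cost_at(mid) < TTE_BASE_PER_PATIENT:
                lo = mid
            else:
                hi = mid
        assert p_closed == pytest.approx(0.5 * (lo + hi), abs=1e-12)

    def test_unreachable_target_raises(self, paper_config):
        with pytest.raises(ValueError, match="outside"):
            calibrate_prevalence(paper_config.params, None, "tte", 10.0)


class TestCurrency:
    @pytest.mark.parametrize(
        "sgd,usd,digits",
        [(145.0, 174, 0), (9074.0, 10893, 0), (12.46, 14.96, 2), (33.98, 40.79, 2), (158.78, 190.61, 2)],
    )
    def test_published_usd_mirrors_at_default_factor(self, paper_params, sgd, usd, digits):
        assert round(convert_currency(sgd, paper_params.sgd_to_usd), digits) == usd

    def test_zero_and_invalid_factor(self):
        assert convert_currency(0.0, 1.2) == 0.0
        with pytest.raises(ValueError):
            convert_currency(1.0, 0.0)

    def test_multiplication_example(self):
        assert convert_currency(145.0, 1.2) == pytest.approx(174.0)
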