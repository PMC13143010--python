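"""Two-arm diagnostic decision tree: build, rollback, calibrate.

Both diagnostic strategies are encoded as a classic decision tree.  A
patient referred with suspected heart failure either truly has LVEF < 50%
(probability = prevalence) or not; the exam then classifies them as test
positive or negative with the arm's sensitivity/specificity; each of the
four outcomes (TP/FN/FP/TN) accrues costs over the 1-year horizon:

* TP — 12 months of quadruple therapy plus the on-treatment hospitalization
  risk times the cost of one HF hospitalization (at most one admission).
* FN — the off-treatment hospitalization risk times the hospitalization
  cost (plus an optional follow-up cost, default 0).
* FP — therapy cost without benefit (duration configurable, default the
  full horizon) and an optional hospitalization risk (default 0).
* TN — nothing beyond the consultation and the exam.

The AI-POC arm first draws whether the novice-acquired images are
interpretable; uninterpretable cases fall back, by default, to a
sonographer TTE rescan (extra exam cost, TTE accuracy).  Hospitalization is
modelled as probability x cost inside the terminal payoff — identical in
expectation to a separate chance node, with a smaller tree.

Node probabilities and cost components are stored as arithmetic expressions
over the named model parameters, so the same tree object supports exact
scalar rollback, vectorized rollback over sampled parameter arrays (PSA),
and an auditable text/JSON export.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from typing import Literal, Mapping, Optional, Union

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from .parameters import ModelParameters, PARAM_ORDER

__all__ = [
    "StructureOptions",
    "ChanceNode",
    "TerminalNode",
    "DecisionNode",
    "DecisionTree",
    "StrategyCosts",
    "TreeStructureError",
    "build_model",
    "rollback_expected_cost",
    "evaluate_base_case",
    "calibrate_prevalence",
    "convert_currency",
    "tree_to_text",
    "tree_to_dict",
]

ARMS = ("aipoc", "tte")

#: maximum tolerated deviation of chance-branch probabilities from 1
_PROB_TOL = 1e-12


class TreeStructureError(RuntimeError):
    """Malformed tree: branch probabilities off unity or negative costs."""


class StructureOptions(BaseModel):
    """Structural assumptions the published model left open.

    ``fp_treated_months=None`` means "the full horizon".  These knobs exist
    so the open assumptions are explicit, auditable and sweepable; the
    defaults reproduce the published base case.
    """

    model_config = ConfigDict(frozen=True)

    uninterpretable_fallback: Literal["tte_rescan", "no_diagnosis"] = "tte_rescan"
    fp_treated_months: Optional[int] = Field(default=None, ge=0)
    fp_hospitalization_prob: float = Field(default=0.0, ge=0, le=1)
    fn_followup_cost: float = Field(default=0.0, ge=0)
    consult_in_both_arms: bool = True

    def resolved_fp_months(self, horizon_months: int) -> int:
        months = self.fp_treated_months if self.fp_treated_months is not None else horizon_months
        if months > horizon_months:
            raise ValueError("fp_treated_months cannot exceed the horizon")
        return months


Expr = str
Value = Union[float, np.ndarray]


@dataclass
class TerminalNode:
    label: str
    cost_components: list[tuple[str, Expr]] = dc_field(default_factory=list)


@dataclass
class ChanceNode:
    label: str
    branches: list[tuple[Expr, "Node"]] = dc_field(default_factory=list)
    cost_components: list[tuple[str, Expr]] = dc_field(default_factory=list)


Node = Union[TerminalNode, ChanceNode]


@dataclass
class DecisionNode:
    label: str
    strategies: dict[str, Node]


@dataclass
class DecisionTree:
    """A decision node plus the evaluation context it was built for.

    ``context`` holds the point-estimate value of every parameter appearing
    in the node expressions; :func:`rollback_expected_cost` may override any
    subset (e.g. with sampled arrays during PSA, or a prevalence grid).
    """

    root: DecisionNode
    context: dict[str, float]
    options: StructureOptions


def _eval(expr: Expr, ctx: Mapping[str, Value]) -> Value:
    return eval(expr, {"__builtins__": {}}, dict(ctx))  # noqa: S307 - internal expressions only


def _outcome_terminals(prefix: str) -> ChanceNode:
    """disease -> test-result subtree with the four outcome payoffs.

    ``prefix`` selects which accuracy parameters govern the test ("ai" or
    "tte"); the cost payoffs are identical across arms by construction
    (costs counted until the diagnostic pathways become equivalent).
    """
    sens, spec = f"sens_{prefix}", f"spec_{prefix}"
    tp = TerminalNode(
        f"{prefix}: true positive",
        [
            ("therapy", "horizon_months * cost_treatment_monthly"),
            ("hospitalization", "p_hosp_treated * cost_hosp"),
        ],
    )
    fn = TerminalNode(
        f"{prefix}: false negative",
        [
            ("hospitalization", "p_hosp_untreated * cost_hosp"),
            ("followup", "fn_followup_cost"),
        ],
    )
    fp = TerminalNode(
        f"{prefix}: false positive",
        [
            ("therapy", "fp_treated_months * cost_treatment_monthly"),
            ("hospitalization", "fp_hospitalization_prob * cost_hosp"),
        ],
    )
    tn = TerminalNode(f"{prefix}: true negative", [])
    return ChanceNode(
        f"{prefix}: LVEF < 50%?",
        [
            (
                "prevalence",
                ChanceNode(f"{prefix}: test result | diseased", [(sens, tp), (f"1 - {sens}", fn)]),
            ),
            (
                "1 - prevalence",
                ChanceNode(
                    f"{prefix}: test result | not diseased", [(f"1 - {spec}", fp), (spec, tn)]
                ),
            ),
        ],
    )


def build_model(params: ModelParameters, opts: StructureOptions | None = None) -> DecisionTree:
    """Build the two-arm tree for the given parameters and assumptions."""
    opts = opts or StructureOptions()
    prevalence = params.require_prevalence()

    consult = [("consultation", "cost_consult")] if opts.consult_in_both_arms else []

    tte_arm = ChanceNode(
        "tte: sonographer-led TTE",
        _outcome_terminals("tte").branches,
        consult + [("exam", "cost_tte_exam")],
    )

    if opts.uninterpretable_fallback == "tte_rescan":
        fallback: Node = ChanceNode(
            "aipoc: uninterpretable, TTE rescan",
            _outcome_terminals("tte").branches,
            [("rescan exam", "cost_tte_exam")],
        )
    else:
        fallback = ChanceNode(
            "aipoc: uninterpretable, no diagnosis",
            [
                (
                    "prevalence",
                    TerminalNode(
                        "aipoc: undiagnosed, diseased",
                        [("hospitalization", "p_hosp_untreated * cost_hosp")],
                    ),
                ),
                ("1 - prevalence", TerminalNode("aipoc: undiagnosed, not diseased", [])),
            ],
        )

    aipoc_arm = ChanceNode(
        "aipoc: novice-led AI-POC",
        [
            ("p_interpretable", _outcome_terminals("ai")),
            ("1 - p_interpretable", fallback),
        ],
        consult + [("exam", "cost_aipoc_exam")],
    )

    context = {name: getattr(params, name) for name in PARAM_ORDER}
    context.update(
        prevalence=prevalence,
        horizon_months=float(params.horizon_months),
        fp_treated_months=float(opts.resolved_fp_months(params.horizon_months)),
        fp_hospitalization_prob=opts.fp_hospitalization_prob,
        fn_followup_cost=opts.fn_followup_cost,
    )
    root = DecisionNode("diagnostic strategy", {"aipoc": aipoc_arm, "tte": tte_arm})
    return DecisionTree(root=root, context=context, options=opts)


def _rollback(node: Node, ctx: Mapping[str, Value]) -> Value:
    cost: Value = 0.0
    for name, expr in node.cost_components:
        component = _eval(expr, ctx)
        if np.any(np.asarray(component) < 0):
            raise TreeStructureError(f"negative cost component '{name}' at '{node.label}'")
        cost = cost + component
    if isinstance(node, TerminalNode):
        return cost
    probs = [_eval(expr, ctx) for expr, _ in node.branches]
    total = sum(np.asarray(p, dtype=float) for p in probs)
    if np.max(np.abs(total - 1.0)) > _PROB_TOL:
        raise TreeStructureError(
            f"branch probabilities at '{node.label}' sum to "
            f"{np.max(total)!r}, not 1"
        )
    for p, (_, child) in zip(probs, node.branches):
        if np.any(np.asarray(p) < 0):
            raise TreeStructureError(f"negative branch probability at '{node.label}'")
        cost = cost + p * _rollback(child, ctx)
    return cost


def rollback_expected_cost(
    tree: DecisionTree, overrides: Mapping[str, Value] | None = None
) -> dict[str, Value]:
    """Exact probability-weighted expected cost per strategy, no sampling.

    ``overrides`` replaces entries of the tree's baked context; array-valued
    overrides broadcast, giving one rollback per array element.
    """
    ctx = dict(tree.context)
    if overrides:
        ctx.update(overrides)
    return {name: _rollback(node, ctx) for name, node in tree.root.strategies.items()}


def convert_currency(sgd: Value, factor: float) -> Value:
    """SGD -> USD by a fixed factor; rounding is a reporting concern only."""
    if factor <= 0:
        raise ValueError("conversion factor must be positive")
    return sgd * factor


class StrategyCosts(BaseModel):
    """Base-case expected costs of both arms, per patient and per cohort."""

    model_config = ConfigDict(frozen=True)

    per_patient_cost_aipoc: float
    per_patient_cost_tte: float
    cohort_cost_aipoc: float
    cohort_cost_tte: float
    incremental_cohort_cost: float
    cohort_size: int
    prevalence: float
    sgd_to_usd: float

    def usd(self, value_sgd: float) -> float:
        return convert_currency(value_sgd, self.sgd_to_usd)


def evaluate_base_case(
    params: ModelParameters, opts: StructureOptions | None = None
) -> StrategyCosts:
    """Roll the tree back at the point estimates."""
    tree = build_model(params, opts)
    per_patient = rollback_expected_cost(tree)
    n = params.cohort_size
    return StrategyCosts(
        per_patient_cost_aipoc=per_patient["aipoc"],
        per_patient_cost_tte=per_patient["tte"],
        cohort_cost_aipoc=per_patient["aipoc"] * n,
        cohort_cost_tte=per_patient["tte"] * n,
        incremental_cohort_cost=(per_patient["aipoc"] - per_patient["tte"]) * n,
        cohort_size=n,
        prevalence=params.require_prevalence(),
        sgd_to_usd=params.sgd_to_usd,
    )


def calibrate_prevalence(
    params: ModelParameters,
    opts: StructureOptions | None,
    arm: Literal["tte", "aipoc"],
    target_per_patient_cost: float,
) -> float:
    """Solve for the prevalence at which ``arm`` costs the target per patient.

    The per-arm expected cost is affine in prevalence (it enters each
    root-to-leaf path probability exactly once), so the solution is closed
    form: p = (target - C(0)) / (C(1) - C(0)).  The result is verified by
    re-evaluation to 1e-9.
    """
    if arm not in ARMS:
        raise ValueError(f"arm must be one of {ARMS}")
    tree = build_model(params.with_prevalence(0.0), opts)
    c0 = float(rollback_expected_cost(tree, {"prevalence": 0.0})[arm])
    c1 = float(rollback_expected_cost(tree, {"prevalence": 1.0})[arm])
    lo, hi = min(c0, c1), max(c0, c1)
    if not (lo <= target_per_patient_cost <= hi):
        raise ValueError(
            f"target {target_per_patient_cost} for arm '{arm}' is outside the "
            f"reachable cost range [{lo:.4f}, {hi:.4f}]"
        )
    p = (target_per_patient_cost - c0) / (c1 - c0)
    check = float(rollback_expected_cost(tree, {"prevalence": p})[arm])
    if abs(check - target_per_patient_cost) > 1e-9:
        raise TreeStructureError(
            "calibration self-check failed: expected cost is not affine in prevalence"
        )
    return p


def resolve_prevalence(config_params: ModelParameters, calibration, opts=None) -> ModelParameters:
    """Return parameters with prevalence set, calibrating if necessary."""
    if config_params.prevalence is not None:
        return config_params
    if calibration is None:
        raise ValueError("prevalence unset and no calibration target available")
    p = calibrate_prevalence(
        config_params, opts, calibration.arm, calibration.target_per_patient_sgd
    )
    return config_params.with_prevalence(p)


def _node_to_dict(node: Node) -> dict:
    out: dict = {"label": node.label, "cost_components": [list(c) for c in node.cost_components]}
    if isinstance(node, ChanceNode):
        out["type"] = "chance"
        out["branches"] = [
            {"probability": expr, "child": _node_to_dict(child)} for expr, child in node.branches
        ]
    else:
        out["type"] = "terminal"
    return out


def tree_to_dict(tree: DecisionTree) -> dict:
    """Machine-readable export for audit."""
    return {
        "root": {
            "label": tree.root.label,
            "type": "decision",
            "strategies": {k: _node_to_dict(v) for k, v in tree.root.strategies.items()},
        },
        "context": tree.context,
        "options": tree.options.model_dump(),
    }


def _node_to_text(node: Node, indent: int, lines: list[str]) -> None:
    pad = "  " * indent
    for name, expr in node.cost_components:
        lines.append(f"{pad}+ {name}: {expr}")
    if isinstance(node, ChanceNode):
        for expr, child in node.branches:
            lines.append(f"{pad}({expr}) -> {child.label}")
            _node_to_text(child, indent + 1, lines)


def tree_to_text(tree: DecisionTree) -> str:
    """Human-readable indented rendering of the full tree."""
    lines = [f"[decision] {tree.root.label}"]
    for name, node in tree.root.strategies.items():
        lines.append(f" strategy: {name} — {node.label}")
        _node_to_text(node, 2, lines)
    return "\n".join(lines)


def tree_to_json(tree: DecisionTree) -> str:
    return json.dumps(tree_to_dict(tree), indent=2)
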