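"""Model parameter container and configuration loading.

The decision model is driven entirely by a structured YAML/JSON config: one
block per published input (point estimate, 95% CI, family, source) plus a
``model`` block (horizon, cohort size, currency factor, prevalence) and an
optional ``calibration`` block used when the prevalence is not supplied
directly.  The bundled ``paper_params.yaml`` ships the published values.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .distributions import DistributionSpec, FitMethod, FittedDistribution, fit_distribution
from .microcosting import CostingInputs, total_cost_per_exam

__all__ = [
    "ModelParameters",
    "CalibrationTarget",
    "ModelConfig",
    "ConfigError",
    "PARAM_ORDER",
    "load_parameters",
    "bundled_config_path",
    "fit_all",
]

#: stable sampling order = published table row order; appending new
#: parameters must not perturb the random sub-streams of earlier ones.
PARAM_ORDER: tuple[str, ...] = (
    "cost_consult",
    "cost_hosp",
    "cost_aipoc_exam",
    "cost_tte_exam",
    "cost_treatment_monthly",
    "sens_ai",
    "spec_ai",
    "p_interpretable",
    "sens_tte",
    "spec_tte",
    "p_hosp_treated",
    "p_hosp_untreated",
)

_COST_NAMES = frozenset(n for n in PARAM_ORDER if n.startswith("cost_"))


class ConfigError(ValueError):
    """Invalid or incomplete model configuration."""


class ModelParameters(BaseModel):
    """Complete set of point-estimate inputs for the decision model.

    Costs are 2023 SGD; probabilities are unitless in [0, 1].  ``prevalence``
    (pre-test probability of LVEF < 50% in the referred population) may be
    left unset and calibrated against a known per-patient cost instead.
    """

    model_config = ConfigDict(validate_assignment=True)

    cost_consult: float = Field(ge=0)
    cost_hosp: float = Field(ge=0)
    cost_aipoc_exam: float = Field(ge=0)
    cost_tte_exam: float = Field(ge=0)
    cost_treatment_monthly: float = Field(ge=0)
    sens_ai: float = Field(ge=0, le=1)
    spec_ai: float = Field(ge=0, le=1)
    p_interpretable: float = Field(ge=0, le=1)
    sens_tte: float = Field(ge=0, le=1)
    spec_tte: float = Field(ge=0, le=1)
    p_hosp_treated: float = Field(ge=0, le=1)
    p_hosp_untreated: float = Field(ge=0, le=1)
    prevalence: Optional[float] = Field(default=None, ge=0, le=1)
    horizon_months: int = Field(default=12, ge=1)
    cohort_size: int = Field(default=100, ge=1)
    sgd_to_usd: float = Field(default=1.20047, gt=0)

    def with_prevalence(self, prevalence: float) -> "ModelParameters":
        return self.model_copy(update={"prevalence": float(prevalence)})

    def require_prevalence(self) -> float:
        if self.prevalence is None:
            raise ConfigError(
                "prevalence is unset; supply it in the config or calibrate it "
                "against a per-patient cost target (calibrate_prevalence)"
            )
        return self.prevalence


class CalibrationTarget(BaseModel):
    """Known per-patient cost used to back out the unprinted prevalence."""

    model_config = ConfigDict(frozen=True)

    arm: Literal["tte", "aipoc"]
    target_per_patient_sgd: float = Field(gt=0)


@dataclass
class ModelConfig:
    """Everything read from one config file."""

    params: ModelParameters
    specs: dict[str, DistributionSpec]
    calibration: Optional[CalibrationTarget]
    costing: dict[str, CostingInputs] = field(default_factory=dict)
    config_sha256: str = ""
    source: str = "<dict>"

    def fits(self, method: FitMethod = "quantile") -> dict[str, FittedDistribution]:
        return fit_all(self.specs, method)


def fit_all(
    specs: dict[str, DistributionSpec], method: FitMethod = "quantile"
) -> dict[str, FittedDistribution]:
    """Fit every spec, in stable table order, reporting all failures at once."""
    fits: dict[str, FittedDistribution] = {}
    errors: list[str] = []
    ordered = [n for n in PARAM_ORDER if n in specs]
    ordered += [n for n in specs if n not in PARAM_ORDER]
    for name in ordered:
        try:
            fits[name] = fit_distribution(specs[name], method)
        except Exception as exc:  # noqa: BLE001 - aggregated and re-raised
            errors.append(f"{name}: {exc}")
    if errors:
        raise ConfigError("distribution fitting failed for: " + "; ".join(errors))
    return fits


def bundled_config_path() -> Path:
    """Path to the packaged config reproducing the published inputs."""
    return Path(resources.files("pocus_cma").joinpath("data/paper_params.yaml"))


def _read_raw(source) -> tuple[dict, str, str]:
    if isinstance(source, dict):
        text = json.dumps(source, sort_keys=True)
        return source, hashlib.sha256(text.encode()).hexdigest(), "<dict>"
    path = Path(source)
    text = path.read_text()
    raw = yaml.safe_load(text)  # YAML is a superset of JSON
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config root must be a mapping")
    return raw, hashlib.sha256(text.encode()).hexdigest(), str(path)


def load_parameters(source=None) -> ModelConfig:
    """Load and validate a model configuration.

    ``source`` is a path to a YAML/JSON file, a pre-parsed dict, or ``None``
    for the bundled published values.  Raises :class:`ConfigError` listing
    every offending or missing field.
    """
    if source is None:
        source = bundled_config_path()
    raw, sha, origin = _read_raw(source)

    errors: list[str] = []
    specs: dict[str, DistributionSpec] = {}
    for block in raw.get("parameters", []):
        try:
            name = block["name"]
            ci = block.get("ci", [block.get("estimate"), block.get("estimate")])
            specs[name] = DistributionSpec(
                name=name,
                family=block.get("family", "point"),
                point_estimate=float(block["estimate"]),
                ci_lower=float(ci[0]),
                ci_upper=float(ci[1]),
                source_label=str(block.get("source", "")),
            )
        except Exception as exc:  # noqa: BLE001
            errors.append(f"parameters[{block.get('name', '?')}]: {exc}")

    costing: dict[str, CostingInputs] = {}
    for name, block in (raw.get("costing") or {}).items():
        try:
            costing[name] = CostingInputs.model_validate(block)
        except Exception as exc:  # noqa: BLE001
            errors.append(f"costing[{name}]: {exc}")

    # exam costs may be derived from a micro-costing block instead of given
    for name, inputs in costing.items():
        if name in _COST_NAMES and name not in specs:
            total = total_cost_per_exam(inputs)
            specs[name] = DistributionSpec(
                name=name,
                family="point",
                point_estimate=total,
                ci_lower=total,
                ci_upper=total,
                source_label="micro-costing block",
            )

    missing = [n for n in PARAM_ORDER if n not in specs]
    if missing:
        errors.append("missing parameters: " + ", ".join(missing))

    model_block = raw.get("model") or {}
    calibration = None
    if raw.get("calibration"):
        try:
            calibration = CalibrationTarget.model_validate(raw["calibration"])
        except Exception as exc:  # noqa: BLE001
            errors.append(f"calibration: {exc}")

    params = None
    if not errors:
        fields = {n: specs[n].point_estimate for n in PARAM_ORDER}
        for key in ("prevalence", "horizon_months", "cohort_size", "sgd_to_usd"):
            if model_block.get(key) is not None:
                fields[key] = model_block[key]
        try:
            params = ModelParameters(**fields)
        except Exception as exc:  # noqa: BLE001
            errors.append(str(exc))

    if params is not None and params.prevalence is None and calibration is None:
        errors.append(
            "prevalence is not set and no calibration target is supplied; "
            "one of the two is required"
        )
    if errors:
        raise ConfigError(f"invalid configuration ({origin}): " + " | ".join(errors))

    return ModelConfig(
        params=params,
        specs=specs,
        calibration=calibration,
        costing=costing,
        config_sha256=sha,
        source=origin,
    )
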