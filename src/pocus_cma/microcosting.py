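"""Per-examination unit costs from annual equipment books and personnel time.

The unit cost of one echocardiographic exam is reconstructed by dividing the
total annual equipment + software cost by the annual outpatient exam volume,
and adding a salary-derived personnel cost: for each role, the annual salary
converted to a per-minute rate times the minutes that role spends per exam.
Training, maintenance and other overheads are assumed already baked into the
annual figures.
"""

from __future__ import annotations

from pydantic import BaseModel, ConfigDict, Field

__all__ = [
    "PersonnelRole",
    "CostingInputs",
    "unit_cost_per_exam",
    "personnel_cost_per_exam",
    "total_cost_per_exam",
]


class PersonnelRole(BaseModel):
    model_config = ConfigDict(frozen=True)

    role: str
    annual_salary: float = Field(ge=0)
    minutes_per_exam: float = Field(ge=0)
    working_minutes_per_year: float = Field(gt=0)


class CostingInputs(BaseModel):
    """Annual books for one exam modality."""

    model_config = ConfigDict(frozen=True)

    annual_equipment_cost: float = Field(ge=0)
    annual_software_cost: float = Field(default=0.0, ge=0)
    annual_exam_volume: int = Field(ge=1)
    personnel: tuple[PersonnelRole, ...] = ()


def unit_cost_per_exam(inputs: CostingInputs) -> float:
    """(equipment + software) per year, amortized over the annual volume."""
    if inputs.annual_exam_volume <= 0:
        raise ValueError("annual_exam_volume must be positive")
    return (inputs.annual_equipment_cost + inputs.annual_software_cost) / inputs.annual_exam_volume


def personnel_cost_per_exam(inputs: CostingInputs) -> float:
    """Sum over roles of per-minute salary rate times minutes per exam."""
    total = 0.0
    for p in inputs.personnel:
        if p.working_minutes_per_year <= 0:
            raise ValueError(f"{p.role}: working_minutes_per_year must be positive")
        total += (p.annual_salary / p.working_minutes_per_year) * p.minutes_per_exam
    return total


def total_cost_per_exam(inputs: CostingInputs) -> float:
    return unit_cost_per_exam(inputs) + personnel_cost_per_exam(inputs)
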