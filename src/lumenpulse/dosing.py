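"""Insulin dosing utility for recurrent-hypoglycemia protocols.

Standalone protocol arithmetic: the dose that targets mild-to-moderate
hypoglycemia is computed from body weight and fasting glucose as

    dose (UI) = 0.75 x body weight (kg) x fasting glucose (mg/dL) / 100

and the administered dose is expected to fall within 1-4 UI/kg.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["DoseInputs", "InsulinDose", "insulin_dose", "DOSE_RANGE_UI_PER_KG"]

DOSE_RANGE_UI_PER_KG = (1.0, 4.0)


@dataclass(frozen=True)
class DoseInputs:
    body_weight_kg: float
    fasting_glucose_mg_dl: float

    def __post_init__(self) -> None:
        if self.body_weight_kg < 0 or self.fasting_glucose_mg_dl < 0:
            raise ValueError("weight and glucose must be non-negative")


@dataclass(frozen=True)
class InsulinDose:
    dose_ui: float
    dose_ui_per_kg: float
    in_range: bool


def insulin_dose(d: DoseInputs) -> InsulinDose:
    """Compute the insulin dose and flag doses outside 1-4 UI/kg.

    For a weightless input the dose is 0 UI and the per-kg dose is
    reported as 0 (out of range).
    """
    dose = 0.75 * d.body_weight_kg * d.fasting_glucose_mg_dl / 100.0
    per_kg = dose / d.body_weight_kg if d.body_weight_kg > 0 else 0.0
    lo, hi = DOSE_RANGE_UI_PER_KG
    return InsulinDose(dose, per_kg, lo <= per_kg <= hi)
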