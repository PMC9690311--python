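"""Chilean front-of-package "high in" warning labels (Law 20.606).

A food carries between 0 and 4 black warning stamps, one per critical
element (energy, sodium, sugars, saturated fat) whose declared content per
100 g (solids) or 100 mL (liquids) strictly exceeds the legal limit for the
food's physical state. The regulation scopes the stamps to foods with
*added* sugars, saturated fat or sodium; that gate is optional here
(``gate=False`` classifies on composition alone, which is what can be read
off a label).
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import FoodRecord, validate_record

LABELS = ("high_calories", "high_sodium", "high_sugars", "high_sat_fat")

#: legal limits per 100 g of solid product
SOLID_LIMITS = {
    "high_calories": 275.0,   # kcal
    "high_sodium": 400.0,     # mg
    "high_sugars": 10.0,      # g
    "high_sat_fat": 4.0,      # g
}
#: legal limits per 100 mL of liquid product
LIQUID_LIMITS = {
    "high_calories": 70.0,
    "high_sodium": 100.0,
    "high_sugars": 5.0,
    "high_sat_fat": 3.0,
}

_PANEL_FIELD = {
    "high_calories": "energy_kcal",
    "high_sodium": "sodium_mg",
    "high_sugars": "sugars_g",
    "high_sat_fat": "saturated_fat_g",
}


class InvalidRecordError(ValueError):
    """Raised when a record fails validation; carries the issues."""

    def __init__(self, issues):
        self.issues = issues
        super().__init__("; ".join(f"{i.field}: {i.message}" for i in issues))


@dataclass(frozen=True, slots=True)
class FoPResult:
    """Warning-label verdict with the signed margin to each limit."""

    labels: frozenset[str]
    thresholds_used: str  # "solid" | "liquid"
    per_nutrient_margin: dict[str, float]

    @property
    def n_labels(self) -> int:
        return len(self.labels)


def fop_thresholds(state: str) -> dict[str, float]:
    """The four legal limits for the given physical state."""
    if state == "solid":
        return dict(SOLID_LIMITS)
    if state == "liquid":
        return dict(LIQUID_LIMITS)
    raise ValueError(f"unknown state {state!r}; expected 'solid' or 'liquid'")


def count_warnings(record: FoodRecord, gate: bool = False) -> FoPResult:
    """Assign warning labels by strict exceedance of the state's limits.

    With ``gate=True`` the sugar/saturated-fat/sodium stamps additionally
    require the corresponding ``added_*`` flag, and the calorie stamp
    requires at least one added flag (the regulation's scope); the default
    classifies on declared composition alone.
    """
    issues = [i for i in validate_record(record) if i.is_fatal]
    if issues:
        raise InvalidRecordError(issues)
    limits = fop_thresholds(record.state)
    margins = {
        lab: getattr(record.panel, _PANEL_FIELD[lab]) - limits[lab] for lab in LABELS
    }
    gate_pass = {
        "high_sugars": record.added_sugar,
        "high_sat_fat": record.added_sat_fat,
        "high_sodium": record.added_sodium,
        "high_calories": record.added_sugar or record.added_sat_fat or record.added_sodium,
    }
    labels = frozenset(
        lab for lab in LABELS
        if margins[lab] > 0 and (not gate or gate_pass[lab])
    )
    return FoPResult(labels=labels, thresholds_used=record.state,
                     per_nutrient_margin=margins)
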