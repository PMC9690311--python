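"""Nutri-Score: continuous nutrient-profiling score (-15 healthiest to +40
least healthy) mapped to the letters A-E.

Implements the 2017 general-food algorithm published by Sante Publique
France. Negative points (0-10 each) accrue from energy, sugars, saturated
fat and sodium; positive points from fruit/vegetable/nut/legume content
(0-5), fibre (0-5) and protein (0-5). Points increment only when the value
*strictly* exceeds a threshold. The N/P balance rule excludes protein when
the negative total reaches 11 unless the FVNL component is maximal; cheeses
always count protein; added fats score saturated fat on the saturated/total
fat ratio; beverages use their own energy, sugar and FVNL scales, with
plain water rated A by definition.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass

from .model import NutrientPanel, ValidationIssue

# negative-component threshold tables: value > table[k] for all k < p earns p points
ENERGY_KJ_GENERAL = (335, 670, 1005, 1340, 1675, 2010, 2345, 2680, 3015, 3350)
ENERGY_KJ_BEVERAGE = (0, 30, 60, 90, 120, 150, 180, 210, 240, 270)
SUGARS_GENERAL = (4.5, 9, 13.5, 18, 22.5, 27, 31, 36, 40, 45)
SUGARS_BEVERAGE = (0, 1.5, 3, 4.5, 6, 7.5, 9, 10.5, 12, 13.5)
SATFAT_GENERAL = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10)
# added fats score the percentage 100 x saturated/total fat instead of grams
SATFAT_RATIO_ADDED_FAT = (10, 16, 22, 28, 34, 40, 46, 52, 58, 64)
SODIUM_MG = (90, 180, 270, 360, 450, 540, 630, 720, 810, 900)

FIBRE_G = (0.9, 1.9, 2.8, 3.7, 4.7)
PROTEIN_G = (1.6, 3.2, 4.8, 6.4, 8.0)

CATEGORIES = ("A", "B", "C", "D", "E")
#: closed score bands for general foods: A [-15,-1], B [0,2], C [3,10], D [11,18], E [19,40]
BAND_UPPER = ((-1, "A"), (2, "B"), (10, "C"), (18, "D"), (40, "E"))

COMPONENTS = ("energy", "sugars", "satfat", "sodium", "fvnl", "fibre", "protein")
VARIANTS = ("general", "beverage", "added_fat")


class InvalidPanelError(ValueError):
    """Raised when a panel cannot be scored; carries the validation issues."""

    def __init__(self, issues: list[ValidationIssue]):
        self.issues = issues
        super().__init__("; ".join(f"{i.field}: {i.message}" for i in issues))


@dataclass(frozen=True, slots=True)
class NutriScorePoints:
    """Full point breakdown of one Nutri-Score computation."""

    energy_pts: int
    sugars_pts: int
    satfat_pts: int
    sodium_pts: int
    fvnl_pts: int
    fibre_pts: int
    protein_pts: int
    protein_counted: bool
    final_score: int
    category: str

    @property
    def n_total(self) -> int:
        return self.energy_pts + self.sugars_pts + self.satfat_pts + self.sodium_pts

    @property
    def p_total(self) -> int:
        return self.fvnl_pts + self.fibre_pts + self.protein_pts

    def as_dict(self) -> dict:
        return {
            "energy_pts": self.energy_pts, "sugars_pts": self.sugars_pts,
            "satfat_pts": self.satfat_pts, "sodium_pts": self.sodium_pts,
            "fvnl_pts": self.fvnl_pts, "fibre_pts": self.fibre_pts,
            "protein_pts": self.protein_pts, "n_total": self.n_total,
            "p_total": self.p_total, "protein_counted": self.protein_counted,
            "final_score": self.final_score, "category": self.category,
        }


def _scan(value: float, table: tuple) -> int:
    # number of thresholds strictly below the value == points earned
    return bisect_left(table, value)


def _fvnl_points(pct: float, beverage: bool) -> int:
    if pct > 80:
        return 10 if beverage else 5
    if pct > 60:
        return 4 if beverage else 2
    if pct > 40:
        return 2 if beverage else 1
    return 0


def component_points(component: str, value: float, variant: str = "general") -> int:
    """Points for a single component at the given amount.

    ``value`` is kJ for energy, g for sugars/satfat/fibre/protein, mg for
    sodium and a 0-100 percentage for fvnl; for the ``added_fat`` variant the
    satfat value is the percentage 100 x saturated/total fat.
    """
    if component not in COMPONENTS:
        raise ValueError(f"unknown component {component!r}")
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    if value < 0:
        raise ValueError(f"negative amount {value} for {component}")
    beverage = variant == "beverage"
    if component == "energy":
        return _scan(value, ENERGY_KJ_BEVERAGE if beverage else ENERGY_KJ_GENERAL)
    if component == "sugars":
        return _scan(value, SUGARS_BEVERAGE if beverage else SUGARS_GENERAL)
    if component == "satfat":
        return _scan(value, SATFAT_RATIO_ADDED_FAT if variant == "added_fat"
                     else SATFAT_GENERAL)
    if component == "sodium":
        return _scan(value, SODIUM_MG)
    if component == "fvnl":
        return _fvnl_points(value, beverage)
    if component == "fibre":
        return _scan(value, FIBRE_G)
    return _scan(value, PROTEIN_G)  # protein


def score_to_category(score: int) -> str:
    """Letter band for a general-food score; errors outside [-15, 40]."""
    if not -15 <= score <= 40:
        raise ValueError(f"score {score} outside [-15, 40]")
    for upper, letter in BAND_UPPER:
        if score <= upper:
            return letter
    raise AssertionError("unreachable")


def _beverage_category(score: int, is_water: bool) -> str:
    if is_water:
        return "A"
    if score <= 1:
        return "B"
    if score <= 5:
        return "C"
    if score <= 9:
        return "D"
    return "E"


def compute_nutriscore(panel: NutrientPanel, special_category: str = "none") -> NutriScorePoints:
    """Score a panel under the variant selected by ``special_category``
    (none -> general food; beverage / added_fat / cheese exceptions)."""
    issues = [
        ValidationIssue("<panel>", f, "fatal", f"invalid value {getattr(panel, f)}")
        for f in ("energy_kcal", "sugars_g", "saturated_fat_g", "total_fat_g",
                  "sodium_mg", "fibre_g", "protein_g", "fvnl_pct")
        if getattr(panel, f) is None or getattr(panel, f) < 0
    ]
    if panel.fvnl_pct is not None and panel.fvnl_pct > 100:
        issues.append(ValidationIssue("<panel>", "fvnl_pct", "fatal",
                                      f"fvnl_pct {panel.fvnl_pct} exceeds 100"))
    if issues:
        raise InvalidPanelError(issues)

    beverage = special_category == "beverage"
    variant = "beverage" if beverage else "general"

    energy_pts = component_points("energy", panel.energy_kj, variant)
    sugars_pts = component_points("sugars", panel.sugars_g, variant)
    if special_category == "added_fat":
        ratio = (100.0 * panel.saturated_fat_g / panel.total_fat_g
                 if panel.total_fat_g > 0 else 0.0)
        satfat_pts = component_points("satfat", ratio, "added_fat")
    else:
        satfat_pts = component_points("satfat", panel.saturated_fat_g, "general")
    sodium_pts = component_points("sodium", panel.sodium_mg, "general")
    fvnl_pts = component_points("fvnl", panel.fvnl_pct, variant)
    fibre_pts = component_points("fibre", panel.fibre_g, "general")
    protein_pts = component_points("protein", panel.protein_g, "general")

    n_total = energy_pts + sugars_pts + satfat_pts + sodium_pts
    fvnl_max = 10 if beverage else 5
    protein_counted = (special_category == "cheese"
                       or n_total < 11
                       or fvnl_pts == fvnl_max)
    p_counted = fvnl_pts + fibre_pts + (protein_pts if protein_counted else 0)
    final_score = n_total - p_counted

    if beverage:
        is_water = (panel.energy_kcal == 0 and panel.sugars_g == 0
                    and panel.total_fat_g == 0 and panel.sodium_mg == 0)
        category = _beverage_category(final_score, is_water)
    else:
        category = score_to_category(final_score)

    return NutriScorePoints(
        energy_pts=energy_pts, sugars_pts=sugars_pts, satfat_pts=satfat_pts,
        sodium_pts=sodium_pts, fvnl_pts=fvnl_pts, fibre_pts=fibre_pts,
        protein_pts=protein_pts, protein_counted=protein_counted,
        final_score=final_score, category=category,
    )
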