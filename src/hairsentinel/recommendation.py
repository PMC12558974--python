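"""Nutrient-deficit quantification and diet/lifestyle recommendations.

Deficits are reconstructed from intake ratios against the RDA table:
``deficit = max(0, (1 - ratio) * per_day requirement)`` — grams per day for
protein and omega-3, milligrams per day for iron. Nutrients in deficit map
to their food lists (eggs/lentils/dairy for protein, spinach/meat/beans for
iron, walnuts/flaxseeds for omega-3); rule-based lifestyle actions trigger
on low iron intake, a low scalp health score, or a high stress impact
score. The deficiency trajectory compares the current nutrient deficiency
score (NDS) with the previous one: a crossing from <= 0 to > 0 is a *new*
deficiency, a shrinking positive score means the user is *improving*.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .errors import ContractError, DomainError
from .indices import NUTRIENTS, DerivedIndices, RDATable

__all__ = [
    "FOOD_SOURCES",
    "LifestyleThresholds",
    "DietPlan",
    "compute_deficits",
    "recommend_foods",
    "lifestyle_rules",
    "deficiency_trajectory",
    "build_diet_plan",
]

FOOD_SOURCES = {
    "protein": ["eggs", "lentils", "dairy products"],
    "iron": ["spinach", "meat", "beans"],
    "omega3": ["walnuts", "flaxseeds"],
}

#: Units of the per-day deficits.
DEFICIT_UNITS = {"protein": "g/day", "iron": "mg/day", "omega3": "g/day"}


@dataclass
class LifestyleThresholds:
    """θ1: iron-ratio floor; θ2: scalp-score floor; θ3: stress-score ceiling."""

    iron_ratio_min: float = 0.8
    shs_min: float = 0.5
    sis_max: float = 5.0


@dataclass
class DietPlan:
    deficits: dict = field(default_factory=dict)          # nutrient -> amount/day
    foods: dict = field(default_factory=dict)             # nutrient -> food list
    lifestyle_actions: list = field(default_factory=list)
    deficiency_status: str = "none"


def compute_deficits(intake_ratios: Mapping[str, float], gender: str, age: float,
                     rda: RDATable) -> dict:
    """Per-nutrient daily shortfall: ``max(0, (1 - ratio) * RDA per day)``."""
    deficits = {}
    for nutrient in NUTRIENTS:
        ratio = float(intake_ratios[nutrient])
        if ratio < 0:
            raise DomainError(f"ratio for {nutrient} must be >= 0")
        entry = rda.lookup(nutrient, gender, age)
        deficits[nutrient] = max(0.0, (1.0 - ratio) * entry.per_day)
    return deficits


def recommend_foods(deficits: Mapping[str, float]) -> dict:
    """Food lists for every nutrient in deficit; empty lists otherwise."""
    unknown = set(deficits) - set(FOOD_SOURCES)
    if unknown:
        raise ContractError(f"unknown nutrients: {sorted(unknown)}")
    return {nutrient: (list(FOOD_SOURCES[nutrient]) if amount > 0 else [])
            for nutrient, amount in deficits.items()}


def lifestyle_rules(indices: DerivedIndices,
                    thresholds: LifestyleThresholds | None = None) -> list:
    """Rule list, in fixed order: iron-rich foods, scalp therapy, meditation."""
    thresholds = thresholds or LifestyleThresholds()
    actions = []
    if indices.iron_ratio < thresholds.iron_ratio_min:
        actions.append("iron_rich_foods")
    shs = indices.shs_refined if indices.shs_refined is not None else indices.shs
    if shs is not None and shs < thresholds.shs_min:
        actions.append("scalp_therapy")
    if indices.sis > thresholds.sis_max:
        actions.append("meditation")
    return actions


def deficiency_trajectory(previous_nds: float, current_nds: float) -> str:
    """Classify the move between two nutrient deficiency scores.

    none: both <= 0; new: crossed into deficiency; improving: still
    deficient but decreasing; persistent: otherwise.
    """
    for v in (previous_nds, current_nds):
        if not (v == v and abs(v) != float("inf")):
            raise DomainError("NDS values must be finite")
    if previous_nds <= 0 and current_nds <= 0:
        return "none"
    if previous_nds <= 0 < current_nds:
        return "new"
    if previous_nds > 0 and current_nds > 0 and current_nds < previous_nds:
        return "improving"
    return "persistent"


def build_diet_plan(indices: DerivedIndices, gender: str, age: float,
                    rda: RDATable, previous_nds: float | None = None,
                    thresholds: LifestyleThresholds | None = None) -> DietPlan:
    """Assemble the full plan for one user's derived indices."""
    ratios = {"protein": indices.protein_ratio, "iron": indices.iron_ratio,
              "omega3": indices.omega_ratio}
    deficits = compute_deficits(ratios, gender, age, rda)
    status = ("none" if previous_nds is None and indices.nds <= 0
              else "persistent" if previous_nds is None
              else deficiency_trajectory(previous_nds, indices.nds))
    return DietPlan(deficits=deficits, foods=recommend_foods(deficits),
                    lifestyle_actions=lifestyle_rules(indices, thresholds),
                    deficiency_status=status)
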