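"""Per-species diet profiles and the three-level specialization
classification used for snake diets.

A species is a *specialist* when one prey category makes up more than 70%
of its diet, shows a *trend toward specialization* when the leading
category holds between 50% and 70% (inclusive), and is a *generalist*
when no category reaches 50%.  The classification depends only on the
diet composition, so it is invariant to the number of prey records.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import DietMatrix, ValidationError

SPECIALIST = "specialist"
TREND = "trend_toward_specialization"
GENERALIST = "generalist"


@dataclass
class DietProfile:
    species_id: str
    proportions: np.ndarray
    prey_categories: list[str]
    n_items: float
    classification: str
    dominant_category: str
    dominant_tied: bool = False

    def to_dict(self) -> dict:
        return {
            "species_id": self.species_id,
            "proportions": dict(zip(self.prey_categories, map(float, self.proportions))),
            "n_items": float(self.n_items),
            "classification": self.classification,
            "dominant_category": self.dominant_category,
            "dominant_tied": self.dominant_tied,
        }


def classify_max_proportion(f: float) -> str:
    """Specialization class from the largest diet proportion ``f``:
    specialist if f > 0.70, trend if 0.50 <= f <= 0.70, else generalist."""
    if f > 0.70:
        return SPECIALIST
    if f >= 0.50:
        return TREND
    return GENERALIST


def classify_diet(counts: np.ndarray, prey_categories: list[str],
                  species_id: str = "") -> DietProfile:
    """Classify one species' diet row (raw counts or proportions)."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValidationError(f"species {species_id!r} has no prey records")
    props = counts / total
    top = int(np.argmax(props))  # argmax returns the first (lexicographically
    # earliest in column order) index on ties
    tied = int(np.sum(np.isclose(props, props[top], rtol=0, atol=1e-12))) > 1
    return DietProfile(
        species_id=species_id,
        proportions=props,
        prey_categories=list(prey_categories),
        n_items=float(total),
        classification=classify_max_proportion(float(props[top])),
        dominant_category=prey_categories[top],
        dominant_tied=tied,
    )


def profile_table(Y: DietMatrix) -> list[DietProfile]:
    """One diet profile per species, in the matrix's row order."""
    return [
        classify_diet(Y.counts[i], Y.prey_categories, species_id=sp)
        for i, sp in enumerate(Y.species_ids)
    ]
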