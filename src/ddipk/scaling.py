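"""Body-surface-area (Km-factor) dose translation between species.

Interspecies dose conversion by surface-area normalization uses the standard
regulatory Km table (body weight divided by surface area, kg/m^2):
the human equivalent dose is HED = animal dose x Km_animal / Km_human, so a
mouse dose converts by the factor 3/37.  Total human dose multiplies the HED
by a reference body weight (70 kg adult) and rounds to a practical dose
increment (nearest 10 mg by default); the unrounded value is reported too.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import UnknownSpeciesError, ValidationError


@dataclass(frozen=True)
class SpeciesKmFactor:
    species: str
    km_factor: float  # body weight / surface area, kg per m^2
    reference_body_weight: float  # kg


#: standard surface-area conversion table (regulatory Km factors)
KM_TABLE: dict[str, SpeciesKmFactor] = {
    s.species: s
    for s in (
        SpeciesKmFactor("mouse", 3.0, 0.02),
        SpeciesKmFactor("hamster", 5.0, 0.08),
        SpeciesKmFactor("rat", 6.0, 0.15),
        SpeciesKmFactor("guinea_pig", 8.0, 0.4),
        SpeciesKmFactor("rabbit", 12.0, 1.8),
        SpeciesKmFactor("dog", 20.0, 10.0),
        SpeciesKmFactor("monkey", 12.0, 3.0),
        SpeciesKmFactor("human", 37.0, 70.0),
    )
}


def _km(species: str) -> float:
    try:
        return KM_TABLE[species.strip().lower().replace(" ", "_")].km_factor
    except KeyError:
        raise UnknownSpeciesError(
            f"unknown species {species!r}; known: {sorted(KM_TABLE)}"
        ) from None


def human_equivalent_dose(animal_dose: float, animal_species: str) -> float:
    """Human equivalent dose (mg/kg) by surface-area normalization."""
    if not animal_dose > 0:
        raise ValidationError(f"dose must be positive, got {animal_dose}")
    return animal_dose * _km(animal_species) / _km("human")


def total_human_dose(
    animal_dose: float,
    animal_species: str,
    body_weight: float = 70.0,
    round_to_mg: float | None = 10.0,
) -> tuple[float, float]:
    """Total human dose in mg for a reference body weight.

    Returns ``(rounded, unrounded)``; ``round_to_mg=None`` disables rounding.
    A 35 mg/kg mouse dose maps to 198.6 mg unrounded, 200 mg at the default
    nearest-10-mg policy.
    """
    if not body_weight > 0:
        raise ValidationError(f"body weight must be positive, got {body_weight}")
    unrounded = human_equivalent_dose(animal_dose, animal_species) * body_weight
    if round_to_mg is None:
        return unrounded, unrounded
    if not round_to_mg > 0:
        raise ValidationError(f"rounding increment must be positive, got {round_to_mg}")
    return round(unrounded / round_to_mg) * round_to_mg, unrounded
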