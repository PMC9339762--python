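"""Per-individual demand evaluation from adult body mass.

Evaluates the catalogue's power laws for one animal: population density
ρ = a·M^b (individuals km⁻²), land-area use L = ρ⁻¹ (km² individual⁻¹),
active-drinking water W (m³ individual⁻¹ day⁻¹) and field metabolic rate
energy E (kJ individual⁻¹ day⁻¹).

Two conventions to keep in mind:

* "Water use" is active drinking only.  Dietary and metabolic water are
  excluded by construction, so reptiles and insects — assumed to satisfy
  their water needs through diet, metabolism and atmospheric uptake — get a
  zero flagged ``assumed-zero`` rather than a modelled value.  Users
  expecting total water turnover will see much smaller numbers here.
* All evaluation is done at full floating precision; rounding to the 2-d.p.
  / few-significant-figure convention of published tables belongs to the
  reporting layer (``round half away from zero``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Optional

from .catalogue import (
    WATER_ASSUMED_ZERO,
    WATER_MODELLED,
    AllometricModel,
    BiologicalClass,
    CoefficientCatalogue,
    Resource,
    TrophicLevel,
)
from .errors import ValidationError


class ExtrapolationWarning(UserWarning):
    """Body mass lies outside the span of data the class's models were fit on."""


#: Package policy for per-class body-mass spans (kg) considered interpolation.
#: The published equations do not state fitted ranges; these spans bracket the
#: masses of real species in each class generously and are configurable.
DEFAULT_MASS_SPANS_KG = {
    BiologicalClass.MAMMAL: (1e-3, 1e4),
    BiologicalClass.BIRD: (1e-3, 2e2),
    BiologicalClass.REPTILE: (1e-3, 5e2),
    BiologicalClass.INSECT: (1e-9, 1e-1),
}


def _check_mass(mass_kg: float) -> float:
    mass_kg = float(mass_kg)
    if not mass_kg > 0:
        raise ValidationError(f"body mass must be positive, got {mass_kg}")
    return mass_kg


def _warn_if_extrapolating(taxon_class: BiologicalClass, mass_kg: float,
                           mass_spans) -> None:
    if mass_spans is None:
        return
    span = mass_spans.get(taxon_class)
    if span is not None and not (span[0] <= mass_kg <= span[1]):
        warnings.warn(
            f"body mass {mass_kg} kg is outside the fitted span "
            f"{span} for {taxon_class.value} models; extrapolating",
            ExtrapolationWarning,
            stacklevel=3,
        )


def evaluate_power_law(model: AllometricModel, mass_kg: float) -> float:
    """a·M^b with the branch coefficient applicable at this mass."""
    mass_kg = _check_mass(mass_kg)
    return model.coefficient_for(mass_kg) * mass_kg ** model.exponent_b


def population_density(mass_kg: float, model: AllometricModel) -> float:
    """Population density ρ = a·M^b (individuals km⁻²)."""
    if model.resource is not Resource.LAND_DENSITY:
        raise ValidationError(
            f"population_density needs a land_density model, got {model.resource.value}"
        )
    return evaluate_power_law(model, mass_kg)


def land_area_use(mass_kg: float, taxon_class, trophic,
                  catalogue: CoefficientCatalogue, *,
                  mass_spans=DEFAULT_MASS_SPANS_KG) -> float:
    """Land-area use L = (a·M^b)⁻¹ (km² individual⁻¹).

    This is the reciprocal of population density: the area one individual
    uses as part of a single-species population, interpreted downstream as a
    constraint on where its resources must lie, not an additive consumable.
    """
    mass_kg = _check_mass(mass_kg)
    taxon_class = BiologicalClass.parse(taxon_class)
    _warn_if_extrapolating(taxon_class, mass_kg, mass_spans)
    model = catalogue.resolve(Resource.LAND_DENSITY, taxon_class,
                              TrophicLevel.parse(trophic), mass_kg)
    return 1.0 / evaluate_power_law(model, mass_kg)


class WaterUse(NamedTuple):
    """Daily active-drinking water with its provenance flag."""

    m3_per_day: float
    provenance: str  # WATER_MODELLED | WATER_ASSUMED_ZERO


def water_use(mass_kg: float, taxon_class, catalogue: CoefficientCatalogue, *,
              mass_spans=DEFAULT_MASS_SPANS_KG) -> WaterUse:
    """Active drinking W (m³ individual⁻¹ day⁻¹); zero-flagged for classes
    assumed to meet water needs through diet and metabolism."""
    mass_kg = _check_mass(mass_kg)
    taxon_class = BiologicalClass.parse(taxon_class)
    model = catalogue.resolve(Resource.WATER, taxon_class, TrophicLevel.ALL, mass_kg)
    if model is None:
        return WaterUse(0.0, WATER_ASSUMED_ZERO)
    _warn_if_extrapolating(taxon_class, mass_kg, mass_spans)
    return WaterUse(evaluate_power_law(model, mass_kg), WATER_MODELLED)


def energy_use(mass_kg: float, taxon_class, trophic,
               catalogue: CoefficientCatalogue, *,
               mass_spans=DEFAULT_MASS_SPANS_KG) -> float:
    """Field metabolic rate E (kJ individual⁻¹ day⁻¹).

    Insects use the BMR→FMR-transformed two-branch model: the branch is
    selected by mass, with the boundary mass on the at-or-above branch.
    """
    mass_kg = _check_mass(mass_kg)
    taxon_class = BiologicalClass.parse(taxon_class)
    _warn_if_extrapolating(taxon_class, mass_kg, mass_spans)
    model = catalogue.resolve(Resource.ENERGY, taxon_class,
                              TrophicLevel.parse(trophic), mass_kg)
    return evaluate_power_law(model, mass_kg)


def bmr_to_fmr(bmr_coefficient: float, small_multiplier: float,
               large_multiplier: float) -> tuple:
    """Scale a basal-metabolic-rate coefficient into field-metabolic-rate
    branch coefficients (below-threshold, at-or-above-threshold).

    The exponent is unchanged by the transformation; only the coefficient is
    multiplied (32× for the smallest insects, 8× for larger ones, in the
    published model).
    """
    for name, val in (("bmr_coefficient", bmr_coefficient),
                      ("small_multiplier", small_multiplier),
                      ("large_multiplier", large_multiplier)):
        if not val > 0:
            raise ValidationError(f"{name} must be positive, got {val}")
    return (bmr_coefficient * small_multiplier, bmr_coefficient * large_multiplier)


@dataclass(frozen=True)
class IndividualDemand:
    """All three per-individual resource needs of one species."""

    species_name: str
    land_area_km2: float
    population_density_per_km2: float
    water_m3_per_day: float
    water_provenance: str
    energy_kj_per_day: float

    def __post_init__(self):
        if not self.land_area_km2 > 0 or not self.population_density_per_km2 > 0:
            raise ValidationError(
                f"{self.species_name}: land area and density must be positive"
            )
        recip = self.land_area_km2 * self.population_density_per_km2
        if abs(recip - 1.0) > 1e-12:
            raise ValidationError(
                f"{self.species_name}: land area is not the reciprocal of density "
                f"(product {recip})"
            )
        if self.water_m3_per_day < 0 or not self.energy_kj_per_day > 0:
            raise ValidationError(
                f"{self.species_name}: water must be nonnegative and energy positive"
            )
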