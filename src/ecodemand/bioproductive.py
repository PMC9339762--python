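"""Bioproductive land area: the energy-budget side of the assessment.

How much land must be producing plant matter to feed the herbivory within a
surveyed population?  The budget takes the plant-derived share of the
population's field-metabolic energy demand (all herbivore energy plus a
configurable plant fraction of omnivore energy), inflates it by assimilation
(in)efficiency to a gross intake, and divides by the suitable energy flux of
the land:

    L_BP = E_population,BP / (C_p · η · NPP · s)

with C_p the calorific value of plant matter (kJ kg⁻¹), η the assimilation
efficiency (kJ kJ⁻¹), NPP the above-ground net primary productivity as a
mass flux (kg km⁻² day⁻¹) and s the fraction of NPP suitable and accessible
for herbivory.  A companion check compares active-drinking water demand plus
socioeconomic abstraction against the throughput of a river crossing the
site (width × velocity, per metre of depth) — a screening number only;
proper water accounting belongs at catchment scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import FrozenSet, Optional

from .catalogue import BiologicalClass, TrophicLevel
from .errors import ValidationError
from .survey import DemandSummary

SUPPORTED = "supported"
NOT_SUPPORTED = "not_supported"
SUFFICIENT = "sufficient"
INSUFFICIENT = "insufficient"

CATCHMENT_NOTE = (
    "river throughput is a screening comparison at the site boundary; "
    "combined socioeconomic and ecosystem water use should be analysed at "
    "the catchment-system level"
)


def round_half_away(value: float, ndigits: int = 0) -> float:
    """Round half away from zero (reporting convention for published tables)."""
    factor = 10.0 ** ndigits
    return math.copysign(math.floor(abs(value) * factor + 0.5) / factor, value)


@dataclass(frozen=True)
class BioproductiveParams:
    """Site parameters of the bioproductive-land budget.

    Defaults for ``omnivore_plant_fraction`` and ``included_classes`` follow
    the demonstration assessment: omnivores take 75% of their energy from
    plants, and mammals plus birds drive the budget (reptile and insect
    energy totals are comparatively negligible and their diet composition
    unresolved).
    """

    calorific_value_cp: float  # C_p, kJ kg⁻¹ plant matter
    assimilation_efficiency_eta: float  # η, kJ kJ⁻¹, in (0, 1]
    npp_kg_per_km2_day: float  # above-ground NPP mass flux
    suitability_s: float  # fraction of NPP suitable/accessible, in (0, 1]
    omnivore_plant_fraction: float = 0.75  # share of omnivore energy from plants
    included_classes: FrozenSet[BiologicalClass] = field(
        default_factory=lambda: frozenset(
            {BiologicalClass.MAMMAL, BiologicalClass.BIRD})
    )

    def __post_init__(self):
        if not self.calorific_value_cp > 0:
            raise ValidationError("calorific value C_p must be positive")
        if not 0 < self.assimilation_efficiency_eta <= 1:
            raise ValidationError("assimilation efficiency must be in (0, 1]")
        if not self.npp_kg_per_km2_day > 0:
            raise ValidationError("NPP must be positive")
        if not 0 < self.suitability_s <= 1:
            raise ValidationError("suitability coefficient must be in (0, 1]")
        if not 0 <= self.omnivore_plant_fraction <= 1:
            raise ValidationError("omnivore plant fraction must be in [0, 1]")
        object.__setattr__(
            self, "included_classes",
            frozenset(BiologicalClass.parse(c) for c in self.included_classes),
        )

    @property
    def npp_energy_flux(self) -> float:
        """NPP × C_p: energy flux of plant production (kJ km⁻² day⁻¹)."""
        return self.npp_kg_per_km2_day * self.calorific_value_cp

    @property
    def suitable_npp_mass_flux(self) -> float:
        """NPP × s: suitability-adjusted plant mass flux (kg km⁻² day⁻¹)."""
        return self.npp_kg_per_km2_day * self.suitability_s


#: Parameter preset of the National Capital Laboratory demonstration site
#: (temperate broadleaf woodland averages; 10% NPP suitability; 75:25
#: omnivore plant:meat split; mammal+bird energy drives the budget).
NCL_PRESET = BioproductiveParams(
    calorific_value_cp=18_812.0,
    assimilation_efficiency_eta=0.475,
    npp_kg_per_km2_day=918.0,
    suitability_s=0.1,
    omnivore_plant_fraction=0.75,
)

PRESETS = {"ncl": NCL_PRESET}


def herbivory_energy_demand(summary: DemandSummary,
                            params: BioproductiveParams) -> float:
    """Plant-derived population energy demand E_population,BP (kJ day⁻¹).

    Sums, over the included classes, 100% of herbivore energy plus
    ``omnivore_plant_fraction`` of omnivore energy; carnivores contribute
    nothing (their needs are met through predation, modelled elsewhere or
    beyond the site boundary).
    """
    total = 0.0
    for key in sorted(summary.cells, key=lambda k: (k[0].value, k[1].value)):
        taxon_class, trophic = key
        if taxon_class not in params.included_classes:
            continue
        energy = summary.cells[key].energy_kj_per_day
        if trophic is TrophicLevel.HERBIVORE:
            total += energy
        elif trophic is TrophicLevel.OMNIVORE:
            total += params.omnivore_plant_fraction * energy
    return total


def consumption_requirement(e_population_bp: float, eta: float) -> float:
    """Gross intake needed to assimilate ``e_population_bp`` (kJ day⁻¹)."""
    if e_population_bp < 0:
        raise ValidationError("population energy demand must be nonnegative")
    if not 0 < eta <= 1:
        raise ValidationError(f"assimilation efficiency must be in (0, 1], got {eta}")
    return e_population_bp / eta


def bioproductive_land_area(e_population_bp: float,
                            params: BioproductiveParams) -> float:
    """L_BP = E_population,BP / (C_p · η · NPP · s), in km²."""
    if e_population_bp < 0:
        raise ValidationError("population energy demand must be nonnegative")
    denominator = (params.calorific_value_cp
                   * params.assimilation_efficiency_eta
                   * params.npp_kg_per_km2_day
                   * params.suitability_s)
    if not denominator > 0:
        raise ValidationError("bioproductive denominator must be positive")
    return e_population_bp / denominator


@dataclass(frozen=True)
class BioproductiveReport:
    """Eq.-chain outputs plus the intermediate fluxes used to derive them."""

    e_population_bp: float  # plant-derived demand, kJ population⁻¹ day⁻¹
    gross_intake: float  # demand / η, kJ population⁻¹ day⁻¹
    l_bp_km2: float  # bioproductive land area
    site_fraction: float  # l_bp / terrestrial site area
    site_percent: int  # nearest-integer percent (reporting convention)
    verdict: str  # SUPPORTED if the site suffices
    npp_energy_flux: float  # NPP × C_p, kJ km⁻² day⁻¹
    suitable_npp_mass_flux: float  # NPP × s, kg km⁻² day⁻¹


def herbivory_sufficiency(l_bp_km2: float,
                          terrestrial_area_km2: float) -> tuple:
    """(fraction of site, nearest-integer percent, verdict)."""
    if not terrestrial_area_km2 > 0:
        raise ValidationError("terrestrial area must be positive")
    if l_bp_km2 < 0:
        raise ValidationError("bioproductive land area must be nonnegative")
    fraction = l_bp_km2 / terrestrial_area_km2
    percent = int(round_half_away(100.0 * fraction))
    verdict = SUPPORTED if fraction <= 1.0 else NOT_SUPPORTED
    return fraction, percent, verdict


def assess_bioproductive(e_population_bp: float, params: BioproductiveParams,
                         terrestrial_area_km2: float) -> BioproductiveReport:
    """Run the full Eq.-chain for a given plant-derived energy demand."""
    gross = consumption_requirement(e_population_bp,
                                    params.assimilation_efficiency_eta)
    l_bp = bioproductive_land_area(e_population_bp, params)
    fraction, percent, verdict = herbivory_sufficiency(l_bp, terrestrial_area_km2)
    return BioproductiveReport(
        e_population_bp=e_population_bp,
        gross_intake=gross,
        l_bp_km2=l_bp,
        site_fraction=fraction,
        site_percent=percent,
        verdict=verdict,
        npp_energy_flux=params.npp_energy_flux,
        suitable_npp_mass_flux=params.suitable_npp_mass_flux,
    )


@dataclass(frozen=True)
class WaterSufficiencyReport:
    """On-site water demand vs river throughput (per metre of depth)."""

    ecosystem_demand_m3_day: float
    abstraction_m3_day: float
    total_demand_m3_day: float
    throughput_m3_per_m_depth_day: float  # width × velocity
    verdict: str  # SUFFICIENT if throughput covers total demand
    note: str = CATCHMENT_NOTE


def water_sufficiency(ecosystem_water_m3_day: float,
                      abstraction_m3_day: float,
                      river_width_m: float,
                      river_velocity_m_day: float) -> WaterSufficiencyReport:
    """Compare combined on-site water demand with river throughput.

    Throughput is width × velocity, i.e. the freshwater volume traversing
    the site per day per metre of river depth.
    """
    if ecosystem_water_m3_day < 0 or abstraction_m3_day < 0:
        raise ValidationError("water demands must be nonnegative")
    if not river_width_m > 0 or not river_velocity_m_day > 0:
        raise ValidationError("river width and velocity must be positive")
    total = ecosystem_water_m3_day + abstraction_m3_day
    throughput = river_width_m * river_velocity_m_day
    return WaterSufficiencyReport(
        ecosystem_demand_m3_day=ecosystem_water_m3_day,
        abstraction_m3_day=abstraction_m3_day,
        total_demand_m3_day=total,
        throughput_m3_per_m_depth_day=throughput,
        verdict=SUFFICIENT if total <= throughput else INSUFFICIENT,
    )
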