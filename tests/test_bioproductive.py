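"""Bioproductive land-area budget and the site worked example."""

import dataclasses

import pytest
from hypothesis import given
from hypothesis import strategies as st

from ecodemand import (
    NCL_PRESET,
    BioproductiveParams,
    BiologicalClass,
    TrophicLevel,
    ValidationError,
    assess_bioproductive,
    bioproductive_land_area,
    consumption_requirement,
    herbivory_energy_demand,
    herbivory_sufficiency,
    water_sufficiency,
)
from ecodemand.bioproductive import (
    NOT_SUPPORTED,
    SUFFICIENT,
    SUPPORTED,
    round_half_away,
)
from ecodemand.catalogue import WATER_ASSUMED_ZERO, WATER_MODELLED
from ecodemand.survey import DemandRow, DemandSummary

M, B, R, I = (BiologicalClass.MAMMAL, BiologicalClass.BIRD,
              BiologicalClass.REPTILE, BiologicalClass.INSECT)
HERB, OMNI, CARN, ALL = (TrophicLevel.HERBIVORE, TrophicLevel.OMNIVORE,
                         TrophicLevel.CARNIVORE, TrophicLevel.ALL)


def _row(n, energy, water=0.0, provenance=WATER_ASSUMED_ZERO):
    return DemandRow(n_individuals=n, land_sum_km2=0.1,
                     land_max_individual_km2=0.1, energy_kj_per_day=energy,
                     water_m3_per_day=water, water_provenance=provenance)


@pytest.fixture()
def published_site_summary():
    """Class x trophic energy cells exactly as published for the surveyed
    site (built directly; the per-species list is not redistributable)."""
    cells = {
        (M, CARN): _row(1, 989.0, 0.003, WATER_MODELLED),
        (M, OMNI): _row(3, 2713.0, 0.002, WATER_MODELLED),
        (M, HERB): _row(5, 17501.0, 0.005, WATER_MODELLED),
        (B, CARN): _row(56, 8214.0, 0.001, WATER_MODELLED),
        (B, OMNI): _row(66, 5249.0, 0.001, WATER_MODELLED),
        (B, HERB): _row(7, 551.0, 0.0001, WATER_MODELLED),
        (R, ALL): _row(2, 4.0),
        (I, ALL): _row(52, 1035.0),
    }
    return DemandSummary.from_cells(cells)


def test_herbivory_energy_demand_from_published_cells(published_site_summary):
    """100% of herbivore + 75% of omnivore energy over mammals and birds:
    (17501 + 551) + 0.75 x (2713 + 5249) = 24023.5 kJ/day."""
    demand = herbivory_energy_demand(published_site_summary, NCL_PRESET)
    assert demand == pytest.approx(18052.0 + 0.75 * 7962.0, rel=1e-12)


def test_herbivory_energy_demand_fraction_zero(published_site_summary):
    params = dataclasses.replace(NCL_PRESET, omnivore_plant_fraction=0.0)
    assert herbivory_energy_demand(published_site_summary, params) == (
        pytest.approx(18052.0, rel=1e-12))


def test_all_carnivore_summary_demands_nothing():
    cells = {(M, CARN): _row(3, 5000.0), (B, CARN): _row(7, 3000.0)}
    summary = DemandSummary.from_cells(cells)
    assert herbivory_energy_demand(summary, NCL_PRESET) == 0.0


def test_included_classes_controls_the_sum(published_site_summary):
    mammals_only = dataclasses.replace(NCL_PRESET,
                                       included_classes=frozenset({M}))
    assert herbivory_energy_demand(published_site_summary, mammals_only) == (
        pytest.approx(17501.0 + 0.75 * 2713.0, rel=1e-12))


def test_consumption_requirement_worked_value():
    """27,051 kJ/day at eta = 0.475 must actually be 5.69e4 kJ/day consumed."""
    gross = consumption_requirement(27051.0, 0.475)
    assert gross == pytest.approx(56949.5, abs=0.1)
    assert consumption_requirement(123.0, 1.0) == 123.0
    assert consumption_requirement(0.0, 0.475) == 0.0
    with pytest.raises(ValidationError):
        consumption_requirement(1.0, 0.0)


def test_bioproductive_land_area_worked_value():
    assert bioproductive_land_area(27051.0, NCL_PRESET) == (
        pytest.approx(0.033, abs=5e-4))
    assert bioproductive_land_area(0.0, NCL_PRESET) == 0.0
    halved_s = dataclasses.replace(NCL_PRESET, suitability_s=0.05)
    assert bioproductive_land_area(27051.0, halved_s) == pytest.approx(
        2 * bioproductive_land_area(27051.0, NCL_PRESET), rel=1e-12)


def test_site_intermediate_fluxes():
    """NPP x C_p = 1.73e7 kJ/km^2/day and NPP x s = 91.8 kg/km^2/day."""
    assert NCL_PRESET.npp_energy_flux == pytest.approx(1.73e7, rel=2e-3)
    assert NCL_PRESET.suitable_npp_mass_flux == pytest.approx(91.8, rel=1e-12)


def test_full_chain_report_consistency():
    report = assess_bioproductive(27051.0, NCL_PRESET, 0.403)
    assert report.gross_intake == pytest.approx(5.69e4, rel=1e-3)
    assert report.l_bp_km2 == pytest.approx(0.033, abs=5e-4)
    assert report.site_percent == 8
    assert report.verdict == SUPPORTED
    # dimensional consistency: L_BP x (C_p eta NPP s) recovers the demand
    denom = (NCL_PRESET.calorific_value_cp
             * NCL_PRESET.assimilation_efficiency_eta
             * NCL_PRESET.npp_kg_per_km2_day * NCL_PRESET.suitability_s)
    assert report.l_bp_km2 * denom == pytest.approx(
        report.e_population_bp, rel=1e-12)
    assert report.l_bp_km2 * report.npp_energy_flux * \
        NCL_PRESET.suitability_s * NCL_PRESET.assimilation_efficiency_eta \
        == pytest.approx(report.e_population_bp, rel=1e-12)


def test_herbivory_sufficiency_verdicts():
    fraction, percent, verdict = herbivory_sufficiency(0.033, 0.403)
    assert percent == 8 and verdict == SUPPORTED
    fraction, percent, verdict = herbivory_sufficiency(0.403, 0.403)
    assert fraction == 1.0 and percent == 100 and verdict == SUPPORTED
    fraction, percent, verdict = herbivory_sufficiency(0.5, 0.403)
    assert percent == 124 and verdict == NOT_SUPPORTED
    with pytest.raises(ValidationError):
        herbivory_sufficiency(0.1, 0.0)


positive = st.floats(min_value=1e-6, max_value=1e6,
                     allow_nan=False, allow_infinity=False)
fractions = st.floats(min_value=1e-6, max_value=1.0,
                      allow_nan=False, allow_infinity=False)


@given(e=positive, cp=positive, eta=fractions, npp=positive, s=fractions,
       k=st.floats(min_value=0.1, max_value=10.0))
def test_land_area_homogeneity(e, cp, eta, npp, s, k):
    """L_BP is degree 1 in the energy demand and degree -1 in each
    denominator factor."""
    params = BioproductiveParams(calorific_value_cp=cp,
                                 assimilation_efficiency_eta=eta,
                                 npp_kg_per_km2_day=npp, suitability_s=s)
    base = bioproductive_land_area(e, params)
    assert bioproductive_land_area(k * e, params) == pytest.approx(
        k * base, rel=1e-9)
    scaled_cp = dataclasses.replace(params, calorific_value_cp=k * cp)
    assert bioproductive_land_area(e, scaled_cp) == pytest.approx(
        base / k, rel=1e-9)
    if k * eta <= 1.0:
        scaled_eta = dataclasses.replace(params,
                                         assimilation_efficiency_eta=k * eta)
        assert bioproductive_land_area(e, scaled_eta) == pytest.approx(
            base / k, rel=1e-9)
    scaled_npp = dataclasses.replace(params, npp_kg_per_km2_day=k * npp)
    assert bioproductive_land_area(e, scaled_npp) == pytest.approx(
        base / k, rel=1e-9)


def test_water_sufficiency_worked_value():
    """0.01 ecosystem + 0.04 abstraction vs a 15 m river at 2160 m/day:
    demand 0.05 m^3/day against 32,400 m^3 per metre of depth per day."""
    report = water_sufficiency(0.01, 0.04, 15.0, 2160.0)
    assert report.total_demand_m3_day == pytest.approx(0.05, rel=1e-12)
    assert report.throughput_m3_per_m_depth_day == pytest.approx(32400.0)
    assert report.verdict == SUFFICIENT
    assert "catchment" in report.note
    zero = water_sufficiency(0.0, 0.0, 15.0, 2160.0)
    assert zero.total_demand_m3_day == 0.0 and zero.verdict == SUFFICIENT
    with pytest.raises(ValidationError):
        water_sufficiency(0.01, 0.04, 0.0, 2160.0)


def test_params_validation():
    with pytest.raises(ValidationError):
        BioproductiveParams(18812.0, 1.5, 918.0, 0.1)
    with pytest.raises(ValidationError):
        BioproductiveParams(18812.0, 0.475, -1.0, 0.1)
    with pytest.raises(ValidationError):
        BioproductiveParams(18812.0, 0.475, 918.0, 0.1,
                            omnivore_plant_fraction=1.5)


def test_round_half_away_reporting_convention():
    assert round_half_away(0.125, 2) == 0.13
    assert round_half_away(-0.125, 2) == -0.13
    assert round_half_away(8.5) == 9.0
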