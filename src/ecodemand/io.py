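"""File formats, assessment reports, and the workflow entry points.

All interchange is comma-separated UTF-8 text with a header row and "." as
the decimal separator; units are fixed by the schema (kg, km², m³ day⁻¹,
kJ day⁻¹, NPP as kg km⁻² day⁻¹).  Readers validate strictly and report
malformed rows with line numbers.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import pandas as pd

from ._version import __version__ as _pkg_version
from .bioproductive import (
    BioproductiveParams,
    BioproductiveReport,
    WaterSufficiencyReport,
    assess_bioproductive,
    herbivory_energy_demand,
    water_sufficiency,
)
from .catalogue import (
    BiologicalClass,
    CoefficientCatalogue,
    TrophicLevel,
    published_default,
)
from .errors import SurveyFormatError, ValidationError
from .regression import (
    DensityObservation,
    FitResult,
    confidence_band,
    fit_loglog,
    to_standard_form,
)
from .survey import (
    ConstraintReport,
    DemandSummary,
    Observation,
    SpeciesRecord,
    Survey,
    aggregate_survey,
    land_constraint_check,
)

logger = logging.getLogger("ecodemand")

SURVEY_COLUMNS = ["species_name", "taxon_class", "trophic", "count", "body_mass_kg"]
DENSITY_COLUMNS = ["species_name", "taxon_class", "trophic", "mass_kg",
                   "density_per_km2", "source"]

#: Sanity range for body masses (kg); breaches are errors in strict mode,
#: logged warnings otherwise.  The upper bound exceeds any terrestrial animal.
MASS_SANITY_RANGE_KG = (1e-9, 1e4)


def read_survey(path, terrestrial_area_km2: float,
                site_name: Optional[str] = None,
                strict: bool = True) -> Survey:
    """Read a survey CSV (one row per species) into a validated Survey."""
    path = Path(path)
    if not path.exists():
        raise SurveyFormatError(f"survey file not found: {path}")
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in SURVEY_COLUMNS if c not in frame.columns]
    if missing:
        raise SurveyFormatError(f"{path}: missing columns {missing}")

    observations: List[Observation] = []
    row_errors: List[str] = []
    for idx, row in frame.iterrows():
        line = idx + 2  # header is line 1
        try:
            mass = float(row["body_mass_kg"])
            count = int(row["count"])
            lo, hi = MASS_SANITY_RANGE_KG
            if not lo <= mass <= hi:
                msg = (f"line {line}: body mass {mass} kg outside sanity "
                       f"range {MASS_SANITY_RANGE_KG}")
                if strict:
                    raise ValidationError(msg)
                logger.warning(msg)
            record = SpeciesRecord(
                name=str(row["species_name"]).strip(),
                taxon_class=row["taxon_class"],
                trophic=row["trophic"],
                mass_kg=mass,
            )
            observations.append(Observation(species=record, count=count))
        except (ValueError, ValidationError) as exc:
            message = str(exc)
            if not message.startswith("line "):
                message = f"line {line}: {message}"
            row_errors.append(message)
            logger.warning("skipping survey row: %s", message)
    if row_errors:
        raise SurveyFormatError(f"{path}: {len(row_errors)} malformed row(s)",
                                row_errors)
    if not observations:
        raise SurveyFormatError(f"{path}: no observations")
    return Survey(site_name=site_name or path.stem,
                  terrestrial_area_km2=terrestrial_area_km2,
                  observations=tuple(observations))


def write_survey(survey: Survey, path) -> None:
    rows = [{
        "species_name": o.species.name,
        "taxon_class": o.species.taxon_class.value,
        "trophic": o.species.trophic.value,
        "count": o.count,
        "body_mass_kg": o.species.mass_kg,
    } for o in survey.observations]
    pd.DataFrame(rows, columns=SURVEY_COLUMNS).to_csv(path, index=False)


def read_density_table(path) -> Tuple[List[DensityObservation], int]:
    """Read a mass–density compilation; rows failing positivity or parsing
    are logged and skipped.  Returns (observations, n_skipped)."""
    path = Path(path)
    if not path.exists():
        raise SurveyFormatError(f"density file not found: {path}")
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = DENSITY_COLUMNS[:5]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SurveyFormatError(f"{path}: missing columns {missing}")
    observations: List[DensityObservation] = []
    skipped = 0
    for idx, row in frame.iterrows():
        line = idx + 2
        try:
            observations.append(DensityObservation(
                species_name=str(row["species_name"]).strip(),
                taxon_class=row["taxon_class"],
                trophic=row["trophic"],
                mass_kg=float(row["mass_kg"]),
                density_per_km2=float(row["density_per_km2"]),
                source_label=str(row.get("source", "")),
            ))
        except (ValueError, ValidationError) as exc:
            skipped += 1
            logger.warning("skipping density row at line %d: %s", line, exc)
    if not observations:
        raise SurveyFormatError(f"{path}: no valid observations "
                                f"({skipped} rows skipped)")
    if skipped:
        logger.info("%s: skipped %d invalid row(s)", path, skipped)
    return observations, skipped


def write_density_table(observations, path) -> None:
    rows = [{
        "species_name": o.species_name,
        "taxon_class": o.taxon_class.value,
        "trophic": o.trophic.value,
        "mass_kg": o.mass_kg,
        "density_per_km2": o.density_per_km2,
        "source": o.source_label,
    } for o in observations]
    pd.DataFrame(rows, columns=DENSITY_COLUMNS).to_csv(path, index=False)


def load_params_config(path) -> dict:
    """Read bioproductive parameters from JSON or flat key=value text."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    try:
        payload = json.loads(text)
        if not isinstance(payload, dict):
            raise ValidationError(f"{path}: config must be a JSON object")
        return payload
    except json.JSONDecodeError:
        payload = {}
        for lineno, line in enumerate(text.splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValidationError(f"{path} line {lineno}: expected key=value")
            key, _, value = line.partition("=")
            payload[key.strip()] = value.strip()
        return payload


# -- assessment report ------------------------------------------------------

@dataclass(frozen=True)
class AssessmentReport:
    """Everything the site assessment computed, plus provenance."""

    survey: Survey
    summary: DemandSummary
    constraint: ConstraintReport
    bioproductive: BioproductiveReport
    params: BioproductiveParams
    water: Optional[WaterSufficiencyReport]
    provenance: Dict[str, object]

    def to_json_dict(self, include_timestamp: bool = True) -> dict:
        provenance = dict(self.provenance)
        if not include_timestamp:
            provenance.pop("created_utc", None)
        summary_records = self.summary.to_frame().to_dict(orient="records")
        payload = {
            "site": {
                "name": self.survey.site_name,
                "terrestrial_area_km2": self.survey.terrestrial_area_km2,
                "n_species": self.survey.n_species,
                "n_individuals": self.survey.n_individuals,
            },
            "demand_summary": summary_records,
            "per_species": [{
                "species_name": item.species.name,
                "taxon_class": item.species.taxon_class.value,
                "trophic": item.species.trophic.value,
                "count": item.count,
                "body_mass_kg": item.species.mass_kg,
                "land_area_km2": item.individual.land_area_km2,
                "population_density_per_km2":
                    item.individual.population_density_per_km2,
                "energy_kj_per_day": item.individual.energy_kj_per_day,
                "water_m3_per_day": item.individual.water_m3_per_day,
                "water_provenance": item.individual.water_provenance,
            } for item in self.summary.per_species],
            "land_constraint": {
                "terrestrial_area_km2": self.constraint.terrestrial_area_km2,
                "n_exceeding": self.constraint.n_exceeding,
                "largest": [dataclasses.asdict(v) for v in self.constraint.largest],
                "verdicts": [dataclasses.asdict(v) for v in self.constraint.verdicts],
            },
            "bioproductive": dataclasses.asdict(self.bioproductive),
            "bioproductive_params": {
                "calorific_value_cp": self.params.calorific_value_cp,
                "assimilation_efficiency_eta":
                    self.params.assimilation_efficiency_eta,
                "npp_kg_per_km2_day": self.params.npp_kg_per_km2_day,
                "suitability_s": self.params.suitability_s,
                "omnivore_plant_fraction": self.params.omnivore_plant_fraction,
                "included_classes": sorted(
                    c.value for c in self.params.included_classes),
            },
            "water_sufficiency": (dataclasses.asdict(self.water)
                                  if self.water is not None else None),
            "provenance": provenance,
        }
        return payload

    def canonical_json(self) -> str:
        """Deterministic serialization (timestamp excluded) for comparisons."""
        return json.dumps(self.to_json_dict(include_timestamp=False),
                          sort_keys=True, indent=2)

    def to_text(self) -> str:
        """Human-readable table view of the report."""
        lines = [
            f"Site: {self.survey.site_name} "
            f"(terrestrial area {self.survey.terrestrial_area_km2} km², "
            f"{self.survey.n_species} species, "
            f"{self.survey.n_individuals} individuals)",
            "",
            "Demand summary (land sums are the naive population-table "
            "convention; land max is the per-individual constraint):",
            self.summary.to_frame().to_string(index=False),
            "",
            "Land-area constraint: "
            f"{self.constraint.n_exceeding} species exceed the site area; "
            "largest: " + ", ".join(
                f"{v.species_name} ({v.land_area_km2:.3g} km², {v.verdict})"
                for v in self.constraint.largest),
            "",
            "Bioproductive land area: "
            f"E_population,BP = {self.bioproductive.e_population_bp:.6g} kJ/day; "
            f"gross intake = {self.bioproductive.gross_intake:.6g} kJ/day; "
            f"L_BP = {self.bioproductive.l_bp_km2:.6g} km² "
            f"({self.bioproductive.site_percent}% of site, "
            f"{self.bioproductive.verdict})",
            f"  NPP energy flux = {self.bioproductive.npp_energy_flux:.6g} "
            "kJ/km²/day; suitable NPP = "
            f"{self.bioproductive.suitable_npp_mass_flux:.6g} kg/km²/day",
        ]
        if self.water is not None:
            lines += [
                "",
                "Water: total on-site demand "
                f"{self.water.total_demand_m3_day:.6g} m³/day vs river "
                f"throughput {self.water.throughput_m3_per_m_depth_day:.6g} "
                f"m³ per m depth per day ({self.water.verdict}); "
                f"{self.water.note}",
            ]
        return "\n".join(lines) + "\n"


def run_assess(
    survey: Survey,
    params: BioproductiveParams,
    catalogue: Optional[CoefficientCatalogue] = None,
    e_population_bp: Optional[float] = None,
    abstraction_m3_day: Optional[float] = None,
    river_width_m: Optional[float] = None,
    river_velocity_m_day: Optional[float] = None,
    input_digest: Optional[str] = None,
) -> AssessmentReport:
    """Aggregate → constraint check → bioproductive budget → water check.

    ``e_population_bp`` overrides the formula path with an externally
    supplied plant-derived energy demand (e.g. one computed from species-
    level diet data); by default it is derived from the summary.
    """
    catalogue = catalogue or published_default()
    summary = aggregate_survey(survey, catalogue)
    constraint = land_constraint_check(summary, survey)
    e_bp_source = "override"
    if e_population_bp is None:
        e_population_bp = herbivory_energy_demand(summary, params)
        e_bp_source = "formula"
    bio = assess_bioproductive(e_population_bp, params,
                               survey.terrestrial_area_km2)
    water = None
    if river_width_m is not None and river_velocity_m_day is not None:
        water = water_sufficiency(
            summary.grand_total.water_m3_per_day,
            abstraction_m3_day or 0.0,
            river_width_m,
            river_velocity_m_day,
        )
    provenance = {
        "package_version": _pkg_version,
        "catalogue_version": catalogue.version,
        "input_digest": input_digest,
        "e_population_bp_source": e_bp_source,
        "created_utc": datetime.now(timezone.utc).isoformat(),
    }
    return AssessmentReport(survey=survey, summary=summary,
                            constraint=constraint, bioproductive=bio,
                            params=params, water=water, provenance=provenance)


def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_report(report: AssessmentReport, out_dir) -> Tuple[Path, Path]:
    """Write report.json and report.txt; returns the two paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    json_path = out_dir / "report.json"
    text_path = out_dir / "report.txt"
    json_path.write_text(
        json.dumps(report.to_json_dict(), sort_keys=True, indent=2) + "\n",
        encoding="utf-8")
    text_path.write_text(report.to_text(), encoding="utf-8")
    return json_path, text_path


def run_fit(observations, grouping: str = "default",
            band_level: Optional[float] = None,
            band_points: int = 50):
    """Fit all groups; return (models_frame, failures, band_frame | None).

    ``models_frame`` uses the catalogue serialization schema so fitted
    coefficients are immediately loadable for assessment.
    """
    fits, failures = fit_loglog(observations, grouping=grouping)
    if not fits:
        raise ValidationError(
            "all groups failed to fit: " + "; ".join(failures.values()))
    models = [to_standard_form(fit) for fit in fits.values()]
    models_frame = CoefficientCatalogue(models, version="fitted").to_frame()

    band_frame = None
    if band_level is not None:
        import numpy as np
        rows = []
        for fit in fits.values():
            obs_masses = [o.mass_kg for o in observations
                          if (o.taxon_class, o.trophic) == fit.group
                          or fit.trophic is TrophicLevel.ALL
                          and o.taxon_class is fit.taxon_class]
            grid = np.logspace(np.log10(min(obs_masses)),
                               np.log10(max(obs_masses)), band_points)
            band = confidence_band(fit, grid, level=band_level)
            for mass, (lo, hi) in zip(grid, band):
                rows.append({
                    "taxon_class": fit.taxon_class.value,
                    "trophic": fit.trophic.value,
                    "mass_kg": mass,
                    "log10_density_lower": lo,
                    "log10_density_upper": hi,
                })
        band_frame = pd.DataFrame(rows)
    return models_frame, failures, band_frame
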