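"""Site-survey aggregation into class×trophic demand summaries.

A survey is a list of species with individual counts for one site.  Energy
and water scale linearly with counts, so their rows are count-weighted sums
of per-individual values.  Land area is different: summing per-individual
land areas across species ignores interspecific sharing, so the summary
reports BOTH the naive count-weighted sum (the convention of published
population-level tables) and the per-individual maximum — the constraint
quantity, since each species' resources must lie within its own land-area
range.  The constraint check compares each species' land area against the
site's terrestrial area.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .catalogue import (
    WATER_ASSUMED_ZERO,
    WATER_MODELLED,
    BiologicalClass,
    CoefficientCatalogue,
    TrophicLevel,
)
from .engine import IndividualDemand, energy_use, land_area_use, water_use
from .errors import EcodemandError, ValidationError

CellKey = Tuple[BiologicalClass, TrophicLevel]

WITHIN_SITE = "within_site"
EXCEEDS_SITE = "exceeds_site"


@dataclass(frozen=True)
class SpeciesRecord:
    """One species: identity, class, trophic level, adult body mass."""

    name: str
    taxon_class: BiologicalClass
    trophic: TrophicLevel
    mass_kg: float

    def __post_init__(self):
        if not str(self.name).strip():
            raise ValidationError("species name must be nonempty")
        object.__setattr__(self, "taxon_class", BiologicalClass.parse(self.taxon_class))
        object.__setattr__(self, "trophic", TrophicLevel.parse(self.trophic))
        if self.trophic is TrophicLevel.ALL:
            raise ValidationError(
                f"{self.name}: species records need a concrete trophic level, not 'all'"
            )
        if not self.mass_kg > 0:
            raise ValidationError(
                f"{self.name}: body mass must be positive, got {self.mass_kg}"
            )


@dataclass(frozen=True)
class Observation:
    """A species observed at a site with its individual count."""

    species: SpeciesRecord
    count: int

    def __post_init__(self):
        if not (isinstance(self.count, int) and self.count >= 1):
            raise ValidationError(
                f"{self.species.name}: count must be a positive integer, "
                f"got {self.count!r}"
            )


@dataclass(frozen=True)
class Survey:
    site_name: str
    terrestrial_area_km2: float
    observations: Tuple[Observation, ...]

    def __post_init__(self):
        object.__setattr__(self, "observations", tuple(self.observations))
        if not self.terrestrial_area_km2 > 0:
            raise ValidationError("terrestrial area must be positive")
        names = [o.species.name for o in self.observations]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValidationError(f"duplicate species in survey: {sorted(dupes)}")

    @property
    def n_species(self) -> int:
        return len(self.observations)

    @property
    def n_individuals(self) -> int:
        return sum(o.count for o in self.observations)


def individual_demand(species: SpeciesRecord,
                      catalogue: CoefficientCatalogue) -> IndividualDemand:
    """Evaluate all three resources once for one species."""
    try:
        land = land_area_use(species.mass_kg, species.taxon_class,
                             species.trophic, catalogue)
        water = water_use(species.mass_kg, species.taxon_class, catalogue)
        energy = energy_use(species.mass_kg, species.taxon_class,
                            species.trophic, catalogue)
    except EcodemandError as exc:
        raise type(exc)(f"{species.name}: {exc}") from exc
    return IndividualDemand(
        species_name=species.name,
        land_area_km2=land,
        population_density_per_km2=1.0 / land,
        water_m3_per_day=water.m3_per_day,
        water_provenance=water.provenance,
        energy_kj_per_day=energy,
    )


@dataclass(frozen=True)
class SpeciesDemand:
    """Per-species line item: record, count, and per-individual demand."""

    species: SpeciesRecord
    count: int
    individual: IndividualDemand

    @property
    def land_sum_km2(self) -> float:
        return self.count * self.individual.land_area_km2

    @property
    def energy_kj_per_day(self) -> float:
        return self.count * self.individual.energy_kj_per_day

    @property
    def water_m3_per_day(self) -> float:
        return self.count * self.individual.water_m3_per_day


@dataclass(frozen=True)
class DemandRow:
    """One class×trophic (or total) row of the demand summary."""

    n_individuals: int
    land_sum_km2: float
    land_max_individual_km2: float
    energy_kj_per_day: float
    water_m3_per_day: float
    water_provenance: str  # modelled if any member species is modelled

    @staticmethod
    def combine(rows: Sequence["DemandRow"]) -> "DemandRow":
        rows = list(rows)
        return DemandRow(
            n_individuals=sum(r.n_individuals for r in rows),
            land_sum_km2=sum(r.land_sum_km2 for r in rows),
            land_max_individual_km2=max(r.land_max_individual_km2 for r in rows),
            energy_kj_per_day=sum(r.energy_kj_per_day for r in rows),
            water_m3_per_day=sum(r.water_m3_per_day for r in rows),
            water_provenance=(
                WATER_MODELLED
                if any(r.water_provenance == WATER_MODELLED for r in rows)
                else WATER_ASSUMED_ZERO
            ),
        )


@dataclass(frozen=True)
class DemandSummary:
    """Class×trophic demand table with per-class and grand totals.

    ``land_sum_km2`` is the naive count-weighted sum (population-table
    convention); ``land_max_individual_km2`` is the largest per-individual
    land area in the group — the constraint quantity.
    """

    cells: Dict[CellKey, DemandRow]
    class_totals: Dict[BiologicalClass, DemandRow]
    grand_total: DemandRow
    per_species: Tuple[SpeciesDemand, ...] = field(default_factory=tuple)

    @classmethod
    def from_cells(cls, cells: Dict[CellKey, DemandRow],
                   per_species: Sequence[SpeciesDemand] = ()) -> "DemandSummary":
        """Build totals from cells with a fixed accumulation order (sorted
        by class then trophic label) so identical inputs sum identically."""
        ordered = sorted(cells, key=lambda k: (k[0].value, k[1].value))
        class_totals: Dict[BiologicalClass, DemandRow] = {}
        for taxon_class in BiologicalClass:
            members = [cells[k] for k in ordered if k[0] is taxon_class]
            if members:
                class_totals[taxon_class] = DemandRow.combine(members)
        grand = DemandRow.combine(list(class_totals.values()))
        return cls(cells=dict(cells), class_totals=class_totals,
                   grand_total=grand, per_species=tuple(per_species))

    def to_frame(self) -> pd.DataFrame:
        """Long-form table: one row per class×trophic cell, per-class 'all'
        rows, and a grand-total row (published-table layout)."""
        records = []

        def _rec(label_class, label_trophic, row: DemandRow):
            records.append({
                "taxon_class": label_class,
                "trophic": label_trophic,
                "n_individuals": row.n_individuals,
                "land_area_sum_km2": row.land_sum_km2,
                "land_area_max_individual_km2": row.land_max_individual_km2,
                "energy_kj_per_day": row.energy_kj_per_day,
                "water_m3_per_day": row.water_m3_per_day,
                "water_provenance": row.water_provenance,
            })

        for taxon_class in BiologicalClass:
            if taxon_class not in self.class_totals:
                continue
            _rec(taxon_class.value, "all", self.class_totals[taxon_class])
            keys = sorted((k for k in self.cells if k[0] is taxon_class),
                          key=lambda k: k[1].value)
            for key in keys:
                if key[1] is not TrophicLevel.ALL or len(keys) > 1:
                    _rec(taxon_class.value, key[1].value, self.cells[key])
        _rec("total", "all", self.grand_total)
        return pd.DataFrame(records)


def aggregate_survey(survey: Survey,
                     catalogue: CoefficientCatalogue) -> DemandSummary:
    """Evaluate every observed species and roll up the demand table."""
    if not survey.observations:
        raise ValidationError("survey has no observations")
    per_species: List[SpeciesDemand] = []
    for obs in sorted(survey.observations, key=lambda o: o.species.name):
        per_species.append(SpeciesDemand(
            species=obs.species,
            count=obs.count,
            individual=individual_demand(obs.species, catalogue),
        ))

    cells: Dict[CellKey, DemandRow] = {}
    grouped: Dict[CellKey, List[SpeciesDemand]] = {}
    for item in per_species:
        rec = item.species
        key = (rec.taxon_class, rec.trophic)
        if rec.taxon_class in (BiologicalClass.REPTILE, BiologicalClass.INSECT):
            key = (rec.taxon_class, TrophicLevel.ALL)  # pooled-model classes
        grouped.setdefault(key, []).append(item)
    for key, items in grouped.items():
        cells[key] = DemandRow(
            n_individuals=sum(i.count for i in items),
            land_sum_km2=sum(i.land_sum_km2 for i in items),
            land_max_individual_km2=max(i.individual.land_area_km2 for i in items),
            energy_kj_per_day=sum(i.energy_kj_per_day for i in items),
            water_m3_per_day=sum(i.water_m3_per_day for i in items),
            water_provenance=(
                WATER_MODELLED
                if any(i.individual.water_provenance == WATER_MODELLED for i in items)
                else WATER_ASSUMED_ZERO
            ),
        )
    return DemandSummary.from_cells(cells, per_species=per_species)


@dataclass(frozen=True)
class SpeciesVerdict:
    species_name: str
    land_area_km2: float
    verdict: str  # WITHIN_SITE | EXCEEDS_SITE


@dataclass(frozen=True)
class ConstraintReport:
    """Per-species land-area-as-constraint verdicts for one site."""

    terrestrial_area_km2: float
    verdicts: Tuple[SpeciesVerdict, ...]
    largest: Tuple[SpeciesVerdict, ...]  # the two largest land-area species

    @property
    def n_exceeding(self) -> int:
        return sum(v.verdict == EXCEEDS_SITE for v in self.verdicts)


def land_constraint_check(summary: DemandSummary,
                          survey: Survey) -> ConstraintReport:
    """Compare each species' land-area constraint with the site area.

    A species whose per-individual land area exceeds the terrestrial site
    area likely draws on natural capital beyond the site boundary (the whole
    site is accessible to it); the boundary case counts as within-site.
    """
    if not summary.per_species:
        raise ValidationError("summary carries no per-species demands")
    area = survey.terrestrial_area_km2
    verdicts = tuple(
        SpeciesVerdict(
            species_name=item.species.name,
            land_area_km2=item.individual.land_area_km2,
            verdict=(WITHIN_SITE if item.individual.land_area_km2 <= area
                     else EXCEEDS_SITE),
        )
        for item in summary.per_species
    )
    largest = tuple(sorted(verdicts, key=lambda v: -v.land_area_km2)[:2])
    return ConstraintReport(terrestrial_area_km2=area, verdicts=verdicts,
                            largest=largest)
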