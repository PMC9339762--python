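"""Published allometric coefficient sets and model resolution.

The framework quantifies the natural-capital "well-being needs" of individual
terrestrial animals as power laws of adult body mass,

    x_i = a_i * M_i ** b_i,

where ``x_i`` is the per-individual use of one resource — population density
(individuals km⁻², whose reciprocal is land-area use), active-drinking water
(m³ day⁻¹) or field metabolic rate energy (kJ day⁻¹) — and the coefficients
``(a_i, b_i)`` are specific to biological class and, for mammals and birds,
trophic level.  Reptile and insect coefficients are fitted pooled across
trophic levels because species-level data are sparse for those classes.

This module stores the published default coefficient set (shipped as a
versioned CSV data file), validates its structural invariants, and resolves
which model applies to a query, including the two-branch insect energy model
whose coefficient switches at a body-mass threshold.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Optional

import pandas as pd

from .errors import CatalogueLookupError, ValidationError

CATALOGUE_VERSION = "published-v1"

#: Columns of the flat catalogue serialization schema (CSV and JSON).
CATALOGUE_COLUMNS = [
    "resource",
    "taxon_class",
    "trophic",
    "coefficient_a",
    "exponent_b",
    "se_log10_a",
    "se_b",
    "mass_threshold_kg",
    "coefficient_a_above_threshold",
]


class BiologicalClass(str, enum.Enum):
    """Closed set of terrestrial animal classes covered by the framework."""

    MAMMAL = "mammal"
    BIRD = "bird"
    REPTILE = "reptile"
    INSECT = "insect"

    @classmethod
    def parse(cls, label: "str | BiologicalClass") -> "BiologicalClass":
        if isinstance(label, cls):
            return label
        try:
            return cls(str(label).strip().lower())
        except ValueError:
            valid = ", ".join(m.value for m in cls)
            raise ValidationError(
                f"unknown biological class {label!r} (expected one of: {valid})"
            ) from None


class TrophicLevel(str, enum.Enum):
    """Dietary category; 'all' marks models pooled across trophic levels."""

    HERBIVORE = "herbivore"
    OMNIVORE = "omnivore"
    CARNIVORE = "carnivore"
    ALL = "all"

    @classmethod
    def parse(cls, label: "str | TrophicLevel") -> "TrophicLevel":
        if isinstance(label, cls):
            return label
        try:
            return cls(str(label).strip().lower())
        except ValueError:
            valid = ", ".join(m.value for m in cls)
            raise ValidationError(
                f"unknown trophic level {label!r} (expected one of: {valid})"
            ) from None


class Resource(str, enum.Enum):
    """Resource kind a model predicts."""

    LAND_DENSITY = "land_density"  # individuals km⁻²; reciprocal = km² ind⁻¹
    WATER = "water"  # m³ individual⁻¹ day⁻¹ (active drinking)
    ENERGY = "energy"  # kJ individual⁻¹ day⁻¹ (field metabolic rate)

    @classmethod
    def parse(cls, label: "str | Resource") -> "Resource":
        if isinstance(label, cls):
            return label
        try:
            return cls(str(label).strip().lower())
        except ValueError:
            valid = ", ".join(m.value for m in cls)
            raise ValidationError(
                f"unknown resource {label!r} (expected one of: {valid})"
            ) from None


#: Water-need provenance flags used across the package.
WATER_MODELLED = "modelled"
WATER_ASSUMED_ZERO = "assumed-zero"


@dataclass(frozen=True)
class AllometricModel:
    """One power law x = a * M**b for a (resource, class, trophic) key.

    ``se_log10_a`` and ``se_b`` are the log10-scale standard errors of the
    fitted intercept and slope (kept on the log scale; never back-transformed).
    The insect energy model carries a mass threshold with a second coefficient
    for the at-or-above-threshold branch; all other models have a single
    coefficient.
    """

    resource: Resource
    taxon_class: BiologicalClass
    trophic: TrophicLevel
    coefficient_a: float
    exponent_b: float
    se_log10_a: Optional[float] = None
    se_b: Optional[float] = None
    mass_threshold_kg: Optional[float] = None
    coefficient_a_above_threshold: Optional[float] = None

    def __post_init__(self):
        object.__setattr__(self, "resource", Resource.parse(self.resource))
        object.__setattr__(self, "taxon_class", BiologicalClass.parse(self.taxon_class))
        object.__setattr__(self, "trophic", TrophicLevel.parse(self.trophic))
        if not self.coefficient_a > 0:
            raise ValidationError(f"coefficient_a must be positive, got {self.coefficient_a}")
        if self.resource is Resource.LAND_DENSITY and not self.exponent_b < 0:
            raise ValidationError(
                "land-density models must have a negative mass exponent "
                f"(got b={self.exponent_b})"
            )
        if self.resource in (Resource.WATER, Resource.ENERGY) and not self.exponent_b > 0:
            raise ValidationError(
                f"{self.resource.value} models must have a positive mass exponent "
                f"(got b={self.exponent_b})"
            )
        if self.resource is Resource.WATER:
            if self.trophic is not TrophicLevel.ALL:
                raise ValidationError("water models are pooled across trophic levels ('all')")
        elif self.trophic is TrophicLevel.ALL and self.taxon_class in (
            BiologicalClass.MAMMAL,
            BiologicalClass.BIRD,
        ):
            raise ValidationError(
                "'all' trophic level is valid only for pooled reptile/insect models"
            )
        has_threshold = self.mass_threshold_kg is not None
        has_branch = self.coefficient_a_above_threshold is not None
        if has_threshold != has_branch:
            raise ValidationError(
                "mass_threshold_kg and coefficient_a_above_threshold must come together"
            )
        if has_threshold:
            if not (
                self.resource is Resource.ENERGY
                and self.taxon_class is BiologicalClass.INSECT
            ):
                raise ValidationError(
                    "threshold branches exist only for the insect energy model"
                )
            if not self.mass_threshold_kg > 0 or not self.coefficient_a_above_threshold > 0:
                raise ValidationError("threshold fields must be positive")
        for name in ("se_log10_a", "se_b"):
            val = getattr(self, name)
            if val is not None and (not math.isfinite(val) or val < 0):
                raise ValidationError(f"{name} must be nonnegative, got {val}")

    @property
    def key(self):
        return (self.resource, self.taxon_class, self.trophic)

    def coefficient_for(self, mass_kg: float) -> float:
        """Coefficient applicable at ``mass_kg`` (branch-aware).

        The boundary mass belongs to the at-or-above branch.
        """
        if not mass_kg > 0:
            raise ValidationError(f"body mass must be positive, got {mass_kg}")
        if self.mass_threshold_kg is not None and mass_kg >= self.mass_threshold_kg:
            return self.coefficient_a_above_threshold
        return self.coefficient_a

    def at_mass(self, mass_kg: float) -> "AllometricModel":
        """Concrete single-branch model applicable at ``mass_kg``."""
        if self.mass_threshold_kg is None:
            return self
        return dataclasses.replace(
            self,
            coefficient_a=self.coefficient_for(mass_kg),
            mass_threshold_kg=None,
            coefficient_a_above_threshold=None,
        )


class CoefficientCatalogue:
    """Set of allometric models keyed by (resource, class, trophic)."""

    def __init__(self, models: Iterable[AllometricModel], version: str = "custom"):
        self.version = version
        self._models: dict = {}
        for model in models:
            if model.key in self._models:
                raise ValidationError(
                    f"duplicate catalogue key {tuple(k.value for k in model.key)}"
                )
            self._models[model.key] = model

    def __len__(self):
        return len(self._models)

    def __iter__(self):
        return iter(self._models.values())

    def models(self):
        return tuple(self._models.values())

    def get(self, resource, taxon_class, trophic) -> Optional[AllometricModel]:
        key = (Resource.parse(resource), BiologicalClass.parse(taxon_class),
               TrophicLevel.parse(trophic))
        return self._models.get(key)

    def lookup(self, resource, taxon_class, trophic) -> AllometricModel:
        model = self.get(resource, taxon_class, trophic)
        if model is None:
            raise CatalogueLookupError(
                Resource.parse(resource).value,
                BiologicalClass.parse(taxon_class).value,
                TrophicLevel.parse(trophic).value,
            )
        return model

    def resolve(self, resource, taxon_class, trophic, mass_kg: float
                ) -> Optional[AllometricModel]:
        """Model applicable to a query, or None where the framework assumes
        zero active drinking (water for reptiles and insects).

        Reptile and insect queries fall back to the pooled ('all') model for
        any requested trophic level; the insect energy model is returned with
        its mass-appropriate branch coefficient substituted in.
        """
        resource = Resource.parse(resource)
        taxon_class = BiologicalClass.parse(taxon_class)
        trophic = TrophicLevel.parse(trophic)
        if not mass_kg > 0:
            raise ValidationError(f"body mass must be positive, got {mass_kg}")
        if taxon_class in (BiologicalClass.REPTILE, BiologicalClass.INSECT):
            if resource is Resource.WATER:
                return None  # assumed dietary/metabolic water only
            trophic = TrophicLevel.ALL
        elif resource is Resource.WATER:
            trophic = TrophicLevel.ALL  # water models are class-pooled
        model = self.lookup(resource, taxon_class, trophic)
        return model.at_mass(mass_kg)

    # -- serialization -----------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for m in self._models.values():
            rows.append({
                "resource": m.resource.value,
                "taxon_class": m.taxon_class.value,
                "trophic": m.trophic.value,
                "coefficient_a": m.coefficient_a,
                "exponent_b": m.exponent_b,
                "se_log10_a": m.se_log10_a,
                "se_b": m.se_b,
                "mass_threshold_kg": m.mass_threshold_kg,
                "coefficient_a_above_threshold": m.coefficient_a_above_threshold,
            })
        return pd.DataFrame(rows, columns=CATALOGUE_COLUMNS)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path) -> None:
        records = self.to_frame().to_dict(orient="records")
        for rec in records:
            for k, v in rec.items():
                if isinstance(v, float) and math.isnan(v):
                    rec[k] = None
        payload = {"version": self.version, "models": records}
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, version: str = "custom"
                   ) -> "CoefficientCatalogue":
        missing = [c for c in CATALOGUE_COLUMNS[:5] if c not in frame.columns]
        if missing:
            raise ValidationError(f"catalogue table missing columns: {missing}")

        def _opt(row, col):
            if col not in frame.columns:
                return None
            val = row[col]
            if val is None or (isinstance(val, float) and math.isnan(val)):
                return None
            return float(val)

        models = []
        for _, row in frame.iterrows():
            models.append(AllometricModel(
                resource=row["resource"],
                taxon_class=row["taxon_class"],
                trophic=row["trophic"],
                coefficient_a=float(row["coefficient_a"]),
                exponent_b=float(row["exponent_b"]),
                se_log10_a=_opt(row, "se_log10_a"),
                se_b=_opt(row, "se_b"),
                mass_threshold_kg=_opt(row, "mass_threshold_kg"),
                coefficient_a_above_threshold=_opt(row, "coefficient_a_above_threshold"),
            ))
        return cls(models, version=version)

    @classmethod
    def read_csv(cls, path, version: str = "custom") -> "CoefficientCatalogue":
        return cls.from_frame(pd.read_csv(path), version=version)

    @classmethod
    def read_json(cls, path) -> "CoefficientCatalogue":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        frame = pd.DataFrame(payload["models"], columns=CATALOGUE_COLUMNS)
        return cls.from_frame(frame, version=payload.get("version", "custom"))


def published_default() -> CoefficientCatalogue:
    """The published default coefficient catalogue.

    Eighteen models: land-area/population-density power laws for mammals and
    birds by trophic level plus pooled reptiles and insects (8); field
    metabolic rate models with the same stratification, the insect model
    carrying its BMR→FMR two-branch transformation (8); and active-drinking
    water models for mammals and birds (2).  Values are stored exactly as
    published; re-fitting lives in :mod:`ecodemand.regression`.
    """
    source = resources.files("ecodemand.data").joinpath("coefficients_v1.csv")
    with resources.as_file(source) as path:
        return CoefficientCatalogue.read_csv(path, version=CATALOGUE_VERSION)
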