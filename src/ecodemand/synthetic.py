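"""Synthetic inputs with the statistical structure the methods assume.

Two generators, both driven by an explicit seed and free of global random
state:

* mass–density compilations that are log10-log10 linear with Gaussian noise
  around a known (slope, intercept) — what the regression module is meant
  to recover;
* multi-class site surveys with species masses drawn log-uniformly from
  plausible per-class ranges — what the aggregation pipeline consumes.

Log-uniform mass draws are a fixture convention (real compilations span
orders of magnitude); they are not a claim about any particular fauna.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Tuple

import numpy as np

from .catalogue import BiologicalClass, TrophicLevel
from .errors import ValidationError
from .regression import DensityObservation
from .survey import Observation, SpeciesRecord, Survey


@dataclass(frozen=True)
class SyntheticSpec:
    """Ground truth and noise level for a synthetic mass–density dataset."""

    true_slope: float
    true_log10_a: float
    noise_sd_log10: float
    n_points: int
    log10_mass_range: Tuple[float, float] = (-2.0, 3.0)
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd_log10 < 0:
            raise ValidationError("noise sd must be nonnegative")
        if self.n_points < 3:
            raise ValidationError("need at least 3 points")
        low, high = self.log10_mass_range
        if not low < high:
            raise ValidationError("log10 mass range must have low < high")


def generate_density_dataset(
    spec: SyntheticSpec,
    taxon_class: BiologicalClass = BiologicalClass.MAMMAL,
    trophic: TrophicLevel = TrophicLevel.CARNIVORE,
) -> list:
    """Draw a compilation around log10 ρ = b·log10 M + log10 a.

    Masses are log-uniform over the spec's range; densities carry Gaussian
    noise of the spec's sd on the log10 scale.  Identical specs (including
    seed) produce identical datasets record-for-record.
    """
    taxon_class = BiologicalClass.parse(taxon_class)
    trophic = TrophicLevel.parse(trophic)
    rng = np.random.default_rng(spec.seed)
    low, high = spec.log10_mass_range
    log_masses = rng.uniform(low, high, size=spec.n_points)
    noise = (rng.normal(0.0, spec.noise_sd_log10, size=spec.n_points)
             if spec.noise_sd_log10 > 0 else np.zeros(spec.n_points))
    log_densities = spec.true_slope * log_masses + spec.true_log10_a + noise
    return [
        DensityObservation(
            species_name=f"synthetic_{taxon_class.value}_{i:05d}",
            taxon_class=taxon_class,
            trophic=trophic,
            mass_kg=float(10.0 ** lm),
            density_per_km2=float(10.0 ** ld),
            source_label="synthetic",
        )
        for i, (lm, ld) in enumerate(zip(log_masses, log_densities))
    ]


#: Plausible adult-body-mass ranges per class (kg) for survey generation.
DEFAULT_MASS_RANGES_KG: Dict[BiologicalClass, Tuple[float, float]] = {
    BiologicalClass.MAMMAL: (0.005, 500.0),
    BiologicalClass.BIRD: (0.005, 10.0),
    BiologicalClass.REPTILE: (0.002, 5.0),
    BiologicalClass.INSECT: (1e-8, 1e-3),
}

#: Species composition shaped like the demonstration-site survey:
#: 6 mammal, 31 bird, 1 reptile and 7 insect species (45 in total).
NCL_LIKE_COMPOSITION: Dict[Tuple[BiologicalClass, TrophicLevel], int] = {
    (BiologicalClass.MAMMAL, TrophicLevel.CARNIVORE): 1,
    (BiologicalClass.MAMMAL, TrophicLevel.OMNIVORE): 2,
    (BiologicalClass.MAMMAL, TrophicLevel.HERBIVORE): 3,
    (BiologicalClass.BIRD, TrophicLevel.CARNIVORE): 13,
    (BiologicalClass.BIRD, TrophicLevel.OMNIVORE): 14,
    (BiologicalClass.BIRD, TrophicLevel.HERBIVORE): 4,
    (BiologicalClass.REPTILE, TrophicLevel.CARNIVORE): 1,
    (BiologicalClass.INSECT, TrophicLevel.HERBIVORE): 7,
}


def generate_survey(
    composition: Mapping[Tuple[BiologicalClass, TrophicLevel], int],
    mass_ranges_kg: Mapping[BiologicalClass, Tuple[float, float]] = None,
    seed: int = 0,
    count_range: Tuple[int, int] = (1, 8),
    site_name: str = "synthetic-site",
    terrestrial_area_km2: float = 1.0,
) -> Survey:
    """Draw a site survey with the given species composition.

    ``composition`` maps (class, trophic) to the number of species wanted in
    that group; per-species individual counts are uniform integers over
    ``count_range`` and masses log-uniform over the class's range.
    Deterministic for a fixed seed.
    """
    if not composition:
        raise ValidationError("composition must name at least one species group")
    if mass_ranges_kg is None:
        mass_ranges_kg = DEFAULT_MASS_RANGES_KG
    lo_count, hi_count = count_range
    if not 1 <= lo_count <= hi_count:
        raise ValidationError("count range must satisfy 1 <= low <= high")

    rng = np.random.default_rng(seed)
    observations = []
    ordered = sorted(composition.items(),
                     key=lambda kv: (kv[0][0].value, kv[0][1].value))
    for (taxon_class, trophic), n_species in ordered:
        taxon_class = BiologicalClass.parse(taxon_class)
        trophic = TrophicLevel.parse(trophic)
        if n_species < 1:
            raise ValidationError("each composition entry needs >= 1 species")
        low, high = mass_ranges_kg[taxon_class]
        log_masses = rng.uniform(np.log10(low), np.log10(high), size=n_species)
        counts = rng.integers(lo_count, hi_count + 1, size=n_species)
        for i, (lm, count) in enumerate(zip(log_masses, counts)):
            record = SpeciesRecord(
                name=f"{taxon_class.value}_{trophic.value}_{i:03d}",
                taxon_class=taxon_class,
                trophic=trophic,
                mass_kg=float(10.0 ** lm),
            )
            observations.append(Observation(species=record, count=int(count)))
    return Survey(site_name=site_name,
                  terrestrial_area_km2=terrestrial_area_km2,
                  observations=tuple(observations))
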