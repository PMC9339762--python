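"""Grouped log10–log10 OLS fitting of mass–density compilations.

New land-area coefficients are derived by ordinary least squares of
log10(population density, individuals km⁻²) on log10(adult body mass, kg),

    log10 ρ = b · log10 M + log10 a,

fitted separately per (class, trophic) group for mammals and birds and pooled
across trophic levels for reptiles and insects.  Slope and intercept standard
errors come from the residual variance in the usual way and are kept on the
log10 scale throughout; plain OLS, no weighting, no phylogenetic correction,
and repeated species records enter as independent points unless averaging is
requested explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Dict, Iterable, List, Sequence, Tuple, Union

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .catalogue import AllometricModel, BiologicalClass, Resource, TrophicLevel
from .errors import FitError, ValidationError

GroupKey = Tuple[BiologicalClass, TrophicLevel]


@dataclass(frozen=True)
class DensityObservation:
    """One species-level (body mass, population density) record."""

    species_name: str
    taxon_class: BiologicalClass
    trophic: TrophicLevel
    mass_kg: float
    density_per_km2: float
    source_label: str = ""

    def __post_init__(self):
        object.__setattr__(self, "taxon_class", BiologicalClass.parse(self.taxon_class))
        object.__setattr__(self, "trophic", TrophicLevel.parse(self.trophic))
        if not self.mass_kg > 0 or not self.density_per_km2 > 0:
            raise ValidationError(
                f"{self.species_name}: mass and density must be strictly positive "
                "(log-transformable)"
            )


@dataclass(frozen=True)
class FitResult:
    """Per-group OLS fit of log10 density on log10 mass.

    ``mean_log10_mass`` and ``sxx_log10_mass`` (centred sum of squares of the
    regressor) are retained so mean-response confidence bands can be rebuilt
    without the raw data.
    """

    taxon_class: BiologicalClass
    trophic: TrophicLevel
    slope_b: float
    intercept_log10_a: float
    se_b: float
    se_intercept: float
    r_squared: float
    n_points: int
    residual_sd: float
    mean_log10_mass: float
    sxx_log10_mass: float

    @property
    def group(self) -> GroupKey:
        return (self.taxon_class, self.trophic)


def default_grouping(obs: DensityObservation) -> GroupKey:
    """Mammals/birds stratified by trophic level; reptiles/insects pooled."""
    if obs.taxon_class in (BiologicalClass.REPTILE, BiologicalClass.INSECT):
        return (obs.taxon_class, TrophicLevel.ALL)
    return (obs.taxon_class, obs.trophic)


def class_trophic_grouping(obs: DensityObservation) -> GroupKey:
    """Every (class, trophic) pair fitted separately; no pooling."""
    return (obs.taxon_class, obs.trophic)


_GROUPINGS: Dict[str, Callable[[DensityObservation], GroupKey]] = {
    "default": default_grouping,
    "class-trophic": class_trophic_grouping,
}


def _fit_one(masses: np.ndarray, densities: np.ndarray,
             group: GroupKey) -> FitResult:
    if len(masses) < 3:
        raise FitError(
            f"group {group[0].value}/{group[1].value}: insufficient observations "
            f"({len(masses)} < 3)"
        )
    x = np.log10(masses)
    y = np.log10(densities)
    if np.unique(x).size < 2:
        raise FitError(
            f"group {group[0].value}/{group[1].value}: all masses identical; "
            "slope is unidentifiable"
        )
    res = sm.OLS(y, sm.add_constant(x)).fit()
    intercept, slope = res.params
    se_intercept, se_slope = res.bse
    return FitResult(
        taxon_class=group[0],
        trophic=group[1],
        slope_b=float(slope),
        intercept_log10_a=float(intercept),
        se_b=float(se_slope),
        se_intercept=float(se_intercept),
        r_squared=float(res.rsquared),
        n_points=int(res.nobs),
        residual_sd=float(np.sqrt(res.mse_resid)),
        mean_log10_mass=float(x.mean()),
        sxx_log10_mass=float(((x - x.mean()) ** 2).sum()),
    )


def fit_loglog(
    observations: Iterable[DensityObservation],
    grouping: Union[str, Callable[[DensityObservation], GroupKey]] = "default",
    species_average: bool = False,
) -> Tuple[Dict[GroupKey, FitResult], Dict[GroupKey, str]]:
    """Fit every group present in the data; failures do not abort the rest.

    Returns ``(fits, failures)`` where ``failures`` maps a group key to the
    reason it could not be fitted.  With ``species_average=True`` repeated
    records of one species are collapsed to their geometric-mean mass and
    density before fitting (off by default: compilations legitimately carry
    several density estimates per species).
    """
    if callable(grouping):
        key_of = grouping
    else:
        try:
            key_of = _GROUPINGS[grouping]
        except KeyError:
            raise ValidationError(
                f"unknown grouping {grouping!r} (expected one of: "
                f"{sorted(_GROUPINGS)} or a callable)"
            ) from None

    grouped: Dict[GroupKey, List[DensityObservation]] = {}
    for obs in observations:
        grouped.setdefault(key_of(obs), []).append(obs)
    if not grouped:
        raise ValidationError("no observations to fit")

    fits: Dict[GroupKey, FitResult] = {}
    failures: Dict[GroupKey, str] = {}
    for group in sorted(grouped, key=lambda g: (g[0].value, g[1].value)):
        members = grouped[group]
        if species_average:
            by_species: Dict[str, List[DensityObservation]] = {}
            for o in members:
                by_species.setdefault(o.species_name, []).append(o)
            masses = np.array([
                10 ** np.mean([math.log10(o.mass_kg) for o in recs])
                for recs in by_species.values()
            ])
            densities = np.array([
                10 ** np.mean([math.log10(o.density_per_km2) for o in recs])
                for recs in by_species.values()
            ])
        else:
            masses = np.array([o.mass_kg for o in members])
            densities = np.array([o.density_per_km2 for o in members])
        try:
            fits[group] = _fit_one(masses, densities, group)
        except FitError as exc:
            failures[group] = str(exc)
    return fits, failures


def to_standard_form(fit: FitResult) -> AllometricModel:
    """Convert a log-space fit into the standard power-law form ρ = a·M^b.

    ``a = 10**intercept``; standard errors are carried through unchanged on
    the log10 scale (they are never back-transformed).
    """
    return AllometricModel(
        resource=Resource.LAND_DENSITY,
        taxon_class=fit.taxon_class,
        trophic=fit.trophic,
        coefficient_a=10.0 ** fit.intercept_log10_a,
        exponent_b=fit.slope_b,
        se_log10_a=fit.se_intercept,
        se_b=fit.se_b,
    )


def confidence_band(fit: FitResult, mass_grid: Sequence[float],
                    level: float = 0.95) -> np.ndarray:
    """Mean-response confidence band for log10 density over a mass grid.

    Returns an array of shape (len(grid), 2) with (lower, upper) bounds on
    the mean log10 density at each mass, using the t quantile at n−2 degrees
    of freedom.  The band is narrowest at the centroid of the fitted
    log-masses and widens hyperbolically away from it.
    """
    if not 0 < level < 1:
        raise ValidationError(f"confidence level must be in (0, 1), got {level}")
    mass_grid = np.asarray(mass_grid, dtype=float)
    if mass_grid.size == 0:
        return np.empty((0, 2))
    if np.any(mass_grid <= 0):
        raise ValidationError("mass grid must be strictly positive")
    x = np.log10(mass_grid)
    mean_line = fit.intercept_log10_a + fit.slope_b * x
    tq = stats.t.ppf(0.5 + level / 2.0, fit.n_points - 2)
    half = tq * fit.residual_sd * np.sqrt(
        1.0 / fit.n_points + (x - fit.mean_log10_mass) ** 2 / fit.sxx_log10_mass
    )
    return np.column_stack([mean_line - half, mean_line + half])
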