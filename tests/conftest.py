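import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ecodemand import (
    BiologicalClass,
    SpeciesRecord,
    SyntheticSpec,
    TrophicLevel,
    fit_loglog,
    generate_density_dataset,
    published_default,
)

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def catalogue():
    return published_default()


@pytest.fixture()
def sika():
    """Sika deer as surveyed: mammalian herbivore, 42 kg average adult mass."""
    return SpeciesRecord(name="Cervus nippon",
                         taxon_class=BiologicalClass.MAMMAL,
                         trophic=TrophicLevel.HERBIVORE,
                         mass_kg=42.0)


def slope_recovery_replicates(n_replicates=200, n_points=500,
                              noise_sd=0.5, true_slope=-0.9,
                              true_log10_a=1.2, base_seed=1000):
    """Monte-Carlo slope estimates and standard errors over fresh synthetic
    mass-density datasets; the shared oracle for recovery and CI coverage."""
    slopes = np.empty(n_replicates)
    ses = np.empty(n_replicates)
    for i in range(n_replicates):
        spec = SyntheticSpec(true_slope=true_slope, true_log10_a=true_log10_a,
                             noise_sd_log10=noise_sd, n_points=n_points,
                             log10_mass_range=(-2.0, 3.0), seed=base_seed + i)
        fits, failures = fit_loglog(generate_density_dataset(spec))
        assert not failures
        (fit,) = fits.values()
        slopes[i] = fit.slope_b
        ses[i] = fit.se_b
    return slopes, ses
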