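import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from coexist_eca.forcing import default_forcing
from coexist_eca.production import solve_equilibria
from coexist_eca.traits import sample_traits, single_trait_variants

AMBIENT = 360.0
ELEVATED = 550.0


@pytest.fixture(scope="session")
def forcing():
    return default_forcing()


@pytest.fixture(scope="session")
def variants():
    return single_trait_variants()


@pytest.fixture(scope="session")
def variant_equilibria(forcing, variants):
    return {
        ca: solve_equilibria(variants, forcing, ca) for ca in (AMBIENT, ELEVATED)
    }


@pytest.fixture(scope="session")
def random_species_200(forcing):
    species = sample_traits(200, 42)
    equilibria = {
        ca: solve_equilibria(species, forcing, ca) for ca in (AMBIENT, ELEVATED)
    }
    return species, equilibria


@pytest.fixture(scope="session")
def key_capture_pairs(forcing, variants):
    """High-vs-low Y and af mixtures at ambient CO2, run to equilibration."""
    from coexist_eca.resource_capture import simulate_mixtures

    by_id = {v.species_id: v for v in variants}
    pairs = [(by_id["+Y"], by_id["-Y"]), (by_id["+af"], by_id["-af"])]
    results = simulate_mixtures(pairs, forcing, AMBIENT, years=120)
    return dict(zip(("Y", "af"), results))


@pytest.fixture(scope="session")
def use_study_500(forcing):
    from coexist_eca.experiments import run_random_use_study

    return run_random_use_study(n=500, seed=2024, forcing=forcing)


@pytest.fixture(scope="session")
def capture_study_500(forcing):
    from coexist_eca.experiments import run_random_capture_study

    return run_random_capture_study(n_pairs=500, seed=2025, forcing=forcing)
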