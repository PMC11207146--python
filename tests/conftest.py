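import warnings

import pytest

from remiforest.config import ScenarioConfig
from remiforest.synthetic import generate_scenario


@pytest.fixture(scope="session")
def default_bundle():
    """Full default scenario: two sites, 458 households, 767 migrants."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_scenario()


@pytest.fixture(scope="session")
def tables_bundle():
    """Default-size scenario without rasters (fast model tests)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_scenario(include_rasters=False)


def small_config(**overrides):
    """A reduced two-site scenario for fast end-to-end runs."""
    base = dict(
        seed=11,
        n_households_per_site=(50, 70),
        n_groups_per_site=(6, 8),
        n_migrants_total=200,
        raster_extent=4000.0,
    )
    base.update(overrides)
    return ScenarioConfig(**base)


def null_config(seed):
    """Small scenario with all forest/EVI effects planted at zero."""
    return small_config(
        seed=seed,
        remit_forest_slope=0.0,
        remit_evi_slope=0.0,
        migrant_drift=0.0,
        evi_migrant_drift=0.0,
    )


@pytest.fixture(scope="session")
def small_bundle():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_scenario(small_config())
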