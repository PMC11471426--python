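"""Shared fixtures: small synthetic grids, species, and a fitted ensemble.

Session scope keeps the expensive objects (climate stacks, one fitted
ensemble) shared across test modules.
"""

import numpy as np
import pytest

from climniche import (
    ClimateNicheModel,
    GridConfig,
    generate_climate_grids,
    generate_jurisdictions,
    make_virtual_species,
    sample_occurrences,
)


@pytest.fixture(scope="session")
def small_grids():
    """60x60 six-scenario climate stack."""
    return generate_climate_grids(GridConfig(n_rows=60, n_cols=60), seed=42)


@pytest.fixture(scope="session")
def recent(small_grids):
    return small_grids["recent"]


@pytest.fixture(scope="session")
def jurisdictions(recent):
    return generate_jurisdictions(recent, n_jurisdictions=6, seed=7)


@pytest.fixture(scope="session")
def species(recent):
    # sharp niche so the shared fitted fixture clears the TSS cutoff
    return make_virtual_species(
        recent, prevalence_target=0.2, breadth_fraction=0.15, seed=1
    )


@pytest.fixture(scope="session")
def occurrences(species, recent):
    return sample_occurrences(species, recent, n=300, seed=2)


@pytest.fixture(scope="session")
def fitted(occurrences, recent):
    """One fitted ensemble shared by model/projection/change tests."""
    model = ClimateNicheModel.from_dataframe(
        occurrences, recent, n_pseudo_absences=800
    )
    return model.fit(seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
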