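import numpy as np
import pandas as pd
import pytest

from gestaltmem import (
    GenerativeParams,
    generate_image_population,
    simulate_categorization_study,
    simulate_rating_study,
    simulate_search_study,
)


@pytest.fixture(scope="session")
def default_params():
    return GenerativeParams(seed=7)


@pytest.fixture(scope="session")
def population(default_params):
    refs, traits, memorability = generate_image_population(default_params)
    return refs, traits, memorability


@pytest.fixture(scope="session")
def traits(population):
    return population[1]


@pytest.fixture(scope="session")
def memorability(population):
    return population[2]


@pytest.fixture(scope="session")
def study1_trials(traits, default_params):
    return simulate_categorization_study(traits, default_params)


@pytest.fixture(scope="session")
def study2_trials(traits, default_params):
    return simulate_search_study(traits, default_params)


@pytest.fixture(scope="session")
def study3_trials(traits, default_params):
    return simulate_rating_study(traits, default_params)


@pytest.fixture(scope="session")
def small_params():
    """A small cohort for fast structural tests."""
    return GenerativeParams(
        seed=11,
        n_categories=4,
        n_images_per_category=10,
        n_participants_study1=20,
        n_participants_study2=15,
        n_participants_study3=20,
        images_per_participant_study2=6,
        mean_blocks_completed=3.0,
    )


@pytest.fixture(scope="session")
def small_population(small_params):
    return generate_image_population(small_params)
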