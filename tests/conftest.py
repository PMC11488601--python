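import numpy as np
import pytest

from gutbrainmap import MicrobiomeBrainModel, SyntheticScenario, generate_cohort


@pytest.fixture(scope="session")
def small_null_cohort():
    """Global-null cohort small enough for fast permutation runs."""
    scenario = SyntheticScenario.global_null(
        n_subjects=40, n_families=20, image_shape=(10, 10, 10), seed=7
    )
    return generate_cohort(scenario)


@pytest.fixture(scope="session")
def planted_cohort():
    """Cohort with one strong planted cluster (families 2 and 3)."""
    scenario = SyntheticScenario.planted(
        families=(2, 3),
        betas=(1.0, 1.0),
        radius=2.0,
        n_subjects=60,
        n_families=20,
        image_shape=(12, 12, 12),
        noise_sd=0.5,
        seed=21,
    )
    return generate_cohort(scenario)


@pytest.fixture(scope="session")
def planted_results(planted_cohort):
    model = MicrobiomeBrainModel.from_cohort(planted_cohort)
    return model.fit(n_perms=50, seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
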