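import pandas as pd
import pytest

from biaindex import calibrate_defaults, derive_all, generate_cohort


@pytest.fixture(scope="session")
def default_config():
    return calibrate_defaults()


@pytest.fixture(scope="session")
def cohort(default_config):
    """One default-calibrated cohort (n=283, fixed seed)."""
    return generate_cohort(default_config.model_copy(update={"seed": 42}))


@pytest.fixture(scope="session")
def derived(cohort):
    """The same cohort with derived bioparameters attached."""
    return derive_all(cohort.table)


@pytest.fixture(scope="session")
def derived_by_seed(default_config):
    """Factory returning (and caching) derived tables for arbitrary seeds."""
    cache: dict[int, pd.DataFrame] = {}

    def get(seed: int) -> pd.DataFrame:
        if seed not in cache:
            sc = generate_cohort(default_config.model_copy(update={"seed": seed}))
            cache[seed] = derive_all(sc.table).table
        return cache[seed]

    return get
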