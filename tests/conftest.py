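import numpy as np
import pytest

from rmcq.preprocess import screen_and_impute
from rmcq.schema import default_factor_specs, default_grouping, default_schema
from rmcq.simulate import SimulationConfig, simulate_latent_ordinal


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture(scope="session")
def specs():
    return default_factor_specs()


@pytest.fixture(scope="session")
def grouping():
    return default_grouping()


def model_cohort(schema, specs, n_total=1216, seed=0, **overrides):
    """Model-faithful 29-item cohort at a given total size (no missingness)."""
    per = n_total // 4
    cfg = SimulationConfig(
        seed=seed,
        items="loaded",
        row_missing_rate=0.0,
        non_scored_rate=0.0,
        n_per_country={
            "Benin": per,
            "Malawi": per,
            "Tanzania": per,
            "Uganda": n_total - 3 * per,
        },
        **overrides,
    )
    return simulate_latent_ordinal(cfg, schema, specs)


@pytest.fixture(scope="session")
def clean_1216(schema, specs):
    """One cleaned model-faithful cohort at the confirmatory subsample size."""
    cohort = model_cohort(schema, specs, n_total=1216, seed=101)
    clean, _ = screen_and_impute(cohort.raw, schema)
    return clean
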