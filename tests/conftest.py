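import numpy as np
import pytest

from esdrought import (
    GridField,
    SyntheticConfig,
    compute_es_stack,
    generate_landscape,
)


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    return SyntheticConfig(n_rows=30, n_cols=30, n_years=10, seed=7, drought_years=(5, 9))


@pytest.fixture(scope="session")
def small_landscape(small_config):
    return generate_landscape(small_config)


@pytest.fixture(scope="session")
def small_es(small_landscape):
    return compute_es_stack(small_landscape)


def make_field(values, mask=None, cell_km=1.0) -> GridField:
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.ones(values.shape, dtype=bool)
    return GridField(values, mask, cell_km)
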