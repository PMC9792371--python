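import numpy as np
import pytest

from histosearch.synthetic import (
    CohortSpec,
    build_database,
    generate_cohort,
    generate_query_set,
)


@pytest.fixture(scope="session")
def separable_cohort():
    """200-slide, 4-class cohort with well-separated classes (eps=0.02)."""
    spec = CohortSpec(bit_flip_rate=0.02, seed=1)
    records = generate_cohort(spec)
    return spec, records


@pytest.fixture(scope="session")
def separable_db(separable_cohort):
    _, records = separable_cohort
    return build_database(records)


@pytest.fixture(scope="session")
def separable_queries(separable_cohort):
    _, records = separable_cohort
    _, queries = generate_query_set(records, 0.0)
    return queries


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
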