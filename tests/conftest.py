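import numpy as np
import pytest

from facetremor import SyntheticConfig, build_feature_table, generate_cohort
from facetremor.schema import DEFAULT_SCHEMA


@pytest.fixture(scope="session")
def schema():
    return DEFAULT_SCHEMA


@pytest.fixture(scope="session")
def small_cohort():
    """Cheap cohort for structural tests: 3+3 subjects, 2 records each."""
    cfg = SyntheticConfig(n_pd=3, n_ctrl=3, records_per_subject=2, seed=42)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic cohort: 30+30 subjects x 3 records, strong effects."""
    return generate_cohort(SyntheticConfig(seed=3))


@pytest.fixture(scope="session")
def default_table(default_cohort):
    return build_feature_table(default_cohort)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_frame(rng, schema=DEFAULT_SCHEMA, spread=100.0):
    """A random non-degenerate frame of absolute coordinates."""
    while True:
        coords = rng.uniform(0.0, spread, size=(schema.n_points, 2))
        li, ri, ni = schema.anchor_indices
        a = coords[ri] - (coords[li] + coords[ri]) / 2
        b = (coords[li] + coords[ri]) / 2 - coords[ni]
        det = a[0] * b[1] - a[1] * b[0]
        if abs(det) > 1e-3 * (np.linalg.norm(a) * np.linalg.norm(b) + 1e-12):
            return coords
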