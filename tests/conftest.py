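import numpy as np
import pytest

import faerspv as f


@pytest.fixture(scope="session")
def planted_config():
    """A small cohort with one strong planted association (lam=10)."""
    return f.SyntheticConfig(
        n_reports=5000,
        planted=(f.PlantedAssociation("drug00", "Vitiligo", 10.0),),
        seed=42,
    )


@pytest.fixture(scope="session")
def planted_bundle(planted_config):
    return f.generate(planted_config)


@pytest.fixture(scope="session")
def planted_synmap(planted_config):
    return f.SynonymMap.from_frame(f.synonym_table(planted_config))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


def random_tables(rng, n, n_min=500, n_max=50000, a_min=0):
    """Random 2x2 tables with realistic spontaneous-report shapes."""
    out = []
    while len(out) < n:
        total = int(rng.integers(n_min, n_max))
        a = int(rng.integers(a_min, 30))
        b = int(rng.integers(1, 400))
        c = int(rng.integers(1, 400))
        d = total - a - b - c
        if d > 0:
            out.append((a, b, c, d))
    return out
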