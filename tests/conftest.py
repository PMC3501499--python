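import numpy as np
import pytest

import rodiso


@pytest.fixture(scope="session")
def table3():
    """Bundled 15-record paired CO3/PO4 dataset (5 individuals x 3 tissues)."""
    return rodiso.load_fixture("table3_arvicola.csv")


@pytest.fixture(scope="session")
def table3_records(table3):
    return table3.records


@pytest.fixture()
def rng():
    return np.random.default_rng(20120919)


@pytest.fixture(scope="session")
def seeded_normal_groups():
    """Three fixed-seed normal samples for cross-implementation oracles."""
    gen = np.random.default_rng(12345)
    return [
        list(gen.normal(27.0, 1.2, 10)),
        list(gen.normal(27.5, 1.0, 8)),
        list(gen.normal(26.5, 1.5, 12)),
    ]
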