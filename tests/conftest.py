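import numpy as np
import pytest

from seqbf.datasets import five_lab_summaries, overall_summary
from seqbf.tables import get_table


@pytest.fixture(scope="session")
def default_table():
    """The interpolated BF surface for the preregistered prior (built once)."""
    return get_table(0.1, "less")


@pytest.fixture(scope="session")
def five_labs():
    return five_lab_summaries()


@pytest.fixture(scope="session")
def overall():
    return overall_summary()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
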