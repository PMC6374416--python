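import numpy as np
import pandas as pd
import pytest

import panrec


@pytest.fixture(scope="session")
def small_cohort():
    """A compact planted cohort shared by read-only tests."""
    spec = panrec.default_spec(seed=11, n_cancer_types=2, samples_per_type=60)
    return panrec.generate_cohort(spec)


@pytest.fixture(scope="session")
def default_panel():
    return panrec.simulate.build_default_panel()


@pytest.fixture(scope="session")
def default_genome():
    return panrec.simulate.build_default_genome()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
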