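import numpy as np
import pytest

from breathprint import bp_core, synthetic


@pytest.fixture(scope="session")
def default_cohort():
    """Reference-design synthetic cohort (56/39/65, Child-Pugh 21/27/17)."""
    return synthetic.generate_cohort(synthetic.default_config(), seed=1)


@pytest.fixture(scope="session")
def default_aubp(default_cohort):
    X = default_cohort[bp_core.response_columns()].to_numpy(dtype=float)
    return np.array([bp_core.compute_aubp(row).area for row in X])


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)
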