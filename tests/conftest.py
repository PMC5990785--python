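import numpy as np
import pytest

from hoovar import call_table, simulate


@pytest.fixture(scope="session")
def paper_table():
    """One paper-like synthetic call table (271 calls, 29 subjects)."""
    fm, truth = simulate.generate_feature_table(simulate.paper_like_truth(seed=7))
    return fm, truth


@pytest.fixture(scope="session")
def transformed_table(paper_table):
    fm, truth = paper_table
    return call_table.apply_transforms(fm, call_table.TransformSpec.table_defaults()), truth


@pytest.fixture(scope="session")
def screened(transformed_table):
    tfm, _ = transformed_table
    return call_table.screen_correlations(tfm)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
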