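import numpy as np
import pytest

import lignoclass as lc


@pytest.fixture(scope="session")
def default_config():
    return lc.SimulationConfig()


@pytest.fixture(scope="session")
def synthetic_panel(default_config):
    """(profiles, labels, planted_family_ids) under the default study conditions."""
    return lc.generate_dataset(default_config)


@pytest.fixture(scope="session")
def binary_matrix(synthetic_panel):
    profiles, labels, _ = synthetic_panel
    return lc.build_matrix(profiles, lc.BINARY, labels)


@pytest.fixture(scope="session")
def committee(binary_matrix):
    """The 5-member voting committee trained on the default synthetic panel."""
    return lc.build_ensemble(binary_matrix)


@pytest.fixture()
def separable_matrix():
    """Perfectly separable panel: the marker family encodes the phenotype.

    Sixteen samples so the marker carries enough aggregate signal to enter
    the L1 support even at C = 0.1 (the model has no intercept).
    """
    rng = np.random.default_rng(0)
    n_pos, n_neg = 8, 8
    marker = np.array([1.0] * n_pos + [0.0] * n_neg)
    background = (rng.random((n_pos + n_neg, 2)) < 0.5).astype(float)
    X = np.column_stack([marker, background])
    return lc.FeatureMatrix(
        sample_ids=[f"s{i:02d}" for i in range(n_pos + n_neg)],
        family_ids=["marker", "bgA", "bgB"],
        X=X,
        labels=np.array([1] * n_pos + [-1] * n_neg),
        encoding=lc.BINARY,
    )
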