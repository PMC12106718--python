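import numpy as np
import pytest

from physiocca import generate_cohort


@pytest.fixture(scope="session")
def tiny_cohort():
    """12 participants, 30 ROIs, 400 frames — enough for structural checks."""
    return generate_cohort(12, n_roi=30, n_frames=400, seed=7)


@pytest.fixture(scope="session")
def mid_cohort():
    """60 participants for fold/permutation structure tests."""
    return generate_cohort(60, n_roi=40, n_frames=300, true_lag_frames=8, seed=17)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
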