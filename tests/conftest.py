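import numpy as np
import pytest

from neoqeeg.synthetic import BackgroundParams, CohortSpec, generate_background


@pytest.fixture(scope="session")
def stationary_background():
    """5 min of fully recovered background (no suppression), 8 channels."""
    params = BackgroundParams(isoelectric_duration_h=0.0, recovery_tau_h=0.0)
    return generate_background(300.0, params, seed=11, start_offset_s=36000.0)


@pytest.fixture(scope="session")
def tiny_cohort_spec():
    """Three animals, strongly compressed: fast but structurally complete."""
    return CohortSpec(
        n_per_group={"A-NT": 1, "A-H2": 1, "A-TH": 1},
        seed=5,
        timeline_compression=960.0,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
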